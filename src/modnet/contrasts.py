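"""Pairwise group contrasts via reference rotation with the AND-rule.

A single moderated network fit only contrasts each group against the chosen
reference. Refitting once per group as reference ("rotation") yields two
estimates of every pairwise difference — (a vs b) from the fit with reference
a and from the fit with reference b. A difference is *detected* only when
both estimates are nonzero (the AND-rule); its combined value is their mean.

All differences are oriented second-minus-first: a positive contrast for pair
(a, b) means the quantity is larger in group b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .estimator import (
    NONZERO_TOL,
    EstimatorSettings,
    MNMFit,
    combine_directed,
    fit_mnm,
)


def percent_difference(x, y):
    """Symmetric percent difference 200 (x - y) / (|x| + |y|), in [-200, 200].

    Returns 0 where both arguments are 0. Values at the +-200 extremes mean
    one estimate is (near) zero or the two disagree in sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 200.0 * (x - y) / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.clip(out, -200.0, 200.0)  # guard float overshoot at the extremes
    if out.ndim == 0:
        return float(out)
    return out


def comparison_universe(G: int, p: int) -> dict:
    """Sizes of the comparison space for G groups over p nodes.

    Ordered co-occurrence slots (p(p-1): each of p nodes with its p-1
    possible connections) are the default reporting denominator; the
    unordered count p(p-1)/2 is also provided.
    """
    if G < 2 or p < 2:
        raise ValueError("need G >= 2 and p >= 2")
    return {
        "group_pairs": G * (G - 1) // 2,
        "symptoms_per_comparison": p,
        "ordered_cooccurrence_slots": p * (p - 1),
        "unordered_cooccurrence_slots": p * (p - 1) // 2,
    }


@dataclass
class RotationEnsemble:
    """One moderated network fit per reference group, on the same cohort."""

    fits: dict[str, MNMFit]
    settings: EstimatorSettings
    fingerprint: dict

    def __post_init__(self) -> None:
        for g, fit in self.fits.items():
            if fit.reference_group != g:
                raise ValueError(f"fit stored under {g!r} has reference {fit.reference_group!r}")
            if fit.fingerprint != self.fingerprint:
                raise ValueError("ensemble fits come from different cohorts")
            if fit.settings != self.settings:
                raise ValueError("ensemble fits used different settings")
        if sorted(self.fits) != sorted(next(iter(self.fits.values())).groups):
            raise ValueError("ensemble must contain exactly one fit per group")

    @property
    def groups(self) -> list[str]:
        return sorted(self.fits)

    @property
    def n_nodes(self) -> int:
        return next(iter(self.fits.values())).n_nodes

    def mean_edge_counts(self) -> np.ndarray:
        """Per-group edge count averaged over the G rotated fits."""
        counts = np.stack([self.fits[g].edge_counts() for g in self.groups])
        return counts.mean(axis=0)


def rotate_references(
    cohort: CohortTable, settings: EstimatorSettings | None = None
) -> RotationEnsemble:
    """Fit one moderated network per reference group (deterministic)."""
    settings = settings or EstimatorSettings()
    fits = {g: fit_mnm(cohort, g, settings) for g in cohort.groups}
    return RotationEnsemble(
        fits=fits, settings=settings, fingerprint=cohort.fingerprint()
    )


@dataclass
class PairwiseContrast:
    """All intercept and edge differences for one group pair (a, b).

    ``intercept_est_a``/``intercept_est_b`` are the two rotation estimates of
    each per-symptom difference (both oriented b - a); ``*_detected`` is the
    rotation-level AND-rule flag, ``*_combined`` the mean of the two estimates
    where detected (else 0). ``*_pvalue`` holds permutation p-values once
    attached (NaN before). Edge arrays are (p, p) symmetric with zero
    diagonal; percent differences compare the two groups' parameter levels.
    """

    pair: tuple[str, str]
    item_names: list[str]
    intercept_est_a: np.ndarray
    intercept_est_b: np.ndarray
    intercept_detected: np.ndarray
    intercept_combined: np.ndarray
    intercept_percent: np.ndarray
    edge_est_a: np.ndarray
    edge_est_b: np.ndarray
    edge_detected: np.ndarray
    edge_combined: np.ndarray
    edge_percent: np.ndarray
    intercept_pvalue: np.ndarray = field(default=None)
    edge_pvalue: np.ndarray = field(default=None)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        p = len(self.item_names)
        if self.intercept_pvalue is None:
            self.intercept_pvalue = np.full(p, np.nan)
        if self.edge_pvalue is None:
            self.edge_pvalue = np.full((p, p), np.nan)

    # -- significance ------------------------------------------------------

    def intercept_significant(self, alpha: float | None = None) -> np.ndarray:
        """Detected by the AND-rule *and* permutation p < alpha.

        Before p-values are attached, falls back to the AND-rule flag alone.
        """
        alpha = self.alpha if alpha is None else alpha
        if np.isnan(self.intercept_pvalue).all():
            return self.intercept_detected.copy()
        return self.intercept_detected & (self.intercept_pvalue < alpha)

    def edge_significant(self, alpha: float | None = None) -> np.ndarray:
        alpha = self.alpha if alpha is None else alpha
        if np.isnan(self.edge_pvalue).all():
            return self.edge_detected.copy()
        return self.edge_detected & (self.edge_pvalue < alpha)

    def counts(self, alpha: float | None = None) -> dict:
        p = len(self.item_names)
        iu = np.triu_indices(p, k=1)
        return {
            "intercept": int(self.intercept_significant(alpha).sum()),
            "edge_unordered": int(self.edge_significant(alpha)[iu].sum()),
            "edge_ordered": 2 * int(self.edge_significant(alpha)[iu].sum()),
        }

    def statistics(self) -> np.ndarray:
        """Flat vector of the pair's contrast statistics (p intercepts, then
        the p(p-1)/2 upper-triangular edges) — the quantities permuted under
        the null."""
        p = len(self.item_names)
        iu = np.triu_indices(p, k=1)
        return np.concatenate([self.intercept_combined, self.edge_combined[iu]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per parameter."""
        a, b = self.pair
        rows = []
        for j, name in enumerate(self.item_names):
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "kind": "intercept",
                    "param": name,
                    "estimate_a": self.intercept_est_a[j],
                    "estimate_b": self.intercept_est_b[j],
                    "combined": self.intercept_combined[j],
                    "percent_diff": self.intercept_percent[j],
                    "detected": bool(self.intercept_detected[j]),
                    "p": self.intercept_pvalue[j],
                }
            )
        p = len(self.item_names)
        for s in range(p):
            for t in range(s + 1, p):
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "kind": "edge",
                        "param": f"{self.item_names[s]}--{self.item_names[t]}",
                        "estimate_a": self.edge_est_a[s, t],
                        "estimate_b": self.edge_est_b[s, t],
                        "combined": self.edge_combined[s, t],
                        "percent_diff": self.edge_percent[s, t],
                        "detected": bool(self.edge_detected[s, t]),
                        "p": self.edge_pvalue[s, t],
                    }
                )
        return pd.DataFrame(rows)


def pairwise_contrast(ensemble: RotationEnsemble, a: str, b: str) -> PairwiseContrast:
    """Extract the (a, b) contrast from the two relevant rotation fits."""
    if a == b:
        raise ValueError("contrast requires two distinct groups")
    for g in (a, b):
        if g not in ensemble.fits:
            raise ValueError(f"group {g!r} has no fit in the ensemble")
    fit_a, fit_b = ensemble.fits[a], ensemble.fits[b]
    groups = fit_a.groups
    ia, ib = groups.index(a), groups.index(b)
    p = ensemble.n_nodes

    # intercepts: b's dummy in fit(ref=a); a's dummy sign-flipped in fit(ref=b)
    est_a = fit_a.dummy_coefs[ib].copy()
    est_b = -fit_b.dummy_coefs[ia]
    detected_i = (np.abs(est_a) > NONZERO_TOL) & (np.abs(est_b) > NONZERO_TOL)
    combined_i = np.where(detected_i, 0.5 * (est_a + est_b), 0.0)
    level_a = 0.5 * (fit_a.group_intercepts[ia] + fit_b.group_intercepts[ia])
    level_b = 0.5 * (fit_a.group_intercepts[ib] + fit_b.group_intercepts[ib])
    percent_i = percent_difference(level_b, level_a)

    # edges: interaction coefficients, nodewise-combined within each rotation
    rule = ensemble.settings.nodewise_rule
    e_a = np.zeros((p, p))
    e_b = np.zeros((p, p))
    det_a = np.zeros((p, p), dtype=bool)
    det_b = np.zeros((p, p), dtype=bool)
    inter_ab = fit_a.inter_coefs[ib]  # [s, t]: t x dummy_b in node s's regression
    inter_ba = fit_b.inter_coefs[ia]
    for s in range(p):
        for t in range(s + 1, p):
            d1, v1 = combine_directed(inter_ab[s, t], inter_ab[t, s], rule)
            d2, v2 = combine_directed(-inter_ba[s, t], -inter_ba[t, s], rule)
            det_a[s, t] = det_a[t, s] = d1
            det_b[s, t] = det_b[t, s] = d2
            e_a[s, t] = e_a[t, s] = v1
            e_b[s, t] = e_b[t, s] = v2
    detected_e = det_a & det_b
    combined_e = np.where(detected_e, 0.5 * (e_a + e_b), 0.0)
    edge_a = 0.5 * (fit_a.group_edges[ia] + fit_b.group_edges[ia])
    edge_b = 0.5 * (fit_a.group_edges[ib] + fit_b.group_edges[ib])
    percent_e = percent_difference(edge_b, edge_a)
    np.fill_diagonal(percent_e, 0.0)

    from .panel import default_panel

    panel_names = default_panel().item_names
    item_names = panel_names if p == len(panel_names) else [f"x{j}" for j in range(p)]

    return PairwiseContrast(
        pair=(a, b),
        item_names=item_names,
        intercept_est_a=est_a,
        intercept_est_b=est_b,
        intercept_detected=detected_i,
        intercept_combined=combined_i,
        intercept_percent=percent_i,
        edge_est_a=e_a,
        edge_est_b=e_b,
        edge_detected=detected_e,
        edge_combined=combined_e,
        edge_percent=percent_e,
    )


def all_contrasts(ensemble: RotationEnsemble) -> dict[tuple[str, str], PairwiseContrast]:
    """Every unordered group pair's contrast, keyed (a, b) with a < b."""
    return {
        (a, b): pairwise_contrast(ensemble, a, b)
        for a, b in combinations(ensemble.groups, 2)
    }


def contrasts_frame(contrasts: dict) -> pd.DataFrame:
    """Concatenate all pairwise contrasts into one long-format table."""
    return pd.concat([c.to_frame() for c in contrasts.values()], ignore_index=True)
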