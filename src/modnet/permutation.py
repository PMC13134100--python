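"""Permutation null for group differences, and the edge-count test.

The null hypothesis is "no group differences": group labels are shuffled
across rows (items and covariates stay attached to their persons), the full
reference-rotation ensemble is refit on each of B shuffled datasets, and
every pairwise contrast statistic is recorded. Empirical p-values use the
add-one smoothing p = (1 + #{|null| >= |observed|}) / (B + 1), which is valid
at any finite B; with B = 100 the smallest attainable p is 1/101.

Aggregate-level inference compares each pair's *count* of AND-rule-detected
differences with its permutation null, which is the primary inferential
surface; individual p-values carry no multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .contrasts import RotationEnsemble, all_contrasts, rotate_references
from .estimator import EstimatorSettings

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationSettings:
    B: int = 100
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def permute_labels(cohort: CohortTable, seed) -> CohortTable:
    """Shuffle group labels uniformly across rows; everything else stays put."""
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    data["group"] = rng.permutation(data["group"].to_numpy())
    return CohortTable(data=data, panel=cohort.panel, n_dropped=cohort.n_dropped)


def empirical_pvalue(observed: float, null_samples) -> float:
    """Two-sided smoothed empirical p: (1 + #{|null| >= |obs|}) / (B + 1).

    Ties count as "at least as extreme", so an observed 0 always gives p = 1.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.ndim != 1 or len(null_samples) < 1:
        raise ValueError("null_samples must be a nonempty vector")
    B = len(null_samples)
    return (1 + int(np.sum(np.abs(null_samples) >= abs(observed)))) / (B + 1)


@dataclass
class PermutationDistribution:
    """Null samples and empirical p-values for one cohort's contrast set.

    ``null_stats`` is (B, n_pairs, n_params) with the per-pair statistic
    vector (20 intercept differences then 190 upper-triangular edge
    differences; zeros where the AND-rule rejected). ``pvalues`` is
    (n_pairs, n_params). Aggregate arrays hold per-pair detected *counts* and
    their one-sided empirical p-values.
    """

    pairs: list[tuple[str, str]]
    n_items: int
    observed_stats: np.ndarray  # (n_pairs, n_params)
    null_stats: np.ndarray  # (B, n_pairs, n_params)
    pvalues: np.ndarray  # (n_pairs, n_params)
    observed_counts: pd.DataFrame  # pair x {intercept, edge_unordered}
    null_counts: np.ndarray  # (B, n_pairs, 2)
    aggregate_pvalues: pd.DataFrame  # pair x {intercept, edge}
    statuses: list[str] = field(default_factory=list)

    @property
    def B(self) -> int:
        return self.null_stats.shape[0]

    def min_attainable_p(self) -> float:
        return 1.0 / (self.B + 1)


def null_distribution(
    cohort: CohortTable,
    settings: EstimatorSettings | None = None,
    psettings: PermutationSettings | None = None,
    ensemble: RotationEnsemble | None = None,
    contrasts: dict | None = None,
) -> tuple[dict, PermutationDistribution]:
    """Permutation null for every pairwise contrast statistic.

    Refits the full rotation ensemble on B label-shuffled copies of the
    cohort (per-permutation seeds derived from the master seed as
    ``SeedSequence([master, b])``), computes empirical p-values for each
    individual difference and each pair's detected-difference counts, and
    attaches the individual p-values to the observed contrasts.

    Returns ``(contrasts, distribution)``; the observed ensemble/contrasts
    are computed here unless passed in (e.g. from an earlier pipeline stage).
    """
    settings = settings or EstimatorSettings()
    psettings = psettings or PermutationSettings()
    if ensemble is None:
        ensemble = rotate_references(cohort, settings)
    if contrasts is None:
        contrasts = all_contrasts(ensemble)

    pairs = sorted(contrasts)
    p = ensemble.n_nodes
    observed_stats = np.stack([contrasts[pr].statistics() for pr in pairs])
    observed_counts = pd.DataFrame(
        [
            {
                "pair": pr,
                "intercept": int(contrasts[pr].intercept_detected.sum()),
                "edge_unordered": int(
                    contrasts[pr].edge_detected[np.triu_indices(p, k=1)].sum()
                ),
            }
            for pr in pairs
        ]
    ).set_index("pair")

    B = psettings.B
    null_stats = np.zeros((B, len(pairs), observed_stats.shape[1]))
    null_counts = np.zeros((B, len(pairs), 2), dtype=int)
    statuses = []
    for b in range(B):
        seed_b = np.random.SeedSequence([psettings.seed, b])
        try:
            perm = permute_labels(cohort, seed_b)
            perm_contrasts = all_contrasts(rotate_references(perm, settings))
        except Exception:
            statuses.append(f"permutation {b}: failed")
            log.exception("permutation %d failed; aborting", b)
            raise
        for i, pr in enumerate(pairs):
            c = perm_contrasts[pr]
            null_stats[b, i] = c.statistics()
            null_counts[b, i, 0] = int(c.intercept_detected.sum())
            null_counts[b, i, 1] = int(c.edge_detected[np.triu_indices(p, k=1)].sum())
        statuses.append(f"permutation {b}: ok")
        if (b + 1) % 10 == 0 or b == B - 1:
            log.info("permutations done: %d / %d", b + 1, B)

    # individual-parameter p-values (two-sided on the combined statistic)
    exceed = (np.abs(null_stats) >= np.abs(observed_stats)[None, :, :]).sum(axis=0)
    pvalues = (1 + exceed) / (B + 1)

    # aggregate p-values: one-sided on the detected-difference count
    obs_counts_arr = observed_counts[["intercept", "edge_unordered"]].to_numpy()
    agg_exceed = (null_counts >= obs_counts_arr[None, :, :]).sum(axis=0)
    agg_p = (1 + agg_exceed) / (B + 1)
    aggregate_pvalues = pd.DataFrame(
        agg_p, columns=["intercept", "edge"], index=observed_counts.index
    )

    # attach individual p-values to the observed contrasts
    iu = np.triu_indices(p, k=1)
    for i, pr in enumerate(pairs):
        c = contrasts[pr]
        c.intercept_pvalue = pvalues[i, :p]
        edge_p = np.full((p, p), np.nan)
        edge_p[iu] = pvalues[i, p:]
        edge_p.T[iu] = pvalues[i, p:]
        c.edge_pvalue = edge_p
        c.alpha = psettings.alpha

    dist = PermutationDistribution(
        pairs=pairs,
        n_items=p,
        observed_stats=observed_stats,
        null_stats=null_stats,
        pvalues=pvalues,
        observed_counts=observed_counts,
        null_counts=null_counts,
        aggregate_pvalues=aggregate_pvalues,
        statuses=statuses,
    )
    return contrasts, dist


def edge_count_chisq(counts) -> dict:
    """Goodness-of-fit of per-group edge counts against a uniform expectation.

    ``counts`` may be a RotationEnsemble (per-group edge counts averaged over
    the rotated fits) or a length-G vector. The statistic is
    sum((c_g - m)^2 / m) with m = total/G, df = G - 1, upper-tail chi-square p.
    """
    if isinstance(counts, RotationEnsemble):
        counts = counts.mean_edge_counts()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need per-group counts for at least 2 groups")
    if np.any(counts < 0):
        raise ValueError("edge counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total edge count: nothing to test")
    G = len(counts)
    expected = total / G
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = G - 1
    return {
        "statistic": statistic,
        "df": df,
        "p": float(stats.chi2.sf(statistic, df)),
    }
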