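"""Synthetic cohorts with known group structure for recovery testing.

The generator emulates the data layout the analysis assumes: 20 bounded
symptom/functioning items whose joint distribution is a Gaussian graphical
model that may differ between groups in two ways — item means (intercept
differences) and pairwise partial associations (edge differences) — plus
linear age and gender effects shared by all groups.

Each group g has a precision matrix built from a partial-association matrix
P_g (base network plus that group's planted edge shifts):

    Omega_g = (1 + delta) * I - P_g

where ``delta >= 0`` is a single diagonal-dominance repair shared by all
groups, chosen as the smallest value making every Omega_g's minimum
eigenvalue reach a fixed floor. The repair shrinks all realized partial
correlations by the common factor 1/(1+delta), so planted *differences*
remain differences. Latent scores are drawn from N(mu_g, Omega_g^{-1}) and
mapped to item scales; ordinal mode rounds and clips to each item's range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .panel import SymptomPanel, default_panel

# age is drawn uniformly on [18, 75]; these are that distribution's moments,
# used to expose a standardized age column with exact mean 0 / sd 1 in law
AGE_LOW, AGE_HIGH = 18.0, 75.0
_AGE_MEAN = (AGE_LOW + AGE_HIGH) / 2
_AGE_SD = (AGE_HIGH - AGE_LOW) / np.sqrt(12.0)
FEMALE_RATE = 0.67  # typical of primary-care psychological service cohorts

PD_FLOOR = 0.05  # minimum eigenvalue after diagonal repair
MAX_REPAIR = 4.0  # give up if the diagonal must grow past (1 + MAX_REPAIR)


class InfeasibleTruthError(ValueError):
    """The requested network configuration cannot be made positive definite."""


@dataclass
class GroundTruthNetwork:
    """Ground-truth group networks: means, partials, covariates, planted cells."""

    panel: SymptomPanel
    groups: list[str]
    base_mean: np.ndarray  # (p,) raw item locations
    item_scale: np.ndarray  # (p,) raw item scales
    group_mean_shift: np.ndarray  # (G, p), latent-SD units
    base_partial: np.ndarray  # (p, p) symmetric, zero diagonal
    group_edge_shift: np.ndarray  # (G, p, p) symmetric, zero diagonal
    covariate_effects: np.ndarray  # (2, p): age-per-SD, gender-indicator
    diag_repair: float = 0.0
    planted_mean_cells: list = field(default_factory=list)  # (group, item, delta)
    planted_edge_cells: list = field(default_factory=list)  # (group, s, t, delta)

    def __post_init__(self) -> None:
        p = self.panel.n_items
        G = len(self.groups)
        assert self.base_mean.shape == (p,)
        assert self.group_mean_shift.shape == (G, p)
        assert self.base_partial.shape == (p, p)
        assert self.group_edge_shift.shape == (G, p, p)
        for M in [self.base_partial, *self.group_edge_shift]:
            if not np.allclose(M, M.T) or np.any(np.diag(M) != 0):
                raise ValueError("partial matrices must be symmetric, zero diagonal")
        for g in range(G):
            if np.linalg.eigvalsh(self.precision(g)).min() <= 0:
                raise InfeasibleTruthError(f"group {self.groups[g]} precision not PD")

    # -- per-group matrices ------------------------------------------------

    def partial_raw(self, g: int) -> np.ndarray:
        """Configured (pre-repair) partial matrix for group g."""
        return self.base_partial + self.group_edge_shift[g]

    def precision(self, g: int) -> np.ndarray:
        p = self.panel.n_items
        return (1.0 + self.diag_repair) * np.eye(p) - self.partial_raw(g)

    def partial_realized(self, g: int) -> np.ndarray:
        """Partial correlations actually implied after the diagonal repair."""
        return self.partial_raw(g) / (1.0 + self.diag_repair)

    def covariance(self, g: int) -> np.ndarray:
        return np.linalg.inv(self.precision(g))

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "groups": self.groups,
            "base_mean": self.base_mean.tolist(),
            "item_scale": self.item_scale.tolist(),
            "group_mean_shift": self.group_mean_shift.tolist(),
            "base_partial": self.base_partial.tolist(),
            "group_edge_shift": self.group_edge_shift.tolist(),
            "covariate_effects": self.covariate_effects.tolist(),
            "diag_repair": self.diag_repair,
            "planted_mean_cells": self.planted_mean_cells,
            "planted_edge_cells": self.planted_edge_cells,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path, panel: SymptomPanel | None = None) -> "GroundTruthNetwork":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            panel=panel or default_panel(),
            groups=list(obj["groups"]),
            base_mean=np.asarray(obj["base_mean"]),
            item_scale=np.asarray(obj["item_scale"]),
            group_mean_shift=np.asarray(obj["group_mean_shift"]),
            base_partial=np.asarray(obj["base_partial"]),
            group_edge_shift=np.asarray(obj["group_edge_shift"]),
            covariate_effects=np.asarray(obj["covariate_effects"]),
            diag_repair=float(obj["diag_repair"]),
            planted_mean_cells=[tuple(c) for c in obj["planted_mean_cells"]],
            planted_edge_cells=[tuple(c) for c in obj["planted_edge_cells"]],
        )


def _default_locations(panel: SymptomPanel) -> tuple[np.ndarray, np.ndarray]:
    """Raw item locations/scales typical of treatment-seeking cohorts."""
    mean, scale = [], []
    for it in panel.items:
        if it.max_score == 3:
            mean.append(1.8)
            scale.append(1.0)
        else:  # 0-8 functioning items
            mean.append(4.0)
            scale.append(2.5)
    return np.array(mean), np.array(scale)


def build_truth(
    G: int,
    n_planted_mean: int = 0,
    n_planted_edge: int = 0,
    effect_mean: float = 0.4,
    effect_edge: float = 0.2,
    density: float = 0.15,
    seed: int = 0,
    panel: SymptomPanel | None = None,
    covariate_scale: float = 0.1,
) -> GroundTruthNetwork:
    """Construct a ground-truth network with planted group differences.

    Planted mean shifts are assigned to uniformly sampled (group, item) cells,
    one fresh item per plant, with magnitude ``effect_mean`` (latent-SD units)
    and random sign. Planted edge shifts go to (group, item-pair) cells whose
    base partial is zero, magnitude ``effect_edge`` — a presence-vs-absence
    edge difference. Every plant on one group implies a difference against
    each of the other G-1 groups; ``planted_differences`` enumerates them.
    """
    if G < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if effect_mean < 0 or effect_edge < 0:
        raise ValueError("effect magnitudes must be nonnegative")
    panel = panel or default_panel()
    p = panel.n_items
    rng = np.random.default_rng(seed)
    groups = [f"g{i + 1:02d}" for i in range(G)]
    base_mean, item_scale = _default_locations(panel)

    # base network: exactly round(density * p(p-1)/2) positive partials
    pairs = [(s, t) for s in range(p) for t in range(s + 1, p)]
    K = int(round(density * len(pairs)))
    base_partial = np.zeros((p, p))
    edge_idx = rng.choice(len(pairs), size=K, replace=False)
    for k in edge_idx:
        s, t = pairs[k]
        w = rng.uniform(0.1, 0.3)
        base_partial[s, t] = base_partial[t, s] = w

    # planted mean shifts: fresh item per plant
    if n_planted_mean > p:
        raise InfeasibleTruthError("more planted mean shifts than items")
    group_mean_shift = np.zeros((G, p))
    mean_items = rng.choice(p, size=n_planted_mean, replace=False)
    planted_mean_cells = []
    for j in mean_items:
        g = int(rng.integers(G))
        delta = float(effect_mean * rng.choice([-1.0, 1.0]))
        group_mean_shift[g, j] += delta
        planted_mean_cells.append((groups[g], panel.item_names[j], delta))

    # planted edge shifts: fresh zero-base pair per plant
    zero_pairs = [k for k, (s, t) in enumerate(pairs) if base_partial[s, t] == 0]
    if n_planted_edge > len(zero_pairs):
        raise InfeasibleTruthError("not enough empty pairs for planted edges")
    group_edge_shift = np.zeros((G, p, p))
    edge_slots = rng.choice(zero_pairs, size=n_planted_edge, replace=False)
    planted_edge_cells = []
    for k in edge_slots:
        s, t = pairs[k]
        g = int(rng.integers(G))
        group_edge_shift[g, s, t] = group_edge_shift[g, t, s] = effect_edge
        planted_edge_cells.append(
            (groups[g], panel.item_names[s], panel.item_names[t], float(effect_edge))
        )

    covariate_effects = rng.normal(0.0, covariate_scale, size=(2, p))

    # shared diagonal repair so every group's precision is PD
    min_eig = min(
        np.linalg.eigvalsh(np.eye(p) - (base_partial + group_edge_shift[g])).min()
        for g in range(G)
    )
    delta = max(0.0, PD_FLOOR - min_eig)
    if delta > MAX_REPAIR:
        raise InfeasibleTruthError(
            f"network too dense/strong: diagonal repair {delta:.2f} exceeds cap"
        )

    return GroundTruthNetwork(
        panel=panel,
        groups=groups,
        base_mean=base_mean,
        item_scale=item_scale,
        group_mean_shift=group_mean_shift,
        base_partial=base_partial,
        group_edge_shift=group_edge_shift,
        covariate_effects=covariate_effects,
        diag_repair=float(delta),
        planted_mean_cells=planted_mean_cells,
        planted_edge_cells=planted_edge_cells,
    )


def sample_cohort(
    truth: GroundTruthNetwork,
    group_sizes: dict[str, int] | list[int],
    ordinal: bool = True,
    seed: int = 0,
) -> CohortTable:
    """Draw a cohort from the ground truth; reproducible given the seed.

    Per group g the latent score vector is N(mu_g, Omega_g^{-1}) with
    mu_g = mean shift + age/gender contributions, mapped to the item scale as
    ``base_mean + item_scale * latent``. Ordinal mode rounds to integers and
    clips to each item's panel range.
    """
    if isinstance(group_sizes, dict):
        sizes = [int(group_sizes[g]) for g in truth.groups]
    else:
        sizes = [int(s) for s in group_sizes]
        if len(sizes) != len(truth.groups):
            raise ValueError("group_sizes length must match number of groups")
    if any(s < 1 for s in sizes):
        raise ValueError("all group sizes must be >= 1")

    rng = np.random.default_rng(seed)
    panel = truth.panel
    frames = []
    for g, (label, n_g) in enumerate(zip(truth.groups, sizes)):
        L = np.linalg.cholesky(truth.covariance(g))
        age = rng.uniform(AGE_LOW, AGE_HIGH, size=n_g)
        z_age = (age - _AGE_MEAN) / _AGE_SD
        gender = rng.binomial(1, FEMALE_RATE, size=n_g).astype(float)
        eps = rng.standard_normal((n_g, panel.n_items))
        latent = (
            truth.group_mean_shift[g]
            + z_age[:, None] * truth.covariate_effects[0]
            + gender[:, None] * truth.covariate_effects[1]
            + eps @ L.T
        )
        items = truth.base_mean + truth.item_scale * latent
        if ordinal:
            items = np.clip(
                np.rint(items),
                np.asarray(panel.min_scores, dtype=float),
                np.asarray(panel.max_scores, dtype=float),
            )
        frame = pd.DataFrame(items, columns=panel.item_names)
        frame["group"] = label
        frame["age"] = age
        frame["gender"] = gender
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data=data, panel=panel)


def planted_differences(truth: GroundTruthNetwork) -> list[dict]:
    """Enumerate every true pairwise contrast implied by the planted shifts.

    Returns one record per unordered group pair and nonzero parameter
    difference, oriented second-group-minus-first (matching the contrast
    convention). This is the recovery oracle.
    """
    out = []
    names = truth.panel.item_names
    G = len(truth.groups)
    for a in range(G):
        for b in range(a + 1, G):
            dmean = truth.group_mean_shift[b] - truth.group_mean_shift[a]
            for j in np.flatnonzero(dmean):
                out.append(
                    {
                        "pair": (truth.groups[a], truth.groups[b]),
                        "kind": "intercept",
                        "param": names[j],
                        "difference": float(dmean[j]),
                    }
                )
            dedge = truth.group_edge_shift[b] - truth.group_edge_shift[a]
            for s, t in zip(*np.nonzero(np.triu(dedge))):
                out.append(
                    {
                        "pair": (truth.groups[a], truth.groups[b]),
                        "kind": "edge",
                        "param": (names[s], names[t]),
                        "difference": float(dedge[s, t]),
                    }
                )
    return out


def detection_scores(contrasts: dict, truth: GroundTruthNetwork) -> dict:
    """Score AND-rule detection against the planted-difference oracle.

    ``contrasts`` maps unordered group pairs (a, b), a < b, to
    PairwiseContrast objects. Returns per-kind confusion counts plus
    sensitivity and specificity over the full slot universe (every pair x
    every symptom, and every pair x unordered item pair).
    """
    names = truth.panel.item_names
    true_set = {
        (d["pair"], d["kind"], d["param"] if d["kind"] == "intercept" else tuple(d["param"]))
        for d in planted_differences(truth)
    }
    scores = {}
    for kind in ("intercept", "edge"):
        tp = fp = fn = tn = 0
        for pair, con in contrasts.items():
            p = len(names)
            if kind == "intercept":
                slots = [(j,) for j in range(p)]
            else:
                slots = [(s, t) for s in range(p) for t in range(s + 1, p)]
            for slot in slots:
                if kind == "intercept":
                    det = bool(con.intercept_detected[slot[0]])
                    key = (pair, "intercept", names[slot[0]])
                else:
                    det = bool(con.edge_detected[slot[0], slot[1]])
                    key = (pair, "edge", (names[slot[0]], names[slot[1]]))
                tru = key in true_set
                tp += det and tru
                fp += det and not tru
                fn += (not det) and tru
                tn += (not det) and not tru
        scores[kind] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
    return scores
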