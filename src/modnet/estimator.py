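"""Moderated network estimation by nodewise regularized regression.

Each of the 20 items is regressed on the 19 other items, G-1 group dummies
(a chosen reference group omitted), all item x dummy interactions, and two
covariates (age, gender). The LASSO penalty for each nodewise regression is
selected by the Extended Bayesian Information Criterion (EBIC). Group-specific
intercepts and edge matrices are then assembled: a group's intercept at a node
is the reference intercept plus that group's dummy coefficient, and a group's
directed edge coefficient is the item main effect plus the item x dummy
interaction. The two directed estimates for an unordered pair are combined by
the nodewise AND-rule (present only if both are nonzero; value is their mean)
or the OR-rule.

Scaling: item scores and age are z-scored on the full sample; dummies and
gender stay 0/1 and interactions are products of z-scored item and raw dummy.
That "base scale" makes dummy/interaction coefficients directly comparable
across reference rotations. For penalty fairness the lasso itself is fit on a
fully standardized copy of the design; selected coefficients are mapped back
to the base scale before any derivation, which leaves the zero/nonzero
pattern untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import lasso_path

from .cohort import CohortTable

NONZERO_TOL = 1e-10  # below this a selected coefficient is floating-point dust


@dataclass(frozen=True)
class EstimatorSettings:
    """Nodewise LASSO/EBIC settings.

    gamma : EBIC hyperparameter (0 recovers plain BIC); 0.25 is the
        customary default for this estimator family.
    lambda_path : explicit penalty grid (strictly decreasing, >= 0; a final 0
        means an unpenalized fit). When None a 50-point log-spaced grid from
        lambda_max down to lambda_max * lambda_min_ratio is built per node.
    nodewise_rule : how the two directed estimates of an edge are combined.
    standardize : fit on a fully standardized design (recommended); when off
        the design is used as-is and no intercept is fit.
    """

    gamma: float = 0.25
    lambda_path: tuple[float, ...] | None = None
    lambda_path_length: int = 50
    lambda_min_ratio: float = 1e-3
    nodewise_rule: str = "AND"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.nodewise_rule not in ("AND", "OR"):
            raise ValueError("nodewise_rule must be 'AND' or 'OR'")
        if self.lambda_path is not None:
            path = np.asarray(self.lambda_path, dtype=float)
            if np.any(path < 0) or np.any(np.diff(path) >= 0):
                raise ValueError("lambda_path must be strictly decreasing, >= 0")
        elif self.lambda_path_length < 2:
            raise ValueError("lambda_path_length must be >= 2")


def ebic_score(rss: float, n: int, df: int, p_candidates: int, gamma: float) -> float:
    """EBIC for a Gaussian regression: n log(RSS/n) + df log n + 2 gamma df log p."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= df <= p_candidates:
        raise ValueError("df must lie in [0, p_candidates]")
    if rss <= 0:
        raise ValueError("RSS <= 0: degenerate (saturated) fit")
    return (
        n * np.log(rss / n)
        + df * np.log(n)
        + 2.0 * gamma * df * np.log(p_candidates)
    )


# ---------------------------------------------------------------------------
# design construction


@dataclass
class NodeDesign:
    """Design for one nodewise regression, on the base scale (see module doc)."""

    node: int
    X: np.ndarray  # (n, p_pred)
    y: np.ndarray  # (n,)
    columns: list[tuple]  # ('item', t) | ('dummy', g) | ('inter', t, g) | ('cov', name)

    def column_index(self) -> dict[tuple, int]:
        return {key: i for i, key in enumerate(self.columns)}


class _CohortArrays:
    """Z-scored items and covariates plus group dummies for one cohort."""

    def __init__(self, cohort: CohortTable, reference_group: str):
        if reference_group not in cohort.groups:
            raise ValueError(f"reference group {reference_group!r} not in cohort")
        for g, size in cohort.group_sizes.items():
            if size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 members")
        items = cohort.items_matrix()
        sd = items.std(axis=0)
        sd[sd == 0] = 1.0
        self.Z = (items - items.mean(axis=0)) / sd
        age = cohort.data["age"].to_numpy(dtype=float)
        age_sd = age.std() or 1.0
        self.z_age = (age - age.mean()) / age_sd
        self.gender = cohort.data["gender"].to_numpy(dtype=float)
        self.groups = cohort.groups
        self.reference = reference_group
        self.nonref = [g for g in self.groups if g != reference_group]
        labels = cohort.data["group"].to_numpy()
        self.D = np.column_stack(
            [(labels == g).astype(float) for g in self.nonref]
        ) if self.nonref else np.empty((len(labels), 0))

    def node_design(self, node: int) -> NodeDesign:
        p = self.Z.shape[1]
        others = [t for t in range(p) if t != node]
        Zo = self.Z[:, others]
        # interactions: for each other item t, its product with each dummy
        inter = (Zo[:, :, None] * self.D[:, None, :]).reshape(len(self.Z), -1)
        X = np.hstack([Zo, self.D, inter, self.z_age[:, None], self.gender[:, None]])
        columns: list[tuple] = (
            [("item", t) for t in others]
            + [("dummy", g) for g in self.nonref]
            + [("inter", t, g) for t in others for g in self.nonref]
            + [("cov", "age"), ("cov", "gender")]
        )
        return NodeDesign(node=node, X=X, y=self.Z[:, node], columns=columns)


def design_matrix(
    cohort: CohortTable,
    node: int,
    reference_group: str,
    settings: EstimatorSettings | None = None,
) -> NodeDesign:
    """Build the nodewise design for one item under a given reference group.

    With ``settings.standardize`` on, the returned response and every
    non-constant predictor column are centered and scaled to unit variance
    (constant columns are left at zero), which is the design the lasso sees.
    """
    settings = settings or EstimatorSettings()
    if not 0 <= node < cohort.panel.n_items:
        raise ValueError(f"node must be in 0..{cohort.panel.n_items - 1}")
    design = _CohortArrays(cohort, reference_group).node_design(node)
    if settings.standardize:
        Xs, _, _, ys, _, _ = _standardize(design.X, design.y)
        return NodeDesign(node=design.node, X=Xs, y=ys, columns=design.columns)
    return design


def _standardize(X: np.ndarray, y: np.ndarray):
    mx = X.mean(axis=0)
    sx = X.std(axis=0)
    keep = sx > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mx[keep]) / sx[keep]
    my = y.mean()
    sy = y.std()
    if sy == 0:
        raise ValueError("response is constant")
    ys = (y - my) / sy
    return Xs, mx, sx, ys, my, sy


# ---------------------------------------------------------------------------
# nodewise fit


@dataclass
class NodewiseFit:
    """One node's selected lasso fit.

    ``coef`` is on the input (base) scale of the design passed in;
    ``coef_std`` on the standardized scale the path was fit on. The EBIC at
    the selected penalty is the path minimum, ties going to the larger
    penalty (sparser model).
    """

    node: int
    columns: list[tuple]
    selected_lambda: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    ebic: float
    intercept: float
    coef: np.ndarray
    coef_std: np.ndarray
    df: int
    n: int
    p_candidates: int
    index: dict[tuple, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {key: i for i, key in enumerate(self.columns)}

    def get(self, key: tuple) -> float:
        return float(self.coef[self.index[key]])


def _path_for(X: np.ndarray, y: np.ndarray, settings: EstimatorSettings) -> np.ndarray:
    if settings.lambda_path is not None:
        return np.asarray(settings.lambda_path, dtype=float)
    n = len(y)
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:  # response orthogonal to every predictor
        lam_max = 1e-3
    return np.geomspace(
        lam_max, lam_max * settings.lambda_min_ratio, settings.lambda_path_length
    )


def _lasso_coefs(X: np.ndarray, y: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Coefficients (p, n_path) along a decreasing penalty path.

    Positive penalties use coordinate descent on the precomputed Gram matrix
    (p << n here, so this dominates runtime); an exact zero penalty is an
    unpenalized least-squares solve.
    """
    p = X.shape[1]
    coefs = np.zeros((p, len(path)))
    pos = path > 0
    if pos.any():
        gram = X.T @ X
        _, cpos, _ = lasso_path(
            X, y, alphas=path[pos], precompute=gram, Xy=X.T @ y
        )
        coefs[:, pos] = cpos
    for j in np.flatnonzero(~pos):
        coefs[:, j] = np.linalg.lstsq(X, y, rcond=None)[0]
    return coefs


def fit_node(
    design: NodeDesign | np.ndarray,
    response: np.ndarray | None = None,
    settings: EstimatorSettings | None = None,
    columns: list[tuple] | None = None,
    node: int = -1,
) -> NodewiseFit:
    """Fit the lasso path for one node and select the EBIC-minimal penalty."""
    settings = settings or EstimatorSettings()
    if isinstance(design, NodeDesign):
        X, y = design.X, design.y
        columns = design.columns
        node = design.node
    else:
        X, y = np.asarray(design, float), np.asarray(response, float)
        columns = columns or [("x", j) for j in range(X.shape[1])]
    n, p = X.shape

    if settings.standardize:
        Xs, mx, sx, ys, my, sy = _standardize(X, y)
    else:
        Xs, ys = X, y
        mx = np.zeros(p)
        sx = np.ones(p)
        my, sy = 0.0, 1.0

    path = _path_for(Xs, ys, settings)
    coefs = _lasso_coefs(Xs, ys, path)

    resid = ys[:, None] - Xs @ coefs
    rss = np.einsum("ij,ij->j", resid, resid)
    dfs = (np.abs(coefs) > NONZERO_TOL).sum(axis=0)
    ebics = np.empty(len(path))
    for j in range(len(path)):
        ebics[j] = ebic_score(max(rss[j], 1e-300), n, int(dfs[j]), p, settings.gamma)
    best = int(np.argmin(ebics))  # first minimum = largest penalty on ties

    coef_std = coefs[:, best].copy()
    coef_std[np.abs(coef_std) <= NONZERO_TOL] = 0.0
    # back to the input scale of the design
    coef = np.zeros(p)
    nz = sx > 0
    coef[nz] = coef_std[nz] * sy / sx[nz]
    intercept = my - float(coef @ mx) if settings.standardize else 0.0

    return NodewiseFit(
        node=node,
        columns=columns,
        selected_lambda=float(path[best]),
        lambda_path=path,
        ebic_path=ebics,
        ebic=float(ebics[best]),
        intercept=intercept,
        coef=coef,
        coef_std=coef_std,
        df=int(dfs[best]),
        n=n,
        p_candidates=p,
    )


# ---------------------------------------------------------------------------
# full moderated network fit


@dataclass
class MNMFit:
    """A moderated network fit under one fixed reference group.

    Arrays are indexed by the sorted group list. ``main_coefs[s, t]`` is the
    coefficient of item t in node s's regression (reference-group edge),
    ``dummy_coefs[g, s]`` the group-g dummy in node s's regression, and
    ``inter_coefs[g, s, t]`` the item-t x group-g interaction in node s's
    regression (all zero for the reference group). ``group_edges`` holds the
    nodewise-rule-combined symmetric edge matrices per group;
    ``group_intercepts`` the per-group adjusted item levels on the
    standardized response scale.
    """

    reference_group: str
    groups: list[str]
    settings: EstimatorSettings
    node_fits: list[NodewiseFit]
    main_coefs: np.ndarray  # (p, p)
    dummy_coefs: np.ndarray  # (G, p)
    inter_coefs: np.ndarray  # (G, p, p)
    covariate_coefs: np.ndarray  # (p, 2)
    intercepts: np.ndarray  # (p,)
    group_intercepts: np.ndarray  # (G, p)
    group_edges: np.ndarray  # (G, p, p)
    edge_presence: np.ndarray  # (G, p, p) bool
    fingerprint: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.main_coefs.shape[0]

    def edge_counts(self) -> np.ndarray:
        """Number of present edges per group (upper triangle count)."""
        p = self.n_nodes
        iu = np.triu_indices(p, k=1)
        return np.array([pres[iu].sum() for pres in self.edge_presence])

    def edge_list(self) -> list[dict]:
        """Weighted edge list per group (nodeA, nodeB, weight, group)."""
        rows = []
        p = self.n_nodes
        for gi, g in enumerate(self.groups):
            for s in range(p):
                for t in range(s + 1, p):
                    if self.edge_presence[gi, s, t]:
                        rows.append(
                            {
                                "nodeA": s,
                                "nodeB": t,
                                "weight": float(self.group_edges[gi, s, t]),
                                "group": g,
                            }
                        )
        return rows


def combine_directed(v1: float, v2: float, rule: str) -> tuple[bool, float]:
    """Nodewise combination of the two directed estimates of one edge."""
    nz1, nz2 = abs(v1) > NONZERO_TOL, abs(v2) > NONZERO_TOL
    if rule == "AND":
        present = nz1 and nz2
        value = 0.5 * (v1 + v2) if present else 0.0
    else:  # OR
        present = nz1 or nz2
        if nz1 and nz2:
            value = 0.5 * (v1 + v2)
        elif nz1:
            value = v1
        elif nz2:
            value = v2
        else:
            value = 0.0
    return present, value


def fit_mnm(
    cohort: CohortTable,
    reference_group: str,
    settings: EstimatorSettings | None = None,
) -> MNMFit:
    """Fit all 20 nodewise regressions and assemble the moderated network."""
    settings = settings or EstimatorSettings()
    arrays = _CohortArrays(cohort, reference_group)
    groups = arrays.groups
    G = len(groups)
    p = cohort.panel.n_items
    ref_idx = groups.index(reference_group)

    node_fits = []
    main_coefs = np.zeros((p, p))
    dummy_coefs = np.zeros((G, p))
    inter_coefs = np.zeros((G, p, p))
    covariate_coefs = np.zeros((p, 2))
    intercepts = np.zeros(p)
    for s in range(p):
        fit = fit_node(arrays.node_design(s), settings=settings)
        node_fits.append(fit)
        intercepts[s] = fit.intercept
        for key, i in fit.index.items():
            val = fit.coef[i]
            if key[0] == "item":
                main_coefs[s, key[1]] = val
            elif key[0] == "dummy":
                dummy_coefs[groups.index(key[1]), s] = val
            elif key[0] == "inter":
                inter_coefs[groups.index(key[2]), s, key[1]] = val
            elif key[0] == "cov":
                covariate_coefs[s, 0 if key[1] == "age" else 1] = val

    group_intercepts = intercepts[None, :] + dummy_coefs
    group_edges = np.zeros((G, p, p))
    edge_presence = np.zeros((G, p, p), dtype=bool)
    directed = main_coefs[None, :, :] + inter_coefs  # (G, p, p): [g, s, t]
    for g in range(G):
        for s in range(p):
            for t in range(s + 1, p):
                present, value = combine_directed(
                    directed[g, s, t], directed[g, t, s], settings.nodewise_rule
                )
                edge_presence[g, s, t] = edge_presence[g, t, s] = present
                group_edges[g, s, t] = group_edges[g, t, s] = value

    assert ref_idx == groups.index(reference_group)
    return MNMFit(
        reference_group=reference_group,
        groups=groups,
        settings=settings,
        node_fits=node_fits,
        main_coefs=main_coefs,
        dummy_coefs=dummy_coefs,
        inter_coefs=inter_coefs,
        covariate_coefs=covariate_coefs,
        intercepts=intercepts,
        group_intercepts=group_intercepts,
        group_edges=group_edges,
        edge_presence=edge_presence,
        fingerprint=cohort.fingerprint(),
    )


def with_rule(fit: MNMFit, rule: str) -> MNMFit:
    """Re-derive edge presence/values from the same nodewise fits under a rule."""
    G, p = len(fit.groups), fit.n_nodes
    group_edges = np.zeros((G, p, p))
    edge_presence = np.zeros((G, p, p), dtype=bool)
    directed = fit.main_coefs[None, :, :] + fit.inter_coefs
    for g in range(G):
        for s in range(p):
            for t in range(s + 1, p):
                present, value = combine_directed(
                    directed[g, s, t], directed[g, t, s], rule
                )
                edge_presence[g, s, t] = edge_presence[g, t, s] = present
                group_edges[g, s, t] = group_edges[g, t, s] = value
    return replace(
        fit,
        settings=replace(fit.settings, nodewise_rule=rule),
        group_edges=group_edges,
        edge_presence=edge_presence,
    )
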