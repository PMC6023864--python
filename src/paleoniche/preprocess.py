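"""Occurrence thinning and predictor selection.

Two standard pre-modelling steps:

* spatial thinning — at most one record per thinning-grid cell per period,
  suppressing pseudo-replication from spatially clustered sampling (the
  classic "one record per 10-km cell" rule);
* predictor selection — agglomerative clustering of variables on the
  distance 1 - |r| with the tree cut at 1 - r_threshold, keeping one
  variable per cluster, followed by iterative variance-inflation-factor
  (VIF) filtering until all VIF < threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .geodata import ClimateStack, OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class VariableSelection:
    """Outcome of a predictor-selection step."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (label, reason, statistic)
    r_threshold: float = 0.7
    vif_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not self.kept:
            raise ValueError("selection kept no variables")

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": [{"label": l, "reason": r, "statistic": s}
                        for l, r, s in self.dropped],
            "r_threshold": self.r_threshold,
            "vif_threshold": self.vif_threshold,
        }


def thin_to_grid(occ: OccurrenceSet, cell_size: float,
                 origin: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """Keep at most one record per thinning-grid cell per period.

    The retained record is the first in input order (deterministic without a
    seed); the rule is applied identically to every role. The thinning grid
    is anchored at ``origin`` with half-open cells. Idempotent; an empty set
    thins to an empty set.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    df = occ.records
    if df.empty:
        return OccurrenceSet(df.copy(), occ.crs_note)
    col = np.floor((df["x"].to_numpy(float) - origin[0]) / cell_size).astype(int)
    row = np.floor((df["y"].to_numpy(float) - origin[1]) / cell_size).astype(int)
    key = df.assign(_col=col, _row=row)
    kept = key.drop_duplicates(subset=["_col", "_row", "period"], keep="first")
    return OccurrenceSet(kept.drop(columns=["_col", "_row"]).reset_index(drop=True),
                         occ.crs_note)


def _pearson_matrix(env: np.ndarray) -> np.ndarray:
    return np.corrcoef(env, rowvar=False)


def correlation_cluster_select(stack: ClimateStack, r_threshold: float = 0.7,
                               preference: list[str] | None = None) -> VariableSelection:
    """Cluster variables on 1 - |Pearson r| and keep one per cluster.

    Average (UPGMA) linkage; the dendrogram is cut at height 1 - r_threshold.
    Within each cluster the kept variable is the first present in
    ``preference``; failing that, the one with maximal variance. Constant
    variables are dropped beforehand with a warning. Note that average
    linkage does not guarantee all pairwise |r| among kept variables are
    below the threshold; violations are logged.
    """
    preference = list(preference or [])
    names = stack.variable_names
    if len(names) < 2:
        raise ValueError("need at least two variables to cluster")
    env = stack.env_table()
    if env.shape[0] < 3:
        raise ValueError("need at least three unmasked cells")
    variances = env.var(axis=0, ddof=1)
    dropped: list[tuple[str, str, float]] = []
    live = [i for i, v in enumerate(variances) if v > 0]
    for i, name in enumerate(names):
        if i not in live:
            logger.warning("correlation_cluster_select: dropping constant variable %s", name)
            dropped.append((name, "correlation_cluster", 0.0))
    live_names = [names[i] for i in live]
    if len(live) == 1:
        return VariableSelection(live_names, dropped, r_threshold)
    # order-stable: cluster in sorted-name order so input order cannot matter
    order = sorted(range(len(live)), key=lambda j: live_names[j])
    sub = env[:, [live[j] for j in order]]
    sub_names = [live_names[j] for j in order]
    R = np.abs(_pearson_matrix(sub))
    dist = np.clip(1.0 - R, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    kept: list[str] = []
    for cluster_id in np.unique(labels):
        members = [sub_names[j] for j in range(len(sub_names)) if labels[j] == cluster_id]
        pick = next((p for p in preference if p in members), None)
        if pick is None:
            pick = max(members, key=lambda m: env[:, names.index(m)].var(ddof=1))
        kept.append(pick)
        for m in members:
            if m != pick:
                r_with_pick = abs(np.corrcoef(env[:, names.index(m)],
                                              env[:, names.index(pick)])[0, 1])
                dropped.append((m, "correlation_cluster", float(r_with_pick)))
    kept = [n for n in names if n in kept]  # report in stack order
    if len(kept) > 1:
        kr = np.abs(_pearson_matrix(env[:, [names.index(n) for n in kept]]))
        np.fill_diagonal(kr, 0.0)
        if kr.max() >= r_threshold:
            logger.warning("kept variables still contain |r| = %.3f >= %.2f "
                           "(average linkage does not guarantee the bound)",
                           kr.max(), r_threshold)
    return VariableSelection(kept, dropped, r_threshold)


def compute_vif(env: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) from OLS of column j on the remaining columns.

    A non-invertible fit (perfect collinearity) yields VIF = +inf.
    """
    n, k = env.shape
    X = (env - env.mean(axis=0)) / env.std(axis=0, ddof=0)
    vifs = np.empty(k)
    for j in range(k):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)  # y is centered and scaled
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(stack: ClimateStack, variables: list[str] | None = None,
               vif_threshold: float = 5.0) -> VariableSelection:
    """Iteratively drop the largest-VIF variable until all VIF < threshold."""
    names = list(variables or stack.variable_names)
    if len(names) < 2:
        raise ValueError("need at least two variables for VIF filtering")
    env_full = stack.env_table(names)
    current = list(names)
    dropped: list[tuple[str, str, float]] = []
    while len(current) >= 2:
        env = env_full[:, [names.index(n) for n in current]]
        vifs = compute_vif(env)
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_threshold:
            break
        dropped.append((current[worst], "vif", float(vifs[worst])))
        logger.info("vif_filter: dropping %s (VIF = %.3g)", current[worst], vifs[worst])
        del current[worst]
    return VariableSelection(current, dropped, vif_threshold=vif_threshold)


def select_predictors(stack: ClimateStack, r_threshold: float = 0.7,
                      vif_threshold: float = 5.0,
                      preference: list[str] | None = None) -> VariableSelection:
    """Correlation clustering followed by VIF filtering (the full reduction)."""
    first = correlation_cluster_select(stack, r_threshold, preference)
    if len(first.kept) < 2:
        return VariableSelection(first.kept, first.dropped, r_threshold, vif_threshold)
    second = vif_filter(stack, first.kept, vif_threshold)
    return VariableSelection(second.kept, first.dropped + second.dropped,
                             r_threshold, vif_threshold)
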