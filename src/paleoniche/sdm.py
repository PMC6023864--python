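"""Species distribution models and their geographic evaluation.

Three presence/contrast algorithms are fitted on a common training table:

* ``glm_poly`` — binomial-logit GLM on per-variable polynomial expansions,
  fit metric D^2 (deviance explained). With a background contrast the
  contrast rows are down-weighted so presence and contrast mass are equal
  ("weighted background"); with pseudoabsences all rows have weight 1.
* ``random_forest`` — regression forest on the 0/1 labels, fit metric the
  out-of-bag variance explained; permutation importance is the percent
  increase in prediction MSE when one variable is shuffled.
* ``maxent_like`` — a penalized log-linear density over background cells
  (linear + quadratic features, L1 penalty scaled by a regularization
  multiplier, default 3), fit metric the gain; suitability output is the
  logistic transform of the linear score (a monotone transform, so
  rank-based statistics such as AUC and Schoener's D are unaffected).

Models are projected across climate scenarios with the predictors clamped
to their training range by default, the standard guard against uncontrolled
extrapolation when hindcasting. Evaluation is by rank-based AUC — internal
(bootstrap data partitioning) and external (independent presences, e.g.
fossil records, against a contrast sample in the target scenario) — plus
multivariate environmental similarity surfaces (MESS) with the
most-dissimilar-variable (MoD) map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .geodata import ClimateStack, OccurrenceSet, SuitabilityMap

logger = logging.getLogger(__name__)

ALGORITHMS = ("glm_poly", "random_forest", "maxent_like")


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Presence/contrast rows in variable space, with weights and ranges."""

    X: np.ndarray               # (n, k) environment vectors
    y: np.ndarray               # 1 = presence, 0 = contrast
    variable_names: list[str]
    contrast_kind: str = "pseudoabsence"   # or "background"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.contrast_kind not in ("background", "pseudoabsence"):
            raise ValueError(f"unknown contrast kind {self.contrast_kind!r}")
        if self.y.sum() < 1 or (self.y == 0).sum() < 1:
            raise ValueError("training table needs >=1 presence and >=1 contrast row")
        if self.weights is None:
            self.weights = np.ones(len(self.y))
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    @property
    def variable_ranges(self) -> np.ndarray:
        """(k, 2) per-variable (min, max) over all rows."""
        return np.column_stack([self.X.min(axis=0), self.X.max(axis=0)])

    def subset(self, idx: np.ndarray) -> "TrainingTable":
        return TrainingTable(self.X[idx], self.y[idx], list(self.variable_names),
                             self.contrast_kind, self.weights[idx])


def build_training_table(stack: ClimateStack, presences: OccurrenceSet,
                         contrast: OccurrenceSet,
                         variables: Sequence[str] | None = None) -> TrainingTable:
    """Assemble a training table from points on a stack.

    Background contrasts are down-weighted to match the total presence
    weight; pseudoabsence contrasts keep unit weights.
    """
    names = list(variables or stack.variable_names)
    px, py = presences.xy
    cx, cy = contrast.xy
    Xp = stack.env_at_points(px, py, names)
    Xc = stack.env_at_points(cx, cy, names)
    contrast_kind = ("background"
                     if (contrast.records["role"] == "background").all()
                     else "pseudoabsence")
    m, N = len(Xp), len(Xc)
    w_contrast = m / N if contrast_kind == "background" else 1.0
    return TrainingTable(
        X=np.vstack([Xp, Xc]),
        y=np.concatenate([np.ones(m, int), np.zeros(N, int)]),
        variable_names=names,
        contrast_kind=contrast_kind,
        weights=np.concatenate([np.ones(m), np.full(N, w_contrast)]),
    )


def sample_background(stack: ClimateStack, fraction: float = 0.2,
                      seed: int = 0, period: str = "current") -> OccurrenceSet:
    """Uniform sample of floor(fraction * n_unmasked) distinct cells."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cells = stack.unmasked_indices()
    if cells.size == 0:
        raise ValueError("no unmasked cells to sample from")
    n = int(np.floor(fraction * cells.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=False)
    x, y = stack.cell_centers(chosen)
    import pandas as pd

    return OccurrenceSet(pd.DataFrame({"x": x, "y": y, "role": "background",
                                       "period": period}))


def sample_pseudoabsences(stack: ClimateStack, presences: OccurrenceSet,
                          n: int | None = None, seed: int = 0,
                          period: str = "current") -> OccurrenceSet:
    """Uniform sample of non-presence cells; default n = number of presences."""
    if n is None:
        n = len(presences)
    px, py = presences.xy
    prow, pcol = stack.cells_of_points(px, py)
    nrows, ncols = stack.shape
    presence_flat = set(np.ravel_multi_index((prow, pcol), (nrows, ncols)).tolist())
    cells = np.array([c for c in stack.unmasked_indices() if c not in presence_flat])
    if n > cells.size:
        raise ValueError(f"requested {n} pseudoabsences but only {cells.size} "
                         "non-presence cells available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n, replace=False)
    x, y = stack.cell_centers(chosen)
    import pandas as pd

    return OccurrenceSet(pd.DataFrame({"x": x, "y": y, "role": "pseudoabsence",
                                       "period": period}))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class SDMModel:
    """A fitted distribution model plus the metadata needed to project it."""

    algorithm: str
    variable_names: list[str]
    variable_ranges: np.ndarray           # (k, 2) training (min, max)
    fit_metric: tuple[str, float]
    _predict: Callable[[np.ndarray], np.ndarray]
    parameters: dict = field(default_factory=dict)
    importance: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Suitability in [0, 1] for rows of X (columns = variable_names)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.variable_names):
            raise ValueError("X has wrong number of columns")
        if clamp:
            lo, hi = self.variable_ranges[:, 0], self.variable_ranges[:, 1]
            X = np.clip(X, lo, hi)
        return np.clip(self._predict(X), 0.0, 1.0)


def _poly_design(X: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                 degree: int) -> np.ndarray:
    """Intercept + per-variable powers 1..degree of standardized values."""
    Z = (X - mean) / sd
    cols = [np.ones(len(X))]
    for j in range(Z.shape[1]):
        for d in range(1, degree + 1):
            cols.append(Z[:, j] ** d)
    return np.column_stack(cols)


def fit_glm(table: TrainingTable, degree: int = 2) -> SDMModel:
    """Binomial-logit GLM on polynomial expansions (no cross-products).

    Row weights are honored (so duplicated rows and weight-2 rows are
    equivalent). Fit metric D^2 = 1 - deviance / null deviance. Complete
    separation falls back to a tiny-ridge fit (L2 = 1e-6) and is flagged.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    mean = table.X.mean(axis=0)
    sd = table.X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    A = _poly_design(table.X, mean, sd, degree)
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(table.y, A, family=sm.families.Binomial(),
                       var_weights=table.weights)
        try:
            res = model.fit(maxiter=100)
            params = res.params
            deviance, null_dev = res.deviance, res.null_deviance
            separated = (not np.isfinite(params).all()
                         or np.abs(params).max() > 1e3)
        except Exception:
            separated = True
        if separated:
            res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, maxiter=200)
            params = np.asarray(res.params)
            mu = expit(A @ params)
            deviance = _binomial_deviance(table.y, mu, table.weights)
            p0 = np.average(table.y, weights=table.weights)
            null_dev = _binomial_deviance(table.y, np.full(len(table.y), p0),
                                          table.weights)
            flags.append("separation_ridge_fallback")
            logger.warning("fit_glm: complete separation; tiny-ridge fallback used")
    d2 = 1.0 - deviance / null_dev if null_dev > 0 else 0.0

    def _predict(X: np.ndarray) -> np.ndarray:
        return expit(_poly_design(X, mean, sd, degree) @ params)

    return SDMModel("glm_poly", list(table.variable_names), table.variable_ranges,
                    ("deviance_explained", float(d2)), _predict,
                    parameters={"coefficients": np.asarray(params), "degree": degree,
                                "standardize_mean": mean, "standardize_sd": sd},
                    flags=flags)


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    ll = y * np.log(mu) + (1 - y) * np.log(1 - mu)
    return float(-2.0 * np.sum(w * ll))


def fit_rf(table: TrainingTable, n_trees: int = 500, seed: int = 0) -> SDMModel:
    """Regression forest on 0/1 labels.

    Fit metric = out-of-bag variance explained (1 - MSE_oob / Var(label)).
    Permutation importance per variable = mean percent increase in the MSE
    of forest predictions on the training rows when that variable's values
    are permuted (constant variables therefore score 0).
    """
    if n_trees < 10:
        logger.warning("fit_rf: n_trees = %d is very small", n_trees)
    if len(np.unique(table.y)) < 2:
        raise ValueError("single-class table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                       random_state=int(seed) % (2 ** 31),
                                       n_jobs=1, bootstrap=True)
        forest.fit(table.X, table.y.astype(float))
    var_explained = float(forest.oob_score_)  # R^2 on OOB = 1 - MSE_oob/Var

    rng = np.random.default_rng(seed)
    base_pred = forest.predict(table.X)
    base_mse = float(np.mean((base_pred - table.y) ** 2))
    importance: dict[str, float] = {}
    for j, name in enumerate(table.variable_names):
        if np.ptp(table.X[:, j]) == 0:
            importance[name] = 0.0
            continue
        Xp = table.X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        mse = float(np.mean((forest.predict(Xp) - table.y) ** 2))
        importance[name] = (100.0 * (mse - base_mse) / base_mse
                            if base_mse > 0 else 0.0)

    def _predict(X: np.ndarray) -> np.ndarray:
        return forest.predict(X)

    return SDMModel("random_forest", list(table.variable_names),
                    table.variable_ranges,
                    ("variance_explained", var_explained), _predict,
                    parameters={"n_trees": n_trees}, importance=importance)


def _maxent_features(X: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                     quadratic: bool) -> np.ndarray:
    Z = (X - mean) / sd
    return np.hstack([Z, Z ** 2]) if quadratic else Z


def fit_maxent_like(table: TrainingTable, features: tuple[str, ...] = ("linear", "quadratic"),
                    reg_multiplier: float = 3.0, seed: int = 0,
                    tol: float = 1e-8) -> SDMModel:
    """Penalized log-linear density over background cells.

    Maximizes ``mean_presence(lambda . f) - log mean_background(exp(lambda . f))
    - sum_k beta_k |lambda_k|`` where features are standardized to the
    background sample, so the base penalty is ``beta_k = reg_multiplier /
    sqrt(m)`` per feature with m presences (the per-feature sample-variance
    scaling absorbed by the standardization). The L1 problem is made smooth
    by the positive/negative split and solved with L-BFGS-B. Gain is the
    unpenalized objective at the optimum; the suitability output is the
    logistic transform of the linear score.
    """
    pres = table.X[table.y == 1]
    bg = table.X[table.y == 0]
    if len(pres) < 2:
        raise ValueError("maxent-like fit needs >= 2 presences")
    if len(pres) < 10:
        logger.warning("fit_maxent_like: only %d presences; coefficients will be "
                       "heavily penalized and unstable", len(pres))
    if len(bg) < len(pres):
        raise ValueError("background must be at least as large as the presence set")
    quadratic = "quadratic" in features
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Fp = _maxent_features(pres, mean, sd, quadratic)
    Fb = _maxent_features(bg, mean, sd, quadratic)
    m, K = Fp.shape
    beta = np.full(K, reg_multiplier / np.sqrt(m))
    fp_mean = Fp.mean(axis=0)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = theta[:K] - theta[K:]
        eta_b = Fb @ lam
        lse = logsumexp(eta_b) - np.log(len(Fb))
        gain = float(fp_mean @ lam - lse)
        q = np.exp(eta_b - logsumexp(eta_b))
        grad_lam = -(fp_mean - q @ Fb)
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return -gain + float(beta @ (theta[:K] + theta[K:])), grad

    theta0 = np.zeros(2 * K)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * K),
                   options={"maxiter": 500, "ftol": tol, "gtol": 1e-7})
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        raise RuntimeError(f"maxent-like solver did not converge: {res.message} "
                           f"(gradient norm {np.linalg.norm(res.jac):.3g})")
    lam = res.x[:K] - res.x[K:]
    eta_b = Fb @ lam
    gain = float(fp_mean @ lam - (logsumexp(eta_b) - np.log(len(Fb))))

    def _predict(X: np.ndarray) -> np.ndarray:
        return expit(_maxent_features(X, mean, sd, quadratic) @ lam)

    return SDMModel("maxent_like", list(table.variable_names), table.variable_ranges,
                    ("gain", gain), _predict,
                    parameters={"lambda": lam, "features": features,
                                "reg_multiplier": reg_multiplier,
                                "standardize_mean": mean, "standardize_sd": sd})


FITTERS: dict[str, Callable[..., SDMModel]] = {
    "glm_poly": fit_glm,
    "random_forest": fit_rf,
    "maxent_like": fit_maxent_like,
}


# ---------------------------------------------------------------------------
# Projection & evaluation
# ---------------------------------------------------------------------------

def project(model: SDMModel, stack: ClimateStack, clamp: bool = True) -> SuitabilityMap:
    """Project a fitted model over a scenario's grid.

    With ``clamp=True`` (default for any cross-scenario transfer) each
    variable is truncated to its training range before prediction, so
    out-of-range cells receive the range-edge response. Nodata cells stay
    nodata.
    """
    missing = [n for n in model.variable_names if n not in stack.variables]
    if missing:
        raise ValueError(f"stack is missing model variables: {missing}")
    ok = ~stack.nodata_mask
    X = np.column_stack([stack.variables[n][ok] for n in model.variable_names])
    values = np.zeros(stack.shape)
    values[ok] = model.predict(X, clamp=clamp)
    return SuitabilityMap(values, stack.cell_size, stack.origin,
                          stack.nodata_mask.copy(),
                          model_id=f"{model.algorithm}@{stack.scenario_id}")


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class EvalReport:
    """Internal (bootstrap) and external (independent-presence) AUC results."""

    auc_internal_mean: float
    auc_internal_sd: float
    auc_external: dict[str, float] = field(default_factory=dict)
    n_iterations: int = 20
    test_fraction: float = 0.4

    def __post_init__(self) -> None:
        for v in [self.auc_internal_mean, *self.auc_external.values()]:
            if not (0.0 <= v <= 1.0):
                raise ValueError("AUC outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "auc_internal_mean": self.auc_internal_mean,
            "auc_internal_sd": self.auc_internal_sd,
            "auc_external": dict(self.auc_external),
            "n_iterations": self.n_iterations,
            "test_fraction": self.test_fraction,
        }


def bootstrap_validate(fit: Callable[[TrainingTable], SDMModel], table: TrainingTable,
                       iterations: int = 20, test_fraction: float = 0.4,
                       seed: int = 0) -> EvalReport:
    """Iterative data partitioning: stratified random test/train splits,
    refit on train, AUC on test; reports mean and SD over iterations."""
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(table.y == 1)
    neg_idx = np.flatnonzero(table.y == 0)
    n_pos_test = int(round(test_fraction * pos_idx.size))
    n_neg_test = int(round(test_fraction * neg_idx.size))
    if min(n_pos_test, n_neg_test) < 1 or (pos_idx.size - n_pos_test) < 1 \
            or (neg_idx.size - n_neg_test) < 1:
        raise ValueError("not enough rows for a stratified split at this test fraction")
    aucs = []
    for _ in range(iterations):
        pos_test = rng.choice(pos_idx, size=n_pos_test, replace=False)
        neg_test = rng.choice(neg_idx, size=n_neg_test, replace=False)
        test = np.zeros(len(table.y), dtype=bool)
        test[pos_test] = True
        test[neg_test] = True
        model = fit(table.subset(~test))
        scores = model.predict(table.X[test], clamp=False)
        y_test = table.y[test]
        aucs.append(auc(scores[y_test == 1], scores[y_test == 0]))
    return EvalReport(float(np.mean(aucs)), float(np.std(aucs, ddof=1)),
                      n_iterations=iterations, test_fraction=test_fraction)


def external_validate(suit: SuitabilityMap, independent_presences: OccurrenceSet,
                      contrast: OccurrenceSet) -> float:
    """AUC of map values at independent presences vs a contrast sample."""
    px, py = independent_presences.xy
    cx, cy = contrast.xy
    return auc(suit.values_at_points(px, py), suit.values_at_points(cx, cy))


# ---------------------------------------------------------------------------
# MESS / MoD
# ---------------------------------------------------------------------------

@dataclass
class MessResult:
    """Multivariate environmental similarity surface and MoD map."""

    mess: np.ndarray                      # percent-similarity; negative = novel
    mod: np.ndarray                       # int index into variable_names (-1 = nodata)
    variable_names: list[str]
    nodata_mask: np.ndarray

    def mod_labels(self) -> np.ndarray:
        out = np.full(self.mod.shape, "", dtype=object)
        for j, name in enumerate(self.variable_names):
            out[self.mod == j] = name
        return out


def _mess_similarity(v: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Per-cell similarity for one variable given sorted reference values."""
    N = ref_sorted.size
    vmin, vmax = ref_sorted[0], ref_sorted[-1]
    span = vmax - vmin
    f = 100.0 * np.searchsorted(ref_sorted, v, side="left") / N
    s = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
    s = np.where(f == 0.0, 100.0 * (v - vmin) / span, s)
    s = np.where(f == 100.0, 100.0 * (vmax - v) / span, s)
    return s


def mess(stack: ClimateStack, reference: TrainingTable) -> MessResult:
    """MESS similarity (min over variables) and the most-dissimilar variable.

    For each cell and variable, with f the percentage of reference values
    below the projected value: s = 100*(v-min)/(max-min) when f = 0,
    s = 2f when f <= 50, s = 2(100-f) when f >= 50, and
    s = 100*(max-v)/(max-min) when f = 100. Negative similarity flags
    climates outside the calibrated range. Ties in the minimizing variable
    go to the first variable in stack order; constant reference variables
    are excluded with a warning.
    """
    names = [n for n in reference.variable_names if n in stack.variables]
    if len(names) != len(reference.variable_names):
        missing = set(reference.variable_names) - set(names)
        raise ValueError(f"stack is missing reference variables: {missing}")
    ok = ~stack.nodata_mask
    usable: list[str] = []
    sims: list[np.ndarray] = []
    for j, name in enumerate(names):
        ref = np.sort(reference.X[:, j])
        if ref[0] == ref[-1]:
            logger.warning("mess: reference variable %s is constant; excluded", name)
            continue
        usable.append(name)
        sims.append(_mess_similarity(stack.variables[name][ok], ref))
    if not usable:
        raise ValueError("no usable (non-constant) reference variables")
    S = np.vstack(sims)                    # (k, n_unmasked)
    mess_grid = np.full(stack.shape, np.nan)
    mod_grid = np.full(stack.shape, -1, dtype=int)
    mess_grid[ok] = S.min(axis=0)
    mod_grid[ok] = S.argmin(axis=0)        # argmin returns first index on ties
    return MessResult(mess_grid, mod_grid, usable, stack.nodata_mask.copy())
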