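"""Niche comparisons in a shared two-axis environmental space.

The framework (after Broennimann-style gridded niche analysis):

1. a single PCA is fitted to the pooled climates of *all* scenarios, so every
   entity is scored in one common two-dimensional environmental space;
2. for each entity an R x R grid over the shared score extent holds a kernel
   density of its occurrences (``o``), a kernel density of its available
   environment (``e``) and the occupancy ``z`` — the ratio o/e where the
   environment exists, rescaled to a maximum of 1, which corrects apparent
   occupancy for how much of each climate was available;
3. niches are compared by Schoener's D = 1 - 0.5 * sum |p_a - p_b| on the
   normalized occupancy, by randomization tests of niche equivalency
   (pool-and-reassign occurrences) and niche similarity (random occurrences
   drawn from the available environment), and by the expansion / stability /
   unfilling decomposition within analogous climates.

Densities use a binned Gaussian kernel estimate: scores are histogrammed on
the grid and smoothed with a Gaussian filter whose per-axis bandwidth comes
from Scott's plug-in rule h_j = sigma_j * n^(-1/6). The kernel is truncated
at four bandwidths, so cells far from any data are exactly zero and niche
membership (z > 0) is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .geodata import ClimateStack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Global PCA
# ---------------------------------------------------------------------------

@dataclass
class PCASpace:
    """Two-axis environmental ordination shared by all scenarios."""

    loadings: np.ndarray          # (k, 2), orthonormal columns
    center: np.ndarray            # pooled mean per variable
    scale: np.ndarray             # pooled SD per variable
    variance_fraction: np.ndarray  # (2,), each axis' share of total variance
    variable_names: list[str]

    def transform(self, env: np.ndarray) -> np.ndarray:
        """Project environment rows (columns = variable_names) to PC scores."""
        Z = (np.asarray(env, float) - self.center) / self.scale
        return Z @ self.loadings


def fit_global_pca(stacks: Sequence[ClimateStack]) -> PCASpace:
    """PCA of the pooled, standardized cells of all scenario stacks.

    Variables are centered and scaled by the pooled mean/SD (so the PCA is
    on the pooled correlation structure); the first two axes are kept with
    a deterministic sign convention (largest-magnitude loading positive).
    """
    if not stacks:
        raise ValueError("need at least one stack")
    names = [n for n in stacks[0].variable_names
             if all(n in s.variables for s in stacks)]
    if len(names) < 2:
        raise ValueError("need >= 2 variables shared by all stacks")
    pooled = np.vstack([s.env_table(names) for s in stacks])
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=0)
    if (scale == 0).any():
        bad = [names[j] for j in np.flatnonzero(scale == 0)]
        raise ValueError(f"constant variables in pooled climate: {bad}")
    Z = (pooled - center) / scale
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()          # (k, 2)
    for axis in range(2):
        j = int(np.argmax(np.abs(loadings[:, axis])))
        if loadings[j, axis] < 0:
            loadings[:, axis] *= -1
    return PCASpace(loadings, center, scale,
                    pca.explained_variance_ratio_.copy(), names)


# ---------------------------------------------------------------------------
# Kernel occupancy grids
# ---------------------------------------------------------------------------

@dataclass
class NicheGrid:
    """R x R environmental-space grid of occurrence density, environment
    density and corrected occupancy."""

    extent: np.ndarray            # (2, 2): per-axis (min, max)
    o: np.ndarray                 # occurrence kernel density, sums to 1
    e: np.ndarray                 # environment kernel density, sums to 1
    z: np.ndarray                 # occupancy in [0, 1]
    entity_id: str = "entity"
    scenario_id: str = "scenario"
    bandwidth: np.ndarray | None = None

    @property
    def resolution(self) -> int:
        return self.o.shape[0]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-axis arrays of grid-cell center coordinates."""
        (x0, x1), (y0, y1) = self.extent
        R = self.resolution
        gx = x0 + (np.arange(R) + 0.5) * (x1 - x0) / R
        gy = y0 + (np.arange(R) + 0.5) * (y1 - y0) / R
        return gx, gy


def shared_extent(score_sets: Sequence[np.ndarray], pad: float = 0.05) -> np.ndarray:
    """Per-axis (min, max) covering all score sets, padded by ``pad``."""
    allscores = np.vstack(score_sets)
    lo = allscores.min(axis=0)
    hi = allscores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.column_stack([lo - pad * span, hi + pad * span])


def scott_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Per-axis plug-in bandwidth h_j = sigma_j * n^(-1/6) (2-D Scott rule)."""
    scores = np.atleast_2d(scores)
    n = len(scores)
    sd = scores.std(axis=0, ddof=1) if n > 1 else np.ones(scores.shape[1])
    sd = np.where(sd > 0, sd, 1e-6)
    return sd * n ** (-1.0 / 6.0)


def kernel_density_grid(scores: np.ndarray, extent: np.ndarray, resolution: int,
                        bandwidth: np.ndarray) -> np.ndarray:
    """Binned Gaussian KDE on the grid, normalized to sum to 1.

    The Gaussian kernel is truncated at 4 bandwidths, so the density has
    compact support (exact zeros away from the data).
    """
    (x0, x1), (y0, y1) = extent
    hist, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=resolution,
                                range=[[x0, x1], [y0, y1]])
    cell = np.array([(x1 - x0) / resolution, (y1 - y0) / resolution])
    sigma_cells = np.maximum(bandwidth / cell, 1e-12)
    dens = ndimage.gaussian_filter(hist, sigma=sigma_cells, mode="constant",
                                   truncate=4.0)
    dens[dens < 0] = 0.0
    total = dens.sum()
    return dens / total if total > 0 else dens


def grid_from_scores(occ_scores: np.ndarray, bg_scores: np.ndarray,
                     extent: np.ndarray, resolution: int = 100,
                     bandwidth: np.ndarray | None = None,
                     e_density: np.ndarray | None = None,
                     entity_id: str = "entity",
                     scenario_id: str = "scenario") -> NicheGrid:
    """Build a niche grid directly from PC scores.

    ``bandwidth`` (applied to the occurrence density) defaults to the Scott
    rule on the occurrence scores; pass it explicitly to hold the kernel
    fixed across randomization replicates. ``e_density`` short-circuits the
    environment KDE when the background does not change between replicates.
    """
    if len(occ_scores) < 1:
        raise ValueError("need at least one occurrence score")
    bw = bandwidth if bandwidth is not None else scott_bandwidth(occ_scores)
    o = kernel_density_grid(np.atleast_2d(occ_scores), extent, resolution, bw)
    if e_density is None:
        e_density = kernel_density_grid(np.atleast_2d(bg_scores), extent,
                                        resolution, scott_bandwidth(bg_scores))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e_density > 0, o / e_density, 0.0)
    zmax = z.max()
    if zmax > 0:
        z = z / zmax
    return NicheGrid(np.asarray(extent, float), o, e_density, z,
                     entity_id, scenario_id, bandwidth=bw)


def build_niche_grid(pca: PCASpace, occ, stack: ClimateStack,
                     background_env: np.ndarray | None = None,
                     extent: np.ndarray | None = None, resolution: int = 100,
                     bandwidth: np.ndarray | None = None,
                     entity_id: str = "entity") -> NicheGrid:
    """Niche grid for an occurrence set against its scenario's environment.

    ``background_env`` defaults to every unmasked cell of the stack; pass a
    subsample for speed. The extent defaults to the background scores padded
    by 5% — for cross-entity comparisons compute a shared extent first and
    pass it to every entity.
    """
    x, y = occ.xy
    if len(x) < 5:
        raise ValueError("need at least 5 occurrences")
    occ_env = stack.env_at_points(x, y, pca.variable_names)
    if background_env is None:
        background_env = stack.env_table(pca.variable_names)
    occ_scores = pca.transform(occ_env)
    bg_scores = pca.transform(background_env)
    if extent is None:
        extent = shared_extent([bg_scores])
    return grid_from_scores(occ_scores, bg_scores, extent, resolution, bandwidth,
                            entity_id=entity_id, scenario_id=stack.scenario_id)


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------

def schoener_d(a: NicheGrid, b: NicheGrid, corrected: bool = True) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_a - p_b|, in [0, 1].

    ``corrected`` compares occupancies z (occurrence density corrected for
    environmental availability); uncorrected compares the raw occurrence
    densities o. Symmetric; 1 for identical niches, 0 for disjoint ones.
    """
    if a.o.shape != b.o.shape or not np.allclose(a.extent, b.extent):
        raise ValueError("grids differ in extent or resolution")
    pa = a.z if corrected else a.o
    pb = b.z if corrected else b.o
    sa, sb = pa.sum(), pb.sum()
    if sa == 0 and sb == 0:
        raise ValueError("both grids have zero total density")
    if sa == 0 or sb == 0:
        # one niche has no occupancy inside its available environment
        # (possible under corrected mode when the compact kernel supports of
        # o and e are disjoint): no overlap by definition
        return 0.0
    if not np.any((pa > 0) & (pb > 0)):
        return 0.0  # disjoint supports: exactly no overlap
    d = 1.0 - 0.5 * np.abs(pa / sa - pb / sb).sum()
    return float(min(max(d, 0.0), 1.0))


@dataclass
class OverlapReport:
    """Machine twin of a niche-overlap table row for one scenario pair."""

    entity_a: str
    entity_b: str
    D: float
    equivalency_p: float | None = None
    similarity_p_AtoB: float | None = None
    similarity_p_BtoA: float | None = None
    expansion: float | None = None
    stability: float | None = None
    unfilling: float | None = None
    n_replicates: int = 0
    occ_centroid_shift: tuple[float, float] | None = None
    env_centroid_shift: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0):
            raise ValueError("D outside [0, 1]")
        for p in (self.equivalency_p, self.similarity_p_AtoB, self.similarity_p_BtoA):
            if p is not None and not (0.0 < p <= 1.0):
                raise ValueError("p-values must lie in (0, 1]")
        if self.expansion is not None and self.stability is not None:
            if abs(self.expansion + self.stability - 1.0) > 1e-9:
                raise ValueError("expansion + stability must equal 1")

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# Randomization tests
# ---------------------------------------------------------------------------

def equivalency_test(a_occ_env: np.ndarray, b_occ_env: np.ndarray,
                     a_bg_env: np.ndarray, b_bg_env: np.ndarray,
                     pca: PCASpace, replicates: int = 100, seed: int = 0,
                     resolution: int = 100,
                     corrected: bool = True) -> tuple[float, float, np.ndarray]:
    """Niche equivalency randomization test.

    Pools the two occurrence sets, reassigns them at random to groups of the
    original sizes, rebuilds both niche grids against their fixed respective
    backgrounds and recomputes D. One-sided lower:
    p = (1 + #{D_null <= D_obs}) / (replicates + 1); small p means the
    observed overlap is less than expected were the niches identical.

    Returns (observed D, p, null distribution). Kernel bandwidths are
    computed from the observed occurrence sets and held fixed across
    replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sa = pca.transform(a_occ_env)
    sb = pca.transform(b_occ_env)
    bga = pca.transform(a_bg_env)
    bgb = pca.transform(b_bg_env)
    extent = shared_extent([bga, bgb])
    bw_a, bw_b = scott_bandwidth(sa), scott_bandwidth(sb)
    e_a = kernel_density_grid(bga, extent, resolution, scott_bandwidth(bga))
    e_b = kernel_density_grid(bgb, extent, resolution, scott_bandwidth(bgb))

    def _pair_d(scores_a, scores_b) -> float:
        ga = grid_from_scores(scores_a, bga, extent, resolution, bw_a, e_density=e_a)
        gb = grid_from_scores(scores_b, bgb, extent, resolution, bw_b, e_density=e_b)
        return schoener_d(ga, gb, corrected=corrected)

    d_obs = _pair_d(sa, sb)
    pooled = np.vstack([sa, sb])
    na = len(sa)
    null = np.empty(replicates)
    for i in range(replicates):
        perm = rng.permutation(len(pooled))
        null[i] = _pair_d(pooled[perm[:na]], pooled[perm[na:]])
    p = (1.0 + np.sum(null <= d_obs)) / (replicates + 1.0)
    return d_obs, float(p), null


def similarity_test(a_grid: NicheGrid, b_occ_env: np.ndarray,
                    b_bg_env: np.ndarray, pca: PCASpace,
                    replicates: int = 100, seed: int = 0,
                    alternative: str = "greater",
                    null_model: str = "random-points",
                    corrected: bool = True) -> tuple[float, float, np.ndarray]:
    """Niche similarity randomization test (one direction).

    The focal niche ``a_grid`` is compared to niches built from ``b``'s
    occurrences; each replicate replaces them with |b_occ| random draws from
    b's available environment (``random-points`` null; the ``shift`` variant
    instead translates the observed occurrence cloud to a random centroid
    within the background envelope). With alternative "greater",
    p = (1 + #{D_null >= D_obs}) / (replicates + 1): small p means the two
    niches are *more* similar than expected from the available environments.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    sb = pca.transform(b_occ_env)
    bgb = pca.transform(b_bg_env)
    extent = a_grid.extent
    resolution = a_grid.resolution
    nb = len(sb)
    if null_model == "random-points" and nb > len(bgb):
        raise ValueError(f"|b_occ| = {nb} exceeds the {len(bgb)} available "
                         "background cells")
    bw_b = scott_bandwidth(sb)
    e_b = kernel_density_grid(bgb, extent, resolution, scott_bandwidth(bgb))

    def _d(scores_b) -> float:
        gb = grid_from_scores(scores_b, bgb, extent, resolution, bw_b, e_density=e_b)
        return schoener_d(a_grid, gb, corrected=corrected)

    d_obs = _d(sb)
    null = np.empty(replicates)
    for i in range(replicates):
        if null_model == "random-points":
            idx = rng.choice(len(bgb), size=nb, replace=False)
            null[i] = _d(bgb[idx])
        elif null_model == "shift":
            target = bgb[rng.integers(len(bgb))]
            null[i] = _d(sb - sb.mean(axis=0) + target)
        else:
            raise ValueError(f"unknown null model {null_model!r}")
    if alternative == "greater":
        p = (1.0 + np.sum(null >= d_obs)) / (replicates + 1.0)
    else:
        p = (1.0 + np.sum(null <= d_obs)) / (replicates + 1.0)
    return d_obs, float(p), null


# ---------------------------------------------------------------------------
# Niche dynamics & centroids
# ---------------------------------------------------------------------------

def niche_dynamics(current: NicheGrid, paleo: NicheGrid,
                   analog_quantile: float = 0.0) -> tuple[float, float, float]:
    """Expansion / stability / unfilling within analogous environments.

    Analogue cells are those where both environments are available (both e
    above the ``analog_quantile`` quantile of their positive values; the
    default 0 means simply e > 0). Within analogues, expansion is the
    z-weighted fraction of the paleo niche outside the current niche,
    stability its complement (the two sum to 1 exactly), and unfilling the
    mirror-image fraction of the current niche outside the paleo niche.
    """
    if current.o.shape != paleo.o.shape or not np.allclose(current.extent, paleo.extent):
        raise ValueError("grids differ in extent or resolution")

    def _thresh(e: np.ndarray) -> float:
        pos = e[e > 0]
        if pos.size == 0:
            return np.inf
        return 0.0 if analog_quantile <= 0 else float(np.quantile(pos, analog_quantile))

    analogue = (current.e > _thresh(current.e)) & (paleo.e > _thresh(paleo.e))
    if not analogue.any():
        raise ValueError("empty analogue region: the environments do not overlap")
    cur_member = current.z > 0
    pal_member = paleo.z > 0

    pal_in = pal_member & analogue
    denom_p = paleo.z[pal_in].sum()
    if denom_p == 0:
        raise ValueError("paleo niche has no mass inside the analogue region")
    expansion = paleo.z[pal_in & ~cur_member].sum() / denom_p
    stability = 1.0 - expansion

    cur_in = cur_member & analogue
    denom_c = current.z[cur_in].sum()
    if denom_c == 0:
        raise ValueError("current niche has no mass inside the analogue region")
    unfilling = current.z[cur_in & ~pal_member].sum() / denom_c
    return float(expansion), float(stability), float(unfilling)


def centroid_shift(a: NicheGrid, b: NicheGrid) -> tuple[np.ndarray, np.ndarray]:
    """Density-weighted centroid shifts (b minus a) for occurrences and
    environments, as 2-vectors in PC units."""
    if not np.allclose(a.extent, b.extent) or a.o.shape != b.o.shape:
        raise ValueError("grids differ in extent or resolution")

    def _centroid(dens: np.ndarray, grid: NicheGrid) -> np.ndarray:
        total = dens.sum()
        if total <= 0:
            raise ValueError("zero total density")
        gx, gy = grid.cell_centers()
        return np.array([(dens.sum(axis=1) @ gx) / total,
                         (dens.sum(axis=0) @ gy) / total])

    occ_shift = _centroid(b.o, b) - _centroid(a.o, a)
    env_shift = _centroid(b.e, b) - _centroid(a.e, a)
    return occ_shift, env_shift
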