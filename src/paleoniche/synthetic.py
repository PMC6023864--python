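"""Synthetic climate scenarios and species occurrences with known niche truth.

The generator stands in for real bioclimatic raster stacks and occurrence /
fossil databases so every downstream stage (variable selection, SDM fitting,
transferability, environmental-space overlap) can be tested against a known
ground truth:

* climate fields are spatially autocorrelated Gaussian random fields with a
  user-imposed cross-correlation structure between variables, built by
  low-pass filtering seeded white noise and mixing through a Cholesky factor;
* a paleo scenario is the current scenario plus a per-variable affine shift
  (e.g. warmer by 3.8 degrees, precipitation scaled by 0.84, mimicking a
  last-interglacial contrast);
* the species responds to climate through a Gaussian niche with a known
  optimum and tolerance, and occurrences ("current" or "fossil") are drawn
  without replacement with probability proportional to true suitability.

All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geodata import ClimateStack, OccurrenceSet, SuitabilityMap

DEFAULT_VARIABLES = ("bio4", "bio8", "bio9", "bio18", "bio19")


@dataclass
class ScenarioConfig:
    """Recipe for one synthetic climate scenario."""

    grid_rows: int = 120
    grid_cols: int = 120
    variable_names: tuple[str, ...] = DEFAULT_VARIABLES
    autocorr_length: float = 6.0
    cross_correlation: np.ndarray | None = None
    variable_means: np.ndarray | None = None
    variable_sds: np.ndarray | None = None
    seed: int = 0
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        k = len(self.variable_names)
        if self.grid_rows * self.grid_cols < 100:
            raise ValueError("grid must have at least 100 cells")
        if self.autocorr_length < 0:
            raise ValueError("autocorr_length must be >= 0")
        if self.cross_correlation is None:
            self.cross_correlation = np.eye(k)
        self.cross_correlation = np.asarray(self.cross_correlation, dtype=float)
        C = self.cross_correlation
        if C.shape != (k, k):
            raise ValueError(f"cross_correlation must be {k}x{k}")
        if not np.allclose(C, C.T):
            raise ValueError("cross_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("cross_correlation must have unit diagonal")
        eig = np.linalg.eigvalsh(C)
        if eig.min() < -1e-10:
            raise ValueError(
                f"cross_correlation is not positive semi-definite (min eigenvalue {eig.min():.3g})")
        if self.variable_means is None:
            self.variable_means = np.zeros(k)
        if self.variable_sds is None:
            self.variable_sds = np.ones(k)
        self.variable_means = np.asarray(self.variable_means, dtype=float)
        self.variable_sds = np.asarray(self.variable_sds, dtype=float)
        if len(self.variable_means) != k or len(self.variable_sds) != k:
            raise ValueError("variable_means / variable_sds length mismatch")


@dataclass
class NicheTruth:
    """Gaussian niche-response ground truth, one optimum/tolerance per variable."""

    optimum: np.ndarray
    tolerance: np.ndarray
    max_prevalence: float = 1.0

    def __post_init__(self) -> None:
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.tolerance = np.asarray(self.tolerance, dtype=float)
        if len(self.optimum) != len(self.tolerance):
            raise ValueError("optimum and tolerance lengths differ")
        if (self.tolerance <= 0).any():
            raise ValueError("tolerance must be strictly positive")
        if not (0 < self.max_prevalence <= 1):
            raise ValueError("max_prevalence must be in (0, 1]")

    def shifted(self, delta: Sequence[float]) -> "NicheTruth":
        """A copy with the optimum moved by ``delta`` (a true niche shift)."""
        return NicheTruth(self.optimum + np.asarray(delta, float),
                          self.tolerance.copy(), self.max_prevalence)


@dataclass
class ShiftSpec:
    """Scenario-to-scenario affine climate offset: value' = value*factor + offset."""

    additive_offset: np.ndarray
    multiplicative_factor: np.ndarray

    def __post_init__(self) -> None:
        self.additive_offset = np.asarray(self.additive_offset, dtype=float)
        self.multiplicative_factor = np.asarray(self.multiplicative_factor, dtype=float)
        if len(self.additive_offset) != len(self.multiplicative_factor):
            raise ValueError("offset and factor lengths differ")
        if (self.multiplicative_factor <= 0).any():
            raise ValueError("multiplicative factors must be positive")


def _smooth_field(white: np.ndarray, autocorr_length: float) -> np.ndarray:
    """Low-pass filter white noise and restandardize to unit variance."""
    if autocorr_length <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=autocorr_length, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def generate_climate_stack(config: ScenarioConfig) -> ClimateStack:
    """Generate one scenario's stack of cross-correlated random climate fields.

    Independent smoothed unit-variance fields are linearly mixed through the
    Cholesky factor of ``cross_correlation`` (eigendecomposition fallback for
    singular matrices), then scaled to the per-variable mean/SD.
    """
    k = len(config.variable_names)
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    base = np.stack([_smooth_field(rng.standard_normal(shape), config.autocorr_length)
                     for _ in range(k)])
    C = config.cross_correlation
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(C)
        L = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    mixed = np.tensordot(L, base, axes=(1, 0))
    variables = {
        name: config.variable_means[j] + config.variable_sds[j] * mixed[j]
        for j, name in enumerate(config.variable_names)
    }
    return ClimateStack(variables, cell_size=1.0, origin=(0.0, 0.0),
                        scenario_id=config.scenario_id)


def shift_scenario(stack: ClimateStack, spec: ShiftSpec,
                   scenario_id: str | None = None) -> ClimateStack:
    """Apply a per-variable affine climate offset; geometry is unchanged."""
    if len(spec.additive_offset) != len(stack.variable_names):
        raise ValueError(
            f"shift spec length {len(spec.additive_offset)} != "
            f"{len(stack.variable_names)} stack variables")
    variables = {
        name: stack.variables[name] * spec.multiplicative_factor[j] + spec.additive_offset[j]
        for j, name in enumerate(stack.variable_names)
    }
    return ClimateStack(variables, stack.cell_size, stack.origin,
                        stack.nodata_mask.copy(),
                        scenario_id or f"{stack.scenario_id}_shifted")


def true_suitability(stack: ClimateStack, niche: NicheTruth) -> SuitabilityMap:
    """Gaussian niche response s(x) = max_prev * exp(-0.5 sum ((x-mu)/sigma)^2)."""
    if len(niche.optimum) != len(stack.variable_names):
        raise ValueError("niche dimensions do not match stack variables")
    q = np.zeros(stack.shape)
    for j, name in enumerate(stack.variable_names):
        q += ((stack.variables[name] - niche.optimum[j]) / niche.tolerance[j]) ** 2
    s = niche.max_prevalence * np.exp(-0.5 * q)
    s[stack.nodata_mask] = 0.0
    return SuitabilityMap(s, stack.cell_size, stack.origin, stack.nodata_mask.copy(),
                          model_id="truth")


def sample_occurrences(suit: SuitabilityMap, n: int, seed: int,
                       role: str = "presence", period: str = "current") -> OccurrenceSet:
    """Sample ``n`` distinct cells with probability proportional to suitability.

    Cells with zero suitability (or nodata) are never sampled; returned
    coordinates are cell centers.
    """
    weights = suit.values.ravel().astype(float).copy()
    weights[suit.nodata_mask.ravel()] = 0.0
    positive = np.flatnonzero(weights > 0)
    if n > positive.size:
        raise ValueError(f"requested {n} occurrences but only {positive.size} "
                         "cells have positive suitability")
    rng = np.random.default_rng(seed)
    p = weights[positive] / weights[positive].sum()
    chosen = rng.choice(positive, size=n, replace=False, p=p)
    helper = ClimateStack({"v": suit.values}, suit.cell_size, suit.origin,
                          suit.nodata_mask)
    x, y = helper.cell_centers(chosen)
    import pandas as pd

    return OccurrenceSet(pd.DataFrame({"x": x, "y": y, "role": role, "period": period}))


def mis5e_like_shift(variable_names: Sequence[str],
                     temperature_offset: float = 3.8,
                     precipitation_factor: float = 0.84) -> ShiftSpec:
    """Convenience preset: warm the temperature variables and dry the
    precipitation variables, a last-interglacial-style contrast (about +3.8
    units of temperature, -16% precipitation).

    Variables named bio4/bio8/bio9 (and anything matching bio1-bio11) are
    treated as temperature, bio12-bio19 as precipitation.
    """
    temp = {f"bio{i}" for i in range(1, 12)}
    offset, factor = [], []
    for name in variable_names:
        if name in temp:
            offset.append(temperature_offset)
            factor.append(1.0)
        else:
            offset.append(0.0)
            factor.append(precipitation_factor)
    return ShiftSpec(np.array(offset), np.array(factor))
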