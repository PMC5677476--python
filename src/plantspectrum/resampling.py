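"""Environment-mixing resampling null for trait-pair correlations.

Intraspecific trait responses to the environment can run in opposite
directions for different organs (e.g. LMA drops in shade while wood and
root tissue densities rise).  When species are sampled haphazardly across
environments, such divergent responses scatter points off the interspecific
axis and can mask an underlying correlation.  The resampling scheme makes
this concrete: each of B simulated datasets draws every species' trait pair
from either the standardized (greenhouse) or the field table with equal
probability — one coin per species per replicate, governing both traits,
because a species' phenotype comes from a single environment — and the
squared Pearson correlation of each mixed dataset is compared with the
observed R^2 in the standardized environment.  An observed R^2 at or above
the 95th quantile of the mixed distribution indicates that mixed-environment
sampling weakens that trait pair's correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, TraitMismatchError


@dataclass
class ResampleResult:
    trait_pair: tuple[str, str]
    observed_r2: float
    simulated_r2: np.ndarray
    quantile_position: float
    exceeds_95th: bool
    B: int
    seed: int
    species: list[str]
    degenerate: bool = False


def observed_quantile_position(observed: float, simulated) -> float:
    """Fraction of simulated values <= observed (ties count as covered)."""
    sim = np.asarray(simulated, dtype=float)
    if sim.size == 0:
        raise InsufficientDataError("empty simulated distribution")
    return float(np.mean(sim <= observed))


def _rowwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each row of x with the matching row of y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r**2


def resample_mixed_environments(
    greenhouse,
    field,
    trait_pair: tuple[str, str],
    B: int = 10_000,
    seed: int = 0,
    p_field: float = 0.5,
    independent_traits: bool = False,
) -> ResampleResult:
    """Simulate B mixed-environment datasets and place the observed R^2.

    ``greenhouse`` and ``field`` are TraitTables (or species x trait
    DataFrames) sharing a species set; the intersection of complete-case
    species for both traits in both tables is used throughout, so every
    replicate keeps the full species set and only the environment of origin
    varies.  The observed R^2 is computed on the greenhouse (standardized
    environment) table.  ``independent_traits=True`` draws a separate coin
    per trait (sensitivity mode, not the default behaviour).
    """
    tx, ty = trait_pair
    g = greenhouse.data if hasattr(greenhouse, "data") else greenhouse
    f = field.data if hasattr(field, "data") else field
    for name, table in (("greenhouse", g), ("field", f)):
        if tx not in table.columns or ty not in table.columns:
            raise TraitMismatchError(f"{name} table lacks trait pair {trait_pair}")
    shared = g[[tx, ty]].dropna().index.intersection(f[[tx, ty]].dropna().index)
    shared = sorted(shared)
    n = len(shared)
    if n < 5:
        raise InsufficientDataError(f"only {n} shared complete-case species (< 5)")
    if B < 100:
        warnings.warn(f"B={B} gives unstable quantile estimates")

    gx = g.loc[shared, tx].to_numpy(dtype=float)
    gy = g.loc[shared, ty].to_numpy(dtype=float)
    fx = f.loc[shared, tx].to_numpy(dtype=float)
    fy = f.loc[shared, ty].to_numpy(dtype=float)

    obs = _rowwise_r2(gx[None, :], gy[None, :])[0]

    rng = np.random.default_rng(seed)
    if independent_traits:
        take_fx = rng.random((B, n)) < p_field
        take_fy = rng.random((B, n)) < p_field
    else:
        take_fx = take_fy = rng.random((B, n)) < p_field
    x = np.where(take_fx, fx, gx)
    y = np.where(take_fy, fy, gy)
    sim = _rowwise_r2(x, y)

    qpos = observed_quantile_position(obs, sim)
    degenerate = float(sim.max() - sim.min()) < 1e-12
    exceeds = bool(qpos >= 0.95) and not degenerate
    if degenerate:
        warnings.warn("simulated R^2 distribution is degenerate (identical environments?)")
    return ResampleResult(
        trait_pair=(tx, ty), observed_r2=float(obs), simulated_r2=sim,
        quantile_position=qpos, exceeds_95th=exceeds, B=B, seed=seed,
        species=list(shared), degenerate=degenerate,
    )
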