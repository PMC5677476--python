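"""Random-effects meta-analysis of site-level trait-growth correlations.

Growth rates of wild plants are measured across sites that differ in
climate, light and species composition, so a single pooled correlation over
all individuals would confound inherent species differences with site
effects.  Instead a Pearson correlation is computed within each site
(species as replicates), Fisher z-transformed (z = atanh r, within-site
variance 1/(n-3)), and pooled across sites with site as a random effect
using the DerSimonian-Laird between-site variance estimator — the default
behaviour of conventional correlation meta-analysis tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

Z_CLIP = 0.9999  # |r| numerically 1 is nudged inside the open interval


def fisher_z(r: float) -> float:
    """Fisher z transform, z = atanh(r); requires |r| < 1."""
    if abs(r) >= 1.0:
        raise ValueError("Fisher z is undefined at |r| >= 1")
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    return float(np.tanh(z))


@dataclass
class SiteCorrelation:
    """One site's trait-growth correlation with its Fisher-z precision."""

    site: str
    trait: str
    growth_measure: str
    r: float
    n: int
    z: float
    v: float


def site_correlation(
    site: str, trait: str, growth_measure: str, r: float, n: int
) -> SiteCorrelation:
    """Build a SiteCorrelation, enforcing n >= 4 and |r| < 1.

    An |r| that is numerically 1 (degenerate but possible at tiny n) is
    nudged to +/-0.9999 with a warning rather than dropped.
    """
    if n < 4:
        raise InsufficientDataError(
            f"site {site!r} has n={n} < 4 species; z-variance 1/(n-3) undefined"
        )
    if abs(r) >= 1.0:
        warnings.warn(f"site {site!r} correlation |r|>=1 nudged to +/-{Z_CLIP}")
        r = float(np.sign(r)) * Z_CLIP
    return SiteCorrelation(
        site=site, trait=trait, growth_measure=growth_measure,
        r=float(r), n=int(n), z=fisher_z(r), v=1.0 / (n - 3),
    )


@dataclass
class MetaResult:
    pooled_z: float
    pooled_r: float
    ci95: tuple[float, float]       # on the r scale
    tau_squared: float
    Q: float
    k: int
    no_pooling: bool = False


def dl_random_effects_pool(sites: list[SiteCorrelation]) -> MetaResult:
    """DerSimonian-Laird random-effects pool of Fisher-z correlations.

    Fixed-effect weights w_i = 1/v_i give the heterogeneity statistic
    Q = sum w_i (z_i - z_fixed)^2; the between-site variance is
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v_i + tau^2) give the pooled z and its 95% CI
    z +/- 1.96/sqrt(sum w*), all back-transformed to the r scale.
    """
    k = len(sites)
    if k == 0:
        raise InsufficientDataError("no sites to pool")
    z = np.array([s.z for s in sites])
    v = np.array([s.v for s in sites])
    if k == 1:
        se = float(np.sqrt(v[0]))
        ci = (inverse_fisher_z(z[0] - 1.96 * se), inverse_fisher_z(z[0] + 1.96 * se))
        return MetaResult(
            pooled_z=float(z[0]), pooled_r=inverse_fisher_z(z[0]), ci95=ci,
            tau_squared=0.0, Q=0.0, k=1, no_pooling=True,
        )
    w = 1.0 / v
    z_fixed = float(np.sum(w * z) / np.sum(w))
    Q = float(np.sum(w * (z - z_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_star = 1.0 / (v + tau2)
    pooled_z = float(np.sum(w_star * z) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    ci = (
        inverse_fisher_z(pooled_z - 1.96 * se),
        inverse_fisher_z(pooled_z + 1.96 * se),
    )
    return MetaResult(
        pooled_z=pooled_z, pooled_r=inverse_fisher_z(pooled_z), ci95=ci,
        tau_squared=tau2, Q=Q, k=k,
    )
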