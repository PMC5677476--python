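"""Tissue-trait derivation from raw organ measurements and growth-rate computation.

Seven economics traits are derived from individual-level organ measurements:

* leaves — leaf mass per area (LMA, g/m^2), leaf dry matter content (LDMC,
  dry/fresh mass fraction) and leaf tissue density (LTD, mg/mm^3, dry mass per
  fresh volume where fresh volume = area x thickness);
* stem wood — wood density (WD, mg/mm^3, dry mass over fresh cylinder volume)
  and wood dry matter content (WDMC);
* fine roots — root tissue density (RTD, mg/mm^3) and root dry matter content
  (RDMC).

Above-ground relative growth rate is computed from repeated stem height and
diameter measurements as ``RGR = (ln(d2^2 h2) - ln(d1^2 h1)) / (t2 - t1)``,
the log change per year of the stem volume index d^2 h (a linear proxy for
mass).  Because suppressed individuals drag species means down in closed
vegetation, the 95th percentile of RGR across individuals (RGR95) is used as
a maximum-realized-growth summary alongside the mean.

All functions accept scalars or numpy arrays; table-level helpers operate on
pandas DataFrames with one row per individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidIntervalError,
    InvalidMeasurementError,
    MissingAllometryError,
)

TRAIT_NAMES = ("LMA", "LTD", "LDMC", "WD", "WDMC", "RTD", "RDMC")

#: dry-matter-content traits are fractions in (0, 1]
DMC_TRAITS = ("LDMC", "WDMC", "RDMC")

#: column schema for the individual organ-measurement table
INDIVIDUAL_COLUMNS = (
    "species",
    "individual",
    "environment",
    "leaf_area_cm2",
    "leaf_thickness_mm",
    "leaf_fresh_g",
    "leaf_dry_g",
    "wood_length_mm",
    "wood_diam_a_mm",
    "wood_diam_b_mm",
    "wood_fresh_mg",
    "wood_dry_mg",
    "root_volume_mm3",
    "root_length_mm",
    "root_fresh_mg",
    "root_dry_mg",
)

#: column schema for the repeated stem-measurement (growth) table
GROWTH_COLUMNS = (
    "species",
    "individual",
    "site",
    "environment",
    "h1_cm",
    "d1_mm",
    "t1_yr",
    "h2_cm",
    "d2_mm",
    "t2_yr",
)


@dataclass
class TraitTable:
    """Species x trait matrix of mean trait values for one environment.

    ``data`` is indexed by species identifier with one column per trait.
    ``counts`` (same shape, optional) holds the replicate count behind each
    cell.  Missing trait values are NaN, never silently zero.
    """

    data: pd.DataFrame
    environment: str
    counts: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("trait table must have one row per species")


def _check_positive(name: str, *values) -> None:
    for v in values:
        if np.any(np.asarray(v) <= 0):
            raise InvalidMeasurementError(f"{name} must be strictly positive")


def _check_dry_le_fresh(dry, fresh, organ: str) -> None:
    dry = np.asarray(dry, dtype=float)
    fresh = np.asarray(fresh, dtype=float)
    if np.any(dry > fresh):
        raise InvalidMeasurementError(f"{organ} dry mass exceeds fresh mass")
    if np.any(dry == fresh):
        warnings.warn(
            f"{organ} dry mass equals fresh mass (dry matter content = 1)",
            stacklevel=3,
        )


def derive_leaf_traits(area_cm2, thickness_mm, fresh_g, dry_g):
    """Return (LMA g/m^2, LDMC fraction, LTD mg/mm^3) from leaf measurements.

    LMA = dry mass / fresh one-sided area; LDMC = dry/fresh mass; LTD = dry
    mass / fresh volume, with fresh volume = area x thickness.
    """
    _check_positive("leaf area", area_cm2)
    _check_positive("leaf thickness", thickness_mm)
    _check_positive("leaf mass", fresh_g, dry_g)
    _check_dry_le_fresh(dry_g, fresh_g, "leaf")
    area_cm2 = np.asarray(area_cm2, dtype=float)
    thickness_mm = np.asarray(thickness_mm, dtype=float)
    fresh_g = np.asarray(fresh_g, dtype=float)
    dry_g = np.asarray(dry_g, dtype=float)
    lma = dry_g / (area_cm2 * 1e-4)            # g per m^2
    ldmc = dry_g / fresh_g
    ltd = (dry_g * 1e3) / (area_cm2 * 1e2 * thickness_mm)  # mg per mm^3
    return lma, ldmc, ltd


def cylinder_volume_mm3(length_mm, diam_a_mm, diam_b_mm):
    """Fresh volume of a wood segment as an elliptical cylinder.

    The two orthogonal caliper diameters define the elliptical cross-section:
    V = pi * (a/2) * (b/2) * L.  With equal diameters this reduces to the
    circular cylinder.
    """
    _check_positive("wood dimensions", length_mm, diam_a_mm, diam_b_mm)
    length_mm = np.asarray(length_mm, dtype=float)
    return np.pi * (np.asarray(diam_a_mm, dtype=float) / 2.0) * (
        np.asarray(diam_b_mm, dtype=float) / 2.0
    ) * length_mm


def derive_wood_traits(length_mm, diam_a_mm, diam_b_mm, fresh_mg, dry_mg):
    """Return (WD mg/mm^3, WDMC fraction) from a wood-segment sample."""
    _check_positive("wood mass", fresh_mg, dry_mg)
    _check_dry_le_fresh(dry_mg, fresh_mg, "wood")
    volume = cylinder_volume_mm3(length_mm, diam_a_mm, diam_b_mm)
    dry_mg = np.asarray(dry_mg, dtype=float)
    wd = dry_mg / volume
    wdmc = dry_mg / np.asarray(fresh_mg, dtype=float)
    return wd, wdmc


def derive_root_traits(volume_mm3, fresh_mg, dry_mg):
    """Return (RTD mg/mm^3, RDMC fraction) from a fine-root sample."""
    _check_positive("root volume", volume_mm3)
    _check_positive("root mass", fresh_mg, dry_mg)
    _check_dry_le_fresh(dry_mg, fresh_mg, "root")
    dry_mg = np.asarray(dry_mg, dtype=float)
    rtd = dry_mg / np.asarray(volume_mm3, dtype=float)
    rdmc = dry_mg / np.asarray(fresh_mg, dtype=float)
    return rtd, rdmc


def compute_rgr(h1, d1, t1, h2, d2, t2):
    """Relative growth rate (per year) from two stem measurements.

    RGR = (ln(d2^2 h2) - ln(d1^2 h1)) / (t2 - t1).  Heights and diameters
    may be in any unit as long as both time points use the same units (the
    units cancel in the log difference).  Negative values are returned as-is;
    filtering is a separate, explicit step.
    """
    h1, d1, h2, d2 = (np.asarray(v, dtype=float) for v in (h1, d1, h2, d2))
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= t1):
        raise InvalidIntervalError("t2 must be strictly greater than t1")
    for name, v in (("height", h1), ("height", h2), ("diameter", d1), ("diameter", d2)):
        if np.any(v <= 0):
            raise InvalidMeasurementError(f"stem {name} must be positive")
    return (np.log(d2**2 * h2) - np.log(d1**2 * h1)) / (t2 - t1)


def add_rgr(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a growth-record table with an ``rgr`` column."""
    out = records.copy()
    out["rgr"] = compute_rgr(
        out["h1_cm"], out["d1_mm"], out["t1_yr"],
        out["h2_cm"], out["d2_mm"], out["t2_yr"],
    )
    return out


def apply_height_allometry(d_cm, a: float, b: float, elevation_adj: float = 1.0):
    """Estimate height (m) from diameter via a power-law allometry.

    ``height = a * d^b * elevation_adj``.  This is a generic pluggable form:
    species- and elevation-specific coefficients must be supplied by the
    caller; there is no default coefficient table.
    """
    if a is None or b is None:
        raise MissingAllometryError("allometry parameters (a, b) are required")
    _check_positive("diameter", d_cm)
    if a <= 0:
        raise InvalidMeasurementError("allometry coefficient a must be positive")
    if b == 0:
        warnings.warn("allometry exponent b = 0: height independent of diameter")
    return a * np.asarray(d_cm, dtype=float) ** b * elevation_adj


#: which negative-growth rule applies in each environment
DEFAULT_FILTER_RULES = {
    "cultivated": "juvenile",
    "wild_juvenile": "juvenile",
    "wild_mature": "mature",
}


def filter_growth_records(
    records: pd.DataFrame, rules: dict[str, str] | str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition growth records into (kept, dropped) by the negative-growth rules.

    Juvenile rule: drop records whose computed d^2 h growth is negative
    (d2^2 h2 < d1^2 h1).  Mature rule: drop records with negative diameter
    growth (d2 < d1); zero growth is kept under both rules.  ``rules`` maps
    environment label to "juvenile" or "mature" (a bare string applies one
    rule to everything); unlisted environments use the juvenile rule.
    """
    if records.empty:
        return records.copy(), records.copy()
    if rules is None:
        rules = DEFAULT_FILTER_RULES
    if isinstance(rules, str):
        rules = {env: rules for env in records["environment"].unique()}
    rule = records["environment"].map(lambda e: rules.get(e, "juvenile"))
    growth = (
        records["d2_mm"].to_numpy() ** 2 * records["h2_cm"].to_numpy()
        - records["d1_mm"].to_numpy() ** 2 * records["h1_cm"].to_numpy()
    )
    neg_diam = records["d2_mm"].to_numpy() < records["d1_mm"].to_numpy()
    drop = np.where(rule.to_numpy() == "mature", neg_diam, growth < 0)
    return records.loc[~drop].copy(), records.loc[drop].copy()


def derive_individual_traits(individuals: pd.DataFrame) -> pd.DataFrame:
    """Derive the seven traits for every row of an organ-measurement table.

    Returns a DataFrame with species / individual / environment plus one
    column per trait.  Rows with missing organ measurements get NaN for that
    organ's traits.
    """
    out = individuals[["species", "individual", "environment"]].copy()
    for trait in TRAIT_NAMES:
        out[trait] = np.nan

    leaf_ok = individuals[["leaf_area_cm2", "leaf_thickness_mm", "leaf_fresh_g", "leaf_dry_g"]].notna().all(axis=1)
    if leaf_ok.any():
        sub = individuals.loc[leaf_ok]
        lma, ldmc, ltd = derive_leaf_traits(
            sub["leaf_area_cm2"], sub["leaf_thickness_mm"], sub["leaf_fresh_g"], sub["leaf_dry_g"]
        )
        out.loc[leaf_ok, "LMA"] = lma
        out.loc[leaf_ok, "LDMC"] = ldmc
        out.loc[leaf_ok, "LTD"] = ltd

    wood_ok = individuals[["wood_length_mm", "wood_diam_a_mm", "wood_diam_b_mm", "wood_fresh_mg", "wood_dry_mg"]].notna().all(axis=1)
    if wood_ok.any():
        sub = individuals.loc[wood_ok]
        wd, wdmc = derive_wood_traits(
            sub["wood_length_mm"], sub["wood_diam_a_mm"], sub["wood_diam_b_mm"],
            sub["wood_fresh_mg"], sub["wood_dry_mg"],
        )
        out.loc[wood_ok, "WD"] = wd
        out.loc[wood_ok, "WDMC"] = wdmc

    root_ok = individuals[["root_volume_mm3", "root_fresh_mg", "root_dry_mg"]].notna().all(axis=1)
    if root_ok.any():
        sub = individuals.loc[root_ok]
        rtd, rdmc = derive_root_traits(sub["root_volume_mm3"], sub["root_fresh_mg"], sub["root_dry_mg"])
        out.loc[root_ok, "RTD"] = rtd
        out.loc[root_ok, "RDMC"] = rdmc
    return out


def species_trait_means(
    individual_traits: pd.DataFrame,
    environment: str | None = None,
    log_traits: tuple[str, ...] = (),
) -> TraitTable:
    """Aggregate per-individual trait values to unweighted species means.

    ``log_traits`` names traits to natural-log transform at the individual
    level before averaging (off by default).
    """
    df = individual_traits
    if environment is not None:
        df = df[df["environment"] == environment]
        if df.empty:
            raise InsufficientDataError(f"no individuals for environment {environment!r}")
    env = environment if environment is not None else "all"
    traits = [t for t in TRAIT_NAMES if t in df.columns]
    values = df[traits].copy()
    for t in log_traits:
        if t in values:
            values[t] = np.log(values[t])
    values["species"] = df["species"].to_numpy()
    grouped = values.groupby("species", sort=True)
    return TraitTable(
        data=grouped.mean(),
        environment=env,
        counts=grouped.count(),
    )


def species_growth_summary(records_with_rgr: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-species RGR mean and RGR95, overall and per site.

    RGR95 is the 95th percentile across individuals using linear
    interpolation between order statistics; with a single individual it
    equals that individual's RGR.  Species with zero records are simply
    absent from the output.
    """
    if "rgr" not in records_with_rgr:
        records_with_rgr = add_rgr(records_with_rgr)

    def summarize(group: pd.DataFrame) -> pd.Series:
        r = group["rgr"].to_numpy()
        return pd.Series(
            {
                "n": len(r),
                "rgr_mean": float(np.mean(r)),
                "rgr95": float(np.percentile(r, 95)),
            }
        )

    overall = (
        records_with_rgr.groupby("species", sort=True)
        .apply(summarize, include_groups=False)
        .astype({"n": int})
    )
    by_site = (
        records_with_rgr.groupby(["species", "site"], sort=True)
        .apply(summarize, include_groups=False)
        .astype({"n": int})
        .reset_index()
    )
    return {"overall": overall, "by_site": by_site}


def variance_components(individual_traits: pd.DataFrame, trait: str) -> tuple[float, float]:
    """One-way random-effects variance decomposition for a trait.

    Returns (interspecific fraction, intraspecific fraction), the intraclass
    correlation computed from the ANOVA mean squares with the unbalanced-design
    coefficient n0 = (N - sum(n_i^2)/N) / (k - 1).  The between-species
    variance estimate is truncated at zero, so the fraction lies in [0, 1].
    """
    df = individual_traits[["species", trait]].dropna()
    sizes = df.groupby("species")[trait].count()
    sizes = sizes[sizes >= 1]
    k = len(sizes)
    if k < 2:
        raise InsufficientDataError("need at least two species")
    if (sizes < 2).all():
        raise InsufficientDataError("need replicate measurements within species")
    values = df[trait].to_numpy(dtype=float)
    groups = df["species"].to_numpy()
    n_total = len(values)
    grand = values.mean()
    group_means = df.groupby("species")[trait].mean()
    n_i = sizes.to_numpy(dtype=float)
    ssb = float(np.sum(n_i * (group_means.to_numpy() - grand) ** 2))
    ssw = float(
        np.sum((values - group_means.loc[groups].to_numpy()) ** 2)
    )
    msb = ssb / (k - 1)
    dof_w = n_total - k
    msw = ssw / dof_w if dof_w > 0 else 0.0
    n0 = (n_total - np.sum(n_i**2) / n_total) / (k - 1)
    sigma_b = max(0.0, (msb - msw) / n0)
    total = sigma_b + msw
    if total == 0.0:
        # all values identical everywhere: no variance to partition
        raise DegenerateInputError(f"trait {trait!r} has zero total variance")
    if msw == 0.0:
        return 1.0, 0.0
    frac = min(1.0, max(0.0, sigma_b / total))
    return frac, 1.0 - frac
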