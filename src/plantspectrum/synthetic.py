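"""Synthetic study generator.

Emulates the structure of a multi-environment trait/growth study of woody
species: a pure-birth phylogeny; seven organ-economics traits evolving by
correlated Brownian motion; per-species intraspecific shifts between a
standardized greenhouse environment and forest-understory field conditions
(divergent for some trait pairs, convergent for others); individual organ
measurements back-constructed from target trait values with multiplicative
lognormal noise so the trait-derivation code is exercised end-to-end; and
repeated stem-dimension records whose true relative growth rate is injected
exactly, with one-sided competitive growth suppression in the field.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, TraitMismatchError
from .measurements import DMC_TRAITS, TRAIT_NAMES, TraitTable
from .phylo import Phylogeny, phylo_vcv

# Root states and Brownian tip standard deviations (trait units, unit-depth
# tree) giving interspecific ranges inside published global trait ranges.
# Root state >= 5 tip SDs keeps species means positive by construction.
DEFAULT_ROOT_STATES = {
    "LMA": 180.0,   # g/m^2
    "LTD": 0.35,    # mg/mm^3
    "LDMC": 0.35,   # fraction
    "WD": 0.55,     # mg/mm^3
    "WDMC": 0.45,   # fraction
    "RTD": 0.25,    # mg/mm^3
    "RDMC": 0.25,   # fraction
}
DEFAULT_TIP_SD = {
    "LMA": 30.0,
    "LTD": 0.07,
    "LDMC": 0.06,
    "WD": 0.10,
    "WDMC": 0.08,
    "RTD": 0.05,
    "RDMC": 0.05,
}


def equicorrelation(n: int, rho: float) -> np.ndarray:
    """Correlation matrix with all off-diagonals equal to rho."""
    R = np.full((n, n), rho)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class TraitShiftSpec:
    """Mean and between-species SD of the greenhouse-to-field trait shift.

    Defaults emulate the shade-response pattern: LMA falls by about one
    interspecific SD while wood and fine-root tissue densities rise by about
    one SD, i.e. divergent for (LMA, WD) and (LMA, RTD) but convergent for
    (WD, RTD).
    """

    mean_shift: dict[str, float] = field(
        default_factory=lambda: {
            "LMA": -30.0, "LTD": 0.0, "LDMC": 0.0,
            "WD": 0.10, "WDMC": 0.0, "RTD": 0.05, "RDMC": 0.0,
        }
    )
    shift_sd: dict[str, float] = field(
        default_factory=lambda: {t: 0.25 * DEFAULT_TIP_SD[t] for t in TRAIT_NAMES}
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.shift_sd.values()):
            raise ValueError("shift_sd must be non-negative elementwise")


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study.

    ``evo_correlation`` is the cross-trait Brownian correlation (default
    equicorrelation 0.7: a strong but imperfect single axis);
    ``evo_variances`` are the per-trait Brownian rates, chosen so tip SD on
    the unit-depth tree matches realistic interspecific spreads.
    """

    n_species: int = 56
    trait_names: tuple[str, ...] = TRAIT_NAMES
    evo_correlation: np.ndarray = field(
        default_factory=lambda: equicorrelation(len(TRAIT_NAMES), 0.7)
    )
    evo_variances: dict[str, float] = field(
        default_factory=lambda: {t: DEFAULT_TIP_SD[t] ** 2 for t in TRAIT_NAMES}
    )
    root_states: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROOT_STATES))
    shift_spec: TraitShiftSpec = field(default_factory=TraitShiftSpec)
    n_replicates_per_species: int = 8       # greenhouse individuals/species
    n_field_replicates_per_species: int = 3
    replicate_cv: float = 0.15              # measurement noise CV
    n_sites: int = 3
    site_occupancy: float = 0.6             # P(species present at a field site)
    growth_individuals_per_site: int = 8
    baseline_rgr: float = 1.0               # per year, d^2 h log scale
    rgr_trait_slope: float = -0.3           # per SD of composite trait score
    suppression_sd: float = 0.6             # field-only, one-sided
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.evo_correlation, dtype=float)
        if self.n_species < 4:
            raise ValueError("n_species must be at least 4")
        if R.shape != (len(self.trait_names),) * 2:
            raise ValueError("evo_correlation shape must match trait count")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("evo_correlation must be symmetric with unit diagonal")
        if any(v < 0 for v in self.evo_variances.values()):
            raise ValueError("Brownian rates must be non-negative")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")
        if self.n_replicates_per_species < 1 or self.n_sites < 1:
            raise ValueError("replicate and site counts must be positive")
        self.evo_correlation = R


@dataclass
class SyntheticStudy:
    phylogeny: Phylogeny
    greenhouse_traits: TraitTable
    field_traits: TraitTable
    individuals: pd.DataFrame
    growth_records: pd.DataFrame
    config: SyntheticConfig


def _subseeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_yule_tree(n_species: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to unit root-to-tip depth.

    Lineages split at exponential waiting times (rate = number of extant
    lineages); a final waiting interval extends all tips to the present, so
    the tree is ultrametric and strictly bifurcating with positive branch
    lengths.  Tips are labelled sp001... in traversal order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    active: list[tuple[dendropy.Node, float]] = [(first, 0.0), (second, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, start = active.pop(i)
        node.edge.length = t - start
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    total = t + rng.exponential(1.0 / n_species)
    for node, start in active:
        node.edge.length = total - start
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length /= total
    width = max(3, len(str(n_species)))
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"sp{k:0{width}d}")
    return Phylogeny(tree=tree)


def simulate_correlated_bm_traits(
    tree: Phylogeny, config: SyntheticConfig, seed: int | None = None
) -> TraitTable:
    """Species trait means under correlated Brownian motion on the tree.

    Tip values are matrix-normal: row covariance C (the tree's phylogenetic
    covariance) and column covariance V = D R D with D = diag(tip SDs), so
    vec(X) ~ N(root, kron(V, C)).
    """
    if seed is None:
        seed = config.seed
    R = np.asarray(config.evo_correlation, dtype=float)
    eigvals = np.linalg.eigvalsh((R + R.T) / 2.0)
    if eigvals.min() < -1e-8:
        raise ValueError("evo_correlation is not positive semidefinite")
    traits = list(config.trait_names)
    sd = np.array([np.sqrt(config.evo_variances[t]) for t in traits])
    V = R * np.outer(sd, sd)
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    A = U * np.sqrt(np.clip(w, 0.0, None))

    C = phylo_vcv(tree)
    species = list(C.index)
    L = np.linalg.cholesky(C.to_numpy())
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((len(species), len(traits)))
    root = np.array([config.root_states[t] for t in traits])
    X = root + L @ Z @ A.T
    return TraitTable(
        data=pd.DataFrame(X, index=species, columns=traits),
        environment="cultivated",
    )


def apply_environment_shifts(
    greenhouse: TraitTable, spec: TraitShiftSpec, seed: int
) -> TraitTable:
    """Field trait table = greenhouse + per-species Normal(mean, sd) displacement."""
    missing = [t for t in spec.mean_shift if t not in greenhouse.data.columns]
    if missing:
        raise TraitMismatchError(f"shift spec names traits absent from table: {missing}")
    rng = np.random.default_rng(seed)
    data = greenhouse.data.copy()
    for trait in greenhouse.data.columns:
        mu = spec.mean_shift.get(trait, 0.0)
        sd = spec.shift_sd.get(trait, 0.0)
        data[trait] = data[trait] + mu + (
            rng.normal(0.0, sd, size=len(data)) if sd > 0 else 0.0
        )
    return TraitTable(data=data, environment="wild_juvenile")


# fixed organ geometry used when back-constructing raw measurements
_LEAF_AREA_CM2 = 25.0
_WOOD_LENGTH_MM = 20.0
_WOOD_DIAM_MM = 4.0
_ROOT_VOLUME_MM3 = 100.0
_ROOT_LENGTH_MM = 500.0


def generate_individual_replicates(
    means: TraitTable, n: int, cv: float, seed: int
) -> pd.DataFrame:
    """Individual organ-measurement rows whose derived traits hit noisy targets.

    Each individual's target trait value is the species mean times a
    lognormal factor with unit mean and the given coefficient of variation
    (so cv=0 reproduces species means exactly).  Raw leaf, wood and root
    measurements are then back-calculated so the trait-derivation functions
    recover the targets to machine precision.
    """
    if n < 1:
        raise ValueError("need at least one replicate per species")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    traits = means.traits
    data = means.data
    if (data[list(traits)] <= 0).any().any():
        bad = data.index[(data[list(traits)] <= 0).any(axis=1)].tolist()
        raise InvalidMeasurementError(f"non-positive species trait means: {bad}")
    rng = np.random.default_rng(seed)
    n_sp = len(data)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        factors = rng.lognormal(-sigma**2 / 2.0, sigma, size=(n_sp, n, len(traits)))
    else:
        factors = np.ones((n_sp, n, len(traits)))
    targets = data.to_numpy()[:, None, :] * factors
    frame = pd.DataFrame(
        targets.reshape(-1, len(traits)), columns=traits
    )
    # dry matter contents are physically bounded by 1
    for t in DMC_TRAITS:
        if t in frame:
            frame[t] = frame[t].clip(upper=0.99)
    species = np.repeat(data.index.to_numpy(), n)
    rep = np.tile(np.arange(1, n + 1), n_sp)

    leaf_dry_g = frame["LMA"] * _LEAF_AREA_CM2 * 1e-4
    out = pd.DataFrame(
        {
            "species": species,
            "individual": [f"{s}_{k:02d}" for s, k in zip(species, rep)],
            "environment": means.environment,
            "leaf_area_cm2": _LEAF_AREA_CM2,
            "leaf_thickness_mm": leaf_dry_g * 1e3 / (_LEAF_AREA_CM2 * 1e2 * frame["LTD"]),
            "leaf_fresh_g": leaf_dry_g / frame["LDMC"],
            "leaf_dry_g": leaf_dry_g,
            "wood_length_mm": _WOOD_LENGTH_MM,
            "wood_diam_a_mm": _WOOD_DIAM_MM,
            "wood_diam_b_mm": _WOOD_DIAM_MM,
        }
    )
    wood_volume = np.pi * (_WOOD_DIAM_MM / 2.0) ** 2 * _WOOD_LENGTH_MM
    out["wood_dry_mg"] = frame["WD"].to_numpy() * wood_volume
    out["wood_fresh_mg"] = out["wood_dry_mg"] / frame["WDMC"].to_numpy()
    out["root_volume_mm3"] = _ROOT_VOLUME_MM3
    out["root_length_mm"] = _ROOT_LENGTH_MM
    out["root_dry_mg"] = frame["RTD"].to_numpy() * _ROOT_VOLUME_MM3
    out["root_fresh_mg"] = out["root_dry_mg"] / frame["RDMC"].to_numpy()
    cols = [
        "species", "individual", "environment",
        "leaf_area_cm2", "leaf_thickness_mm", "leaf_fresh_g", "leaf_dry_g",
        "wood_length_mm", "wood_diam_a_mm", "wood_diam_b_mm",
        "wood_fresh_mg", "wood_dry_mg",
        "root_volume_mm3", "root_length_mm", "root_fresh_mg", "root_dry_mg",
    ]
    return out[cols]


_ENV_ALIASES = {
    "cultivated": "cultivated", "greenhouse": "cultivated",
    "wild_juvenile": "wild_juvenile", "field": "wild_juvenile",
}


def composite_trait_score(traits: TraitTable, keys=("LMA", "WD", "RTD")) -> pd.Series:
    """Standardized composite score: mean of per-trait z-scores, re-standardized."""
    z = (traits.data[list(keys)] - traits.data[list(keys)].mean()) / traits.data[
        list(keys)
    ].std(ddof=1)
    comp = z.mean(axis=1)
    s = comp.std(ddof=1)
    return (comp - comp.mean()) / s if s > 0 else comp * 0.0


def generate_growth_trajectories(
    traits: TraitTable,
    config: SyntheticConfig,
    environment: str,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated stem-measurement records with an exactly injected true RGR.

    Each individual's true RGR is baseline + slope x composite trait score,
    minus (field only) a half-normal suppression term so competition can
    only lower growth.  Final dimensions are solved from the RGR equation,
    d2 = d1 e^{r dt/3} and h2 = h1 e^{r dt/3}, so recomputing RGR from the
    record returns the injected value exactly.  Greenhouse records sit in a
    single "greenhouse" site; field individuals are spread over n_sites
    sites with random species occupancy.
    """
    env = _ENV_ALIASES.get(environment)
    if env is None:
        raise ValueError(f"unknown environment label {environment!r}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    score = composite_trait_score(traits)
    species_rgr = config.baseline_rgr + config.rgr_trait_slope * score

    rows: list[dict] = []

    def emit(sp: str, site: str, idx: int, r_true: float, dt: float) -> None:
        h1 = float(rng.lognormal(np.log(30.0), 0.3))
        d1 = float(rng.lognormal(np.log(4.0), 0.25))
        g = np.exp(r_true * dt / 3.0)
        rows.append(
            {
                "species": sp,
                "individual": f"{sp}_{site}_{idx:03d}",
                "site": site,
                "environment": env,
                "h1_cm": h1,
                "d1_mm": d1,
                "t1_yr": 0.0,
                "h2_cm": h1 * g,
                "d2_mm": d1 * g,
                "t2_yr": dt,
                "true_rgr": r_true,
            }
        )

    if env == "cultivated":
        for sp in traits.species:
            for k in range(config.n_replicates_per_species):
                emit(sp, "greenhouse", k + 1, float(species_rgr[sp]), 0.31)
    else:
        for s in range(1, config.n_sites + 1):
            site = f"site{s:02d}"
            for sp in traits.species:
                if rng.random() >= config.site_occupancy:
                    continue
                for k in range(config.growth_individuals_per_site):
                    suppression = (
                        abs(rng.normal(0.0, config.suppression_sd))
                        if config.suppression_sd > 0
                        else 0.0
                    )
                    dt = float(rng.uniform(1.0, 3.0))
                    emit(sp, site, k + 1, float(species_rgr[sp]) - suppression, dt)
    return pd.DataFrame(rows)


def make_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the complete synthetic study from a single master seed."""
    s = _subseeds(config.seed, 7)
    tree = generate_yule_tree(config.n_species, s[0])
    greenhouse = simulate_correlated_bm_traits(tree, config, s[1])
    fieldtab = apply_environment_shifts(greenhouse, config.shift_spec, s[2])
    ind = pd.concat(
        [
            generate_individual_replicates(
                greenhouse, config.n_replicates_per_species, config.replicate_cv, s[3]
            ),
            generate_individual_replicates(
                fieldtab, config.n_field_replicates_per_species, config.replicate_cv, s[4]
            ),
        ],
        ignore_index=True,
    )
    growth = pd.concat(
        [
            generate_growth_trajectories(greenhouse, config, "cultivated", s[5]),
            generate_growth_trajectories(fieldtab, config, "wild_juvenile", s[6]),
        ],
        ignore_index=True,
    )
    return SyntheticStudy(
        phylogeny=tree,
        greenhouse_traits=greenhouse,
        field_traits=fieldtab,
        individuals=ind,
        growth_records=growth,
        config=config,
    )


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["evo_correlation"] = np.asarray(config.evo_correlation).tolist()
    d["trait_names"] = list(config.trait_names)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["evo_correlation"] = np.asarray(d["evo_correlation"], dtype=float)
    d["trait_names"] = tuple(d["trait_names"])
    d["shift_spec"] = TraitShiftSpec(**d["shift_spec"])
    return SyntheticConfig(**d)


def write_study_bundle(study: SyntheticStudy, directory: str | Path) -> dict:
    """Write tree.nwk, individuals.csv, growth.csv, config.json + manifest.

    The bundle is sufficient input for the full pipeline; the returned (and
    written) manifest lists each file with its row count and sha256.
    """
    if len(study.greenhouse_traits.species) == 0:
        raise ValueError("study has no species; nothing to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, dict] = {}

    def register(name: str, rows: int | None) -> None:
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        files[name] = {"rows": rows, "sha256": digest}

    (directory / "tree.nwk").write_text(study.phylogeny.newick())
    register("tree.nwk", None)
    study.individuals.to_csv(directory / "individuals.csv", index=False)
    register("individuals.csv", len(study.individuals))
    study.growth_records.to_csv(directory / "growth.csv", index=False)
    register("growth.csv", len(study.growth_records))
    (directory / "config.json").write_text(
        json.dumps(_config_to_jsonable(study.config), indent=2, sort_keys=True) + "\n"
    )
    register("config.json", None)

    manifest = {"files": files}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def read_study_bundle(directory: str | Path) -> dict:
    """Load a bundle written by :func:`write_study_bundle`.

    Returns a dict with keys phylogeny, individuals, growth, config (config
    is None when config.json is absent, e.g. for user-supplied bundles).
    """
    from .phylo import read_newick

    directory = Path(directory)
    tree_path = directory / "tree.nwk"
    ind_path = directory / "individuals.csv"
    if not tree_path.exists():
        raise FileNotFoundError(f"bundle is missing {tree_path}")
    if not ind_path.exists():
        raise FileNotFoundError(f"bundle is missing {ind_path}")
    growth_path = directory / "growth.csv"
    config_path = directory / "config.json"
    return {
        "phylogeny": read_newick(tree_path.read_text()),
        # round_trip parsing keeps a write/read cycle bit-exact
        "individuals": pd.read_csv(ind_path, float_precision="round_trip"),
        "growth": (
            pd.read_csv(growth_path, float_precision="round_trip")
            if growth_path.exists()
            else None
        ),
        "config": (
            config_from_dict(json.loads(config_path.read_text()))
            if config_path.exists()
            else None
        ),
    }
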