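"""End-to-end orchestration of the whole-plant economic spectrum analysis.

Stages, in order: trait derivation and species-level averaging per
environment; variance partitioning (interspecific vs intraspecific);
growth-record filtering and RGR / RGR95 summaries (overall and per site);
phylogenetically corrected PCA with integration index and Kaiser
dimensionality per environment; SMA regressions on raw species means and on
independent contrasts for the key trait pairs and for trait-growth
relationships; random-effects meta-analysis of site-level trait-growth
correlations; paired greenhouse-vs-field comparisons (Wilcoxon signed-rank
and cultivated-vs-wild SMA); and the environment-mixing resampling null.

Each stage records the species count it used.  All report files are
byte-deterministic for a fixed seed; wall-clock timestamps appear only in
run.log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import measurements as ms
from . import synthetic as syn
from .bivariate import sma_fit, sma_fit_origin, wilcoxon_signed_rank
from .errors import InsufficientDataError, PlantSpectrumError
from .meta import dl_random_effects_pool, site_correlation
from .phylo import Phylogeny, compute_pics, phylo_pca, prune_to_species
from .resampling import resample_mixed_environments

DEFAULT_PAIRS = (("LMA", "WD"), ("LMA", "RTD"), ("WD", "RTD"))
KEY_TRAITS = ("LMA", "WD", "RTD")


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` or ``bundle`` must be set."""

    synthetic: syn.SyntheticConfig | None = None
    bundle: str | Path | None = None
    log_traits: tuple[str, ...] = ()
    b_resample: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    skip_growth: bool = False
    resample_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    key_traits: tuple[str, ...] = KEY_TRAITS

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.bundle is None):
            raise ValueError("set exactly one of synthetic config or bundle path")


class PipelineLog:
    """Collects ISO-8601 timestamped plain-text log lines."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def info(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.lines.append(f"{stamp} {message}")

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _sma_row(fit, extra: dict) -> dict:
    row = {
        "n": fit.n,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r": fit.r,
        "r_squared": fit.r_squared,
        "p_value": fit.p_value,
    }
    row.update(extra)
    return row


def _raw_and_pic_sma(
    phylogeny: Phylogeny, table: ms.TraitTable, x: pd.Series, y: pd.Series,
    alpha: float,
) -> dict | None:
    """SMA on raw species means plus through-origin SMA on contrasts."""
    both = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(both) < 4:
        return None
    raw = sma_fit(both["x"], both["y"])
    pruned = prune_to_species(phylogeny, list(both.index))
    xc = compute_pics(pruned, both["x"])
    yc = compute_pics(pruned, both["y"])
    pic = sma_fit_origin(xc.contrasts, yc.contrasts)
    return {
        "n": raw.n,
        "slope": raw.slope,
        "intercept": raw.intercept,
        "r_raw": raw.r,
        "r2_raw": raw.r_squared,
        "p_raw": raw.p_value,
        "r_pic": pic.r,
        "p_pic": pic.p_value,
        "both_significant": bool(raw.p_value < alpha and pic.p_value < alpha),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return a results dictionary.

    Keys: config, log, species_traits (env -> TraitTable),
    individual_traits, variance_components, growth (env -> summaries),
    ppca (env -> PhyloPCAResult), sma_pairs, trait_growth, meta,
    paired, resampling (list of ResampleResult), phylogeny.
    """
    log = PipelineLog()
    results: dict = {"config": config, "log": log}

    # ------------------------------------------------------------ inputs
    if config.synthetic is not None:
        study = syn.make_study(config.synthetic)
        phylogeny = study.phylogeny
        individuals = study.individuals
        growth = None if config.skip_growth else study.growth_records
        log.info(f"generated synthetic study: {config.synthetic.n_species} species")
    else:
        bundle = syn.read_study_bundle(config.bundle)
        phylogeny = bundle["phylogeny"]
        individuals = bundle["individuals"]
        growth = bundle["growth"]
        if growth is None and not config.skip_growth:
            raise FileNotFoundError(
                f"bundle {config.bundle} has no growth.csv; rerun with skip_growth "
                "for trait-only analyses"
            )
        if config.skip_growth:
            growth = None
        log.info(f"loaded bundle from {config.bundle}")
    results["phylogeny"] = phylogeny

    # ------------------------------------------------- traits per environment
    ind_traits = ms.derive_individual_traits(individuals)
    results["individual_traits"] = ind_traits
    environments = sorted(ind_traits["environment"].unique())
    tables: dict[str, ms.TraitTable] = {}
    for env in environments:
        tables[env] = ms.species_trait_means(ind_traits, env, config.log_traits)
        log.info(f"trait table [{env}]: {len(tables[env].species)} species")
    results["species_traits"] = tables

    # ------------------------------------------------------ variance components
    vc_rows = []
    for env in environments:
        sub = ind_traits[ind_traits["environment"] == env]
        for trait in ms.TRAIT_NAMES:
            try:
                inter, intra = ms.variance_components(sub, trait)
            except PlantSpectrumError:
                continue
            vc_rows.append(
                {
                    "environment": env,
                    "trait": trait,
                    "interspecific_fraction": inter,
                    "intraspecific_fraction": intra,
                }
            )
    results["variance_components"] = pd.DataFrame(vc_rows)

    # ----------------------------------------------------------------- growth
    growth_results: dict[str, dict] = {}
    if growth is not None:
        with_rgr = ms.add_rgr(growth)
        kept, dropped = ms.filter_growth_records(with_rgr)
        log.info(
            f"growth filtering: kept {len(kept)}, dropped {len(dropped)} "
            "negative-growth records"
        )
        for env in sorted(kept["environment"].unique()):
            env_records = kept[kept["environment"] == env]
            growth_results[env] = ms.species_growth_summary(env_records)
            growth_results[env]["n_dropped"] = int(
                (dropped["environment"] == env).sum()
            )
    results["growth"] = growth_results

    # ------------------------------------------------------------------ pPCA
    ppca: dict[str, object] = {}
    for env, table in tables.items():
        try:
            ppca[env] = phylo_pca(phylogeny, table)
        except InsufficientDataError as exc:
            log.info(f"pPCA [{env}] skipped: {exc}")
            continue
        res = ppca[env]
        log.info(
            f"pPCA [{env}]: n={res.n_species}, integration index "
            f"{res.integration_index:.3f}, dimensionality {res.dimensionality}"
        )
    results["ppca"] = ppca

    # ------------------------------------------------------- trait-pair SMA
    sma_rows = []
    for env, table in tables.items():
        for tx, ty in config.resample_pairs:
            row = _raw_and_pic_sma(
                phylogeny, table, table.data[tx], table.data[ty], config.alpha
            )
            if row is None:
                continue
            row.update({"group": env, "trait_x": tx, "trait_y": ty})
            sma_rows.append(row)
    results["sma_pairs"] = pd.DataFrame(sma_rows)

    # ------------------------------------------------------ trait-growth SMA
    tg_rows = []
    for env, summaries in growth_results.items():
        if env not in tables:
            continue
        table = tables[env]
        if env == "cultivated":
            per_species = summaries["overall"][["rgr_mean", "rgr95"]]
        else:
            # wild plants: species value = average across the sites it occupies
            per_species = (
                summaries["by_site"].groupby("species")[["rgr_mean", "rgr95"]].mean()
            )
        for trait in config.key_traits:
            for measure in ("rgr95", "rgr_mean"):
                row = _raw_and_pic_sma(
                    phylogeny, table, table.data[trait], per_species[measure],
                    config.alpha,
                )
                if row is None:
                    continue
                row.update({"group": env, "trait_x": trait, "trait_y": measure})
                tg_rows.append(row)
    results["trait_growth"] = pd.DataFrame(tg_rows)

    # ------------------------------------------------------------ meta-analysis
    meta_rows = []
    for env, summaries in growth_results.items():
        if env == "cultivated" or env not in tables:
            continue  # single standardized environment: nothing to pool
        table = tables[env]
        by_site = summaries["by_site"]
        for trait in config.key_traits:
            for measure in ("rgr95", "rgr_mean"):
                sites = []
                for site, group in by_site.groupby("site"):
                    joined = group.set_index("species")[[measure]].join(
                        table.data[[trait]], how="inner"
                    ).dropna()
                    if len(joined) < 4:
                        continue
                    if joined[trait].std() == 0 or joined[measure].std() == 0:
                        continue
                    r = float(np.corrcoef(joined[trait], joined[measure])[0, 1])
                    sites.append(
                        site_correlation(str(site), trait, measure, r, len(joined))
                    )
                if not sites:
                    continue
                pooled = dl_random_effects_pool(sites)
                meta_rows.append(
                    {
                        "environment": env,
                        "trait": trait,
                        "growth_measure": measure,
                        "k_sites": pooled.k,
                        "pooled_r": pooled.pooled_r,
                        "ci_low": pooled.ci95[0],
                        "ci_high": pooled.ci95[1],
                        "tau_squared": pooled.tau_squared,
                        "Q": pooled.Q,
                        "significant": bool(
                            pooled.ci95[0] > 0 or pooled.ci95[1] < 0
                        ),
                    }
                )
    results["meta"] = pd.DataFrame(meta_rows)

    # ------------------------------------------------ paired env comparisons
    paired_rows = []
    if "cultivated" in tables and "wild_juvenile" in tables:
        gh, fld = tables["cultivated"], tables["wild_juvenile"]
        shared = gh.data.index.intersection(fld.data.index)
        for trait in config.key_traits:
            pair = pd.concat(
                [gh.data.loc[shared, trait], fld.data.loc[shared, trait]],
                axis=1, keys=["greenhouse", "field"],
            ).dropna()
            if len(pair) < 5:
                continue
            wsr = wilcoxon_signed_rank(pair["greenhouse"], pair["field"])
            fit = sma_fit(pair["greenhouse"], pair["field"])
            paired_rows.append(
                {
                    "trait": trait,
                    "n": wsr.n,
                    "W": wsr.statistic,
                    "p_wilcoxon": wsr.p_value,
                    "median_difference": wsr.median_difference,
                    "direction": wsr.direction,
                    "sma_slope": fit.slope,
                    "sma_r": fit.r,
                    "sma_p": fit.p_value,
                }
            )
    results["paired"] = pd.DataFrame(paired_rows)

    # ----------------------------------------------------------- resampling
    resamples = []
    if "cultivated" in tables and "wild_juvenile" in tables:
        sub = np.random.SeedSequence(config.seed).generate_state(
            len(config.resample_pairs), dtype=np.uint32
        )
        for pair, s in zip(config.resample_pairs, sub):
            res = resample_mixed_environments(
                tables["cultivated"], tables["wild_juvenile"], pair,
                B=config.b_resample, seed=int(s & 0x7FFFFFFF),
            )
            resamples.append(res)
            log.info(
                f"resampling {pair}: observed R2 {res.observed_r2:.3f}, "
                f"quantile position {res.quantile_position:.3f}"
            )
    results["resampling"] = resamples
    return results


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_reports(results: dict, directory: str | Path) -> dict:
    """Write CSV reports, a JSON summary and a manifest; return the manifest.

    Stable file names; every tabular report is CSV; summary.json holds the
    headline statistics (integration indices, dimensionalities, SMA fits,
    meta-analysis pools, resampling flags) with per-analysis species counts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    if not any(k not in ("config", "log") for k in results):
        import warnings

        warnings.warn("no results to write; empty manifest")
        manifest: dict = {"files": {}}
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest

    def write_csv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(directory / name, index=False)
        files[name] = len(df)

    tables = results.get("species_traits", {})
    if tables:
        stacked = pd.concat(
            [t.data.assign(environment=env).reset_index(names="species") for env, t in tables.items()],
            ignore_index=True,
        )
        write_csv("species_traits.csv", stacked)

    growth = results.get("growth", {})
    if growth:
        overall = pd.concat(
            [s["overall"].assign(environment=env).reset_index() for env, s in growth.items()],
            ignore_index=True,
        )
        write_csv("species_growth.csv", overall)
        by_site = pd.concat(
            [s["by_site"].assign(environment=env) for env, s in growth.items()],
            ignore_index=True,
        )
        write_csv("species_growth_by_site.csv", by_site)

    vc = results.get("variance_components")
    if vc is not None and len(vc):
        write_csv("variance_components.csv", vc)

    ppca = results.get("ppca", {})
    if ppca:
        eig = pd.concat(
            [
                pd.DataFrame(
                    {
                        "environment": env,
                        "component": [f"PC{i+1}" for i in range(len(r.eigenvalues))],
                        "eigenvalue": r.eigenvalues,
                    }
                )
                for env, r in ppca.items()
            ],
            ignore_index=True,
        )
        write_csv("ppca_eigenvalues.csv", eig)
        load = pd.concat(
            [r.loadings.assign(environment=env).reset_index(names="trait") for env, r in ppca.items()],
            ignore_index=True,
        )
        write_csv("ppca_loadings.csv", load)
        scores = pd.concat(
            [r.scores.assign(environment=env).reset_index(names="species") for env, r in ppca.items()],
            ignore_index=True,
        )
        write_csv("ppca_scores.csv", scores)

    for key, name in (
        ("sma_pairs", "sma_trait_pairs.csv"),
        ("trait_growth", "sma_trait_growth.csv"),
        ("meta", "meta_results.csv"),
        ("paired", "paired_tests.csv"),
    ):
        df = results.get(key)
        if df is not None and len(df):
            write_csv(name, df)

    resamples = results.get("resampling", [])
    if resamples:
        summary = [
            {
                "trait_pair": list(r.trait_pair),
                "observed_r2": r.observed_r2,
                "simulated_mean_r2": float(np.mean(r.simulated_r2)),
                "simulated_q95_r2": float(np.quantile(r.simulated_r2, 0.95)),
                "quantile_position": r.quantile_position,
                "exceeds_95th": r.exceeds_95th,
                "B": r.B,
                "seed": r.seed,
                "n_species": len(r.species),
            }
            for r in resamples
        ]
        (directory / "resample_summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
        )
        files["resample_summary.json"] = len(summary)
        sim = pd.DataFrame(
            {f"{r.trait_pair[0]}_{r.trait_pair[1]}": r.simulated_r2 for r in resamples}
        )
        write_csv("resample_r2.csv", sim)

    summary = {
        "seed": getattr(results.get("config"), "seed", None),
        "environments": sorted(tables),
        "species_counts": {env: len(t.species) for env, t in tables.items()},
        "ppca": {
            env: {
                "n_species": r.n_species,
                "eigenvalues": r.eigenvalues,
                "integration_index": r.integration_index,
                "dimensionality": r.dimensionality,
            }
            for env, r in ppca.items()
        },
        "meta": results["meta"].to_dict("records") if len(results.get("meta", [])) else [],
        "sma_pairs": results["sma_pairs"].to_dict("records") if len(results.get("sma_pairs", [])) else [],
        "paired": results["paired"].to_dict("records") if len(results.get("paired", [])) else [],
        "resampling": [
            {
                "trait_pair": list(r.trait_pair),
                "observed_r2": r.observed_r2,
                "quantile_position": r.quantile_position,
                "exceeds_95th": r.exceeds_95th,
            }
            for r in resamples
        ],
    }
    (directory / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
    files["summary.json"] = 1

    manifest = {"files": {name: {"rows": rows} for name, rows in sorted(files.items())}}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log = results.get("log")
    if log is not None:
        (directory / "run.log").write_text(log.text())
    return manifest
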