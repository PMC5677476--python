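"""The synthetic study generator: trees, traits, shifts, replicates, growth."""

import numpy as np
import pandas as pd
import pytest

import plantspectrum as ps
from plantspectrum import measurements as ms
from plantspectrum.errors import InvalidMeasurementError, TraitMismatchError
from plantspectrum.synthetic import DEFAULT_TIP_SD


class TestYuleTree:
    def test_two_tips_equal_branches(self):
        phy = ps.generate_yule_tree(2, seed=123)
        lengths = [leaf.edge.length for leaf in phy.tree.leaf_node_iter()]
        assert len(lengths) == 2
        assert lengths[0] == pytest.approx(lengths[1])

    def test_counts_and_ultrametricity(self):
        phy = ps.generate_yule_tree(56, seed=1)
        assert phy.n_tips == 56
        internal = sum(1 for nd in phy.tree.preorder_node_iter() if not nd.is_leaf())
        assert internal == 55
        assert phy.is_ultrametric(tol=1e-9)
        assert all(
            nd.edge.length > 0
            for nd in phy.tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def test_byte_identical_for_fixed_seed(self):
        a = ps.generate_yule_tree(17, seed=7).newick()
        b = ps.generate_yule_tree(17, seed=7).newick()
        assert a == b

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            ps.generate_yule_tree(1, seed=0)


class TestBrownianTraits:
    def test_star_tree_uncorrelated_traits(self):
        labels = [f"sp{i:03d}" for i in range(20)]
        star = ps.read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        cfg = ps.SyntheticConfig(n_species=20, evo_correlation=np.eye(7))
        draws = [
            ps.simulate_correlated_bm_traits(star, cfg, seed).data
            for seed in range(50)
        ]
        stacked = pd.concat(draws).to_numpy()   # 1000 independent rows
        corr = np.corrcoef(stacked.T)
        off = corr[~np.eye(7, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_high_equicorrelation_dominant_eigenvalue(self):
        # eigenvalue of 7x7 equicorrelation(0.95) is 6.7: sample lambda1 > 5
        hits = 0
        for seed in range(100):
            tree = ps.generate_yule_tree(56, seed)
            cfg = ps.SyntheticConfig(evo_correlation=ps.equicorrelation(7, 0.95))
            tab = ps.simulate_correlated_bm_traits(tree, cfg, seed + 1)
            lam = np.linalg.eigvalsh(np.corrcoef(tab.data.to_numpy().T)).max()
            hits += lam > 5.0
        assert hits >= 95

    def test_zero_rates_collapse_to_root(self):
        tree = ps.generate_yule_tree(10, seed=2)
        cfg = ps.SyntheticConfig(
            n_species=10, evo_variances={t: 0.0 for t in ps.TRAIT_NAMES}
        )
        tab = ps.simulate_correlated_bm_traits(tree, cfg, 5)
        for t in ps.TRAIT_NAMES:
            assert np.allclose(tab.data[t], cfg.root_states[t])

    def test_non_psd_correlation_rejected(self):
        R = ps.equicorrelation(7, -0.5)     # not PSD for 7 traits
        tree = ps.generate_yule_tree(8, seed=2)
        with pytest.raises(ValueError, match="positive semidefinite"):
            ps.simulate_correlated_bm_traits(
                tree, ps.SyntheticConfig(n_species=8, evo_correlation=R), 1
            )


class TestEnvironmentShifts:
    def test_zero_spec_is_identity(self, small_study):
        spec = ps.TraitShiftSpec(
            mean_shift={t: 0.0 for t in ps.TRAIT_NAMES},
            shift_sd={t: 0.0 for t in ps.TRAIT_NAMES},
        )
        shifted = ps.apply_environment_shifts(small_study.greenhouse_traits, spec, 1)
        pd.testing.assert_frame_equal(shifted.data, small_study.greenhouse_traits.data)

    def test_deterministic_offset(self, small_study):
        spec = ps.TraitShiftSpec(
            mean_shift={"LMA": -30.0, **{t: 0.0 for t in ps.TRAIT_NAMES if t != "LMA"}},
            shift_sd={t: 0.0 for t in ps.TRAIT_NAMES},
        )
        shifted = ps.apply_environment_shifts(small_study.greenhouse_traits, spec, 1)
        diff = shifted.data["LMA"] - small_study.greenhouse_traits.data["LMA"]
        assert np.allclose(diff, -30.0)

    def test_divergent_default_signs(self):
        # LMA falls while WD rises, in every seeded run
        for seed in range(100):
            tree = ps.generate_yule_tree(20, seed)
            cfg = ps.SyntheticConfig(n_species=20, seed=seed)
            gh = ps.simulate_correlated_bm_traits(tree, cfg, seed + 1)
            fld = ps.apply_environment_shifts(gh, ps.TraitShiftSpec(), seed + 2)
            delta = (fld.data - gh.data).mean()
            assert delta["LMA"] < 0 and delta["WD"] > 0 and delta["RTD"] > 0

    def test_trait_mismatch(self, small_study):
        spec = ps.TraitShiftSpec(mean_shift={"NOT_A_TRAIT": 1.0}, shift_sd={})
        with pytest.raises(TraitMismatchError):
            ps.apply_environment_shifts(small_study.greenhouse_traits, spec, 1)


class TestIndividualReplicates:
    def test_zero_cv_reproduces_means_exactly(self, small_study):
        gh = small_study.greenhouse_traits
        ind = ps.generate_individual_replicates(gh, n=4, cv=0.0, seed=1)
        derived = ms.derive_individual_traits(ind)
        means = ms.species_trait_means(derived, gh.environment)
        assert np.allclose(means.data.to_numpy(), gh.data.to_numpy(), atol=1e-9)

    def test_round_trip_derivation(self, small_study):
        ind = ps.generate_individual_replicates(
            small_study.greenhouse_traits, n=1, cv=0.0, seed=1
        )
        derived = ms.derive_individual_traits(ind)
        target = small_study.greenhouse_traits.data
        got = derived.set_index("species")[list(target.columns)]
        assert np.allclose(got.to_numpy(), target.to_numpy(), atol=1e-9)

    def test_sample_cv_near_nominal(self):
        tree = ps.generate_yule_tree(56, seed=3)
        cfg = ps.SyntheticConfig(seed=3)
        gh = ps.simulate_correlated_bm_traits(tree, cfg, 4)
        ind = ps.generate_individual_replicates(gh, n=10, cv=0.2, seed=5)
        derived = ms.derive_individual_traits(ind)
        by_sp = derived.groupby("species")["LMA"]
        cv = by_sp.std(ddof=1) / by_sp.mean()
        frac_ok = ((cv >= 0.05) & (cv <= 0.4)).mean()
        assert frac_ok >= 0.9

    def test_negative_cv_rejected(self, small_study):
        with pytest.raises(ValueError):
            ps.generate_individual_replicates(small_study.greenhouse_traits, 3, -0.1, 1)


class TestGrowthTrajectories:
    def test_rgr_inversion_exact(self, small_study):
        cfg = ps.SyntheticConfig(
            n_species=20, suppression_sd=0.0, n_replicates_per_species=1
        )
        rec = ps.generate_growth_trajectories(
            small_study.greenhouse_traits, cfg, "cultivated", seed=1
        )
        computed = ms.add_rgr(rec)
        assert np.allclose(computed["rgr"], computed["true_rgr"], atol=1e-12)

    def test_trait_slope_recovered_in_greenhouse(self):
        # negative composite-score slope implies negative trait-growth r
        from plantspectrum.synthetic import composite_trait_score

        hits = 0
        for seed in range(100):
            tree = ps.generate_yule_tree(56, seed)
            cfg = ps.SyntheticConfig(seed=seed, rgr_trait_slope=-0.3)
            gh = ps.simulate_correlated_bm_traits(tree, cfg, seed + 1)
            rec = ps.generate_growth_trajectories(gh, cfg, "cultivated", seed + 2)
            summary = ms.species_growth_summary(ms.add_rgr(rec))["overall"]
            score = composite_trait_score(gh).loc[summary.index]
            r, p, _ = ps.pearson_r(score, summary["rgr_mean"])
            hits += (r < 0) and (p < 0.05)
        assert hits >= 95

    def test_field_suppression_inflates_rgr95_ratio(self):
        ratios = []
        for seed in range(10):
            tree = ps.generate_yule_tree(30, seed)
            cfg = ps.SyntheticConfig(n_species=30, seed=seed, suppression_sd=0.6)
            gh = ps.simulate_correlated_bm_traits(tree, cfg, seed + 1)
            rec = ps.generate_growth_trajectories(gh, cfg, "field", seed + 2)
            s = ms.species_growth_summary(ms.add_rgr(rec))["overall"]
            ok = s[s["rgr_mean"] > 0]
            ratios.append(float((ok["rgr95"] / ok["rgr_mean"]).mean()))
        assert np.mean(ratios) > 1.5

    def test_unknown_environment(self, small_study):
        cfg = ps.SyntheticConfig(n_species=20)
        with pytest.raises(ValueError, match="environment"):
            ps.generate_growth_trajectories(
                small_study.greenhouse_traits, cfg, "orbital", seed=1
            )


class TestStudyBundle:
    def test_manifest_checksums_reproducible(self, tmp_path):
        study1 = ps.make_study(ps.SyntheticConfig(seed=8, n_species=10))
        study2 = ps.make_study(ps.SyntheticConfig(seed=8, n_species=10))
        m1 = ps.write_study_bundle(study1, tmp_path / "a")
        m2 = ps.write_study_bundle(study2, tmp_path / "b")
        assert m1 == m2
        assert set(m1["files"]) == {
            "tree.nwk", "individuals.csv", "growth.csv", "config.json"
        }

    def test_empty_species_is_error(self, tmp_path, small_study):
        empty = ps.SyntheticStudy(
            phylogeny=small_study.phylogeny,
            greenhouse_traits=ps.TraitTable(
                data=small_study.greenhouse_traits.data.iloc[:0],
                environment="cultivated",
            ),
            field_traits=small_study.field_traits,
            individuals=small_study.individuals,
            growth_records=small_study.growth_records,
            config=small_study.config,
        )
        with pytest.raises(ValueError):
            ps.write_study_bundle(empty, tmp_path / "empty")
        assert not (tmp_path / "empty" / "individuals.csv").exists()

    def test_bundle_round_trip_exact(self, tmp_path, small_study):
        ps.write_study_bundle(small_study, tmp_path / "bundle")
        back = ps.read_study_bundle(tmp_path / "bundle")
        pd.testing.assert_frame_equal(back["individuals"], small_study.individuals)
        pd.testing.assert_frame_equal(back["growth"], small_study.growth_records)
        assert back["phylogeny"].tip_labels == small_study.phylogeny.tip_labels
        assert back["config"].n_species == small_study.config.n_species
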