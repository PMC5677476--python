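"""Tree I/O, phylogenetic covariance, contrasts, and phylogenetic PCA."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest

import plantspectrum as ps
from plantspectrum.errors import (
    InsufficientDataError,
    PhylogenyError,
    ZeroVarianceContrastError,
)
from plantspectrum.phylo import _gls_mean_and_cov


class TestReadNewick:
    def test_two_taxon(self):
        phy = ps.read_newick("(A:1,B:1);")
        assert phy.n_tips == 2
        assert sorted(phy.tip_labels) == ["A", "B"]

    def test_polytomy_resolved_to_zero_length(self):
        phy = ps.read_newick("(A:1,B:1,C:1);")
        internal = [
            nd for nd in phy.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert len(internal) == 1 and internal[0].edge.length == 0.0
        assert phy.n_tips == 3

    def test_missing_branch_length(self):
        with pytest.raises(PhylogenyError, match="branch length"):
            ps.read_newick("(A:1,B);")

    def test_duplicate_tips(self):
        with pytest.raises(PhylogenyError, match="duplicate"):
            ps.read_newick("(A:1,A:1);")

    def test_underscores_preserved(self):
        phy = ps.read_newick("(Genus_species:1,Other_taxon:1);")
        assert "Genus_species" in phy.tip_labels


class TestPhyloVCV:
    def test_hand_example(self):
        C = ps.phylo_vcv(ps.read_newick("((A:1,B:1):1,C:2);"))
        expected = pd.DataFrame(
            [[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        pd.testing.assert_frame_equal(C.loc[list("ABC"), list("ABC")], expected)

    def test_star_tree_is_identity(self):
        C = ps.phylo_vcv(ps.read_newick("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(C.to_numpy(), np.eye(4))

    def test_branch_scaling_linearity(self):
        C1 = ps.phylo_vcv(ps.read_newick("((A:1,B:1):1,C:2);")).to_numpy()
        C3 = ps.phylo_vcv(ps.read_newick("((A:3,B:3):3,C:6);")).to_numpy()
        assert np.allclose(C3, 3 * C1)


class TestContrasts:
    def test_single_pair(self):
        cs = ps.compute_pics(ps.read_newick("(A:1,B:1);"), {"A": 3.0, "B": 1.0})
        assert cs.contrasts == pytest.approx([2.0 / np.sqrt(2)])

    def test_equal_values_zero_contrast(self):
        cs = ps.compute_pics(ps.read_newick("(A:1,B:1);"), {"A": 5.0, "B": 5.0})
        assert cs.contrasts == pytest.approx([0.0])

    def test_three_taxon_pruning(self, three_taxon_tree):
        # ancestral node gets mean(4,2)=3 with its branch extended by 0.5
        cs = ps.compute_pics(three_taxon_tree, {"A": 4.0, "B": 2.0, "C": 0.0})
        assert sorted(np.round(cs.contrasts, 6)) == pytest.approx(
            sorted([2.0 / np.sqrt(2), 3.0 / np.sqrt(4.0)])
        )
        assert len(cs) == 2

    def test_zero_variance_contrast_is_error(self):
        phy = ps.read_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(ZeroVarianceContrastError):
            ps.compute_pics(phy, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_missing_tip_value(self, three_taxon_tree):
        with pytest.raises(PhylogenyError, match="without trait values"):
            ps.compute_pics(three_taxon_tree, {"A": 1.0, "B": 2.0})

    def test_contrast_variance_matches_brownian_rate(self):
        # standardized contrasts of a BM trait have variance equal to the rate
        tree = ps.generate_yule_tree(16, 5)
        cfg = ps.SyntheticConfig(
            n_species=16,
            evo_variances={t: 1.0 for t in ps.TRAIT_NAMES},
            evo_correlation=np.eye(7),
        )
        sq = []
        for rep in range(1000):
            tab = ps.simulate_correlated_bm_traits(tree, cfg, seed=rep)
            sq.extend(ps.compute_pics(tree, tab.data["LMA"]).contrasts ** 2)
        assert np.mean(sq) == pytest.approx(1.0, rel=0.05)

    def test_agrees_with_dendropy_reference(self, small_study):
        from dendropy.model import continuous

        tab = small_study.greenhouse_traits
        mine = np.sort(np.abs(
            ps.compute_pics(small_study.phylogeny, tab.data["WD"]).contrasts
        ))
        t2 = dendropy.Tree.get(
            data=small_study.phylogeny.newick(), schema="newick",
            preserve_underscores=True,
        )
        cdm = dendropy.ContinuousCharacterMatrix.from_dict(
            {sp: [float(tab.data.loc[sp, "WD"])] for sp in tab.data.index},
            taxon_namespace=t2.taxon_namespace,
        )
        pic = continuous.PhylogeneticIndependentContrasts(tree=t2, char_matrix=cdm)
        ct = pic.contrasts_tree(character_index=0, annotate_pic_statistics=True)
        ref = np.sort([
            abs(nd.pic_contrast_standardized)
            for nd in ct.postorder_internal_node_iter()
        ])
        assert np.allclose(mine, ref, atol=1e-10)


class TestPhyloPCA:
    def test_star_tree_reduces_to_ordinary_pca(self, rng):
        n = 24
        labels = [f"s{i:02d}" for i in range(n)]
        star = ps.read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        X = rng.standard_normal((n, 5)) @ rng.standard_normal((5, 5))
        df = pd.DataFrame(X, index=labels, columns=list("abcde"))
        res = ps.phylo_pca(star, df)
        ordinary = np.sort(np.linalg.eigvalsh(np.corrcoef(X.T)))[::-1]
        assert np.allclose(res.eigenvalues, ordinary, atol=1e-8)

    def test_duplicate_trait_columns(self, rng):
        n = 12
        labels = [f"s{i:02d}" for i in range(n)]
        star = ps.read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        x = rng.standard_normal(n)
        df = pd.DataFrame({"a": x, "b": x}, index=labels)
        res = ps.phylo_pca(star, df)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_too_few_species(self, rng):
        labels = ["a", "b", "c"]
        star = ps.read_newick("(a:1,b:1,c:1);")
        df = pd.DataFrame(rng.standard_normal((3, 4)), index=labels)
        with pytest.raises(InsufficientDataError):
            ps.phylo_pca(star, df)

    def test_loadings_orthonormal_and_scores_gls_centered(self, small_study):
        res = ps.phylo_pca(small_study.phylogeny, small_study.greenhouse_traits)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(7), atol=1e-10)
        C = ps.phylo_vcv(small_study.phylogeny)
        order = res.scores.index
        Cinv = np.linalg.inv(C.loc[order, order].to_numpy())
        ones = np.ones(len(order))
        gls_mean = ones @ Cinv @ res.scores.to_numpy() / (ones @ Cinv @ ones)
        assert np.allclose(gls_mean, 0.0, atol=1e-9)

    def test_pic_gls_equivalence(self):
        # through-origin contrast correlation == GLS evolutionary correlation
        for seed in range(20):
            tree = ps.generate_yule_tree(8, seed)
            cfg = ps.SyntheticConfig(n_species=8, seed=seed)
            tab = ps.simulate_correlated_bm_traits(tree, cfg, seed + 1000)
            order = ps.phylo_vcv(tree).index
            X = tab.data.loc[order, ["LMA", "WD"]].to_numpy()
            _, _, R = _gls_mean_and_cov(X, ps.phylo_vcv(tree).to_numpy())
            r_gls = R[0, 1] / np.sqrt(R[0, 0] * R[1, 1])
            xc = ps.compute_pics(tree, tab.data["LMA"]).contrasts
            yc = ps.compute_pics(tree, tab.data["WD"]).contrasts
            r_pic = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
            assert abs(r_pic - r_gls) < 1e-10

    def test_agrees_with_r_phytools(self, small_study, tmp_path):
        """Independent cross-check of the GLS eigenanalysis against phytools."""
        tab = small_study.greenhouse_traits
        (tmp_path / "tree.nwk").write_text(small_study.phylogeny.newick())
        tab.data.to_csv(tmp_path / "traits.csv")
        script = textwrap.dedent(f"""
            suppressMessages({{library(ape); library(phytools)}})
            tr <- read.tree("{tmp_path}/tree.nwk")
            X <- read.csv("{tmp_path}/traits.csv", row.names=1)
            p <- phyl.pca(tr, as.matrix(X), method="BM", mode="corr")
            cat(paste(sprintf("%.12f", diag(p$Eval)), collapse=","))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.sort([float(v) for v in out.stdout.strip().split(",")])[::-1]
        res = ps.phylo_pca(small_study.phylogeny, tab)
        assert np.allclose(res.eigenvalues, ref, atol=1e-8)


class TestIntegrationIndex:
    @pytest.mark.parametrize("lam,expected", [
        ((1, 1, 1, 1, 1, 1, 1), 0.0),
        ((7, 0, 0, 0, 0, 0, 0), 6.0),
        ((2, 2, 1, 1, 0.5, 0.3, 0.2), (1 + 1 + 0 + 0 + 0.25 + 0.49 + 0.64) / 7),
    ])
    def test_examples(self, lam, expected):
        assert ps.integration_index(lam) == pytest.approx(expected)

    def test_equicorrelation_closed_form(self):
        # eigenvalues 1+(N-1)rho and N-1 copies of 1-rho => index (N-1)rho^2
        for rho in (0.0, 0.3, 0.5, 1.0):
            lam = np.linalg.eigvalsh(ps.equicorrelation(7, rho))
            assert ps.integration_index(lam) == pytest.approx(6 * rho**2, abs=1e-8)

    def test_non_correlation_input_warns(self):
        with pytest.warns(UserWarning, match="sum to the trait count"):
            ps.integration_index((3.0, 2.0))


class TestKaiser:
    @pytest.mark.parametrize("lam,expected", [
        ((7, 0, 0, 0, 0, 0, 0), 1),
        ((2, 2, 1, 1, 0.5, 0.3, 0.2), 2),   # eigenvalues exactly 1 excluded
    ])
    def test_strict_threshold(self, lam, expected):
        assert ps.kaiser_dimensionality(lam) == expected

    def test_flat_spectrum_warns(self):
        with pytest.warns(UserWarning, match="degenerate spectrum"):
            assert ps.kaiser_dimensionality((1.0, 1.0, 1.0)) == 0
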