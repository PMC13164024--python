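import numpy as np
import pandas as pd
import pytest

from burdencif.burden_scores import (
    SCORE_NAMES,
    WeightTable,
    collapse_blocks,
    compute_scores,
    dichotomize,
    estimate_weights,
    ld_blocks,
    standardize_iqr,
)
from burdencif.io_cohort import GenotypeMatrix, VariantAnnotation

from conftest import make_dataset, simulate_competing


def _ann(vid, gene="APP", vclass="non_causative"):
    return VariantAnnotation(variant_id=vid, gene=gene, chrom="21", pos=100,
                             variant_class=vclass)


def _geno(dosage, variants, subjects=None):
    dosage = np.asarray(dosage, dtype=float)
    subjects = subjects or [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


class TestLDBlocks:
    def test_duplicated_column_forms_block(self):
        rng = np.random.default_rng(0)
        v = rng.binomial(2, 0.3, 100)
        G = _geno(np.column_stack([v, v, rng.binomial(2, 0.3, 100)]),
                  ["a", "b", "c"])
        anns = [_ann("a"), _ann("b"), _ann("c")]
        ld = ld_blocks(G, anns)
        assert ld.r2[0, 1] == pytest.approx(1.0)
        assert ld.blocks == [["a", "b"]]

    def test_independent_variants_no_block(self):
        rng = np.random.default_rng(1)
        G = _geno(rng.binomial(2, 0.3, size=(500, 8)),
                  [f"v{i}" for i in range(8)])
        anns = [_ann(f"v{i}") for i in range(8)]
        assert ld_blocks(G, anns).blocks == []

    def test_cross_gene_pairs_never_linked(self):
        rng = np.random.default_rng(2)
        v = rng.binomial(2, 0.3, 200)
        G = _geno(np.column_stack([v, v]), ["a", "b"])
        anns = [_ann("a", gene="APP"), _ann("b", gene="GRN")]
        ld = ld_blocks(G, anns)
        assert ld.r2[0, 1] == pytest.approx(1.0)
        assert ld.blocks == []  # perfect LD but different genes

    def test_copy_with_flip_block_like_psen1(self):
        # six near-copies of one variant form a single 6-variant block
        rng = np.random.default_rng(3)
        n = 426
        anchor = rng.binomial(1, 0.2, size=(n, 2))
        cols = [anchor.sum(1)]
        for _ in range(5):
            flip = rng.binomial(1, 0.01, size=(n, 2))
            cols.append(np.abs(anchor - flip).sum(1))
        cols.append(rng.binomial(2, 0.3, n))  # unlinked PSEN1 variant
        ids = [f"p{i}" for i in range(7)]
        G = _geno(np.column_stack(cols), ids)
        anns = [_ann(i, gene="PSEN1") for i in ids]
        ld = ld_blocks(G, anns, r2_threshold=0.8)
        assert ld.blocks == [[f"p{i}" for i in range(6)]]

    def test_zero_variance_variant_r2_zero(self):
        rng = np.random.default_rng(4)
        G = _geno(np.column_stack([np.zeros(50), rng.binomial(2, 0.4, 50)]),
                  ["mono", "v"])
        ld = ld_blocks(G, [_ann("mono"), _ann("v")])
        assert ld.r2[0, 1] == 0.0
        assert ld.blocks == []

    def test_single_variant_errors(self):
        G = _geno(np.zeros((10, 1)), ["v"])
        with pytest.raises(ValueError, match="two variants"):
            ld_blocks(G, [_ann("v")])


class TestCollapseBlocks:
    def _ld(self, G, anns, thr=0.8):
        return ld_blocks(G, anns, r2_threshold=thr)

    def test_block_dosages_sum(self):
        rng = np.random.default_rng(5)
        v = rng.binomial(2, 0.4, 60)
        other = rng.binomial(2, 0.4, 60)
        G = _geno(np.column_stack([v, v, other]), ["a", "b", "c"])
        anns = [_ann("a"), _ann("b"), _ann("c")]
        Gc, ann_c = collapse_blocks(G, self._ld(G, anns), anns)
        assert Gc.variants == ["block_a_b", "c"]
        np.testing.assert_array_equal(Gc.dosage[:, 0], 2 * v)
        np.testing.assert_array_equal(Gc.dosage[:, 1], other)
        assert ann_c[0].gene == "APP"

    def test_no_blocks_identity(self):
        rng = np.random.default_rng(6)
        G = _geno(rng.binomial(2, 0.3, size=(200, 3)), ["a", "b", "c"])
        anns = [_ann(v) for v in "abc"]
        Gc, _ = collapse_blocks(G, self._ld(G, anns), anns)
        assert Gc.variants == ["a", "b", "c"]
        np.testing.assert_array_equal(Gc.dosage, G.dosage)

    def test_64_variants_with_one_6_block_gives_59(self, study_bundle):
        from burdencif.io_cohort import filter_region_variants

        anns = [a for a in study_bundle.annotations
                if a.variant_class == "non_causative"]
        G = study_bundle.genotypes.subset_variants([a.variant_id for a in anns])
        ld = ld_blocks(G, anns)
        assert [len(b) for b in ld.blocks] == [6]
        Gc, _ = collapse_blocks(G, ld, anns)
        assert len(Gc.variants) == 64 - 6 + 1


class TestEstimateWeights:
    def _data(self, n=300, seed=7, beta1=0.0, x=None):
        rng = np.random.default_rng(seed)
        t, e, x = simulate_competing(rng, n, beta1=beta1, x=x)
        return make_dataset(t, e), x

    def test_monomorphic_variant_zero_weight(self):
        data, _ = self._data(80)
        G = _geno(np.zeros((80, 2)), ["mono", "mono2"])
        G.dosage[:, 1] = np.tile([0, 1], 40)
        wt = estimate_weights(G, data, [_ann("mono"), _ann("mono2")])
        row = wt.table.set_index("variant_id").loc["mono"]
        assert row.beta_ad == 0.0 and row.beta_ftd == 0.0
        assert not row.estimable_ad and not row.estimable_ftd

    def test_one_row_per_column(self):
        data, _ = self._data(100)
        rng = np.random.default_rng(8)
        G = _geno(rng.binomial(2, 0.3, size=(100, 4)),
                  [f"v{i}" for i in range(4)])
        wt = estimate_weights(G, data, [_ann(f"v{i}") for i in range(4)])
        assert list(wt.table.variant_id) == G.variants

    def test_recovers_simulated_effect(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(2, 0.3, 2000).astype(float)
        t, e, _ = simulate_competing(rng, 2000, beta1=0.7, x=x,
                                     censor=(0.5, 4.0))
        data = make_dataset(t, e)
        G = _geno(x.reshape(-1, 1), ["v"])
        wt = estimate_weights(G, data, [_ann("v")])
        assert wt.table.beta_ad[0] == pytest.approx(0.7, abs=0.1)
        assert wt.table.estimable_ad[0]

    def test_causative_variant_rejected(self):
        data, _ = self._data(50)
        G = _geno(np.tile([0, 1], 25).reshape(-1, 1), ["bad"])
        with pytest.raises(ValueError, match="causative"):
            estimate_weights(G, data, [_ann("bad", vclass="causative")])

    def test_non_estimable_weight_must_be_zero(self):
        df = pd.DataFrame(
            {"variant_id": ["v"], "gene": ["APP"], "beta_ad": [0.5],
             "beta_ftd": [0.0], "estimable_ad": [False],
             "estimable_ftd": [True], "source": ["single_variant"]}
        )
        with pytest.raises(ValueError, match="zero"):
            WeightTable(df)


class TestComputeScores:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        genes = ["APP", "PSEN1", "MAPT", "GRN"]
        ids = [f"v{i}" for i in range(4)]
        anns = [_ann(i, gene=g) for i, g in zip(ids, genes)]
        G = _geno(rng.binomial(2, 0.3, size=(n, 4)), ids)
        wt = WeightTable(pd.DataFrame(
            {"variant_id": ids, "gene": genes,
             "beta_ad": [0.5, -0.2, 0.1, 0.0],
             "beta_ftd": [0.3, 0.0, -0.4, 0.25],
             "estimable_ad": [True, True, True, True],
             "estimable_ftd": [True, True, True, True],
             "source": ["single_variant"] * 4}
        ))
        return G, wt, anns

    def test_matches_per_subject_loop_oracle(self):
        from burdencif.io_cohort import AD_GENES

        G, wt, anns = self._setup()
        sc = compute_scores(G, wt, anns)
        w = wt.table.set_index("variant_id")
        gene = {a.variant_id: a.gene for a in anns}
        for i in range(len(G.subjects)):
            expect = {k: 0.0 for k in SCORE_NAMES}
            for j, v in enumerate(G.variants):
                gs = "ad" if gene[v] in AD_GENES else "ftd"
                expect[f"{gs}_w_ad"] += G.dosage[i, j] * w.loc[v, "beta_ad"]
                expect[f"{gs}_w_ftd"] += G.dosage[i, j] * w.loc[v, "beta_ftd"]
            for k in SCORE_NAMES:
                assert sc.scores.loc[i, k] == expect[k]

    def test_single_variant_single_term(self):
        ids = ["v"]
        anns = [_ann("v", gene="APP")]
        G = _geno(np.array([[2.0], [0.0]]), ids, subjects=["a", "b"])
        wt = WeightTable(pd.DataFrame(
            {"variant_id": ids, "gene": ["APP"], "beta_ad": [0.5],
             "beta_ftd": [0.0], "estimable_ad": [True],
             "estimable_ftd": [False], "source": ["single_variant"]}
        ))
        sc = compute_scores(G, wt, anns)
        assert sc.scores.loc[0, "ad_w_ad"] == 1.0
        assert sc.scores.loc[1, "ad_w_ad"] == 0.0
        assert (sc.scores[["ad_w_ftd", "ftd_w_ad", "ftd_w_ftd"]] == 0).all().all()

    def test_linearity_in_weights(self):
        G, wt, anns = self._setup(seed=1)
        sc1 = compute_scores(G, wt, anns)
        wt2 = WeightTable(wt.table.assign(beta_ad=2 * wt.table.beta_ad,
                                          beta_ftd=2 * wt.table.beta_ftd))
        sc2 = compute_scores(G, wt2, anns)
        np.testing.assert_allclose(sc2.scores, 2 * sc1.scores)

    def test_zero_weight_variant_removal_invariance(self):
        G, wt, anns = self._setup(seed=2)
        tbl = wt.table.copy()
        tbl.loc[1, ["beta_ad", "beta_ftd"]] = 0.0
        tbl.loc[1, ["estimable_ad", "estimable_ftd"]] = False
        sc_with = compute_scores(G, WeightTable(tbl), anns)
        keep = [v for v in G.variants if v != "v1"]
        sc_without = compute_scores(
            G.subset_variants(keep),
            WeightTable(tbl[tbl.variant_id != "v1"]),
            [a for a in anns if a.variant_id != "v1"],
        )
        np.testing.assert_array_equal(sc_with.scores, sc_without.scores)

    def test_all_zero_weights_all_zero_scores(self):
        G, wt, anns = self._setup(seed=3)
        tbl = wt.table.assign(beta_ad=0.0, beta_ftd=0.0,
                              estimable_ad=False, estimable_ftd=False)
        sc = compute_scores(G, WeightTable(tbl), anns)
        assert (sc.scores == 0).all().all()

    def test_missing_weight_row_errors(self):
        G, wt, anns = self._setup(seed=4)
        with pytest.raises(ValueError, match="cover"):
            compute_scores(G, WeightTable(wt.table.iloc[:2]), anns)

    def test_score_independent_of_causative_status(self):
        # on synthetic data where causative carriage is independent of the
        # scored variants, the score must not correlate with it
        rng = np.random.default_rng(11)
        n = 1000
        G, wt, anns = self._setup(seed=5, n=n)
        sc = compute_scores(G, wt, anns)
        causative = rng.binomial(1, 0.5, n)
        r = np.corrcoef(sc.scores["ad_w_ad"], causative)[0, 1]
        assert abs(r) < 0.1


class TestDichotomize:
    def test_median_split(self):
        np.testing.assert_array_equal(dichotomize([1, 2, 3, 4]), [0, 0, 1, 1])

    def test_ties_at_median_are_low(self):
        np.testing.assert_array_equal(dichotomize([1, 1, 1, 2]), [0, 0, 0, 1])

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize([2, 2, 2])

    def test_reference_population(self):
        labels = dichotomize([0, 10], reference=[1, 2, 3, 4])
        np.testing.assert_array_equal(labels, [0, 1])


class TestStandardizeIQR:
    def test_mean_zero_and_unit_p80_p20_gap(self):
        rng = np.random.default_rng(12)
        x = rng.gamma(2, 1, 500)
        z = standardize_iqr(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        p20, p80 = np.quantile(z, [0.2, 0.8])
        assert p80 - p20 == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance_up_to_sign(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=300)
        np.testing.assert_allclose(standardize_iqr(2 * x + 7),
                                   standardize_iqr(x), atol=1e-12)
        np.testing.assert_allclose(standardize_iqr(-x), -standardize_iqr(x),
                                   atol=1e-12)

    def test_degenerate_spread_errors(self):
        with pytest.raises(ValueError, match="spread"):
            standardize_iqr([1.0] * 10 + [100.0])
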