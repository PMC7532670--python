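"""Signature importance, rank tests, and the genomic/transcriptomic scores."""

import numpy as np
import pandas as pd
import pytest

from epla.aggregation import feature_names, signature_matrix
from epla.signatures_omics import (
    MMR_GENE_SET,
    association_table,
    cyt_score,
    gene_set_score,
    indel_load,
    load_maf,
    minmax_normalize,
    pathway_deficiency,
    permutation_importance,
    spearman_corr,
    tmb,
    wilcoxon_rank_sum,
)

TOY_MUT = pd.DataFrame(
    [
        ("S1", "TP53", "missense"),
        ("S1", "TP53", "missense"),
        ("S1", "KRAS", "missense"),
        ("S1", "APC", "missense"),
        ("S1", "APC", "missense"),
        ("S1", "BRAF", "synonymous"),
        ("S1", "BRAF", "synonymous"),
        ("S1", "TTN", "INS"),
        ("S2", "MSH2", "missense"),
        ("S2", "MLH1", "synonymous"),
        ("S3", "MSH2", "synonymous"),
    ],
    columns=["sample_id", "gene", "variant_class"],
)


class TestWilcoxon:
    def test_exact_enumeration_case(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.9

    def test_shifted_gaussians(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(2, 1, 30)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_exact_vs_normal_agreement(self, rng):
        """Exact and asymptotic p agree within 0.02 at n=6/6 tie-free."""
        from scipy import stats

        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            _, p_exact = wilcoxon_rank_sum(x, y)  # exact path (n<=12, no ties)
            p_norm = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestGenomicScalars:
    def test_tmb_arithmetic(self):
        # S1: 5 missense + 1 INS nonsynonymous, 2 synonymous excluded
        assert tmb(TOY_MUT, "S1") == pytest.approx(6 / 38)

    def test_tmb_synonymous_only(self):
        assert tmb(TOY_MUT, "S3") == 0.0

    def test_tmb_unknown_sample(self):
        with pytest.raises(KeyError):
            tmb(TOY_MUT, "S9")

    def test_indel_load(self):
        assert indel_load(TOY_MUT, "S1") == 1
        assert indel_load(TOY_MUT, "S2") == 0

    def test_indel_duplicate_rows_counted(self):
        prof = pd.DataFrame(
            [("S", "G", "DEL"), ("S", "G", "DEL")],
            columns=["sample_id", "gene", "variant_class"],
        )
        assert indel_load(prof, "S") == 2

    def test_pathway_deficiency_nonsynonymous_hit(self):
        assert pathway_deficiency(TOY_MUT, "S2", MMR_GENE_SET) == "deficient"

    def test_pathway_deficiency_synonymous_ignored(self):
        assert pathway_deficiency(TOY_MUT, "S3", MMR_GENE_SET) == "proficient"

    def test_pathway_deficiency_no_hits(self):
        assert pathway_deficiency(TOY_MUT, "S1", MMR_GENE_SET) == "proficient"

    def test_pathway_empty_gene_set(self):
        with pytest.raises(ValueError):
            pathway_deficiency(TOY_MUT, "S1", set())

    def test_row_order_invariance(self, rng):
        shuffled = TOY_MUT.sample(frac=1, random_state=1).reset_index(drop=True)
        assert tmb(shuffled, "S1") == tmb(TOY_MUT, "S1")
        assert indel_load(shuffled, "S1") == indel_load(TOY_MUT, "S1")

    def test_maf_synonym_mapping(self, tmp_path):
        p = tmp_path / "muts.maf"
        p.write_text(
            "Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\n"
            "S1\tMLH1\tFrame_Shift_Ins\nS1\tTP53\tSilent\n"
        )
        prof = load_maf(p)
        assert list(prof["variant_class"]) == ["INS", "synonymous"]


class TestMinmax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_degenerate(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize([5, 5])
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_idempotent(self, rng):
        x = rng.uniform(size=10)
        once = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)


class TestExpressionScores:
    @pytest.fixture()
    def expr(self):
        genes = ["GZMA", "PRF1", "CD8A", "IFNG", "CXCL9", "CXCL10", "TBX21", "GZMB"]
        return pd.DataFrame({"X": [3.0, 8.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                             "Z": [0.0] * 8}, index=genes)

    def test_cyt_closed_form(self, expr):
        assert cyt_score(expr, "X") == pytest.approx(np.sqrt(4 * 9) - 1)  # 5

    def test_cyt_identity(self):
        expr = pd.DataFrame({"X": [7.0, 7.0]}, index=["GZMA", "PRF1"])
        assert cyt_score(expr, "X") == pytest.approx(7.0)

    def test_cyt_zeros(self, expr):
        assert cyt_score(expr, "Z") == 0.0

    def test_cyt_missing_gene(self):
        expr = pd.DataFrame({"X": [1.0]}, index=["GZMA"])
        with pytest.raises(KeyError, match="PRF1"):
            cyt_score(expr, "X")

    def test_gene_set_all_ones(self):
        genes = list(("CD8A", "IFNG", "GZMA", "PRF1", "CXCL9", "CXCL10", "TBX21", "GZMB"))
        expr = pd.DataFrame({"X": [1.0] * 8}, index=genes)
        assert gene_set_score(expr, "X") == pytest.approx(1.0)  # log2(2) = 1

    def test_gene_set_partial_with_warning(self):
        expr = pd.DataFrame({"X": [1.0, 3.0, 0.0, 7.0]},
                            index=["CD8A", "IFNG", "GZMA", "PRF1"])
        with pytest.warns(UserWarning, match="4"):
            got = gene_set_score(expr, "X")
        want = np.mean(np.log2(np.array([1, 3, 0, 7]) + 1))
        assert got == pytest.approx(want)

    def test_gene_set_all_missing(self):
        expr = pd.DataFrame({"X": [1.0]}, index=["OTHER"])
        with pytest.raises(KeyError):
            gene_set_score(expr, "X")


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=20)
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        from scipy import stats

        x = rng.uniform(size=100)
        y = rng.uniform(size=100)
        rho, _ = spearman_corr(x, y)
        want = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


class TestPermutationImportance:
    def test_constant_column_zero(self, default_cohort, fitted_epla):
        bags = {s: default_cohort["bags"][s] for s in default_cohort["train_ids"][:80]}
        sig = signature_matrix(bags, fitted_epla.vocab)
        # bin 45 of the histogram is (almost surely) constant zero here
        col = sig.columns[44]
        if sig[col].nunique() == 1:
            y = default_cohort["labels"].loc[sig.index].to_numpy()
            ranking = permutation_importance(sig, y, fitted_epla, n_repeats=2, seed=0)
            row = ranking.table[ranking.table["feature_name"] == col]
            assert row["importance"].iloc[0] == 0.0

    def test_layout_mismatch_errors(self, fitted_epla):
        bad = pd.DataFrame(np.zeros((3, 5)), columns=list("abcde"))
        with pytest.raises(ValueError):
            permutation_importance(bad, [0, 1, 0], fitted_epla)

    def test_ranks_are_permutation_and_sorted(self, default_cohort, fitted_epla):
        bags = {s: default_cohort["bags"][s] for s in default_cohort["train_ids"][:60]}
        sig = signature_matrix(bags, fitted_epla.vocab)
        y = default_cohort["labels"].loc[sig.index].to_numpy()
        ranking = permutation_importance(sig, y, fitted_epla, n_repeats=2, seed=0)
        t = ranking.table
        assert sorted(t["rank"]) == list(range(1, 201))
        assert (t["importance"].diff().dropna() <= 1e-12).all()


def test_association_table_bh():
    tab = association_table(["a", "b", "c"], [1.0, 2.0, 3.0], [0.01, 0.04, 0.03])
    # BH: sorted p (0.01,0.03,0.04) -> adjusted (0.03, 0.04, 0.045->min chain)
    assert tab.loc[tab["name"] == "a", "adjusted_p"].iloc[0] == pytest.approx(0.03)
    assert (tab["adjusted_p"] >= tab["p"] - 1e-15).all()
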