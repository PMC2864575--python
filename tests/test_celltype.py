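"""Cell-type DE: moderation, marker thresholds, calls, conservation overlap."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devocompare.celltype import (
    SAMPLE_COLUMNS,
    call_enriched,
    conserved_overlap,
    derive_thresholds,
    fold_change,
    nucleotide_de,
    whole_transcript_de,
)
from devocompare.errors import MissingDataError


def _counts(rows):
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).rename(
        index=lambda i: f"g{i}"
    )


class TestWholeTranscriptDE:
    def test_identical_cell_types_give_zero_fold(self):
        counts = _counts([[100, 110, 100, 110], [50, 55, 50, 55]])
        de = whole_transcript_de(counts)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)
        called = call_enriched(de, threshold=0.5)
        assert (called["call"] == "none").all()

    def test_prior_df_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.poisson(200, size=(300, 4)), columns=list(SAMPLE_COLUMNS)
        )
        de = whole_transcript_de(counts, prior_df=0)
        y = np.log2(counts.to_numpy(dtype=float) + 1)
        design = np.array([[1, 0, 1], [1, 1, 1], [1, 0, 0], [1, 1, 0]], dtype=float)
        beta, res_ss, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        s2 = res_ss  # residual df = 1
        c = np.linalg.inv(design.T @ design)[2, 2]
        t_manual = beta[2] / np.sqrt(s2 * c)
        p_manual = 2 * stats.t.sf(np.abs(t_manual), 1)
        np.testing.assert_allclose(de["statistic"], t_manual, rtol=1e-9)
        np.testing.assert_allclose(de["pvalue"], p_manual, rtol=1e-9)
        assert (de["df"] == 1.0).all()

    def test_moderation_stabilizes_small_variances(self):
        rng = np.random.default_rng(9)
        base = rng.poisson(500, size=(400, 1)).astype(float)
        counts = pd.DataFrame(
            base + rng.normal(0, 5, size=(400, 4)), columns=list(SAMPLE_COLUMNS)
        )
        de = whole_transcript_de(counts)
        de_raw = whole_transcript_de(counts, prior_df=0)
        # moderated statistics are less dispersed than df=1 ordinary t
        assert np.abs(de["statistic"]).max() < np.abs(de_raw["statistic"]).max()

    def test_swapping_cell_type_labels_negates_folds_and_calls(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(200, size=(200, 4)), columns=list(SAMPLE_COLUMNS)
        )
        counts.iloc[:50, :2] *= 4  # plant prespore enrichment
        swapped = counts[["prestalk_R1", "prestalk_R2", "prespore_R1", "prespore_R2"]]
        swapped.columns = list(SAMPLE_COLUMNS)
        de = whole_transcript_de(counts)
        de_sw = whole_transcript_de(swapped)
        np.testing.assert_allclose(de["log2fc"], -de_sw["log2fc"], atol=1e-12)
        calls = call_enriched(de, 0.05)["call"]
        calls_sw = call_enriched(de_sw, 0.05)["call"]
        assert (calls[calls == "prespore"].index == calls_sw[calls_sw == "prestalk"].index).all()

    def test_missing_replicate_column_raises(self):
        with pytest.raises(MissingDataError):
            whole_transcript_de(pd.DataFrame({"prespore_R1": [1.0]}))


class TestNucleotideDE:
    def test_identical_coverage_gives_zero_effect(self):
        cov = {"g": np.tile([[3, 3, 3, 3]], (60, 1)).astype(float)}
        de = nucleotide_de(cov)
        assert de.loc["g", "log2fc"] == pytest.approx(0.0)
        assert de.loc["g", "status"] == "ok"

    def test_uniform_twofold_shift_gives_unit_effect(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(2, 10, size=60)
        cov = {"g": np.column_stack([2 * base, 2 * base, base, base])}
        de = nucleotide_de(cov, pseudocount=0.0)
        assert de.loc["g", "log2fc"] == pytest.approx(1.0)

    def test_short_gene_skipped(self):
        cov = {"g": np.ones((10, 4))}
        de = nucleotide_de(cov, min_nucleotides=50)
        assert de.loc["g", "status"] == "too_few_nucleotides"
        assert np.isnan(de.loc["g", "pvalue"])

    def test_variable_sparse_coverage_not_called_but_flat_is(self):
        """The repeated-measures model punishes noisy sparse coverage."""
        rng = np.random.default_rng(12)
        L = 300
        flat = np.column_stack(
            [rng.poisson(8.0, L), rng.poisson(8.0, L), rng.poisson(2.0, L), rng.poisson(2.0, L)]
        ).astype(float)
        bias = np.exp2(rng.normal(0, 3.0, L))
        lam = 0.2 * bias / bias.mean()
        sparse = np.column_stack(
            [rng.poisson(4 * lam), rng.poisson(4 * lam), rng.poisson(lam), rng.poisson(lam)]
        ).astype(float)
        de = nucleotide_de({"flat": flat, "sparse": sparse})
        called = call_enriched(de, threshold=de.loc["flat", "pvalue"])
        assert called.loc["flat", "call"] == "prespore"
        assert called.loc["sparse", "call"] == "none"


class TestThresholdsAndCalls:
    def _de(self, pvals, lfc=None):
        idx = [f"g{i}" for i in range(len(pvals))]
        return pd.DataFrame(
            {
                "log2fc": lfc if lfc is not None else [2.0] * len(pvals),
                "pvalue": pvals,
            },
            index=idx,
        )

    def test_threshold_is_max_marker_p(self):
        de = self._de([0.001, 0.01, 0.04, 0.5])
        thr, absent = derive_thresholds(de, ["g0", "g1", "g2"])
        assert thr == 0.04 and absent == []

    def test_single_marker_threshold(self):
        de = self._de([0.007])
        thr, _ = derive_thresholds(de, ["g0"])
        assert thr == 0.007

    def test_absent_markers_listed_and_no_marker_raises(self):
        de = self._de([0.01])
        thr, absent = derive_thresholds(de, ["g0", "missing"])
        assert absent == ["missing"]
        with pytest.raises(MissingDataError):
            derive_thresholds(de, ["missing"])

    @pytest.mark.parametrize(
        "lfc,p,thr,expected",
        [
            (1.1, 0.03, 0.04, "prespore"),
            (0.85, 0.001, 0.04, "none"),   # fold 1.8 fails the two-fold rule
            (-1.2, 0.05, 0.04, "none"),    # P above the empirical threshold
            (-1.2, 0.03, 0.04, "prestalk"),
        ],
    )
    def test_call_rule(self, lfc, p, thr, expected):
        de = self._de([p], lfc=[lfc])
        assert call_enriched(de, thr)["call"].iloc[0] == expected

    def test_fold_change_override(self):
        de = self._de([0.001], lfc=[5.0])
        shared = pd.Series({"g0": 0.2})  # abundance-based fold below two-fold
        assert call_enriched(de, 0.04, log2fc=shared)["call"].iloc[0] == "none"

    def test_fold_change_helper_uses_replicate_means(self):
        counts = _counts([[30, 50, 9, 11]])
        fc = fold_change(counts)
        assert fc.iloc[0] == pytest.approx(np.log2(41) - np.log2(11))


class TestConservedOverlap:
    def _calls(self, mapping_):
        return pd.Series(mapping_)

    def test_disjoint_and_identical_sets(self):
        orth = pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]})
        calls_a = self._calls({"a1": "prespore", "a2": "none"})
        calls_b = self._calls({"b1": "none", "b2": "prestalk"})
        res = conserved_overlap(calls_a, calls_b, orth)
        assert res.n_conserved == 0
        calls_b2 = self._calls({"b1": "prespore", "b2": "none"})
        res2 = conserved_overlap(calls_a, calls_b2, orth)
        assert res2.n_conserved == 1
        assert res2.per_celltype["prespore"]["conserved"] == 1

    def test_hypergeometric_closed_form(self):
        orth = pd.DataFrame(
            {"gene_a": [f"a{i}" for i in range(10)], "gene_b": [f"b{i}" for i in range(10)]}
        )
        calls_a = self._calls({f"a{i}": "prespore" if i < 5 else "none" for i in range(10)})
        calls_b = self._calls({f"b{i}": "prespore" if i < 5 else "none" for i in range(10)})
        res = conserved_overlap(
            calls_a, calls_b, orth, other_set={f"a{i}" for i in range(5)}
        )
        assert res.enrichment["overlap"] == 5
        assert res.enrichment["pvalue"] == pytest.approx(1 / 252)

    def test_universe_too_small_raises(self):
        orth = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b1"]})
        calls = self._calls({"a1": "prespore", "b1": "prespore"})
        with pytest.raises(ValueError):
            conserved_overlap(
                calls, calls, orth, other_set={"x1", "x2"}, universe={"a1"}
            )


def test_nucleotide_calls_are_subset_of_whole_transcript_calls():
    """On the canonical expressed-filtered dataset, the repeated-measures
    nucleotide method calls no gene the whole-transcript method misses."""
    from devocompare import mapping, quantify
    from devocompare.synthetic import SimConfig, generate_toy_genomes, simulate_celltype_coverage

    cfg = SimConfig(n_genes_per_species=2000, seed=1)
    genomes, _, truth = generate_toy_genomes(cfg)
    data = simulate_celltype_coverage(genomes, truth, cfg, include_coverage=True)
    lens = pd.Series({g.gene_id: g.exonic_length for g in genomes["A"].genes})
    eff = mapping.EffectiveLengths(per_gene=lens, median=float(np.median(lens)))
    scaled = quantify.scale_abundance(data["A"].counts, eff)
    expressed = data["A"].counts.index[(data["A"].counts > 30).any(axis=1)]
    de_w = whole_transcript_de(scaled.values.loc[expressed])
    thr_w, _ = derive_thresholds(de_w, data["A"].markers)
    calls_w = call_enriched(de_w, thr_w)
    cov = {k: v for k, v in data["A"].coverage.items() if k in set(expressed)}
    de_n = nucleotide_de(cov)
    de_n = de_n[de_n["status"] == "ok"]
    thr_n, _ = derive_thresholds(de_n, data["A"].markers)
    calls_n = call_enriched(de_n, thr_n)
    set_w = set(calls_w.index[calls_w["call"] != "none"])
    set_n = set(calls_n.index[calls_n["call"] != "none"])
    assert set_n <= set_w
    assert len(set_n) < len(set_w)  # the nucleotide method is the stricter one
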