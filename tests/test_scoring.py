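"""Normalization, fold changes, medians, gene ranking and hit calling."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from poolscreen import (
    ScoringConfig,
    build_library,
    build_pairing,
    fold_change,
    median_fold_change,
    normalize,
    normalize_to_input,
    score_genes,
    waterfall,
)


def _df(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return df


class TestNormalize:
    def test_symmetric_counts_split_evenly(self):
        counts = pd.DataFrame({"s": [1, 1]}, index=["g1", "g2"])
        rep = normalize(counts, ScoringConfig(pseudocount=0))
        assert rep["s"].tolist() == [500000.0, 500000.0]

    def test_three_to_one_split(self):
        counts = pd.DataFrame({"s": [3, 1]}, index=["g1", "g2"])
        rep = normalize(counts, ScoringConfig(pseudocount=0))
        assert rep["s"].tolist() == [750000.0, 250000.0]

    def test_all_zero_sample_without_pseudocount_errors(self):
        counts = pd.DataFrame({"ok": [1, 2], "bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            normalize(counts, ScoringConfig(pseudocount=0))

    def test_pseudocount_makes_all_entries_positive(self):
        counts = pd.DataFrame({"s": [0, 10]}, index=["g1", "g2"])
        rep = normalize(counts, ScoringConfig(pseudocount=1.0))
        assert (rep > 0).all().all()
        assert rep["s"].sum() == pytest.approx(1e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(20, 3)), columns=["a", "b", "c"]
        )
        cfg = ScoringConfig(pseudocount=0)
        rep1 = normalize(counts, cfg)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 17
        rep2 = normalize(scaled, cfg)
        pd.testing.assert_frame_equal(rep1, rep2.astype(float))


class TestFoldChange:
    def test_basic_ratios(self):
        rep = pd.DataFrame({"T0": [100.0, 100.0], "T12": [50.0, 300.0]}, index=["g1", "g2"])
        fc = fold_change(rep, {"m1": ("T12", "T0")})
        assert fc.loc["g1", "m1"] == 0.5
        assert fc.loc["g2", "m1"] == 3.0

    def test_identical_columns_give_unity(self):
        rep = pd.DataFrame({"T0": [10.0, 20.0], "T12": [10.0, 20.0]}, index=["g1", "g2"])
        fc = fold_change(rep, {"m1": ("T12", "T0")})
        assert (fc["m1"] == 1.0).all()

    def test_shared_t0_pairs_with_every_replicate(self):
        rep = pd.DataFrame(
            {"T0": [100.0], "T12_m1": [50.0], "T12_m2": [200.0]}, index=["g1"]
        )
        pairing = {"m1": ("T12_m1", "T0"), "m2": ("T12_m2", "T0")}
        fc = fold_change(rep, pairing)
        assert fc.loc["g1", "m1"] == 0.5 and fc.loc["g1", "m2"] == 2.0

    def test_missing_sample_errors(self):
        rep = pd.DataFrame({"T0": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="T12_m1"):
            fold_change(rep, {"m1": ("T12_m1", "T0")})

    def test_build_pairing_from_sample_sheet(self):
        samples = pd.DataFrame(
            {
                "timepoint": ["T0", "T12", "T12"],
                "replicate_id": ["", "m1", "m2"],
            },
            index=pd.Index(["T0", "T12_m1", "T12_m2"], name="sample_id"),
        )
        assert build_pairing(samples) == {
            "m1": ("T12_m1", "T0"),
            "m2": ("T12_m2", "T0"),
        }


class TestMedianFoldChange:
    @pytest.mark.parametrize(
        "values,expected_median",
        [
            ([0.25, 0.5, 1.0], 0.5),
            ([0.7], 0.7),  # single replicate: identity
            ([0.5, 2.0], 1.25),  # even count: midpoint of central pair
        ],
    )
    def test_median_values(self, values, expected_median):
        fc = pd.DataFrame([values], index=["g1"])
        med = median_fold_change(fc)
        assert med.loc["g1", "median_fc"] == pytest.approx(expected_median)
        assert med.loc["g1", "log2_median_fc"] == pytest.approx(
            math.log2(expected_median)
        )

    def test_log2_column_is_exactly_log2_of_median(self):
        rng = np.random.default_rng(1)
        fc = pd.DataFrame(rng.lognormal(0, 1, size=(30, 5)))
        med = median_fold_change(fc)
        assert (med["log2_median_fc"] == np.log2(med["median_fc"])).all()


def _medians_frame(log2_by_guide: dict) -> pd.DataFrame:
    med = {g: 2.0**v for g, v in log2_by_guide.items()}
    return pd.DataFrame(
        {"median_fc": pd.Series(med), "log2_median_fc": pd.Series(log2_by_guide)}
    )


class TestScoreGenes:
    def _library(self, genes, per_gene=5, ntc=1):
        return build_library(list(genes), per_gene, n_nontargeting=ntc, seed=0)

    def test_fully_depleted_gene_is_positive_regulator(self):
        lib = self._library(["A"], per_gene=5)
        log2 = {f"A_sg{i}": -1.5 for i in range(1, 6)}
        log2["NTC_sg1"] = 0.0
        scores = score_genes(_medians_frame(log2), lib)
        (a,) = [s for s in scores.depletion if s.gene == "A"]
        assert a.n_depleted == 5 and a.classification == "positive_regulator"

    def test_two_guides_past_threshold_suffice(self):
        lib = self._library(["A"], per_gene=5, ntc=0)
        log2 = dict(
            zip(
                [f"A_sg{i}" for i in range(1, 6)],
                [-2.1, -0.5, -0.2, 0.1, -3.0],
            )
        )
        scores = score_genes(_medians_frame(log2), lib)
        (a,) = scores.depletion
        assert a.n_depleted == 2 and a.n_enriched == 0
        assert a.classification == "positive_regulator"

    def test_neutral_gene_classifies_none(self):
        lib = self._library(["A"], per_gene=3, ntc=0)
        log2 = {f"A_sg{i}": 0.0 for i in range(1, 4)}
        scores = score_genes(_medians_frame(log2), lib)
        (a,) = scores.depletion
        assert a.n_depleted == a.n_enriched == 0 and a.classification == "none"

    def test_ntc_reported_separately_not_scored(self):
        lib = self._library(["A"], per_gene=2, ntc=1)
        log2 = {"A_sg1": 0.0, "A_sg2": 0.0, "NTC_sg1": -2.0}
        scores = score_genes(_medians_frame(log2), lib)
        assert [s.gene for s in scores.depletion] == ["A"]
        assert list(scores.ntc.index) == ["NTC_sg1"]

    def test_unknown_guide_errors(self):
        lib = self._library(["A"], per_gene=1, ntc=0)
        med = _medians_frame({"A_sg1": 0.0, "ghost": 0.0})
        with pytest.raises(ValueError, match="ghost"):
            score_genes(med, lib)

    def test_threshold_boundary_is_inclusive(self):
        lib = self._library(["A"], per_gene=2, ntc=0)
        med = pd.DataFrame(
            {
                "median_fc": pd.Series({"A_sg1": 0.5, "A_sg2": 2.0}),
                "log2_median_fc": pd.Series({"A_sg1": -1.0, "A_sg2": 1.0}),
            }
        )
        (a,) = score_genes(med, lib).depletion
        assert a.n_depleted == 1 and a.n_enriched == 1
        assert a.classification == "none"  # tie: neither direction dominates

    def test_agrees_with_brute_force_threshold_oracle(self):
        rng = random.Random(5)
        genes = [f"G{i}" for i in range(12)]
        lib = self._library(genes, per_gene=4, ntc=1)
        cfg = ScoringConfig()
        for _ in range(10):
            log2 = {g.guide_id: rng.uniform(-3, 3) for g in lib}
            med = _medians_frame(log2)
            scores = score_genes(med, lib, cfg)
            by_gene = {s.gene: s for s in scores.depletion}
            for gene in genes:
                gids = [g.guide_id for g in lib.guides_for_gene(gene)]
                n_dep = sum(med.loc[gid, "median_fc"] <= 0.5 for gid in gids)
                n_enr = sum(med.loc[gid, "median_fc"] >= 2.0 for gid in gids)
                assert by_gene[gene].n_depleted == n_dep
                assert by_gene[gene].n_enriched == n_enr
                expected = "none"
                if n_dep >= 2 and n_dep > n_enr:
                    expected = "positive_regulator"
                elif n_enr >= 2 and n_enr > n_dep:
                    expected = "negative_regulator"
                assert by_gene[gene].classification == expected
            # ranking keys: count desc, |summary| desc, name asc
            dep = scores.depletion
            keys = [(-s.n_depleted, -abs(s.summary_log2fc), s.gene) for s in dep]
            assert keys == sorted(keys)
            assert [s.rank for s in dep] == list(range(1, len(dep) + 1))


class TestWaterfall:
    def test_sorted_descending_with_annotations(self):
        lib = build_library(["A"], 3, n_nontargeting=0, seed=0)
        log2 = {"A_sg1": -2.0, "A_sg2": 0.0, "A_sg3": 1.5}
        wf = waterfall(_medians_frame(log2), lib)
        assert wf["log2_median_fc"].tolist() == [1.5, 0.0, -2.0]
        assert wf["enriched"].tolist() == [True, False, False]
        assert wf["depleted"].tolist() == [False, False, True]
        assert wf.attrs["log2_threshold"] == 1.0
        assert len(wf) == 3
        assert set(wf.columns) >= {"gene", "role"}

    def test_ties_keep_stable_input_order(self):
        lib = build_library(["A"], 4, n_nontargeting=0, seed=0)
        log2 = {f"A_sg{i}": 0.0 for i in range(1, 5)}
        wf = waterfall(_medians_frame(log2), lib)
        assert list(wf.index) == [f"A_sg{i}" for i in range(1, 5)]


class TestNormalizeToInput:
    @pytest.mark.parametrize(
        "out,inp,expected", [(30, 60, 0.5), (90, 45, 2.0), (37.5, 37.5, 1.0)]
    )
    def test_ratio(self, out, inp, expected):
        assert normalize_to_input(out, inp) == pytest.approx(expected)

    def test_zero_input_errors(self):
        with pytest.raises(ValueError):
            normalize_to_input(10, 0)
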