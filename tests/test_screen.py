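"""Screen pipeline: normalization, phenotype scoring, Wald testing,
classification."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclust.screen import (classify_hits, compute_log2_ratios,
                               compute_phenotype_scores, count_protospacers,
                               downsample_to_common_depth, filter_low_abundance,
                               qc_essential_depletion, score_screen)
from phenoclust.screen import test_significance as wald_test

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


def _samples(n_reps=3, with_drug=True):
    rows = [("T0", "baseline", "T0", 1)]
    arms = ("vehicle", "drug") if with_drug else ("vehicle",)
    for arm in arms:
        for r in range(1, n_reps + 1):
            rows.append((f"{arm}_T10_r{r}", arm, "T10", r))
    return pd.DataFrame(
        rows, columns=["sample_id", "arm", "timepoint", "replicate"]
    ).set_index("sample_id")


class TestDownsampling:
    def test_equal_depth_is_identity(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [15, 15]}, index=["c1", "c2"])
        out = downsample_to_common_depth(counts, seed=0)
        pd.testing.assert_frame_equal(out, counts)

    def test_column_sums_equal_minimum(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 200, size=(50, 4)),
                              index=[f"c{i}" for i in range(50)])
        out = downsample_to_common_depth(counts, seed=1)
        assert (out.sum(axis=0) == counts.sum(axis=0).min()).all()
        assert (out.to_numpy() <= counts.to_numpy()).all()

    def test_hypergeometric_moments(self):
        """Downsampling (800, 200) to 500 reads: mean output matches the
        multivariate hypergeometric expectation (400, 100) within 3 SE."""
        counts = pd.DataFrame({"deep": [800, 200], "shallow": [400, 100]},
                              index=["c1", "c2"])
        n_rep = 10_000
        draws = np.array(
            [downsample_to_common_depth(counts, seed=s)["deep"].to_numpy()
             for s in range(n_rep)]
        )
        # Var of hypergeometric draw of 500 from 800/1000
        var = 500 * 0.8 * 0.2 * (1000 - 500) / (1000 - 1)
        se = np.sqrt(var / n_rep)
        assert abs(draws[:, 0].mean() - 400) < 3 * se

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"ok": [5, 5], "empty": [0, 0]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="empty"):
            downsample_to_common_depth(counts, seed=0)


class TestAbundanceFilter:
    def test_threshold_is_at_least_50(self):
        counts = pd.DataFrame(
            [[50] * 4, [49] * 4], index=["keep", "drop"],
            columns=["s1", "s2", "s3", "s4"],
        )
        kept, excluded = filter_low_abundance(counts)
        assert list(kept.index) == ["keep"]
        assert excluded == ["drop"]

    def test_zero_threshold_is_identity(self):
        counts = pd.DataFrame({"s": [0, 3]}, index=["c1", "c2"])
        kept, excluded = filter_low_abundance(counts, min_mean=0)
        pd.testing.assert_frame_equal(kept, counts)
        assert excluded == []

    def test_toy_means(self):
        means = [10, 49.9, 50, 120, 0]
        counts = pd.DataFrame({"s1": means, "s2": means},
                              index=[f"c{i}" for i in range(5)])
        kept, _ = filter_low_abundance(counts)
        assert len(kept) == 2


class TestLog2Ratios:
    def test_closed_forms(self):
        samples = _samples(n_reps=1)
        counts = pd.DataFrame(
            {
                "T0": [10, 10, 0],
                "vehicle_T10_r1": [10, 20, 31],
                "drug_T10_r1": [10, 20, 31],
            },
            index=["flat", "doubled", "fromzero"],
        )
        ratios = compute_log2_ratios(counts, samples, pseudocount=1)
        vehicle = ratios["vehicle"][1]
        assert vehicle["flat"] == 0.0
        assert vehicle["doubled"] == pytest.approx(np.log2(21 / 11))
        assert vehicle["fromzero"] == pytest.approx(5.0)  # log2(32/1)

    def test_exact_doubling_without_pseudocount(self):
        samples = _samples(n_reps=1)
        counts = pd.DataFrame(
            {"T0": [8], "vehicle_T10_r1": [16], "drug_T10_r1": [16]}, index=["c"]
        )
        ratios = compute_log2_ratios(counts, samples, pseudocount=0)
        assert ratios[("vehicle", 1)]["c"] == 1.0

    def test_missing_baseline_is_reported(self):
        samples = _samples(n_reps=2).drop("T0")
        counts = pd.DataFrame(
            np.ones((2, 4), dtype=int), index=["c1", "c2"], columns=samples.index
        )
        with pytest.raises(ValueError, match="T0"):
            compute_log2_ratios(counts, samples)


class TestPhenotypeScores:
    def _toy_ratios(self):
        # 3 NTCs with mean ratios -0.1, 0, 0.1 and one target at 1.6
        data = {("vehicle", 1): [-0.1, 0.0, 0.1, 1.6],
                ("drug", 1): [-0.1, 0.0, 0.1, 1.6]}
        ratios = pd.DataFrame(data, index=["n1", "n2", "n3", "t"])
        ratios.columns = pd.MultiIndex.from_tuples(ratios.columns,
                                                   names=["arm", "replicate"])
        ntc = pd.Series([True, True, True, False], index=ratios.index)
        return ratios, ntc

    def test_hand_computed_oracle(self):
        ratios, ntc = self._toy_ratios()
        table, ntc_stats = compute_phenotype_scores(
            ratios, {"vehicle": 8.0, "drug": 8.0}, ntc, min_ntc=3
        )
        assert table[("vehicle", "phenotype")]["t"] == pytest.approx(0.2)
        # NTC phenotypes are {-0.0125, 0, 0.0125}; sample SD = 0.0125
        assert ntc_stats["vehicle"].sd_phenotype == pytest.approx(0.0125)
        assert table[("vehicle", "z")]["t"] == pytest.approx(0.2 / 0.0125)

    def test_ntc_median_centering(self):
        ratios, ntc = self._toy_ratios()
        table, _ = compute_phenotype_scores(
            ratios, {"vehicle": 8.0, "drug": 8.0}, ntc, min_ntc=3
        )
        assert table[("vehicle", "phenotype")]["n2"] == 0.0
        assert table[("vehicle", "z")]["n2"] == 0.0

    def test_doubling_scaling(self):
        ratios, ntc = self._toy_ratios()
        t8, _ = compute_phenotype_scores(ratios, {"vehicle": 8.0, "drug": 8.0},
                                         ntc, min_ntc=3)
        t4, _ = compute_phenotype_scores(ratios, {"vehicle": 4.0, "drug": 4.0},
                                         ntc, min_ntc=3)
        assert t8[("vehicle", "phenotype")]["t"] == pytest.approx(
            t4[("vehicle", "phenotype")]["t"] / 2
        )

    def test_too_few_ntcs_rejected(self):
        ratios, ntc = self._toy_ratios()
        with pytest.raises(ValueError, match="NTC"):
            compute_phenotype_scores(ratios, {"vehicle": 8.0, "drug": 8.0}, ntc)


class TestWald:
    def test_benjamini_hochberg_properties(self, small_screen):
        _, lib, samples, counts, _ = small_screen
        filtered, _ = filter_low_abundance(downsample_to_common_depth(counts, seed=0))
        table = wald_test(filtered, samples, "vehicle")
        assert (table["padj"] >= table["p"]).all()
        ordered = table.sort_values("p")
        assert ordered["padj"].is_monotonic_increasing

    def test_matches_statsmodels_glm(self, small_screen):
        """The closed-form Wald coefficient and SE agree with an explicit
        statsmodels NB GLM fit at the same dispersion."""
        import statsmodels.api as sm

        _, lib, samples, counts, _ = small_screen
        filtered, _ = filter_low_abundance(downsample_to_common_depth(counts, seed=0))
        table = wald_test(filtered, samples, "vehicle")
        t10 = samples[(samples.arm == "vehicle") & (samples.timepoint == "T10")].index
        for construct in filtered.index[:5]:
            y = np.concatenate([
                filtered.loc[construct, ["T0"]].to_numpy(dtype=float),
                filtered.loc[construct, t10].to_numpy(dtype=float),
            ])
            X = sm.add_constant(np.array([0.0, 1.0, 1.0, 1.0]))
            alpha = table.loc[construct, "dispersion"]
            fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            z_sm = fit.params[1] / fit.bse[1]
            assert table.loc[construct, "wald_z"] == pytest.approx(z_sm, rel=1e-4)

    def test_single_replicate_rejected(self):
        samples = _samples(n_reps=1)
        counts = pd.DataFrame(
            np.full((3, 3), 100), index=["c1", "c2", "c3"], columns=samples.index
        )
        with pytest.raises(ValueError, match="dispersion"):
            wald_test(counts, samples, "vehicle")


class TestClassification:
    @pytest.mark.parametrize(
        "vehicle, drug, expected",
        [
            ((3.57, 8.10e-86), (2.18, 6.33e-31), "shared_enriched"),   # NF2-like
            ((-0.63, 0.38), (-2.12, 0.0001), "drug_selective_depleted"),  # KRAS-like
            ((1.01, 0.24), (1.66, 0.04), "drug_selective_enriched"),   # RB1-like
            ((-3.57, 1.12e-6), (-3.47, 2.08e-6), "shared_depleted"),   # CDH2-like
            ((2.0, 0.001), (0.5, 0.5), "vehicle_only_enriched"),
            ((2.0, 0.001), (-2.0, 0.001), "not_significant"),  # discordant
        ],
    )
    def test_significance_patterns(self, vehicle, drug, expected):
        pv = pd.DataFrame({"log2fc": [vehicle[0]], "padj": [vehicle[1]]}, index=["g"])
        pdr = pd.DataFrame({"log2fc": [drug[0]], "padj": [drug[1]]}, index=["g"])
        classes, listings = classify_hits(pv, pdr)
        assert classes["g"] == expected
        if expected != "not_significant":
            assert "g" in listings[expected]

    def test_mismatched_constructs_rejected(self):
        pv = pd.DataFrame({"log2fc": [1.0], "padj": [0.01]}, index=["a"])
        pdr = pd.DataFrame({"log2fc": [1.0], "padj": [0.01]}, index=["b"])
        with pytest.raises(ValueError, match="symmetric"):
            classify_hits(pv, pdr)


class TestEssentialQC:
    def test_planted_essentials_predominantly_depleted(self, small_screen):
        _, lib, samples, counts, truth = small_screen
        results, _ = score_screen(lib, samples, counts, seed=0)
        essentials = set(
            lib.loc[truth.construct_classes.reindex(lib.index) == "essential", "gene"]
        )
        pheno = results[["gene", "vehicle_log2fc", "vehicle_padj"]].rename(
            columns={"vehicle_log2fc": "log2fc", "vehicle_padj": "padj"}
        )
        qc = qc_essential_depletion(pheno, essentials)
        assert qc.n_depleted / qc.n_essential_tested >= 0.8
        assert qc.n_enriched <= 0.05 * qc.n_essential_tested
        assert qc.passed

    def test_degenerate_alpha_counts_every_construct(self):
        pheno = pd.DataFrame(
            {"gene": ["a", "b"], "log2fc": [1.0, -1.0], "padj": [0.9, 0.7]},
            index=["c1", "c2"],
        )
        qc = qc_essential_depletion(pheno, {"a", "b"}, alpha=1.0)
        assert qc.n_depleted + qc.n_enriched == qc.n_essential_tested == 2

    def test_disjoint_essential_set_rejected(self):
        pheno = pd.DataFrame(
            {"gene": ["a"], "log2fc": [1.0], "padj": [0.9]}, index=["c1"]
        )
        with pytest.raises(ValueError, match="intersect"):
            qc_essential_depletion(pheno, {"zzz"})


class TestProtospacerCounting:
    def _library(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B"],
                "protospacer_a": ["ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"],
                "protospacer_b": ["GGGGGGGGGGGGGGGGGGGG", "CCCCCCCCCCCCCCCCCCCC"],
                "is_ntc": [False, False],
            },
            index=pd.Index(["cA", "cB"], name="construct_id"),
        )

    @staticmethod
    def _fastq(seqs):
        return io.StringIO(
            "".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs))
        )

    def test_exact_matching(self):
        reads = self._fastq(["ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT",
                             "TTTTCCCCGGGGAAAATTTT"])
        counts, report = count_protospacers(reads, self._library())
        assert counts["cA"] == 2 and counts["cB"] == 1
        assert report["match_rate"] == 1.0

    def test_single_mismatch_unassigned(self):
        reads = self._fastq(["ACGTACGTACGTACGTACGA"])
        counts, report = count_protospacers(reads, self._library())
        assert counts.sum() == 0
        assert report["unassigned"] == 1

    def test_empty_stream(self):
        with pytest.warns(UserWarning, match="empty"):
            counts, report = count_protospacers(self._fastq([]), self._library())
        assert counts.sum() == 0
        assert np.isnan(report["match_rate"])

    def test_collisions_rejected(self):
        lib = self._library()
        lib.loc["cB", "protospacer_a"] = lib.loc["cA", "protospacer_a"]
        with pytest.raises(ValueError, match="collision"):
            count_protospacers(self._fastq([]), lib)


class TestEndToEnd:
    def test_construct_permutation_invariance(self, small_screen):
        _, lib, samples, counts, _ = small_screen
        base, _ = score_screen(lib, samples, counts, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(counts))
        shuffled, _ = score_screen(lib.iloc[perm], samples, counts.iloc[perm], seed=4)
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5), st.floats(1e-12, 1), st.floats(-5, 5),
                st.floats(1e-12, 1),
            ),
            min_size=1, max_size=30,
        )
    )
    def test_hit_classes_consistent_with_significance_pattern(self, rows):
        """Property: every assigned class agrees with the padj/direction
        pattern that defines it."""
        idx = [f"c{i}" for i in range(len(rows))]
        pv = pd.DataFrame({"log2fc": [r[0] for r in rows],
                           "padj": [r[1] for r in rows]}, index=idx)
        pdr = pd.DataFrame({"log2fc": [r[2] for r in rows],
                            "padj": [r[3] for r in rows]}, index=idx)
        classes, _ = classify_hits(pv, pdr, alpha=0.05)
        for cid in idx:
            sig_v, sig_d = pv.padj[cid] < 0.05, pdr.padj[cid] < 0.05
            cls = classes[cid]
            if cls.startswith("shared"):
                assert sig_v and sig_d
                assert (pv.log2fc[cid] > 0) == (pdr.log2fc[cid] > 0)
            elif cls.startswith("drug_selective"):
                assert sig_d and not sig_v
            elif cls.startswith("vehicle_only"):
                assert sig_v and not sig_d
            else:
                assert not (sig_v and sig_d
                            and (pv.log2fc[cid] > 0) == (pdr.log2fc[cid] > 0)) \
                    and not (sig_d ^ sig_v)
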