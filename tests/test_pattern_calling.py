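import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dynamark as dm
from dynamark.io_formats import BinnedTrack, GeneModel, GenomicInterval
from dynamark.pattern_calling import (
    CallParameters,
    call_peak_patterns,
    classify_code,
    compare_fc_distributions,
    consistency_filter,
    iu_call,
    mann_whitney_one_sided,
    summarize_patterns,
)
from dynamark.quantify import WindowSpec


# ---------------------------------------------------------------------------
# independent oracle: exact permutation enumeration of the U statistic


def mwu_permutation_p(x, y, alternative="greater"):
    """Brute-force Mann-Whitney p: enumerate all labelings of the combined
    sample and count those at least as extreme as the observed U."""
    x, y = list(x), list(y)
    n1 = len(x)
    combined = x + y

    def u_stat(xs, ys):
        return sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys
        )

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        sel = set(idx)
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in sel]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater":
            count += u >= u_obs
        else:
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return count / total


class TestMannWhitneyOneSided:
    def test_identical_samples_not_significant(self, rng):
        v = rng.uniform(0, 1, 20)
        assert mann_whitney_one_sided(v, v) >= 0.5

    def test_near_complete_separation(self):
        assert mann_whitney_one_sided([5, 6, 7, 8, 9], [1, 2, 3, 4, 5]) < 0.05

    def test_single_observations_least_favorable(self):
        # x below y: one-sided "greater" p is 1.0 by exact enumeration
        assert mann_whitney_one_sided([1.0], [2.0]) == 1.0

    def test_all_values_identical_returns_one(self):
        assert mann_whitney_one_sided([3.0] * 10, [3.0] * 10) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (4, 4), (3, 8), (8, 8)])
    def test_matches_permutation_oracle_tie_free(self, rng, n1, n2):
        """Exact-path p equals brute-force enumeration on tie-free samples."""
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            assert mann_whitney_one_sided(x, y) == pytest.approx(
                mwu_permutation_p(x, y), abs=1e-9
            )

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        """Tie-corrected normal approximation tracks enumeration at n=8."""
        import scipy.stats

        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, 17.0))
            x, y = vals[:8], vals[8:]
            exact = mwu_permutation_p(x, y)
            approx = float(
                scipy.stats.mannwhitneyu(
                    x, y, alternative="greater", method="asymptotic"
                ).pvalue
            )
            assert approx == pytest.approx(exact, abs=0.03)


class TestCompareFcDistributions:
    def test_identical_distributions_not_significant(self, rng):
        v = rng.uniform(0.5, 2.0, 200)
        assert compare_fc_distributions(v, v) >= 0.99

    def test_fully_separated_samples(self, rng):
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(10, 11, 20)
        assert compare_fc_distributions(a, b) < 1e-6

    def test_symmetry(self, rng):
        a, b = rng.uniform(0, 1, 30), rng.uniform(0.2, 1.2, 25)
        assert compare_fc_distributions(a, b) == compare_fc_distributions(b, a)

    def test_matches_two_sided_permutation_oracle(self, rng):
        vals = rng.permutation(np.arange(1.0, 13.0))
        x, y = vals[:6], vals[6:]
        assert compare_fc_distributions(x, y) == pytest.approx(
            mwu_permutation_p(x, y, "two-sided"), abs=1e-9
        )


class TestIUCall:
    def test_identical_signal_is_unchanged(self, rng):
        v = rng.uniform(1, 5, 20)
        call = iu_call("u", "c", v, v)
        assert call.designation == "U"
        assert call.fold_change == pytest.approx(1.0)

    def test_fc_below_threshold_blocks_i_despite_tiny_p(self, rng):
        # 1.4-fold uniform elevation: p is tiny but the fc gate holds
        inp = rng.uniform(10, 11, 100)
        chip = inp * 1.4
        call = iu_call("u", "c", chip, inp, CallParameters(pseudocount=1e-9))
        assert call.p_value < 1e-6
        assert call.fold_change == pytest.approx(1.4, rel=1e-6)
        assert call.designation == "U"

    def test_three_fold_enrichment_called_increased(self, rng):
        inp = rng.gamma(10, 1, 20)
        chip = 3 * inp + rng.normal(0, 0.3, 20)
        call = iu_call("u", "c", chip, inp)
        assert call.designation == "I"
        assert call.p_value < 0.05 and call.fold_change > 1.5

    def test_low_coverage_units_called_unchanged(self):
        call = iu_call("u", "c", [9.0, 9.0, 9.0], [1.0, 1.0, 1.0])
        assert call.designation == "U"
        assert call.low_coverage

    @given(
        chip=st.lists(st.floats(0, 50, allow_nan=False), min_size=4, max_size=30),
        seed=st.integers(0, 1000),
    )
    def test_designation_is_exact_conjunction(self, chip, seed):
        """I holds iff p < alpha AND fc > fc_min, for arbitrary inputs."""
        rng = np.random.default_rng(seed)
        inp = rng.uniform(0, 50, len(chip))
        params = CallParameters()
        call = iu_call("u", "c", chip, inp, params)
        expect_i = call.p_value < params.alpha and call.fold_change > params.fc_min
        assert (call.designation == "I") == expect_i


class TestClassifyCode:
    ALL_CODES = ["".join(c) for c in itertools.product("IU", repeat=3)]

    @pytest.mark.parametrize(
        "code,label", [("IUI", "GP1"), ("IUU", "GP2"), ("UII", "GP3"), ("UIU", "GP4")]
    )
    def test_dynamic_mapping_genes(self, code, label):
        assert classify_code(code, "gene") == label

    def test_peak_variant(self):
        assert classify_code("UIU", "peak") == "PP4"
        assert classify_code("IUI", "peak") == "PP1"

    def test_total_over_eight_codes_four_dynamic_bijective(self):
        labels = [classify_code(c, "gene") for c in self.ALL_CODES]
        dynamic = [l for l in labels if l != "static"]
        assert len(dynamic) == 4 and len(set(dynamic)) == 4
        assert labels.count("static") == 4

    @pytest.mark.parametrize("bad", ["IU", "IUIX", "AUI", "iui"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_code(bad)


class TestConsistencyFilter:
    def test_all_i_vacuous(self, rng):
        vecs = [rng.normal(1.5, 0.2, 30) for _ in range(3)]
        assert consistency_filter(vecs, "III") is True

    def test_identical_fc_vectors_fail(self, rng):
        v = rng.normal(0, 1, 30)
        assert consistency_filter([v, v.copy(), v.copy()], "IUU") is False

    def test_separated_fc_vectors_pass(self, rng):
        i_fc = rng.normal(1.5, 0.2, 30)
        u_fc1 = rng.normal(0, 0.2, 30)
        u_fc2 = rng.normal(0, 0.2, 30)
        i_fc2 = rng.normal(1.5, 0.2, 30)
        assert consistency_filter([i_fc, u_fc1, i_fc2], "IUI") is True
        assert consistency_filter([i_fc, u_fc1, u_fc2], "IUU") is True

    def test_demotion_monotone_in_alpha(self, rng):
        """Lowering consistency_alpha never flips False -> True."""
        for _ in range(20):
            vecs = [rng.normal(rng.uniform(0, 1), 0.5, 15) for _ in range(3)]
            results = [
                consistency_filter(vecs, "IUU", a) for a in (0.2, 0.05, 0.01, 0.001)
            ]
            # passes can only be lost as alpha decreases
            assert all(a or not b for a, b in zip(results, results[1:]))


def _uniform_tracks(value_by_cond, n_bins=50, bin_size=200):
    """Constant-value chip/input tracks per condition for hand-built cases."""
    tracks = {}
    for cond, (chip_v, inp_v) in value_by_cond.items():
        tracks[cond] = {
            "chip": BinnedTrack(bin_size, {"chr1": np.full(n_bins, chip_v)}, 1e6),
            "input": BinnedTrack(bin_size, {"chr1": np.full(n_bins, inp_v)}, 1e6),
        }
    return tracks


class TestCallPeakPatterns:
    CONDS = ["reference", "disease", "rescue"]

    def test_zero_signal_peak_is_all_unchanged(self):
        tracks = _uniform_tracks({c: (0.0, 0.0) for c in self.CONDS})
        peaks = [GenomicInterval("chr1", 0, 4000, name="pk1")]
        out = call_peak_patterns(tracks, peaks, CallParameters(), conditions=self.CONDS)
        assert out.loc[0, "code"] == "UUU"
        assert out.loc[0, "class_label"] == "static"

    def test_dynamic_peak_demoted_when_consistency_fails(self, rng):
        # reference barely clears both I gates (fc ~1.55) while disease and
        # rescue sit just under the fc gate (~1.45) with heavily overlapping
        # per-bin log2fc distributions: the I-vs-U fold-change comparison is
        # then far from significant and the IUU peak must demote to static
        n = 40
        inp = np.full(n, 100.0)
        mk = lambda shift: np.clip(100.0 * 2 ** rng.normal(shift, 0.5, n), 0, None)
        tracks = {
            "reference": {
                "chip": BinnedTrack(200, {"chr1": mk(0.55)}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
            "disease": {
                "chip": BinnedTrack(200, {"chr1": mk(0.44)}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
            "rescue": {
                "chip": BinnedTrack(200, {"chr1": mk(0.44)}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
        }
        peak = [GenomicInterval("chr1", 0, 200 * n, name="pk1")]
        out = call_peak_patterns(tracks, peak, CallParameters(), conditions=self.CONDS)
        assert out.loc[0, "code"] == "IUU"
        assert out.loc[0, "class_label"] == "static"
        assert bool(out.loc[0, "consistency_pass"]) is False

    def test_synthetic_pp1_peak_passes_both_stages(self, rng):
        n = 40
        inp = rng.gamma(20, 0.5, n)
        enriched = lambda: inp * 3 + rng.normal(0, 0.5, n)
        tracks = {
            "reference": {
                "chip": BinnedTrack(200, {"chr1": np.clip(enriched(), 0, None)}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
            "disease": {
                "chip": BinnedTrack(200, {"chr1": inp + rng.normal(0, 0.2, n) ** 2}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
            "rescue": {
                "chip": BinnedTrack(200, {"chr1": np.clip(enriched(), 0, None)}, 1e6),
                "input": BinnedTrack(200, {"chr1": inp.copy()}, 1e6),
            },
        }
        peak = [GenomicInterval("chr1", 0, 200 * n, name="pk1")]
        out = call_peak_patterns(tracks, peak, CallParameters(), conditions=self.CONDS)
        assert out.loc[0, "class_label"] == "PP1"
        assert bool(out.loc[0, "consistency_pass"]) is True


class TestSummarizePatterns:
    def test_reproduces_published_style_percentages(self):
        counts = {"GP1": 2293, "GP2": 786, "GP3": 154, "GP4": 66, "static": 1000}
        df = pd.DataFrame(
            {"class_label": [c for c, n in counts.items() for _ in range(n)]}
        )
        summary = summarize_patterns(df).set_index("class_label")
        assert summary.loc["total", "count"] == 3299
        assert summary.loc["GP1", "percent"] == 70  # 69.51 rounds half-away
        assert summary.loc["GP2", "percent"] == 24
        assert summary.loc["GP3", "percent"] == 5
        assert summary.loc["GP4", "percent"] == 2

    def test_single_class(self):
        df = pd.DataFrame({"class_label": ["GP1"]})
        s = summarize_patterns(df).set_index("class_label")
        assert s.loc["GP1", "percent"] == 100

    def test_even_split(self):
        df = pd.DataFrame({"class_label": ["GP1", "GP4"]})
        s = summarize_patterns(df).set_index("class_label")
        assert s.loc["GP1", "percent"] == 50 and s.loc["GP4", "percent"] == 50

    def test_no_dynamic_units_gives_empty_summary(self):
        df = pd.DataFrame({"class_label": ["static", "static"]})
        assert summarize_patterns(df).empty


class TestGenomewideFc:
    def test_identical_tracks_give_unit_fc(self):
        conds = ["reference", "disease", "rescue"]
        tracks = _uniform_tracks({c: (2.0, 2.0) for c in conds})
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 6000, 8000, "+", "g1")),
        ]
        sizes = {"chr1": 10_000}
        fc = dm.genomewide_fc_table(
            tracks, genes, WindowSpec(), sizes, conditions=conds
        )
        for c in conds:
            assert fc.loc[0, f"fc_{c}"] == pytest.approx(1.0)

    def test_doubled_chip_gives_fc_two(self):
        conds = ["reference", "disease", "rescue"]
        tracks = _uniform_tracks({c: (4.0, 2.0) for c in conds})
        genes = [GeneModel("g1", GenomicInterval("chr1", 6000, 8000, "+", "g1"))]
        fc = dm.genomewide_fc_table(
            tracks, genes, WindowSpec(), {"chr1": 10_000}, conditions=conds
        )
        assert fc.loc[0, "fc_reference"] == pytest.approx(4.25 / 2.25)

    def test_row_count_matches_unskipped_genes(self, sim_dataset, sim_config):
        tracks, genes, _, sizes = sim_dataset
        fc = dm.genomewide_fc_table(
            tracks, genes, WindowSpec(), sizes, conditions=list(sim_config.conditions)
        )
        assert len(fc) == len(genes)
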