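"""Copy-number profiling: ratios, segmentation, calls, group summaries and
exact tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import methylcascade as mc
from methylcascade.cnv import (
    CnvCallParams,
    _freeman_halton_2x3,
    bin_and_segment,
    call_segments,
    cnv_profile,
    fisher_exact_table,
)


def _flat_manifest(n_probes, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, n_probes + 1) * 1000, "gene": ""},
        index=pd.Index([f"cg{i:06d}" for i in range(n_probes)], name="probe_id"),
    )


class TestLog2Ratio:
    def _panel(self, seed=0, n_probes=100, n_ctrl=5):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"cg{i:06d}" for i in range(n_probes)])
        return pd.DataFrame(
            rng.lognormal(np.log(5000), 0.1, size=(n_probes, n_ctrl)), index=idx
        )

    def test_query_equal_to_baseline_median_gives_zero(self):
        panel = self._panel()
        query = panel.median(axis=1)
        ratios = mc.compute_log2_ratio(query, panel)
        np.testing.assert_allclose(ratios.iloc[:, 0], 0.0, atol=1e-12)

    @pytest.mark.parametrize("factor,expected", [(2.0, 1.0), (0.5, -1.0)])
    def test_scaled_region_recovers_log2_factor(self, factor, expected):
        panel = self._panel(seed=1)
        query = panel.median(axis=1).copy()
        query.iloc[:10] *= factor
        ratios = mc.compute_log2_ratio(query, panel).iloc[:, 0]
        # median-centering is anchored by the 90 unchanged probes
        np.testing.assert_allclose(ratios.iloc[:10], expected, atol=1e-9)
        np.testing.assert_allclose(ratios.iloc[10:], 0.0, atol=1e-9)

    def test_nonpositive_intensity_raises(self):
        panel = self._panel()
        query = panel.median(axis=1).copy()
        query.iloc[3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            mc.compute_log2_ratio(query, panel)

    def test_small_baseline_panel_rejected(self):
        panel = self._panel(n_ctrl=2)
        with pytest.raises(ValueError, match=">= 3"):
            mc.compute_log2_ratio(panel.iloc[:, 0], panel)


class TestSegmentation:
    def test_flat_profile_single_neutral_segment(self):
        man = _flat_manifest(200)
        ratios = pd.Series(0.0, index=man.index)
        bins, segs = bin_and_segment(ratios, man, CnvCallParams(probes_per_bin=10))
        assert len(segs) == 1
        assert segs.iloc[0].mean_ratio == pytest.approx(0.0)
        prof = call_segments("s", bins, segs)
        assert (prof.segments["call"] == "neutral").all()

    def test_step_function_breakpoint_recovered(self):
        man = _flat_manifest(200)
        vals = np.zeros(200)
        vals[100:] = 0.4
        rng = np.random.default_rng(0)
        ratios = pd.Series(vals + rng.normal(0, 0.02, 200), index=man.index)
        bins, segs = bin_and_segment(ratios, man, CnvCallParams(probes_per_bin=10))
        assert len(segs) == 2
        # breakpoint at bin 10 (+-1)
        assert abs(segs.iloc[1].start_bin - 10) <= 1
        assert segs.iloc[0].mean_ratio == pytest.approx(0.0, abs=0.05)
        assert segs.iloc[1].mean_ratio == pytest.approx(0.4, abs=0.05)

    def test_three_breakpoints_recovered_within_one_bin(self):
        man = _flat_manifest(400)
        vals = np.zeros(400)
        vals[100:180] = 0.3
        vals[250:320] = -0.3
        rng = np.random.default_rng(1)
        ratios = pd.Series(vals + rng.normal(0, 0.03, 400), index=man.index)
        bins, segs = bin_and_segment(ratios, man, CnvCallParams(probes_per_bin=10))
        starts = sorted(segs.start_bin)[1:]
        expected = [10, 18, 25, 32]
        assert len(starts) == 4
        for s, e in zip(starts, expected):
            assert abs(s - e) <= 1

    def test_segment_means_reconstruct_global_mean(self):
        man = _flat_manifest(300)
        rng = np.random.default_rng(2)
        vals = np.zeros(300)
        vals[120:] = 0.5
        ratios = pd.Series(vals + rng.normal(0, 0.05, 300), index=man.index)
        bins, segs = bin_and_segment(ratios, man, CnvCallParams(probes_per_bin=10))
        weighted = (segs.mean_ratio * segs.n_bins).sum() / segs.n_bins.sum()
        assert weighted == pytest.approx(bins.ratio.mean(), abs=1e-9)


class TestCalls:
    @pytest.mark.parametrize(
        "mean,expected", [(0.15, "neutral"), (-0.30, "loss"), (0.16, "gain")]
    )
    def test_call_threshold_is_strict(self, mean, expected):
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [10],
                             "n_probes": [10], "ratio": [mean]})
        segs = pd.DataFrame({"chrom": ["chr1"], "start_bin": [0], "end_bin": [0],
                             "start": [1], "end": [10], "n_bins": [1],
                             "mean_ratio": [mean]})
        prof = call_segments("s", bins, segs, CnvCallParams(tau=0.15))
        assert prof.segments.iloc[0].call == expected

    def test_raising_tau_never_creates_calls(self):
        rng = np.random.default_rng(3)
        means = rng.uniform(-0.5, 0.5, 50)
        segs = pd.DataFrame({"chrom": "chr1", "start_bin": range(50),
                             "end_bin": range(50), "start": 1, "end": 2,
                             "n_bins": 1, "mean_ratio": means})
        bins = pd.DataFrame({"chrom": ["chr1"] * 50, "start": 1, "end": 2,
                             "n_probes": 1, "ratio": means})
        loose = call_segments("s", bins, segs, CnvCallParams(tau=0.15)).segments.call
        tight = call_segments("s", bins, segs, CnvCallParams(tau=0.25)).segments.call
        newly_called = (loose == "neutral") & (tight != "neutral")
        assert not newly_called.any()

    def test_spiked_single_copy_loss_always_called(self, small_cohort):
        co = small_cohort
        man = co.manifest
        chr5 = man[man.chrom == "chr5"]
        region = ("chr5", int(chr5.pos.min()), int(chr5.pos.max()))
        sp = mc.spike_copy_number(co, region, 1, ["S0000"])
        baseline = sp.total_intensity.iloc[:, 60:80]
        prof = cnv_profile(sp.total_intensity["S0000"], baseline, man,
                           CnvCallParams(), "S0000")
        hit = prof.segments[(prof.segments.chrom == "chr5")
                            & (prof.segments.call == "loss")]
        assert len(hit) >= 1
        assert hit.mean_ratio.min() == pytest.approx(-1.0, abs=0.1)

    def test_small_shift_below_threshold_never_called(self):
        man = _flat_manifest(200)
        vals = np.zeros(200)
        vals[50:100] = 0.14  # 10%-magnitude shift, below tau
        ratios = pd.Series(vals, index=man.index)
        bins, segs = bin_and_segment(ratios, man, CnvCallParams(probes_per_bin=10))
        prof = call_segments("s", bins, segs)
        assert (prof.segments.call == "neutral").all()


class TestGroupSummary:
    def _profile(self, vals, man):
        bins, segs = bin_and_segment(pd.Series(vals, index=man.index), man,
                                     CnvCallParams(probes_per_bin=10))
        return call_segments("s", bins, segs)

    def test_shared_deletion_frequency_one(self):
        man = _flat_manifest(200)
        vals = np.zeros(200)
        vals[100:150] = -1.0
        profs = [self._profile(vals, man) for _ in range(4)]
        freq = mc.summarize_group(profs)
        assert (freq.loss_freq.iloc[10:15] == 1.0).all()
        assert (freq.loss_freq.iloc[:10] == 0.0).all()
        assert (freq.gain_freq == 0.0).all()

    def test_frequencies_match_brute_force_recount(self):
        man = _flat_manifest(100)
        rng = np.random.default_rng(4)
        profs = []
        for _ in range(5):
            vals = np.zeros(100)
            if rng.random() < 0.8:
                s = rng.integers(0, 60)
                vals[s : s + 40] = rng.choice([-1.0, 1.0])
            profs.append(self._profile(vals, man))
        freq = mc.summarize_group(profs)
        calls = np.stack([p.bin_calls() for p in profs])
        np.testing.assert_allclose(freq.gain_freq, (calls == "gain").mean(axis=0))
        np.testing.assert_allclose(freq.loss_freq, (calls == "loss").mean(axis=0))

    def test_mismatched_bin_schemes_rejected(self):
        man = _flat_manifest(100)
        p1 = self._profile(np.zeros(100), man)
        p2 = self._profile(np.zeros(90), _flat_manifest(90))
        with pytest.raises(ValueError, match="bin schemes"):
            mc.summarize_group([p1, p2])


def _fisher_2x2_enumeration(table):
    """Brute-force two-sided Fisher p by enumerating all tables with the
    observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(c1, x, exact=True) * comb(n - c1, r1 - x, exact=True)
                / comb(n, r1, exact=True))

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestExactTests:
    def test_diagonal_2x2_gives_one_third(self):
        assert fisher_exact_table([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_2x2_matches_enumeration_on_margin_grid(self):
        for a, b, c, d in product(range(0, 6), repeat=4):
            if a + b + c + d == 0 or a + b + c + d > 30:
                continue
            t = [[a, b], [c, d]]
            assert fisher_exact_table(t) == pytest.approx(
                _fisher_2x2_enumeration(t), abs=1e-9
            ), t

    def test_2x3_probabilities_sum_to_one_and_match_2x2_embedding(self):
        # A 2x3 table with an empty column reduces to the 2x2 test.
        p23 = _freeman_halton_2x3(np.array([[2, 0, 0], [0, 2, 0]]))
        p22 = fisher_exact_table([[2, 0], [0, 2]])
        assert p23 == pytest.approx(p22)

    def test_gene_alteration_bonferroni(self):
        calls = {
            "KRAS": {"g1": (5, 5), "g2": (0, 5)},
            "TP53": {"g1": (3, 5), "g2": (2, 5)},
        }
        res = mc.gene_alteration_test(calls, n_tests=14)
        kras = res[res.gene == "KRAS"].iloc[0]
        assert kras.p_bonferroni == pytest.approx(min(1.0, kras.p * 14))
        tp53 = res[res.gene == "TP53"].iloc[0]
        assert tp53.p_bonferroni == 1.0  # capped

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty group"):
            mc.gene_alteration_test({"G": {"a": (0, 0), "b": (1, 2)}}, n_tests=1)
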