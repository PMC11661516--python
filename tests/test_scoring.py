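import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcpa.normalization import normalize_against_cache, prepare_sample
from ctcpa.scoring import (
    MODE_EQ1,
    MODE_LENGTH_WEIGHTED,
    ScoreResult,
    build_cumulative_profile,
    classify_sample,
    cpa_score,
    ctcpa_from_z,
    ctcpa_score,
    ctcpa_threshold,
    healthy_threshold_cpa,
)
from ctcpa.segmentation import NEUTRAL, SegmentProfile, stouffer
from ctcpa.synthetic_cohort import (
    CNVSegmentSpec,
    _draw_sample,
    copy_ratio_track,
    true_bin_states,
)

from conftest import profile_from_codes


def _seg_profile(rows):
    return SegmentProfile(
        sample_id="S",
        segments=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_bins", "seg_z", "state"]
        ),
    )


MB = 1_000_000


class TestCpaScore:
    def test_length_weighted_mean(self):
        prof = _seg_profile(
            [("c1", 0, 100 * MB, 100, 3.0, NEUTRAL),
             ("c1", 100 * MB, 200 * MB, 100, -1.0, NEUTRAL)]
        )
        assert cpa_score(prof) == pytest.approx(2.0)

    def test_zero_profile(self):
        prof = _seg_profile([("c1", 0, 50 * MB, 50, 0.0, NEUTRAL)])
        assert cpa_score(prof) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cpa_score(_seg_profile([]))

    def test_unequal_lengths_weighting(self):
        prof = _seg_profile(
            [("c1", 0, 300 * MB, 300, 2.0, NEUTRAL),
             ("c1", 300 * MB, 400 * MB, 100, -6.0, NEUTRAL)]
        )
        assert cpa_score(prof) == pytest.approx((2 * 300 + 6 * 100) / 400)


def _cum(grid, usable, codes_list, timepoints=None, horizon=None):
    profiles = [profile_from_codes(grid, usable, c, sample_id=f"S{i}")
                for i, c in enumerate(codes_list)]
    timepoints = timepoints or [f"T{i}" for i in range(len(profiles))]
    horizon = horizon or timepoints[-1]
    return build_cumulative_profile(
        profiles, timepoints, grid, usable, horizon=horizon, patient_id="P"
    )


class TestCumulativeProfile:
    def test_conflict_exclusion_rule(self, grid):
        # S1 gain chr1:0-50Mb, S2 loss chr1:30-60Mb
        sl = grid.chrom_slice("chr1")
        s1 = np.zeros(grid.n_bins, np.int8)
        s1[sl.start:sl.start + 50] = 1
        s2 = np.zeros(grid.n_bins, np.int8)
        s2[sl.start + 30:sl.start + 60] = -1
        cum = _cum(grid, grid.usable, [s1, s2])
        seg = cum.segments.sort_values("start").reset_index(drop=True)
        assert len(seg) == 2
        assert (seg.loc[0, "start"], seg.loc[0, "end"], seg.loc[0, "direction"]) == (0, 30 * MB, 1)
        assert (seg.loc[1, "start"], seg.loc[1, "end"], seg.loc[1, "direction"]) == (50 * MB, 60 * MB, -1)
        excl = cum.excluded
        assert len(excl) == 1
        assert (excl.loc[0, "start"], excl.loc[0, "end"]) == (30 * MB, 50 * MB)

    def test_single_sample_identity(self, grid):
        sl = grid.chrom_slice("chr3")
        s1 = np.zeros(grid.n_bins, np.int8)
        s1[sl.start + 10:sl.start + 30] = 1
        cum = _cum(grid, grid.usable, [s1])
        assert cum.n_segments == 1
        assert cum.segments.loc[0, "n_bins"] == 20
        assert len(cum.excluded) == 0

    def test_recurrent_call_counted_once(self, grid):
        sl = grid.chrom_slice("chr2")
        s = np.zeros(grid.n_bins, np.int8)
        s[sl.start + 5:sl.start + 25] = 1
        cum = _cum(grid, grid.usable, [s, s])
        assert cum.n_segments == 1
        assert cum.segments.loc[0, "n_bins"] == 20

    def test_horizon_limits_contributions(self, grid):
        sl = grid.chrom_slice("chr1")
        s1 = np.zeros(grid.n_bins, np.int8)
        late = np.zeros(grid.n_bins, np.int8)
        late[sl.start:sl.start + 20] = 1
        cum = _cum(grid, grid.usable, [s1, late], timepoints=["BL", "END"], horizon="BL")
        assert cum.is_empty

    def test_unknown_horizon_rejected(self, grid):
        s = np.zeros(grid.n_bins, np.int8)
        with pytest.raises(ValueError, match="horizon"):
            _cum(grid, grid.usable, [s], timepoints=["BL"], horizon="M6")

    def test_empty_profile_is_valid(self, grid):
        cum = _cum(grid, grid.usable, [np.zeros(grid.n_bins, np.int8)])
        assert cum.is_empty


class TestCtcpaScore:
    def _directed_cum(self, grid, spec):
        codes = np.zeros(grid.n_bins, np.int8)
        for chrom, lo, hi, d in spec:
            sl = grid.chrom_slice(chrom)
            codes[sl.start + lo:sl.start + hi] = d
        return _cum(grid, grid.usable, [codes])

    def test_eq1_oracle_equivalence(self, grid):
        # independent direct evaluation of sum(Z_i * D_i) / n
        cum = self._directed_cum(
            grid, [("chr1", 0, 25, 1), ("chr2", 10, 30, -1), ("chr3", 5, 45, 1)]
        )
        rng = np.random.default_rng(0)
        z = np.full(grid.n_bins, np.nan)
        z[grid.usable] = rng.normal(0, 1, int(grid.usable.sum()))
        got = ctcpa_from_z(z, cum, mode=MODE_EQ1)
        acc = 0.0
        for bins, d in zip(cum.segment_bins, cum.segments["direction"]):
            acc += (z[bins].sum() / np.sqrt(len(bins))) * d
        assert got == pytest.approx(acc / cum.n_segments, abs=1e-12)

    def test_printed_equation_arithmetic(self, grid):
        # Z = (+4, -3), D = (+1, -1) -> (4 + 3)/2
        cum = self._directed_cum(grid, [("chr1", 0, 16, 1), ("chr2", 0, 16, -1)])
        z = np.zeros(grid.n_bins)
        z[cum.segment_bins[0]] = 1.0   # Z_1 = 16/4 = 4
        z[cum.segment_bins[1]] = -0.75  # Z_2 = -12/4 = -3
        assert ctcpa_from_z(z, cum) == pytest.approx((4 + 3) / 2)

    def test_zero_z_gives_zero(self, grid):
        cum = self._directed_cum(grid, [("chr1", 0, 20, 1)])
        assert ctcpa_from_z(np.zeros(grid.n_bins), cum) == 0.0

    def test_empty_cum_rejected(self, grid):
        cum = _cum(grid, grid.usable, [np.zeros(grid.n_bins, np.int8)])
        with pytest.raises(ValueError, match="CNV space"):
            ctcpa_from_z(np.zeros(grid.n_bins), cum)

    def test_negative_score_on_mismatched_direction(self, grid):
        cum = self._directed_cum(grid, [("chr1", 0, 20, -1)])
        z = np.zeros(grid.n_bins)
        z[cum.segment_bins[0]] = 1.0
        assert ctcpa_from_z(z, cum) < 0

    def test_length_weighted_mode(self, grid):
        cum = self._directed_cum(grid, [("chr1", 0, 10, 1), ("chr2", 0, 30, 1)])
        z = np.zeros(grid.n_bins)
        z[cum.segment_bins[0]] = 1.0
        z[cum.segment_bins[1]] = 0.5
        z1 = 10 / np.sqrt(10)
        z2 = 15 / np.sqrt(30)
        want = (z1 * 10 * MB + z2 * 30 * MB) / (40 * MB)
        assert ctcpa_from_z(z, cum, mode=MODE_LENGTH_WEIGHTED) == pytest.approx(want)

    def test_low_tf_matched_directions_beat_healthy(self, grid, config57, cache57, pon57):
        # ctCPA on the truth-direction profile separates tf=0.05 samples
        # from healthy donors (Mann-Whitney, 30 sims)
        cnvs = [CNVSegmentSpec("chr1", 10 * MB, 45 * MB, 3),
                CNVSegmentSpec("chr2", 20 * MB, 50 * MB, 1),
                CNVSegmentSpec("chr3", 5 * MB, 40 * MB, 3)]
        cum = _cum(grid, pon57.usable, [true_bin_states(grid, cnvs)])
        rng = np.random.default_rng(77)
        ratio = copy_ratio_track(grid, cnvs, 0.05)
        patient_scores, healthy_scores = [], []
        for _ in range(30):
            pc = _draw_sample(rng, grid, config57, copy_ratio=ratio)
            hz = _draw_sample(rng, grid, config57)
            patient_scores.append(
                ctcpa_from_z(normalize_against_cache(prepare_sample(pc, grid), pon57), cum)
            )
            healthy_scores.append(
                ctcpa_from_z(normalize_against_cache(prepare_sample(hz, grid), pon57), cum)
            )
        _, p = stats.mannwhitneyu(patient_scores, healthy_scores, alternative="greater")
        assert p < 0.01

    def test_monotone_in_tumor_fraction(self, grid, config57, cache57, pon57):
        cnvs = [CNVSegmentSpec("chr1", 10 * MB, 45 * MB, 3),
                CNVSegmentSpec("chr4", 5 * MB, 35 * MB, 1)]
        cum = _cum(grid, pon57.usable, [true_bin_states(grid, cnvs)])
        rng = np.random.default_rng(5)
        medians = []
        tf_grid = [0.0, 0.02, 0.05, 0.1, 0.2]
        for tf in tf_grid:
            ratio = copy_ratio_track(grid, cnvs, tf)
            scores = [
                ctcpa_from_z(
                    normalize_against_cache(
                        prepare_sample(
                            _draw_sample(rng, grid, config57, copy_ratio=ratio), grid
                        ),
                        pon57,
                    ),
                    cum,
                )
                for _ in range(30)
            ]
            medians.append(np.median(scores))
        rho, _ = stats.spearmanr(tf_grid, medians)
        assert rho > 0.9

    def test_median_over_iterations(self, grid):
        cum = self._directed_cum(grid, [("chr1", 0, 20, 1)])
        z0 = np.zeros(grid.n_bins)
        z1 = np.zeros(grid.n_bins)
        z1[cum.segment_bins[0]] = 1.0
        z2 = np.zeros(grid.n_bins)
        z2[cum.segment_bins[0]] = 2.0
        res = ctcpa_score([z0, z1, z2], cum)
        assert res.score == pytest.approx(np.median(res.iteration_scores))
        single = ctcpa_score([z1], cum)
        assert single.score == pytest.approx(single.iteration_scores[0])


class TestThresholds:
    def test_max_rule(self):
        assert healthy_threshold_cpa([0.40, 0.65, 1.04]) == pytest.approx(1.04)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            healthy_threshold_cpa([1.0])

    def test_exceedance_probability(self):
        # exchangeability oracle: P(fresh > max of N) = 1/(N+1)
        rng = np.random.default_rng(11)
        N = 10
        n_sims = 4000
        hits = 0
        for _ in range(n_sims):
            scores = rng.normal(0, 1, N + 1)
            thr = healthy_threshold_cpa(scores[:N])
            hits += classify_sample(scores[N], thr)
        rate = hits / n_sims
        expect = 1 / (N + 1)
        se = np.sqrt(expect * (1 - expect) / n_sims)
        assert abs(rate - expect) < 3.5 * se

    def test_ctcpa_threshold_is_donor_max(self, grid):
        sl = grid.chrom_slice("chr1")
        codes = np.zeros(grid.n_bins, np.int8)
        codes[sl.start:sl.start + 20] = 1
        cum = _cum(grid, grid.usable, [codes])
        donor_z = {}
        rng = np.random.default_rng(2)
        for d in range(5):
            donor_z[f"HD{d}"] = rng.normal(0, 1, (3, grid.n_bins))
        thr = ctcpa_threshold(cum, donor_z)
        expect = max(ctcpa_score(zm, cum).score for zm in donor_z.values())
        assert thr == pytest.approx(expect)

    def test_adding_donor_monotone(self, grid):
        sl = grid.chrom_slice("chr1")
        codes = np.zeros(grid.n_bins, np.int8)
        codes[sl.start:sl.start + 20] = 1
        cum = _cum(grid, grid.usable, [codes])
        rng = np.random.default_rng(3)
        donors = {f"HD{d}": rng.normal(0, 1, (1, grid.n_bins)) for d in range(6)}
        some = {k: donors[k] for k in list(donors)[:4]}
        assert ctcpa_threshold(cum, donors) >= ctcpa_threshold(cum, some)

    def test_empty_cum_rejected(self, grid):
        cum = _cum(grid, grid.usable, [np.zeros(grid.n_bins, np.int8)])
        with pytest.raises(ValueError):
            ctcpa_threshold(cum, {"HD1": np.zeros((1, grid.n_bins))})


class TestClassify:
    def test_above(self):
        assert classify_sample(1.10, 1.044)

    def test_boundary_strict(self):
        assert not classify_sample(1.044, 1.044)

    def test_below(self):
        assert not classify_sample(0.5, 1.044)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_sample(float("nan"), 1.0)


class TestSexChromosomeExclusion:
    def test_chrx_perturbation_changes_nothing(self, grid, config57, cache57, pon57):
        from ctcpa.pipeline import _profile_from_z
        from ctcpa.segmentation import call_states, cbs_segment

        rng = np.random.default_rng(21)
        counts = _draw_sample(rng, grid, config57)
        perturbed = counts.copy()
        on_x = grid.chrom == "chrX"
        perturbed[on_x] = perturbed[on_x] * 5 + 1234

        scores = []
        for c in (counts, perturbed):
            z = normalize_against_cache(prepare_sample(c, grid), pon57)
            seg = call_states(
                cbs_segment(_profile_from_z(z, pon57.usable, "S"), grid,
                            n_perm=200, seed=4)
            )
            codes = np.zeros(grid.n_bins, np.int8)
            sl = grid.chrom_slice("chr1")
            codes[sl.start:sl.start + 20] = 1
            cum = _cum(grid, pon57.usable, [codes])
            scores.append((cpa_score(seg), ctcpa_from_z(z, cum)))
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)


class TestScoreResult:
    def test_reported_is_median(self):
        res = ScoreResult(sample_id="S", kind="CPA", iteration_scores=[1.0, 5.0, 2.0])
        assert res.score == 2.0

    def test_positive_needs_threshold(self):
        res = ScoreResult(sample_id="S", kind="CPA", iteration_scores=[1.0])
        with pytest.raises(ValueError):
            _ = res.positive
        res.threshold = 0.5
        assert res.positive
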