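"""Synthetic-data generator: seeding statistics, mask ground truth,
renderings, trajectories, dose cohorts, and the overview scan."""

import numpy as np
import pytest
from scipy import stats

from patternoid import synth
from patternoid.geometry import ArrayLayout, GeometryError, PixelCalibration
from patternoid.morphometry import measure_invasion
from patternoid.pipeline import binarize, denoise, max_projection


class TestSeeding:
    def test_zero_mean_gives_all_zero(self):
        counts = synth.simulate_seeding(ArrayLayout(), 0.0, seed=1)
        assert counts.shape == (650,)
        assert not counts.any()

    def test_negative_mean_rejected(self):
        with pytest.raises(GeometryError):
            synth.simulate_seeding(ArrayLayout(), -1.0, seed=1)

    def test_sample_mean_within_clt_bound(self):
        # 5 independent gels; each sample mean within 3 SE of 20
        for seed in range(5):
            counts = synth.simulate_seeding(ArrayLayout(), 20.0, seed=seed)
            assert abs(counts.mean() - 20.0) <= 3 * np.sqrt(20.0 / 650)

    def test_class_fraction_matches_poisson_pmf(self):
        # fraction of counts in [18, 22] vs the exact pmf sum oracle
        counts = np.concatenate(
            [synth.simulate_seeding(ArrayLayout(), 20.0, seed=s) for s in range(20)]
        )
        p = stats.poisson(20.0).pmf(np.arange(18, 23)).sum()
        frac = np.mean((counts >= 18) & (counts <= 22))
        se = np.sqrt(p * (1 - p) / len(counts))
        assert abs(frac - p) <= 3 * se

    def test_reproducible_under_seed(self):
        a = synth.simulate_seeding(ArrayLayout(), 20.0, seed=11)
        b = synth.simulate_seeding(ArrayLayout(), 20.0, seed=11)
        assert np.array_equal(a, b)


class TestMaskGenerator:
    def test_zero_root_profile_is_disk_only(self):
        profile = synth.SubtypeProfile(
            name="noninvasive",
            roots_mean=0,
            roots_sd=0,
            branching_factor_mean=1.0,
            branching_factor_sd=0.0,
            max_distance_mean_um=100.0,
            max_distance_sd_um=0.0,
            invasive_area_logmean=7.0,
            invasive_area_logsd=0.5,
            noninv_area_norm_mean=0.9,
            branch_width_um=6.0,
            growth_rate_r=0.02,
            noninv_plateau_frac=0.8,
            invasion_onset_h=30.0,
        )
        mask, truth = synth.generate_patternoid_mask(profile, seed=3)
        assert truth.roots == truth.tips == 0
        assert truth.invasive_area_um2 == 0.0
        assert truth.max_invasive_distance_um == 0.0
        assert np.isnan(truth.branching_factor)
        dist = mask.radial_distance_um()
        assert not mask.pixels[dist > mask.cavity_radius_um].any()

    def test_bit_reproducible(self):
        m1, t1 = synth.generate_patternoid_mask(synth.M_16992, seed=21)
        m2, t2 = synth.generate_patternoid_mask(synth.M_16992, seed=21)
        assert np.array_equal(m1.pixels, m2.pixels)
        assert t1 == t2

    def test_truth_matches_measurement(self):
        # construction truth and the measurement pipeline agree mask by mask
        rng = np.random.default_rng(50)
        agree = 0
        for _ in range(20):
            mask, truth = synth.generate_patternoid_mask(synth.M_16992, seed=rng)
            m = measure_invasion(mask)
            assert m.max_invasive_distance_um == pytest.approx(truth.max_invasive_distance_um, abs=2.5)
            agree += (m.roots, m.tips) == (truth.roots, truth.tips)
        assert agree >= 18  # rare rasterization merges only

    @pytest.mark.parametrize(
        "profile,attr,mean,sd",
        [
            (synth.M_16992, "bf", 3.15, 0.965),
            (synth.E_9591, "roots", 7.5, 3.725),
            (synth.M_16992, "dist", 379.7, 96.1),
        ],
    )
    def test_truth_moments_converge(self, profile, attr, mean, sd):
        rng = np.random.default_rng(123)
        vals = []
        for _ in range(150):
            _, t = synth.generate_patternoid_mask(profile, seed=rng)
            if attr == "bf":
                if t.roots:
                    vals.append(t.tips / t.roots)
            elif attr == "roots":
                vals.append(t.roots)
            else:
                vals.append(t.max_invasive_distance_um)
        vals = np.asarray(vals, float)
        assert abs(vals.mean() - mean) <= 3 * sd / np.sqrt(len(vals))


class TestRenderIntensity:
    def test_noiseless_roundtrip(self):
        mask, _ = synth.generate_patternoid_mask(synth.E_9591, seed=8)
        stack = synth.render_intensity(mask, snr=np.inf, n_slices=4, seed=0)
        assert np.array_equal(binarize(max_projection(stack), "fixed", threshold=0.5), mask.pixels)

    def test_single_slice_equals_projection(self):
        mask, _ = synth.generate_patternoid_mask(synth.E_9591, seed=8)
        stack = synth.render_intensity(mask, snr=10.0, n_slices=1, seed=0)
        assert np.array_equal(max_projection(stack), stack[0])

    def test_snr5_recovery_dice(self):
        mask, _ = synth.generate_patternoid_mask(synth.E_9591, seed=8)
        stack = synth.render_intensity(mask, snr=5.0, n_slices=4, seed=1)
        rec = binarize(denoise(max_projection(stack), 1), "otsu")
        dice = 2 * (rec & mask.pixels).sum() / (rec.sum() + mask.pixels.sum())
        assert dice >= 0.95

    def test_invalid_snr(self):
        mask, _ = synth.generate_patternoid_mask(synth.E_9591, seed=8)
        with pytest.raises(GeometryError):
            synth.render_intensity(mask, snr=0.0)


class TestTimeseries:
    def test_initial_conditions(self):
        ts = synth.generate_timeseries(synth.MLOW_8028, [0.0, 24.0, 48.0], seed=0, noise_sd=0.0)
        assert ts["noninv_frac_true"].iloc[0] == pytest.approx(synth.MLOW_8028.noninv_baseline_frac)
        assert ts["inv_area_true"].iloc[0] == 0.0

    def test_plateau_reached(self):
        ts = synth.generate_timeseries(synth.MLOW_8028, np.arange(0, 73, 1.0), seed=0, noise_sd=0.0)
        assert ts["noninv_frac_true"].iloc[-1] == pytest.approx(0.40, rel=0.01)

    def test_noiseless_monotone(self):
        ts = synth.generate_timeseries(synth.E_9591, np.linspace(0, 72, 289), seed=0, noise_sd=0.0)
        assert np.all(np.diff(ts["noninv_frac_true"]) >= 0)
        assert np.all(np.diff(ts["inv_area_true"]) >= 0)

    def test_invasion_starts_at_onset(self):
        ts = synth.generate_timeseries(synth.E_9591, np.arange(0, 73, 1.0), seed=0, noise_sd=0.0)
        assert (ts.loc[ts["time_h"] < synth.E_9591.invasion_onset_h, "inv_area_true"] == 0).all()
        assert (ts.loc[ts["time_h"] > synth.E_9591.invasion_onset_h, "inv_area_true"] > 0).all()

    def test_unordered_grid_rejected(self):
        with pytest.raises(GeometryError):
            synth.generate_timeseries(synth.E_9591, [10.0, 5.0], seed=0)


class TestDoseCohort:
    truth = synth.DoseResponseTruth(ec50_nM=500.0, hill_coef=1.0, top=100.0, bottom=10.0, noise_cv=0.1)

    def test_hill_limits(self):
        assert self.truth.expected(0.0) == pytest.approx(100.0)
        assert self.truth.expected(500.0) == pytest.approx(55.0)  # (top+bottom)/2
        assert self.truth.expected(1e9) == pytest.approx(10.0, abs=1e-3)

    def test_noise_is_mean_preserving(self):
        df = synth.generate_dose_response_cohort(
            synth.M_16992, self.truth, [0.0, 500.0], n_per_dose=4000, seed=2
        )
        for c in (0.0, 500.0):
            vals = df.loc[df["concentration_nM"] == c, "value"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - self.truth.expected(c)) <= 3 * se

    def test_invalid_truth_rejected(self):
        with pytest.raises(GeometryError):
            synth.DoseResponseTruth(ec50_nM=-1.0)
        with pytest.raises(GeometryError):
            synth.DoseResponseTruth(ec50_nM=100.0, top=1.0, bottom=2.0)


class TestOverviewScan:
    def _records(self, rates, seed=0):
        layout = ArrayLayout(rows=10, cols=10)
        counts = synth.simulate_seeding(layout, 20.0, seed=seed)
        _, rec = synth.generate_overview_scan(layout, counts, rates, seed=seed)
        return rec

    def test_zero_rates_all_pass_day0(self):
        rec = self._records({k: 0.0 for k in synth.DEFAULT_QC_RATES})
        assert not rec[["agglomeration_d0", "excess_cells_d0"]].any().any()

    def test_full_agglomeration_all_fail(self):
        rates = {k: 0.0 for k in synth.DEFAULT_QC_RATES}
        rates["agglomeration_d0"] = 1.0
        rec = self._records(rates)
        assert rec["agglomeration_d0"].all()

    def test_default_rates_yield_10_to_25_percent(self):
        from patternoid.cohort import classify_c0

        layout = ArrayLayout()  # full 650-cavity gel
        counts = synth.simulate_seeding(layout, 20.0, seed=4)
        _, rec = synth.generate_overview_scan(layout, counts, seed=4)
        flags = rec[list(synth.DEFAULT_QC_RATES)].astype(bool).any(axis=1)
        classed = rec["c0"].map(lambda c: classify_c0(c, [10, 20, 30]) is not None)
        frac = (~flags & classed).mean()
        assert 0.10 <= frac <= 0.25

    def test_image_and_truth_consistent(self):
        layout = ArrayLayout(rows=3, cols=3)
        counts = np.full(9, 15)
        img, rec = synth.generate_overview_scan(layout, counts, {k: 0.0 for k in synth.DEFAULT_QC_RATES}, seed=0)
        assert len(rec) == 9
        assert img.ndim == 2 and (img >= 0).all()
        assert (rec["c0"] == 15).all()
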