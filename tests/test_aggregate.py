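"""Repeat filtration, run pooling, calibration curves, aggregate spectra and
drift summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import platecal as pc
from platecal.aggregate import rmse_to_trend
from platecal.errors import PlatecalError


def transient_repeats(plate_map, instructions, seed, n_repeats=6):
    err = pc.ErrorConfig(
        transient_prob=0.15, transient_scale=0.6, transient_decay=0.5,
        independent_cv=0.01, measurement_noise_sd=0.003, seed=seed,
    )
    return pc.simulate_plate(plate_map, instructions, error=err, n_repeats=n_repeats)


class TestRepeatFiltration:
    def test_identical_repeats_select_repeat_zero(self, ideal_linear_sim, linear_map):
        reading = ideal_linear_sim.reading
        filtered = pc.repeat_filtration([reading, reading, reading], linear_map, 524.0)
        assert (filtered.table["selected_repeat"] == 0).all()
        vals = reading.at_wavelength(524.0)
        assert filtered.values() == pytest.approx(vals)

    def test_filtered_rmse_bounded_by_every_repeat(
        self, linear_map, linear_instructions
    ):
        sim = transient_repeats(linear_map, linear_instructions, seed=7)
        filtered = pc.repeat_filtration(sim.readings, linear_map, 524.0)
        f_rmse = filtered.rmse_to_trend()
        for reading in sim.readings:
            r_rmse = rmse_to_trend(
                reading.at_wavelength(524.0), linear_map, filtered.trend
            )
            assert f_rmse <= r_rmse + 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 5))
    def test_rmse_bound_holds_on_arbitrary_random_repeats(self, seed, n):
        # the per-well min-deviation rule implies the plate-level bound for
        # any inputs, not just simulator output
        plate_map = pc.build_linear_map()
        rng = np.random.default_rng(seed)
        grid = np.array([500.0, 524.0])
        repeats = [
            pc.PlateReading(
                wavelengths=grid, absorbance=np.abs(rng.normal(0.3, 0.2, (96, 2)))
            )
            for _ in range(n)
        ]
        filtered = pc.repeat_filtration(repeats, plate_map, 524.0)
        f_rmse = filtered.rmse_to_trend()
        for reading in repeats:
            assert f_rmse <= rmse_to_trend(
                reading.at_wavelength(524.0), plate_map, filtered.trend
            ) + 1e-12

    def test_filtration_never_invents_values(self, linear_map, linear_instructions):
        sim = transient_repeats(linear_map, linear_instructions, seed=3)
        filtered = pc.repeat_filtration(sim.readings, linear_map, 524.0)
        per_repeat = [r.at_wavelength(524.0) for r in sim.readings]
        for _, row in filtered.table.iterrows():
            observed = {vals[row["well"]] for vals in per_repeat}
            assert row["selected_value"] in observed

    def test_single_repeat_passes_through_with_warning(
        self, ideal_linear_sim, linear_map
    ):
        filtered = pc.repeat_filtration([ideal_linear_sim.reading], linear_map, 524.0)
        assert filtered.warning is not None
        assert filtered.n_repeats == 1

    def test_iterated_selection_is_stable(self, linear_map, linear_instructions):
        sim = transient_repeats(linear_map, linear_instructions, seed=9)
        once = pc.repeat_filtration(sim.readings, linear_map, 524.0, iterate=False)
        iterated = pc.repeat_filtration(sim.readings, linear_map, 524.0, iterate=True)
        assert set(iterated.table["well"]) == set(once.table["well"])

    def test_excursion_free_filtration_matches_median_in_rmse(
        self, linear_map, linear_instructions
    ):
        # with symmetric noise and no transients, min-deviation selection and
        # the per-well median should perform alike on average
        diffs = []
        for seed in range(10):
            err = pc.ErrorConfig(measurement_noise_sd=0.01, seed=seed)
            sim = pc.simulate_plate(
                linear_map, linear_instructions, error=err, n_repeats=5
            )
            filtered = pc.repeat_filtration(sim.readings, linear_map, 524.0)
            per_repeat = pd.DataFrame(
                [r.at_wavelength(524.0) for r in sim.readings]
            )
            medians = per_repeat.median(axis=0).to_dict()
            diffs.append(
                filtered.rmse_to_trend()
                - rmse_to_trend(medians, linear_map, filtered.trend)
            )
        assert abs(np.mean(diffs)) < 0.005


class TestCombineAndCalibrate:
    def test_concentration_conversion(self, ideal_linear_sim, linear_map):
        filtered = pc.repeat_filtration([ideal_linear_sim.reading], linear_map, 524.0)
        meta = pc.RunMetadata("run1", stock_concentration=0.5, working_factor=4 / 100)
        points = pc.combine_runs([filtered], [meta])
        by_well = points.set_index("well")["concentration"]
        half = [w.address for w in linear_map.sample_wells() if w.target_ratio == 0.5]
        assert by_well[str(half[0])] == pytest.approx(0.01)
        blanks = points[points["well"].str.contains("11|12")]
        assert (blanks["concentration"] == 0).all()

    def test_two_runs_concatenate(self, ideal_linear_sim, linear_map):
        filtered = pc.repeat_filtration([ideal_linear_sim.reading], linear_map, 524.0)
        metas = [pc.RunMetadata("a", 0.5, 0.04), pc.RunMetadata("b", 0.5, 0.004)]
        points = pc.combine_runs([filtered, filtered], metas)
        assert len(points) == 2 * len(filtered.table)
        assert set(points["run_id"]) == {"a", "b"}

    def test_exact_recovery_on_noiseless_points(self):
        conc = np.linspace(0, 0.02, 21)
        points = pd.DataFrame({"concentration": conc, "value": 7.2 * conc + 0.03})
        curve = pc.build_calibration(points, degree=1, robust=False)
        assert curve.model.b_ == pytest.approx(7.2, abs=1e-9)
        assert curve.model.c_ == pytest.approx(0.03, abs=1e-9)
        assert curve.rmse == pytest.approx(0.0, abs=1e-9)
        assert curve.pearson == pytest.approx(1.0, abs=1e-9)

    def test_calibration_invariant_to_point_order(self):
        rng = np.random.default_rng(2)
        conc = np.tile(np.linspace(0, 0.02, 11), 3)
        vals = 7.2 * conc + 0.03 + rng.normal(0, 0.002, len(conc))
        points = pd.DataFrame({"concentration": conc, "value": vals})
        a = pc.build_calibration(points, degree=1)
        b = pc.build_calibration(points.sample(frac=1, random_state=0), degree=1)
        assert b.model.b_ == pytest.approx(a.model.b_, rel=1e-9)
        assert b.rmse == pytest.approx(a.rmse, rel=1e-9)

    def test_filtration_improves_calibration_under_transients(
        self, linear_map, linear_instructions
    ):
        meta = [pc.RunMetadata("r", 0.5, 0.04)]
        wins = 0
        for seed in range(20):
            sim = transient_repeats(linear_map, linear_instructions, seed=seed)
            filtered = pc.repeat_filtration(sim.readings, linear_map, 524.0)
            pts_f = pc.combine_runs([filtered], meta)
            pts_f = pts_f[pts_f["concentration"] > 0]
            rows = []
            for r in sim.readings:
                vals = r.at_wavelength(524.0)
                for w in linear_map.sample_wells():
                    rows.append((0.5 * 0.04 * w.target_ratio, vals[str(w.address)]))
            pts_n = pd.DataFrame(rows, columns=["concentration", "value"])
            with_f = pc.build_calibration(pts_f, degree=1)
            without = pc.build_calibration(pts_n, degree=1)
            wins += with_f.rmse <= without.rmse
        assert wins > 10


class TestAggregateSpectrum:
    def test_generator_peaks_detected_within_one_grid_step(self):
        cfg = pc.SpectrumConfig()
        _, peaks = pc.aggregate_spectrum([cfg.solute_spectrum()], cfg.wavelengths)
        centers = [lam for lam, _ in peaks]
        for expected in (458.0, 488.0, 524.0):
            assert min(abs(c - expected) for c in centers) <= 2.0

    def test_fully_aged_spectrum_has_no_triplet(self):
        cfg = pc.SpectrumConfig(aging_flatness=1.0)
        _, peaks = pc.aggregate_spectrum([cfg.solute_spectrum()], cfg.wavelengths)
        assert len(peaks) <= 1  # single broad hump at most, no resolved triplet

    def test_single_spectrum_aggregates_to_itself_normalized(self):
        cfg = pc.SpectrumConfig()
        s = cfg.solute_spectrum()
        mean, _ = pc.aggregate_spectrum([s], cfg.wavelengths)
        assert mean == pytest.approx(s / s.max(), abs=1e-12)

    def test_flat_spectrum_yields_zero_peaks(self):
        grid = np.arange(350.0, 651.0, 2.0)
        _, peaks = pc.aggregate_spectrum([np.ones_like(grid)], grid)
        assert peaks == []

    def test_normalization_wavelength_honored(self):
        cfg = pc.SpectrumConfig()
        s = cfg.solute_spectrum()
        mean, _ = pc.aggregate_spectrum(
            [s], cfg.wavelengths, normalization_wavelength=524.0
        )
        j = int(np.argmin(np.abs(cfg.wavelengths - 524.0)))
        assert mean[j] == pytest.approx(1.0)


class TestSpectralDrift:
    def test_identical_timepoints_are_stable(self, ideal_linear_sim):
        reading = ideal_linear_sim.reading
        summary = pc.spectral_drift([reading, reading, reading])
        assert summary.table["similarity"].to_numpy() == pytest.approx(np.ones(3))
        assert summary.table["peak_retention"].to_numpy() == pytest.approx(np.ones(3))

    def test_aging_ramp_degrades_similarity_monotonically(
        self, linear_map, linear_instructions
    ):
        comp = pc.execute_instructions(linear_instructions, linear_map)
        series = []
        for i, aging in enumerate(np.linspace(0, 1, 5)):
            cfg = pc.SpectrumConfig(aging_flatness=aging)
            (reading,) = pc.render_absorbance(comp, cfg)
            reading.repeat_index = i
            series.append(reading)
        summary = pc.spectral_drift(series)
        sims = summary.table["similarity"].to_numpy()
        assert np.all(np.diff(sims) <= 1e-12)

    def test_all_baseline_timepoint_retention(self, linear_map, linear_instructions):
        comp = pc.execute_instructions(linear_instructions, linear_map)
        cfg = pc.SpectrumConfig()
        (t0,) = pc.render_absorbance(comp, cfg)
        B = cfg.baseline()
        t1 = pc.PlateReading(
            wavelengths=cfg.wavelengths, absorbance=np.tile(B, (96, 1))
        )
        summary = pc.spectral_drift([t0, t1])
        j = int(np.argmax(t0.absorbance.mean(axis=0)))
        expected = B[j] / t0.absorbance.mean(axis=0)[j]
        assert summary.table["peak_retention"].iloc[1] == pytest.approx(expected)

    def test_grid_mismatch_rejected(self, ideal_linear_sim):
        reading = ideal_linear_sim.reading
        other = pc.PlateReading(
            wavelengths=reading.wavelengths[:-1],
            absorbance=reading.absorbance[:, :-1],
            wells=list(reading.wells),
        )
        with pytest.raises(PlatecalError):
            pc.spectral_drift([reading, other])
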