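"""Lag/rate fits, molar and cell yields, qPCR conversion."""

import numpy as np
import pytest

from dcmflux.kinetics import (
    CsvFormatError,
    TimeSeriesExperiment,
    cell_yield,
    cells_from_copies,
    fit_lag_rate,
    molar_yield,
)
from dcmflux.synthetic_data import GeneratorConfig, generate_timeseries, preset


def noise_free(name, **overrides):
    return generate_timeseries(
        preset(name, seed=1, conc_noise_cv=0.0, qpcr_noise_cv=0.0, **overrides)
    )


class TestFitLagRate:
    def test_noise_free_exact_recovery(self):
        ts = noise_free("dcm")
        fit = fit_lag_rate(ts)
        assert fit.lag_days == pytest.approx(21.0, abs=1e-9)
        assert fit.rate == pytest.approx(133.0, rel=1e-8)
        assert not fit.no_decline

    def test_noisy_triplicate_within_two_se(self):
        ts = generate_timeseries(preset("dcm", seed=42))
        fit = fit_lag_rate(ts)
        assert abs(fit.rate - 133.0) <= 2 * fit.rate_se

    def test_flat_series_flagged(self):
        cfg = GeneratorConfig(
            substrate="DCM", initial_substrate_um=1000, lag_days=1000,
            rate_um_per_day=100, yields={}, timepoints=tuple(np.arange(0.0, 50, 7.0)),
            conc_noise_cv=0.0, qpcr_noise_cv=0.0, seed=1,
        )
        fit = fit_lag_rate(generate_timeseries(cfg))
        assert fit.rate == 0.0
        assert fit.no_decline

    def test_invariant_to_constant_shift(self):
        ts = generate_timeseries(preset("dcm", seed=9))
        shifted = ts.data.copy()
        mask = shifted["analyte"] == "DCM"
        shifted.loc[mask, "value"] += 500.0
        fit0 = fit_lag_rate(ts)
        fit1 = fit_lag_rate(TimeSeriesExperiment(data=shifted, substrate="DCM"))
        assert fit1.rate == pytest.approx(fit0.rate, rel=1e-9)
        assert fit1.lag_days == pytest.approx(fit0.lag_days, abs=1e-9)

    def test_repeat_amendments_use_cumulative_consumption(self):
        cfg = GeneratorConfig(
            substrate="DCM", initial_substrate_um=1000, lag_days=7, rate_um_per_day=100,
            yields={"acetate": 0.5}, timepoints=tuple(np.arange(0.0, 43, 3.5)),
            amendments=((17.0, 1000.0), (27.0, 1000.0)),
            conc_noise_cv=0.0, qpcr_noise_cv=0.0, seed=3,
        )
        ts = generate_timeseries(cfg)
        t, cons = ts.consumption("R1")
        assert cons[-1] == pytest.approx(3000.0)  # all three 1 mM doses
        fit = fit_lag_rate(ts)
        assert fit.lag_days == pytest.approx(7.0)
        assert fit.rate == pytest.approx(100.0, rel=1e-8)

    def test_too_few_timepoints_rejected(self):
        cfg = GeneratorConfig(
            substrate="DCM", initial_substrate_um=1000, lag_days=0, rate_um_per_day=100,
            yields={}, timepoints=(0.0, 5.0, 10.0), conc_noise_cv=0.0, qpcr_noise_cv=0.0, seed=1,
        )
        with pytest.raises(ValueError, match=">=4 timepoints"):
            fit_lag_rate(generate_timeseries(cfg))


class TestMolarYield:
    def test_product_identical_to_consumption_gives_unity(self):
        ts = noise_free("dcm", yields={"acetate": 1.0})
        assert molar_yield(ts, "acetate").value == pytest.approx(1.0, rel=1e-12)

    def test_noise_free_roundtrip_exact(self):
        assert molar_yield(noise_free("dcm"), "acetate").value == pytest.approx(0.76, rel=1e-12)
        assert molar_yield(noise_free("choline"), "monomethylamine").value == pytest.approx(1.3, rel=1e-12)

    def test_noisy_within_two_sd(self):
        ts = generate_timeseries(preset("dcm", seed=11))
        y = molar_yield(ts, "acetate")
        assert abs(y.value - 0.76) <= 2 * max(y.sd, y.se)

    def test_endpoint_mode_matches_final_ratio_arithmetic(self):
        """Endpoint mode reproduces the final-concentration quotient, e.g.
        15 mM acetate from 4.4 mM glycine betaine + H2."""
        ts = noise_free("glycine-betaine-h2")
        y = molar_yield(ts, "acetate", mode="endpoint")
        assert y.value == pytest.approx(15.0 / 4.4, abs=0.01)

    def test_zero_consumption_rejected(self):
        cfg = GeneratorConfig(
            substrate="DCM", initial_substrate_um=1000, lag_days=1000, rate_um_per_day=100,
            yields={"acetate": 0.5}, timepoints=(0.0, 7.0, 14.0, 21.0),
            conc_noise_cv=0.0, qpcr_noise_cv=0.0, seed=1,
        )
        with pytest.raises(ValueError, match="no substrate consumption"):
            molar_yield(generate_timeseries(cfg), "acetate")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="yield mode"):
            molar_yield(noise_free("dcm"), "acetate", mode="magic")


class TestCellsFromCopies:
    def test_divide_by_operon_count(self):
        assert cells_from_copies(8e8) == 2e8
        assert cells_from_copies(0.0) == 0.0
        assert cells_from_copies(5e8, operon_count=1) == 5e8

    def test_arrays_supported(self):
        np.testing.assert_allclose(cells_from_copies(np.array([4.0, 8.0])), [1.0, 2.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cells_from_copies(100.0, operon_count=0)
        with pytest.raises(ValueError):
            cells_from_copies(-1.0)


class TestCellYield:
    def test_noise_free_roundtrip_exact(self):
        cy = cell_yield(noise_free("dcm"))
        assert cy.value == pytest.approx(2.0e14, rel=1e-9)

    def test_noisy_within_two_sd(self):
        cy = cell_yield(generate_timeseries(preset("dcm", seed=5)))
        assert abs(cy.value - 2.0e14) <= 2 * max(cy.sd, 0.0)

    def test_zero_growth_gives_zero(self):
        ts = noise_free("dcm", cell_yield_per_mol=0.0)
        assert cell_yield(ts).value == 0.0


class TestParameterRecoveryProperties:
    def test_bias_and_coverage_over_seeded_simulations(self):
        """Across 100 seeded triplicate simulations at default noise, the mean
        fitted rate and yield sit within 5% of truth and the ±2 s.e.
        intervals cover truth at least 90% of the time."""
        rates, yields_, rate_cov, yield_cov = [], [], 0, 0
        for s in range(100):
            ts = generate_timeseries(preset("dcm", seed=20_000 + s))
            fit = fit_lag_rate(ts)
            y = molar_yield(ts, "acetate")
            rates.append(fit.rate)
            yields_.append(y.value)
            rate_cov += abs(fit.rate - 133.0) <= 2 * fit.rate_se
            yield_cov += abs(y.value - 0.76) <= 2 * y.se
        assert abs(np.mean(rates) / 133.0 - 1) < 0.05
        assert abs(np.mean(yields_) / 0.76 - 1) < 0.05
        assert rate_cov >= 90
        assert yield_cov >= 90


class TestTimeSeriesContainer:
    def test_csv_roundtrip(self, tmp_path):
        ts = generate_timeseries(preset("dcm", seed=2))
        p, ap = tmp_path / "ts.csv", tmp_path / "amend.csv"
        ts.to_csv(p, ap)
        back = TimeSeriesExperiment.from_csv(p, substrate="DCM", amendments_path=ap)
        assert back.replicates == ts.replicates
        assert back.analytes == ts.analytes
        np.testing.assert_allclose(back.series("R1", "DCM")[1], ts.series("R1", "DCM")[1])

    def test_missing_column_diagnostic(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_d,replicate,analyte,value\n0,R1,DCM,100\n")
        with pytest.raises(CsvFormatError, match="missing columns.*unit"):
            TimeSeriesExperiment.from_csv(p, substrate="DCM")

    def test_non_numeric_value_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_d,replicate,analyte,value,unit\n0,R1,DCM,oops,uM\n")
        with pytest.raises(CsvFormatError, match="line 2"):
            TimeSeriesExperiment.from_csv(p, substrate="DCM")

    def test_wrong_unit_refused(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_d,replicate,analyte,value,unit\n0,R1,DCM,100,mM\n")
        with pytest.raises(CsvFormatError, match="unit"):
            TimeSeriesExperiment.from_csv(p, substrate="DCM")

    def test_empty_file_refused(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(CsvFormatError, match="empty"):
            TimeSeriesExperiment.from_csv(p, substrate="DCM")
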