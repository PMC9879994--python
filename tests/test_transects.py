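"""Frame-scale conversion, per-coral biomass and density aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefmass import (
    CoralMeasurement,
    FrameScale,
    PowerLawParams,
    TransectRecord,
    biomass_density,
    estimate_coral_biomass,
    pixels_to_cm,
    summarise_density,
)
from reefmass.mcmc import PosteriorDraws
from reefmass.simulate import generate_transects, TransectSimConfig


class TestPixelsToCm:
    def test_proportionality(self):
        assert pixels_to_cm(FrameScale(1.0, 500.0), 60.0) == pytest.approx(12.0)

    def test_identity_at_reference_length(self):
        assert pixels_to_cm(FrameScale(1.0, 500.0), 500.0) == pytest.approx(100.0)

    def test_non_round_reference(self):
        assert pixels_to_cm(FrameScale(1.0, 333.0), 100.0) == pytest.approx(30.030, abs=5e-4)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            pixels_to_cm(FrameScale(1.0, 500.0), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ref=st.floats(10.0, 5000.0), px=st.floats(1.0, 5000.0),
           k=st.floats(0.1, 10.0))
    def test_scale_invariance(self, ref, px, k):
        """Rescaling reference and measurement together leaves cm unchanged."""
        base = pixels_to_cm(FrameScale(1.0, ref), px)
        assert pixels_to_cm(FrameScale(1.0, k * ref), k * px) == pytest.approx(base)


class TestCoralBiomass:
    PARAMS = PowerLawParams(0.3, 2.7, 10.0)

    def test_worked_point_estimate(self):
        m = CoralMeasurement("sp", 10.0)
        # 0.3 * 10^2.7 evaluated independently
        assert estimate_coral_biomass(m, self.PARAMS).point_g == pytest.approx(
            150.356, abs=5e-4)

    def test_unit_diameter_returns_a(self):
        m = CoralMeasurement("sp", 1.0)
        assert estimate_coral_biomass(m, self.PARAMS).point_g == pytest.approx(0.3)

    def test_degenerate_draws_collapse_to_point(self):
        arr = np.tile(np.array([0.3, 2.7, 0.0]), (2, 50, 1))
        draws = PosteriorDraws(("a", "b", "sigma"), arr)
        est = estimate_coral_biomass(CoralMeasurement("sp", 10.0), draws)
        assert est.hdi95[0] == est.hdi95[1] == pytest.approx(est.point_g)

    def test_posterior_interval_brackets_point(self, fitted_lognormal):
        reg, _ = fitted_lognormal
        est = estimate_coral_biomass(CoralMeasurement("sp", 8.0), reg.draws_,
                                     likelihood="lognormal",
                                     rng=np.random.default_rng(0))
        assert est.hdi95[0] < est.point_g < est.hdi95[1]

    def test_extrapolation_flagged(self):
        m = CoralMeasurement("sp", 90.67)
        est = estimate_coral_biomass(m, self.PARAMS, fitted_max_diameter_cm=13.4)
        assert est.extrapolated


class TestDensity:
    FITS = {"sp": PowerLawParams(0.3, 2.7, 10.0)}

    def _transect(self, lengths, species="sp", **kw):
        corals = tuple(CoralMeasurement(species, l) for l in lengths)
        return TransectRecord(transect_id="T1", state="QLD", corals=corals, **kw)

    def test_worked_density(self):
        """Per-coral weights {100, 250, 150} g on 50 m² give 10 g·m⁻²."""
        # choose diameters whose predicted weights are exactly those values
        inv = lambda w: (w / 0.3) ** (1 / 2.7)
        t = self._transect([inv(100.0), inv(250.0), inv(150.0)])
        est = biomass_density(t, "sp", self.FITS)
        assert est.density_g_per_m2 == pytest.approx(10.0, rel=1e-9)
        assert est.n_corals == 3

    def test_absent_species_yields_none(self):
        t = self._transect([5.0], species="other")
        assert biomass_density(t, "sp", self.FITS) is None

    def test_single_coral_worked_value(self):
        t = self._transect([10.0])
        # 150.356 g over 50 m²
        assert biomass_density(t, "sp", self.FITS).density_g_per_m2 == pytest.approx(
            3.007, abs=5e-4)

    def test_conservation_exact(self):
        rng = np.random.default_rng(1)
        t = self._transect(rng.uniform(2, 20, 37), length_m=25.0, width_m=2.0)
        est = biomass_density(t, "sp", self.FITS)
        assert est.density_g_per_m2 == est.total_biomass_g / est.area_m2
        assert est.density_g_per_m2 * est.area_m2 == pytest.approx(
            est.total_biomass_g, rel=4e-16)

    def test_partially_visible_excluded_by_default(self):
        corals = (CoralMeasurement("sp", 10.0),
                  CoralMeasurement("sp", 10.0, partially_visible=True))
        t = TransectRecord(transect_id="T1", state="QLD", corals=corals)
        est = biomass_density(t, "sp", self.FITS)
        assert est.n_corals == 1 and est.n_skipped == 1
        est2 = biomass_density(t, "sp", self.FITS, include_partial=True)
        assert est2.n_corals == 2

    def test_unfitted_species_skipped(self):
        t = self._transect([5.0])
        assert biomass_density(t, "sp", {}) is None

    def test_plugin_consistency_zero_noise(self, recovery_cfg):
        """With zero generator noise and matched parameters, estimated
        density equals generated density to machine precision."""
        import dataclasses
        cfg = dataclasses.replace(recovery_cfg, sigma_log=0.0)
        ts = generate_transects([cfg], TransectSimConfig(
            n_transects=30, mean_count_per_transect=2.0,
            large_outlier_prob=0.0, seed=7))
        fits = {cfg.species: PowerLawParams(cfg.true_a, cfg.true_b, 1.0)}
        for t in ts:
            if not t.corals:
                continue
            est = biomass_density(t, cfg.species, fits)
            truth = sum(cfg.true_a * c.max_length_cm**cfg.true_b
                        for c in t.corals) / t.area_m2
            assert est.density_g_per_m2 == pytest.approx(truth, rel=1e-12)


class TestSummaries:
    def _est(self, density, species="sp", state="QLD", tid="T1"):
        from reefmass.datatypes import DensityEstimate
        return DensityEstimate(species=species, transect_id=tid, state=state,
                               total_biomass_g=density * 50.0, area_m2=50.0,
                               n_corals=1)

    def test_worked_summary(self):
        (s,) = summarise_density([self._est(d, tid=f"T{d}") for d in (1.0, 2.0, 3.0)])
        assert s.mean == pytest.approx(2.0)
        assert s.median == pytest.approx(2.0)
        assert s.se == pytest.approx(0.577, abs=5e-4)
        assert (s.min, s.max) == (1.0, 3.0)

    def test_single_transect_se_unavailable(self):
        (s,) = summarise_density([self._est(4.0)])
        assert s.se is None and s.n_transects == 1

    def test_outlier_pulls_mean_above_median(self):
        ests = [self._est(d, tid=f"T{i}") for i, d in enumerate([2.0, 3.0, 2.5, 600.0])]
        (s,) = summarise_density(ests)
        assert s.mean > s.median
        assert s.mean_median_ratio > 10

    def test_empty_input_empty_output(self):
        assert summarise_density([]) == []

    def test_grouping_by_state(self):
        ests = [self._est(1.0, state="QLD", tid="T1"),
                self._est(5.0, state="WA", tid="T2")]
        out = summarise_density(ests)
        assert {s.state for s in out} == {"QLD", "WA"}
        pooled = summarise_density(ests, by_state=False)
        assert len(pooled) == 1 and pooled[0].n_transects == 2
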