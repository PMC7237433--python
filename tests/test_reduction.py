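"""Reduction chain: transmission, absorption, subtraction, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import reduce_triplet, single_population_spec
from oracles import mc_slab_attenuation
from sporedyn.msd import LOW_Q, extract_msd_series
from sporedyn.reduction import (ReductionConfig, SlabGeometry,
                                normalize_to_vanadium, paalman_pings_slab,
                                q_to_length, relative_summed_intensity,
                                subtract_empty_cell, transmission)
from sporedyn.scans import ElasticScan
from sporedyn.synthetic import germinating_spec, simulate_scan_triplet


def flat_scan(value=1.0, err=0.1, nq=6, nT=4, kind="sample", **meta):
    q = np.linspace(0.5, 2.0, nq)
    T = np.linspace(280, 310, nT)
    return ElasticScan(q=q, T=T, intensity=np.full((nT, nq), value),
                       error=np.full((nT, nq), err), kind=kind, meta=meta)


class TestTransmission:
    def test_no_absorption_is_unity(self):
        assert transmission(SlabGeometry(mu_s=0, mu_c=0, tilt=0)) == 1.0

    def test_threshold_geometry_is_exactly_090(self):
        # mu_s d_s + mu_c d_c = ln(10/9) at normal incidence
        geo = SlabGeometry(mu_s=math.log(10 / 9) / 0.02, mu_c=0.0,
                           d_s=0.02, d_c=0.1, tilt=0.0)
        assert transmission(geo) == pytest.approx(0.90, abs=1e-12)

    def test_tilt_60_squares_the_normal_transmission(self):
        geo0 = SlabGeometry(tilt=0.0)
        geo60 = SlabGeometry(tilt=60.0)
        assert transmission(geo60) == pytest.approx(transmission(geo0) ** 2, rel=1e-12)

    def test_grazing_tilt_rejected(self):
        with pytest.raises(ValueError):
            SlabGeometry(tilt=90.0)


class TestPaalmanPings:
    def test_zero_attenuation_gives_unit_coefficients(self):
        geo = SlabGeometry(mu_s=0.0, mu_c=0.0)
        coeffs = paalman_pings_slab(geo, [30.0, 90.0, 120.0])
        for name in ("A_ss", "A_ssc", "A_csc", "A_cc"):
            assert np.allclose(getattr(coeffs, name), 1.0, atol=1e-9)

    def test_vanishing_container_makes_assc_approach_ass(self):
        geo_thin = SlabGeometry(mu_s=0.5, mu_c=0.3, d_s=0.04, d_c=1e-7)
        coeffs = paalman_pings_slab(geo_thin, [40.0, 90.0])
        assert np.allclose(coeffs.A_ssc, coeffs.A_ss, atol=1e-6)

    def test_slab_plane_exit_angle_rejected(self):
        geo = SlabGeometry(tilt=45.0)
        with pytest.raises(ValueError, match="slab plane"):
            paalman_pings_slab(geo, [135.0])

    def test_quadrature_matches_monte_carlo_ray_oracle(self):
        # the spec'd reference case, 1e6 uniformly sampled scattering depths
        geo = SlabGeometry(mu_s=0.5, mu_c=0.1, d_s=0.04, d_c=0.05, tilt=45.0)
        coeffs = paalman_pings_slab(geo, [90.0])
        cases = {"A_ss": ("sample", "s"), "A_ssc": ("sample", "sc"),
                 "A_csc": ("container", "sc"), "A_cc": ("container", "c")}
        for name, (region, atten) in cases.items():
            oracle = mc_slab_attenuation(geo.mu_s, geo.mu_c, geo.d_s, geo.d_c,
                                         geo.tilt, 90.0, region, atten,
                                         n_rays=1_000_000, seed=7)
            assert getattr(coeffs, name)[0] == pytest.approx(oracle, rel=5e-4)

    def test_coefficients_decrease_with_attenuation_and_thickness(self, rng):
        for _ in range(20):
            geo = SlabGeometry(mu_s=rng.uniform(0.1, 2.0), mu_c=rng.uniform(0.05, 0.5),
                               d_s=rng.uniform(0.01, 0.08), d_c=rng.uniform(0.02, 0.2),
                               tilt=rng.uniform(0, 60))
            angle = [float(rng.uniform(20, 70))]
            base = paalman_pings_slab(geo, angle)
            thicker = paalman_pings_slab(
                SlabGeometry(geo.mu_s * 1.5, geo.mu_c * 1.5, geo.d_s * 1.2,
                             geo.d_c * 1.2, geo.tilt), angle)
            for name in ("A_ss", "A_ssc", "A_csc", "A_cc"):
                assert thicker.__dict__[name][0] < base.__dict__[name][0]
                assert 0 < base.__dict__[name][0] <= 1


class TestSubtractEmptyCell:
    def test_unit_coefficients_and_zero_empty_is_identity(self):
        sample = flat_scan(5.0)
        empty = flat_scan(0.0, err=0.0, kind="empty")
        coeffs = paalman_pings_slab(SlabGeometry(mu_s=0, mu_c=0), [90.0])
        # broadcast single-angle coefficients over the Q grid
        import dataclasses
        coeffs = dataclasses.replace(
            coeffs, two_theta=np.repeat(coeffs.two_theta, sample.q.size),
            A_ss=np.repeat(coeffs.A_ss, sample.q.size),
            A_ssc=np.repeat(coeffs.A_ssc, sample.q.size),
            A_csc=np.repeat(coeffs.A_csc, sample.q.size),
            A_cc=np.repeat(coeffs.A_cc, sample.q.size))
        out = subtract_empty_cell(sample, empty, coeffs)
        assert np.allclose(out.intensity, sample.intensity)
        sample_eq = flat_scan(5.0)
        out2 = subtract_empty_cell(sample_eq, flat_scan(5.0, kind="empty"), coeffs)
        assert np.allclose(out2.intensity, 0.0, atol=1e-12)
        assert out2.meta["n_negative"] == 0

    def test_grid_mismatch_names_the_axis(self):
        sample = flat_scan(nq=6)
        empty = flat_scan(nq=5, kind="empty")
        coeffs = paalman_pings_slab(SlabGeometry(mu_s=0, mu_c=0), [90.0] * 6)
        with pytest.raises(ValueError, match="Q grid"):
            subtract_empty_cell(sample, empty, coeffs)

    def test_noiseless_triplet_recovers_pure_sample_term(self, germinating_noiseless):
        trip = germinating_noiseless
        corrected = subtract_empty_cell(trip.sample, trip.empty,
                                        trip.truth["coefficients"])
        expected = trip.truth["efficiency"][None, :] * trip.truth["mix_mean"]
        rel = np.abs(corrected.intensity - expected) / expected
        assert rel.max() < 1e-6


class TestVanadiumNormalization:
    def test_unit_vanadium_is_identity(self):
        scan = flat_scan(3.0)
        vana = flat_scan(1.0, err=0.0, nT=4, kind="vanadium")
        out = normalize_to_vanadium(scan, vana)
        assert np.allclose(out.intensity, scan.intensity)

    def test_vanadium_2_halves_and_grows_relative_errors(self):
        scan = flat_scan(4.0, err=0.2)
        vana = flat_scan(2.0, err=0.2, nT=1, kind="vanadium")
        out = normalize_to_vanadium(scan, vana)
        assert np.allclose(out.intensity, 2.0)
        rel_in = 0.2 / 4.0
        rel_v = 0.2 / 2.0
        assert np.allclose(out.error / out.intensity,
                           math.hypot(rel_in, rel_v), rtol=1e-12)
        out_nov = normalize_to_vanadium(scan, vana, propagate_vanadium_error=False)
        assert np.allclose(out_nov.error / out_nov.intensity, rel_in, rtol=1e-12)

    def test_nonpositive_vanadium_q_is_automasked(self, caplog):
        scan = flat_scan(3.0)
        vana = flat_scan(1.0, err=0.1, nT=1, kind="vanadium")
        vana.intensity[0, 2] = 0.0
        with caplog.at_level("WARNING"):
            out = normalize_to_vanadium(scan, vana)
        assert "masked_q" in out.meta
        keep = ReductionConfig(q_exclude=frozenset()).usable_q(out.q, out.meta)
        assert not keep[2] and keep.sum() == scan.q.size - 1

    def test_efficiency_draw_cancels_after_division(self):
        # same dynamics, different efficiency draws -> identical noiseless MSDs
        msds = []
        for seed in (21, 22):
            spec = single_population_spec(u0=0.7, slope=0.004, seed=seed,
                                          detector_efficiency_sd=0.20)
            reduced = reduce_triplet(simulate_scan_triplet(spec, noise=False))
            msds.append(extract_msd_series(reduced, LOW_Q).msd)
        assert np.allclose(msds[0], msds[1], atol=1e-10)


class TestRelativeSummedIntensity:
    def test_lowest_temperature_anchors_at_100(self, wt_noiseless):
        table = relative_summed_intensity(wt_noiseless.sample)
        assert table["percent"].iloc[0] == 100.0
        assert table["error"].iloc[0] == 0.0

    def test_temperature_independent_scan_stays_at_100(self):
        table = relative_summed_intensity(flat_scan(2.0), ReductionConfig())
        assert np.allclose(table["percent"], 100.0)

    def test_germinating_thermogram_drops_faster_above_breakpoint(self):
        trip = simulate_scan_triplet(germinating_spec(seed=31), noise=False)
        table = relative_summed_intensity(trip.sample)
        pct = table["percent"].to_numpy()
        assert np.all(np.diff(pct) < 0)
        steps = np.diff(pct) / np.diff(table["T"].to_numpy())
        before = steps[table["T"].to_numpy()[1:] <= 305.0]
        after = steps[table["T"].to_numpy()[1:] > 305.0]
        assert after.mean() < before.mean() < 0

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_global_rescaling(self, factor):
        scan = flat_scan(2.0, err=0.3)
        scan.intensity[2, :] *= 1.7  # some temperature structure
        scaled = scan.copy(intensity=scan.intensity * factor,
                           error=scan.error * factor)
        a = relative_summed_intensity(scan)
        b = relative_summed_intensity(scaled)
        assert np.allclose(a["percent"], b["percent"], rtol=1e-9)

    def test_nonpositive_reference_sum_is_hard_error(self):
        scan = flat_scan(1.0)
        scan.intensity[0, :] = 0.0
        with pytest.raises(ValueError, match="lowest temperature"):
            relative_summed_intensity(scan)


class TestSpaceWindow:
    @pytest.mark.parametrize("q, expected, sig", [
        (0.3, 21.0, 2),      # largest accessible length scale
        (4.9, 1.3, 2),       # smallest accessible length scale
        (2 * math.pi, 1.0, 12),
    ])
    def test_q_to_length(self, q, expected, sig):
        value = q_to_length(q)
        assert float(f"{value:.{sig - 1}e}") == pytest.approx(expected, rel=10**-(sig + 1))

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            q_to_length(0.0)
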