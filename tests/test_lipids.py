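import dataclasses

import numpy as np
import pytest

from gonadnmr.lipids import (
    FISH_OIL_REFERENCE, LipidIndices, RegionIntegrals, RegionWindows,
    integrate_regions, qc_check, solve_indices, summarize_batch,
)
from gonadnmr.spectra import Spectrum1D
from gonadnmr.synth import CohortConfig, LipidComposition, generate_apolar_spectrum


def lorentzian_spectrum(center, area=1.0, hw=0.003, n=32768):
    ppm = np.linspace(-0.5, 11.0, n)
    inten = (area * hw / np.pi) / ((ppm - center) ** 2 + hw ** 2)
    return Spectrum1D(ppm, inten, solvent="cdcl3", reference="residual_solvent")


def integrals(values, windows=None, spectrum_id=""):
    base = {k: 0.0 for k in RegionWindows().windows}
    base.update(values)
    return RegionIntegrals(integrals=base, windows=windows or RegionWindows(),
                           spectrum_id=spectrum_id)


class TestIntegration:
    def test_unit_lorentzian_in_region_g(self):
        # closed-form CDF: nearly all area of a peak centred in G stays in G
        sp = lorentzian_spectrum(2.80, area=1.0)
        ri = integrate_regions(sp)
        assert ri["G"] == pytest.approx(1.0, rel=0.02)
        for letter in ("A", "B", "C", "D", "E", "F", "Fprime", "H", "I", "J"):
            assert abs(ri[letter]) < 0.01

    def test_zero_spectrum(self):
        sp = Spectrum1D(np.linspace(-0.5, 11.0, 8192), np.zeros(8192),
                        solvent="cdcl3", reference="residual_solvent")
        ri = integrate_regions(sp)
        assert all(v == 0.0 for v in ri.integrals.values())

    def test_default_fprime_bounds(self):
        assert RegionWindows()["Fprime"] == (2.37, 2.40)

    def test_out_of_grid_window_reported_absent(self):
        sp = Spectrum1D(np.linspace(0.0, 3.0, 4096), np.ones(4096),
                        solvent="cdcl3", reference="residual_solvent")
        ri = integrate_regions(sp)
        assert ri["H"] is None and ri["J"] is None
        assert ri["A"] is not None


class TestSolver:
    def test_fully_saturated_limit(self):
        li = solve_indices(integrals({"A": 0.0, "B": 300.0, "J": 0.0}))
        assert (li.n_unsat, li.s_sat, li.omega3, li.dha) == (0.0, 100.0, 0.0, 0.0)
        assert not li.excluded

    def test_round_trip_recovery(self):
        cfg = CohortConfig(seed=0, noise_sd=0.0, grid_points=16384)
        comp = LipidComposition(n_unsat=60, s_sat=40, omega3=20, dha=2)
        li = solve_indices(integrate_regions(generate_apolar_spectrum(comp, cfg, seed=1)))
        for name, want in (("n_unsat", 60), ("s_sat", 40), ("omega3", 20), ("dha", 2)):
            assert getattr(li, name) == pytest.approx(want, abs=0.5)

    def test_conservation_identity(self):
        li = solve_indices(integrals({"A": 50.0, "B": 250.0, "E": 180.0,
                                      "Fprime": 3.0, "J": 400.0}))
        assert li.n_unsat + li.s_sat == pytest.approx(100.0, abs=1e-12)

    def test_undefined_chain_count_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            solve_indices(integrals({"A": 0.0, "B": 0.0}))

    def test_scale_invariance(self):
        cfg = CohortConfig(seed=0, noise_sd=0.0, grid_points=16384)
        comp = LipidComposition(n_unsat=55, s_sat=45, omega3=18, dha=1.5)
        sp = generate_apolar_spectrum(comp, cfg, seed=2)
        li1 = solve_indices(integrate_regions(sp))
        sp2 = dataclasses.replace(sp, intensity=sp.intensity * 37.5)
        li2 = solve_indices(integrate_regions(sp2))
        for name in ("n_unsat", "s_sat", "omega3", "dha"):
            assert getattr(li1, name) == pytest.approx(getattr(li2, name), rel=1e-9)


class TestQC:
    def _clean(self):
        return LipidIndices(n_unsat=60, s_sat=40, omega3=20, dha=2)

    def test_ordering_violation_flagged(self):
        li = LipidIndices(n_unsat=60, s_sat=40, omega3=3, dha=5)
        out = qc_check(li, integrals({"A": 9, "B": 291, "E": 240, "J": 360}))
        assert "dha_exceeds_omega3" in out.qc_flags
        assert out.excluded

    def test_all_constraints_met(self):
        out = qc_check(self._clean(),
                       integrals({"A": 60, "B": 240, "E": 240, "J": 360}))
        assert out.qc_flags == [] and not out.excluded

    def test_negative_integral_flagged(self):
        out = qc_check(self._clean(),
                       integrals({"A": 60, "B": 240, "E": 240, "J": 360, "C": -5}))
        assert "negative_integral_C" in out.qc_flags

    def test_olefinic_deficit_flagged(self):
        out = qc_check(self._clean(),
                       integrals({"A": 60, "B": 240, "E": 240, "J": 10}))
        assert "olefinic_deficit" in out.qc_flags

    def test_corrupted_spectra_exactly_excluded(self):
        """Three deliberately corrupted spectra in a batch of 37 are the
        only ones the QC filter removes."""
        cfg = CohortConfig(seed=0, noise_sd=0.0, grid_points=8192)
        comp = LipidComposition(n_unsat=60, s_sat=40, omega3=20, dha=2)
        results = []
        corrupt = {4, 18, 30}
        for i in range(37):
            sp = generate_apolar_spectrum(comp, cfg, seed=i, sample_id=f"S{i}")
            if i in corrupt:
                bad = sp.intensity.copy()
                sel = (sp.ppm >= 5.30) & (sp.ppm <= 5.45)  # destroy olefinic J
                bad[sel] = 0.0
                sp = dataclasses.replace(sp, intensity=bad)
            results.append(solve_indices(integrate_regions(sp)))
        excluded = {r.spectrum_id for r in results if r.excluded}
        assert excluded == {f"S{i}" for i in corrupt}


class TestBatchSummary:
    def _batch(self, values, sexes=None):
        res = [LipidIndices(n_unsat=v, s_sat=100 - v, omega3=v / 3, dha=v / 30,
                            spectrum_id=f"B{i}") for i, v in enumerate(values)]
        return summarize_batch(res, sexes)

    def test_identical_batch_has_zero_iqr(self):
        out = self._batch([60.0] * 5)
        assert out["summary"].loc["n_unsat", "iqr_high"] == \
            out["summary"].loc["n_unsat", "iqr_low"]

    def test_benchmark_reports_below_fish_oil_dha(self):
        out = self._batch([60.0] * 5)  # dha median 2.0 < 7.0
        assert out["benchmark"]["dha"]["relative_to_fish_oil_range"] == "below"
        assert out["benchmark"]["dha"]["fish_oil"]["low"] == \
            FISH_OIL_REFERENCE["dha"]["low"]

    def test_sex_stratified_test_present(self):
        out = self._batch([55, 60, 65, 58, 62, 61], ["F", "F", "F", "M", "M", "M"])
        assert "omega3" in out["tests"]
        assert 0 < out["tests"]["omega3"].p_two_sided <= 1

    def test_all_excluded_rejected(self):
        bad = LipidIndices(n_unsat=60, s_sat=40, omega3=20, dha=2,
                           qc_flags=["x"], excluded=True)
        with pytest.raises(ValueError, match="empty"):
            summarize_batch([bad])


class TestRoundTripGrid:
    def test_composition_grid_recovery(self):
        """Generator -> integrator -> solver recovers every composition on
        a 20-point grid to 0.5 mol% in the noise-free limit."""
        cfg = CohortConfig(seed=0, noise_sd=0.0, grid_points=16384)
        grid = [
            LipidComposition(n_unsat=n, s_sat=100 - n, omega3=w, dha=h)
            for n in (20.0, 45.0, 60.0, 75.0, 90.0)
            for (w, h) in ((n * 0.15, 0.0), (n * 0.3, n * 0.02),
                           (n * 0.5, n * 0.1), (n * 0.8, n * 0.25))
        ]
        assert len(grid) == 20
        for k, comp in enumerate(grid):
            sp = generate_apolar_spectrum(comp, cfg, seed=k)
            li = solve_indices(integrate_regions(sp))
            assert li.n_unsat == pytest.approx(comp.n_unsat, abs=0.5)
            assert li.omega3 == pytest.approx(comp.omega3, abs=0.5)
            assert li.dha == pytest.approx(comp.dha, abs=0.5)
            assert li.n_unsat + li.s_sat == pytest.approx(100.0, abs=1e-9)
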