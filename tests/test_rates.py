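import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from borondose import (
    EnergyGrid,
    OneOverVModel,
    TumorSpec,
    boron_atom_count,
    capture_reaction_rate,
    fold_flux_xs,
    fusion_reaction_rate,
    percent_increase,
)
from borondose.grids import GridMismatchError, LogEnergyGrid, ParticleSpectrum
from borondose.rates import PhantomSpec, rate_from_folded_sum


class TestBoronAtomCount:
    def test_default_b11_loading_matches_printed_inventory(self, shallow_tumor):
        assert boron_atom_count(shallow_tumor) == pytest.approx(9.0e18, rel=0.01)

    def test_zero_ppm(self, shallow_tumor):
        assert boron_atom_count(shallow_tumor.with_ppm(0.0)) == 0.0

    def test_b10_loading(self, shallow_tumor):
        # 1.65e-4 g / 10.013 g/mol * N_A
        expected = 1.65e-4 / 10.013 * 6.02214076e23
        got = boron_atom_count(shallow_tumor.with_isotope("B10"))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(9.9e18, rel=0.01)

    def test_linear_in_ppm(self, shallow_tumor):
        assert boron_atom_count(shallow_tumor.with_ppm(1000.0)) == pytest.approx(
            10.0 * boron_atom_count(shallow_tumor), rel=1e-12
        )


class TestTumorPhantomSpecs:
    def test_volume_radius_consistency_enforced(self):
        with pytest.raises(ValueError):
            TumorSpec(radius=0.71, volume=3.0)

    def test_negative_ppm_rejected(self):
        with pytest.raises(ValueError):
            TumorSpec(ppm=-1.0)

    def test_unknown_isotope_rejected(self):
        with pytest.raises(ValueError):
            TumorSpec(boron_isotope="B12")

    def test_phantom_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PhantomSpec(mass_fractions={"H": 0.5, "O": 0.4})

    def test_phantom_atom_inventory_hand_check(self):
        phantom = PhantomSpec()
        inv = phantom.atom_inventory()
        mass = 4.0 / 3.0 * np.pi * 9.0**3 * 1.1
        assert inv["H"] == pytest.approx(mass * 0.10 / 1.008 * 6.02214076e23, rel=1e-9)


class TestFoldFluxXs:
    def _spectrum(self, flux, bin_width=0.1):
        grid = EnergyGrid(bin_width=bin_width, i_min=0, i_max=len(flux) - 1)
        return ParticleSpectrum("proton", grid, np.asarray(flux, dtype=float))

    def test_zero_flux(self):
        spec = self._spectrum([0.0] * 10)
        assert fold_flux_xs(spec, np.ones(10), 0.0, 1.0) == 0.0

    def test_two_bin_toy(self):
        spec = self._spectrum([1.0, 2.0])
        sigma = np.array([1000.0, 500.0])
        assert fold_flux_xs(spec, sigma, 0.0, 1.0) == pytest.approx(2000.0)

    def test_window_endpoints_inclusive_at_midpoints(self):
        # bin_width 0.25 keeps the midpoints exactly representable
        spec = self._spectrum([1.0, 1.0, 1.0, 1.0], bin_width=0.25)
        sigma = np.ones(4)
        assert fold_flux_xs(spec, sigma, 0.125, 0.875) == pytest.approx(4.0)
        assert fold_flux_xs(spec, sigma, 0.126, 0.875) == pytest.approx(3.0)
        assert fold_flux_xs(spec, sigma, 0.125, 0.874) == pytest.approx(3.0)

    def test_grid_mismatch_rejected(self):
        spec = self._spectrum([1.0, 2.0])
        with pytest.raises(GridMismatchError):
            fold_flux_xs(spec, np.ones(3), 0.0, 1.0)

    def test_bad_window_rejected(self):
        spec = self._spectrum([1.0, 2.0])
        with pytest.raises(ValueError):
            fold_flux_xs(spec, np.ones(2), 1.0, 1.0)

    @given(
        flux=arrays(np.float64, 400, elements=st.floats(0, 1e3)),
        sigma=arrays(np.float64, 400, elements=st.floats(0, 1e4)),
    )
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_loop_oracle(self, flux, sigma):
        spec = self._spectrum(flux)
        mid = spec.grid.midpoints
        expected = 0.0
        for i in range(400):
            if 0.6 <= mid[i] <= 40.0:
                expected += flux[i] * sigma[i]
        assert fold_flux_xs(spec, sigma, 0.6, 40.0) == expected

    def test_linear_under_spectrum_scaling(self):
        rng = np.random.default_rng(7)
        flux = rng.random(50)
        sigma = rng.random(50)
        spec = self._spectrum(flux)
        base = fold_flux_xs(spec, sigma, 0.0, 10.0)
        assert fold_flux_xs(spec.scaled(3.5), sigma, 0.0, 10.0) == pytest.approx(
            3.5 * base, rel=1e-12
        )


class TestFusionRate:
    def test_printed_factor_product(self):
        # product of the printed folded sum and inventory
        assert rate_from_folded_sum(70.52, 9.0e18) == pytest.approx(6.35e-7, rel=0.005)

    def test_zero_ppm_gives_zero_rate(
        self, shallow_proton_spectrum, b11_table, shallow_tumor
    ):
        result = fusion_reaction_rate(
            shallow_proton_spectrum, b11_table, shallow_tumor.with_ppm(0.0)
        )
        assert result.rate == 0.0

    def test_linear_in_ppm(self, shallow_proton_spectrum, b11_table, shallow_tumor):
        r100 = fusion_reaction_rate(shallow_proton_spectrum, b11_table, shallow_tumor)
        r1000 = fusion_reaction_rate(
            shallow_proton_spectrum, b11_table, shallow_tumor.with_ppm(1000.0)
        )
        assert r1000.rate == pytest.approx(10.0 * r100.rate, rel=1e-12)

    def test_wrong_isotope_rejected(
        self, shallow_proton_spectrum, b11_table, shallow_tumor
    ):
        with pytest.raises(ValueError):
            fusion_reaction_rate(
                shallow_proton_spectrum, b11_table, shallow_tumor.with_isotope("B10")
            )

    def test_result_invariant_and_serialization(
        self, shallow_proton_spectrum, b11_table, shallow_tumor, tmp_path
    ):
        result = fusion_reaction_rate(shallow_proton_spectrum, b11_table, shallow_tumor)
        assert result.rate == pytest.approx(
            result.n_atoms * result.folded_sum * 1e-27, rel=1e-12
        )
        path = tmp_path / "rate.json"
        result.to_json(path)
        data = json.loads(path.read_text())
        assert data["energy_window_mev"] == [0.6, 40.0]
        assert data["config_hash"]

    def test_depth_robustness_of_folded_sums(
        self,
        shallow_proton_spectrum,
        deep_proton_spectrum,
        b11_table,
        shallow_tumor,
        deep_tumor,
    ):
        shallow = fusion_reaction_rate(shallow_proton_spectrum, b11_table, shallow_tumor)
        deep = fusion_reaction_rate(deep_proton_spectrum, b11_table, deep_tumor)
        hi = max(shallow.folded_sum, deep.folded_sum)
        assert abs(shallow.folded_sum - deep.folded_sum) / hi < 0.25


class TestCaptureRate:
    def test_zero_spectrum(self, shallow_tumor):
        grid = LogEnergyGrid.spanning(1e-9, 130.0, per_decade=5)
        spec = ParticleSpectrum("neutron", grid, np.zeros(grid.nbins))
        result = capture_reaction_rate(
            spec, OneOverVModel(), shallow_tumor.with_isotope("B10")
        )
        assert result.rate == 0.0

    def test_single_bin_toy(self, shallow_tumor):
        # one bin whose geometric midpoint sits at the 0.0253 eV reference
        e_ref = 0.0253e-6
        grid = LogEnergyGrid([e_ref / 1.1, e_ref * 1.1])
        spec = ParticleSpectrum("neutron", grid, np.array([1e-5]))
        tumor = shallow_tumor.with_isotope("B10")
        result = capture_reaction_rate(spec, OneOverVModel(), tumor)
        n = boron_atom_count(tumor)
        assert result.rate == pytest.approx(n * 1e-5 * 3837e-24, rel=1e-9)
        assert result.rate == pytest.approx(3.8e-7, rel=0.02)

    def test_deep_calibrated_rate_in_printed_band(
        self, deep_neutron_spectrum, shallow_tumor
    ):
        result = capture_reaction_rate(
            deep_neutron_spectrum, OneOverVModel(), shallow_tumor.with_isotope("B10")
        )
        assert 1e-7 <= result.rate <= 1e-6

    def test_wrong_isotope_rejected(self, deep_neutron_spectrum, shallow_tumor):
        with pytest.raises(ValueError):
            capture_reaction_rate(deep_neutron_spectrum, OneOverVModel(), shallow_tumor)


class TestPercentIncrease:
    def test_printed_mcnpx_pair(self):
        assert percent_increase(9.5e-8, 1.09e-6) == 91.3

    def test_printed_geant4_pair(self):
        assert percent_increase(8.14e-8, 7.6e-7) == 89.3

    def test_equal_inputs(self):
        assert percent_increase(5.0, 5.0) == 0.0

    def test_zero_deep_rate_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(1.0, 0.0)
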