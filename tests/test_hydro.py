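"""Closed-form hydrodynamics: Svedberg/Stokes, Hill, frictional ratio."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from aucbind.hydro import (
    BSA,
    InteractionParams,
    ParticleSpec,
    ProteinSpec,
    SolventModel,
    complex_density,
    complex_s,
    diffusion_coefficient,
    diffusion_from_s_fr,
    frictional_ratio,
    hill_n_avg,
    isotherm_s,
    particle_from_sD,
    sedimentation_coefficient,
)
from aucbind.units import from_svedberg, gcm3_to_si, nm_to_m, to_svedberg

particles = st.builds(
    ParticleSpec,
    hydrodynamic_diameter=st.floats(1e-9, 100e-9),
    density=st.floats(1100.0, 20000.0),
)
solvents = st.builds(
    SolventModel,
    viscosity=st.floats(0.5e-3, 2e-3),
    density=st.floats(950.0, 1100.0),
    temperature=st.floats(277.0, 320.0),
)


class TestSvedbergStokes:
    def test_dense_sphere_sedimentation(self, water):
        """10 nm sphere at 2.0 g/cm³ sediments at ~55.5 S in water."""
        p = ParticleSpec(10e-9, 2000.0)
        assert to_svedberg(sedimentation_coefficient(p, water)) == pytest.approx(
            55.5, rel=1e-3
        )

    def test_neutral_buoyancy_is_zero(self, water):
        p = ParticleSpec(10e-9, water.density)
        assert sedimentation_coefficient(p, water) == 0.0

    def test_quadratic_diameter_scaling(self, water):
        p1 = ParticleSpec(10e-9, 2000.0)
        p2 = ParticleSpec(20e-9, 2000.0)
        assert sedimentation_coefficient(p2, water) == pytest.approx(
            4.0 * sedimentation_coefficient(p1, water)
        )

    def test_stokes_einstein_value(self, water):
        """10 nm sphere diffuses at ~4.29e-11 m²/s at 20 °C."""
        p = ParticleSpec(10e-9, 2000.0)
        assert diffusion_coefficient(p, water) == pytest.approx(
            4.286e-11, rel=1e-3
        )

    def test_diffusion_inverse_diameter_scaling(self, water):
        p1, p2 = ParticleSpec(10e-9, 2000.0), ParticleSpec(20e-9, 2000.0)
        assert diffusion_coefficient(p2, water) == pytest.approx(
            0.5 * diffusion_coefficient(p1, water)
        )


class TestSizingInversion:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(particle=particles, solvent=solvents)
    def test_round_trip_identity(self, particle, solvent):
        """(s, D) -> (d_H, rho) -> (s, D) is the identity to 1e-12."""
        assume(particle.density > solvent.density + 50.0)
        s = sedimentation_coefficient(particle, solvent)
        d = diffusion_coefficient(particle, solvent)
        back = particle_from_sD(s, d, solvent)
        assert back.hydrodynamic_diameter == pytest.approx(
            particle.hydrodynamic_diameter, rel=1e-12
        )
        assert back.density == pytest.approx(particle.density, rel=1e-12)

    def test_round_trip_bulk(self, water, rng):
        """1000 random valid particles round-trip to 1e-12 relative."""
        d = rng.uniform(2e-9, 50e-9, 1000)
        rho = rng.uniform(1200.0, 19000.0, 1000)
        for di, ri in zip(d, rho):
            p = ParticleSpec(di, ri)
            s = sedimentation_coefficient(p, water)
            dc = diffusion_coefficient(p, water)
            back = particle_from_sD(s, dc, water)
            np.testing.assert_allclose(
                [back.hydrodynamic_diameter, back.density], [di, ri],
                rtol=1e-12,
            )

    def test_reported_pair_inversion(self, water):
        """A (119 S, 5.78e-11 m²/s) pair inverts to a consistent sphere,
        which need not match independently reported size/density."""
        p = particle_from_sD(from_svedberg(119.0), 5.78e-11, water)
        assert to_svedberg(sedimentation_coefficient(p, water)) == pytest.approx(119.0)
        assert diffusion_coefficient(p, water) == pytest.approx(5.78e-11)

    def test_d_scaling_propagation(self, water):
        """Doubling D at fixed s halves d_H and quadruples the density excess."""
        s, d = from_svedberg(100.0), 4e-11
        p1 = particle_from_sD(s, d, water)
        p2 = particle_from_sD(s, 2 * d, water)
        assert p2.hydrodynamic_diameter == pytest.approx(
            p1.hydrodynamic_diameter / 2
        )
        assert (p2.density - water.density) == pytest.approx(
            4 * (p1.density - water.density)
        )

    def test_nonpositive_inputs_rejected(self, water):
        with pytest.raises(ValueError):
            particle_from_sD(-1e-13, 4e-11, water)
        with pytest.raises(ValueError):
            particle_from_sD(1e-13, 0.0, water)


class TestComplexHydrodynamics:
    def test_density_limits_and_example(self):
        np_spec = ParticleSpec(
            (6 * 50e-27 / math.pi) ** (1 / 3), 5500.0
        )  # 50 nm³ at 5.5 g/cm³
        prot = ProteinSpec(100e-27, 1300.0)
        assert complex_density(np_spec, prot, 0.0) == np_spec.density
        assert complex_density(np_spec, prot, 2.0) == pytest.approx(2140.0)
        assert complex_density(np_spec, prot, 1e9) == pytest.approx(
            prot.density, rel=1e-6
        )

    def test_density_monotone_in_coverage(self, mus_m_particle, bsa):
        n = np.linspace(0, 50, 200)
        rho = np.array([complex_density(mus_m_particle, bsa, x) for x in n])
        assert np.all(np.diff(rho) < 0)  # protein is lighter than this NP
        assert np.all((rho >= bsa.density) & (rho <= mus_m_particle.density))

    def test_negative_coverage_rejected(self, mus_m_particle, bsa):
        with pytest.raises(ValueError):
            complex_density(mus_m_particle, bsa, -0.1)

    def test_protein_coat_slows_dense_particle(self, mus_m_particle, bsa, water):
        """A 7 nm, 5.5 g/cm³ NP slows from ~122 S to ~90 S under 10 BSA."""
        bare = complex_s(mus_m_particle, bsa, 0.0, water)
        coated = complex_s(mus_m_particle, bsa, 10.0, water)
        assert to_svedberg(bare) == pytest.approx(122.3, rel=1e-2)
        assert to_svedberg(coated) == pytest.approx(89.7, rel=1e-2)
        assert coated < bare

    def test_zero_coverage_is_bare_particle(self, mus_m_particle, bsa, water):
        assert complex_s(mus_m_particle, bsa, 0.0, water) == pytest.approx(
            sedimentation_coefficient(mus_m_particle, water)
        )

    def test_neutral_protein_strictly_slows(self, mus_m_particle, water):
        """With protein density = solvent density the complex only gains
        friction, so s decreases strictly with coverage."""
        with pytest.warns(UserWarning):
            prot = ProteinSpec(100e-27, water.density)
        n = np.linspace(0, 30, 100)
        s = np.array([complex_s(mus_m_particle, prot, x, water) for x in n])
        assert np.all(np.diff(s) < 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        particle=particles,
        rho_p=st.floats(1050.0, 1950.0),
        n_avg=st.floats(0.1, 100.0),
    )
    def test_monotonicity_matches_sign_criterion(self, particle, rho_p, n_avg):
        """ds/dN_avg has the sign of (rho_P - rho_s) - (rho_cx - rho_s)/3."""
        solvent = SolventModel()
        prot = ProteinSpec(100e-27, rho_p)
        rho_cx = complex_density(particle, prot, n_avg)
        criterion = (rho_p - solvent.density) - (rho_cx - solvent.density) / 3
        eps = 1e-5 * max(n_avg, 1.0)
        ds = complex_s(particle, prot, n_avg + eps, solvent) - complex_s(
            particle, prot, n_avg - eps, solvent
        )
        if abs(criterion) > 1e-3:
            assert math.copysign(1, ds) == math.copysign(1, criterion)


class TestHillIsotherm:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        kd=st.floats(1e-8, 1e-4),
        n_max=st.floats(0.5, 100.0),
        n=st.floats(0.2, 5.0),
    )
    def test_half_saturation_identity(self, kd, n_max, n):
        """Coverage at [P] = K_D is exactly N_max/2 for every Hill n."""
        p = InteractionParams(kd, n_max, n)
        assert hill_n_avg(p, kd) == pytest.approx(n_max / 2, rel=1e-12)

    def test_zero_concentration_zero_coverage(self, mua_params):
        assert hill_n_avg(mua_params, 0.0) == 0.0

    def test_reference_evaluation(self):
        """K_D 5.4 uM, N_max 18, n 0.8 at 54 uM: ~15.5 proteins bound."""
        p = InteractionParams(5.4e-6, 18.0, 0.8)
        assert hill_n_avg(p, 54e-6) == pytest.approx(15.5, abs=0.05)

    def test_monotone_and_bounded(self, mua_params):
        c = np.geomspace(1e-9, 1e-2, 200)
        n = hill_n_avg(mua_params, c)
        assert np.all(np.diff(n) > 0)
        assert np.all(n < mua_params.n_max)

    def test_negative_concentration_rejected(self, mua_params):
        with pytest.raises(ValueError):
            hill_n_avg(mua_params, -1e-6)


class TestIsothermModel:
    def test_zero_conc_is_bare_s(self, mus_m_particle, bsa, mua_params, water):
        assert isotherm_s(
            mus_m_particle, bsa, mua_params, 0.0, water
        ) == pytest.approx(sedimentation_coefficient(mus_m_particle, water))

    def test_saturation_limit(self, mus_m_particle, bsa, mua_params, water):
        s_inf = isotherm_s(mus_m_particle, bsa, mua_params, 1.0, water)
        assert s_inf == pytest.approx(
            complex_s(mus_m_particle, bsa, mua_params.n_max, water), rel=1e-4
        )

    def test_half_saturation_composition(self, mus_m_particle, bsa, water):
        for n in (0.5, 1.0, 2.3):
            p = InteractionParams(2e-6, 12.0, n)
            assert isotherm_s(
                mus_m_particle, bsa, p, p.k_d, water
            ) == pytest.approx(
                complex_s(mus_m_particle, bsa, p.n_max / 2, water), rel=1e-12
            )


class TestFrictionalRatio:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(particle=particles, solvent=solvents)
    def test_sphere_gives_unity(self, particle, solvent):
        """(s, D) generated from one sphere always yields f/f0 = 1."""
        s = sedimentation_coefficient(particle, solvent)
        if s <= 0:
            return
        d = diffusion_coefficient(particle, solvent)
        assert frictional_ratio(s, d, particle.density, solvent) == pytest.approx(
            1.0, rel=1e-10
        )

    def test_reported_pair_value(self, water):
        """1080 S / 3.38e-11 m²/s at 17.7 g/cm³: f/f0 ≈ 1.11."""
        fr = frictional_ratio(
            from_svedberg(1080.0), 3.38e-11, gcm3_to_si(17.7), water
        )
        assert fr == pytest.approx(1.11, abs=0.005)

    def test_decreasing_in_diffusion(self, water):
        s, rho = from_svedberg(100.0), 5500.0
        d = np.linspace(2e-11, 8e-11, 20)
        fr = np.array([frictional_ratio(s, x, rho, water) for x in d])
        assert np.all(np.diff(fr) < 0)

    def test_perturbed_diffusion_grows_continuously(self, water):
        p = ParticleSpec(10e-9, 3000.0)
        s = sedimentation_coefficient(p, water)
        d0 = diffusion_coefficient(p, water)
        factors = np.linspace(1.0, 0.5, 10)
        frs = np.array(
            [frictional_ratio(s, f * d0, p.density, water) for f in factors]
        )
        assert frs[0] == pytest.approx(1.0, rel=1e-10)
        assert np.all(np.diff(frs) > 0)

    def test_buoyant_density_required(self, water):
        with pytest.raises(ValueError):
            frictional_ratio(1e-11, 4e-11, water.density * 0.99, water)

    def test_scaling_law_inverse(self, water):
        """diffusion_from_s_fr is the exact inverse of frictional_ratio."""
        s, rho = from_svedberg(119.0), 5500.0
        for fr in (1.0, 1.3, 2.0):
            d = diffusion_from_s_fr(s, fr, rho, water)
            assert frictional_ratio(s, d, rho, water) == pytest.approx(
                fr, rel=1e-12
            )


class TestUnitConsistency:
    def test_si_vs_conventional_units(self):
        """Computing in SI then converting equals converting inputs first."""
        d_nm, rho_gcm3 = 8.0, 4.2
        solvent = SolventModel()
        p_si = ParticleSpec(nm_to_m(d_nm), gcm3_to_si(rho_gcm3))
        s_sved = to_svedberg(sedimentation_coefficient(p_si, solvent))
        # same computation carried out directly in nm / g/cm³ / mPa·s
        s_direct = (
            (d_nm * 1e-9) ** 2
            * (rho_gcm3 - 0.99823) * 1e3
            / (18 * 1.002e-3)
            / 1e-13
        )
        assert s_sved == pytest.approx(s_direct, rel=1e-12)


class TestValidation:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ParticleSpec(-1e-9, 2000.0)
        with pytest.raises(ValueError):
            SolventModel(temperature=400.0)
        with pytest.raises(ValueError):
            InteractionParams(k_d=-1e-6, n_max=10.0, hill_n=1.0)
        with pytest.raises(ValueError):
            InteractionParams(k_d=1e-6, n_max=10.0, hill_n=0.0)

    def test_protein_density_warning(self):
        with pytest.warns(UserWarning):
            ProteinSpec(100e-27, 2500.0)

    def test_bsa_prism_volume(self):
        """Packaged BSA volume is the 8.4 nm / 3.2 nm triangular prism."""
        assert BSA.hydrodynamic_volume == pytest.approx(97.77e-27, rel=1e-3)
        assert BSA.density == 1300.0
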