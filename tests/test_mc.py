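"""Simplified Monte Carlo: transport physics, tallies, scoring."""

import numpy as np
import pytest
from scipy import stats

from cherenkov_polarimetry._tables import (
    collisional_stopping_power,
    photon_attenuation_coefficient,
)
from cherenkov_polarimetry.mc import (
    BeamSpec,
    PhotonTally,
    ScoringRegion,
    score_distributions,
    simulate_beam,
    transport_electron,
    transport_photon_primary,
)
from cherenkov_polarimetry.physics import (
    ELECTRON_REST_MASS_KEV,
    ChargedParticleState,
    beta_from_kinetic_energy,
    cherenkov_angle,
)


def polar_angles_deg(tally):
    return np.degrees(np.arccos(np.clip(tally.directions[:, 2], -1.0, 1.0)))


class TestTables:
    def test_stopping_power_matches_tabulated_anchors(self):
        # direct grid points must come back exactly (keV/cm at unit density)
        assert collisional_stopping_power(1000.0) == pytest.approx(1849.0, rel=1e-6)
        assert collisional_stopping_power(100.0) == pytest.approx(4115.0, rel=1e-6)

    def test_attenuation_anchors(self):
        assert photon_attenuation_coefficient(2000.0) == pytest.approx(0.0494, rel=1e-6)
        assert photon_attenuation_coefficient(5000.0) == pytest.approx(0.0303, rel=1e-6)


class TestElectronTransport:
    def test_below_threshold_emits_nothing(self):
        state = ChargedParticleState(kinetic_energy=200.0, position=[0, 0, 1.0])
        assert len(transport_electron(state, rng=0)) == 0

    def test_no_scatter_matches_analytic_cone(self):
        # degenerate limit: every photon's polar angle equals the analytic
        # Cherenkov angle at the (slowing) electron energy
        state = ChargedParticleState(kinetic_energy=6000.0, position=[0, 0, 1e-9])
        tally = transport_electron(state, rng=3, scattering=False, step_cm=0.05)
        assert len(tally) > 100
        theta = polar_angles_deg(tally)
        # reconstruct the energy at each emission depth to get the local angle
        energy = 6000.0
        z = 1e-9
        expected = {}
        while True:
            beta = beta_from_kinetic_energy(energy)
            if beta * 1.33 < 1:
                break
            expected[round(z + 0.025, 6)] = cherenkov_angle(beta, 1.33)
            z += 0.05
            energy -= float(collisional_stopping_power(energy)) * 0.05
        for depth, th in zip(tally.generation_depths, theta):
            assert th == pytest.approx(expected[round(depth, 6)], abs=1e-9)

    def test_shallow_polar_mode_near_cone_angle_18mev(self):
        rng = np.random.default_rng(11)
        tallies = [transport_electron(
            ChargedParticleState(kinetic_energy=18000.0, position=[0, 0, 1e-6]),
            rng=rng) for _ in range(60)]
        tally = PhotonTally.concatenate(tallies)
        sel = tally.generation_depths < 1.0
        theta = polar_angles_deg(tally)[sel]
        assert sel.sum() > 10_000
        hist, edges = np.histogram(theta, bins=np.arange(0.0, 181.0, 1.0))
        mode = edges[np.argmax(hist)]
        assert mode == pytest.approx(41.0, abs=1.0)

    def test_deterministic_given_seed(self):
        state = ChargedParticleState(kinetic_energy=6000.0, position=[0, 0, 0.5])
        t1 = transport_electron(state, rng=42)
        t2 = transport_electron(state, rng=42)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.directions, t2.directions)

    def test_step_halving_keeps_shallow_mode_bin(self):
        modes = []
        for step in (0.1, 0.05):
            rng = np.random.default_rng(5)
            tallies = [transport_electron(
                ChargedParticleState(kinetic_energy=18000.0, position=[0, 0, 1e-6]),
                rng=rng, step_cm=step) for _ in range(40)]
            tally = PhotonTally.concatenate(tallies)
            theta = polar_angles_deg(tally)[tally.generation_depths < 1.0]
            hist, edges = np.histogram(theta, bins=np.arange(0.0, 181.0, 1.0))
            modes.append(edges[np.argmax(hist)])
        assert modes[0] == modes[1]

    def test_polarization_transverse_to_photon(self):
        state = ChargedParticleState(kinetic_energy=10000.0, position=[0, 0, 1.0])
        tally = transport_electron(state, rng=9)
        dots = np.einsum("ij,ij->i", tally.directions, tally.polarizations)
        np.testing.assert_allclose(dots, 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(tally.polarizations, axis=1),
                                   1.0, atol=1e-10)

    def test_outside_tank_rejected(self):
        with pytest.raises(ValueError):
            transport_electron(ChargedParticleState(
                kinetic_energy=1000.0, position=[0, 0, -5.0]), rng=0)


class TestPhotonTransport:
    def test_mean_free_path_matches_attenuation(self):
        # depth of first interaction should average 1/mu (restricted to the
        # tank, so compare against the truncated-exponential mean)
        rng = np.random.default_rng(2)
        mu = float(photon_attenuation_coefficient(2000.0))
        depths = []
        for _ in range(3000):
            path = rng.exponential(1.0 / mu)
            if path < 20.0:
                depths.append(path)
        expected = np.mean(depths)
        tally_depths = []
        rng2 = np.random.default_rng(2)
        for _ in range(600):
            t = transport_photon_primary(2000.0, rng=rng2)
            if len(t):
                tally_depths.append(t.generation_depths.min())
        got = np.mean(tally_depths)
        assert got == pytest.approx(expected, rel=0.15)

    def test_compton_electron_below_kinematic_edge(self):
        from cherenkov_polarimetry.mc import _sample_klein_nishina
        rng = np.random.default_rng(3)
        e = 2000.0
        k = e / ELECTRON_REST_MASS_KEV
        edge = e * 2.0 * k / (1.0 + 2.0 * k)
        for _ in range(2000):
            electron_kev, _ = _sample_klein_nishina(e, rng)
            assert 0.0 <= electron_kev <= edge + 1e-9

    def test_invalid_energy_rejected(self):
        with pytest.raises(ValueError):
            transport_photon_primary(-5.0, rng=0)


class TestScoring:
    def test_histogram_sums_equal_photon_count(self):
        tally = simulate_beam(BeamSpec.preset("6MeV"), 30, seed=1)
        [dist] = score_distributions(
            tally, [ScoringRegion(depth=1.0, size=40.0)],
            camera_side_filter=False)
        assert dist.polar_hist.sum() == dist.n_photons == len(tally)
        assert dist.azimuth_hist.sum() == dist.n_photons

    def test_camera_side_filter_keeps_forward_hemisphere(self):
        tally = simulate_beam(BeamSpec.preset("6MeV"), 30, seed=1)
        [dist] = score_distributions(
            tally, [ScoringRegion(depth=1.0, size=40.0)],
            camera_side_filter=True)
        kept = (tally.directions[:, 0] > 0).sum()
        assert dist.n_photons == kept

    def test_pencil_beam_azimuth_uniform(self):
        # cylindrical symmetry of an on-axis pencil beam: chi-square test
        tally = simulate_beam(BeamSpec("electron", 18000.0), 120, seed=4)
        [dist] = score_distributions(
            tally, [ScoringRegion(depth=2.0, size=4.0)],
            camera_side_filter=False, azimuth_bin_deg=30.0)
        assert dist.n_photons > 5000
        _, p = stats.chisquare(dist.azimuth_hist)
        assert p > 0.01

    def test_empty_region_flagged(self):
        tally = simulate_beam(BeamSpec("electron", 1000.0), 5, seed=0)
        [dist] = score_distributions(tally, [ScoringRegion(depth=19.5)])
        assert dist.empty
        assert dist.n_photons == 0
        assert dist.polar_hist.sum() == 0

    def test_density_normalization(self):
        tally = simulate_beam(BeamSpec.preset("6MeV"), 30, seed=1)
        [dist] = score_distributions(tally, [ScoringRegion(depth=1.0, size=40.0)])
        theta = np.linspace(0.5, 179.5, 180)
        integral = np.trapezoid(dist.polar_density(theta), theta)
        assert integral == pytest.approx(1.0, abs=0.02)


class TestQualitativeDistributionBehaviour:
    """Depth evolution mirrors the expected beam physics."""

    def test_electron_polar_distributions_broaden_and_shift_with_depth(self):
        tally = simulate_beam(BeamSpec("electron", 18000.0), 250, seed=8)
        shallow, deep = score_distributions(
            tally,
            [ScoringRegion(depth=0.75, size=1.5), ScoringRegion(depth=6.0, size=1.5)],
            camera_side_filter=False)
        def mean_angle(d):
            centers = 0.5 * (d.polar_edges[:-1] + d.polar_edges[1:])
            return np.average(centers, weights=d.polar_hist)
        def spread(d):
            centers = 0.5 * (d.polar_edges[:-1] + d.polar_edges[1:])
            m = np.average(centers, weights=d.polar_hist)
            return np.sqrt(np.average((centers - m) ** 2, weights=d.polar_hist))
        assert mean_angle(deep) > mean_angle(shallow)
        assert spread(deep) > spread(shallow)

    def test_photon_distributions_consistent_beyond_buildup(self):
        # photon-beam polar distributions at two depths past d_max agree
        # much more closely than electron-beam ones do
        photon = simulate_beam(BeamSpec("photon", 5000.0), 900, seed=10)
        electron = simulate_beam(BeamSpec("electron", 18000.0), 250, seed=10)
        regions = [ScoringRegion(depth=4.0, size=2.0),
                   ScoringRegion(depth=9.0, size=2.0)]

        def l1_distance(tally):
            a, b = score_distributions(tally, regions, camera_side_filter=False)
            pa = a.polar_hist / max(a.polar_hist.sum(), 1)
            pb = b.polar_hist / max(b.polar_hist.sum(), 1)
            return np.abs(pa - pb).sum()

        d_photon = l1_distance(photon)
        d_electron = l1_distance(electron)
        assert d_photon < 0.35
        assert d_electron > 2.0 * d_photon

    def test_off_axis_azimuthal_asymmetry_grows_for_electrons(self):
        tally = simulate_beam(BeamSpec.preset("6MeV"), 600, seed=12)
        dists = score_distributions(
            tally,
            [ScoringRegion(depth=1.3, off_axis=o, size=1.0) for o in (0.0, 2.0, 3.0)],
            camera_side_filter=False)

        def asymmetry(d):
            if d.n_photons == 0:
                return 0.0
            centers = 0.5 * (d.azimuth_edges[:-1] + d.azimuth_edges[1:])
            p = d.azimuth_hist / d.azimuth_hist.sum()
            # first circular moment magnitude: 0 for a uniform azimuth
            c = np.sum(p * np.cos(np.deg2rad(centers)))
            s = np.sum(p * np.sin(np.deg2rad(centers)))
            return float(np.hypot(c, s))

        asym = [asymmetry(d) for d in dists]
        assert asym[2] > asym[0]


class TestBeamSpec:
    def test_presets(self):
        assert BeamSpec.preset("6MV").particle == "photon"
        assert BeamSpec.preset("18MeV").energy_spectrum == 18000.0
        with pytest.raises(ValueError):
            BeamSpec.preset("10MV")

    def test_spectrum_sampling_normalizes_weights(self, rng):
        beam = BeamSpec("electron", [(1000.0, 2.0), (2000.0, 6.0)])
        draws = beam.sample_energy(rng, 4000)
        assert set(np.unique(draws)) == {1000.0, 2000.0}
        assert np.mean(draws == 2000.0) == pytest.approx(0.75, abs=0.05)

    def test_photon_count_scales_linearly_with_primaries(self):
        n1 = len(simulate_beam(BeamSpec("electron", 6000.0), 30, seed=1))
        n2 = len(simulate_beam(BeamSpec("electron", 6000.0), 60, seed=2))
        ratio = n2 / n1
        assert ratio == pytest.approx(2.0, rel=0.2)
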