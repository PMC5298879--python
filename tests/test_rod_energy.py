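"""Discrete rod energies against continuum closed forms and gradients."""

import numpy as np
import pytest

from axonmech.errors import DiscretizationError, InvalidParameterError
from axonmech.params import MechParams
from axonmech.rod import M_TO_UM, RodCore, RodState, build_rod, elastic_energy


@pytest.fixture
def params():
    return MechParams(E=5000.0, nu=0.5, radius=100e-9, mu=1.0)


def bent_arc_rod(params, n, L, R):
    """Rod of length L bent into a circular arc of radius R, untwisted."""
    rod = build_rod(n, L, params)
    s = np.linspace(0, L, n)
    phi = s / R
    rod.vertices = np.column_stack([R * np.sin(phi), R * (1 - np.cos(phi)), np.zeros(n)])
    rod.reference_frames = None
    rod.__post_init__()
    return rod


class TestBuildRod:
    def test_total_imposed_twist_forty_turns(self):
        # 360 deg per 1.5 um over 60 um -> 40 turns
        rod = build_rod(200, 60e-6, MechParams(E=5000.0), 2 * np.pi / 1.5e-6)
        total = rod.theta[-1] - rod.theta[0]
        # theta spans edge midpoints: (n-2)/(n-1) of the full ramp
        frac = (rod.n_edges - 1) / rod.n_edges
        assert total / (2 * np.pi) == pytest.approx(40.0 * frac, rel=1e-9)
        assert rod.total_rest_length == pytest.approx(60e-6)

    def test_zero_twist_zero_twist_energy(self, params):
        rod = build_rod(100, 50e-6, params, 0.0)
        assert elastic_energy(rod, params).twist == 0.0

    def test_refinement_leaves_rest_length_unchanged(self, params):
        r1 = build_rod(100, 50e-6, params)
        r2 = build_rod(200, 50e-6, params)
        assert r1.total_rest_length == pytest.approx(r2.total_rest_length)

    def test_too_coarse_discretization_rejected(self):
        fat = MechParams(E=5000.0, radius=5e-6)
        with pytest.raises(DiscretizationError):
            build_rod(1001, 10e-6, fat)

    def test_too_few_vertices_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            build_rod(2, 10e-6, params)


class TestElasticEnergy:
    def test_straight_untwisted_rod_zero_energy(self, params):
        rod = build_rod(150, 60e-6, params)
        eb = elastic_energy(rod, params)
        assert eb.total == pytest.approx(0.0, abs=1e-30)

    @pytest.mark.parametrize("n", [150, 250])
    def test_circular_arc_matches_continuum(self, params, n):
        L, R = 60e-6, 30e-6
        rod = bent_arc_rod(params, n, L, R)
        eb = elastic_energy(rod, params)
        expected = 0.5 * params.B * L / R**2
        assert eb.bend == pytest.approx(expected, rel=0.01)
        assert eb.twist == pytest.approx(0.0, abs=1e-25 * expected)

    def test_refinement_convergence_under_doubling(self, params):
        L, R = 60e-6, 30e-6
        e100 = elastic_energy(bent_arc_rod(params, 100, L, R), params).bend
        e200 = elastic_energy(bent_arc_rod(params, 200, L, R), params).bend
        assert abs(e200 - e100) / e100 < 0.01

    def test_uniform_twist_matches_continuum(self, params):
        L, tau = 60e-6, 2 * np.pi / 3e-6  # rad/m
        rod = build_rod(200, L, params, tau)
        eb = elastic_energy(rod, params)
        expected = 0.5 * params.C * tau**2 * L
        assert eb.twist == pytest.approx(expected, rel=0.01)

    def test_stretch_energy_hookean(self, params):
        rod = build_rod(100, 50e-6, params)
        rod.vertices = rod.vertices * [1.01, 1.0, 1.0]  # uniform 1% strain
        eb = elastic_energy(rod, params)
        EA = params.k * params.A
        expected = 0.5 * EA * 0.01**2 * 50e-6
        assert eb.stretch == pytest.approx(expected, rel=1e-3)

    def test_total_is_sum_of_parts(self, params):
        rod = bent_arc_rod(params, 120, 60e-6, 25e-6)
        eb = elastic_energy(rod, params)
        assert eb.total == pytest.approx(
            eb.bend + eb.twist + eb.stretch + eb.contact_penalty
        )


class TestForceGradient:
    def test_analytic_forces_match_finite_differences(self, params):
        rng = np.random.default_rng(0)
        rod = build_rod(50, 40e-6, params, 2 * np.pi / 1.5e-6)
        n = rod.n_vertices
        pert = np.zeros((n, 3))
        s = np.linspace(0, 1, n)
        for m in range(1, 5):
            for ax in (1, 2):
                pert[:, ax] += rng.normal(0, 0.3e-6) * np.sin(np.pi * m * s)
        rod = rod.displaced(pert)
        core = RodCore(rod, params)
        x = rod.vertices * M_TO_UM
        core.rebuild_pairs(x)

        def energy_of(r):
            return sum(core.energies(r.vertices * M_TO_UM, r.material_twists())[:3])

        F = core.forces(x, rod.material_twists())
        h = 1e-5  # um
        F_fd = np.zeros_like(F)
        for i in range(2, n - 2):
            for ax in range(3):
                dx = np.zeros((n, 3))
                dx[i, ax] = h / M_TO_UM
                F_fd[i, ax] = -(energy_of(rod.displaced(dx)) - energy_of(rod.displaced(-dx))) / (
                    2 * h
                )
        scale = np.abs(F[2:-2]).max()
        assert np.abs(F[2:-2] - F_fd[2:-2]).max() / scale < 1e-4

    def test_contact_penalty_gradient(self, params):
        # two crossing strands: push-apart force matches finite difference
        n = 31
        line1 = np.column_stack([np.linspace(0, 10e-6, n), np.zeros(n), np.zeros(n)])
        line2 = np.column_stack(
            [np.full(n, 5e-6), np.linspace(-5e-6, 5e-6, n), np.full(n, 0.15e-6)]
        )
        verts = np.vstack([line1, line2])
        rod = RodState(
            vertices=verts,
            theta=np.zeros(len(verts) - 1),
            rest_lengths=np.full(len(verts) - 1, 10e-6 / (n - 1)),
        )
        core = RodCore(rod, params)
        x = rod.vertices * M_TO_UM
        core.rebuild_pairs(x)
        assert core._contact_energy(x) > 0
        phi = np.zeros(len(verts) - 2)
        F = core.forces(x, phi)
        i = n + n // 2  # midpoint of the crossing strand
        h = 1e-5
        for ax in (2,):
            xp, xm = x.copy(), x.copy()
            xp[i, ax] += h
            xm[i, ax] -= h
            f_fd = -(core._contact_energy(xp) - core._contact_energy(xm)) / (2 * h)
            # compare against the contact part of the force
            F_nc = core.forces(x, phi)
            assert F_nc[i, ax] == pytest.approx(f_fd, rel=1e-3, abs=1e-9)
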