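"""Unit and property tests for the constrained FQ/FQFμ polarization solver.

The independent oracle throughout is direct numerical minimization of the
quadratic charge energy under per-molecule total-charge constraints
(scipy trust-constr), never the bordered linear solve under test.
"""
import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize
from scipy.spatial.transform import Rotation

from colorspec import fq
from colorspec.units import BOHR_PER_ANGSTROM, bohr_to_angstrom

from conftest import make_droplet


def _solve(droplet, params, chi_map, model="fq", ext=None, source=None):
    kernels = fq.assemble_kernels(droplet, params, model=model)
    mm_idx = droplet.solvent_atom_indices
    if source is not None:
        ext = fq.source_fields(source, droplet.frame.positions[mm_idx])
    chi = np.array([chi_map[droplet.topology.atoms[i].element] for i in mm_idx])
    return fq.solve_polarization(kernels, chi, ext), kernels, ext


def _qp_oracle(kernels, chi, ext):
    """Constrained quadratic minimization of E(q) — the brute-force reference."""
    n = kernels.n_atoms
    V = ext.V if ext is not None else np.zeros(n)

    def energy(q):
        return chi @ q + 0.5 * q @ kernels.Tqq @ q + q @ V

    res = minimize(
        energy,
        np.zeros(n),
        method="trust-constr",
        jac=lambda q: chi + kernels.Tqq @ q + V,
        hess=lambda q: kernels.Tqq,
        constraints=[LinearConstraint(kernels.constraint.T, kernels.qtot, kernels.qtot)],
        options={"gtol": 1e-13, "xtol": 1e-14},
    )
    return res.x


class TestSourceFields:
    def test_unit_charge_coulomb(self):
        src = fq.SoluteSource(positions=[[0.0, 0, 0]], charges=[1.0])
        site = [[bohr_to_angstrom(1.0), 0.0, 0.0]]
        ext = fq.source_fields(src, site)
        assert ext.V[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(ext.E[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_pure_dipole_potential(self):
        src = fq.SoluteSource(
            positions=[[0.0, 0, 0]], charges=[0.0], dipoles=[[0.0, 0.0, 1.0]]
        )
        site = [[0.0, 0.0, bohr_to_angstrom(2.0)]]
        ext = fq.source_fields(src, site)
        assert ext.V[0] == pytest.approx(0.25, abs=1e-12)  # μ·r̂/r² = 1/4

    def test_field_is_minus_gradient_of_potential(self, rng):
        """E from the analytic formulas matches −∇V by central differences."""
        src = fq.SoluteSource(
            positions=rng.normal(0, 2, (4, 3)),
            charges=rng.normal(0, 1, 4),
            dipoles=rng.normal(0, 0.5, (4, 3)),
        )
        pts = rng.normal(0, 8, (5, 3)) + 15.0
        ext = fq.source_fields(src, pts)
        h = 1e-5  # Å
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            vp = fq.source_fields(src, pts + e).V
            vm = fq.source_fields(src, pts - e).V
            grad_k = (vp - vm) / (2 * h) * (1.0 / BOHR_PER_ANGSTROM)
            np.testing.assert_allclose(-grad_k, ext.E[:, k], atol=1e-6)

    def test_coincident_site_rejected(self):
        src = fq.SoluteSource(positions=[[1.0, 2.0, 3.0]], charges=[1.0])
        with pytest.raises(ValueError, match="coincides"):
            fq.source_fields(src, [[1.0, 2.0, 3.0]])


class TestKernels:
    def test_two_atom_tqq_structure(self, water_like_droplet):
        params = fq.FQParams({"H": (0.1, 0.7), "O": (0.45, 0.6)})
        k = fq.assemble_kernels(water_like_droplet, params)
        assert k.Tqq.shape == (3, 3)
        np.testing.assert_allclose(np.diag(k.Tqq), [0.7, 0.6, 0.7])
        np.testing.assert_allclose(k.Tqq, k.Tqq.T, atol=1e-12)

    def test_bordered_matrix_symmetric(self, water_like_droplet):
        params = fq.FQParams({"H": (0.1, 0.7, 0.5), "O": (0.45, 0.6, 1.1)})
        k = fq.assemble_kernels(water_like_droplet, params, model="fqmu")
        A = k.bordered_matrix()
        np.testing.assert_allclose(A, A.T, atol=1e-12)

    def test_ohno_kernel_asymptotes_to_coulomb(self):
        d = make_droplet(
            [
                [("O", (0.0, 0.0, 0.0))],
                [("O", (100.0, 0.0, 0.0))],
            ]
        )
        params = fq.FQParams({"O": (0.45, 0.6)})
        k = fq.assemble_kernels(d, params)
        r = 100.0 * BOHR_PER_ANGSTROM
        # leading deviation from Coulomb is d²/(2r²) with d = 2/(η_i+η_j)
        d_smear = 2.0 / 1.2
        expected_rel = d_smear**2 / (2 * r**2)
        assert k.Tqq[0, 1] == pytest.approx(1.0 / r, rel=2 * expected_rel)
        assert abs(k.Tqq[0, 1] * r - 1.0) < 1e-4

    def test_missing_parameter_names_type(self, water_like_droplet):
        with pytest.raises(KeyError, match="'H'"):
            fq.assemble_kernels(water_like_droplet, fq.FQParams({"O": (0.45, 0.6)}))

    def test_zero_alpha_rejected_for_fqmu(self, water_like_droplet):
        params = fq.FQParams({"H": (0.1, 0.7, 0.0), "O": (0.45, 0.6, 1.0)})
        with pytest.raises(ValueError, match="α"):
            fq.assemble_kernels(water_like_droplet, params, model="fqmu")

    def test_gaussian_damping_reduces_short_range_coupling(self):
        d = make_droplet([[("O", (0.0, 0, 0))], [("O", (1.0, 0, 0))]])
        point = fq.FQParams({"O": (0.45, 0.6, 3.0)})
        damped = fq.FQParams({"O": (0.45, 0.6, 3.0)}, mu_damping="gaussian")
        kp = fq.assemble_kernels(d, point, "fqmu")
        kd = fq.assemble_kernels(d, damped, "fqmu")
        assert np.abs(kd.Tqmu).max() < np.abs(kp.Tqmu).max()
        # far apart the damping must vanish
        d2 = make_droplet([[("O", (0.0, 0, 0))], [("O", (25.0, 0, 0))]])
        kp2 = fq.assemble_kernels(d2, point, "fqmu")
        kd2 = fq.assemble_kernels(d2, damped, "fqmu")
        np.testing.assert_allclose(kd2.Tmumu, kp2.Tmumu, atol=1e-10)


PARAMS = fq.FQParams({"H": (0.1, 0.7), "O": (0.45, 0.6)})
CHI = {"H": 0.1, "O": 0.45}


class TestSolvePolarization:
    def test_symmetric_ion_splits_charge(self):
        d = make_droplet(
            [[("O", (0.0, 0, 0)), ("O", (1.2, 0, 0))]], qtot={1: -1.0}
        )
        state, *_ = _solve(d, PARAMS, CHI)
        np.testing.assert_allclose(state.q, [-0.5, -0.5], atol=1e-10)

    def test_neutral_equal_chi_gives_zero_charges(self):
        d = make_droplet([[("O", (0.0, 0, 0)), ("O", (1.2, 0, 0)), ("O", (0.6, 1.0, 0))]])
        state, *_ = _solve(d, PARAMS, CHI)
        np.testing.assert_allclose(state.q, 0.0, atol=1e-12)

    def test_matches_quadratic_programming_oracle(self, water_like_droplet):
        src = fq.SoluteSource(positions=[[3.0, 0.0, 0.0]], charges=[1.0])
        state, kernels, ext = _solve(water_like_droplet, PARAMS, CHI, source=src)
        chi = np.array([0.1, 0.45, 0.1])
        q_ref = _qp_oracle(kernels, chi, ext)
        np.testing.assert_allclose(state.q, q_ref, atol=1e-8)

    def test_charge_conservation_random_geometries(self, rng):
        """Per-molecule charge sums equal Qtot to 1e-10 for arbitrary geometry."""
        for trial in range(20):
            mols = []
            qtot = {}
            for m in range(3):
                base = rng.random(3) * 10
                mols.append(
                    [("O", tuple(base)), ("H", tuple(base + rng.normal(0, 1, 3)))]
                )
                qtot[m + 1] = float(rng.choice([-1.0, 0.0, 1.0]))
            d = make_droplet(mols, qtot=qtot)
            src = fq.SoluteSource(
                positions=[d.center + rng.normal(0, 2, 3)], charges=[1.0]
            )
            state, kernels, _ = _solve(d, PARAMS, CHI, source=src)
            sums = kernels.constraint.T @ state.q
            np.testing.assert_allclose(sums, kernels.qtot, atol=1e-10)

    def test_response_linear_in_external_field(self, water_like_droplet):
        src = fq.SoluteSource(positions=[[4.0, 1.0, 0.0]], charges=[0.5])
        state0, kernels, _ = _solve(water_like_droplet, PARAMS, CHI)
        state1, _, ext1 = _solve(water_like_droplet, PARAMS, CHI, source=src)
        chi = np.array([0.1, 0.45, 0.1])
        scaled = fq.ExternalFieldAtSites(V=3.0 * ext1.V, E=3.0 * ext1.E)
        state3 = fq.solve_polarization(kernels, chi, scaled)
        np.testing.assert_allclose(
            state3.q - state0.q, 3.0 * (state1.q - state0.q), atol=1e-10
        )

    def test_rigid_motion_invariance(self, rng):
        """Translation/rotation of droplet+source leaves q and the energy
        unchanged; dipoles co-rotate."""
        mols = [
            [("H", (0.76, 0.59, 0.0)), ("O", (0.0, 0.0, 0.0)), ("H", (-0.76, 0.59, 0.0))],
            [("O", (3.5, 2.0, 1.0)), ("H", (4.2, 2.4, 1.0))],
        ]
        params = fq.FQParams({"H": (0.1, 0.7, 0.4), "O": (0.45, 0.6, 1.1)})
        src_pos = np.array([[2.0, -2.0, 0.5]])

        def run(transform):
            d = make_droplet(
                [[(el, tuple(transform(np.array(p)))) for el, p in mol] for mol in mols],
                solute_positions=[tuple(transform(np.array([50.0, 50.0, 50.0])))],
            )
            src = fq.SoluteSource(positions=transform(src_pos), charges=[1.0])
            state, _, ext = _solve(d, params, CHI, model="fqmu", source=src)
            return state, fq.interaction_energy(state, ext, "fqmu")

        state_ref, e_ref = run(lambda x: x)
        shift = rng.normal(0, 5, 3)
        state_t, e_t = run(lambda x: x + shift)
        np.testing.assert_allclose(state_t.q, state_ref.q, atol=1e-10)
        assert e_t == pytest.approx(e_ref, abs=1e-10)
        R = Rotation.random(random_state=7)
        state_r, e_r = run(lambda x: R.apply(x))
        np.testing.assert_allclose(state_r.q, state_ref.q, atol=1e-10)
        assert e_r == pytest.approx(e_ref, abs=1e-10)
        np.testing.assert_allclose(state_r.mu, R.apply(state_ref.mu), atol=1e-10)

    def test_fqmu_approaches_fq_as_alpha_vanishes(self, water_like_droplet):
        src = fq.SoluteSource(positions=[[3.0, 0.0, 0.0]], charges=[1.0])
        state_fq, _, ext = _solve(water_like_droplet, PARAMS, CHI, source=src)
        e_fq = fq.interaction_energy(state_fq, ext, "fq")
        mu_norms = []
        for alpha in (1e-2, 1e-4, 1e-8):
            p = fq.FQParams({"H": (0.1, 0.7, alpha), "O": (0.45, 0.6, alpha)})
            st, _, ext_mu = _solve(water_like_droplet, p, CHI, model="fqmu", source=src)
            mu_norms.append(np.linalg.norm(st.mu))
            if alpha == 1e-8:
                assert fq.interaction_energy(st, ext_mu, "fqmu") == pytest.approx(
                    e_fq, abs=1e-6
                )
                np.testing.assert_allclose(st.q, state_fq.q, atol=1e-6)
        # dipole magnitude shrinks linearly with α
        assert mu_norms[0] / mu_norms[1] == pytest.approx(1e2, rel=0.05)


class TestEnergiesAndEmbedding:
    def test_null_state_zero_energy(self):
        state = fq.PolarizationState(
            q=np.zeros(2), mu=np.zeros((2, 3)), lagrange=np.zeros(1),
            positions=np.zeros((2, 3)),
        )
        ext = fq.ExternalFieldAtSites(V=np.array([1.0, -2.0]), E=np.zeros((2, 3)))
        assert fq.interaction_energy(state, ext, "fq") == 0.0

    def test_single_term_energy(self):
        state = fq.PolarizationState(
            q=np.array([1.0]), mu=np.zeros((1, 3)), lagrange=np.zeros(1),
            positions=np.zeros((1, 3)),
        )
        ext = fq.ExternalFieldAtSites(V=np.array([0.2]), E=np.zeros((1, 3)))
        assert fq.interaction_energy(state, ext, "fq") == pytest.approx(0.2)

    def test_model_state_mismatch_rejected(self):
        state = fq.PolarizationState(
            q=np.array([1.0]), mu=np.ones((1, 3)), lagrange=np.zeros(1),
            positions=np.zeros((1, 3)),
        )
        ext = fq.ExternalFieldAtSites(V=np.array([0.2]), E=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            fq.interaction_energy(state, ext, "fq")

    def test_embedding_potential_coulomb_and_superposition(self):
        def point_state(q, pos):
            return fq.PolarizationState(
                q=np.array(q), mu=np.zeros((len(q), 3)), lagrange=np.zeros(1),
                positions=np.array(pos),
            )

        probe = [[bohr_to_angstrom(1.0), 0.0, 0.0]]
        s1 = point_state([1.0], [[0.0, 0.0, 0.0]])
        assert fq.embedding_potential_at(s1, probe)[0] == pytest.approx(1.0, abs=1e-12)
        s2 = point_state([0.7], [[0.0, 2.0, 0.0]])
        both = point_state([1.0, 0.7], [[0.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        v = fq.embedding_potential_at(both, probe)[0]
        v12 = (
            fq.embedding_potential_at(s1, probe)[0]
            + fq.embedding_potential_at(s2, probe)[0]
        )
        assert v == pytest.approx(v12, abs=1e-12)

    def test_neutral_molecule_far_field_decays_faster_than_coulomb(self, water_like_droplet):
        src = fq.SoluteSource(positions=[[3.0, 0.0, 0.0]], charges=[1.0])
        state, *_ = _solve(water_like_droplet, PARAMS, CHI, source=src)
        r = np.linspace(50.0, 100.0, 8)
        pts = np.column_stack([np.zeros_like(r), r, np.zeros_like(r)])
        v = np.abs(fq.embedding_potential_at(state, pts))
        # log-log slope ≤ −2 for a neutral charge distribution
        slope = np.polyfit(np.log(r), np.log(v), 1)[0]
        assert slope < -1.9

    def test_probe_on_atom_rejected(self):
        state = fq.PolarizationState(
            q=np.array([1.0]), mu=np.zeros((1, 3)), lagrange=np.zeros(1),
            positions=np.array([[1.0, 1.0, 1.0]]),
        )
        with pytest.raises(ValueError, match="coincides"):
            fq.embedding_potential_at(state, [[1.0, 1.0, 1.0]])


class TestParamsIO:
    def test_parameter_file_round_trip(self, tmp_path):
        p = tmp_path / "params.tsv"
        p.write_text("# test params\nO 0.45 0.6 1.1\nH 0.1 0.7\n")
        params = fq.FQParams.from_file(p)
        assert params.chi("O") == 0.45
        assert params.alpha("O") == 1.1
        assert params.alpha("H") == 0.0

    @pytest.mark.parametrize("name", ["water_fq", "water_fqmu", "ethanol_fq"])
    def test_builtin_parameter_sets_load(self, name):
        params = fq.FQParams.builtin(name)
        assert params.eta("O") > 0

    def test_nonpositive_hardness_rejected(self):
        with pytest.raises(ValueError):
            fq.FQParams({"O": (0.4, 0.0)})
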