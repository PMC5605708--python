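"""Master-equation operators, stationary solve and propagation oracle."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from rpcidnp.chain import MotionModel
from rpcidnp.liouville import (
    RDModelParams,
    ReactionModel,
    RelaxationModel,
    SolvabilityError,
    _initial_density,
    _redfield_cell,
    assemble_liouvillian,
    geminate_cidnp,
    propagate_oracle,
    reaction_operator,
    redfield_operator,
)
from rpcidnp.spin_system import (
    GAMMA_E_RAD_PER_S_MT,
    ExchangeModel,
    NucleusSpec,
    RadicalPairSystem,
    RadicalSpec,
    build_pair_basis,
    hamiltonian,
)


def equal_g_pair(hfc=1.0, j0=0.0, alpha=0.0):
    nuc = (NucleusSpec("h", 0.5, hfc, 2),) if hfc is not None else ()
    return RadicalPairSystem(
        RadicalSpec("F", 2.002319),
        RadicalSpec("W", 2.002319, nuc),
        ExchangeModel(j0, alpha),
    )


class TestReactionOperator:
    def setup_method(self):
        self.system = equal_g_pair()
        self.basis = build_pair_basis(self.system)

    def test_pure_triplet_sees_only_the_loss_channel(self, small_grid):
        K = reaction_operator(ReactionModel(4.7e7, 1e4), self.basis, small_grid)
        pt = self.basis.projector_triplet / 3.0 / self.basis.nuclear_dim
        v = np.zeros(K.shape[0], complex)
        v[: self.basis.dim**2] = pt.reshape(-1)
        assert np.allclose(K @ v, -1e4 * v, rtol=1e-12)

    def test_pure_singlet_decays_at_recombination_plus_loss(self, small_grid):
        K = reaction_operator(ReactionModel(4.7e7, 1e4), self.basis, small_grid)
        ps = self.basis.projector_singlet / self.basis.nuclear_dim
        v = np.zeros(K.shape[0], complex)
        v[: self.basis.dim**2] = ps.reshape(-1)
        assert np.allclose(K @ v, -(4.7e7 + 1e4) * v, rtol=1e-12)

    def test_st_coherence_decays_at_half_recombination(self, small_grid):
        # Haberkorn anticommutator halves the rate on S/T off-diagonals
        K = reaction_operator(ReactionModel(4.7e7, 1e4), self.basis, small_grid)
        states = self.basis.electron_states()
        coh = np.outer(states["S"], states["T0"].conj())
        rho = np.kron(coh, np.eye(self.basis.nuclear_dim) / self.basis.nuclear_dim)
        v = np.zeros(K.shape[0], complex)
        v[: self.basis.dim**2] = rho.reshape(-1)
        assert np.allclose(K @ v, -(4.7e7 / 2 + 1e4) * v, rtol=1e-12)

    def test_both_rates_zero_is_a_solvability_error(self, small_grid):
        with pytest.raises(SolvabilityError):
            reaction_operator(ReactionModel(0.0, 0.0), self.basis, small_grid)


class TestRedfield:
    def test_no_stochastic_interaction_gives_zero_operator(self, small_grid):
        system = equal_g_pair()
        R = redfield_operator(
            RelaxationModel(0.0, 5e-11, include_dipolar=False),
            system,
            5.0,
            small_grid,
        )
        assert R.nnz == 0

    def test_single_spin_longitudinal_rate_matches_textbook_T1(self):
        # isotropic random field of rms b per component on one spin-1/2:
        # 1/T1 = 2 gamma^2 b^2 J(omega_0), independently coded here
        sx = np.array([[0, 0.5], [0.5, 0]], complex)
        sy = np.array([[0, -0.5j], [0.5j, 0]], complex)
        sz = np.array([[0.5, 0], [0, -0.5]], complex)
        b, tau, field_mT = 0.3, 5e-11, 50.0
        w0 = GAMMA_E_RAD_PER_S_MT * field_mT
        sig2 = (GAMMA_E_RAD_PER_S_MT * b) ** 2
        R = _redfield_cell(w0 * sz, [(sx, sig2), (sy, sig2), (sz, sig2)], tau)
        decay = (R @ sz.reshape(-1)).reshape(2, 2)
        rate = -np.trace(sz @ decay).real / np.trace(sz @ sz).real
        textbook = 2 * sig2 * tau / (1 + (w0 * tau) ** 2)
        assert rate == pytest.approx(textbook, rel=1e-8)

    def test_dipolar_rates_scale_as_inverse_sixth_power(self):
        from rpcidnp.chain import DistanceGrid

        # doubling r: amplitude d ~ r^-3, rates ~ d^2 -> factor 64
        grid = DistanceGrid(np.array([10.0, 20.0]), np.array([0.5, 0.5]))
        system = equal_g_pair(hfc=None, j0=0.0)
        R = redfield_operator(
            RelaxationModel(0.0, 5e-11, include_dipolar=True), system, 5.0, grid
        )
        ldim = build_pair_basis(system).dim ** 2
        R = R.toarray()
        near, far = R[:ldim, :ldim], R[ldim:, ldim:]
        assert np.allclose(near, 64.0 * far, rtol=1e-10)

    def test_trace_and_hermiticity_preserved(self, small_grid, toy_system):
        basis = build_pair_basis(toy_system)
        R = redfield_operator(RelaxationModel(0.3, 5e-11, True), toy_system, 2.0, small_grid)
        rng = np.random.default_rng(1)
        m = rng.normal(size=(basis.dim, basis.dim)) + 1j * rng.normal(size=(basis.dim, basis.dim))
        rho = m + m.conj().T
        v = np.zeros(R.shape[0], complex)
        v[: basis.dim**2] = rho.reshape(-1)
        out = (R @ v)[: basis.dim**2].reshape(basis.dim, basis.dim)
        assert abs(np.trace(out)) < 1e-9 * np.abs(out).max()
        assert np.allclose(out, out.conj().T, atol=1e-9 * np.abs(out).max())


class TestAssembly:
    def test_coherent_part_is_the_commutator_superoperator(self, small_grid):
        from rpcidnp.chain import DistanceGrid

        grid = DistanceGrid(np.array([10.0]), np.array([1.0]))
        system = equal_g_pair(hfc=0.8, j0=-5e3, alpha=0.8)
        basis = build_pair_basis(system)
        params = RDModelParams(
            system.exchange,
            MotionModel(2.5e-6, grid),
            ReactionModel(0.0, 1.0),  # negligible uniform loss to keep L solvable
            RelaxationModel(0.0, 5e-11, False),
        )
        L = assemble_liouvillian(params, system, 3.0, basis).toarray()
        H = GAMMA_E_RAD_PER_S_MT * hamiltonian(system, 3.0, 10.0, basis)
        eye = np.eye(basis.dim)
        expected = -1j * (np.kron(H, eye) - np.kron(eye, H.T)) - 1.0 * np.eye(basis.dim**2)
        assert np.allclose(L, expected, atol=1e-6 * np.abs(expected).max())

    def test_block_structure_reproduces_diffusion_on_scalars(self, small_grid):
        # H = 0 (equal g, no nuclei, J = 0, B = 0), no relaxation: the action
        # on (distance profile) x (fixed spin state) is W alone plus the loss
        system = equal_g_pair(hfc=None, j0=0.0)
        basis = build_pair_basis(system)
        params = RDModelParams(
            system.exchange,
            MotionModel(2.5e-6, small_grid),
            ReactionModel(0.0, 1e4),
            RelaxationModel(0.0, 5e-11, False),
        )
        from rpcidnp.chain import diffusion_operator

        L = assemble_liouvillian(params, system, 0.0, basis)
        W = diffusion_operator(MotionModel(2.5e-6, small_grid.regularized()), regularize=False)
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 1.0, small_grid.n_cells)
        rho = basis.projector_triplet.reshape(-1) / 3 / basis.nuclear_dim
        v = np.kron(p, rho)
        expected = np.kron(W @ p, rho) - 1e4 * v
        assert np.allclose(L @ v, expected, rtol=1e-10, atol=1e-12 * np.abs(expected).max())

    def test_dimension_mismatch_raises(self, small_params, toy_system):
        from rpcidnp.liouville import AssemblyError

        wrong_basis = build_pair_basis(equal_g_pair(hfc=None))
        with pytest.raises(AssemblyError):
            assemble_liouvillian(small_params, toy_system, 1.0, wrong_basis)


class TestGeminate:
    def test_zero_hyperfine_means_zero_polarization(self, small_params):
        system = equal_g_pair(hfc=0.0, j0=-1.6e9, alpha=2.14)
        for B in (0.05, 5.0, 100.0):
            res = geminate_cidnp(small_params, system, B)
            assert abs(res.polarizations["h"]) < 1e-12

    def test_yield_is_a_probability_and_solve_is_tight(self, small_params, toy_system):
        res = geminate_cidnp(small_params, toy_system, 5.0)
        assert 0.0 <= res.singlet_yield <= 1.0
        assert res.residual_norm < 1e-8

    def test_loss_rate_insensitivity_near_default(self, table_params, f10t):
        """Tenfold slower loss (toward the ms-scale ground-state recovery)
        shifts the 5 mT polarization by only a few percent (measured 4.0%)."""
        from rpcidnp.spin_system import subsystem

        sub = subsystem(f10t, ["H2", "betaCH2_a"])
        base = geminate_cidnp(table_params, sub, 5.0).polarizations["H2"]
        slow = dataclasses.replace(
            table_params, reaction=ReactionModel(table_params.reaction.k_rec_Hz, 1e3)
        )
        p_slow = geminate_cidnp(slow, sub, 5.0).polarizations["H2"]
        assert abs(p_slow - base) / abs(base) < 0.10

    def test_high_field_sorting_balance(self, table_params, toy_system):
        """At 7 T (pure S-T0 sorting) the nuclear polarization leaving through
        the recombination channel cancels the loss-channel counterpart."""
        basis = build_pair_basis(toy_system)
        grid = table_params.motion.grid.regularized()
        L = assemble_liouvillian(table_params, toy_system, 7000.0, basis)
        rho0 = _initial_density(toy_system, basis, grid)
        x = spla.splu(L, permc_spec="NATURAL").solve(-rho0)
        ldim = basis.dim**2
        inz = basis.I_ops["H_toy"][2]
        ps = basis.projector_singlet
        X0 = x[:ldim].reshape(basis.dim, basis.dim)
        p_prod = table_params.reaction.k_rec_Hz * 0.5 * np.trace(inz @ (ps @ X0 + X0 @ ps)).real
        p_loss = sum(
            table_params.reaction.k_loss_Hz
            * np.trace(inz @ x[c * ldim : (c + 1) * ldim].reshape(basis.dim, basis.dim)).real
            for c in range(grid.n_cells)
        )
        scale = max(abs(p_prod), abs(p_loss))
        assert scale > 0
        assert abs(p_prod + p_loss) < 1e-2 * scale


class TestOracle:
    def test_trace_conserved_without_open_channels(self):
        # closed system (no reaction, no relaxation): coherent evolution and
        # hyperfine mixing conserve the trace exactly
        from rpcidnp.chain import DistanceGrid

        grid = DistanceGrid(np.array([10.0]), np.array([1.0]))
        system = equal_g_pair(hfc=0.8, j0=-5.0, alpha=0.0)
        params = RDModelParams(
            system.exchange,
            MotionModel(2.5e-6, grid),
            ReactionModel(0.0, 0.0),
            RelaxationModel(0.0, 5e-11, False),
        )
        # span many hyperfine/exchange periods (~1e9 rad/s coherences)
        traj = propagate_oracle(params, system, 1.0, t_max=1e-5)
        assert np.all(np.abs(traj.trace - 1.0) < 1e-9)

    def test_uniform_loss_decays_the_trace_exponentially(self, small_grid):
        system = equal_g_pair(hfc=None, j0=0.0)
        params = RDModelParams(
            system.exchange,
            MotionModel(2.5e-6, small_grid),
            ReactionModel(0.0, 1e4),
            RelaxationModel(0.0, 5e-11, False),
        )
        traj = propagate_oracle(params, system, 1.0, t_max=2e-4)
        assert np.allclose(traj.trace, np.exp(-1e4 * traj.t), rtol=1e-6)

    def test_density_stays_hermitian_and_trace_monotone(self, small_params, toy_system):
        traj = propagate_oracle(small_params, toy_system, 3.0)
        for i in (0, len(traj.t) // 2, len(traj.t) - 1):
            for c in (0, traj.n_cells - 1):
                rho = traj.rho_cell(i, c)
                assert np.max(np.abs(rho - rho.conj().T)) < 1e-9
        assert np.all(np.diff(traj.trace) <= 1e-12)

    def test_oracle_matches_stationary_solve(self, small_params, toy_system):
        stat = geminate_cidnp(small_params, toy_system, 2.0)
        orc = propagate_oracle(small_params, toy_system, 2.0)
        p_s, p_o = stat.polarizations["H_toy"], orc.polarizations["H_toy"]
        assert p_s == pytest.approx(p_o, rel=1e-4)
        assert stat.singlet_yield == pytest.approx(orc.singlet_yield, rel=1e-4)
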