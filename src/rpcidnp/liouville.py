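"""Distance-resolved Liouville-space master equation for the radical pair.

The density operator rho(r, t) lives on (distance grid cell) x (spin
Liouville space) and evolves under

    d rho / dt = -i H^x rho + W rho + K rho + R rho

where H^x is the commutator superoperator of the distance-local spin
Hamiltonian, W the restricted-diffusion generator hopping population
between neighbouring distance cells, K the chemical reaction term and R
electron spin relaxation.

Reaction term (Haberkorn form): spin-selective singlet recombination at
the contact cell, -(k_rec/2) {P_S, rho}, plus a uniform loss channel
-k_loss rho in every cell that stands in for the slow deprotonation /
escape pathway.

Relaxation: a Bloch-Redfield kernel with Lorentzian spectral density
J(w) = tau_c / (1 + w^2 tau_c^2), built in the lab frame as a
frequency-weighted double commutator.  Two stochastic interactions are
included: (i) isotropic, uncorrelated fluctuating local fields of rms
amplitude b_loc at each electron, and (ii) the electron-electron dipolar
coupling d(r) = d0 / r^3, modulated by molecular tumbling, evaluated per
grid cell.  The kernel preserves Hermiticity and trace exactly and
reduces to the familiar secular rates away from level degeneracies while
remaining well behaved at the S/T- anticrossing itself.

The geminate observables are the time-integrated singlet flux at contact:
per-nucleus product polarization P_n = k_rec Tr[I_nz P_S X P_S] (negative
= emissive) and the singlet recombination yield Phi_S = k_rec Tr[P_S X],
with X = integral of rho(t) dt obtained from the stationary linear solve
L X = -rho(0).  An exact exponential time propagator is shipped alongside
as an independent cross-check of the stationary solve.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .chain import DistanceGrid, MotionModel, diffusion_operator
from .spin_system import (
    DIPOLAR_D0_MT_A3,
    GAMMA_E_RAD_PER_S_MT,
    ExchangeModel,
    RadicalPairSystem,
    SpinBasis,
    build_pair_basis,
    hamiltonian,
)

__all__ = [
    "ReactionModel",
    "RelaxationModel",
    "RDModelParams",
    "PolarizationResult",
    "SolvabilityError",
    "AssemblyError",
    "reaction_operator",
    "redfield_operator",
    "assemble_liouvillian",
    "geminate_cidnp",
    "propagate_oracle",
    "OracleTrajectory",
]


class SolvabilityError(ValueError):
    """The master equation has no decaying stationary solution."""


class AssemblyError(ValueError):
    """Inconsistent operator dimensions during Liouvillian assembly."""


@dataclass(frozen=True)
class ReactionModel:
    """Chemical reaction rates: singlet recombination at contact plus a
    uniform loss channel."""

    k_rec_Hz: float = 4.7e7
    k_loss_Hz: float = 1.0e4

    def __post_init__(self) -> None:
        if self.k_rec_Hz < 0 or self.k_loss_Hz < 0:
            raise ValueError("reaction rates must be non-negative")
        # note: k_rec + k_loss > 0 (solvability of the stationary problem) is
        # enforced where it matters - reaction_operator and geminate_cidnp -
        # so that a closed system can still be time-propagated


@dataclass(frozen=True)
class RelaxationModel:
    """Stochastic interactions driving electron spin relaxation.

    ``b_loc_mT`` is the rms amplitude per Cartesian component of the
    fluctuating local field at each electron; ``tau_c_s`` the correlation
    time shared by both mechanisms; ``include_dipolar`` switches the
    r-dependent electron-electron dipolar source on or off.
    """

    b_loc_mT: float = 0.3
    tau_c_s: float = 5.0e-11
    include_dipolar: bool = True

    def __post_init__(self) -> None:
        if self.b_loc_mT < 0:
            raise ValueError("b_loc_mT must be >= 0")
        if self.tau_c_s <= 0:
            raise ValueError("tau_c_s must be > 0")


@dataclass(frozen=True)
class RDModelParams:
    """Full parameter set of the restricted-diffusion model."""

    exchange: ExchangeModel
    motion: MotionModel
    reaction: ReactionModel
    relaxation: RelaxationModel


@dataclass(frozen=True)
class PolarizationResult:
    """Geminate observables at one polarizing field."""

    B_mT: float
    polarizations: dict[str, float]
    singlet_yield: float
    residual_norm: float


# ---------------------------------------------------------------------------
# superoperator helpers (row-major vectorization: vec(A rho B) = (A kron B^T) vec(rho))


def _kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = a.shape[0], b.shape[0]
    return (a[:, None, :, None] * b[None, :, None, :]).reshape(n * m, n * m)


def _spre(A: np.ndarray) -> np.ndarray:
    return _kron(A, np.eye(A.shape[0]))


def _spost(A: np.ndarray) -> np.ndarray:
    return _kron(np.eye(A.shape[0]), A.T)


def _commutator_superop(H: np.ndarray) -> np.ndarray:
    return _spre(H) - _spost(H)


# ---------------------------------------------------------------------------
# reaction


def reaction_operator(
    reaction: ReactionModel, basis: SpinBasis, grid: DistanceGrid
) -> sp.csr_matrix:
    """Reaction superoperator K over (grid cell) x (Liouville space).

    Haberkorn recombination -(k_rec/2){P_S, .} acts in the contact (first)
    cell only; the loss channel -k_loss acts uniformly everywhere.
    """
    if reaction.k_rec_Hz + reaction.k_loss_Hz <= 0:
        raise SolvabilityError("k_rec and k_loss cannot both be zero")
    ldim = basis.dim**2
    n_cells = grid.n_cells
    ps = basis.projector_singlet
    k_contact = -0.5 * reaction.k_rec_Hz * (_spre(ps) + _spost(ps))
    blocks = [sp.csr_matrix(k_contact)] + [
        sp.csr_matrix((ldim, ldim), dtype=complex) for _ in range(n_cells - 1)
    ]
    K = sp.block_diag(blocks, format="csr")
    K = K - reaction.k_loss_Hz * sp.identity(n_cells * ldim, format="csr")
    return K.tocsr()


# ---------------------------------------------------------------------------
# relaxation


def _dipolar_components(basis: SpinBasis) -> list[np.ndarray]:
    """Five Hermitian rank-2 components of the electron-electron dipolar
    interaction, Frobenius-orthonormal on the electron pair space."""
    cached = getattr(basis, "_dipolar_components_cache", None)
    if cached is not None:
        return cached
    s1x, s1y, s1z = basis.S1
    s2x, s2y, s2z = basis.S2
    s1p, s1m = s1x + 1j * s1y, s1x - 1j * s1y
    s2p, s2m = s2x + 1j * s2y, s2x - 1j * s2y
    t20 = (4 * s1z @ s2z - s1p @ s2m - s1m @ s2p) / math.sqrt(6)
    t21 = s1z @ s2p + s1p @ s2z
    t22 = s1p @ s2p
    ops = [t20]
    for t in (t21, t22):
        ops.append((t + t.conj().T) / math.sqrt(2))
        ops.append(1j * (t - t.conj().T) / math.sqrt(2))
    basis._dipolar_components_cache = ops
    return ops


def _redfield_cell(
    H_rad: np.ndarray,
    hermitian_ops: list[tuple[np.ndarray, float]],
    tau_c: float,
) -> np.ndarray:
    """Bloch-Redfield superoperator for one distance cell.

    For each Hermitian fluctuating operator A with variance sigma^2
    (rad^2/s^2) and exponential correlation, the contribution is the
    frequency-weighted double commutator

        R rho = -sigma^2 [A, [A~, rho]],
        A~_{ab} = A_{ab} * J(w_a - w_b),  J(w) = tau_c / (1 + w^2 tau_c^2)

    evaluated in the eigenbasis of the cell Hamiltonian.  Trace and
    Hermiticity are preserved exactly (J is even, so A~ is Hermitian).
    """
    w, V = np.linalg.eigh(H_rad)
    dw = w[:, None] - w[None, :]
    jfac = tau_c / (1.0 + (dw * tau_c) ** 2)
    dim = H_rad.shape[0]
    eye = np.eye(dim)
    m_left = np.zeros((dim, dim), dtype=complex)
    m_right = np.zeros((dim, dim), dtype=complex)
    cross = np.zeros((dim * dim, dim * dim), dtype=complex)
    for A, var in hermitian_ops:
        if var == 0.0:
            continue
        Atil = V @ ((V.conj().T @ A @ V) * jfac) @ V.conj().T
        m_left += var * (A @ Atil)
        m_right += var * (Atil @ A)
        cross += var * (_kron(Atil, A.T) + _kron(A, Atil.T))
    return -(_kron(m_left, eye) + _kron(eye, m_right.T) - cross)


def _relaxation_ops(
    relaxation: RelaxationModel, basis: SpinBasis, r_A: float
) -> list[tuple[np.ndarray, float]]:
    ops: list[tuple[np.ndarray, float]] = []
    sigma_loc2 = (GAMMA_E_RAD_PER_S_MT * relaxation.b_loc_mT) ** 2
    if sigma_loc2 > 0:
        for comp in range(3):
            ops.append((basis.S1[comp], sigma_loc2))
            ops.append((basis.S2[comp], sigma_loc2))
    if relaxation.include_dipolar:
        d_mT = DIPOLAR_D0_MT_A3 / r_A**3
        # isotropic tumbling distributes the rank-2 interaction evenly over
        # its five components; 6/25 per orthonormal component reproduces a
        # total mean-square coupling of (6/5) (gamma_e d)^2
        sigma_dip2 = (6.0 / 25.0) * (GAMMA_E_RAD_PER_S_MT * d_mT) ** 2
        for A in _dipolar_components(basis):
            ops.append((A, sigma_dip2))
    return ops


def redfield_operator(
    relaxation: RelaxationModel,
    system: RadicalPairSystem,
    B_mT: float,
    grid: DistanceGrid,
    basis: SpinBasis | None = None,
) -> sp.csr_matrix:
    """Relaxation superoperator R over (grid cell) x (Liouville space)."""
    if basis is None:
        basis = build_pair_basis(system)
    blocks = []
    for r in grid.interaction_radii:
        ops = _relaxation_ops(relaxation, basis, float(r))
        if not ops:
            blocks.append(sp.csr_matrix((basis.dim**2, basis.dim**2), dtype=complex))
            continue
        H_rad = GAMMA_E_RAD_PER_S_MT * hamiltonian(system, B_mT, float(r), basis)
        blocks.append(sp.csr_matrix(_redfield_cell(H_rad, ops, relaxation.tau_c_s)))
    return sp.block_diag(blocks, format="csr")


# ---------------------------------------------------------------------------
# assembly and solution


def assemble_liouvillian(
    params: RDModelParams,
    system: RadicalPairSystem,
    B_mT: float,
    basis: SpinBasis | None = None,
) -> sp.csc_matrix:
    """Sparse block operator L = -i H^x + W + K + R on (cells) x (Liouville).

    The Hamiltonian part is distance-local (one commutator superoperator
    per cell, with the exchange coupling evaluated at the cell centre);
    W couples neighbouring cells identically on every Liouville component.
    """
    if basis is None:
        basis = build_pair_basis(system)
    if basis.dim != system.hilbert_dimension:
        raise AssemblyError(
            f"basis dimension {basis.dim} does not match system "
            f"dimension {system.hilbert_dimension}"
        )
    # the parameter set owns the exchange model (it is a fitted quantity);
    # override whatever the spin-system fixture carries
    system = dataclasses.replace(system, exchange=params.exchange)
    grid = params.motion.grid.regularized()
    ldim = basis.dim**2
    n_cells = grid.n_cells

    motion = MotionModel(params.motion.D_eff_cm2s, grid)
    W = diffusion_operator(motion, regularize=False)

    ps = basis.projector_singlet
    k_contact = -0.5 * params.reaction.k_rec_Hz * (_spre(ps) + _spost(ps))
    k_loss = params.reaction.k_loss_Hz
    eye_l = np.eye(ldim)

    # per-cell diagonal blocks: coherent + relaxation (+ reaction at contact)
    tau_c = params.relaxation.tau_c_s
    radii = grid.interaction_radii
    blocks = []
    for c in range(n_cells):
        H_rad = GAMMA_E_RAD_PER_S_MT * hamiltonian(system, B_mT, float(radii[c]), basis)
        cell = -1j * _commutator_superop(H_rad)
        ops = _relaxation_ops(params.relaxation, basis, float(radii[c]))
        if ops:
            cell = cell + _redfield_cell(H_rad, ops, tau_c)
        cell = cell - k_loss * eye_l
        if c == 0:
            cell = cell + k_contact
        blocks.append(sp.csr_matrix(cell))
    L = sp.block_diag(blocks, format="csr")
    # nearest-neighbour diffusion coupling, identical on every Liouville component
    L = L + sp.kron(sp.csr_matrix(W), sp.identity(ldim, format="csr"), format="csr")
    return L.tocsc()


def _initial_density(
    system: RadicalPairSystem, basis: SpinBasis, grid: DistanceGrid
) -> np.ndarray:
    """rho(0): equilibrium spatial distribution, electron triplet (equal
    incoherent mixture of T+, T0, T-) or singlet, nuclei at infinite
    temperature.  Total trace 1."""
    if system.initial_state == "triplet":
        rho_e = basis.projector_triplet / (3.0 * basis.nuclear_dim)
    else:
        rho_e = basis.projector_singlet / basis.nuclear_dim
    return np.concatenate([f * rho_e.reshape(-1) for f in grid.f_eq])


def geminate_cidnp(
    params: RDModelParams,
    system: RadicalPairSystem,
    B_mT: float,
    basis: SpinBasis | None = None,
) -> PolarizationResult:
    """Per-nucleus geminate product polarization and singlet yield.

    Solves the stationary linear system L x = -rho(0) for the
    time-integrated density, then reads off the contact-cell singlet flux.
    Sign convention: negative polarization = emissive NMR line.
    """
    if basis is None:
        basis = build_pair_basis(system)
    if params.reaction.k_rec_Hz + params.reaction.k_loss_Hz <= 0:
        raise SolvabilityError(
            "k_rec and k_loss cannot both be zero: the time-integrated density "
            "diverges (no decay channel); set a loss rate or a recombination rate"
        )
    grid = params.motion.grid.regularized()
    L = assemble_liouvillian(params, system, B_mT, basis)
    rho0 = _initial_density(system, basis, grid)

    # the natural ordering preserves the narrow block-tridiagonal band and
    # factors markedly faster here than fill-reducing permutations
    lu = spla.splu(L, permc_spec="NATURAL")
    x = lu.solve(-rho0)
    residual = float(np.linalg.norm(L @ x + rho0) / np.linalg.norm(rho0))

    ldim = basis.dim**2
    X0 = x[:ldim].reshape(basis.dim, basis.dim)
    ps = basis.projector_singlet
    ps_x_ps = ps @ X0 @ ps
    k_rec = params.reaction.k_rec_Hz
    pols = {
        nuc.label: float(k_rec * np.trace(basis.I_ops[nuc.label][2] @ ps_x_ps).real)
        for nuc in basis.nuclei
    }
    singlet_yield = float(k_rec * np.trace(ps @ X0).real)
    return PolarizationResult(B_mT, pols, singlet_yield, residual)


# ---------------------------------------------------------------------------
# explicit time-integration oracle


@dataclass(frozen=True)
class OracleTrajectory:
    """Explicitly propagated rho(t) with accumulated geminate observables.

    ``t`` is a dyadic time ladder t_k = dt0 * 2^k; ``states`` holds the
    vectorized distance-resolved density at those times.
    """

    t: np.ndarray
    states: np.ndarray  # (n_times, n_cells * dim^2), vectorized rho per cell
    trace: np.ndarray
    polarizations: dict[str, float]
    singlet_yield: float
    dim: int
    n_cells: int

    def rho_cell(self, time_index: int, cell: int) -> np.ndarray:
        ldim = self.dim**2
        seg = self.states[time_index, cell * ldim : (cell + 1) * ldim]
        return seg.reshape(self.dim, self.dim)


def propagate_oracle(
    params: RDModelParams,
    system: RadicalPairSystem,
    B_mT: float,
    t_max: float | None = None,
    dt0: float | None = None,
) -> OracleTrajectory:
    """Exact exponential time propagation of the master equation.

    Independent cross-check of :func:`geminate_cidnp`.  The coherent part
    of L oscillates at up to ~1e9 rad/s while the chemistry decays over
    milliseconds, so step-by-step integration is hopeless; instead the
    propagator and its running integral are built exactly by dyadic
    doubling of the matrix-exponential pair

        Phi(2 dt) = Phi(dt)^2,
        Psi(2 dt) = (1 + Phi(dt)) Psi(dt),    Psi(t) = int_0^t e^(L s) ds

    starting from a Taylor evaluation at a step dt0 << 1/||L||.  The
    per-nucleus polarizations and singlet yield are then read off the
    time-integrated density Psi(t_max) rho(0).  Dense linear algebra
    throughout - deliberately disjoint from the sparse-LU stationary
    path.  Small systems only (a couple of nuclei, ~10 distance cells).
    """
    basis = build_pair_basis(system)
    grid = params.motion.grid.regularized()
    n_state = basis.dim**2 * grid.n_cells
    if n_state > 1300:
        raise ValueError(
            f"oracle propagation is for small systems only (state size {n_state})"
        )
    L = assemble_liouvillian(params, system, B_mT, basis).toarray()
    rho0 = _initial_density(system, basis, grid).astype(complex)

    if t_max is None:
        k_loss = params.reaction.k_loss_Hz
        if k_loss <= 0:
            raise ValueError("provide t_max explicitly when k_loss = 0")
        t_max = 30.0 / k_loss

    scale = np.linalg.norm(L, np.inf)
    if not np.isfinite(scale):
        raise ValueError("non-finite Liouvillian")
    if dt0 is None:
        dt0 = min(0.01 / max(scale, 1.0), t_max)
    n_doublings = max(0, math.ceil(math.log2(t_max / dt0)))
    dt0 = t_max / 2.0**n_doublings  # land exactly on t_max

    # Taylor series for Phi(dt0) and Psi(dt0); ||L dt0|| <= 0.01 so a few
    # terms reach machine precision
    eye = np.eye(n_state, dtype=complex)
    phi = eye.copy()
    psi = dt0 * eye.copy()
    # seed truncation error is amplified by ~2^n_doublings, so push the
    # series to well below machine precision
    term = eye.copy()
    for k in range(1, 35):
        term = (term @ L) * (dt0 / k)
        phi += term
        psi += term * (dt0 / (k + 1))
        if np.linalg.norm(term, np.inf) < 1e-25:
            break

    times = [dt0]
    states = [phi @ rho0]
    for _ in range(n_doublings):
        psi = psi + phi @ psi
        phi = phi @ phi
        times.append(2.0 * times[-1])
        states.append(phi @ rho0)

    x = psi @ rho0  # time-integrated density over [0, t_max]
    ldim = basis.dim**2
    X0 = x[:ldim].reshape(basis.dim, basis.dim)
    ps = basis.projector_singlet
    ps_x_ps = ps @ X0 @ ps
    k_rec = params.reaction.k_rec_Hz
    pols = {
        nuc.label: float(k_rec * np.trace(basis.I_ops[nuc.label][2] @ ps_x_ps).real)
        for nuc in basis.nuclei
    }
    singlet_yield = float(k_rec * np.trace(ps @ X0).real)

    states_arr = np.array(states)
    traces = np.array(
        [
            sum(
                states_arr[i, c * ldim : (c + 1) * ldim]
                .reshape(basis.dim, basis.dim)
                .trace()
                .real
                for c in range(grid.n_cells)
            )
            for i in range(states_arr.shape[0])
        ]
    )
    return OracleTrajectory(
        t=np.array(times),
        states=states_arr,
        trace=traces,
        polarizations=pols,
        singlet_yield=singlet_yield,
        dim=basis.dim,
        n_cells=grid.n_cells,
    )
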