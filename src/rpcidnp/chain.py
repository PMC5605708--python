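"""Linker conformational sampling and the diffusion operator W.

The two radicals are tethered by an aliphatic chain.  Its end-to-end
distance r is sampled with a rotational-isomeric-state (RIS) Monte Carlo:
fixed bond lengths and bond angles, discrete trans/gauche+/gauche-
dihedrals with a Boltzmann weight for the gauche states.  The resulting
equilibrium distribution f_eq(r), histogrammed onto a distance grid,
defines the restricted-diffusion motion model: a one-dimensional
Smoluchowski generator W with nearest-neighbour hopping rates

    k(i -> j) = (D' / dr^2) * sqrt(f_j / f_i),   j = i +/- 1

which satisfies detailed balance (W f_eq = 0) by construction and
conserves probability exactly (columns sum to zero).  The first grid cell
is the reaction ("contact") cell; the outer boundary is reflecting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainModel",
    "DistanceGrid",
    "MotionModel",
    "ChainError",
    "sample_end_to_end",
    "distance_distribution",
    "diffusion_operator",
    "GAS_CONSTANT_KJ_PER_MOL_K",
]

GAS_CONSTANT_KJ_PER_MOL_K = 8.31446e-3

#: floor applied to empty distribution cells before renormalization, so the
#: hopping rates (which involve 1/f) are defined everywhere on the grid
F_EQ_FLOOR = 1e-6


class ChainError(ValueError):
    """Invalid chain model or distance-grid construction."""


@dataclass(frozen=True)
class ChainModel:
    """Rotational-isomeric-state chain.

    ``bond_angle_deg`` is the tetrahedral-like valence angle at each chain
    atom (112 deg for an aliphatic chain); setting it to ``None`` switches
    to a freely-jointed chain (isotropic bond directions), useful as an
    analytic limit.  ``gauche_energy_kJmol`` is the energy of each gauche
    rotamer relative to trans.  ``exclude_pentane`` suppresses g+/g-
    neighbouring dihedral pairs (the "pentane effect").
    ``dihedral_sigma_deg`` is the rms thermal libration of each dihedral
    about its rotamer minimum; it smooths the otherwise discrete RIS
    distance spectrum into the continuous distribution a diffusion model
    needs (set to 0 for the idealized three-state chain).
    """

    n_bonds: int
    bond_length_A: float = 1.54
    bond_angle_deg: float | None = 112.0
    gauche_energy_kJmol: float = 2.1
    temperature_K: float = 293.0
    n_samples: int = 100_000
    seed: int = 7
    exclude_pentane: bool = False
    dihedral_sigma_deg: float = 12.0

    def __post_init__(self) -> None:
        if self.n_bonds < 1:
            raise ChainError(f"n_bonds must be >= 1, got {self.n_bonds}")
        if self.n_samples < 1_000:
            raise ChainError(f"n_samples must be >= 1000, got {self.n_samples}")
        if self.bond_length_A <= 0:
            raise ChainError("bond_length_A must be positive")
        if self.temperature_K <= 0:
            raise ChainError("temperature_K must be positive")

    @property
    def rotamer_probabilities(self) -> tuple[float, float, float]:
        """(p_trans, p_gauche+, p_gauche-), Boltzmann-weighted; sums to 1."""
        w = math.exp(
            -self.gauche_energy_kJmol
            / (GAS_CONSTANT_KJ_PER_MOL_K * self.temperature_K)
        )
        z = 1.0 + 2.0 * w
        return (1.0 / z, w / z, w / z)


@dataclass(frozen=True)
class DistanceGrid:
    """Discretized end-to-end distance axis with equilibrium occupancies.

    ``r_values`` are cell centres (A), strictly increasing and uniformly
    spaced; ``f_eq`` are the cell probabilities (sum to 1).

    ``contact_wall_A`` optionally marks the closest-approach wall: chain
    conformers whose end-to-end distance falls below it are folded into
    the first cell and physically sit *at* the wall, so distance-dependent
    interactions (exchange, dipolar) for the contact cell are evaluated at
    the wall rather than at the cell midpoint.  The transport grid (cell
    centres, spacing) is unaffected.
    """

    r_values: np.ndarray
    f_eq: np.ndarray
    contact_wall_A: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=float)
        f = np.asarray(self.f_eq, dtype=float)
        object.__setattr__(self, "r_values", r)
        object.__setattr__(self, "f_eq", f)
        if r.ndim != 1 or len(r) < 1 or np.any(np.diff(r) <= 0):
            raise ChainError("r_values must be strictly increasing")
        if f.shape != r.shape:
            raise ChainError("f_eq and r_values must have the same length")
        if np.any(f < 0):
            raise ChainError("f_eq must be non-negative")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ChainError(f"f_eq must sum to 1 within 1e-12, got {f.sum()!r}")
        if self.contact_wall_A is not None and self.contact_wall_A > r[0]:
            raise ChainError("contact_wall_A must not exceed the first cell centre")

    @property
    def n_cells(self) -> int:
        return len(self.r_values)

    @property
    def dr(self) -> float:
        return float(self.r_values[1] - self.r_values[0]) if self.n_cells > 1 else 0.0

    @property
    def interaction_radii(self) -> np.ndarray:
        """Radii at which r-dependent spin interactions are evaluated."""
        r = self.r_values.copy()
        if self.contact_wall_A is not None:
            r[0] = self.contact_wall_A
        return r

    def regularized(self, floor: float = F_EQ_FLOOR) -> "DistanceGrid":
        """Copy with f_eq floored at ``floor`` and renormalized."""
        f = np.maximum(self.f_eq, floor)
        return DistanceGrid(self.r_values, f / f.sum(), self.contact_wall_A)


@dataclass(frozen=True)
class MotionModel:
    """Effective one-dimensional diffusion of the inter-radical distance."""

    D_eff_cm2s: float
    grid: DistanceGrid

    def __post_init__(self) -> None:
        if self.D_eff_cm2s <= 0:
            raise ChainError(f"D_eff_cm2s must be positive, got {self.D_eff_cm2s}")


# ---------------------------------------------------------------------------
# Monte-Carlo sampling


def sample_end_to_end(chain: ChainModel) -> np.ndarray:
    """Sample end-to-end distances (A) of the RIS chain.

    Vectorized over samples; bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(chain.seed)
    n, l, ns = chain.n_bonds, chain.bond_length_A, chain.n_samples

    if n == 1:
        return np.full(ns, l)

    if chain.bond_angle_deg is None:
        # freely-jointed chain: isotropic independent bond directions
        u = rng.normal(size=(n, ns, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        return l * np.linalg.norm(u.sum(axis=0), axis=1)

    theta = math.radians(chain.bond_angle_deg)
    # angle between successive bond *vectors* is pi - theta
    c, s = -math.cos(theta), math.sin(theta)

    u_pprev = np.tile(np.array([0.0, 0.0, 1.0]), (ns, 1))
    u_prev = np.tile(np.array([s, 0.0, c]), (ns, 1))
    acc = u_pprev + u_prev

    p_t, p_g, _ = chain.rotamer_probabilities
    # dihedral convention: trans = 180 deg, gauche = +/-60 deg
    phis = np.array([math.pi, math.pi / 3.0, -math.pi / 3.0])

    prev_state = np.zeros(ns, dtype=np.int64)  # 0=t, 1=g+, 2=g-
    for _ in range(n - 2):
        if chain.exclude_pentane:
            # forbid g+ after g- and vice versa; renormalize row-wise
            probs = np.tile([p_t, p_g, p_g], (ns, 1))
            probs[prev_state == 1, 2] = 0.0
            probs[prev_state == 2, 1] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            cum = np.cumsum(probs, axis=1)
            draw = rng.random(ns)[:, None]
            states = (draw > cum[:, :2]).sum(axis=1)
        else:
            states = rng.choice(3, size=ns, p=[p_t, p_g, p_g])
        phi = phis[states]
        if chain.dihedral_sigma_deg > 0:
            phi = phi + rng.normal(
                0.0, math.radians(chain.dihedral_sigma_deg), size=ns
            )
        prev_state = states

        normal = np.cross(u_pprev, u_prev)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        binormal = np.cross(normal, u_prev)
        u_new = (
            c * u_prev
            + s * (np.cos(phi)[:, None] * binormal + np.sin(phi)[:, None] * normal)
        )
        acc += u_new
        u_pprev, u_prev = u_prev, u_new

    return l * np.linalg.norm(acc, axis=1)


def all_trans_length(n_bonds: int, bond_length_A: float, bond_angle_deg: float) -> float:
    """Closed-form end-to-end length of the planar all-trans zigzag."""
    half = math.radians(bond_angle_deg) / 2.0
    along = n_bonds * bond_length_A * math.sin(half)
    across = (n_bonds % 2) * bond_length_A * math.cos(half)
    return math.hypot(along, across)


# ---------------------------------------------------------------------------
# distance grid and diffusion operator


def distance_distribution(
    samples: np.ndarray,
    r_contact_A: float = 9.14,
    r_max_A: float = 20.0,
    n_cells: int = 40,
) -> DistanceGrid:
    """Histogram end-to-end samples onto [r_contact, r_max].

    Samples below the contact distance are folded into the contact cell
    (the chain cannot bring the radicals closer than van der Waals
    contact); samples beyond ``r_max_A`` are discarded.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1_000:
        raise ChainError(f"need >= 1000 samples, got {samples.size}")
    if not (r_contact_A < r_max_A) or n_cells < 1:
        raise ChainError("invalid grid specification")

    clipped = np.maximum(samples, r_contact_A)
    kept = clipped[clipped <= r_max_A]
    if kept.size == 0:
        raise ChainError(
            f"all {samples.size} samples fall outside [{r_contact_A}, {r_max_A}] A"
        )
    counts, edges = np.histogram(kept, bins=n_cells, range=(r_contact_A, r_max_A))
    centres = 0.5 * (edges[:-1] + edges[1:])
    f = counts / counts.sum()
    return DistanceGrid(centres, f, contact_wall_A=r_contact_A)


def diffusion_operator(motion: MotionModel, regularize: bool = True) -> np.ndarray:
    """Finite-difference Smoluchowski generator on the distance grid.

    Returns the (n_cells x n_cells) rate matrix W acting on probability
    column vectors, dp/dt = W p.  Detailed balance gives W f_eq = 0 to
    machine precision and the diagonal is built as minus the column sums,
    so probability conservation (1^T W = 0) holds exactly in structure.
    Boundaries are reflecting.  Rates scale as D'/dr^2 with the diffusion
    coefficient converted from cm^2/s to A^2/s.
    """
    grid = motion.grid.regularized() if regularize else motion.grid
    f = grid.f_eq
    if np.any(f <= 0):
        raise ChainError("f_eq must be strictly positive; regularize the grid first")
    n = grid.n_cells
    W = np.zeros((n, n))
    if n == 1:
        return W
    d_A2s = motion.D_eff_cm2s * 1e16  # cm^2/s -> A^2/s
    k0 = d_A2s / grid.dr**2
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                W[j, i] = k0 * math.sqrt(f[j] / f[i])
    np.fill_diagonal(W, 0.0)
    # probability conservation by construction: the diagonal is exactly the
    # negated (compensated) sum of the off-diagonal column entries
    for j in range(n):
        W[j, j] = -math.fsum(W[:, j])
    return W
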