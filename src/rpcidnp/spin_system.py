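"""Spin-system description and Hamiltonian for a linked radical pair.

A spin-correlated radical pair (SCRP) is described by two electron spins
(one per radical, each with its own g-factor) coupled to a set of magnetic
nuclei through isotropic hyperfine interactions, and to each other through
a distance-dependent exchange interaction

    J_ex(r) = J_0 * exp(-alpha * r)

All spin interactions are parameterized in field units (mT) and converted
to angular frequency with the electron gyromagnetic ratio where dynamics
are needed.  With the exchange term written as ``-J_ex(r) * S1.S2`` the
singlet-triplet splitting at fixed distance is exactly ``|J_ex|`` in mT,
so for negative J the S/T- levels cross at a field B = |J_ex| - the level
anticrossing (LAC) at the heart of the low-field mechanism.  (Conventions
with 2J instead of J exist in the literature; this package uses the form
above throughout.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_E_RAD_PER_S_MT",
    "G_ELECTRON",
    "GAMMA_P_OVER_GAMMA_E",
    "DIPOLAR_D0_MT_A3",
    "NucleusSpec",
    "RadicalSpec",
    "ExchangeModel",
    "RadicalPairSystem",
    "SpinBasis",
    "ConfigError",
    "SizingError",
    "build_pair_basis",
    "exchange_coupling",
    "hamiltonian",
    "subsystem",
]

#: electron gyromagnetic ratio, rad s^-1 mT^-1
GAMMA_E_RAD_PER_S_MT = 1.76086e8
#: free-electron g value
G_ELECTRON = 2.002319
#: proton-to-electron gyromagnetic ratio (gamma_p / gamma_e)
GAMMA_P_OVER_GAMMA_E = 1.0 / 658.2107
#: electron-electron dipolar constant (mu0/4pi) g mu_B in mT * Angstrom^3,
#: i.e. d(r) = DIPOLAR_D0_MT_A3 / r^3 is the dipolar coupling in mT
DIPOLAR_D0_MT_A3 = 1.857e3

_ALLOWED_SPINS = (0.5, 1.0, 1.5)


class ConfigError(ValueError):
    """Invalid spin-system configuration."""


class SizingError(ValueError):
    """Hilbert-space dimension exceeds the configured cap."""


@dataclass(frozen=True)
class NucleusSpec:
    """One magnetic nucleus with an isotropic hyperfine coupling.

    ``hfc_mT`` is signed; ``radical_index`` (1 or 2) says which electron
    it is coupled to.  ``shift_ppm`` is carried for reporting only.
    """

    label: str
    spin: float
    hfc_mT: float
    radical_index: int
    shift_ppm: float | None = None
    source: str | None = None  # provenance annotation for fixture values

    def __post_init__(self) -> None:
        if self.spin not in _ALLOWED_SPINS:
            raise ConfigError(
                f"nucleus {self.label!r}: spin must be one of {_ALLOWED_SPINS}, "
                f"got {self.spin}"
            )
        if not math.isfinite(self.hfc_mT):
            raise ConfigError(f"nucleus {self.label!r}: hfc_mT must be finite")
        if self.radical_index not in (1, 2):
            raise ConfigError(
                f"nucleus {self.label!r}: radical_index must be 1 or 2, "
                f"got {self.radical_index}"
            )

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class RadicalSpec:
    """One radical: electron g-factor plus its hyperfine-coupled nuclei."""

    label: str
    g_factor: float
    nuclei: tuple[NucleusSpec, ...] = ()

    def __post_init__(self) -> None:
        if not (1.9 < self.g_factor < 2.1):
            raise ConfigError(
                f"radical {self.label!r}: g-factor {self.g_factor} outside (1.9, 2.1)"
            )
        object.__setattr__(self, "nuclei", tuple(self.nuclei))


@dataclass(frozen=True)
class ExchangeModel:
    """Exponentially decaying exchange interaction J(r) = J0 exp(-alpha r)."""

    J0_mT: float
    alpha_invA: float

    def __post_init__(self) -> None:
        if self.alpha_invA < 0:
            raise ConfigError(f"alpha_invA must be >= 0, got {self.alpha_invA}")


@dataclass(frozen=True)
class RadicalPairSystem:
    """Two radicals, their exchange coupling, and the initial electron state.

    For a triplet-born pair (the photochemistry modelled here: intramolecular
    electron transfer out of a molecular triplet) ``initial_state`` is
    "triplet"; "singlet" is supported for completeness.
    """

    radical1: RadicalSpec
    radical2: RadicalSpec
    exchange: ExchangeModel
    initial_state: str = "triplet"
    dimension_cap: int = 64

    def __post_init__(self) -> None:
        if self.initial_state not in ("triplet", "singlet"):
            raise ConfigError(
                f"initial_state must be 'triplet' or 'singlet', got {self.initial_state!r}"
            )
        labels = [n.label for n in self.nuclei]
        if len(labels) != len(set(labels)):
            raise ConfigError(f"nucleus labels must be unique, got {labels}")

    @property
    def nuclei(self) -> tuple[NucleusSpec, ...]:
        """All nuclei, radical 1 first, in declaration order."""
        per_radical = []
        for idx, rad in ((1, self.radical1), (2, self.radical2)):
            for nuc in rad.nuclei:
                if nuc.radical_index != idx:
                    raise ConfigError(
                        f"nucleus {nuc.label!r} declared on radical {idx} but has "
                        f"radical_index={nuc.radical_index}"
                    )
                per_radical.append(nuc)
        return tuple(per_radical)

    @property
    def hilbert_dimension(self) -> int:
        dim = 4
        for nuc in self.nuclei:
            dim *= nuc.multiplicity
        return dim


def subsystem(system: RadicalPairSystem, keep_labels: Sequence[str]) -> RadicalPairSystem:
    """Reduced copy of ``system`` retaining only the named nuclei.

    Used for per-proton simulations where the target nucleus is kept
    together with one or two dominant partner nuclei to hold the
    Liouville-space dimension at desk scale.
    """
    keep = set(keep_labels)
    known = {n.label for n in system.nuclei}
    missing = keep - known
    if missing:
        raise ConfigError(f"unknown nucleus labels {sorted(missing)}; known: {sorted(known)}")
    r1 = replace(system.radical1, nuclei=tuple(n for n in system.radical1.nuclei if n.label in keep))
    r2 = replace(system.radical2, nuclei=tuple(n for n in system.radical2.nuclei if n.label in keep))
    return replace(system, radical1=r1, radical2=r2)


# ---------------------------------------------------------------------------
# spin operators and basis


def _spin_matrices(spin: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian spin matrices (Sx, Sy, Sz) for arbitrary spin quantum number."""
    dim = int(round(2 * spin + 1))
    m = spin - np.arange(dim)  # m = I, I-1, ..., -I
    sz = np.diag(m).astype(complex)
    # <m-1| S- |m> = sqrt(I(I+1) - m(m-1))
    lowering = np.zeros((dim, dim), dtype=complex)
    for k in range(dim - 1):
        mm = m[k]
        lowering[k + 1, k] = math.sqrt(spin * (spin + 1) - mm * (mm - 1))
    sp = lowering.conj().T
    sx = 0.5 * (sp + lowering)
    sy = -0.5j * (sp - lowering)
    return sx, sy, sz


class SpinBasis:
    """Product basis |electron1> x |electron2> x |nucleus_1> x ... and the
    operator factory on it.

    Electron ordering within the 4-dimensional electron space is
    (aa, ab, ba, bb).  The singlet projector is built from the operator
    identity P_S = 1/4 - S1.S2.
    """

    def __init__(self, system: RadicalPairSystem):
        if system.hilbert_dimension > system.dimension_cap:
            offenders = ", ".join(
                f"{n.label}(2I+1={n.multiplicity})" for n in system.nuclei
            )
            raise SizingError(
                f"Hilbert dimension {system.hilbert_dimension} exceeds cap "
                f"{system.dimension_cap}; nuclei: {offenders}"
            )
        self.system = system
        self.nuclei = system.nuclei
        self.site_dims = [2, 2] + [n.multiplicity for n in self.nuclei]
        self.dim = int(np.prod(self.site_dims))
        self.nuclear_dim = self.dim // 4

        self._site_ops = [_spin_matrices(0.5), _spin_matrices(0.5)] + [
            _spin_matrices(n.spin) for n in self.nuclei
        ]

        self.S1 = tuple(self._embed(0, c) for c in range(3))
        self.S2 = tuple(self._embed(1, c) for c in range(3))
        self.I_ops = {
            nuc.label: tuple(self._embed(2 + k, c) for c in range(3))
            for k, nuc in enumerate(self.nuclei)
        }
        s1s2 = sum(self.S1[c] @ self.S2[c] for c in range(3))
        self.S1S2 = s1s2
        self.projector_singlet = 0.25 * np.eye(self.dim, dtype=complex) - s1s2
        self.projector_triplet = np.eye(self.dim, dtype=complex) - self.projector_singlet

    def _embed(self, site: int, component: int) -> np.ndarray:
        op = np.array([[1.0 + 0j]])
        for s, d in enumerate(self.site_dims):
            factor = self._site_ops[s][component] if s == site else np.eye(d)
            op = np.kron(op, factor)
        return op

    # electron spin-adapted states (in the 4-dim electron space), for tests
    # and reporting: S, T+, T0, T-
    @staticmethod
    def electron_states() -> dict[str, np.ndarray]:
        aa = np.array([1, 0, 0, 0], dtype=complex)
        ab = np.array([0, 1, 0, 0], dtype=complex)
        ba = np.array([0, 0, 1, 0], dtype=complex)
        bb = np.array([0, 0, 0, 1], dtype=complex)
        s = (ab - ba) / math.sqrt(2)
        t0 = (ab + ba) / math.sqrt(2)
        return {"S": s, "T+": aa, "T0": t0, "T-": bb}

    def electron_spin_for(self, nucleus_label: str) -> tuple[np.ndarray, ...]:
        for nuc in self.nuclei:
            if nuc.label == nucleus_label:
                return self.S1 if nuc.radical_index == 1 else self.S2
        raise ConfigError(f"unknown nucleus {nucleus_label!r}")


def build_pair_basis(system: RadicalPairSystem) -> SpinBasis:
    """Construct the product spin basis and operator factory for a pair."""
    return SpinBasis(system)


# ---------------------------------------------------------------------------
# interactions


def exchange_coupling(model: ExchangeModel, r: float) -> float:
    """Exchange interaction J_ex(r) = J0 exp(-alpha r) in mT at distance r (A)."""
    if r <= 0:
        raise ValueError(f"inter-radical distance must be positive, got {r}")
    return model.J0_mT * math.exp(-model.alpha_invA * r)


def hamiltonian(
    system: RadicalPairSystem,
    B_mT: float,
    r_A: float,
    basis: SpinBasis | None = None,
    nuclear_zeeman: bool = True,
) -> np.ndarray:
    """Spin Hamiltonian of the pair at field ``B_mT`` and separation ``r_A``.

    Returned in field units (mT); multiply by :data:`GAMMA_E_RAD_PER_S_MT`
    to obtain angular frequency.  Terms: electron Zeeman (per-radical g),
    isotropic hyperfine ``a_k I_k . S``, exchange ``-J_ex(r) S1.S2`` and,
    optionally, the (tiny) nuclear Zeeman contribution.
    """
    if B_mT < 0:
        raise ValueError(f"field must be non-negative, got {B_mT}")
    if basis is None:
        basis = build_pair_basis(system)
    H = np.zeros((basis.dim, basis.dim), dtype=complex)

    g1 = system.radical1.g_factor / G_ELECTRON
    g2 = system.radical2.g_factor / G_ELECTRON
    H += g1 * B_mT * basis.S1[2] + g2 * B_mT * basis.S2[2]

    for nuc in basis.nuclei:
        S = basis.S1 if nuc.radical_index == 1 else basis.S2
        I = basis.I_ops[nuc.label]
        H += nuc.hfc_mT * sum(I[c] @ S[c] for c in range(3))
        if nuclear_zeeman:
            # proton-like gyromagnetic ratio; opposite sense to the electron
            H -= GAMMA_P_OVER_GAMMA_E * B_mT * I[2]

    J = exchange_coupling(system.exchange, r_A)
    H -= J * basis.S1S2
    return H
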