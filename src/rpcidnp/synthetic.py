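"""Fixture spin systems, model parameter sets and synthetic MFE curves.

Everything needed to exercise the pipeline without external data lives
here: a reduced flavin-tryptophan dyad spin system, full hyperfine sets
for the Weller estimate, the fitted restricted-diffusion parameter set,
and a noisy synthetic-curve generator for parameter-recovery studies.

Hyperfine couplings are transcriptions of literature EPR/ENDOR/CIDNP
values for the lumiflavin radical anion and the tryptophan cation
radical (each entry carries a ``source`` annotation); they are not
measured quantities of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .chain import ChainModel, DistanceGrid, MotionModel, distance_distribution, sample_end_to_end
from .liouville import RDModelParams, ReactionModel, RelaxationModel
from .pipeline import FieldCurve, WellerInput, normalize_curves, per_proton_field_sweep
from .spin_system import ExchangeModel, NucleusSpec, RadicalPairSystem, RadicalSpec

__all__ = [
    "SyntheticCurveSpec",
    "fixture",
    "available_fixtures",
    "generate_curves",
    "default_distance_grid",
]

_LIT = "literature EPR/ENDOR transcription (lumiflavin anion / TrpH cation radicals)"


def _flavin_radical(nuclei: tuple[NucleusSpec, ...] = ()) -> RadicalSpec:
    return RadicalSpec(label="flavin_anion", g_factor=2.0034, nuclei=nuclei)


def _trp_radical(nuclei: tuple[NucleusSpec, ...]) -> RadicalSpec:
    return RadicalSpec(label="trpH_cation", g_factor=2.0025, nuclei=nuclei)


_TABLE_EXCHANGE = ExchangeModel(J0_mT=-1.6e9, alpha_invA=2.14)


def _one_nucleus_toy() -> RadicalPairSystem:
    nuc = NucleusSpec("H_toy", 0.5, 1.0, radical_index=2, source="toy value")
    return RadicalPairSystem(
        radical1=_flavin_radical(),
        radical2=_trp_radical((nuc,)),
        exchange=_TABLE_EXCHANGE,
        initial_state="triplet",
    )


def _f10t_reduced() -> RadicalPairSystem:
    """Reduced dyad: the four most informative tryptophan protons.

    The two beta-CH2 protons are conformationally inequivalent (distinct
    couplings); ring protons carry negative couplings from spin
    polarization.  Flavin nuclei are omitted to keep the Hilbert space at
    the 64-dimensional cap.
    """
    trp = (
        NucleusSpec("betaCH2_a", 0.5, 1.61, 2, shift_ppm=3.29, source=_LIT),
        NucleusSpec("betaCH2_b", 0.5, 0.60, 2, shift_ppm=3.12, source=_LIT),
        NucleusSpec("H2", 0.5, -0.50, 2, shift_ppm=7.09, source=_LIT),
        NucleusSpec("H6", 0.5, -0.35, 2, shift_ppm=7.03, source=_LIT),
    )
    return RadicalPairSystem(
        radical1=_flavin_radical(),
        radical2=_trp_radical(trp),
        exchange=_TABLE_EXCHANGE,
        initial_state="triplet",
    )


def _weller_lumiflavin_trp() -> WellerInput:
    """Full isotropic hyperfine sets for the Weller B_1/2 estimate.

    (coupling in mT, nuclear spin I); signs do not enter the estimate.
    """
    flavin = (
        (0.523, 1.0),  # N5
        (0.176, 1.0),  # N10
        (0.198, 0.5),  # H6
        (0.407, 0.5),  # 8a-CH3 (x3)
        (0.407, 0.5),
        (0.407, 0.5),
        (0.32, 0.5),  # N10-CH3 (x3)
        (0.32, 0.5),
        (0.32, 0.5),
    )
    trp = (
        (1.61, 0.5),  # beta-CH2 a
        (0.60, 0.5),  # beta-CH2 b
        (0.50, 0.5),  # H2
        (0.245, 0.5),  # H4
        (0.35, 0.5),  # H6
        (0.20, 0.5),  # H7
        (0.32, 1.0),  # N1
        (0.35, 0.5),  # N1-H
    )
    return WellerInput(radical1=flavin, radical2=trp)


@lru_cache(maxsize=8)
def default_distance_grid(n_cells: int = 40) -> DistanceGrid:
    """Equilibrium end-to-end distribution of the default 12-bond linker
    on the [9.14, 20] A grid (contact wall at 9.14 A)."""
    chain = ChainModel(n_bonds=12, n_samples=200_000, seed=7)
    samples = sample_end_to_end(chain)
    return distance_distribution(samples, r_contact_A=9.14, r_max_A=20.0, n_cells=n_cells)


def _table1_params(n_cells: int = 40) -> RDModelParams:
    return RDModelParams(
        exchange=_TABLE_EXCHANGE,
        motion=MotionModel(D_eff_cm2s=2.5e-6, grid=default_distance_grid(n_cells)),
        reaction=ReactionModel(k_rec_Hz=4.7e7, k_loss_Hz=1.0e4),
        relaxation=RelaxationModel(b_loc_mT=0.3, tau_c_s=5.0e-11, include_dipolar=True),
    )


_FIXTURES = {
    "one_nucleus_toy": _one_nucleus_toy,
    "f10t_reduced": _f10t_reduced,
    "weller_lumiflavin_trp": _weller_lumiflavin_trp,
    "table1_params": _table1_params,
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str):
    """Return a named fixture (spin system, hyperfine set or parameter set).

    All fixtures are frozen dataclasses built fresh on each call.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# synthetic curves


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for noisy synthetic field-dependence curves.

    ``noise_sigma`` is the Gaussian noise standard deviation as a fraction
    of the reference maximum (the normalized scale is 100).
    """

    params: RDModelParams
    system: RadicalPairSystem
    B_mT: np.ndarray
    targets: tuple[str, ...]
    reference: str = "betaCH2_a"
    noise_sigma: float = 0.05
    n_partners: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "B_mT", np.asarray(self.B_mT, dtype=float))
        object.__setattr__(self, "targets", tuple(self.targets))


def generate_curves(
    spec: SyntheticCurveSpec,
) -> tuple[dict[str, FieldCurve], dict]:
    """Forward-model curves with additive Gaussian noise, plus ground truth.

    Curves are normalized so the reference maximum magnitude is 100, then
    i.i.d. Gaussian noise of sigma * 100 is added to every point.
    Bit-reproducible for a fixed seed.
    """
    raw = per_proton_field_sweep(
        spec.params, spec.system, spec.B_mT, list(spec.targets), spec.n_partners
    )
    curves = normalize_curves(raw, spec.reference)
    rng = np.random.default_rng(spec.seed)
    noisy = {}
    for label in spec.targets:
        c = curves[label]
        noise = rng.normal(0.0, spec.noise_sigma * 100.0, size=len(c.B_mT))
        noisy[label] = FieldCurve(
            c.nucleus, c.B_mT, c.intensity + noise, c.normalization_ref
        )
    truth = {
        "J0_mT": spec.params.exchange.J0_mT,
        "alpha_invA": spec.params.exchange.alpha_invA,
        "D_eff_cm2s": spec.params.motion.D_eff_cm2s,
        "k_rec_Hz": spec.params.reaction.k_rec_Hz,
        "k_loss_Hz": spec.params.reaction.k_loss_Hz,
        "b_loc_mT": spec.params.relaxation.b_loc_mT,
        "tau_c_s": spec.params.relaxation.tau_c_s,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "reference": spec.reference,
        "n_partners": spec.n_partners,
    }
    return noisy, truth
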