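"""Field sweeps and the downstream magnetic-field-effect analysis.

Produces per-nucleus CIDNP field-dependence curves from the master
equation, normalizes them the way field-cycling experiments are reported
(one global factor setting the strongest reference curve to 100%), and
extracts the standard MFE descriptors: the extremum position, the
half-effect field B_1/2, Lorentzian fits of the low-field dip, the Weller
hyperfine estimate of B_1/2 and the S/T- level-anticrossing field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from lmfit import Model

from .liouville import RDModelParams, geminate_cidnp
from .spin_system import RadicalPairSystem, build_pair_basis, subsystem

__all__ = [
    "FieldCurve",
    "LorentzianFitResult",
    "WellerInput",
    "NormalizationError",
    "NoExtremumError",
    "ExtractionError",
    "FitConvergenceError",
    "default_field_grid",
    "field_sweep",
    "per_proton_field_sweep",
    "normalize_curves",
    "extract_extremum",
    "extract_B_half",
    "lorentzian_fit",
    "weller_b_half",
    "st_minus_crossing",
]


class NormalizationError(ValueError):
    pass


class NoExtremumError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, best: "LorentzianFitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FieldCurve:
    """Signed CIDNP intensity of one nucleus versus polarizing field."""

    nucleus: str
    B_mT: np.ndarray
    intensity: np.ndarray
    normalization_ref: str = "raw"

    def __post_init__(self) -> None:
        b = np.asarray(self.B_mT, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "B_mT", b)
        object.__setattr__(self, "intensity", y)
        if b.ndim != 1 or y.shape != b.shape:
            raise ValueError("B_mT and intensity must be 1-d and equal length")
        if len(b) > 1 and np.any(np.diff(b) <= 0):
            raise ValueError(f"curve {self.nucleus!r}: B_mT must be strictly increasing")


@dataclass(frozen=True)
class LorentzianFitResult:
    """I(B) = I0 + A (G/2)^2 / ((B - B0)^2 + (G/2)^2), G = FWHM."""

    baseline: float
    amplitude: float
    center_mT: float
    fwhm_mT: float
    stderr: dict[str, float | None]
    residual_norm: float
    converged: bool

    def __post_init__(self) -> None:
        if self.fwhm_mT <= 0:
            raise ValueError("fwhm_mT must be positive")


@dataclass(frozen=True)
class WellerInput:
    """Per-radical lists of (hyperfine coupling in mT, nuclear spin I)."""

    radical1: tuple[tuple[float, float], ...]
    radical2: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "radical1", tuple(map(tuple, self.radical1)))
        object.__setattr__(self, "radical2", tuple(map(tuple, self.radical2)))
        if not any(a != 0 for a, _ in self.radical1 + self.radical2):
            raise ValueError("at least one hyperfine coupling must be nonzero")


# ---------------------------------------------------------------------------
# sweeps


def default_field_grid(
    b_min_mT: float = 0.05, b_max_mT: float = 100.0, n: int = 30
) -> np.ndarray:
    """Logarithmic polarizing-field grid matching field-cycling practice."""
    return np.geomspace(b_min_mT, b_max_mT, n)


def field_sweep(
    params: RDModelParams,
    system: RadicalPairSystem,
    B_list: np.ndarray,
) -> dict[str, FieldCurve]:
    """Raw per-nucleus polarization curves over the given fields."""
    B_list = np.asarray(B_list, dtype=float)
    if B_list.size == 0 or np.any(B_list <= 0):
        raise ValueError("B_list must be non-empty and positive")
    basis = build_pair_basis(system)
    values: dict[str, list[float]] = {n.label: [] for n in basis.nuclei}
    for B in B_list:
        try:
            result = geminate_cidnp(params, system, float(B), basis)
        except Exception as exc:  # annotate which field failed
            raise type(exc)(f"at B = {B} mT: {exc}") from exc
        for label, p in result.polarizations.items():
            values[label].append(p)
    return {
        label: FieldCurve(label, B_list, np.array(v)) for label, v in values.items()
    }


def per_proton_field_sweep(
    params: RDModelParams,
    system: RadicalPairSystem,
    B_list: np.ndarray,
    targets: list[str] | None = None,
    n_partners: int = 1,
) -> dict[str, FieldCurve]:
    """Per-proton curves from reduced subsystems.

    For each target nucleus a reduced pair is simulated containing the
    target plus its ``n_partners`` strongest-coupled partner nuclei; the
    target's curve is collected.  This keeps the Liouville dimension small
    while retaining the dominant hyperfine partner in each run.
    """
    all_nuclei = list(system.nuclei)
    if targets is None:
        targets = [n.label for n in all_nuclei]
    curves: dict[str, FieldCurve] = {}
    for target in targets:
        partners = sorted(
            (n for n in all_nuclei if n.label != target),
            key=lambda n: abs(n.hfc_mT),
            reverse=True,
        )[: max(0, n_partners)]
        sub = subsystem(system, [target] + [p.label for p in partners])
        curves[target] = field_sweep(params, sub, B_list)[target]
    return curves


# ---------------------------------------------------------------------------
# normalization and feature extraction


def normalize_curves(
    curves: dict[str, FieldCurve], reference: str
) -> dict[str, FieldCurve]:
    """Scale all curves by one global factor so max|reference| = 100.

    Signs are preserved: an emissive reference dips to -100.
    """
    if reference not in curves:
        raise NormalizationError(
            f"reference nucleus {reference!r} not among {sorted(curves)}"
        )
    ref_max = float(np.max(np.abs(curves[reference].intensity)))
    if ref_max == 0:
        raise NormalizationError(f"reference curve {reference!r} is identically zero")
    factor = 100.0 / ref_max
    return {
        label: replace(c, intensity=c.intensity * factor, normalization_ref=reference)
        for label, c in curves.items()
    }


def extract_extremum(curve: FieldCurve) -> tuple[float, float]:
    """Field position and value of the largest-magnitude extremum.

    Takes the discrete point of largest |intensity| and refines it by the
    exact vertex of the quadratic through it and its two neighbours
    (valid for unevenly spaced field grids).
    """
    b, y = curve.B_mT, curve.intensity
    if len(b) < 5:
        raise ValueError("need at least 5 points")
    diffs = np.diff(y)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise NoExtremumError(f"curve {curve.nucleus!r} is monotone")
    i = int(np.argmax(np.abs(y)))
    if i == 0 or i == len(b) - 1:
        raise NoExtremumError(
            f"curve {curve.nucleus!r}: largest magnitude at the grid boundary"
        )
    x0, x1, x2 = b[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a_coef = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b_coef = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a_coef == 0:
        return float(x1), float(y1)
    xv = -b_coef / (2 * a_coef)
    c_coef = y1 - a_coef * x1**2 - b_coef * x1
    return float(xv), float(a_coef * xv**2 + b_coef * xv + c_coef)


def extract_B_half(curve: FieldCurve) -> float:
    """Half-effect field on the low-field shoulder of the main extremum.

    Scans from the extremum towards lower fields and linearly interpolates
    the first crossing of half the extremal value.
    """
    b, y = curve.B_mT, curve.intensity
    b0, y0 = extract_extremum(curve)
    half = y0 / 2.0
    i_ext = int(np.argmax(np.abs(y)))
    for j in range(i_ext - 1, -1, -1):
        lo, hi = y[j] - half, y[j + 1] - half
        if lo == 0.0:
            return float(b[j])
        if lo * hi < 0:
            frac = (half - y[j]) / (y[j + 1] - y[j])
            return float(b[j] + frac * (b[j + 1] - b[j]))
    raise ExtractionError(
        f"curve {curve.nucleus!r}: no half-effect crossing on the low-field side"
    )


# ---------------------------------------------------------------------------
# Lorentzian fit


def _lorentzian(B, baseline, amplitude, center, fwhm):
    hw2 = (fwhm / 2.0) ** 2
    return baseline + amplitude * hw2 / ((B - center) ** 2 + hw2)


def lorentzian_fit(
    curve: FieldCurve,
    initial_guess: dict[str, float] | None = None,
) -> LorentzianFitResult:
    """Least-squares Lorentzian fit of an MFE dip (FWHM parameterization,
    floated baseline).  Without an explicit guess, three deterministic
    starting widths are tried and the best fit kept."""
    b, y = curve.B_mT, curve.intensity
    if len(b) < 5:
        raise ValueError("need at least 5 points")
    model = Model(_lorentzian)
    span = float(b[-1] - b[0])
    baseline0 = float(np.median(y))
    i_pk = int(np.argmax(np.abs(y - baseline0)))
    guesses: list[dict[str, float]]
    if initial_guess is not None:
        guesses = [dict(initial_guess)]
    else:
        guesses = [
            {
                "baseline": baseline0,
                "amplitude": float(y[i_pk] - baseline0),
                "center": float(b[i_pk]),
                "fwhm": frac * span,
            }
            for frac in (0.1, 0.25, 0.5)
        ]
    best = None
    for g in guesses:
        pars = model.make_params(**g)
        pars["fwhm"].set(min=1e-9 * max(span, 1.0))
        try:
            fit = model.fit(y, pars, B=b)
        except Exception:
            continue
        if best is None or fit.chisqr < best.chisqr:
            best = fit
    if best is None:
        raise FitConvergenceError("all Lorentzian fit starts failed")
    stderr = {name: best.params[name].stderr for name in best.params}
    result = LorentzianFitResult(
        baseline=float(best.params["baseline"].value),
        amplitude=float(best.params["amplitude"].value),
        center_mT=float(best.params["center"].value),
        fwhm_mT=float(best.params["fwhm"].value),
        stderr=stderr,
        residual_norm=float(np.linalg.norm(best.residual)),
        converged=bool(best.success),
    )
    if not best.success:
        raise FitConvergenceError("Lorentzian fit did not converge", best=result)
    return result


# ---------------------------------------------------------------------------
# closed-form estimates


def weller_b_half(hyperfine: WellerInput) -> float:
    """Hyperfine estimate of the half-effect field.

    B_i = sqrt(sum_k a_ik^2 I_k (I_k + 1)) per radical and
    B_1/2 = 2 (B_1^2 + B_2^2) / (B_1 + B_2), all in mT.
    """
    b = []
    for couplings in (hyperfine.radical1, hyperfine.radical2):
        b.append(math.sqrt(sum(a * a * spin * (spin + 1) for a, spin in couplings)))
    b1, b2 = b
    if b1 + b2 <= 0:
        raise ValueError("all hyperfine couplings are zero")
    return 2.0 * (b1 * b1 + b2 * b2) / (b1 + b2)


def st_minus_crossing(J_ex_mT: float) -> float:
    """Field (mT) of the S/T- level crossing: B = |J_ex| for a triplet-born
    pair with negative exchange coupling."""
    if J_ex_mT == 0:
        raise ValueError("J_ex must be nonzero")
    return abs(J_ex_mT)
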