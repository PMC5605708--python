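"""File formats and configuration.

Curve files are delimited text (comma or tab) with header
``nucleus,B_mT,intensity`` and ``#`` comment lines.  Spin systems and run
configurations are YAML with strict schema validation: unknown keys are
rejected and schema errors name the offending key path (YAML syntax
errors carry the line number from the parser).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml


from .pipeline import FieldCurve
from .spin_system import (
    ConfigError,
    ExchangeModel,
    NucleusSpec,
    RadicalPairSystem,
    RadicalSpec,
)

__all__ = [
    "CurveFormatError",
    "RunConfig",
    "load_run_config",
    "read_curves",
    "write_curves",
    "read_spin_system",
    "write_spin_system",
    "spin_system_to_dict",
    "spin_system_from_dict",
]


class CurveFormatError(ValueError):
    pass


_CURVE_COLUMNS = ("nucleus", "B_mT", "intensity")


def read_curves(path: str | Path) -> dict[str, FieldCurve]:
    """Read per-nucleus field curves from delimited text.

    Groups rows by nucleus and sorts each curve by ascending field.
    Errors carry 1-based line numbers.
    """
    path = Path(path)
    rows: list[tuple[str, float, float]] = []
    header: list[str] | None = None
    delimiter = ","
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                delimiter = "\t" if "\t" in line else ","
                header = [c.strip() for c in line.split(delimiter)]
                missing = [c for c in _CURVE_COLUMNS if c not in header]
                if missing:
                    raise CurveFormatError(
                        f"{path}:{lineno}: missing column(s) {missing}; "
                        f"header was {header}"
                    )
                idx = {c: header.index(c) for c in _CURVE_COLUMNS}
                continue
            parts = [c.strip() for c in line.split(delimiter)]
            if len(parts) < len(header):
                raise CurveFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[idx["nucleus"]],
                        float(parts[idx["B_mT"]]),
                        float(parts[idx["intensity"]]),
                    )
                )
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: non-numeric cell: {exc}") from None
    if header is None:
        raise CurveFormatError(f"{path}: empty file (no header)")

    curves: dict[str, FieldCurve] = {}
    labels = sorted({r[0] for r in rows})
    for label in labels:
        pts = sorted((b, y) for _, b, y in (r for r in rows if r[0] == label))
        b = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        curves[label] = FieldCurve(label, b, y)
    return curves


def write_curves(curves: dict[str, FieldCurve], path: str | Path) -> None:
    """Write curves as comma-delimited text with 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("nucleus,B_mT,intensity\n")
        for label in sorted(curves):
            c = curves[label]
            for b, y in zip(c.B_mT, c.intensity):
                fh.write(f"{label},{b:.6g},{y:.6g}\n")


# ---------------------------------------------------------------------------
# spin-system YAML


def _require(mapping: dict, key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"{path}: missing required key {key!r}")
    return mapping[key]


def _reject_unknown(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def spin_system_from_dict(doc: dict) -> RadicalPairSystem:
    if not isinstance(doc, dict):
        raise ConfigError("top level: expected a mapping")
    _reject_unknown(
        doc, {"radicals", "exchange", "initial_state", "dimension_cap"}, "top level"
    )
    radicals_doc = _require(doc, "radicals", "top level")
    if not isinstance(radicals_doc, list) or len(radicals_doc) != 2:
        raise ConfigError("radicals: expected a list of exactly 2 radicals")
    radicals = []
    for i, rdoc in enumerate(radicals_doc, start=1):
        rpath = f"radicals[{i - 1}]"
        if not isinstance(rdoc, dict):
            raise ConfigError(f"{rpath}: expected a mapping")
        _reject_unknown(rdoc, {"label", "g", "nuclei"}, rpath)
        nuclei = []
        for k, ndoc in enumerate(rdoc.get("nuclei") or []):
            npath = f"{rpath}.nuclei[{k}]"
            if not isinstance(ndoc, dict):
                raise ConfigError(f"{npath}: expected a mapping")
            _reject_unknown(
                ndoc, {"label", "spin", "hfc_mT", "shift_ppm", "source"}, npath
            )
            try:
                nuclei.append(
                    NucleusSpec(
                        label=str(_require(ndoc, "label", npath)),
                        spin=float(_require(ndoc, "spin", npath)),
                        hfc_mT=float(_require(ndoc, "hfc_mT", npath)),
                        radical_index=i,
                        shift_ppm=ndoc.get("shift_ppm"),
                        source=ndoc.get("source"),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{npath}: {exc}") from None
        try:
            radicals.append(
                RadicalSpec(
                    label=str(_require(rdoc, "label", rpath)),
                    g_factor=float(_require(rdoc, "g", rpath)),
                    nuclei=tuple(nuclei),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{rpath}: {exc}") from None

    edoc = _require(doc, "exchange", "top level")
    _reject_unknown(edoc, {"J0_mT", "alpha_invA"}, "exchange")
    exchange = ExchangeModel(
        J0_mT=float(_require(edoc, "J0_mT", "exchange")),
        alpha_invA=float(_require(edoc, "alpha_invA", "exchange")),
    )
    return RadicalPairSystem(
        radical1=radicals[0],
        radical2=radicals[1],
        exchange=exchange,
        initial_state=doc.get("initial_state", "triplet"),
        dimension_cap=int(doc.get("dimension_cap", 64)),
    )


def spin_system_to_dict(system: RadicalPairSystem) -> dict:
    def nuc_doc(n: NucleusSpec) -> dict:
        d = {"label": n.label, "spin": n.spin, "hfc_mT": n.hfc_mT}
        if n.shift_ppm is not None:
            d["shift_ppm"] = n.shift_ppm
        if n.source is not None:
            d["source"] = n.source
        return d

    return {
        "radicals": [
            {
                "label": rad.label,
                "g": rad.g_factor,
                "nuclei": [nuc_doc(n) for n in rad.nuclei],
            }
            for rad in (system.radical1, system.radical2)
        ],
        "exchange": {
            "J0_mT": system.exchange.J0_mT,
            "alpha_invA": system.exchange.alpha_invA,
        },
        "initial_state": system.initial_state,
        "dimension_cap": system.dimension_cap,
    }


def read_spin_system(path: str | Path) -> RadicalPairSystem:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from None
    return spin_system_from_dict(doc)


def write_spin_system(system: RadicalPairSystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spin_system_to_dict(system), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run configuration


_RUN_CONFIG_KEYS = {
    "spin_system_file",
    "overrides",
    "field_grid",
    "n_cells",
    "n_partners",
    "reference",
    "seed",
    "verbosity",
}
_OVERRIDE_KEYS = {
    "J0_mT",
    "alpha_invA",
    "D_eff_cm2s",
    "k_rec_Hz",
    "k_loss_Hz",
    "b_loc_mT",
    "tau_c_s",
}


@dataclass(frozen=True)
class RunConfig:
    """One validated document driving a full pipeline run.

    Everything a sweep or fit needs in one auditable place: the
    spin-system file, numeric parameter overrides, the field grid, the
    root seed and verbosity.  Unknown keys are rejected outright.
    """

    spin_system_file: str | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    b_min_mT: float = 0.05
    b_max_mT: float = 100.0
    n_fields: int = 30
    n_cells: int = 40
    n_partners: int = 1
    reference: str = "betaCH2_a"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.b_min_mT < self.b_max_mT):
            raise ConfigError("field_grid: need 0 < min < max")
        if self.n_fields < 1 or self.n_cells < 1:
            raise ConfigError("field_grid/n_cells: counts must be positive")
        unknown = set(self.overrides) - _OVERRIDE_KEYS
        if unknown:
            raise ConfigError(f"overrides: unknown key(s) {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level: expected a mapping")
    _reject_unknown(doc, _RUN_CONFIG_KEYS, "top level")
    grid = doc.get("field_grid") or {}
    if not isinstance(grid, dict):
        raise ConfigError("field_grid: expected a mapping")
    _reject_unknown(grid, {"min_mT", "max_mT", "n"}, "field_grid")
    overrides = doc.get("overrides") or {}
    try:
        overrides = {str(k): float(v) for k, v in overrides.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"overrides: {exc}") from None
    return RunConfig(
        spin_system_file=doc.get("spin_system_file"),
        overrides=overrides,
        b_min_mT=float(grid.get("min_mT", 0.05)),
        b_max_mT=float(grid.get("max_mT", 100.0)),
        n_fields=int(grid.get("n", 30)),
        n_cells=int(doc.get("n_cells", 40)),
        n_partners=int(doc.get("n_partners", 1)),
        reference=str(doc.get("reference", "betaCH2_a")),
        seed=int(doc.get("seed", 0)),
        verbosity=int(doc.get("verbosity", 0)),
    )
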