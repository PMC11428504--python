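"""Physical constants, energy-unit conversion, and per-phase reference enthalpies.

Everything downstream works in kcal/mol; raw quantum-chemistry enthalpies in
hartree are converted once, at the input boundary.  The reference enthalpies of
the hydrogen atom H(H•), proton H(H+) and electron H(e−) close the descriptor
equations: a radical-scavenging descriptor is always the enthalpy of the
organic products minus the parent, plus one of these small-species terms.

Only the composite

    C = H(H+) + H(e−) − H(H•)

is observable from a descriptor table, because IP + PDE − BDE = PA + ETE − BDE
= C in every phase.  The bundled default table therefore anchors C per phase
(gas 313.3, water 53.9, ethanol 47.0 kcal/mol, inferred from the bundled
descriptor fixture) and documents the per-species split as a convention; any
file with the same layout can override it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd
from scipy import constants as _codata

from .errors import InvalidInputError, ParseError

#: kcal·mol⁻¹ per hartree (CODATA-derived, fixed project-wide).
HARTREE_TO_KCALMOL = 627.5094740631

#: Default temperature (K); all bundled thermochemistry is at 298.15 K, 1 M.
DEFAULT_TEMPERATURE = 298.15

GAS = "gas"
WATER = "water"
ETHANOL = "ethanol"
KNOWN_PHASES = (GAS, WATER, ETHANOL)


def normalize_phase(label: str) -> str:
    """Canonical phase label: stripped, lower-case. Arbitrary labels allowed."""
    if not isinstance(label, str) or not label.strip():
        raise InvalidInputError(f"phase label must be a non-empty string, got {label!r}")
    return label.strip().lower()


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants in the mixed units this package computes with.

    ``boltzmann`` and ``planck`` are SI (J/K, J·s) so that k_B·T/h is a plain
    s⁻¹ frequency; ``gas_constant_kcal`` is kcal·mol⁻¹·K⁻¹ so that exp(−ΔG‡/RT)
    takes kcal/mol directly; ``speed_of_light_cm`` (cm/s) turns a wavenumber
    in cm⁻¹ into a frequency.
    """

    boltzmann: float = _codata.k
    planck: float = _codata.h
    gas_constant_kcal: float = _codata.R / (_codata.calorie * 1000.0)
    hartree_to_kcalmol: float = HARTREE_TO_KCALMOL
    speed_of_light_cm: float = _codata.c * 100.0
    avogadro: float = _codata.N_A

    def __post_init__(self):
        for name in ("boltzmann", "planck", "gas_constant_kcal",
                     "hartree_to_kcalmol", "speed_of_light_cm", "avogadro"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"constant {name} must be strictly positive")
        # k_B × N_A must equal R (consistency of the constant set)
        r_si = self.gas_constant_kcal * _codata.calorie * 1000.0
        if abs(self.boltzmann * self.avogadro - r_si) > 1e-9 * r_si:
            raise InvalidInputError("boltzmann × avogadro inconsistent with gas constant")


CODATA = PhysicalConstants()


def hartree_to_kcalmol(value: float) -> float:
    """Convert an energy from hartree to kcal/mol (exact linear map)."""
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"energy must be finite, got {value!r}")
    return value * HARTREE_TO_KCALMOL


@dataclass(frozen=True)
class ReferenceEnthalpies:
    """Per-phase enthalpies (kcal/mol) of H•, H+ and e− closing Eqs. BDE/IP/PDE/PA/ETE."""

    phase: str
    h_hydrogen_atom: float
    h_proton: float
    h_electron: float
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "phase", normalize_phase(self.phase))
        for name in ("h_hydrogen_atom", "h_proton", "h_electron"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)

    @property
    def composite(self) -> float:
        """C = H(H+) + H(e−) − H(H•), the amount by which IP+PDE (= PA+ETE) exceeds BDE."""
        return self.h_proton + self.h_electron - self.h_hydrogen_atom


def reference_constant(refs: ReferenceEnthalpies) -> float:
    """The phase's composite constant C = h_proton + h_electron − h_hydrogen_atom."""
    return refs.composite


_REF_COLUMNS = ["phase", "h_hydrogen_atom", "h_proton", "h_electron"]


def load_reference_enthalpies(path=None) -> dict[str, ReferenceEnthalpies]:
    """Read a reference-enthalpy table (phase → H(H•), H(H+), H(e−), kcal/mol).

    With ``path=None`` the bundled default table is used; its provenance strings
    document how each value was fixed.  Returns a dict keyed by canonical phase.
    """
    if path is None:
        path = files("radscav.data") / "reference_enthalpies.csv"
    with open(str(path), encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"reference table missing columns: {', '.join(missing)}")
    out: dict[str, ReferenceEnthalpies] = {}
    for i, row in df.iterrows():
        refs = ReferenceEnthalpies(
            phase=row["phase"],
            h_hydrogen_atom=row["h_hydrogen_atom"],
            h_proton=row["h_proton"],
            h_electron=row["h_electron"],
            provenance=str(row.get("provenance", "")),
        )
        if refs.phase in out:
            raise ParseError(f"duplicate phase {refs.phase!r} in reference table", rows=[i + 1])
        out[refs.phase] = refs
    return out


def default_reference_enthalpies() -> dict[str, ReferenceEnthalpies]:
    """The bundled default reference table (C anchored at 313.3 / 53.9 / 47.0 kcal/mol)."""
    return load_reference_enthalpies(None)
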