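"""The five thermodynamic antioxidant descriptors and descriptor tables.

For a phenol ArOH in a given phase, the three radical-scavenging routes are
characterised by (all in kcal/mol):

====  ======================================  ==========================
HAT   BDE = H(ArO•)  + H(H•) − H(ArOH)        one-step H-atom transfer
SET-PT IP  = H(ArOH•+) + H(e−) − H(ArOH)      electron loss, then
      PDE = H(ArO•)  + H(H+) − H(ArOH•+)      proton loss
SPLET PA  = H(ArO−)  + H(H+) − H(ArOH)        proton loss, then
      ETE = H(ArO•)  + H(e−) − H(ArO−)        electron loss
====  ======================================  ==========================

Because the three routes share end points, IP + PDE = PA + ETE exactly and
both exceed BDE by the phase constant C = H(H+) + H(e−) − H(H•) — a Hess-cycle
identity this module exposes as a per-row closure check for any descriptor
table, printed or computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as _dc_fields
from importlib.resources import files

import pandas as pd

from .constants import ReferenceEnthalpies, normalize_phase, reference_constant
from .errors import (
    InvalidInputError,
    NotComputableError,
    ParseError,
    PhaseMismatchError,
    RoleMismatchError,
)
from .species import (
    ANION,
    PARENT,
    RADICAL,
    RADICAL_CATION,
    Species,
    SpeciesSet,
    normalize_site,
    site_sort_key,
)

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("bde", "ip", "pde", "pa", "ete")

#: one-decimal printed tables close the Hess cycle only to rounding
PRINTED_CLOSURE_TOL = 0.3
#: species sets computed in double precision close it to machine accuracy
MACHINE_CLOSURE_TOL = 1e-9


def _check_pair(a: Species, a_role: str, b: Species, b_role: str) -> None:
    if a.role != a_role:
        raise RoleMismatchError(f"expected a {a_role} species, got role {a.role!r}")
    if b.role != b_role:
        raise RoleMismatchError(f"expected a {b_role} species, got role {b.role!r}")
    if a.compound != b.compound:
        raise RoleMismatchError(
            f"species from different compounds: {a.compound!r} vs {b.compound!r}")
    if a.phase != b.phase:
        raise PhaseMismatchError(
            f"species from different phases: {a.phase!r} vs {b.phase!r}")


def bde(parent: Species, radical: Species, refs: ReferenceEnthalpies) -> float:
    """Bond dissociation enthalpy, H(ArO•) + H(H•) − H(ArOH)."""
    _check_pair(parent, PARENT, radical, RADICAL)
    return radical.enthalpy + refs.h_hydrogen_atom - parent.enthalpy


def ip(parent: Species, cation: Species, refs: ReferenceEnthalpies) -> float:
    """Adiabatic ionisation potential, H(ArOH•+) + H(e−) − H(ArOH)."""
    _check_pair(parent, PARENT, cation, RADICAL_CATION)
    return cation.enthalpy + refs.h_electron - parent.enthalpy


def pde(cation: Species, radical: Species, refs: ReferenceEnthalpies) -> float:
    """Proton dissociation enthalpy of the radical cation, H(ArO•) + H(H+) − H(ArOH•+).

    Negative values are legitimate (strongly solvated protons).
    """
    _check_pair(cation, RADICAL_CATION, radical, RADICAL)
    return radical.enthalpy + refs.h_proton - cation.enthalpy


def pa(parent: Species, anion: Species, refs: ReferenceEnthalpies) -> float:
    """Proton affinity (deprotonation enthalpy), H(ArO−) + H(H+) − H(ArOH)."""
    _check_pair(parent, PARENT, anion, ANION)
    return anion.enthalpy + refs.h_proton - parent.enthalpy


def ete(anion: Species, radical: Species, refs: ReferenceEnthalpies) -> float:
    """Electron transfer enthalpy of the phenolate, H(ArO•) + H(e−) − H(ArO−)."""
    _check_pair(anion, ANION, radical, RADICAL)
    return radical.enthalpy + refs.h_electron - anion.enthalpy


@dataclass(frozen=True)
class DescriptorRecord:
    """Descriptors for one (compound, site, phase); absent values are None, never 0."""

    compound: str
    site: str
    phase: str
    bde: float | None = None
    ip: float | None = None
    pde: float | None = None
    pa: float | None = None
    ete: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "site", normalize_site(self.site))
        object.__setattr__(self, "phase", normalize_phase(self.phase))
        present = [n for n in DESCRIPTOR_NAMES if getattr(self, n) is not None]
        if not present:
            raise InvalidInputError(
                f"descriptor record {self.compound}/{self.site}/{self.phase} "
                "has no descriptor values")
        for n in present:
            v = float(getattr(self, n))
            if not math.isfinite(v):
                raise InvalidInputError(f"{n} must be finite, got {v!r}")
            object.__setattr__(self, n, v)

    @property
    def complete(self) -> bool:
        return all(getattr(self, n) is not None for n in DESCRIPTOR_NAMES)

    def closure_deviation(self) -> float | None:
        """(IP + PDE) − (PA + ETE); None unless all four legs are present."""
        if None in (self.ip, self.pde, self.pa, self.ete):
            return None
        return (self.ip + self.pde) - (self.pa + self.ete)


class DescriptorTable:
    """A collection of :class:`DescriptorRecord` with the reference enthalpies used.

    ``refs_used`` maps phase → :class:`ReferenceEnthalpies` (may be empty for
    tables transcribed from print, whose references are unknown).
    IP must be identical across the site rows of one compound-phase: the
    ionisation involves no site.
    """

    def __init__(self, records, refs_used=None, ip_tol=1e-6):
        records = tuple(records)
        by_cp = {}
        for rec in records:
            if not isinstance(rec, DescriptorRecord):
                raise InvalidInputError(f"not a DescriptorRecord: {rec!r}")
            if rec.ip is not None:
                by_cp.setdefault((rec.compound, rec.phase), []).append(rec.ip)
        for (compound, phase), ips in by_cp.items():
            if max(ips) - min(ips) > ip_tol:
                raise InvalidInputError(
                    f"IP differs across sites of {compound}/{phase}: {sorted(set(ips))}")
        self.records = records
        self.refs_used = dict(refs_used or {})

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def compounds(self):
        return sorted({r.compound for r in self.records})

    def phases(self):
        return sorted({r.phase for r in self.records})

    def rows(self, compound=None, phase=None, site=None):
        site = normalize_site(site)
        phase = normalize_phase(phase) if phase is not None else None
        out = [r for r in self.records
               if (compound is None or r.compound == compound)
               and (phase is None or r.phase == phase)
               and (site is None or r.site == site)]
        return sorted(out, key=lambda r: (r.compound, r.phase, site_sort_key(r.site)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{f.name: getattr(r, f.name) for f in _dc_fields(DescriptorRecord)}
             for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, refs_used=None) -> "DescriptorTable":
        records = []
        for _, row in df.iterrows():
            kwargs = {n: (None if pd.isna(row.get(n)) else float(row[n]))
                      for n in DESCRIPTOR_NAMES if n in df.columns}
            records.append(DescriptorRecord(
                compound=row["compound"], site=row["site"], phase=row["phase"], **kwargs))
        return cls(records, refs_used=refs_used)


def build_descriptor_table(species_set: SpeciesSet,
                           refs_by_phase: dict[str, ReferenceEnthalpies],
                           spin_policy: str = "lowest") -> DescriptorTable:
    """Compute every descriptor the species set supports, one record per
    (compound, site, phase).

    Sites are enumerated from the radical and anion records present; missing
    species leave the corresponding descriptors absent (logged, never zeroed).
    IP involves no site and is broadcast to every site row of its
    compound-phase.
    """
    records = []
    pairs = sorted({(sp.compound, sp.phase) for sp in species_set})
    for compound, phase in pairs:
        if phase not in refs_by_phase:
            logger.warning("no reference enthalpies for phase %r; skipping %s",
                           phase, compound)
            continue
        refs = refs_by_phase[phase]
        parent = species_set.get(compound, PARENT, None, phase)
        if parent is None:
            continue
        try:
            cation = species_set.select(compound, RADICAL_CATION, None, phase,
                                        spin_policy=spin_policy)
        except Exception:
            cation = None
        ip_val = ip(parent, cation, refs) if cation is not None else None

        sites = sorted({sp.site for sp in species_set
                        if sp.compound == compound and sp.phase == phase
                        and sp.site is not None and sp.role in (RADICAL, ANION)},
                       key=site_sort_key)
        for site in sites:
            try:
                radical = species_set.select(compound, RADICAL, site, phase,
                                             spin_policy=spin_policy)
            except Exception:
                radical = None
            try:
                anion = species_set.select(compound, ANION, site, phase,
                                           spin_policy=spin_policy)
            except Exception:
                anion = None
            vals = dict.fromkeys(DESCRIPTOR_NAMES)
            vals["ip"] = ip_val
            if radical is not None:
                vals["bde"] = bde(parent, radical, refs)
                if cation is not None:
                    vals["pde"] = pde(cation, radical, refs)
            if anion is not None:
                vals["pa"] = pa(parent, anion, refs)
                if radical is not None:
                    vals["ete"] = ete(anion, radical, refs)
            absent = [n for n, v in vals.items() if v is None]
            if absent:
                logger.info("descriptors absent for %s/%s/%s: %s",
                            compound, site, phase, ", ".join(absent))
            if any(v is not None for v in vals.values()):
                records.append(DescriptorRecord(compound=compound, site=site,
                                                phase=phase, **vals))
    return DescriptorTable(records, refs_used=dict(refs_by_phase))


def check_hess_closure(table: DescriptorTable, tolerance: float = PRINTED_CLOSURE_TOL,
                       refs_by_phase=None) -> pd.DataFrame:
    """Per-row Hess-cycle report for every record carrying all five descriptors.

    Columns: the row key, ``splet_minus_setpt`` = (IP+PDE) − (PA+ETE),
    ``setpt_minus_bde_minus_c`` = (IP+PDE) − BDE − C (NaN when no reference
    constant is available for the phase), and a ``flagged`` column marking rows
    whose available deviations exceed ``tolerance``.
    """
    refs_by_phase = refs_by_phase if refs_by_phase is not None else table.refs_used
    rows = []
    for rec in table:
        if not rec.complete:
            continue
        dev1 = rec.closure_deviation()
        refs = refs_by_phase.get(rec.phase)
        dev2 = ((rec.ip + rec.pde) - rec.bde - reference_constant(refs)
                if refs is not None else float("nan"))
        flagged = abs(dev1) > tolerance or (math.isfinite(dev2) and abs(dev2) > tolerance)
        rows.append({"compound": rec.compound, "site": rec.site, "phase": rec.phase,
                     "splet_minus_setpt": dev1, "setpt_minus_bde_minus_c": dev2,
                     "flagged": flagged})
    if not rows:
        raise NotComputableError("no row carries all five descriptors")
    return pd.DataFrame(rows)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero — the convention of printed one-decimal tables."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


# ---------------------------------------------------------------------------
# delimited-text I/O and bundled fixtures


def load_descriptor_table(path, refs_used=None) -> DescriptorTable:
    """Read a long-format descriptor table (compound, site, phase, bde..ete)."""
    with open(str(path), encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    for required in ("compound", "site", "phase"):
        if required not in df.columns:
            raise ParseError(f"descriptor table missing column '{required}'")
    return DescriptorTable.from_frame(df, refs_used=refs_used)


def write_descriptor_table(table: DescriptorTable, path) -> None:
    table.to_frame().to_csv(str(path), index=False)


def load_table1(refs_by_phase=None) -> DescriptorTable:
    """The bundled verbatim transcription of the published descriptor table
    (5 anthocyanins × up to 5 OH sites × 3 phases, 19 site rows per phase)."""
    from .constants import default_reference_enthalpies
    refs = refs_by_phase if refs_by_phase is not None else default_reference_enthalpies()
    return load_descriptor_table(files("radscav.data") / "table1_descriptors.csv",
                                 refs_used=refs)


def load_bde_ranking_fixture() -> DescriptorTable:
    """The text-quoted gas-phase 4′-OH BDE ranking (differs from the printed
    table for Cy-3-O-glc; both sources ship unedited)."""
    return load_descriptor_table(files("radscav.data") / "section321_bde_ranking.csv")
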