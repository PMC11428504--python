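"""Per-species thermochemistry records and delimited-text I/O.

A :class:`Species` is one chemical entity in one phase — a parent phenol ArOH,
its phenoxyl radical ArO•, phenolate anion ArO−, radical cation ArOH•+, or one
of the stationary points of a reaction path (pre-complex, transition state,
post-complex, product) — together with its enthalpy and, optionally, Gibbs
energy in kcal/mol.  A :class:`SpeciesSet` is the validated collection that
every downstream stage consumes.

The table format is plain delimited text (comma or tab, auto-detected), UTF-8,
``#`` comment lines allowed, with columns::

    compound, role, site, phase, enthalpy, gibbs, imag_wavenumber, spin

Energies are kcal/mol by default; naming the energy columns
``enthalpy_hartree`` / ``gibbs_hartree`` declares hartree inputs, which are
converted once on ingest.  The writer emits floats at full precision (repr) so
that load → write → load is the identity.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import hartree_to_kcalmol, normalize_phase
from .errors import (
    AmbiguousSpinError,
    DuplicateKeyError,
    InvalidInputError,
    OrphanSpeciesError,
    ParseError,
    SpeciesNotFoundError,
)

PRIME = "′"

# phenolic positions on the anthocyanidin skeleton, in canonical order
CANONICAL_SITES = (f"3{PRIME}-OH", f"4{PRIME}-OH", f"5{PRIME}-OH", "5-OH", "7-OH")
_SITE_RANK = {s: i for i, s in enumerate(CANONICAL_SITES)}

PARENT = "parent"
RADICAL = "radical"
ANION = "anion"
RADICAL_CATION = "radical_cation"
TRANSITION_STATE = "transition_state"
PRE_COMPLEX = "pre_complex"
POST_COMPLEX = "post_complex"
PRODUCT = "product"
CO_REACTANT = "co_reactant"

ROLES = (PARENT, RADICAL, ANION, RADICAL_CATION, TRANSITION_STATE,
         PRE_COMPLEX, POST_COMPLEX, PRODUCT, CO_REACTANT)

#: roles derived from a parent by H•/H+/e− loss; each needs a parent record
DERIVED_ROLES = (RADICAL, ANION, RADICAL_CATION)

SPIN_STATES = ("singlet", "doublet", "triplet", "n/a")


def normalize_site(label):
    """Canonical site label: ASCII apostrophes → the prime character, whitespace stripped.

    ``None`` (or blank) stays ``None`` — many roles carry no site.
    """
    if label is None:
        return None
    if isinstance(label, float) and math.isnan(label):
        return None
    label = str(label).strip()
    if not label:
        return None
    return label.replace("'", PRIME).replace("’", PRIME)


def site_sort_key(label):
    """Canonical ordering 3′ < 4′ < 5′ < 5 < 7; unknown sites after, alphabetically."""
    label = normalize_site(label)
    return (_SITE_RANK.get(label, len(CANONICAL_SITES)), label or "")


@dataclass(frozen=True)
class Species:
    """One chemical entity in one phase with its thermochemistry (kcal/mol)."""

    compound: str
    role: str
    phase: str
    enthalpy: float
    site: str | None = None
    gibbs: float | None = None
    imaginary_wavenumber: float | None = None
    spin_state: str = "n/a"

    def __post_init__(self):
        if not self.compound or not str(self.compound).strip():
            raise InvalidInputError("compound identifier must be non-empty")
        object.__setattr__(self, "compound", str(self.compound).strip())
        if self.role not in ROLES:
            raise InvalidInputError(
                f"unknown role {self.role!r}; expected one of {', '.join(ROLES)}")
        object.__setattr__(self, "phase", normalize_phase(self.phase))
        object.__setattr__(self, "site", normalize_site(self.site))
        h = float(self.enthalpy)
        if not math.isfinite(h):
            raise InvalidInputError(f"enthalpy must be finite, got {h!r}")
        object.__setattr__(self, "enthalpy", h)
        if self.gibbs is not None:
            g = float(self.gibbs)
            if not math.isfinite(g):
                raise InvalidInputError(f"gibbs must be finite, got {g!r}")
            object.__setattr__(self, "gibbs", g)
        if self.spin_state not in SPIN_STATES:
            raise InvalidInputError(
                f"unknown spin state {self.spin_state!r}; expected one of {', '.join(SPIN_STATES)}")
        if self.imaginary_wavenumber is not None:
            w = float(self.imaginary_wavenumber)
            if not (w > 0):
                raise InvalidInputError(
                    "imaginary_wavenumber must be a positive magnitude (cm⁻¹) when present")
            if self.role != TRANSITION_STATE:
                raise InvalidInputError(
                    "imaginary_wavenumber is only meaningful on transition states")
            object.__setattr__(self, "imaginary_wavenumber", w)
        if self.role == TRANSITION_STATE and self.gibbs is None:
            raise InvalidInputError("transition states must carry a Gibbs energy")

    @property
    def key(self):
        return (self.compound, self.role, self.site, self.phase, self.spin_state)


class SpeciesSet:
    """Validated collection of :class:`Species`.

    Enforces key uniqueness and, for every radical / anion / radical-cation
    record, the presence of a parent in the same compound and phase.
    """

    def __init__(self, records, metadata=None, _row_numbers=None):
        records = tuple(records)
        rows = _row_numbers or {}
        index = {}
        for i, sp in enumerate(records):
            if not isinstance(sp, Species):
                raise InvalidInputError(f"record {i} is not a Species: {sp!r}")
            if sp.key in index:
                raise DuplicateKeyError(
                    f"duplicate species key {sp.key}",
                    rows=[r for r in (rows.get(index[sp.key]), rows.get(i)) if r],
                )
            index[sp.key] = i
        parents = {(sp.compound, sp.phase) for sp in records if sp.role == PARENT}
        orphans = [i for i, sp in enumerate(records)
                   if sp.role in DERIVED_ROLES and (sp.compound, sp.phase) not in parents]
        if orphans:
            bad = records[orphans[0]]
            raise OrphanSpeciesError(
                f"derived species without a parent record, e.g. {bad.compound} "
                f"{bad.role} in {bad.phase}",
                rows=[rows[i] for i in orphans if i in rows] or None,
            )
        self.records = records
        self.metadata = dict(metadata or {})
        self._index = index

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def compounds(self):
        return sorted({sp.compound for sp in self.records})

    def phases(self):
        return sorted({sp.phase for sp in self.records})

    def _matches(self, compound, role, site, phase):
        site = normalize_site(site)
        phase = normalize_phase(phase)
        hits = []
        for spin in SPIN_STATES:  # key lookup per spin state keeps this O(1)
            i = self._index.get((compound, role, site, phase, spin))
            if i is not None:
                hits.append(self.records[i])
        return hits

    def lookup(self, compound, role, site=None, phase="gas", spin=None) -> Species:
        """Unique record for the key, or a structured error.

        When several spin states exist for the key, ``spin`` must be given —
        a silently wrong spin state is never returned.
        """
        hits = self._matches(compound, role, site, phase)
        if spin is not None:
            hits = [sp for sp in hits if sp.spin_state == spin]
        if not hits:
            raise SpeciesNotFoundError(
                f"no species ({compound}, {role}, {normalize_site(site)}, {phase}"
                + (f", spin={spin})" if spin else ")"))
        if len(hits) > 1:
            spins = sorted(sp.spin_state for sp in hits)
            raise AmbiguousSpinError(
                f"({compound}, {role}, {normalize_site(site)}, {phase}) matches spin states "
                f"{spins}; request one explicitly")
        return hits[0]

    def select(self, compound, role, site=None, phase="gas", spin=None,
               spin_policy="lowest") -> Species:
        """Like :meth:`lookup`, but with a declared policy for multiple spin states.

        ``spin_policy='lowest'`` (the default) picks the lowest-enthalpy state,
        recording no ambiguity; ``'strict'`` defers to :meth:`lookup`.
        """
        if spin is not None or spin_policy == "strict":
            return self.lookup(compound, role, site, phase, spin=spin)
        hits = self._matches(compound, role, site, phase)
        if not hits:
            raise SpeciesNotFoundError(
                f"no species ({compound}, {role}, {normalize_site(site)}, {phase})")
        return min(hits, key=lambda sp: sp.enthalpy)

    def get(self, compound, role, site=None, phase="gas", spin=None):
        """``lookup`` returning ``None`` instead of raising on a missing key."""
        try:
            return self.lookup(compound, role, site, phase, spin=spin)
        except SpeciesNotFoundError:
            return None
        except AmbiguousSpinError:
            raise


_COLUMNS = ["compound", "role", "site", "phase", "enthalpy", "gibbs",
            "imag_wavenumber", "spin"]


def _resolve_energy_columns(columns):
    """Map the file's energy headers onto (enthalpy column, gibbs column, in_hartree)."""
    cols = set(columns)
    if "enthalpy" in cols:
        h_col, hartree = "enthalpy", False
    elif "enthalpy_kcalmol" in cols:
        h_col, hartree = "enthalpy_kcalmol", False
    elif "enthalpy_hartree" in cols:
        h_col, hartree = "enthalpy_hartree", True
    else:
        raise ParseError("missing required column 'enthalpy' "
                         "(or 'enthalpy_hartree' / 'enthalpy_kcalmol')")
    g_col = None
    for cand in (("gibbs_hartree",) if hartree else ("gibbs", "gibbs_kcalmol")):
        if cand in cols:
            g_col = cand
    if not hartree and g_col is None and "gibbs" in cols:
        g_col = "gibbs"
    return h_col, g_col, hartree


def load_species_table(path) -> SpeciesSet:
    """Read and validate a species table (see module docstring for the dialect).

    Errors name the offending 1-based data rows.
    """
    with open(str(path), encoding="utf-8") as fh:
        text = fh.read()
    header = next((line for line in text.splitlines()
                   if line.strip() and not line.lstrip().startswith("#")), "")
    sep = "\t" if "\t" in header else ","
    # the C engine's round_trip parser keeps load(write(x)) bit-exact
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#",
                     skip_blank_lines=True, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    for required in ("compound", "role", "phase"):
        if required not in df.columns:
            raise ParseError(f"missing required column '{required}'")
    h_col, g_col, hartree = _resolve_energy_columns(df.columns)

    records, row_numbers = [], {}
    for pos, (_, row) in enumerate(df.iterrows()):
        rownum = pos + 1
        try:
            enthalpy = float(row[h_col])
            gibbs = row[g_col] if g_col is not None else None
            gibbs = None if gibbs is None or pd.isna(gibbs) else float(gibbs)
            if hartree:
                enthalpy = hartree_to_kcalmol(enthalpy)
                gibbs = hartree_to_kcalmol(gibbs) if gibbs is not None else None
            imag = row.get("imag_wavenumber")
            imag = None if imag is None or pd.isna(imag) else float(imag)
            spin = row.get("spin")
            spin = "n/a" if spin is None or pd.isna(spin) or not str(spin).strip() else str(spin).strip()
            sp = Species(
                compound=row["compound"], role=str(row["role"]).strip(),
                phase=row["phase"], enthalpy=enthalpy, site=row.get("site"),
                gibbs=gibbs, imaginary_wavenumber=imag, spin_state=spin,
            )
        except (InvalidInputError, TypeError, ValueError) as exc:
            raise ParseError(f"invalid species record: {exc}", rows=[rownum]) from exc
        row_numbers[len(records)] = rownum
        records.append(sp)
    return SpeciesSet(records, metadata={"source": str(path)}, _row_numbers=row_numbers)


def write_species_table(species_set: SpeciesSet, path, delimiter=",") -> None:
    """Write a species table; floats at full precision so the round trip is exact."""

    def fmt(x):
        return "" if x is None else repr(float(x))

    with open(str(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for sp in species_set:
            writer.writerow([
                sp.compound, sp.role, sp.site or "", sp.phase,
                fmt(sp.enthalpy), fmt(sp.gibbs), fmt(sp.imaginary_wavenumber),
                sp.spin_state,
            ])
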