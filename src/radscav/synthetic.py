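"""Synthetic thermochemistry generator: species sets and reaction profiles
with prescribed descriptors, barriers and reaction energies.

The generator inverts the descriptor equations: given target BDE/IP/PDE/PA/ETE
values and a phase's reference enthalpies it constructs parent, radical, anion
and radical-cation enthalpies that reproduce the targets exactly (to 1e-9
kcal/mol) — the stand-in for quantum-chemistry runs that makes every
downstream stage testable offline.  Because descriptors are invariant under a
uniform shift of all species enthalpies, the absolute parent enthalpy is an
arbitrary, documented base (−1000 kcal/mol by default).

Optional Gaussian noise (independent per enthalpy, seeded) emulates method
error; all randomness flows through ``numpy.random.default_rng`` (PCG64), so
one seed reproduces one data set on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, ReferenceEnthalpies, normalize_phase
from .errors import ConstructibilityError, InvalidInputError
from .species import (
    ANION,
    CO_REACTANT,
    PARENT,
    POST_COMPLEX,
    PRE_COMPLEX,
    PRODUCT,
    RADICAL,
    RADICAL_CATION,
    TRANSITION_STATE,
    Species,
    SpeciesSet,
    normalize_site,
)

DEFAULT_BASE_ENTHALPY = -1000.0

_DESCRIPTOR_FIELDS = ("bde", "ip", "pde", "pa", "ete")


@dataclass(frozen=True)
class TargetRow:
    """Descriptor targets for one (compound, site, phase); any subset may be set."""

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
        if all(getattr(self, n) is None for n in _DESCRIPTOR_FIELDS):
            raise InvalidInputError(
                f"target row {self.compound}/{self.site}/{self.phase} sets no descriptor")

    @property
    def label(self):
        return f"{self.compound}/{self.site}/{self.phase}"


@dataclass(frozen=True)
class DescriptorTargets:
    """A batch of target rows plus the references and generator settings."""

    rows: tuple
    refs: dict  # phase -> ReferenceEnthalpies
    base_parent_enthalpy: float = DEFAULT_BASE_ENTHALPY
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be ≥ 0")
        for row in self.rows:
            if row.phase not in self.refs:
                raise InvalidInputError(
                    f"no reference enthalpies for phase {row.phase!r} (row {row.label})")


def _solve_row(row: TargetRow, refs: ReferenceEnthalpies, base: float,
               cation_h: float | None, tol: float):
    """Enthalpies (radical, anion, updated cation) consistent with the row's targets."""
    h_h, h_p, h_e = refs.h_hydrogen_atom, refs.h_proton, refs.h_electron
    if row.ip is not None:
        c = base + row.ip - h_e
        if cation_h is not None and abs(c - cation_h) > tol:
            raise ConstructibilityError(
                f"row {row.label}: IP target conflicts with the compound-phase "
                f"cation implied by earlier rows (Δ={c - cation_h:.3g} kcal/mol)")
        cation_h = c

    radical_h = anion_h = None
    if row.bde is not None:
        radical_h = base + row.bde - h_h
    if row.pa is not None:
        anion_h = base + row.pa - h_p
    if radical_h is None and row.pde is not None and cation_h is not None:
        radical_h = cation_h + row.pde - h_p
    if radical_h is None and row.ete is not None and anion_h is not None:
        radical_h = row.ete + anion_h - h_e
    if anion_h is None and row.ete is not None and radical_h is not None:
        anion_h = radical_h + h_e - row.ete
    if cation_h is None and row.pde is not None and radical_h is not None:
        cation_h = radical_h + h_p - row.pde

    # verify every supplied target against the solved enthalpies
    checks = {
        "bde": None if radical_h is None else radical_h + h_h - base,
        "ip": None if cation_h is None else cation_h + h_e - base,
        "pde": None if (cation_h is None or radical_h is None)
               else radical_h + h_p - cation_h,
        "pa": None if anion_h is None else anion_h + h_p - base,
        "ete": None if (anion_h is None or radical_h is None)
               else radical_h + h_e - anion_h,
    }
    for name in _DESCRIPTOR_FIELDS:
        want = getattr(row, name)
        if want is None:
            continue
        got = checks[name]
        if got is None:
            raise ConstructibilityError(
                f"row {row.label}: target {name} cannot be realised — the species "
                "it constrains are not determined by the other targets")
        if abs(got - want) > tol:
            raise ConstructibilityError(
                f"row {row.label}: targets are mutually inconsistent — "
                f"{name} would be {got:.6f}, target {want:.6f} "
                f"(|Δ|={abs(got - want):.3g} > tol={tol:g})")
    return radical_h, anion_h, cation_h


def make_species_set(targets: DescriptorTargets, tol: float = 1e-9) -> SpeciesSet:
    """Construct a species set whose descriptors reproduce the targets.

    ``tol`` is the consistency tolerance for over-determined rows: 1e-9 (the
    default) for exact synthetic targets; use the printed-table rounding
    tolerance (0.3 kcal/mol) to regenerate a one-decimal published table,
    where IP+PDE and PA+ETE close only to rounding.  Inconsistent targets
    raise :class:`ConstructibilityError` naming the row.
    """
    base = float(targets.base_parent_enthalpy)
    records: list[Species] = []
    made_parent: set = set()
    cation_by_cp: dict = {}
    for row in targets.rows:
        refs = targets.refs[row.phase]
        cp = (row.compound, row.phase)
        radical_h, anion_h, cation_h = _solve_row(
            row, refs, base, cation_by_cp.get(cp), tol)
        if cp not in made_parent:
            records.append(Species(compound=row.compound, role=PARENT,
                                   phase=row.phase, enthalpy=base))
            made_parent.add(cp)
        if cation_h is not None and cp not in cation_by_cp:
            records.append(Species(compound=row.compound, role=RADICAL_CATION,
                                   phase=row.phase, enthalpy=cation_h))
        if cation_h is not None:
            cation_by_cp[cp] = cation_h
        if radical_h is not None:
            records.append(Species(compound=row.compound, role=RADICAL,
                                   site=row.site, phase=row.phase, enthalpy=radical_h))
        if anion_h is not None:
            records.append(Species(compound=row.compound, role=ANION,
                                   site=row.site, phase=row.phase, enthalpy=anion_h))
    out = SpeciesSet(records, metadata={
        "generator": "radscav.synthetic.make_species_set",
        "rng": "numpy.random.default_rng (PCG64)",
        "seed": targets.seed, "noise_sd": targets.noise_sd,
        "base_parent_enthalpy": base,
    })
    if targets.noise_sd > 0:
        out = perturb(out, targets.noise_sd, targets.seed)
    return out


def perturb(species_set: SpeciesSet, noise_sd: float, seed: int) -> SpeciesSet:
    """Independent seeded Gaussian perturbation of every enthalpy.

    ``noise_sd = 0`` is the identity; the same seed always yields the same
    output (PCG64, draws in record order).
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(species_set.records))
    records = [replace(sp, enthalpy=sp.enthalpy + float(eps))
               for sp, eps in zip(species_set.records, noise)]
    meta = dict(species_set.metadata)
    meta.update({"noise_sd": noise_sd, "seed": seed,
                 "rng": "numpy.random.default_rng (PCG64)"})
    return SpeciesSet(records, metadata=meta)


@dataclass(frozen=True)
class PESTargetRow:
    """Prescribed energetics for one bimolecular reaction profile (kcal/mol)."""

    reaction_id: str
    barrier: float
    reaction_energy: float
    rc_complexation: float = 5.0
    pc_complexation: float = 5.0
    imaginary_wavenumber: float | None = None
    phase: str = "gas"
    compound: str = "synthetic-phenol"
    site: str | None = None
    allow_barrierless: bool = False

    def __post_init__(self):
        object.__setattr__(self, "phase", normalize_phase(self.phase))
        object.__setattr__(self, "site", normalize_site(self.site))
        if self.barrier < 0 and not self.allow_barrierless:
            raise InvalidInputError(
                f"reaction {self.reaction_id!r}: negative barrier requires "
                "allow_barrierless=True")


@dataclass(frozen=True)
class PESTargets:
    rows: tuple
    temperature: float = DEFAULT_TEMPERATURE
    base_gibbs: float = -500.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive")


def make_pes(targets: PESTargets) -> dict:
    """Species lists realising each target profile, keyed by reaction id.

    The separated reactants (parent + co-reactant) sit ``rc_complexation``
    above the RC; the TS sits ``barrier`` above the RC; the PC sits
    ``reaction_energy`` above (below, when negative) the RC; the separated
    products sit ``pc_complexation`` above the PC.  Feeding the output to
    ``build_pes`` + ``activation_free_energy`` returns the target barrier
    exactly.
    """
    out: dict[str, list[Species]] = {}
    for row in targets.rows:
        g_parent = targets.base_gibbs
        g_co = 0.0
        g_r = g_parent + g_co
        g_rc = g_r - row.rc_complexation
        g_ts = g_rc + row.barrier
        g_pc = g_rc + row.reaction_energy
        g_prod = g_pc + row.pc_complexation

        def _sp(role, gibbs, **kw):
            return Species(compound=row.compound, role=role, phase=row.phase,
                           enthalpy=gibbs, gibbs=gibbs, **kw)

        out[row.reaction_id] = [
            _sp(PARENT, g_parent),
            _sp(CO_REACTANT, g_co),
            _sp(PRE_COMPLEX, g_rc, site=row.site),
            _sp(TRANSITION_STATE, g_ts, site=row.site,
                imaginary_wavenumber=row.imaginary_wavenumber),
            _sp(POST_COMPLEX, g_pc, site=row.site),
            _sp(PRODUCT, g_prod, site=row.site),
        ]
    return out


def targets_from_descriptor_table(table, refs, base_parent_enthalpy=DEFAULT_BASE_ENTHALPY,
                                  noise_sd=0.0, seed=0,
                                  fields=("bde", "ip", "pa")) -> DescriptorTargets:
    """Targets regenerating a descriptor table's species sets.

    ``fields`` defaults to the minimal generating triple (BDE, IP, PA): PDE
    and ETE then follow from the Hess identities, so one-decimal printed
    tables — whose five columns close only to rounding — remain constructible
    at machine tolerance.  Pass all five fields plus a rounding tolerance to
    enforce a printed table exactly.
    """
    rows = []
    for rec in table:
        kwargs = {n: getattr(rec, n) for n in fields if getattr(rec, n) is not None}
        if not kwargs:
            continue
        rows.append(TargetRow(compound=rec.compound, site=rec.site,
                              phase=rec.phase, **kwargs))
    return DescriptorTargets(rows=tuple(rows), refs=dict(refs),
                             base_parent_enthalpy=base_parent_enthalpy,
                             noise_sd=noise_sd, seed=seed)
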