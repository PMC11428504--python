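"""Mechanism-level analysis: site activity, rankings, solvent shifts,
preferred-mechanism classification and the double-HAT second step.

The thermodynamically preferred scavenging route in a phase is decided by the
first (committing) step of each mechanism: the minimum-site BDE for HAT, the
IP for SET-PT, and the minimum-site PA for SPLET.  The route with the smallest
of those three costs wins.  For catechol/guaiacyl-bearing phenols the first
phenoxyl radical can lose a second H atom, cyclising to a benzodioxole (via an
ortho-methoxy) or oxidising to an o-quinone (via an ortho-hydroxyl); the
cheaper second step identifies the favoured closed-shell product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constants import ReferenceEnthalpies, normalize_phase
from .descriptors import DESCRIPTOR_NAMES, DescriptorTable, bde as _bde_eq
from .errors import (
    InvalidInputError,
    NotComputableError,
    RoleMismatchError,
)
from .species import PARENT, RADICAL, Species, normalize_site, site_sort_key

logger = logging.getLogger(__name__)

HAT = "HAT"
SET_PT = "SET-PT"
SPLET = "SPLET"

#: fixed tie priority: concerted before stepwise, electron-first before proton-first
MECHANISM_PRIORITY = (HAT, SET_PT, SPLET)


def min_site(table: DescriptorTable, compound: str, phase: str,
             descriptor: str) -> tuple[str, float]:
    """Site with the minimal value of ``descriptor`` for one compound-phase.

    Ties break to the canonically earlier site (3′ < 4′ < 5′ < 5 < 7).
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise InvalidInputError(f"unknown descriptor {descriptor!r}")
    rows = [(r.site, getattr(r, descriptor)) for r in table.rows(compound, phase)
            if getattr(r, descriptor) is not None]
    if not rows:
        raise NotComputableError(
            f"descriptor {descriptor!r} absent for every site of {compound}/{phase}")
    return min(rows, key=lambda sv: (sv[1], site_sort_key(sv[0])))


@dataclass(frozen=True)
class RankResult:
    """Ascending cross-compound ranking of one descriptor at one site and phase."""

    descriptor: str
    site: str
    phase: str
    ranked: tuple  # ((compound, value), ...) ascending, ties alphabetical
    unranked: tuple = ()

    def order(self):
        return tuple(c for c, _ in self.ranked)


def rank_compounds(table: DescriptorTable, descriptor: str, site: str,
                   phase: str, compounds=None) -> RankResult:
    """Rank compounds by ascending ``descriptor`` at a fixed site and phase.

    Compounds lacking the row are listed as unranked with a warning rather
    than silently dropped.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise InvalidInputError(f"unknown descriptor {descriptor!r}")
    site = normalize_site(site)
    phase = normalize_phase(phase)
    compounds = list(compounds) if compounds is not None else table.compounds()
    values, unranked = [], []
    for compound in compounds:
        rows = table.rows(compound, phase, site)
        vals = [getattr(r, descriptor) for r in rows if getattr(r, descriptor) is not None]
        if vals:
            values.append((compound, vals[0]))
        else:
            unranked.append(compound)
    if unranked:
        logger.warning("no %s/%s/%s row for: %s", descriptor, site, phase,
                       ", ".join(unranked))
    values.sort(key=lambda cv: (cv[1], cv[0]))
    return RankResult(descriptor=descriptor, site=site, phase=phase,
                      ranked=tuple(values), unranked=tuple(unranked))


@dataclass(frozen=True)
class MechanismVerdict:
    """Preferred radical-scavenging mechanism for one compound in one phase.

    ``evidence`` holds the compared triple: (site, min BDE), IP, (site, min PA).
    """

    compound: str
    phase: str
    mechanism: str
    min_bde: tuple[str, float]
    ip: float
    min_pa: tuple[str, float]
    tie: bool = False

    @property
    def evidence(self):
        return {"min_bde": self.min_bde, "ip": self.ip, "min_pa": self.min_pa}


def classify_mechanism(table: DescriptorTable, compound: str, phase: str) -> MechanismVerdict:
    """Argmin over {min-site BDE → HAT, IP → SET-PT, min-site PA → SPLET}.

    Exact ties report the first mechanism in the fixed priority
    HAT > SET-PT > SPLET and set the ``tie`` flag.
    """
    phase = normalize_phase(phase)
    try:
        bde_site, bde_val = min_site(table, compound, phase, "bde")
        pa_site, pa_val = min_site(table, compound, phase, "pa")
    except NotComputableError as exc:
        raise NotComputableError(
            f"cannot classify {compound}/{phase}: {exc}") from exc
    ips = [r.ip for r in table.rows(compound, phase) if r.ip is not None]
    if not ips:
        raise NotComputableError(
            f"cannot classify {compound}/{phase}: IP absent everywhere")
    ip_val = ips[0]
    legs = {HAT: bde_val, SET_PT: ip_val, SPLET: pa_val}
    best = min(legs.values())
    winners = [m for m in MECHANISM_PRIORITY if legs[m] == best]
    return MechanismVerdict(compound=compound, phase=phase, mechanism=winners[0],
                            min_bde=(bde_site, bde_val), ip=ip_val,
                            min_pa=(pa_site, pa_val), tie=len(winners) > 1)


@dataclass(frozen=True)
class SolventShift:
    """Per-compound and mean descriptor shift between two phases (value(a) − value(b))."""

    descriptor: str
    phase_a: str
    phase_b: str
    per_compound: dict
    mean: float


def solvent_shift_summary(table: DescriptorTable, descriptor: str,
                          phase_a: str, phase_b: str) -> SolventShift:
    """Mean shift of ``descriptor`` from ``phase_a`` to ``phase_b``.

    Site-independent descriptors (IP) contribute one value per compound;
    site-bearing descriptors are first averaged over the sites shared by the
    two phases within each compound.  The headline number is the unweighted
    arithmetic mean over compounds.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise InvalidInputError(f"unknown descriptor {descriptor!r}")
    phase_a, phase_b = normalize_phase(phase_a), normalize_phase(phase_b)
    per_compound = {}
    for compound in table.compounds():
        if descriptor == "ip":
            va = [r.ip for r in table.rows(compound, phase_a) if r.ip is not None]
            vb = [r.ip for r in table.rows(compound, phase_b) if r.ip is not None]
            if va and vb:
                per_compound[compound] = va[0] - vb[0]
        else:
            a = {r.site: getattr(r, descriptor) for r in table.rows(compound, phase_a)
                 if getattr(r, descriptor) is not None}
            b = {r.site: getattr(r, descriptor) for r in table.rows(compound, phase_b)
                 if getattr(r, descriptor) is not None}
            shared = sorted(set(a) & set(b), key=site_sort_key)
            if shared:
                per_compound[compound] = sum(a[s] - b[s] for s in shared) / len(shared)
    if not per_compound:
        raise NotComputableError(
            f"{descriptor!r} present in both {phase_a!r} and {phase_b!r} for no compound")
    mean = sum(per_compound.values()) / len(per_compound)
    return SolventShift(descriptor=descriptor, phase_a=phase_a, phase_b=phase_b,
                        per_compound=per_compound, mean=mean)


def substituent_contrast(table: DescriptorTable, descriptor: str, site: str,
                         phase: str, reference_compound: str,
                         contrast_compounds) -> float:
    """Mean of (reference value − contrast value) over the contrast compounds.

    Quantifies how much a substitution pattern lowers (positive result) a
    descriptor relative to the reference compound at one site and phase.
    """
    site = normalize_site(site)
    phase = normalize_phase(phase)

    def value(compound):
        rows = table.rows(compound, phase, site)
        vals = [getattr(r, descriptor) for r in rows if getattr(r, descriptor) is not None]
        if not vals:
            raise NotComputableError(
                f"no {descriptor}/{site}/{phase} row for {compound!r}")
        return vals[0]

    ref_val = value(reference_compound)
    contrasts = list(contrast_compounds)
    if not contrasts:
        raise InvalidInputError("contrast_compounds must be non-empty")
    return sum(ref_val - value(c) for c in contrasts) / len(contrasts)


@dataclass(frozen=True)
class SecondHATResult:
    """Second H+/e− step from a first-formed phenoxyl radical.

    ``channels`` maps product name → (spin_state, second-step energy cost in
    kcal/mol, on the same H-acceptor convention as the first-step BDE);
    ``favored`` is the minimal-cost product.
    """

    compound: str
    phase: str
    first_site: str
    channels: dict
    favored: str

    def __post_init__(self):
        if not self.channels:
            raise InvalidInputError("second-HAT result needs at least one channel")
        best = min(cost for _, cost in self.channels.values())
        if self.channels[self.favored][1] != best:
            raise InvalidInputError("favored channel is not the minimal-cost channel")


def _favored(channels: dict) -> str:
    # argmin on cost; ties break alphabetically so the result is order-invariant
    return min(channels, key=lambda name: (channels[name][1], name))


def second_hat_analysis(parent: Species, first_radical: Species,
                        channel_products, refs: ReferenceEnthalpies,
                        spin_policy: str = "lowest") -> SecondHATResult:
    """Energy cost of each second-HAT channel and the favoured product.

    Each channel product is a closed-shell :class:`Species` (role ``product``)
    reachable from ``first_radical`` by loss of one more H atom; its cost is
    H(product) + H(H•) − H(first radical), the same acceptor convention as the
    first-step BDE.  Products supplied in several spin states are grouped by
    name; ``spin_policy='lowest'`` keeps the lowest-enthalpy state.
    """
    if parent.role != PARENT:
        raise RoleMismatchError(f"expected a parent species, got {parent.role!r}")
    if first_radical.role != RADICAL:
        raise RoleMismatchError(f"expected a radical species, got {first_radical.role!r}")
    if first_radical.compound != parent.compound or first_radical.phase != parent.phase:
        raise RoleMismatchError("first radical must derive from the parent "
                                "(same compound and phase)")
    products = list(channel_products)
    if not products:
        raise InvalidInputError("second-HAT analysis needs at least one channel product")
    grouped: dict[str, list[Species]] = {}
    for prod in products:
        if prod.phase != parent.phase:
            raise RoleMismatchError(
                f"channel product {prod.compound!r} is in phase {prod.phase!r}, "
                f"expected {parent.phase!r}")
        grouped.setdefault(prod.compound, []).append(prod)
    channels = {}
    for name, states in grouped.items():
        if spin_policy == "lowest":
            chosen = min(states, key=lambda sp: sp.enthalpy)
        else:
            if len(states) > 1:
                raise InvalidInputError(
                    f"multiple spin states for product {name!r} under strict policy")
            chosen = states[0]
        cost = chosen.enthalpy + refs.h_hydrogen_atom - first_radical.enthalpy
        channels[name] = (chosen.spin_state, cost)
    return SecondHATResult(compound=parent.compound, phase=parent.phase,
                           first_site=first_radical.site, channels=channels,
                           favored=_favored(channels))


def second_hat_from_costs(compound: str, phase: str, first_site: str,
                          channels: dict) -> SecondHATResult:
    """Build a :class:`SecondHATResult` from pre-computed channel costs.

    ``channels`` maps product name → (spin_state, cost) or plain cost.  Used
    for tables (like the bundled reaction-scheme fixture) that state the
    second-step energies directly.
    """
    norm = {}
    for name, val in channels.items():
        if isinstance(val, (tuple, list)):
            spin, cost = val
        else:
            spin, cost = "n/a", val
        norm[str(name)] = (spin, float(cost))
    if not norm:
        raise InvalidInputError("second-HAT result needs at least one channel")
    return SecondHATResult(compound=compound, phase=normalize_phase(phase),
                           first_site=normalize_site(first_site),
                           channels=norm, favored=_favored(norm))


def load_double_hat_fixture():
    """Bundled double-HAT second-step fixture → list of :class:`SecondHATResult`
    (one per phase), transcribed from the published reaction scheme."""
    import pandas as pd
    from importlib.resources import files

    with open(str(files("radscav.data") / "fig2_double_hat.csv"), encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    results = []
    for (compound, first_site, phase), g in df.groupby(
            ["compound", "first_site", "phase"], sort=True):
        channels = {row["product"]: (row["spin"], float(row["cost"]))
                    for _, row in g.iterrows()}
        results.append(second_hat_from_costs(compound, phase, first_site, channels))
    return results
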