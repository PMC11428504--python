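"""Reaction energy profiles and conventional transition-state-theory rates.

A bimolecular H-abstraction R + •OH proceeds through a pre-reaction complex
(RC), a transition state (TS) and a post-reaction complex (PC) before the
separated products.  With Gibbs energies referenced to the RC, conventional
TST with a Wigner tunnelling factor gives

    k = σ · κ · (k_B·T / h) · exp(−ΔG‡ / R·T)
    κ = 1 + (1/24) · (h·c·ν̃ / (k_B·T))²

where σ is the reaction-path degeneracy, ν̃ the magnitude of the TS imaginary
wavenumber (cm⁻¹), and ΔG‡ = G(TS) − G(RC) in kcal/mol.  Gibbs energies are
assumed to be at the 1 M standard state already, which makes the bimolecular
rate constant directly comparable in M⁻¹ s⁻¹; for inputs at the 1 atm gas
standard state an opt-in RT·ln(R′T) correction is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import CODATA, DEFAULT_TEMPERATURE, normalize_phase
from .errors import InvalidInputError, NotComputableError, PhaseMismatchError
from .species import (
    CO_REACTANT,
    PARENT,
    POST_COMPLEX,
    PRE_COMPLEX,
    PRODUCT,
    TRANSITION_STATE,
    Species,
)

RC = "rc"
TS = "ts"
PC = "pc"
REACTANTS = "reactants"
PRODUCTS = "products"


@dataclass(frozen=True)
class PESProfile:
    """Gibbs-energy profile of one reaction on a common absolute reference.

    ``gibbs`` maps station → absolute Gibbs energy (kcal/mol); RC and TS are
    mandatory, separated reactants/products optional.  ``relative`` re-zeroes
    every station on the RC.  A TS below the RC marks the profile barrierless
    instead of raising.
    """

    reaction_id: str
    phase: str
    gibbs: dict
    temperature: float = DEFAULT_TEMPERATURE
    imaginary_wavenumber: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "phase", normalize_phase(self.phase))
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive")
        g = dict(self.gibbs)
        for station in (RC, TS):
            if station not in g or g[station] is None:
                raise InvalidInputError(
                    f"profile {self.reaction_id!r} lacks the mandatory {station.upper()} station")
        for station, v in g.items():
            if v is not None and not math.isfinite(float(v)):
                raise InvalidInputError(f"non-finite Gibbs energy at {station!r}")
        object.__setattr__(self, "gibbs", g)

    @property
    def barrierless(self) -> bool:
        return self.gibbs[TS] < self.gibbs[RC]

    @property
    def relative(self) -> dict:
        ref = self.gibbs[RC]
        return {k: (None if v is None else v - ref) for k, v in self.gibbs.items()}


def build_pes(species_list, reaction_id=None, temperature=DEFAULT_TEMPERATURE) -> PESProfile:
    """Assemble a :class:`PESProfile` from the species of one reaction.

    Roles map onto stations: pre_complex → RC, transition_state → TS,
    post_complex → PC; parent + co_reactant Gibbs energies (both required if
    either is present) sum to the separated reactants, product records sum to
    the separated products.  All species must share one phase and carry Gibbs
    energies.
    """
    species = list(species_list)
    if not species:
        raise InvalidInputError("no species supplied")
    phases = {sp.phase for sp in species}
    if len(phases) > 1:
        raise PhaseMismatchError(f"species span several phases: {sorted(phases)}")
    by_role: dict[str, list[Species]] = {}
    for sp in species:
        if sp.gibbs is None:
            raise InvalidInputError(
                f"species {sp.compound!r} (role {sp.role}) lacks a Gibbs energy")
        by_role.setdefault(sp.role, []).append(sp)
    for station, role in ((RC, PRE_COMPLEX), (TS, TRANSITION_STATE)):
        if role not in by_role:
            raise InvalidInputError(f"reaction lacks a {role} species")
        if len(by_role[role]) > 1:
            raise InvalidInputError(f"reaction has several {role} species")
    ts = by_role[TRANSITION_STATE][0]
    gibbs = {
        RC: by_role[PRE_COMPLEX][0].gibbs,
        TS: ts.gibbs,
        PC: by_role[POST_COMPLEX][0].gibbs if POST_COMPLEX in by_role else None,
        REACTANTS: None,
        PRODUCTS: None,
    }
    if PARENT in by_role or CO_REACTANT in by_role:
        gibbs[REACTANTS] = (sum(sp.gibbs for sp in by_role.get(PARENT, []))
                            + sum(sp.gibbs for sp in by_role.get(CO_REACTANT, [])))
    if PRODUCT in by_role:
        gibbs[PRODUCTS] = sum(sp.gibbs for sp in by_role[PRODUCT])
    rid = reaction_id or f"{ts.compound}" + (f"-{ts.site}" if ts.site else "")
    return PESProfile(reaction_id=rid, phase=ts.phase, gibbs=gibbs,
                      temperature=temperature,
                      imaginary_wavenumber=ts.imaginary_wavenumber)


def activation_free_energy(profile: PESProfile) -> float:
    """ΔG‡ = G(TS) − G(RC), kcal/mol (negative only for barrierless profiles)."""
    return profile.gibbs[TS] - profile.gibbs[RC]


def reaction_free_energy(profile: PESProfile, endpoint: str = PC) -> float:
    """ΔG = G(endpoint) − G(RC); endpoint ``'pc'`` (default) or ``'products'``."""
    if endpoint not in (PC, PRODUCTS, RC):
        raise InvalidInputError(f"unknown endpoint {endpoint!r}")
    g = profile.gibbs.get(endpoint)
    if g is None:
        raise NotComputableError(
            f"profile {profile.reaction_id!r} has no {endpoint!r} station")
    return g - profile.gibbs[RC]


def wigner_kappa(imaginary_wavenumber: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Wigner tunnelling factor κ = 1 + (1/24)·(h·c·ν̃ / k_B·T)² ≥ 1."""
    if not imaginary_wavenumber > 0:
        raise InvalidInputError("imaginary wavenumber must be positive (cm⁻¹ magnitude)")
    if not temperature > 0:
        raise InvalidInputError("temperature must be positive")
    u = (CODATA.planck * CODATA.speed_of_light_cm * imaginary_wavenumber
         / (CODATA.boltzmann * temperature))
    return 1.0 + u * u / 24.0


def standard_state_correction(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Opt-in ΔG correction (kcal/mol) from the 1 atm gas standard state to 1 M.

    RT·ln(R′T) with R′ in L·atm·mol⁻¹·K⁻¹; add it to a per-molecule ΔG‡ or ΔG
    of a bimolecular step whose inputs are at 1 atm.
    """
    r_latm = 0.082057366080960  # L·atm·mol⁻¹·K⁻¹
    return CODATA.gas_constant_kcal * temperature * math.log(r_latm * temperature)


def tst_rate(delta_g_activation: float, temperature: float = DEFAULT_TEMPERATURE,
             sigma: int = 1, kappa: float = 1.0) -> float:
    """Conventional TST rate constant σ·κ·(k_B·T/h)·exp(−ΔG‡/RT).

    Returned in s⁻¹; under the 1 M standard-state convention of the input
    Gibbs energies this is numerically the bimolecular constant in M⁻¹ s⁻¹.
    """
    if not temperature > 0:
        raise InvalidInputError("temperature must be positive")
    if not (isinstance(sigma, (int,)) and sigma >= 1):
        raise InvalidInputError("sigma must be a positive integer")
    if not kappa >= 1.0:
        raise InvalidInputError("kappa must be ≥ 1")
    if not math.isfinite(float(delta_g_activation)):
        raise InvalidInputError("delta_g_activation must be finite")
    prefactor = CODATA.boltzmann * temperature / CODATA.planck
    return (sigma * kappa * prefactor
            * math.exp(-float(delta_g_activation)
                       / (CODATA.gas_constant_kcal * temperature)))


@dataclass(frozen=True)
class RateResult:
    """TST rate and the quantities behind it for one reaction.

    σ and κ are always reported explicitly so no correction is applied
    silently; κ = 1 means no tunnelling correction was available or requested.
    """

    reaction_id: str
    delta_g_activation: float
    delta_g_reaction: float | None
    sigma: int
    kappa: float
    temperature: float
    rate_constant: float
    is_fastest: bool = False
    is_lowest_barrier: bool = False

    def __post_init__(self):
        if not self.rate_constant > 0:
            raise InvalidInputError("rate constant must be positive")
        if not self.kappa >= 1.0:
            raise InvalidInputError("kappa must be ≥ 1")


def rate_table(profiles, sigma_map=None, kappa_policy="wigner",
               endpoint: str = PC) -> list[RateResult]:
    """One :class:`RateResult` per profile, ranked by rate constant descending.

    ``sigma_map`` maps reaction id → path degeneracy (default 1 everywhere).
    ``kappa_policy='wigner'`` computes the Wigner factor from each profile's
    TS imaginary wavenumber when present (κ = 1 otherwise, reported as such);
    ``'unit'`` forces κ = 1.  The fastest and lowest-barrier reactions are
    flagged on the returned records.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("no profiles supplied")
    if kappa_policy not in ("wigner", "unit"):
        raise InvalidInputError(f"unknown kappa policy {kappa_policy!r}")
    sigma_map = dict(sigma_map or {})
    results = []
    for profile in profiles:
        dg_act = activation_free_energy(profile)
        try:
            dg_rxn = reaction_free_energy(profile, endpoint)
        except NotComputableError:
            dg_rxn = None
        sigma = int(sigma_map.get(profile.reaction_id, 1))
        kappa = 1.0
        if kappa_policy == "wigner" and profile.imaginary_wavenumber is not None:
            kappa = wigner_kappa(profile.imaginary_wavenumber, profile.temperature)
        k = tst_rate(dg_act, profile.temperature, sigma=sigma, kappa=kappa)
        results.append(RateResult(
            reaction_id=profile.reaction_id, delta_g_activation=dg_act,
            delta_g_reaction=dg_rxn, sigma=sigma, kappa=kappa,
            temperature=profile.temperature, rate_constant=k))
    results.sort(key=lambda r: -r.rate_constant)
    k_max = max(r.rate_constant for r in results)
    dg_min = min(r.delta_g_activation for r in results)
    return [
        RateResult(**{**r.__dict__,
                      "is_fastest": r.rate_constant == k_max,
                      "is_lowest_barrier": r.delta_g_activation == dg_min})
        for r in results
    ]


def load_table2():
    """Bundled transcription of the published kinetics table: ΔG and ΔG‡ (kcal/mol,
    RC-referenced) and the printed rate constant as a reference column."""
    import pandas as pd
    from importlib.resources import files

    with open(str(files("radscav.data") / "table2_kinetics.csv"), encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def check_rank_consistency(delta_g_activation, reference_rates) -> bool:
    """True when ordering by reference rate (descending) matches ordering by
    barrier (ascending) — the internal-consistency check the pipeline asserts
    on the bundled kinetics fixture."""
    pairs = list(zip(delta_g_activation, reference_rates))
    by_rate = sorted(pairs, key=lambda p: -p[1])
    by_barrier = sorted(pairs, key=lambda p: p[0])
    return by_rate == by_barrier
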