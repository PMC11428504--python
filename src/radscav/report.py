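"""End-to-end analysis orchestration and report rendering.

``run_full_analysis`` ties the stages together — descriptor table (computed
from a species table, or loaded pre-computed), Hess-closure audit, per-phase
composite constants, mechanism verdicts, rankings, solvent shifts, the
double-HAT second step, and the kinetics table — and returns an
:class:`AnalysisReport` whose machine-readable form is byte-stable across
reruns with the same inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .constants import (
    DEFAULT_TEMPERATURE,
    load_reference_enthalpies,
    reference_constant,
)
from .descriptors import (
    DescriptorTable,
    PRINTED_CLOSURE_TOL,
    check_hess_closure,
    load_descriptor_table,
    load_table1,
    load_bde_ranking_fixture,
    round_half_away,
)
from .errors import InvalidInputError, NotComputableError, RadScavError
from .kinetics import check_rank_consistency, load_table2, tst_rate, wigner_kappa
from .mechanism import (
    classify_mechanism,
    load_double_hat_fixture,
    min_site,
    rank_compounds,
    solvent_shift_summary,
)
from .species import load_species_table
from .descriptors import build_descriptor_table


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one analysis run.

    ``species_path`` (a per-species thermochemistry table) and
    ``descriptor_path`` (a pre-computed descriptor table) are alternatives;
    with neither, the bundled printed-table fixtures are analysed.
    """

    species_path: str | None = None
    descriptor_path: str | None = None
    kinetics_path: str | None = None
    refs_path: str | None = None
    phases: tuple = ()
    temperature: float = DEFAULT_TEMPERATURE
    sigma: int = 1
    kappa_policy: str = "wigner"  # 'wigner' | 'unit'
    closure_tolerance: float = PRINTED_CLOSURE_TOL
    seed: int = 0

    def __post_init__(self):
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive")
        if self.kappa_policy not in ("wigner", "unit"):
            raise InvalidInputError(f"unknown kappa policy {self.kappa_policy!r}")
        if self.species_path and self.descriptor_path:
            raise InvalidInputError(
                "give either a species table or a descriptor table, not both")

    def hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in sorted(self.__dict__.items())},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Aggregated stage outputs plus provenance; see ``to_dict`` for the schema."""

    descriptor_table: DescriptorTable
    closure_report: pd.DataFrame
    composite_constants: dict
    verdicts: list
    rankings: list
    solvent_shifts: list
    double_hat: list
    kinetics: pd.DataFrame | None
    kinetics_recomputed: list
    kinetics_rank_consistent: bool | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "composite_constants": self.composite_constants,
            "closure": {
                "n_rows": int(len(self.closure_report)),
                "max_abs_splet_minus_setpt": (
                    float(self.closure_report["splet_minus_setpt"].abs().max())
                    if len(self.closure_report) else None),
                "n_flagged": int(self.closure_report["flagged"].sum())
                if len(self.closure_report) else 0,
            },
            "verdicts": [
                {"compound": v.compound, "phase": v.phase, "mechanism": v.mechanism,
                 "min_bde": list(v.min_bde), "ip": v.ip, "min_pa": list(v.min_pa),
                 "tie": v.tie}
                for v in self.verdicts
            ],
            "rankings": [
                {"descriptor": r.descriptor, "site": r.site, "phase": r.phase,
                 "ranked": [[c, val] for c, val in r.ranked],
                 "unranked": list(r.unranked), "source": src}
                for r, src in self.rankings
            ],
            "solvent_shifts": [
                {"descriptor": s.descriptor, "from": s.phase_a, "to": s.phase_b,
                 "mean": round_half_away(s.mean, 1),
                 "per_compound": {c: round_half_away(v, 1)
                                  for c, v in sorted(s.per_compound.items())}}
                for s in self.solvent_shifts
            ],
            "double_hat": [
                {"compound": r.compound, "phase": r.phase, "first_site": r.first_site,
                 "channels": {name: {"spin": spin, "cost": cost}
                              for name, (spin, cost) in sorted(r.channels.items())},
                 "favored": r.favored}
                for r in self.double_hat
            ],
            "kinetics": None if self.kinetics is None else {
                "rows": self.kinetics.to_dict(orient="records"),
                "rank_consistent": self.kinetics_rank_consistent,
                "recomputed": self.kinetics_recomputed,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          ensure_ascii=False) + "\n"


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the whole pipeline under ``config``; deterministic given inputs."""
    refs = load_reference_enthalpies(config.refs_path)
    refs_source = config.refs_path or "bundled default (composite-anchored)"

    if config.species_path:
        species = load_species_table(config.species_path)
        if not len(species):
            raise RadScavError("stage species_model: species table is empty")
        table = build_descriptor_table(species, refs)
        table_source = config.species_path
    elif config.descriptor_path:
        table = load_descriptor_table(config.descriptor_path, refs_used=refs)
        table_source = config.descriptor_path
    else:
        table = load_table1(refs)
        table_source = "bundled descriptor-table fixture"
    if not len(table.records):
        raise RadScavError("stage descriptors: no descriptor rows could be formed")

    phases = list(config.phases) or table.phases()

    try:
        closure = check_hess_closure(table, tolerance=config.closure_tolerance)
    except NotComputableError:
        closure = pd.DataFrame(columns=["compound", "site", "phase",
                                        "splet_minus_setpt",
                                        "setpt_minus_bde_minus_c", "flagged"])

    composite = {}
    frame = table.to_frame()
    for phase in phases:
        sub = frame[(frame.phase == phase)
                    & frame[["bde", "ip", "pde"]].notna().all(axis=1)]
        entry = {"reference_constant": reference_constant(refs[phase])
                 if phase in refs else None}
        if len(sub):
            c = sub.ip + sub.pde - sub.bde
            entry.update({"table_mean": float(c.mean()),
                          "table_range": float(c.max() - c.min()),
                          "n_rows": int(len(sub))})
        composite[phase] = entry

    verdicts = []
    for phase in phases:
        for compound in table.compounds():
            try:
                verdicts.append(classify_mechanism(table, compound, phase))
            except NotComputableError:
                pass

    rankings = []
    for phase in phases:
        try:
            rankings.append((rank_compounds(table, "bde", "4'-OH", phase),
                             table_source))
        except (NotComputableError, RadScavError):
            pass
    if config.descriptor_path is None and config.species_path is None:
        rankings.append((rank_compounds(load_bde_ranking_fixture(), "bde",
                                        "4'-OH", "gas"),
                         "bundled text-quoted ranking fixture"))

    shifts = []
    for other in phases:
        if other == "gas" or "gas" not in phases:
            continue
        try:
            shifts.append(solvent_shift_summary(table, "ip", "gas", other))
        except NotComputableError:
            pass

    double_hat = load_double_hat_fixture() if (config.species_path is None
                                               and config.descriptor_path is None) else []

    kin = None
    rank_ok = None
    recomputed = []
    if config.kinetics_path or (config.species_path is None
                                and config.descriptor_path is None):
        kin = (pd.read_csv(config.kinetics_path, comment="#")
               if config.kinetics_path else load_table2())
        if {"delta_g_activation", "k_ref"}.issubset(kin.columns):
            rank_ok = check_rank_consistency(kin.delta_g_activation.tolist(),
                                             kin.k_ref.tolist())
        for _, row in kin.iterrows():
            kappa = 1.0
            if (config.kappa_policy == "wigner"
                    and "imag_wavenumber" in kin.columns
                    and not pd.isna(row.get("imag_wavenumber"))):
                kappa = wigner_kappa(float(row["imag_wavenumber"]), config.temperature)
            recomputed.append({
                "reaction_id": row["reaction_id"],
                "delta_g_activation": float(row["delta_g_activation"]),
                "sigma": config.sigma, "kappa": kappa,
                "temperature": config.temperature,
                "rate_constant": tst_rate(float(row["delta_g_activation"]),
                                          config.temperature, sigma=config.sigma,
                                          kappa=kappa),
            })

    provenance = {
        "package": "radscav", "version": __version__,
        "config_hash": config.hash(),
        "descriptor_source": table_source,
        "reference_enthalpies": refs_source,
        "sigma_policy": f"sigma={config.sigma} (explicit, applied uniformly)",
        "kappa_policy": config.kappa_policy,
        "temperature_K": config.temperature,
        "seed": config.seed,
    }
    return AnalysisReport(
        descriptor_table=table, closure_report=closure,
        composite_constants=composite, verdicts=verdicts, rankings=rankings,
        solvent_shifts=shifts, double_hat=double_hat, kinetics=kin,
        kinetics_recomputed=recomputed, kinetics_rank_consistent=rank_ok,
        provenance=provenance)


def format_scientific(value: float) -> str:
    """``5.72e9 → '5.72 × 10^9'`` — the printed-table convention for rate constants."""
    if value == 0 or not math.isfinite(value):
        raise InvalidInputError("rate constant must be finite and non-zero")
    exponent = math.floor(math.log10(abs(value)))
    mantissa = value / 10 ** exponent
    mantissa = round(mantissa, 2)
    if abs(mantissa) >= 10:  # rounding pushed the mantissa out of [1, 10)
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.2f} × 10^{exponent}"


def render_tables(report: AnalysisReport, out_dir) -> list:
    """Write the report's tables and documents; byte-identical across reruns.

    Emits a one-decimal descriptor table, the kinetics table with rates in
    ``m.mm × 10^e`` notation, the machine-readable JSON report and a
    human-readable text report.  Returns the written paths.
    """
    import os

    os.makedirs(str(out_dir), exist_ok=True)
    written = []

    def _path(name):
        p = os.path.join(str(out_dir), name)
        written.append(p)
        return p

    df = report.descriptor_table.to_frame()
    for col in ("bde", "ip", "pde", "pa", "ete"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v)
                              else f"{round_half_away(v, 1):.1f}")
    df.to_csv(_path("descriptor_table.csv"), index=False)

    with open(_path("report.json"), "w", encoding="utf-8") as fh:
        fh.write(report.to_json())

    lines = ["radscav analysis report", "=" * 24, ""]
    lines.append("Provenance:")
    for k, v in sorted(report.provenance.items()):
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("Hess-closure audit:")
    if len(report.closure_report):
        lines.append(f"  rows checked: {len(report.closure_report)}; "
                     f"flagged: {int(report.closure_report['flagged'].sum())}; "
                     f"max |(IP+PDE)-(PA+ETE)|: "
                     f"{report.closure_report['splet_minus_setpt'].abs().max():.3f} kcal/mol")
    else:
        lines.append("  not computed")
    lines.append("")
    lines.append("Preferred mechanisms:")
    if report.verdicts:
        for v in report.verdicts:
            lines.append(f"  {v.compound:12s} {v.phase:8s} {v.mechanism:7s} "
                         f"(min BDE {v.min_bde[1]:.1f} @ {v.min_bde[0]}, "
                         f"IP {v.ip:.1f}, min PA {v.min_pa[1]:.1f} @ {v.min_pa[0]})")
    else:
        lines.append("  not computed")
    lines.append("")
    lines.append("Solvent shifts:")
    if report.solvent_shifts:
        for s in report.solvent_shifts:
            lines.append(f"  {s.descriptor.upper()} {s.phase_a}->{s.phase_b}: "
                         f"mean {round_half_away(s.mean, 1):.1f} kcal/mol")
    else:
        lines.append("  not computed")
    lines.append("")
    lines.append("Double-HAT second step:")
    if report.double_hat:
        for r in report.double_hat:
            chans = ", ".join(f"{n} {c:.1f}" for n, (_, c) in sorted(r.channels.items()))
            lines.append(f"  {r.compound} {r.phase} (first H from {r.first_site}): "
                         f"{chans} -> favored {r.favored}")
    else:
        lines.append("  not computed")
    lines.append("")
    lines.append("Kinetics:")
    if report.kinetics is not None:
        if "k_ref" in report.kinetics.columns:
            for _, row in report.kinetics.iterrows():
                lines.append(
                    f"  {row['reaction_id']:16s} dG {row['delta_g']:.1f}  "
                    f"dG# {row['delta_g_activation']:.1f}  "
                    f"k_ref {format_scientific(float(row['k_ref']))}")
        if report.kinetics_rank_consistent is not None:
            lines.append("  reference-rate ordering matches barrier ordering: "
                         f"{report.kinetics_rank_consistent}")
        for rec in report.kinetics_recomputed:
            lines.append(
                f"  {rec['reaction_id']:16s} plain TST k "
                f"(sigma={rec['sigma']}, kappa={rec['kappa']:.2f}): "
                f"{format_scientific(rec['rate_constant'])} M^-1 s^-1")
    else:
        lines.append("  not computed")
    lines.append("")
    with open(_path("report.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return written
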