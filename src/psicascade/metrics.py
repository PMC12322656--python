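"""Biocatalytic process metrics and the route-comparison table.

Metrics follow the conventions customary in process-chemistry reporting:

* conversion yield — mol product per mol substrate charged, in percent;
* productivity (space-time yield) — titer/time, reported both molar (mM/h)
  and mass-based (g/L/h), linked exactly by the product molar mass;
* mass-based TON — grams of product formed per gram of total enzyme used;
* E-factor — mass of waste per mass of product, a green-chemistry metric
  (enzyme production excluded by default, water included by default);
* scale-up volume — reaction volume needed for a target product mass at a
  given titer.

Mass metrics for the nucleotide product default to the anhydrous free acid
(324.18 g/mol); the disodium salt (368.15 g/mol) applies to gravimetric
yields of the isolated solid.  Both constants live in the constants table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .constants import get_constant
from .errors import InvalidInputError

__all__ = [
    "ReactionOutcome",
    "MassLedger",
    "RouteRecord",
    "conversion_yield",
    "productivity",
    "ton_mass_based",
    "e_factor",
    "scaleup_volume",
    "build_route_table",
    "preparative_ledger",
]

PSIMP_FREE_ACID = get_constant("psimp_free_acid_mass")
PSIMP_DISODIUM = get_constant("psimp_disodium_mass")

LEDGER_CATEGORIES = ("substrate", "water", "salt", "base", "enzyme")


@dataclass(frozen=True)
class ReactionOutcome:
    """Summary of one reaction run for metric computation."""

    substrate_in_mmol: float
    product_out_mmol: float
    titer_mM: float
    duration_h: float
    volume_L: float
    enzyme_load_g_per_L: float
    product_molar_mass: float = PSIMP_FREE_ACID

    def __post_init__(self) -> None:
        for name in ("substrate_in_mmol", "product_out_mmol", "titer_mM", "duration_h",
                     "volume_L", "enzyme_load_g_per_L", "product_molar_mass"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.product_out_mmol > self.substrate_in_mmol > 0:
            raise InvalidInputError("product cannot exceed substrate (1:1 stoichiometry)")


@dataclass(frozen=True)
class MassLedger:
    """Mass inventory of one run: (name, mass g, category) inputs and the
    isolated product mass."""

    inputs: tuple[tuple[str, float, str], ...]
    product_mass_g: float

    def __post_init__(self) -> None:
        for name, mass, category in self.inputs:
            if mass < 0:
                raise InvalidInputError(f"mass of {name!r} must be >= 0")
            if category not in LEDGER_CATEGORIES:
                raise InvalidInputError(
                    f"unknown category {category!r} for {name!r}; use one of {LEDGER_CATEGORIES}"
                )
        if self.product_mass_g <= 0:
            raise InvalidInputError("product mass must be > 0")


@dataclass
class RouteRecord:
    """One row of the route-comparison table."""

    identifier: str
    enzymes: tuple[str, ...]
    substrate: str
    product: str
    productivity_g_per_L_h: float
    productivity_mM_per_h: float
    ton_g_per_g: float
    enzyme_loading_g_per_L: float
    yield_percent: float
    purity_percent: float
    titer_mM: float
    e_factor: float
    auxiliaries: str
    product_molar_mass: float = PSIMP_FREE_ACID
    flags: list[str] = field(default_factory=list)


def conversion_yield(outcome: ReactionOutcome) -> float:
    """Molar conversion yield in percent (raw value; round for display)."""
    if outcome.substrate_in_mmol <= 0:
        raise InvalidInputError("substrate charge must be > 0")
    return 100.0 * outcome.product_out_mmol / outcome.substrate_in_mmol


def productivity(outcome: ReactionOutcome) -> tuple[float, float]:
    """(molar, mass) space-time yield: mM/h and g/L/h, linked by the product
    molar mass."""
    if outcome.duration_h <= 0:
        raise InvalidInputError("duration must be > 0")
    molar = outcome.titer_mM / outcome.duration_h
    mass = molar * outcome.product_molar_mass / 1000.0
    return molar, mass


def ton_mass_based(outcome: ReactionOutcome) -> float:
    """Grams of product per gram of enzyme: (titer·M/1000)/loading."""
    if outcome.enzyme_load_g_per_L <= 0:
        raise InvalidInputError("enzyme loading must be > 0")
    return outcome.titer_mM * outcome.product_molar_mass / 1000.0 / outcome.enzyme_load_g_per_L


def e_factor(
    ledger: MassLedger,
    include_water: bool = True,
    exclude_enzymes: bool = True,
) -> float:
    """(Σ counted input masses − product mass)/product mass, floored at 0.

    Default accounting counts water and excludes the enzymes (their
    production is outside the balance); both toggles are exposed because
    waste inventories differ between reports.
    """
    total = 0.0
    for _name, mass, category in ledger.inputs:
        if category == "water" and not include_water:
            continue
        if category == "enzyme" and exclude_enzymes:
            continue
        total += mass
    return max((total - ledger.product_mass_g) / ledger.product_mass_g, 0.0)


def scaleup_volume(target_product_mass_g: float, titer_mM: float,
                   product_molar_mass: float = PSIMP_FREE_ACID) -> float:
    """Reaction volume (L) required for a target product mass at a titer."""
    if titer_mM <= 0:
        raise InvalidInputError("titer must be > 0")
    if target_product_mass_g < 0:
        raise InvalidInputError("target mass must be >= 0")
    return target_product_mass_g / (titer_mM * product_molar_mass / 1000.0)


def preparative_ledger(
    substrate_g: float = 1.84,
    mncl2_g: float = 0.009,
    naoh_g: float = 0.02,
    enzyme_g: float = 0.015,
    final_volume_mL: float = 5.0,
    product_g: float = 1.60,
    water_by_difference: bool = True,
) -> MassLedger:
    """Mass ledger of the gram-scale run (1.0 M substrate in 5.0 mL).

    Water is counted by difference to the final volume at 1 g/mL density
    when ``water_by_difference`` (solutes displace water), otherwise as the
    full final volume — the two conventions bracket typical waste
    accountings.  The NaOH mass is the ~0.1 mL of 1 M titrant used for pH
    adjustment; enzyme mass is the summed protein charge.
    """
    solutes = substrate_g + mncl2_g + naoh_g
    water_g = final_volume_mL - solutes if water_by_difference else final_volume_mL
    if water_g < 0:
        raise InvalidInputError("solute masses exceed the final-volume water estimate")
    return MassLedger(
        inputs=(
            ("UMP disodium", substrate_g, "substrate"),
            ("MnCl2", mncl2_g, "salt"),
            ("NaOH", naoh_g, "base"),
            ("water", water_g, "water"),
            ("enzymes", enzyme_g, "enzyme"),
        ),
        product_mass_g=product_g,
    )


def _consistent(implied: float, printed: float, printed_unit: float = 1.0) -> bool:
    # printed values are rounded to their last digit; accept within half a unit
    return abs(implied - printed) <= 0.5 * printed_unit


def check_route_record(record: RouteRecord, printed_unit: float = 1.0) -> list[str]:
    """Consistency checks on one record; returns flag strings (empty = clean)."""
    flags: list[str] = []
    implied_mass_prod = record.productivity_mM_per_h * record.product_molar_mass / 1000.0
    if not _consistent(implied_mass_prod, record.productivity_g_per_L_h, printed_unit):
        flags.append(
            f"productivity pair inconsistent: {record.productivity_mM_per_h:g} mM/h implies "
            f"{implied_mass_prod:.1f} g/L/h, printed {record.productivity_g_per_L_h:g}"
        )
    if record.enzyme_loading_g_per_L > 0:
        implied_ton = (record.titer_mM * record.product_molar_mass / 1000.0
                       / record.enzyme_loading_g_per_L)
        if not _consistent(implied_ton, record.ton_g_per_g, printed_unit):
            flags.append(
                f"TON inconsistent: titer and loading imply {implied_ton:.1f} g/g, "
                f"printed {record.ton_g_per_g:g}"
            )
    return flags


def build_route_table(records: Sequence[RouteRecord]) -> pd.DataFrame:
    """Assemble the comparison table, annotating (never correcting) records
    whose derived fields disagree with the printed ones."""
    if len(records) == 0:
        raise InvalidInputError("need at least one route record")
    rows = []
    for rec in records:
        flags = check_route_record(rec)
        rec.flags = flags
        rows.append({
            "route": rec.identifier,
            "enzymes": "+".join(rec.enzymes),
            "substrate": rec.substrate,
            "product": rec.product,
            "productivity_g_per_L_h": rec.productivity_g_per_L_h,
            "productivity_mM_per_h": rec.productivity_mM_per_h,
            "TON_g_per_g": rec.ton_g_per_g,
            "enzyme_loading_g_per_L": rec.enzyme_loading_g_per_L,
            "yield_percent": rec.yield_percent,
            "purity_percent": rec.purity_percent,
            "titer_mM": rec.titer_mM,
            "E_factor": rec.e_factor,
            "auxiliaries": rec.auxiliaries,
            "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows)


def route_records_from_csv(path, molar_masses: dict[str, float] | None = None) -> list[RouteRecord]:
    """Read route records from a CSV mirroring the table's columns."""
    df = pd.read_csv(path)
    molar_masses = molar_masses or {}
    records = []
    for _, row in df.iterrows():
        records.append(RouteRecord(
            identifier=str(row["route"]),
            enzymes=tuple(str(row["enzymes"]).split("+")),
            substrate=str(row["substrate"]),
            product=str(row["product"]),
            productivity_g_per_L_h=float(row["productivity_g_per_L_h"]),
            productivity_mM_per_h=float(row["productivity_mM_per_h"]),
            ton_g_per_g=float(row["TON_g_per_g"]),
            enzyme_loading_g_per_L=float(row["enzyme_loading_g_per_L"]),
            yield_percent=float(row["yield_percent"]),
            purity_percent=float(row["purity_percent"]),
            titer_mM=float(row["titer_mM"]),
            e_factor=float(row["E_factor"]),
            auxiliaries=str(row.get("auxiliaries", "")),
            product_molar_mass=molar_masses.get(str(row["product"]), PSIMP_FREE_ACID),
        ))
    return records


def published_routes() -> list[RouteRecord]:
    """The four literature routes of the comparison table (products: Ψ uses
    its own molar mass, the nucleotide routes use the free acid)."""
    psi_mass = get_constant("pseudouridine_mass")
    return [
        RouteRecord("2", ("YjjG", "UP", "DeoB", "YeiN"), "UMP", "Psi",
                    18, 74, 22, 9.0, 80, 80, 800, 3.4, "Mn2+", psi_mass),
        RouteRecord("1", ("UP", "DeoB", "YeiN"), "U", "PsiMP",
                    30, 93, 74, 4.3, 97, 95, 970, 2.4, "Mn2+", PSIMP_FREE_ACID),
        RouteRecord("4", ("RbsK", "AcK", "YeiN"), "Rib+Ura", "PsiMP",
                    38, 117, 146, 2.0, 90, 70, 650, 43, "ATP, AcP, Mg2+", PSIMP_FREE_ACID),
        RouteRecord("5", ("RY", "YeiN"), "UMP", "PsiMP",
                    294, 906, 103, 3.0, 95, 95, 950, 3.0, "Mn2+", PSIMP_FREE_ACID),
    ]
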