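"""Module presence calling and metabolic role classification.

A module is called present in a genome when every KO requirement group of
the module is satisfied by at least one member KO from the genome (strict
all-of over groups, any-of within a group — the rule the nitrogenase module
makes explicit: all of *nifH*, *nifD*, *nifK* must be found).

The reductive-TCA status uses a three-slot rule: fumarate reductase (P35),
a 2-oxoglutarate:ferredoxin oxidoreductase (P37 or P42), and ATP-citrate
lyase (P40). All three slots → the genome can run the full cycle in the
carbon-fixing direction ("complete"); exactly two slots → "partial"
(possibly genuine truncation, possibly bin incompleteness); otherwise
"absent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

import pandas as pd

from .catalog import Catalog, ModuleDef

__all__ = [
    "RolePolicy",
    "RoleAssignment",
    "is_module_present",
    "build_presence_matrix",
    "classify_rtca",
    "assign_roles",
    "assign_roles_frame",
    "RTCA_SLOT_MODULES",
    "TRUNCATED_TCA_MODULES",
]

RTCA_SLOT_MODULES = ("P35", "P37", "P42", "P40")
TRUNCATED_TCA_MODULES = tuple(f"P{i}" for i in range(25, 34))  # P25..P33

ROLE_FLAGS = (
    "primary_producer",
    "ttca_consumer",
    "fermenter_PATACK",
    "formate_exporter",
    "nitrogen_fixer",
    "rgly_ser",
    "serine_deaminase",
    "glycine_reductase",
    "lactate_utilizer",
    "acl_bearer",
    "aspartate_utilizer",
    "fa_exporter",
    "malate_importer",
)


@dataclass(frozen=True)
class RolePolicy:
    """Tunable thresholds for role assignment.

    ``min_ttca`` — how many of the nine truncated-TCA modules (P25..P33) a
    genome must carry to count as a truncated-TCA consumer. The survey's
    wording ("carrying modules P25 to P33") is ambiguous between any-of and
    all-of; default 1 (any), with the all-of reading available as 9.
    """

    min_ttca: int = 1


def is_module_present(ko_set: Iterable[str], module: ModuleDef) -> bool:
    """True iff every KO group of *module* has ≥1 member in *ko_set*."""
    kos = ko_set if isinstance(ko_set, (set, frozenset)) else set(ko_set)
    return all(g.satisfied_by(kos) for g in module.requirement)


def build_presence_matrix(genomes, catalog: Catalog) -> pd.DataFrame:
    """Boolean genomes × modules presence matrix.

    *genomes* is a list of objects with ``genome_id`` and ``ko_set``
    attributes (or (genome_id, ko_set) pairs). Row/column order follows the
    input order; presence never depends on abundance.
    """
    ids: list[str] = []
    rows: list[list[bool]] = []
    for g in genomes:
        if hasattr(g, "genome_id"):
            gid, kos = g.genome_id, g.ko_set
        else:
            gid, kos = g
        kos = set(kos)
        ids.append(gid)
        rows.append([is_module_present(kos, m) for m in catalog.modules])
    return pd.DataFrame(rows, index=pd.Index(ids, name="genome_id"),
                        columns=catalog.module_ids, dtype=bool)


def classify_rtca(presence_row: pd.Series | dict) -> str:
    """Three-slot reductive-TCA status: ``complete`` / ``partial`` / ``absent``.

    Slots: s1 = P35, s2 = (P37 or P42), s3 = P40. Complete iff all three,
    partial iff exactly two, absent otherwise. Raises KeyError if the
    presence row was built against a catalog lacking any slot module.
    """
    missing = [m for m in RTCA_SLOT_MODULES if m not in presence_row]
    if missing:
        raise KeyError(f"presence row lacks rTCA slot modules: {missing}")
    s1 = bool(presence_row["P35"])
    s2 = bool(presence_row["P37"]) or bool(presence_row["P42"])
    s3 = bool(presence_row["P40"])
    n = s1 + s2 + s3
    if n == 3:
        return "complete"
    if n == 2:
        return "partial"
    return "absent"


def _has(row, module_id: str) -> bool:
    return module_id in row and bool(row[module_id])


def _formate_producing_modules(catalog: Catalog) -> list[str]:
    return [
        m.module_id
        for m in catalog.modules
        if not m.is_transporter and "formate" in m.products
    ]


@dataclass
class RoleAssignment:
    genome_id: str
    rtca_status: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.flags - set(ROLE_FLAGS)
        if unknown:
            raise ValueError(f"unknown role flags: {sorted(unknown)}")


def assign_roles(
    presence_row: pd.Series | dict,
    catalog: Catalog,
    policy: RolePolicy | None = None,
    genome_id: str = "",
) -> RoleAssignment:
    """Derive role flags for one genome from its presence row."""
    policy = policy or RolePolicy()
    rtca = classify_rtca(presence_row) if all(
        m in presence_row for m in RTCA_SLOT_MODULES
    ) else "absent"
    flags: set[str] = set()
    if rtca in ("complete", "partial"):
        flags.add("primary_producer")
    n_ttca = sum(_has(presence_row, m) for m in TRUNCATED_TCA_MODULES)
    if n_ttca >= policy.min_ttca and rtca != "complete":
        flags.add("ttca_consumer")
    if _has(presence_row, "P18") and _has(presence_row, "P19"):
        flags.add("fermenter_PATACK")
    formate_mods = _formate_producing_modules(catalog)
    if any(_has(presence_row, m) for m in formate_mods) and _has(presence_row, "P60"):
        flags.add("formate_exporter")
    if _has(presence_row, "PN6"):
        flags.add("nitrogen_fixer")
    if _has(presence_row, "P8") and _has(presence_row, "P9"):
        flags.add("rgly_ser")
    if _has(presence_row, "P14"):
        flags.add("serine_deaminase")
    if _has(presence_row, "P17"):
        flags.add("glycine_reductase")
    if _has(presence_row, "P15"):
        flags.add("lactate_utilizer")
    if _has(presence_row, "P40"):
        flags.add("acl_bearer")
    if _has(presence_row, "P29") or _has(presence_row, "P34"):
        flags.add("aspartate_utilizer")
    if _has(presence_row, "P51") and _has(presence_row, "P63"):
        flags.add("fa_exporter")
    if _has(presence_row, "P64") or _has(presence_row, "P65"):
        flags.add("malate_importer")
    return RoleAssignment(genome_id=genome_id, rtca_status=rtca, flags=flags)


def assign_roles_frame(
    presence: pd.DataFrame,
    catalog: Catalog,
    policy: RolePolicy | None = None,
) -> pd.DataFrame:
    """Role table: one row per genome, rtca_status plus one bool column per flag."""
    records = []
    for gid, row in presence.iterrows():
        ra = assign_roles(row, catalog, policy, genome_id=str(gid))
        rec = {"genome_id": gid, "rtca_status": ra.rtca_status}
        for f in ROLE_FLAGS:
            rec[f] = f in ra.flags
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    return out.set_index("genome_id") if records else pd.DataFrame(
        columns=["rtca_status", *ROLE_FLAGS]
    )


def rtca_truth_table() -> dict[tuple[bool, bool, bool, bool], str]:
    """Exhaustive slot-rule outcomes for all 16 {P35,P37,P42,P40} combinations."""
    out = {}
    for combo in product([False, True], repeat=4):
        row = dict(zip(RTCA_SLOT_MODULES, combo))
        out[combo] = classify_rtca(row)
    return out
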