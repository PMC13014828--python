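"""Metabolic module catalog: KO-defined modules, transporters, and compounds.

A *module* is a short pathway segment (IDs ``P1``..``P83`` for carbon
metabolism and transport, ``PN1``..``PN7`` for nitrogen acquisition) that
starts and/or ends at an exchangeable intermediate compound.  Each module is
defined by a list of KO requirement *groups*: the module is encoded by a
genome when every group is satisfied, and a group is satisfied by any one of
its member KOs (isoenzymes / alternative subunits).

The packaged full catalog (``data/catalog_fsgd_synthetic.tsv``) is a synthetic
reconstruction of the deep-groundwater module map: its category counts
(58 carbon-fixation modules containing 168 KOs, 25 intermediate-compound
transporters encoded by 39 KOs, 5 nitrogen-acquisition modules of 10 KOs)
and all module identifiers with a documented role are faithful to the
published survey, while KO memberships of modules whose exact gene content
was never printed are plausible stand-ins.  A small hand-written catalog
(``data/catalog_mini.tsv``) is packaged for tests.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "KO_PATTERN",
    "MODULE_ID_PATTERN",
    "PATHWAYS",
    "COMPOUND_VOCABULARY",
    "DIRECTIONS",
    "KoGroup",
    "ModuleDef",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "save_catalog",
    "catalog_to_json",
    "catalog_from_json",
    "catalog_summary",
    "validate_catalog",
    "packaged_catalog_path",
    "load_packaged_catalog",
]

KO_PATTERN = re.compile(r"^K\d{5}$")
MODULE_ID_PATTERN = re.compile(r"^PN?\d+$")

PATHWAYS = frozenset(
    {
        "rTCA",
        "WLP",
        "rGly_Ser",
        "CBB",
        "3HP",
        "PAT_ACK",
        "dicarboxylate_hydroxybutyrate",
        "fermentation",
        "anaplerotic",
        "fatty_acid",
        "nitrogen",
        "transport",
    }
)

DIRECTIONS = frozenset({"import", "export", "bidirectional", "none"})

#: Controlled vocabulary of exchangeable compounds. Matching is
#: case-insensitive; canonical spelling is the one listed here.
COMPOUND_VOCABULARY = (
    "formate",
    "acetate",
    "acetyl-CoA",
    "pyruvate",
    "lactate",
    "malate",
    "fumarate",
    "succinate",
    "citrate",
    "OAA",
    "2OG",
    "glycine",
    "serine",
    "aspartate",
    "glutamate",
    "glutamine",
    "malonyl-CoA",
    "fatty-acid",
    "ammonium",
    "nitrate",
    "nitrite",
    "N2",
)

_CANONICAL = {c.lower(): c for c in COMPOUND_VOCABULARY}


class CatalogError(ValueError):
    """Raised on malformed or inconsistent catalog input."""


def canonical_compound(name: str) -> str:
    """Return the canonical spelling of *name*, case-insensitively.

    Raises :class:`CatalogError` for names outside the vocabulary.
    """
    key = name.strip().lower()
    if key not in _CANONICAL:
        raise CatalogError(f"unknown compound: {name!r}")
    return _CANONICAL[key]


@dataclass(frozen=True)
class KoGroup:
    """One requirement group; satisfied by any one member KO."""

    members: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise CatalogError("KoGroup must be non-empty")

    def satisfied_by(self, ko_set: Iterable[str]) -> bool:
        kos = ko_set if isinstance(ko_set, (set, frozenset)) else set(ko_set)
        return not self.members.isdisjoint(kos)


@dataclass(frozen=True)
class ModuleDef:
    """A metabolic module: ALL groups required, ANY member within a group."""

    module_id: str
    name: str
    pathway: str
    requirement: tuple[KoGroup, ...]
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    direction: str = "none"

    @property
    def kos(self) -> frozenset[str]:
        """Union of member KOs over all requirement groups."""
        out: set[str] = set()
        for g in self.requirement:
            out |= g.members
        return frozenset(out)

    @property
    def is_transporter(self) -> bool:
        return self.pathway == "transport"

    @property
    def is_nitrogen(self) -> bool:
        return self.module_id.startswith("PN")

    def compounds(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)


@dataclass
class Catalog:
    """An ordered collection of module definitions plus compound vocabulary."""

    modules: list[ModuleDef]
    compounds: frozenset[str] = field(default_factory=lambda: frozenset(COMPOUND_VOCABULARY))
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.module_id in seen:
                raise CatalogError(f"duplicate module_id: {m.module_id}")
            seen.add(m.module_id)
        self._by_id = {m.module_id: m for m in self.modules}

    def __len__(self) -> int:
        return len(self.modules)

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._by_id

    def __getitem__(self, module_id: str) -> ModuleDef:
        return self._by_id[module_id]

    def get(self, module_id: str) -> ModuleDef | None:
        return self._by_id.get(module_id)

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return (
            self.modules == other.modules
            and self.compounds == other.compounds
            and self.version == other.version
        )


# ---------------------------------------------------------------------------
# TSV dialect
#
# Tab-separated, one row per module. Columns: module_id, name, pathway,
# ko_groups (groups "|"-separated, members ";"-separated), substrates,
# products (";"-separated compound names), direction.
# ---------------------------------------------------------------------------

_COLUMNS = ["module_id", "name", "pathway", "ko_groups", "substrates", "products", "direction"]


def _parse_groups(cell: str, row_label: str) -> tuple[KoGroup, ...]:
    cell = cell.strip()
    if not cell:
        raise CatalogError(f"{row_label}: empty ko_groups")
    groups: list[KoGroup] = []
    for chunk in cell.split("|"):
        members = []
        for tok in chunk.split(";"):
            tok = tok.strip()
            if not tok:
                continue
            if not KO_PATTERN.match(tok):
                raise CatalogError(f"{row_label}: malformed KO token {tok!r}")
            members.append(tok)
        if not members:
            raise CatalogError(f"{row_label}: empty KO group")
        groups.append(KoGroup(frozenset(members)))
    return tuple(groups)


def _parse_compounds(cell: str, row_label: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    out = []
    for tok in cell.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        try:
            out.append(canonical_compound(tok))
        except CatalogError as exc:
            raise CatalogError(f"{row_label}: {exc}") from exc
    return tuple(out)


def load_catalog(source: str | Path, version: str | None = None) -> Catalog:
    """Load and validate a catalog from its TSV serialization.

    Row order is preserved; a duplicate ``module_id`` or any malformed KO
    token or unknown compound raises :class:`CatalogError` naming the row.
    """
    path = Path(source)
    lines = path.read_text().splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty file (header required)")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise CatalogError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in _COLUMNS}
    modules: list[ModuleDef] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        row_label = f"{path.name}:{lineno}"
        mid = cells[idx["module_id"]].strip()
        if not MODULE_ID_PATTERN.match(mid):
            raise CatalogError(f"{row_label}: bad module_id {mid!r}")
        pathway = cells[idx["pathway"]].strip()
        if pathway not in PATHWAYS:
            raise CatalogError(f"{row_label}: unknown pathway {pathway!r}")
        direction = cells[idx["direction"]].strip() or "none"
        if direction not in DIRECTIONS:
            raise CatalogError(f"{row_label}: unknown direction {direction!r}")
        modules.append(
            ModuleDef(
                module_id=mid,
                name=cells[idx["name"]].strip(),
                pathway=pathway,
                requirement=_parse_groups(cells[idx["ko_groups"]], row_label),
                substrates=_parse_compounds(cells[idx["substrates"]], row_label),
                products=_parse_compounds(cells[idx["products"]], row_label),
                direction=direction,
            )
        )
    cat = Catalog(modules=modules, version=version or path.stem)
    violations = validate_catalog(cat)
    if violations:
        raise CatalogError(
            "catalog failed validation: " + "; ".join(f"{m}:{r}" for m, r in violations)
        )
    return cat


def save_catalog(catalog: Catalog, dest: str | Path) -> Path:
    """Serialize *catalog* back to the TSV dialect (round-trips load_catalog)."""
    dest = Path(dest)
    rows = ["\t".join(_COLUMNS)]
    for m in catalog.modules:
        groups = "|".join(";".join(sorted(g.members)) for g in m.requirement)
        rows.append(
            "\t".join(
                [
                    m.module_id,
                    m.name,
                    m.pathway,
                    groups,
                    ";".join(m.substrates),
                    ";".join(m.products),
                    m.direction,
                ]
            )
        )
    dest.write_text("\n".join(rows) + "\n")
    return dest


def catalog_to_json(catalog: Catalog) -> str:
    obj = {
        "version": catalog.version,
        "compounds": sorted(catalog.compounds),
        "modules": [
            {
                "module_id": m.module_id,
                "name": m.name,
                "pathway": m.pathway,
                "requirement": [sorted(g.members) for g in m.requirement],
                "substrates": list(m.substrates),
                "products": list(m.products),
                "direction": m.direction,
            }
            for m in catalog.modules
        ],
    }
    return json.dumps(obj, indent=2)


def catalog_from_json(text: str) -> Catalog:
    obj = json.loads(text)
    modules = [
        ModuleDef(
            module_id=m["module_id"],
            name=m["name"],
            pathway=m["pathway"],
            requirement=tuple(KoGroup(frozenset(g)) for g in m["requirement"]),
            substrates=tuple(m["substrates"]),
            products=tuple(m["products"]),
            direction=m["direction"],
        )
        for m in obj["modules"]
    ]
    return Catalog(modules=modules, compounds=frozenset(obj["compounds"]), version=obj["version"])


# ---------------------------------------------------------------------------
# Summary and validation
# ---------------------------------------------------------------------------

def _category(m: ModuleDef) -> str:
    if m.is_nitrogen:
        return "nitrogen_transport" if m.is_transporter else "nitrogen"
    return "transporter" if m.is_transporter else "fixation"


def catalog_summary(catalog: Catalog) -> dict:
    """Per-category module and KO counts.

    ``*_kos`` is the distinct-KO tally (a KO shared by two modules counts
    once); ``*_kos_with_multiplicity`` sums per-module KO counts.
    """
    out: dict[str, int] = {}
    for cat_name in ("fixation", "transporter", "nitrogen", "nitrogen_transport"):
        mods = [m for m in catalog.modules if _category(m) == cat_name]
        distinct: set[str] = set()
        multi = 0
        for m in mods:
            kos = m.kos
            distinct |= kos
            multi += len(kos)
        out[f"{cat_name}_modules"] = len(mods)
        out[f"{cat_name}_kos"] = len(distinct)
        out[f"{cat_name}_kos_with_multiplicity"] = multi
    out["total_modules"] = len(catalog.modules)
    all_kos: set[str] = set()
    for m in catalog.modules:
        all_kos |= m.kos
    out["total_kos"] = len(all_kos)
    return out


def validate_catalog(catalog: Catalog) -> list[tuple[str, str]]:
    """Check type invariants; returns (module_id, rule) violation records.

    Violations are data, not exceptions; an empty list means the catalog is
    valid.
    """
    violations: list[tuple[str, str]] = []
    for m in catalog.modules:
        if not MODULE_ID_PATTERN.match(m.module_id):
            violations.append((m.module_id, "module_id pattern"))
        if m.pathway not in PATHWAYS:
            violations.append((m.module_id, "unknown pathway"))
        if not m.requirement:
            violations.append((m.module_id, "no KO groups"))
        for g in m.requirement:
            for ko in g.members:
                if not KO_PATTERN.match(ko):
                    violations.append((m.module_id, f"KO pattern: {ko}"))
        if m.pathway == "nitrogen" and not m.module_id.startswith("PN"):
            violations.append((m.module_id, "nitrogen module without PN prefix"))
        if m.is_transporter and m.direction == "none":
            violations.append((m.module_id, "transporter with direction none"))
        if not m.is_transporter and m.direction != "none":
            violations.append((m.module_id, "non-transporter with direction"))
        for c in m.compounds():
            if c not in catalog.compounds:
                violations.append((m.module_id, f"compound outside vocabulary: {c}"))
    return violations


# ---------------------------------------------------------------------------
# Packaged catalogs
# ---------------------------------------------------------------------------

def packaged_catalog_path(which: str = "full") -> Path:
    """Path of a packaged catalog: ``full`` (synthetic reconstruction of the
    groundwater module map) or ``mini`` (small test catalog)."""
    fname = {"full": "catalog_fsgd_synthetic.tsv", "mini": "catalog_mini.tsv"}[which]
    return Path(str(resources.files("modmet.data").joinpath(fname)))


def load_packaged_catalog(which: str = "full") -> Catalog:
    return load_catalog(packaged_catalog_path(which))
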