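"""Compound-mediated cross-feeding networks per borehole.

The graph is a typed multigraph over genome and compound nodes. Edge types:

* ``produce`` — genome → compound: a non-transport module the genome carries
  lists the compound among its products;
* ``consume`` — compound → genome: a non-transport module lists it among its
  substrates;
* ``import`` / ``export`` — transporter modules with the matching direction
  (``bidirectional`` transporters yield both edges);
* formate may additionally leave the cell by passive diffusion: producers of
  a configured "diffusive" compound get an export edge flagged
  ``mechanism=diffusion`` even without a transporter.

Every edge carries the module that justifies it and the borehole scope, and
means *could exchange* — genomic potential only (edge attribute
``evidence="genomic_potential"``), never observed flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .catalog import Catalog
from .presence import is_module_present

__all__ = [
    "DEFAULT_PUBLIC_GOODS",
    "DEFAULT_DIFFUSIVE",
    "ReciprocalPair",
    "producers_of",
    "consumers_of",
    "build_network",
    "reciprocal_pairs",
    "module_composition",
    "audit_edges",
    "edge_table",
    "write_graphml",
]

#: Compounds treated as community "public goods" by default.
DEFAULT_PUBLIC_GOODS = (
    "formate",
    "acetate",
    "lactate",
    "malate",
    "citrate",
    "aspartate",
    "fatty-acid",
)

#: Compounds allowed to leave the cell without a dedicated exporter.
DEFAULT_DIFFUSIVE = ("formate",)


def _check_compound(compound: str, catalog: Catalog) -> None:
    if compound not in catalog.compounds:
        raise KeyError(f"unknown compound {compound!r}")


def producers_of(compound: str, presence: pd.DataFrame, catalog: Catalog) -> set[str]:
    """Genomes carrying ≥1 metabolic (non-transport) module that lists
    *compound* among its products."""
    _check_compound(compound, catalog)
    out: set[str] = set()
    for m in catalog.modules:
        if m.is_transporter or compound not in m.products or m.module_id not in presence:
            continue
        out |= set(presence.index[presence[m.module_id]].astype(str))
    return out


def consumers_of(compound: str, presence: pd.DataFrame, catalog: Catalog) -> set[str]:
    """Genomes carrying a metabolic module with *compound* among its
    substrates, or an import-capable transporter for it."""
    _check_compound(compound, catalog)
    out: set[str] = set()
    for m in catalog.modules:
        if m.module_id not in presence:
            continue
        if m.is_transporter:
            relevant = compound in m.substrates and m.direction in ("import", "bidirectional")
        else:
            relevant = compound in m.substrates
        if relevant:
            out |= set(presence.index[presence[m.module_id]].astype(str))
    return out


def build_network(
    borehole_id: str,
    membership: list[str] | set[str],
    presence: pd.DataFrame,
    catalog: Catalog,
    taxonomy: dict[str, str] | None = None,
    compounds: tuple[str, ...] = DEFAULT_PUBLIC_GOODS,
    diffusive: tuple[str, ...] = DEFAULT_DIFFUSIVE,
) -> nx.MultiDiGraph:
    """Build the borehole's cross-feeding graph over *membership* genomes.

    Node/edge insertion order is sorted, so the graph is byte-reproducible.
    An empty membership yields an empty graph.
    """
    g = nx.MultiDiGraph(borehole=borehole_id, evidence="genomic_potential")
    taxonomy = taxonomy or {}
    members = sorted(str(x) for x in membership)
    compound_set = set(compounds)
    for c in sorted(compound_set):
        _check_compound(c, catalog)
        g.add_node(c, kind="compound")
    for gid in members:
        if gid not in presence.index:
            raise KeyError(f"genome {gid} has no presence row")
        g.add_node(gid, kind="genome", phylum=taxonomy.get(gid, "unclassified"))
    for gid in members:
        row = presence.loc[gid]
        diffusion_candidates: set[str] = set()
        for m in catalog.modules:
            if m.module_id not in presence.columns or not bool(row[m.module_id]):
                continue
            attrs = dict(module_id=m.module_id, borehole=borehole_id,
                         evidence="genomic_potential")
            if m.is_transporter:
                for c in m.substrates:
                    if c not in compound_set:
                        continue
                    if m.direction in ("import", "bidirectional"):
                        g.add_edge(c, gid, edge_type="import", compound=c,
                                   mechanism="transporter", **attrs)
                    if m.direction in ("export", "bidirectional"):
                        g.add_edge(gid, c, edge_type="export", compound=c,
                                   mechanism="transporter", **attrs)
            else:
                for c in m.products:
                    if c in compound_set:
                        g.add_edge(gid, c, edge_type="produce", compound=c, **attrs)
                        if c in diffusive:
                            diffusion_candidates.add((c, m.module_id))
                for c in m.substrates:
                    if c in compound_set:
                        g.add_edge(c, gid, edge_type="consume", compound=c, **attrs)
        for c, mid in sorted(diffusion_candidates):
            g.add_edge(gid, c, edge_type="export", compound=c, module_id=mid,
                       borehole=borehole_id, mechanism="diffusion",
                       evidence="genomic_potential")
    return g


@dataclass(frozen=True)
class ReciprocalPair:
    """Two genomes exchanging in both directions via (possibly different)
    compounds, with the module evidence per direction."""

    genome_a: str
    genome_b: str
    compound_ab: str
    compound_ba: str
    modules_ab: tuple[str, ...]
    modules_ba: tuple[str, ...]


def _give_take(graph: nx.MultiDiGraph):
    """Per-compound producer/consumer maps with supporting modules.

    gives[c][genome] / takes[c][genome] → set of module ids justifying that
    the genome can release / take up compound c.
    """
    gives: dict[str, dict[str, set[str]]] = {}
    takes: dict[str, dict[str, set[str]]] = {}
    for u, v, d in graph.edges(data=True):
        t = d.get("edge_type")
        c = d.get("compound")
        if t in ("produce", "export"):
            gives.setdefault(c, {}).setdefault(u, set()).add(d["module_id"])
        elif t in ("consume", "import"):
            takes.setdefault(c, {}).setdefault(v, set()).add(d["module_id"])
    return gives, takes


def reciprocal_pairs(graph: nx.MultiDiGraph) -> list[ReciprocalPair]:
    """Unordered genome pairs with exchange chains in both directions.

    A chain a→c1→b exists when a can release c1 (produce or export edge) and
    b can take it up (consume or import edge). A pair qualifies when chains
    exist both ways with c1 ≠ c2 or differing supporting modules (the same
    compound through the identical module set is not reciprocity). One
    record per pair, with the lexicographically smallest qualifying
    (compound_ab, compound_ba) as representative evidence.
    """
    gives, takes = _give_take(graph)
    # ordered exchange routes: (a, b) -> {compound: source-side modules}
    routes: dict[tuple[str, str], dict[str, tuple[str, ...]]] = {}
    for c in gives:
        if c not in takes:
            continue
        for ga, mods in gives[c].items():
            for gb in takes[c]:
                if gb != ga:
                    routes.setdefault((ga, gb), {})[c] = tuple(sorted(mods))
    out: list[ReciprocalPair] = []
    for a, b in sorted(routes):
        if a >= b or (b, a) not in routes:
            continue
        found = None
        for c1 in sorted(routes[(a, b)]):
            for c2 in sorted(routes[(b, a)]):
                if c1 == c2 and set(routes[(a, b)][c1]) == set(routes[(b, a)][c2]):
                    continue
                found = (c1, c2)
                break
            if found:
                break
        if found:
            c1, c2 = found
            out.append(
                ReciprocalPair(
                    genome_a=a, genome_b=b, compound_ab=c1, compound_ba=c2,
                    modules_ab=routes[(a, b)][c1], modules_ba=routes[(b, a)][c2],
                )
            )
    return out


def module_composition(
    module_id: str,
    membership: list[str] | set[str],
    presence: pd.DataFrame,
    taxonomy: dict[str, str],
) -> dict[str, int]:
    """Phylum → carrier count for one module among the borehole's members."""
    if module_id not in presence.columns:
        raise KeyError(f"module {module_id} not in presence matrix")
    out: dict[str, int] = {}
    for gid in sorted(str(x) for x in membership):
        if gid in presence.index and bool(presence.loc[gid, module_id]):
            ph = taxonomy.get(gid, "unclassified")
            out[ph] = out.get(ph, 0) + 1
    return out


def audit_edges(graph: nx.MultiDiGraph, presence: pd.DataFrame, catalog: Catalog) -> list[str]:
    """Edge-soundness audit: re-check that every edge's justifying module is
    genuinely present in its genome. Returns human-readable violations."""
    problems: list[str] = []
    genome_nodes = {n for n, d in graph.nodes(data=True) if d.get("kind") == "genome"}
    for u, v, d in graph.edges(data=True):
        genome = u if u in genome_nodes else v
        mid = d.get("module_id")
        mod = catalog.get(mid) if mid else None
        if mod is None:
            problems.append(f"edge {u}->{v}: unknown module {mid}")
            continue
        if genome not in presence.index:
            problems.append(f"edge {u}->{v}: genome {genome} missing from presence")
            continue
        # independent re-evaluation would need KO sets; presence row re-check:
        if not bool(presence.loc[genome, mid]):
            problems.append(f"edge {u}->{v}: module {mid} absent in {genome}")
    return problems


def edge_table(graph: nx.MultiDiGraph) -> pd.DataFrame:
    """Typed edge list (src, dst, edge_type, compound, module_id, borehole,
    mechanism, evidence) in deterministic order."""
    rows = [
        {
            "src": u,
            "dst": v,
            "edge_type": d.get("edge_type"),
            "compound": d.get("compound"),
            "module_id": d.get("module_id"),
            "borehole": d.get("borehole"),
            "mechanism": d.get("mechanism", "enzymatic"),
            "evidence": d.get("evidence"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["src", "dst", "edge_type", "compound",
                                     "module_id", "borehole", "mechanism", "evidence"])
    return df.sort_values(list(df.columns)).reset_index(drop=True)


def write_graphml(graph: nx.MultiDiGraph, path) -> None:
    nx.write_graphml(graph, path)
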