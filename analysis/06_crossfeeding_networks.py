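#!/usr/bin/env python
"""Per-borehole cross-feeding networks over the public-goods compounds.

Restricts the presence matrix to each borehole's detected members, builds
the typed produce/consume/import/export multigraph, audits edge soundness,
mines reciprocal exchange pairs, and tabulates the phylum composition of
module carriers. Writes edge lists, GraphML files, and composition tables
under results/networks/.
"""

from pathlib import Path

import pandas as pd

from modmet.abundance import AbundanceTable
from modmet.catalog import load_packaged_catalog
from modmet.ingest import read_genome_metadata, read_sample_metadata, parse_taxonomy
from modmet.network import (audit_edges, build_network, edge_table,
                            module_composition, reciprocal_pairs, write_graphml)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = load_packaged_catalog("full")
    comm = RESULTS / "community"
    presence = pd.read_csv(RESULTS / "presence_matrix.tsv", sep="\t",
                           index_col=0).astype(bool)
    table = AbundanceTable(
        tpm=pd.read_csv(comm / "tpm.tsv", sep="\t", index_col=0),
        sample_meta=read_sample_metadata(comm / "sample_metadata.tsv"),
    )
    meta = read_genome_metadata(comm / "genome_metadata.tsv")
    taxonomy = {str(g): parse_taxonomy(t).get("phylum", "unclassified")
                for g, t in meta["taxonomy"].items()}
    outdir = RESULTS / "networks"
    outdir.mkdir(parents=True, exist_ok=True)
    comp_rows = []
    for bh in table.boreholes:
        membership = [g for g in table.members(bh) if g in presence.index]
        graph = build_network(bh, membership, presence, catalog, taxonomy)
        assert audit_edges(graph, presence, catalog) == []
        edge_table(graph).to_csv(outdir / f"edges_{bh}.tsv", sep="\t", index=False)
        write_graphml(graph, outdir / f"network_{bh}.graphml")
        pairs = reciprocal_pairs(graph)
        for mid in ("P32", "P40", "P15", "P19"):
            for phylum, count in sorted(
                module_composition(mid, membership, presence, taxonomy).items()
            ):
                comp_rows.append({"borehole_id": bh, "module_id": mid,
                                  "phylum": phylum, "carriers": count})
        print(f"  {bh}: {len(membership)} members, "
              f"{graph.number_of_edges()} edges, "
              f"{len(pairs)} reciprocal genome pairs")
    pd.DataFrame(comp_rows).to_csv(outdir / "module_composition.tsv", sep="\t",
                                   index=False)


if __name__ == "__main__":
    main()
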