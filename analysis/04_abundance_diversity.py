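#!/usr/bin/env python
"""Abundance structure: Shannon-Wiener diversity per borehole, population
sizes, and TPM abundance per 1-Mb genome-size category.

Reads the TPM table and sample metadata from 01, computes per-borehole
diversity (membership = nonzero TPM in >=1 sample), each genome's
population size (mean log10 nonzero TPM), and the pooled mean nonzero TPM
per EGS category. Writes three tables under results/.
"""

from pathlib import Path

import pandas as pd

from modmet.abundance import (AbundanceTable, diversity_table,
                              interval_abundance, population_size)
from modmet.binning import egs_categories
from modmet.ingest import (build_genome_records, read_annotations,
                           read_genome_metadata, read_quality,
                           read_sample_metadata)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    comm = RESULTS / "community"
    table = AbundanceTable(
        tpm=pd.read_csv(comm / "tpm.tsv", sep="\t", index_col=0),
        sample_meta=read_sample_metadata(comm / "sample_metadata.tsv"),
    )
    genomes = build_genome_records(
        read_genome_metadata(comm / "genome_metadata.tsv"),
        read_quality(comm / "quality.tsv"),
        read_annotations(comm / "annotations.emapper.annotations.tsv"),
    )
    div = diversity_table(table)
    div.to_csv(RESULTS / "diversity.tsv", sep="\t", index=False, na_rep="NA")
    for _, row in div.iterrows():
        print(f"  {row.borehole_id}: richness {row.richness}, "
              f"H = {row.shannon_nats:.3f} nats")

    pop_rows = [
        {"genome_id": g, "borehole_id": bh,
         "population_size": population_size(g, bh, table)}
        for bh in table.boreholes for g in table.members(bh)
    ]
    pd.DataFrame(pop_rows).to_csv(RESULTS / "population_size.tsv", sep="\t",
                                  index=False, na_rep="NA")

    egs = pd.Series({g.genome_id: g.egs_bp / 1e6 for g in genomes})
    cats = egs_categories(egs)
    rows = [
        {"borehole_id": bh, "egs_category": c,
         "egs_lo_mb": 0.6 + c, "egs_hi_mb": 1.6 + c,
         "mean_nonzero_tpm": interval_abundance(bh, c, cats, table)}
        for bh in table.boreholes for c in range(10)
    ]
    iv = pd.DataFrame(rows)
    iv.to_csv(RESULTS / "interval_abundance.tsv", sep="\t", index=False,
              na_rep="NA")
    deepest = table.boreholes[-1]
    top = iv[iv.borehole_id == deepest].nlargest(1, "mean_nonzero_tpm").iloc[0]
    print(f"  {deepest}: abundance peaks in EGS category {int(top.egs_category)} "
          f"({top.egs_lo_mb:.1f}-{top.egs_hi_mb:.1f} Mb)")


if __name__ == "__main__":
    main()
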