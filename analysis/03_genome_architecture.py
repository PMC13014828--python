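#!/usr/bin/env python
"""Genome architecture: GC-EGS correlation and module prevalence by bin.

Computes the completeness-corrected estimated genome size for every genome,
the GC-EGS Pearson correlation, and module prevalence across five GC bins
(25-75 %) and ten EGS bins (0.6-10.3 Mb). Writes prevalence tables and a
correlation report under results/.
"""

from pathlib import Path

import pandas as pd

from modmet.binning import correlate, make_bins, prevalence_by_bin
from modmet.catalog import load_packaged_catalog
from modmet.ingest import (build_genome_records, read_annotations,
                           read_genome_metadata, read_quality)
from modmet.presence import build_presence_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = load_packaged_catalog("full")
    comm = RESULTS / "community"
    genomes = build_genome_records(
        read_genome_metadata(comm / "genome_metadata.tsv"),
        read_quality(comm / "quality.tsv"),
        read_annotations(comm / "annotations.emapper.annotations.tsv"),
    )
    presence = build_presence_matrix(genomes, catalog)
    gc = pd.Series({g.genome_id: g.gc_percent for g in genomes})
    egs = pd.Series({g.genome_id: g.egs_bp / 1e6 for g in genomes})

    r, p, n = correlate(gc.to_numpy(), egs.to_numpy())
    pd.DataFrame([{"x": "gc_percent", "y": "egs_mb", "method": "pearson",
                   "r": r, "p": p, "n": n}]).to_csv(
        RESULTS / "architecture_correlations.tsv", sep="\t", index=False)
    print(f"GC vs EGS: Pearson R = {r:.3f} (p = {p:.2e}, n = {n})")

    gc_tab = prevalence_by_bin(gc, presence, make_bins(25, 75, 5))
    egs_tab = prevalence_by_bin(egs, presence, make_bins(0.6, 10.3, 10))
    gc_tab.to_csv(RESULTS / "prevalence_gc.tsv", sep="\t", index=False, na_rep="NA")
    egs_tab.to_csv(RESULTS / "prevalence_egs.tsv", sep="\t", index=False, na_rep="NA")

    acl = gc_tab[(gc_tab.module_id == "P40") & (gc_tab.bin_index >= 0)]
    prev = acl.sort_values("bin_index")["prevalence"].round(3).tolist()
    print(f"ATP-citrate lyase (P40) prevalence across GC bins 25->75: {prev}")


if __name__ == "__main__":
    main()
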