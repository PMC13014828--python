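"""TPM-based abundance statistics: per-borehole population size,
Shannon–Wiener diversity, and abundance over genome-size categories.

TPM values are consumed as produced by the read mapper, never recomputed.
A genome is *present* in a borehole when it has nonzero TPM in at least one
of that borehole's samples; a genome's population size there is the mean of
the log10 of its nonzero TPM values across those samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import SampleMetadata

__all__ = [
    "AbundanceTable",
    "population_size",
    "shannon_wiener",
    "interval_abundance",
]


@dataclass
class AbundanceTable:
    """Genomes × samples TPM matrix with sample → borehole metadata."""

    tpm: pd.DataFrame  # index genome_id, columns sample_id, values >= 0
    sample_meta: dict[str, SampleMetadata]

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        missing = [s for s in self.tpm.columns if s not in self.sample_meta]
        if missing:
            raise ValueError(f"samples without borehole metadata: {missing}")

    @property
    def boreholes(self) -> list[str]:
        return sorted({m.borehole_id for s, m in self.sample_meta.items()
                       if s in self.tpm.columns})

    def borehole_samples(self, borehole_id: str) -> list[str]:
        samples = [s for s in self.tpm.columns
                   if self.sample_meta[s].borehole_id == borehole_id]
        if not samples:
            raise KeyError(f"unknown borehole {borehole_id!r}")
        return samples

    def members(self, borehole_id: str) -> list[str]:
        """Genomes with nonzero TPM in ≥1 sample of the borehole."""
        sub = self.tpm[self.borehole_samples(borehole_id)]
        present = (sub > 0).any(axis=1)
        return [str(g) for g in sub.index[present]]

    def check_tpm_normalization(self, rel_tol: float = 0.01) -> list[str]:
        """Warn for sample columns whose TPM sum deviates from 1e6 by more
        than *rel_tol*; returns offending sample ids."""
        sums = self.tpm.sum(axis=0)
        bad = sums.index[(sums - 1e6).abs() > rel_tol * 1e6].tolist()
        if bad:
            warnings.warn(f"TPM columns deviating from 1e6: {bad}")
        return [str(b) for b in bad]


def population_size(
    genome_id: str, borehole_id: str, table: AbundanceTable
) -> float:
    """Mean of log10 of the genome's nonzero TPM over the borehole's samples.

    NaN (undefined, not 0) when the genome is absent from every sample.
    """
    samples = table.borehole_samples(borehole_id)
    vals = table.tpm.loc[genome_id, samples].to_numpy(dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        return float("nan")
    return float(np.mean(np.log10(nz)))


def _borehole_weights(
    borehole_id: str, table: AbundanceTable, weight_scale: str
) -> pd.Series:
    samples = table.borehole_samples(borehole_id)
    sub = table.tpm[samples]
    out = {}
    for gid in sub.index:
        vals = sub.loc[gid].to_numpy(dtype=float)
        nz = vals[vals > 0]
        if nz.size == 0:
            continue
        if weight_scale == "linear":
            out[gid] = float(np.mean(nz))
        elif weight_scale == "log10":
            out[gid] = float(np.mean(np.log10(nz)))
        else:
            raise ValueError(f"unknown weight_scale {weight_scale!r}")
    return pd.Series(out, dtype=float)


def shannon_wiener(
    borehole_id: str,
    table: AbundanceTable,
    weight_scale: str = "linear",
    base: str = "e",
) -> float:
    """Shannon–Wiener diversity of the borehole's community.

    Membership is nonzero TPM in ≥1 borehole sample; p_i derive from each
    member's mean nonzero TPM (linear scale by default; ``log10`` switches
    to the mean log10 abundance), normalized to sum to 1. Natural log by
    default; ``base='2'`` reports bits. NaN when no genome is present.
    """
    w = _borehole_weights(borehole_id, table, weight_scale)
    if w.empty:
        return float("nan")
    if (w <= 0).any():
        # log10 weights can go non-positive for TPM <= 1; shift is not
        # defensible, so refuse rather than fabricate proportions
        raise ValueError("non-positive abundance weights; use linear weight_scale")
    p = w / w.sum()
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= math.log(2)
    return h


def interval_abundance(
    borehole_id: str,
    egs_category: int,
    categories: pd.Series,
    table: AbundanceTable,
) -> float:
    """Mean of the nonzero TPM cells pooled over all genomes of the given
    genome-size category across the borehole's samples; NaN for an empty pool.

    Pooling is cell-wise on the linear TPM scale (all nonzero genome × sample
    entries contribute equally), not sample-averaged first.
    """
    samples = table.borehole_samples(borehole_id)
    genomes = [g for g in categories.index[categories == egs_category]
               if g in table.tpm.index]
    if not genomes:
        return float("nan")
    block = table.tpm.loc[genomes, samples].to_numpy(dtype=float)
    nz = block[block > 0]
    if nz.size == 0:
        return float("nan")
    return float(nz.mean())


def diversity_table(table: AbundanceTable, weight_scale: str = "linear") -> pd.DataFrame:
    """Per-borehole richness and Shannon–Wiener index (nats and bits)."""
    rows = []
    for bh in table.boreholes:
        members = table.members(bh)
        h = shannon_wiener(bh, table, weight_scale=weight_scale) if members else float("nan")
        rows.append(
            {
                "borehole_id": bh,
                "n_samples": len(table.borehole_samples(bh)),
                "richness": len(members),
                "shannon_nats": h,
                "shannon_bits": h / math.log(2) if not math.isnan(h) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
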