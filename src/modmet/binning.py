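"""Module prevalence across GC-content / genome-size bins, and
genome-architecture correlation statistics.

Prevalence in a bin is the number of genomes in that bin carrying the
module divided by the number of genomes in the bin. The survey's
normalization ranges are the defaults: GC 25–75 % in five equal intervals,
estimated genome size 0.6–10.3 Mb in ten; Fig.-style genome-size categories
use ten 1-Mb-wide intervals starting at 0.6 Mb. Empty bins are undefined
(NaN), never zero — a zero would fabricate signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinSpec",
    "make_bins",
    "assign_bin",
    "prevalence_by_bin",
    "egs_categories",
    "correlate",
    "bh_adjust",
    "GC_BINS",
    "EGS_BINS",
]

OVERFLOW = -1  # bin index for values outside [lo, hi]


@dataclass(frozen=True)
class BinSpec:
    lo: float
    hi: float
    n_bins: int
    edges: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        edges = np.linspace(self.lo, self.hi, self.n_bins + 1)
        object.__setattr__(self, "edges", tuple(float(e) for e in edges))

    def assign(self, values) -> np.ndarray:
        """Bin index per value: left-closed right-open, final bin right-closed;
        out-of-range and NaN values map to the OVERFLOW category (-1)."""
        v = np.asarray(values, dtype=float)
        idx = np.floor((v - self.lo) / (self.hi - self.lo) * self.n_bins).astype(int)
        idx = np.where(v == self.hi, self.n_bins - 1, idx)  # closed right edge
        out_of_range = ~np.isfinite(v) | (v < self.lo) | (v > self.hi)
        return np.where(out_of_range, OVERFLOW, idx)


def make_bins(lo: float, hi: float, n_bins: int) -> BinSpec:
    return BinSpec(lo=lo, hi=hi, n_bins=n_bins)


def assign_bin(value: float, bins: BinSpec) -> int:
    return int(bins.assign([value])[0])


GC_BINS = make_bins(25.0, 75.0, 5)
EGS_BINS = make_bins(0.6, 10.3, 10)  # Mb, prevalence normalization range


def prevalence_by_bin(
    values: pd.Series,
    presence: pd.DataFrame | pd.Series,
    bins: BinSpec,
) -> pd.DataFrame:
    """Per-bin module prevalence.

    *values* — one number (GC %, EGS in Mb, ...) per genome; *presence* —
    boolean column(s) aligned on the same genome index. Returns one row per
    (module, bin) with counts and prevalence; empty bins carry NaN
    prevalence. Out-of-range genomes are tallied in an ``overflow`` row per
    module (bin_index −1) so that counts conserve.
    """
    if isinstance(presence, pd.Series):
        presence = presence.to_frame()
    if not values.index.equals(presence.index):
        if set(values.index) != set(presence.index):
            raise ValueError("values and presence are not aligned on genome_id")
        presence = presence.loc[values.index]
    idx = bins.assign(values.to_numpy())
    records = []
    for module in presence.columns:
        carr = presence[module].to_numpy(dtype=bool)
        for b in range(bins.n_bins):
            in_bin = idx == b
            n = int(in_bin.sum())
            k = int((in_bin & carr).sum())
            records.append(
                {
                    "module_id": module,
                    "bin_index": b,
                    "bin_lo": bins.edges[b],
                    "bin_hi": bins.edges[b + 1],
                    "n_in_bin": n,
                    "n_with_module": k,
                    "prevalence": (k / n) if n > 0 else np.nan,
                }
            )
        over = idx == OVERFLOW
        n = int(over.sum())
        k = int((over & carr).sum())
        records.append(
            {
                "module_id": module,
                "bin_index": OVERFLOW,
                "bin_lo": np.nan,
                "bin_hi": np.nan,
                "n_in_bin": n,
                "n_with_module": k,
                "prevalence": (k / n) if n > 0 else np.nan,
            }
        )
    return pd.DataFrame.from_records(records)


def egs_categories(
    egs_mb: pd.Series,
    start_mb: float = 0.6,
    width_mb: float = 1.0,
    n_categories: int = 10,
) -> pd.Series:
    """Genome-size category per genome at 1-Mb width (ten categories spanning
    0.6–10.6 Mb by default); same boundary rule as :func:`make_bins`."""
    spec = make_bins(start_mb, start_mb + width_mb * n_categories, n_categories)
    return pd.Series(spec.assign(egs_mb.to_numpy()), index=egs_mb.index, name="egs_category")


def correlate(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation coefficient, two-sided p-value, and n after dropping
    incomplete pairs. Zero variance in either vector yields (nan, nan, n)."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), n


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (helper; raw p-values are the
    default everywhere in this package)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
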