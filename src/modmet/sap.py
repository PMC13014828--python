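"""Sugar–acid preference (SAP) scoring.

SAP summarizes a genome's carbon-substrate leaning on a (−1, 1) scale:
``SAP = tanh(s·S + a·A)`` with published coefficients s = 60.76 and
a = −20.21, where S and A are the per-gene-normalized abundances of genes
from curated sugar- and acid-metabolism lists. +1 marks an extreme sugar
specialist, −1 an extreme acid specialist. The coefficients are fixed
published parameters and are not re-derived here.

The curated gene lists belong to an external supplement; the packaged
``data/sap_genes_synthetic.tsv`` is a synthetic stand-in keyed by KO
identifiers, and any user-supplied two-column list (identifier, class ∈
{sugar, acid}) can be used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SapCoefficients",
    "SapFeatures",
    "load_gene_lists",
    "packaged_gene_lists",
    "sap_features",
    "sap_score",
    "sap_table",
]


@dataclass(frozen=True)
class SapCoefficients:
    s: float = 60.76
    a: float = -20.21

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s) and math.isfinite(self.a)):
            raise ValueError("SAP coefficients must be finite")


@dataclass(frozen=True)
class SapFeatures:
    """Relative abundances of sugar (S) and acid (A) genes, per total gene."""

    S: float
    A: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.S <= 1 and 0 <= self.A <= 1):
            raise ValueError("S and A must lie in [0, 1]")


def load_gene_lists(path: str | Path) -> tuple[frozenset[str], frozenset[str]]:
    """Read a two-column (identifier, class) TSV into (sugar, acid) sets.

    Identifiers are matched case-insensitively; they are stored lowercase.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"identifier", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["class"].unique()) - {"sugar", "acid"}
    if bad:
        raise ValueError(f"{path}: unknown classes {sorted(bad)}")
    sugar = frozenset(df.loc[df["class"] == "sugar", "identifier"].str.lower())
    acid = frozenset(df.loc[df["class"] == "acid", "identifier"].str.lower())
    return sugar, acid


def packaged_gene_lists() -> tuple[frozenset[str], frozenset[str]]:
    path = Path(str(resources.files("modmet.data").joinpath("sap_genes_synthetic.tsv")))
    return load_gene_lists(path)


def sap_features(
    gene_annotations: list[str],
    sugar_list: frozenset[str] | set[str],
    acid_list: frozenset[str] | set[str],
    n_genes: int | None = None,
) -> SapFeatures:
    """Count sugar/acid gene matches with multiplicity and normalize by the
    gene total.

    *gene_annotations* is one identifier (KO or gene symbol) per annotated
    gene copy — a gene carrying a listed KO counts every time it occurs.
    *n_genes* defaults to ``len(gene_annotations)`` and should be the
    genome's total predicted gene count when annotations cover only a
    subset.
    """
    if n_genes is None:
        n_genes = len(gene_annotations)
    if n_genes <= 0:
        raise ValueError("empty genome: n_genes must be positive")
    sugar = {x.lower() for x in sugar_list}
    acid = {x.lower() for x in acid_list}
    s_count = sum(1 for g in gene_annotations if g.lower() in sugar)
    a_count = sum(1 for g in gene_annotations if g.lower() in acid)
    return SapFeatures(S=s_count / n_genes, A=a_count / n_genes, n_genes=n_genes)


def sap_score(features: SapFeatures, coeffs: SapCoefficients | None = None) -> float:
    """``tanh(s·S + a·A)``; strictly increasing in S, decreasing in A for the
    default coefficients."""
    c = coeffs or SapCoefficients()
    return math.tanh(c.s * features.S + c.a * features.A)


def sap_table(
    gene_kos: dict[str, list[str]],
    gene_counts: dict[str, int],
    sugar_list: frozenset[str] | set[str] | None = None,
    acid_list: frozenset[str] | set[str] | None = None,
    coeffs: SapCoefficients | None = None,
) -> pd.DataFrame:
    """Per-genome SAP table (genome_id, S, A, sap) from annotation multisets."""
    if sugar_list is None or acid_list is None:
        sugar_list, acid_list = packaged_gene_lists()
    rows = []
    for gid in sorted(gene_kos):
        n = gene_counts.get(gid, len(gene_kos[gid]))
        if n <= 0:
            continue
        f = sap_features(gene_kos[gid], sugar_list, acid_list, n_genes=n)
        rows.append({"genome_id": gid, "S": f.S, "A": f.A,
                     "sap": sap_score(f, coeffs)})
    return pd.DataFrame(rows).set_index("genome_id") if rows else pd.DataFrame(
        columns=["S", "A", "sap"]
    )
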