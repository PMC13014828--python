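"""Seeded generator of synthetic genome communities and abundance tables.

The generator emulates the statistical structure of a deep-groundwater
genome collection so that every analysis stage is testable without external
downloads: a trimodal GC distribution (major component near 40 %, minor
components near 57 and 63 %), a positive GC–genome-size relationship, three
genome archetypes (streamlined small-genome symbionts with truncated
metabolism and transporter-heavy gene content; mid-size generalists;
large high-GC generalists with broad pathway repertoires), GC-dependent
presence of designated modules (logistic in GC), and borehole-structured
sparse TPM tables in which the symbiont archetype declines with depth.

All randomness flows through one integer seed via ``numpy``'s Generator;
the sampling order (archetypes → GC → EGS → quality → module presence →
KO emission → decoys → degradation → abundance) is fixed, so identical
seeds give identical communities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .catalog import Catalog, load_packaged_catalog
from .ingest import GenomeRecord, SampleMetadata
from .abundance import AbundanceTable

__all__ = [
    "ArchetypeSpec",
    "CommunitySpec",
    "SyntheticCommunity",
    "generate_genomes",
    "generate_abundance",
    "generate_community",
    "ground_truth",
    "write_community",
]

# per-pathway base module-presence probability for the three default archetypes
_BASE_PROFILES = {
    "symbiont": {
        "transport": 0.45, "fermentation": 0.30, "PAT_ACK": 0.40, "rTCA": 0.08,
        "WLP": 0.05, "rGly_Ser": 0.08, "CBB": 0.02, "3HP": 0.05,
        "anaplerotic": 0.10, "fatty_acid": 0.05,
        "dicarboxylate_hydroxybutyrate": 0.02, "nitrogen": 0.03,
    },
    "mid_generalist": {
        "transport": 0.35, "fermentation": 0.45, "PAT_ACK": 0.45, "rTCA": 0.35,
        "WLP": 0.30, "rGly_Ser": 0.25, "CBB": 0.10, "3HP": 0.25,
        "anaplerotic": 0.45, "fatty_acid": 0.45,
        "dicarboxylate_hydroxybutyrate": 0.10, "nitrogen": 0.20,
    },
    "high_gc_generalist": {
        "transport": 0.40, "fermentation": 0.55, "PAT_ACK": 0.50, "rTCA": 0.55,
        "WLP": 0.45, "rGly_Ser": 0.35, "CBB": 0.08, "3HP": 0.40,
        "anaplerotic": 0.65, "fatty_acid": 0.60,
        "dicarboxylate_hydroxybutyrate": 0.15, "nitrogen": 0.35,
    },
}

_PHYLA = {
    "symbiont": ("Patescibacteria", "Nanoarchaeota", "Micrarchaeota"),
    "mid_generalist": ("Proteobacteria", "Desulfobacterota", "Bacteroidota",
                       "Chloroflexota"),
    "high_gc_generalist": ("Actinobacteriota", "Myxococcota", "Thermoplasmatota"),
}

#: Modules whose presence probability is logistic in GC by default — the
#: carbon-fixation / nitrogen-acquisition modules the survey found enriched
#: in high-GC lineages.
DEFAULT_GC_RESPONSIVE = (
    "P26", "P27", "P28", "P29", "P30", "P31", "P37", "P40", "P42",
    "P43", "P44", "P45", "P46", "P47",
    "PN1", "PN2", "PN3", "PN6",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    name: str
    fraction: float
    gc_mean: float
    gc_sd: float
    egs_mean: float  # Mb
    egs_sd: float
    depth_response: float  # slope of log10 abundance vs depth (per mbsl)
    tpm_baseline: float  # log10 TPM at the reference depth
    dropout: float  # per-cell probability of absence before normalization
    module_profile: dict[str, float] = field(default_factory=dict)
    phyla: tuple[str, ...] = ()
    sugar_gene_rate: float = 0.01
    acid_gene_rate: float = 0.01


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    return (
        ArchetypeSpec(
            name="symbiont", fraction=0.55, gc_mean=40.0, gc_sd=5.0,
            egs_mean=1.4, egs_sd=0.4, depth_response=-0.004,
            tpm_baseline=2.2, dropout=0.50,
            module_profile=dict(_BASE_PROFILES["symbiont"]),
            phyla=_PHYLA["symbiont"],
            sugar_gene_rate=0.020, acid_gene_rate=0.004,
        ),
        ArchetypeSpec(
            name="mid_generalist", fraction=0.30, gc_mean=57.0, gc_sd=3.0,
            egs_mean=3.0, egs_sd=0.7, depth_response=0.001,
            tpm_baseline=2.0, dropout=0.35,
            module_profile=dict(_BASE_PROFILES["mid_generalist"]),
            phyla=_PHYLA["mid_generalist"],
            sugar_gene_rate=0.012, acid_gene_rate=0.018,
        ),
        ArchetypeSpec(
            name="high_gc_generalist", fraction=0.15, gc_mean=63.0, gc_sd=3.0,
            egs_mean=4.2, egs_sd=0.9, depth_response=0.002,
            tpm_baseline=2.0, dropout=0.30,
            module_profile=dict(_BASE_PROFILES["high_gc_generalist"]),
            phyla=_PHYLA["high_gc_generalist"],
            sugar_gene_rate=0.006, acid_gene_rate=0.040,
        ),
    )


@dataclass(frozen=True)
class CommunitySpec:
    seed: int
    n_genomes: int = 600
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    gc_range: tuple[float, float] = (25.0, 75.0)
    egs_range: tuple[float, float] = (0.6, 10.3)  # Mb
    gc_egs_slope: float = 0.05  # Mb per GC point, within archetype
    gc_module_slope: float = 0.15  # logit units per GC point
    gc_responsive_modules: tuple[str, ...] = DEFAULT_GC_RESPONSIVE
    gc_responsive_base: float = 0.5  # presence probability at GC 50
    boreholes: tuple[tuple[str, float], ...] = (
        ("BH-070", 70.0), ("BH-250", 250.0), ("BH-420", 420.0), ("BH-530", 530.0),
    )
    samples_per_borehole: int = 3
    reference_depth: float = 200.0
    tpm_noise: float = 0.35
    decoy_ko_mean: float = 25.0
    degradation_fraction: float = 0.10
    genes_per_mb: float = 950.0

    def __post_init__(self) -> None:
        if self.n_genomes <= 0:
            raise ValueError("n_genomes must be positive")
        total = sum(a.fraction for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total}, not 1")
        for a in self.archetypes:
            bad = {k: v for k, v in a.module_profile.items() if not 0 <= v <= 1}
            if bad:
                raise ValueError(f"{a.name}: probabilities outside [0,1]: {bad}")


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    genomes: list[GenomeRecord]
    gene_kos: dict[str, list[str]]
    truth: dict
    abundance: AbundanceTable | None = None


def _truncated_normal(rng, mean, sd, lo, hi, max_iter: int = 1000) -> np.ndarray:
    """Vectorized rejection sampling of N(mean, sd) truncated to [lo, hi]."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    for _ in range(max_iter):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out = np.where(bad, rng.normal(mean, sd), out)
    raise RuntimeError("truncation region too narrow: resampling failed")


def _module_probability(spec: CommunitySpec, archetype: ArchetypeSpec,
                        module, gc: np.ndarray) -> np.ndarray:
    if module.module_id in spec.gc_responsive_modules:
        alpha = logit(spec.gc_responsive_base)
        return expit(alpha + spec.gc_module_slope * (gc - 50.0))
    base = archetype.module_profile.get(module.pathway, 0.1)
    return np.full_like(gc, base, dtype=float)


def generate_genomes(
    spec: CommunitySpec, catalog: Catalog | None = None
) -> SyntheticCommunity:
    """Draw a community of genomes with KO sets and a ground-truth record."""
    catalog = catalog or load_packaged_catalog("full")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genomes
    arch_idx = rng.choice(len(spec.archetypes), size=n,
                          p=[a.fraction for a in spec.archetypes])
    gc_lo, gc_hi = spec.gc_range
    egs_lo, egs_hi = spec.egs_range
    gc_means = np.array([spec.archetypes[i].gc_mean for i in arch_idx])
    gc_sds = np.array([spec.archetypes[i].gc_sd for i in arch_idx])
    gc = _truncated_normal(rng, gc_means, gc_sds, gc_lo, gc_hi)
    egs_means = np.array([spec.archetypes[i].egs_mean for i in arch_idx])
    egs_sds = np.array([spec.archetypes[i].egs_sd for i in arch_idx])
    egs = _truncated_normal(
        rng, egs_means + spec.gc_egs_slope * (gc - gc_means), egs_sds,
        egs_lo, egs_hi,
    )
    completeness = rng.uniform(55.0, 100.0, size=n)
    contamination = rng.uniform(0.0, 5.0, size=n)

    # presence truth, per module (column order = catalog order)
    module_list = catalog.modules
    presence_true = np.zeros((n, len(module_list)), dtype=bool)
    for j, mod in enumerate(module_list):
        p = np.empty(n)
        for ai, arch in enumerate(spec.archetypes):
            mask = arch_idx == ai
            if mask.any():
                p[mask] = _module_probability(spec, arch, mod, gc[mask])
        presence_true[:, j] = rng.random(n) < p

    decoy_pool = [f"K9{i:04d}" for i in range(400)]
    genomes: list[GenomeRecord] = []
    gene_kos: dict[str, list[str]] = {}
    truth_genomes = []
    degrade = rng.random(n) < spec.degradation_fraction
    sugar_pool, acid_pool = _sap_pools()
    for i in range(n):
        gid = f"SYN{i:04d}"
        arch = spec.archetypes[int(arch_idx[i])]
        kos: list[str] = []
        for j, mod in enumerate(module_list):
            if not presence_true[i, j]:
                continue
            for grp in mod.requirement:
                members = sorted(grp.members)
                kos.append(members[int(rng.integers(len(members)))])
        n_decoys = int(rng.poisson(spec.decoy_ko_mean))
        kos.extend(decoy_pool[int(k)] for k in rng.integers(len(decoy_pool),
                                                            size=n_decoys))
        deleted: str | None = None
        if degrade[i]:
            present_mods = [module_list[j].module_id
                            for j in range(len(module_list)) if presence_true[i, j]]
            if present_mods:
                target = present_mods[int(rng.integers(len(present_mods)))]
                mod = catalog[target]
                grp = mod.requirement[int(rng.integers(len(mod.requirement)))]
                kos = [k for k in kos if k not in grp.members]
                deleted = target
        n_genes = max(len(kos) + 1,
                      int(round(egs[i] * spec.genes_per_mb * rng.uniform(0.85, 1.0))))
        n_sugar = rng.binomial(n_genes, arch.sugar_gene_rate)
        n_acid = rng.binomial(n_genes, arch.acid_gene_rate)
        kos.extend(sugar_pool[int(k)] for k in rng.integers(len(sugar_pool), size=n_sugar))
        kos.extend(acid_pool[int(k)] for k in rng.integers(len(acid_pool), size=n_acid))
        phylum = arch.phyla[int(rng.integers(len(arch.phyla)))] if arch.phyla else "Unknown"
        size_bp = int(round(egs[i] * 1e6 * (completeness[i] / 100.0)
                            / (1.0 - contamination[i] / 100.0)))
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                taxonomy={"phylum": phylum, "class": f"{phylum}_c"},
                gc_percent=float(gc[i]),
                genome_size_bp=size_bp,
                completeness_percent=float(completeness[i]),
                contamination_percent=float(contamination[i]),
                egs_bp=float(egs[i] * 1e6),
                ko_set=set(kos),
                n_genes=n_genes,
                source_type="MAG",
            )
        )
        gene_kos[gid] = kos
        truth_genomes.append(
            {
                "genome_id": gid,
                "archetype": arch.name,
                "gc_percent": float(gc[i]),
                "egs_mb": float(egs[i]),
                "true_modules": [module_list[j].module_id
                                 for j in range(len(module_list))
                                 if presence_true[i, j]],
                "degraded_module": deleted,
            }
        )
    truth = {
        "spec": _spec_to_dict(spec),
        "genomes": truth_genomes,
        "gc_responsive_modules": list(spec.gc_responsive_modules),
        "gc_module_slope": spec.gc_module_slope,
    }
    return SyntheticCommunity(spec=spec, genomes=genomes, gene_kos=gene_kos,
                              truth=truth)


def _sap_pools() -> tuple[list[str], list[str]]:
    from .sap import packaged_gene_lists

    sugar, acid = packaged_gene_lists()
    return sorted(k.upper() for k in sugar), sorted(k.upper() for k in acid)


def generate_abundance(
    community: SyntheticCommunity, seed_offset: int = 1
) -> AbundanceTable:
    """Borehole-structured sparse TPM table for an already-generated community.

    Per cell: log10 abundance = archetype baseline + depth_response × (depth −
    reference) + lognormal noise; random dropout; every sample column is then
    rescaled to sum to 1e6 (the TPM convention).
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + seed_offset)
    arch_by_name = {a.name: a for a in spec.archetypes}
    arch = [arch_by_name[t["archetype"]] for t in community.truth["genomes"]]
    gids = [g.genome_id for g in community.genomes]
    sample_meta: dict[str, SampleMetadata] = {}
    columns: dict[str, np.ndarray] = {}
    for bh, depth in spec.boreholes:
        for s in range(spec.samples_per_borehole):
            sid = f"{bh}_S{s + 1}"
            sample_meta[sid] = SampleMetadata(sample_id=sid, borehole_id=bh,
                                              depth_mbsl=depth)
            log_tpm = np.array(
                [a.tpm_baseline + a.depth_response * (depth - spec.reference_depth)
                 for a in arch]
            ) + rng.normal(0.0, spec.tpm_noise, size=len(arch))
            present = rng.random(len(arch)) >= np.array([a.dropout for a in arch])
            col = np.where(present, np.power(10.0, log_tpm), 0.0)
            total = col.sum()
            if total > 0:
                col = col * (1e6 / total)
            columns[sid] = col
    tpm = pd.DataFrame(columns, index=pd.Index(gids, name="genome_id"))
    table = AbundanceTable(tpm=tpm, sample_meta=sample_meta)
    community.abundance = table
    return table


def generate_community(spec: CommunitySpec,
                       catalog: Catalog | None = None) -> SyntheticCommunity:
    community = generate_genomes(spec, catalog)
    generate_abundance(community)
    return community


def _spec_to_dict(spec: CommunitySpec) -> dict:
    d = asdict(spec)
    d["archetypes"] = [asdict(a) for a in spec.archetypes]
    return d


def ground_truth(community: SyntheticCommunity) -> str:
    """JSON record of every generating parameter — sufficient to score any
    recovery experiment without re-running the generator."""
    return json.dumps(community.truth, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not serializable: {type(o)}")


# ---------------------------------------------------------------------------
# File emission in the exact dialects the ingest module reads
# ---------------------------------------------------------------------------

def write_community(community: SyntheticCommunity, outdir) -> dict[str, str]:
    """Write annotations / quality / genome metadata / sample metadata / TPM
    files so the full pipeline can run from disk. Returns name → path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ann = outdir / "annotations.emapper.annotations.tsv"
    with ann.open("w") as fh:
        fh.write("#query\tKEGG_ko\n")
        for g in community.genomes:
            kos = community.gene_kos[g.genome_id]
            for k, ko in enumerate(kos):
                fh.write(f"{g.genome_id}_{k:05d}\tko:{ko}\n")
            for k in range(len(kos), g.n_genes):
                fh.write(f"{g.genome_id}_{k:05d}\t-\n")
    paths["annotations"] = str(ann)

    qual = outdir / "quality.tsv"
    pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in community.genomes],
            "completeness": [round(g.completeness_percent, 2) for g in community.genomes],
            "contamination": [round(g.contamination_percent, 2) for g in community.genomes],
        }
    ).to_csv(qual, sep="\t", index=False)
    paths["quality"] = str(qual)

    meta = outdir / "genome_metadata.tsv"
    pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in community.genomes],
            "taxonomy": [f"p__{g.phylum};c__{g.taxonomy.get('class', '')}"
                          for g in community.genomes],
            "gc_percent": [round(g.gc_percent, 3) for g in community.genomes],
            "genome_size_bp": [g.genome_size_bp for g in community.genomes],
            "source_type": [g.source_type for g in community.genomes],
        }
    ).to_csv(meta, sep="\t", index=False)
    paths["genome_metadata"] = str(meta)

    if community.abundance is None:
        generate_abundance(community)
    table = community.abundance
    smeta = outdir / "sample_metadata.tsv"
    pd.DataFrame(
        {
            "sample_id": list(table.sample_meta),
            "borehole_id": [m.borehole_id for m in table.sample_meta.values()],
            "depth_mbsl": [m.depth_mbsl for m in table.sample_meta.values()],
        }
    ).to_csv(smeta, sep="\t", index=False)
    paths["sample_metadata"] = str(smeta)

    tpm = outdir / "tpm.tsv"
    table.tpm.to_csv(tpm, sep="\t", float_format="%.6f")
    paths["tpm"] = str(tpm)
    return paths
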