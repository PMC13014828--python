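"""End-to-end orchestration: configuration, stage sequencing, report output.

``run_pipeline`` takes a validated :class:`PipelineConfig` and writes a
report directory containing the presence matrix, role table, prevalence
tables over GC and genome-size bins, SAP scores, per-borehole diversity and
interval-abundance tables, per-borehole cross-feeding networks, and a
machine-readable manifest. Reruns with identical config produce
byte-identical text outputs (no timestamps, sorted orderings, fixed float
formatting).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import binning, network, sap
from .abundance import AbundanceTable, diversity_table, interval_abundance
from .catalog import Catalog, catalog_summary, load_catalog, load_packaged_catalog
from .ingest import (AnnotationSet, build_genome_records, read_annotations,
                     read_genome_metadata, read_quality, read_sample_metadata)
from .presence import RolePolicy, assign_roles_frame, build_presence_matrix
from .simulate import CommunitySpec, generate_community, write_community

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected at load time."""

    seed: int = 0
    out_dir: str = "modmet_report"
    catalog: str = "full"  # "full", "mini", or a TSV path
    n_genomes: int = 240  # synthetic community size when no inputs given
    inputs: dict = field(default_factory=dict)  # optional real-input paths
    min_ttca: int = 1
    egs_correct_contamination: bool = True
    diversity_weight_scale: str = "linear"
    sap_gene_list: str | None = None
    gc_bins: tuple[float, float, int] = (25.0, 75.0, 5)
    egs_bins: tuple[float, float, int] = (0.6, 10.3, 10)
    public_goods: tuple[str, ...] = network.DEFAULT_PUBLIC_GOODS

    def __post_init__(self) -> None:
        if self.diversity_weight_scale not in ("linear", "log10"):
            raise ConfigError(f"bad diversity_weight_scale {self.diversity_weight_scale!r}")
        if self.min_ttca < 1 or self.min_ttca > 9:
            raise ConfigError("min_ttca must be in 1..9")
        known_inputs = {"annotations", "quality", "genome_metadata",
                        "sample_metadata", "tpm"}
        unknown = set(self.inputs) - known_inputs
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Read a YAML config file, apply keyword overrides, and validate."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("gc_bins", "egs_bins", "public_goods"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _load_catalog_choice(choice: str) -> Catalog:
    if choice in ("full", "mini"):
        return load_packaged_catalog(choice)
    return load_catalog(choice)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = _load_catalog_choice(config.catalog)
    manifest: dict = {
        "config": _config_to_jsonable(config),
        "catalog_version": catalog.version,
        "catalog_summary": catalog_summary(catalog),
        "stages": {},
    }

    # --- stage 1: inputs (simulate unless real inputs are configured) ------
    if config.inputs:
        annotations = read_annotations(config.inputs["annotations"])
        quality = read_quality(config.inputs["quality"])
        metadata = read_genome_metadata(config.inputs["genome_metadata"])
        n_in = len(metadata)
        genomes = build_genome_records(
            metadata, quality, annotations,
            correct_contamination=config.egs_correct_contamination,
        )
        sample_meta = read_sample_metadata(config.inputs["sample_metadata"])
        tpm = pd.read_csv(config.inputs["tpm"], sep="\t", index_col=0)
        table = AbundanceTable(tpm=tpm, sample_meta=sample_meta)
        gene_kos = annotations.gene_kos
        gene_counts = annotations.gene_counts
    else:
        spec = CommunitySpec(seed=config.seed, n_genomes=config.n_genomes)
        community = generate_community(spec, catalog)
        sim_dir = out / "community"
        write_community(community, sim_dir)
        genomes = community.genomes
        n_in = len(genomes)
        table = community.abundance
        gene_kos = community.gene_kos
        gene_counts = {g.genome_id: g.n_genes for g in genomes}
        (out / "ground_truth.json").write_text(
            json.dumps(community.truth, indent=2, sort_keys=True, default=str)
        )
    manifest["stages"]["ingest"] = {
        "genomes_in": n_in,
        "genomes_retained": len(genomes),
        "genomes_filtered": n_in - len(genomes),
        "samples": int(table.tpm.shape[1]),
    }
    if not genomes:
        raise RuntimeError("stage ingest: no genomes retained")

    # --- stage 2: presence + roles -----------------------------------------
    presence = build_presence_matrix(genomes, catalog)
    _write_tsv(presence.astype(int), out / "presence_matrix.tsv")
    roles = assign_roles_frame(presence, catalog, RolePolicy(min_ttca=config.min_ttca))
    _write_tsv(roles, out / "roles.tsv")
    manifest["stages"]["presence"] = {
        "modules": int(presence.shape[1]),
        "calls_true": int(presence.to_numpy().sum()),
        "rtca_complete": int((roles["rtca_status"] == "complete").sum()),
        "rtca_partial": int((roles["rtca_status"] == "partial").sum()),
        "nitrogen_fixers": int(roles["nitrogen_fixer"].sum()),
    }

    # --- stage 3: prevalence over GC and EGS bins --------------------------
    gc = pd.Series({g.genome_id: g.gc_percent for g in genomes}, name="gc")
    egs_mb = pd.Series({g.genome_id: g.egs_bp / 1e6 for g in genomes}, name="egs_mb")
    gc_spec = binning.make_bins(*config.gc_bins)
    egs_spec = binning.make_bins(*config.egs_bins)
    prev_gc = binning.prevalence_by_bin(gc, presence.loc[gc.index], gc_spec)
    prev_egs = binning.prevalence_by_bin(egs_mb, presence.loc[egs_mb.index], egs_spec)
    _write_tsv(prev_gc, out / "prevalence_gc.tsv", index=False, na_rep="NA")
    _write_tsv(prev_egs, out / "prevalence_egs.tsv", index=False, na_rep="NA")
    r, p, n = binning.correlate(gc.to_numpy(), egs_mb.to_numpy())
    manifest["stages"]["prevalence"] = {
        "gc_bins": gc_spec.n_bins, "egs_bins": egs_spec.n_bins,
        "gc_egs_pearson_r": round(r, 6), "gc_egs_pearson_p": float(p), "n": n,
    }

    # --- stage 4: abundance and diversity ----------------------------------
    div = diversity_table(table, weight_scale=config.diversity_weight_scale)
    _write_tsv(div, out / "diversity.tsv", index=False, na_rep="NA")
    cats = binning.egs_categories(egs_mb)
    rows = []
    for bh in table.boreholes:
        for cat in range(10):
            rows.append(
                {
                    "borehole_id": bh,
                    "egs_category": cat,
                    "mean_nonzero_tpm": interval_abundance(bh, cat, cats, table),
                }
            )
    _write_tsv(pd.DataFrame(rows), out / "interval_abundance.tsv",
               index=False, na_rep="NA")
    manifest["stages"]["abundance"] = {
        "boreholes": len(table.boreholes),
        "members_per_borehole": {bh: len(table.members(bh))
                                 for bh in table.boreholes},
    }

    # --- stage 5: SAP -------------------------------------------------------
    if config.sap_gene_list:
        sugar, acid = sap.load_gene_lists(config.sap_gene_list)
    else:
        sugar, acid = sap.packaged_gene_lists()
    sap_df = sap.sap_table(gene_kos, gene_counts, sugar, acid)
    _write_tsv(sap_df, out / "sap.tsv")
    manifest["stages"]["sap"] = {"genomes_scored": len(sap_df)}

    # --- stage 6: cross-feeding networks ------------------------------------
    taxonomy = {g.genome_id: g.phylum for g in genomes}
    edge_frames = []
    recip_rows = []
    comp_rows = []
    net_counts = {}
    for bh in table.boreholes:
        membership = [g for g in table.members(bh) if g in presence.index]
        graph = network.build_network(bh, membership, presence, catalog,
                                      taxonomy, compounds=config.public_goods)
        problems = network.audit_edges(graph, presence, catalog)
        if problems:
            raise RuntimeError(f"stage crossfeed ({bh}): unsound edges: {problems[:3]}")
        network.write_graphml(graph, out / f"network_{bh}.graphml")
        edges = network.edge_table(graph)
        edges.insert(0, "borehole_id", bh)
        edge_frames.append(edges)
        for pr in network.reciprocal_pairs(graph):
            recip_rows.append(
                {
                    "borehole_id": bh, "genome_a": pr.genome_a,
                    "genome_b": pr.genome_b, "compound_ab": pr.compound_ab,
                    "compound_ba": pr.compound_ba,
                    "modules_ab": ";".join(pr.modules_ab),
                    "modules_ba": ";".join(pr.modules_ba),
                }
            )
        for mid in catalog.module_ids:
            for phylum, count in sorted(
                network.module_composition(mid, membership, presence, taxonomy).items()
            ):
                comp_rows.append({"borehole_id": bh, "module_id": mid,
                                  "phylum": phylum, "carriers": count})
        net_counts[bh] = {"members": len(membership),
                          "edges": int(graph.number_of_edges())}
    _write_tsv(pd.concat(edge_frames, ignore_index=True) if edge_frames
               else pd.DataFrame(), out / "network_edges.tsv", index=False)
    _write_tsv(pd.DataFrame(recip_rows), out / "reciprocal_pairs.tsv", index=False)
    _write_tsv(pd.DataFrame(comp_rows), out / "module_composition.tsv", index=False)
    manifest["stages"]["crossfeed"] = net_counts

    # --- manifest ------------------------------------------------------------
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    outputs = sorted(p for p in out.rglob("*") if p.is_file()
                     and p.name != "manifest.json")
    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir")  # a location, not an analysis parameter
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
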