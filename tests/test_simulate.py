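"""Synthetic community generator: determinism, contracts, recovery."""

import json

import numpy as np
import pytest

from modmet.binning import GC_BINS, correlate, prevalence_by_bin
from modmet.ingest import read_annotations
from modmet.presence import build_presence_matrix
from modmet.simulate import (
    ArchetypeSpec,
    CommunitySpec,
    default_archetypes,
    generate_abundance,
    generate_community,
    generate_genomes,
    ground_truth,
    write_community,
)

import pandas as pd


def small_spec(seed=1, n=150, **kw):
    return CommunitySpec(seed=seed, n_genomes=n, **kw)


class TestDeterminism:
    def test_same_seed_identical_output(self, full_catalog):
        a = generate_community(small_spec(), full_catalog)
        b = generate_community(small_spec(), full_catalog)
        assert [g.genome_id for g in a.genomes] == [g.genome_id for g in b.genomes]
        assert all(x.ko_set == y.ko_set for x, y in zip(a.genomes, b.genomes))
        assert all(x.gc_percent == y.gc_percent for x, y in zip(a.genomes, b.genomes))
        assert a.abundance.tpm.equals(b.abundance.tpm)

    def test_different_seed_differs(self, full_catalog):
        a = generate_genomes(small_spec(seed=1), full_catalog)
        b = generate_genomes(small_spec(seed=2), full_catalog)
        assert any(x.ko_set != y.ko_set for x, y in zip(a.genomes, b.genomes))


class TestGenomeContracts:
    def test_ranges_and_quality_filter_by_construction(self, full_catalog):
        c = generate_genomes(small_spec(n=300), full_catalog)
        for g in c.genomes:
            assert 25 <= g.gc_percent <= 75
            assert 0.6e6 <= g.egs_bp <= 10.3e6
            assert g.completeness_percent >= 50
            assert g.contamination_percent <= 5
            assert g.n_genes >= len(g.ko_set)

    def test_flat_gc_egs_slope_yields_near_zero_correlation(self):
        # one archetype, no GC-EGS coupling: |r| within 0.1 of 0 at n=2000
        arch = ArchetypeSpec(
            name="only", fraction=1.0, gc_mean=50, gc_sd=8, egs_mean=3.0,
            egs_sd=1.0, depth_response=0.0, tpm_baseline=2.0, dropout=0.3,
            module_profile={}, phyla=("X",),
        )
        spec = CommunitySpec(seed=9, n_genomes=2000, archetypes=(arch,),
                             gc_egs_slope=0.0)
        c = generate_genomes(spec)
        r, _, _ = correlate([g.gc_percent for g in c.genomes],
                            [g.egs_bp for g in c.genomes])
        assert abs(r) < 0.1

    def test_default_conditions_give_positive_gc_egs_correlation(self, full_catalog):
        c = generate_genomes(small_spec(n=500), full_catalog)
        r, p, _ = correlate([g.gc_percent for g in c.genomes],
                            [g.egs_bp for g in c.genomes])
        assert r > 0.5 and p < 1e-6

    def test_decoy_kos_do_not_hit_catalog(self, full_catalog):
        c = generate_genomes(small_spec(), full_catalog)
        catalog_kos = set().union(*(m.kos for m in full_catalog.modules))
        decoys = {k for g in c.genomes for k in g.ko_set if k.startswith("K9")}
        assert decoys and not (decoys & catalog_kos)

    def test_fractions_must_sum_to_one(self):
        arch = default_archetypes()[0]
        with pytest.raises(ValueError):
            CommunitySpec(seed=1, archetypes=(arch,))


class TestAbundanceContracts:
    def test_every_sample_column_sums_to_tpm_million(self, full_catalog):
        c = generate_community(small_spec(), full_catalog)
        sums = c.abundance.tpm.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_full_dropout_makes_population_size_undefined(self, full_catalog):
        arch = ArchetypeSpec(
            name="ghost", fraction=1.0, gc_mean=50, gc_sd=5, egs_mean=2.0,
            egs_sd=0.5, depth_response=0.0, tpm_baseline=2.0, dropout=1.0,
            module_profile={}, phyla=("X",),
        )
        spec = CommunitySpec(seed=4, n_genomes=10, archetypes=(arch,))
        c = generate_community(spec)
        assert (c.abundance.tpm.to_numpy() == 0).all()

    def test_borehole_structure_present(self, full_catalog):
        c = generate_community(small_spec(), full_catalog)
        assert len(c.abundance.boreholes) == 4
        for bh in c.abundance.boreholes:
            assert len(c.abundance.borehole_samples(bh)) == 3


class TestGroundTruth:
    def test_round_trips_through_json(self, full_catalog):
        c = generate_genomes(small_spec(), full_catalog)
        restored = json.loads(ground_truth(c))
        assert restored == json.loads(json.dumps(c.truth, default=str))

    def test_one_entry_per_genome_and_recorded_slopes(self, full_catalog):
        spec = small_spec()
        c = generate_genomes(spec, full_catalog)
        assert len(c.truth["genomes"]) == spec.n_genomes
        assert c.truth["gc_module_slope"] == spec.gc_module_slope
        assert c.truth["spec"]["gc_egs_slope"] == spec.gc_egs_slope


class TestRecovery:
    def test_gc_responsive_module_slope_recovered_by_logistic_fit(self, full_catalog):
        # presence of a designated module regresses positively on GC
        import statsmodels.api as sm

        hits = 0
        for s in range(10):
            c = generate_genomes(CommunitySpec(seed=100 + s, n_genomes=1000),
                                 full_catalog)
            pres = build_presence_matrix(c.genomes, full_catalog)
            gc = np.array([g.gc_percent for g in c.genomes])
            y = pres["P40"].to_numpy().astype(float)
            fit = sm.Logit(y, sm.add_constant(gc)).fit(disp=0)
            hits += fit.params[1] > 0
        assert hits >= 9

    def test_degradation_flips_some_calls_against_truth(self, full_catalog):
        c = generate_genomes(small_spec(n=400), full_catalog)
        pres = build_presence_matrix(c.genomes, full_catalog)
        mismatches = 0
        for t in c.truth["genomes"]:
            if t["degraded_module"] is None:
                continue
            if not pres.loc[t["genome_id"], t["degraded_module"]]:
                mismatches += 1
        assert mismatches > 0  # observed calls differ from genomic truth


class TestFileEmission:
    def test_emitted_files_round_trip_through_ingest(self, full_catalog, tmp_path):
        c = generate_community(small_spec(n=30), full_catalog)
        paths = write_community(c, tmp_path)
        ann = read_annotations(paths["annotations"])
        for g in c.genomes:
            assert ann.ko_sets[g.genome_id] == g.ko_set
            assert ann.gene_counts[g.genome_id] == g.n_genes
        tpm = pd.read_csv(paths["tpm"], sep="\t", index_col=0)
        assert list(tpm.index) == [g.genome_id for g in c.genomes]
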