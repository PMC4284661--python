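import filecmp

import numpy as np
import pytest

from teislands.io_model import (
    build_gene_models,
    read_count_table,
    read_depth_table,
    read_fasta,
    read_gff,
    read_vcf_snvs,
)
from teislands.synthetic import (
    SimulationParams,
    simulate_counts,
    simulate_coverage,
    simulate_dataset,
    simulate_genome,
    simulate_snvs,
    substitute_snvs,
    write_dataset,
)

from conftest import small_params


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        p = SimulationParams(
            seed=3, n_scaffolds=1, scaffold_length=300_000, n_islands=1,
            island_length_range=(60_000, 80_000), n_duplications=2,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_dataset(p), d1)
        write_dataset(simulate_dataset(p), d2)
        names = [f.name for f in d1.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert not mismatch and not errors

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationParams(seed=1, n_scaffolds=1,
                                              scaffold_length=300_000,
                                              n_islands=1,
                                              island_length_range=(60_000, 80_000),
                                              n_duplications=1))
        b = simulate_dataset(SimulationParams(seed=2, n_scaffolds=1,
                                              scaffold_length=300_000,
                                              n_islands=1,
                                              island_length_range=(60_000, 80_000),
                                              n_duplications=1))
        assert a.scaffolds[0].sequence != b.scaffolds[0].sequence


class TestGenome:
    def test_realized_island_te_density(self, small_dataset):
        truth = small_dataset.truth
        te_bp = {}
        for f in small_dataset.features:
            if f.kind != "te_copy":
                continue
            in_island = any(
                sc == f.scaffold and s <= f.midpoint <= e
                for sc, s, e in truth.islands
            )
            te_bp["island" if in_island else "ldr"] = (
                te_bp.get("island" if in_island else "ldr", 0) + f.length
            )
        island_bp = sum(e - s + 1 for _, s, e in truth.islands)
        realized = te_bp["island"] / island_bp
        assert abs(realized - 0.45) < 0.1

    def test_zero_density_no_te(self):
        p = SimulationParams(
            seed=1, n_scaffolds=1, scaffold_length=300_000, n_islands=1,
            island_length_range=(60_000, 80_000), te_density_island=0.0,
            te_density_ldr=0.0, n_duplications=0,
        )
        _, features, _, _ = simulate_genome(p)
        assert not any(f.kind == "te_copy" for f in features)

    def test_impossible_density_rejected(self):
        p = SimulationParams(te_density_island=1.2)
        with pytest.raises(ValueError):
            p.validate()

    def test_gene_cds_valid_frames(self, small_dataset):
        from Bio.Seq import Seq

        seqs = {s.id: s.sequence for s in small_dataset.scaffolds}
        for g in small_dataset.genes[:50]:
            assert g.complete
            cds = "".join(seqs[g.scaffold][s - 1 : e] for s, e in g.cds)
            if g.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            prot = str(Seq(cds).translate())
            assert prot.startswith("M")
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_island_genes_cpg_depleted(self, small_dataset):
        from teislands.cpg_expression import gene_exon_cpg_oe

        seqs = {s.id: s for s in small_dataset.scaffolds}
        oe = {"island": [], "ldr": []}
        for g in small_dataset.genes:
            region = small_dataset.truth.gene_regions[g.id]
            val = gene_exon_cpg_oe(g, seqs[g.scaffold]).oe
            if val is not None:
                oe[region].append(val)
        assert np.median(oe["island"]) < np.median(oe["ldr"])


class TestCoverage:
    def test_mean_depth_near_target_without_duplications(self):
        p = small_params(seed=11)
        p.n_duplications = 0
        _, _, _, truth = simulate_genome(p)
        tracks = simulate_coverage(truth, p)
        for track in tracks.values():
            mean = np.mean(np.concatenate(list(track.depths.values())))
            assert abs(mean - 60.0) < 1.0

    def test_duplication_doubles_affected_lineage(self, small_dataset):
        """Mean depth over planted duplications sits near 2x baseline in the
        affected lineage and near 1x in the other (block noise averaged over
        all duplications)."""
        ratios = {"affected": [], "other": []}
        for scaf, s, e, lin in small_dataset.truth.duplications:
            for lineage, track in small_dataset.coverage.items():
                key = "affected" if lineage == lin else "other"
                ratios[key].append(track.depths[scaf][s - 1 : e].mean() / 60.0)
        assert 1.7 < np.mean(ratios["affected"]) < 2.3
        assert 0.7 < np.mean(ratios["other"]) < 1.3

    def test_zero_depth_all_zero(self):
        p = SimulationParams(seed=1, n_scaffolds=1, scaffold_length=200_000,
                             n_islands=1, island_length_range=(50_000, 60_000),
                             depth=0.0, n_duplications=1)
        _, _, _, truth = simulate_genome(p)
        tracks = simulate_coverage(truth, p)
        for t in tracks.values():
            assert all(arr.sum() == 0 for arr in t.depths.values())


class TestSnvs:
    def test_rates_within_poisson_bounds(self, small_dataset):
        truth = small_dataset.truth
        island_bp = sum(e - s + 1 for _, s, e in truth.islands)
        total_bp = sum(s.length for s in small_dataset.scaffolds)
        hom_island = sum(
            1 for (scaf, pos), cls in truth.snv_classes.items()
            if cls == "hom"
            and any(sc == scaf and s <= pos <= e for sc, s, e in truth.islands)
        )
        lam = 2.0 * island_bp / 1000.0
        assert abs(hom_island - lam) < 3.5 * np.sqrt(lam)
        hom_ldr = sum(1 for cls in truth.snv_classes.values() if cls == "hom") - hom_island
        lam_ldr = 0.5 * (total_bp - island_bp) / 1000.0
        assert abs(hom_ldr - lam_ldr) < 3.5 * np.sqrt(lam_ldr)

    def test_zero_rates_empty(self):
        p = SimulationParams(
            seed=1, n_scaffolds=1, scaffold_length=300_000, n_islands=1,
            island_length_range=(60_000, 80_000), hom_snv_rate_island=0.0,
            hom_snv_rate_ldr=0.0, het_snv_rate=0.0, dup_het_rate=0.0,
            n_duplications=1,
        )
        scaffolds, _, _, truth = simulate_genome(p)
        assert simulate_snvs(truth, scaffolds, p) == []

    def test_hets_only_in_duplications_when_background_zero(self):
        p = SimulationParams(
            seed=2, n_scaffolds=1, scaffold_length=300_000, n_islands=1,
            island_length_range=(60_000, 80_000), het_snv_rate=0.0,
            n_duplications=2,
        )
        scaffolds, _, _, truth = simulate_genome(p)
        snvs = simulate_snvs(truth, scaffolds, p)
        dups = [(s, e) for _, s, e, _ in truth.duplications]
        for v in snvs:
            if "het" in v.genotypes.values():
                assert any(s <= v.pos <= e for s, e in dups)

    def test_ref_matches_sequence(self, small_dataset):
        seqs = {s.id: s.sequence for s in small_dataset.scaffolds}
        for v in small_dataset.snvs[:200]:
            assert seqs[v.scaffold][v.pos - 1] == v.ref


class TestCounts:
    def test_null_down_factor_ratio_near_one(self):
        p = small_params(seed=4)
        p.island_down_factor = 1.0
        p.island_queen_factor = 1.0
        scaffolds, _, _, truth = simulate_genome(p)
        table = simulate_counts(truth, p)
        med = table.counts.median(axis=1)
        isl = med[[g for g, r in truth.gene_regions.items() if r == "island"]]
        ldr = med[[g for g, r in truth.gene_regions.items() if r == "ldr"]]
        ratio = (isl.median() + 1) / (ldr.median() + 1)
        assert 0.3 < ratio < 3.0

    def test_down_factor_suppresses_island_genes(self, small_dataset):
        med = small_dataset.counts.counts.median(axis=1)
        regions = small_dataset.truth.gene_regions
        isl = med[[g for g, r in regions.items() if r == "island"]]
        ldr = med[[g for g, r in regions.items() if r == "ldr"]]
        assert isl.median() < ldr.median() / 5

    def test_zero_dispersion_poisson_fallback(self):
        p = small_params(seed=5)
        p.nb_dispersion = 0.0
        _, _, _, truth = simulate_genome(p)
        table = simulate_counts(truth, p)
        assert (table.counts.to_numpy() >= 0).all()


class TestSubstituteSnvs:
    def test_no_snvs_identity(self, small_dataset):
        s = small_dataset.scaffolds[0]
        assert substitute_snvs(s, [], "BR").sequence == s.sequence

    def test_hom_alt_substituted_het_untouched(self):
        from teislands.io_model import ScaffoldSeq, SNVRecord

        scaffold = ScaffoldSeq("s1", 8, "AAAAAAAA")
        hom = SNVRecord("s1", 5, "A", "G", {"BR": "hom_alt"}, {"BR": 30})
        het = SNVRecord("s1", 2, "A", "C", {"BR": "het"}, {"BR": 30})
        out = substitute_snvs(scaffold, [hom, het], "BR")
        assert out.sequence == "AAAAGAAA"


class TestPipelineClosure:
    def test_emitted_files_parse_through_io_model(self, small_dataset, dataset_dir):
        scaffolds = read_fasta(dataset_dir / "genome.fasta")
        assert [s.id for s in scaffolds] == [s.id for s in small_dataset.scaffolds]
        assert scaffolds[0].sequence == small_dataset.scaffolds[0].sequence

        features = read_gff(dataset_dir / "annotation.gff3")
        assert len(features) == len(small_dataset.features)
        genes = build_gene_models(features)
        assert len(genes) == len(small_dataset.genes)

        res = read_vcf_snvs(dataset_dir / "snvs.vcf", ["BR", "JP"])
        assert res.n_skipped == 0
        assert len(res.snvs) == len(small_dataset.snvs)
        assert res.snvs[0].genotypes == small_dataset.snvs[0].genotypes

        lengths = {s.id: s.length for s in scaffolds}
        for lineage in ("BR", "JP"):
            track = read_depth_table(
                dataset_dir / f"depth_{lineage}.tsv", lineage, lengths
            )
            for scaf, arr in track.depths.items():
                assert np.array_equal(
                    arr, small_dataset.coverage[lineage].depths[scaf]
                )

        table = read_count_table(
            dataset_dir / "counts.tsv", small_dataset.counts.groups
        )
        assert table.counts.equals(small_dataset.counts.counts)
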