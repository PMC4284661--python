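import numpy as np
import pytest
from Bio.Seq import Seq

from teislands.io_model import CoverageTrack, GeneModel, ScaffoldSeq, SNVRecord
from teislands.island_scan import Island, RegionPartition
from teislands.lineage_divergence import (
    annotate_snv_effect,
    classify_het_snvs,
    coverage_ratio_windows,
    flag_cnv_candidates,
    gene_dn_ds,
    region_deviation_summary,
    snv_region_summary,
)


def snv(scaffold, pos, gt="het", depth=60, ref="A", alt="G", lineage="BR"):
    return SNVRecord(
        scaffold, pos, ref, alt, {lineage: gt}, {lineage: depth}
    )


def track(lineage, arr):
    return CoverageTrack(lineage, {"s1": np.asarray(arr, dtype=np.int32)})


class TestCoverageRatio:
    def test_identical_tracks_all_deviation_zero(self):
        a = track("BR", np.full(3000, 40))
        b = track("JP", np.full(3000, 40))
        wins = coverage_ratio_windows(a, b)
        assert all(w.ratio == 1.0 and w.deviation == 0.0 for w in wins)

    def test_hand_median_normalization(self):
        # three windows with ratios 1, 1, 2 -> median 1, deviations 0, 0, 1
        a = track("BR", [10] * 1000 + [10] * 1000 + [20] * 1000)
        b = track("JP", [10] * 3000)
        wins = coverage_ratio_windows(a, b)
        assert [w.ratio for w in wins] == [1.0, 1.0, 2.0]
        assert [w.deviation for w in wins] == [0.0, 0.0, 1.0]

    def test_low_depth_window_masked(self):
        a = track("BR", [10] * 1000 + [10] * 1000)
        b = track("JP", [10] * 1000 + [2] * 1000)
        wins = coverage_ratio_windows(a, b, min_depth=5)
        assert [w.masked for w in wins] == [False, True]

    def test_all_masked_errors(self):
        a = track("BR", [1] * 1000)
        b = track("JP", [1] * 1000)
        with pytest.raises(ValueError):
            coverage_ratio_windows(a, b, min_depth=5)

    def test_mean_normalization_mode(self):
        a = track("BR", [10] * 1000 + [30] * 1000)
        b = track("JP", [10] * 2000)
        wins = coverage_ratio_windows(a, b, center="mean")
        # mean ratio = 2 -> deviations |1/2-1|, |3/2-1|
        assert [w.deviation for w in wins] == [0.5, 0.5]


class TestRegionDeviation:
    def _partition(self):
        return RegionPartition(
            {"s1": 1_000_000}, [Island("i1", "s1", 1, 2000, 0.5)]
        )

    def test_direct_medians(self):
        part = self._partition()
        a = track("BR", [20] * 2000 + [10] * 2000)
        b = track("JP", [10] * 4000)
        wins = coverage_ratio_windows(a, b)
        out = region_deviation_summary(wins, part)
        # median ratio over [2, 2, 1, 1] = 1.5; island d = |2/1.5 - 1|
        assert out["median_island"] == pytest.approx(abs(2 / 1.5 - 1))
        assert out["median_ldr"] == pytest.approx(abs(1 / 1.5 - 1))

    def test_all_zero_deviations(self):
        part = self._partition()
        a = track("BR", [10] * 4000)
        b = track("JP", [10] * 4000)
        out = region_deviation_summary(coverage_ratio_windows(a, b), part)
        assert out["median_island"] == 0.0
        assert out["median_ldr"] == 0.0
        assert out["p"] == 1.0

    def test_empty_island_flagged_undefined(self):
        part = RegionPartition({"s1": 1_000_000}, [])
        a = track("BR", [10] * 2000)
        b = track("JP", [10] * 2000)
        out = region_deviation_summary(coverage_ratio_windows(a, b), part)
        assert out["undefined"]
        assert np.isnan(out["median_island"])


class TestClassifyHets:
    def test_twofold_signature(self):
        cls = classify_het_snvs([snv("s1", 10, "het", 120)], "BR", 60)
        assert cls[0].label == "collapsed_duplication"
        assert cls[0].fold == 2.0

    def test_normal_depth_true_het(self):
        cls = classify_het_snvs([snv("s1", 10, "het", 60)], "BR", 60)
        assert cls[0].label == "true_het"

    def test_boundary_inclusive(self):
        cls = classify_het_snvs([snv("s1", 10, "het", 90)], "BR", 60, 1.5)
        assert cls[0].label == "collapsed_duplication"

    def test_hom_and_masked(self):
        cls = classify_het_snvs(
            [snv("s1", 10, "hom_alt", 60), snv("s1", 20, "het", 0)], "BR", 60
        )
        assert [c.label for c in cls] == ["hom", "masked"]

    def test_negative_threshold_errors(self):
        with pytest.raises(ValueError):
            classify_het_snvs([], "BR", 60, fold_threshold=-1)


class TestSnvRegionSummary:
    def test_toy_fraction(self):
        part = RegionPartition(
            {"s1": 1_000_000}, [Island("i1", "s1", 1, 10_000, 0.5)]
        )
        snvs = [snv("s1", 100 * k + 1, "hom_alt") for k in range(3)]  # inside
        snvs += [snv("s1", 500_000 + k, "hom_alt") for k in range(9)]  # outside
        out = snv_region_summary(snvs, part)
        assert out["n_island"] == 3
        assert out["n_total"] == 12
        assert out["island_share_pct"] == 25.0

    def test_counts_sum_per_category(self, small_dataset, small_report):
        part = small_report["_partition"]
        out = snv_region_summary(small_dataset.snvs, part)
        for rec in out["by_lineage_zygosity"].values():
            assert 0 <= rec["island"] <= rec["total"]
        assert out["n_total"] + out["n_unassigned"] == len(small_dataset.snvs)

    def test_no_snvs(self):
        part = RegionPartition({"s1": 1_000_000}, [])
        out = snv_region_summary([], part)
        assert out["n_total"] == 0
        assert out["island_share_pct"] == 0.0


def _gene_on(seq, cds_intervals, strand="+", gid="g1"):
    return GeneModel(gid, "s1", strand, cds_intervals, cds_intervals)


class TestAnnotateEffect:
    # scaffold: AAAA ATG GCT TAA AAAA  (CDS at 5..13)
    SEQ = "AAAAATGGCTTAAAAAA"

    def test_third_position_synonymous(self):
        gene = _gene_on(self.SEQ, [(5, 13)])
        v = snv("s1", 10, ref="T", alt="C")  # GCT -> GCC, Ala -> Ala
        assert annotate_snv_effect(v, gene, self.SEQ) == "synonymous"

    def test_second_position_nonsynonymous(self):
        gene = _gene_on(self.SEQ, [(5, 13)])
        v = snv("s1", 9, ref="C", alt="A")  # GCT -> GAT, Ala -> Asp
        assert annotate_snv_effect(v, gene, self.SEQ) == "nonsynonymous"

    def test_intron_noncoding(self):
        gene = GeneModel("g1", "s1", "+", [(5, 7), (11, 13)], [(5, 7), (11, 13)])
        v = snv("s1", 9, ref="C", alt="A")
        assert annotate_snv_effect(v, gene, self.SEQ) == "noncoding"

    def test_incomplete_cds_unknown(self):
        gene = _gene_on(self.SEQ, [(5, 12)])  # 8 bp, not divisible by 3
        v = snv("s1", 10, ref="T", alt="C")
        assert annotate_snv_effect(v, gene, self.SEQ) == "unknown"

    def test_n_in_codon_unknown(self):
        seq = "AAAAATGGNTTAAAAAA"
        gene = _gene_on(seq, [(5, 13)])
        v = snv("s1", 10, ref="T", alt="C")
        assert annotate_snv_effect(v, gene, seq) == "unknown"

    def test_minus_strand(self):
        # CDS revcomp(ATG GAT TAA) on the plus strand at 3..11
        plus = str(Seq("ATGGATTAA").reverse_complement())
        seq = "AA" + plus + "AAAA"
        gene = _gene_on(seq, [(3, 11)], strand="-")
        # mutate the codon GAT's second base (plus-strand position of CDS
        # offset 4 is total-1-4 = offset 4 from the right end): compute ref
        cds_pos = 4  # 0-based within the minus-strand CDS: the A of GAT
        plus_pos = 11 - cds_pos  # = 7
        ref = seq[plus_pos - 1]
        alt = str(Seq("C").reverse_complement())  # minus-strand A->C change
        v = snv("s1", plus_pos, ref=ref, alt=alt)
        # GAT -> GCT is Asp -> Ala: nonsynonymous
        assert annotate_snv_effect(v, gene, seq) == "nonsynonymous"

    def test_brute_force_oracle_agreement(self):
        """Codon-level labels match retranslating the whole mutated CDS."""
        rng = np.random.default_rng(11)
        n_checked = 0
        while n_checked < 60:
            gene, seq = _random_gene(rng)
            cds_positions = [
                p for s, e in gene.cds for p in range(s, e + 1)
            ]
            pos = int(rng.choice(cds_positions))
            ref = seq[pos - 1]
            alt = "ACGT"["ACGT".index(ref) - int(rng.integers(1, 4))]
            v = snv("s1", pos, ref=ref, alt=alt)
            got = annotate_snv_effect(v, gene, seq)
            assert got == _oracle_effect(v, gene, seq)
            n_checked += 1


def _random_gene(rng, scaffold_len=2_000):
    n_ex = int(rng.integers(1, 4))
    lens = [int(rng.integers(2, 30)) * 1 for _ in range(n_ex)]
    # force total divisible by 3
    total = sum(lens)
    lens[-1] += (3 - total % 3) % 3
    seq = "".join(rng.choice(list("ACGT"), size=scaffold_len))
    pos = int(rng.integers(1, scaffold_len // 2))
    cds = []
    for L in lens:
        cds.append((pos, pos + L - 1))
        pos += L + int(rng.integers(5, 50))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel("g", "s1", strand, cds, cds), seq


def _oracle_effect(v, gene, seq):
    """Independent oracle: rebuild and translate the full CDS for both alleles."""
    mutated = seq[: v.pos - 1] + v.alt + seq[v.pos :]
    if seq[v.pos - 1] != v.ref:
        return "unknown"

    def protein(s):
        cds = "".join(s[a - 1 : b] for a, b in gene.cds)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    in_cds = any(a <= v.pos <= b for a, b in gene.cds)
    if not in_cds:
        return "noncoding"
    if gene.cds_length % 3:
        return "unknown"
    return "synonymous" if protein(seq) == protein(mutated) else "nonsynonymous"


class TestGeneDnDs:
    def _setup(self):
        part = RegionPartition(
            {"s1": 1_000_000}, [Island("i1", "s1", 1, 10_000, 0.5)]
        )
        g_isl = GeneModel("gi", "s1", "+", [(100, 399)], [(100, 399)])
        g_ldr = GeneModel("gl", "s1", "+", [(500_000, 500_299)], [(500_000, 500_299)])
        return part, [g_isl, g_ldr]

    def test_fraction_and_exclusion(self):
        part, genes = self._setup()
        effects = [("gi", "nonsynonymous")] * 2 + [("gi", "synonymous")] * 2
        records, cmp_ = gene_dn_ds(effects, genes, part)
        by_id = {r.gene_id: r for r in records}
        assert by_id["gi"].fraction == 0.5
        assert by_id["gl"].fraction is None  # dN+dS = 0: excluded
        assert cmp_["n_ldr"] == 0

    def test_direct_fractions(self):
        part, genes = self._setup()
        effects = (
            [("gi", "nonsynonymous")] * 3 + [("gi", "synonymous")]
            + [("gl", "nonsynonymous")] + [("gl", "synonymous")] * 3
        )
        records, cmp_ = gene_dn_ds(effects, genes, part)
        by_id = {r.gene_id: r for r in records}
        assert by_id["gi"].fraction == 0.75
        assert by_id["gl"].fraction == 0.25
        assert cmp_["syn_per_cds_kb_island"] == pytest.approx(1000 / 300)
        assert cmp_["syn_per_cds_kb_ldr"] == pytest.approx(3000 / 300)


class TestCnvCandidates:
    def _windows(self, deviations, masked=None):
        from teislands.lineage_divergence import CoverageRatioWindow

        masked = masked or [False] * len(deviations)
        return [
            CoverageRatioWindow(
                "s1", i * 1000 + 1, (i + 1) * 1000, 1.0, d, m
            )
            for i, (d, m) in enumerate(zip(deviations, masked))
        ]

    def test_single_window_flagged(self):
        df = flag_cnv_candidates(self._windows([0.0, 1.0, 0.0]), [], 0.5)
        assert len(df) == 1
        assert df.loc[0, ["start", "end"]].tolist() == [1001, 2000]

    def test_uniform_ratio_no_candidates(self):
        df = flag_cnv_candidates(self._windows([0.0, 0.0]), [], 0.5)
        assert len(df) == 0

    def test_adjacent_windows_merged(self):
        df = flag_cnv_candidates(self._windows([0.0, 0.9, 0.8, 0.0]), [], 0.5)
        assert len(df) == 1
        assert df.loc[0, "start"] == 1001
        assert df.loc[0, "end"] == 3000
        assert df.loc[0, "deviation"] == 0.9

    def test_gene_overlap_annotated(self):
        gene = GeneModel("g1", "s1", "+", [(1200, 1400)], [])
        df = flag_cnv_candidates(self._windows([0.0, 1.0]), [gene], 0.5)
        assert df.loc[0, "genes"] == "g1"
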