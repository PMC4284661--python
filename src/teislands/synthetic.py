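"""Synthetic genomes with planted TE islands, for recovery and direction tests.

The generator emulates the statistical structure the analysis assumes on a
pair of inbred, pooled-sequenced lineages sharing one reference assembly:

* scaffolds with a uniform background sequence and planted high-TE islands
  (annotation-only TE copies, longer inside islands, superfamily weights
  optionally island-biased);
* protein-coding genes (valid CDS frames) whose exon sequence is CpG-depleted
  inside islands, with the depletion coupled to a latent expression level so
  island and LDR genes show opposite o/e-vs-expression trends;
* per-base Poisson coverage per lineage with collapsed duplications planted
  inside islands (depth doubled in one randomly chosen lineage);
* homozygous SNVs at region-specific rates, spurious heterozygous SNVs inside
  the planted duplications, background true heterozygous SNVs elsewhere;
* negative-binomial read counts with island genes down-scaled and a
  group (queen vs larva) effect applied to island genes only.

All randomness flows from one seed; outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    AnnotationFeature,
    CountTable,
    CoverageTrack,
    GeneModel,
    ScaffoldSeq,
    SNVRecord,
    write_count_table,
    write_depth_table,
    write_fasta,
    write_gff,
)

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_coverage",
    "simulate_snvs",
    "simulate_counts",
    "simulate_dataset",
    "substitute_snvs",
    "write_dataset",
    "write_vcf",
    "load_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_PATCH = {"TAA": "TCA", "TAG": "TTG", "TGA": "TCA"}

# (name, class, weight, island_bias): bias multiplies the weight inside islands
DEFAULT_SUPERFAMILIES = (
    ("Gypsy", "I", 3.0, 1.0),
    ("LINE-R1", "I", 2.0, 1.0),
    ("BEL-Pao", "I", 1.0, 3.0),
    ("DIRS", "I", 0.5, 3.0),
    ("hAT", "II", 2.0, 1.0),
    ("TcMar-Mariner", "II", 1.0, 3.0),
    ("Helitron", "II", 1.5, 1.0),
    ("Maverick", "II", 0.5, 2.0),
)


@dataclass
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Defaults are desk-scale: 3 scaffolds of 2 Mb with 2 planted 300 kb-scale
    islands, TE occupancy 0.45 inside islands vs 0.05 outside, island TE
    copies drawn longer, 60x Poisson coverage per lineage, and an island
    expression down-factor of 0.02.
    """

    seed: int = 0
    lineages: tuple = ("BR", "JP")
    n_scaffolds: int = 3
    scaffold_length: int = 2_000_000
    n_islands: int = 2
    island_length_range: tuple = (250_000, 350_000)
    te_density_island: float = 0.45
    te_density_ldr: float = 0.05
    te_length_island: tuple = (1_500, 6_000)
    te_length_ldr: tuple = (200, 1_500)
    superfamilies: tuple = DEFAULT_SUPERFAMILIES
    gene_gap_mean: float = 4_000.0
    n_exons_range: tuple = (2, 6)
    exon_codons_range: tuple = (40, 200)
    intron_length_range: tuple = (200, 2_000)
    minus_strand_prob: float = 0.5
    hom_snv_rate_island: float = 2.0  # per kb
    hom_snv_rate_ldr: float = 0.5
    het_snv_rate: float = 0.05  # background true hets, per kb
    dup_het_rate: float = 5.0  # spurious hets inside duplications, per kb
    n_duplications: int = 8
    dup_length_range: tuple = (3_000, 8_000)
    depth: float = 60.0
    # per-kb-block lognormal depth multiplier per lineage: local mapping
    # efficiency varies where the pools diverge from the reference, most
    # strongly inside islands — the dominant source of coverage-ratio
    # deviation at pool scale
    depth_noise_sigma_island: float = 0.25
    depth_noise_sigma_ldr: float = 0.10
    depth_noise_block: int = 1_000
    cpg_depletion_island: float = 0.5
    expression_log_mean: float = 3.0
    expression_log_sigma: float = 1.5
    nb_dispersion: float = 0.3
    island_down_factor: float = 0.02
    island_queen_factor: float = 4.0
    n_queens: int = 4
    n_larvae: int = 4
    library_size_sigma: float = 0.2

    def validate(self) -> None:
        if self.te_density_island >= 1.0 or self.te_density_ldr >= 1.0:
            raise ValueError("TE densities must be below full occupancy")
        for rate in (
            self.te_density_island,
            self.te_density_ldr,
            self.hom_snv_rate_island,
            self.hom_snv_rate_ldr,
            self.het_snv_rate,
            self.dup_het_rate,
        ):
            if rate < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted structure: what a perfect analysis should recover."""

    islands: list  # (scaffold, start, end)
    duplications: list  # (scaffold, start, end, affected lineage)
    gene_regions: dict  # gene id -> island / ldr
    snv_classes: dict  # (scaffold, pos) -> hom / true_het / collapsed_duplication
    gene_base_means: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    scaffolds: list
    features: list
    genes: list
    snvs: list
    coverage: dict  # lineage -> CoverageTrack
    counts: CountTable
    truth: SyntheticTruth


def _random_seq_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int64)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _place_intervals(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    density: float,
    length_range: tuple,
) -> list[tuple[int, int]]:
    """Non-overlapping intervals covering ~density of [lo, hi] via a renewal
    walk: exponential gaps tuned so expected occupancy equals density."""
    if density <= 0:
        return []
    mean_len = (length_range[0] + length_range[1]) / 2.0
    mean_gap = mean_len * (1.0 - density) / density
    out = []
    pos = lo + int(rng.exponential(mean_gap))
    while True:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if pos + length - 1 > hi:
            break
        out.append((pos, pos + length - 1))
        pos = pos + length + int(rng.exponential(mean_gap)) + 1
    return out


def _gene_cds_codes(
    rng: np.random.Generator, n_codons: int, cpg_keep: float
) -> np.ndarray:
    """Uniform-random CDS (codes): ATG start, TAA stop, no internal stops,
    then CG dinucleotides thinned to a survival probability ``cpg_keep``."""
    codes = _random_seq_codes(rng, n_codons * 3)
    codes[0:3] = [0, 3, 2]  # ATG
    codes[-3:] = [3, 0, 0]  # TAA
    arr = np.frombuffer(bytes(_patch_stops(bytearray(_BASES[codes]))),
                        dtype=np.uint8).copy()
    if cpg_keep < 1.0:
        c, g = ord("C"), ord("G")
        cg = np.where((arr[:-1] == c) & (arr[1:] == g))[0]
        kill = cg[rng.random(len(cg)) >= cpg_keep]
        if len(kill):
            # replace the G with A or T: destroys the CpG without creating a
            # new one; the substitution can produce a stop codon (e.g.
            # TGG -> TAG, GAA -> TAA), so stops are patched again below
            repl = rng.integers(0, 2, size=len(kill))
            arr[kill + 1] = np.where(repl == 0, ord("A"), ord("T"))
        arr = np.frombuffer(bytes(_patch_stops(bytearray(arr.tobytes()))),
                            dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int64)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    return lut[arr]


def _patch_stops(seq: bytearray) -> bytearray:
    """Rewrite internal stop codons to near-neighbours that introduce no CpG."""
    for i in range(3, len(seq) - 3, 3):
        patched = _STOP_PATCH.get(seq[i : i + 3].decode())
        if patched:
            seq[i : i + 3] = patched.encode()
    return seq


_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


def simulate_genome(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list, list, list, SyntheticTruth]:
    """Simulate scaffolds, TE/gene annotation and planted-island truth.

    Returns (scaffolds, features, gene_models, truth).  Deterministic given
    ``params.seed`` (or a caller-supplied generator).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    scaffold_names = [f"scf{i + 1}" for i in range(params.n_scaffolds)]
    L = params.scaffold_length

    # plant islands on randomly chosen scaffolds, away from scaffold edges
    islands: list[tuple[str, int, int]] = []
    island_by_scaf: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffold_names}
    margin = min(100_000, max(1, L // 10))
    for k in range(params.n_islands):
        for _ in range(100):
            scaf = scaffold_names[int(rng.integers(0, params.n_scaffolds))]
            ilen = int(rng.integers(*params.island_length_range))
            start = int(rng.integers(margin, L - margin - ilen))
            iv = (start, start + ilen - 1)
            if all(
                iv[1] + 50_000 < s or iv[0] - 50_000 > e
                for s, e in island_by_scaf[scaf]
            ):
                island_by_scaf[scaf].append(iv)
                islands.append((scaf, *iv))
                break
        else:
            raise RuntimeError("could not place all islands")
    for ivs in island_by_scaf.values():
        ivs.sort()

    sf_names = [s[0] for s in params.superfamilies]
    sf_class = {s[0]: s[1] for s in params.superfamilies}
    w_ldr = np.array([s[2] for s in params.superfamilies], dtype=float)
    w_isl = np.array([s[2] * s[3] for s in params.superfamilies], dtype=float)
    w_ldr /= w_ldr.sum()
    w_isl /= w_isl.sum()

    features: list[AnnotationFeature] = []
    genes: list[GeneModel] = []
    gene_regions: dict[str, str] = {}
    gene_base_means: dict[str, float] = {}
    scaffolds: list[ScaffoldSeq] = []
    gene_no = 0

    for scaf in scaffold_names:
        codes = _random_seq_codes(rng, L)
        te_mask = np.zeros(L, dtype=bool)

        # region segments: complement of islands is LDR
        segments: list[tuple[int, int, bool]] = []
        pos = 1
        for s, e in island_by_scaf[scaf]:
            if s > pos:
                segments.append((pos, s - 1, False))
            segments.append((s, e, True))
            pos = e + 1
        if pos <= L:
            segments.append((pos, L, False))

        for s, e, is_island in segments:
            density = params.te_density_island if is_island else params.te_density_ldr
            lrange = params.te_length_island if is_island else params.te_length_ldr
            weights = w_isl if is_island else w_ldr
            for ts, te_ in _place_intervals(rng, s, e, density, lrange):
                sf = sf_names[int(rng.choice(len(sf_names), p=weights))]
                features.append(
                    AnnotationFeature(
                        scaffold=scaf,
                        start=ts,
                        end=te_,
                        strand="+" if rng.random() < 0.5 else "-",
                        kind="te_copy",
                        attrs={"superfamily": sf, "te_class": sf_class[sf]},
                    )
                )
                te_mask[ts - 1 : te_] = True

        te_prefix = np.concatenate([[0], np.cumsum(te_mask)])

        # genes: sequential walk, reject placements with >= 50% TE overlap
        pos = 1 + int(rng.exponential(params.gene_gap_mean))
        while True:
            n_ex = int(rng.integers(*params.n_exons_range))
            ex_codons = rng.integers(*params.exon_codons_range, size=n_ex)
            introns = rng.integers(*params.intron_length_range, size=n_ex - 1)
            span = int(ex_codons.sum() * 3 + introns.sum())
            placed = False
            for _ in range(5):
                if pos + span - 1 > L:
                    break
                overlap = te_prefix[pos + span - 1] - te_prefix[pos - 1]
                if overlap / span < 0.5:
                    placed = True
                    break
                pos += max(span // 2, 1000)
            if pos + span - 1 > L:
                break
            if not placed:
                pos += span + int(rng.exponential(params.gene_gap_mean))
                continue

            gene_no += 1
            gid = f"gene_{gene_no:05d}"
            strand = "-" if rng.random() < params.minus_strand_prob else "+"
            exons = []
            p = pos
            for i, nc in enumerate(ex_codons):
                exons.append((p, p + int(nc) * 3 - 1))
                p = exons[-1][1] + 1 + (int(introns[i]) if i < n_ex - 1 else 0)
            mid = (pos + pos + span - 1) // 2
            region = (
                "island"
                if any(s <= mid <= e for s, e in island_by_scaf[scaf])
                else "ldr"
            )
            base_mean = float(
                rng.lognormal(params.expression_log_mean, params.expression_log_sigma)
            )
            gene_regions[gid] = region
            gene_base_means[gid] = base_mean

            # CpG survival coupled to the latent expression percentile:
            # decreasing for LDR genes, increasing (and lower) inside islands
            u = _lognormal_percentile(
                base_mean, params.expression_log_mean, params.expression_log_sigma
            )
            if region == "island":
                keep = params.cpg_depletion_island * (0.8 + 0.4 * u)
            else:
                keep = min(1.0, 1.05 - 0.45 * u)

            cds_codes = _gene_cds_codes(rng, int(ex_codons.sum()), keep)
            if strand == "-":
                lut = np.array([3, 2, 1, 0])
                cds_codes = lut[cds_codes[::-1]]
            off = 0
            for s, e in exons:
                codes[s - 1 : e] = cds_codes[off : off + (e - s + 1)]
                off += e - s + 1

            features.append(
                AnnotationFeature(
                    scaffold=scaf, start=pos, end=pos + span - 1, strand=strand,
                    kind="gene", attrs={"ID": gid},
                )
            )
            for s, e in exons:
                for kind in ("exon", "CDS"):
                    features.append(
                        AnnotationFeature(
                            scaffold=scaf, start=s, end=e, strand=strand,
                            kind=kind, attrs={"Parent": gid},
                        )
                    )
            genes.append(
                GeneModel(id=gid, scaffold=scaf, strand=strand, exons=exons, cds=exons)
            )
            pos = pos + span + int(rng.exponential(params.gene_gap_mean))

        scaffolds.append(ScaffoldSeq(scaf, L, _codes_to_str(codes)))

    # planted duplications: inside islands, non-overlapping, one affected lineage
    duplications: list[tuple[str, int, int, str]] = []
    for _ in range(params.n_duplications):
        for _ in range(200):
            scaf, s, e = islands[int(rng.integers(0, len(islands)))]
            dlen = int(rng.integers(*params.dup_length_range))
            if e - s < dlen + 2:
                continue
            ds = int(rng.integers(s, e - dlen))
            de = ds + dlen - 1
            if all(
                sc != scaf or de < a or ds > b for sc, a, b, _ in duplications
            ):
                lineage = params.lineages[int(rng.integers(0, 2))]
                duplications.append((scaf, ds, de, lineage))
                break
        else:
            raise RuntimeError("could not place all duplications")

    truth = SyntheticTruth(
        islands=islands,
        duplications=duplications,
        gene_regions=gene_regions,
        snv_classes={},
        gene_base_means=gene_base_means,
        params=asdict(params),
    )
    return scaffolds, features, genes, truth


def _lognormal_percentile(x: float, mu: float, sigma: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf((np.log(x) - mu) / sigma))


def simulate_coverage(
    truth: SyntheticTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-base Poisson depth per lineage; planted duplications are doubled in
    their affected lineage.

    On top of the Poisson sampling, each ``depth_noise_block`` gets an
    independent lognormal depth multiplier per lineage (sigma larger inside
    islands), emulating locally varying mapping efficiency between diverged
    pools — without it the coverage-ratio deviation would be pure counting
    noise, which real pooled data is not.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    L = params.scaffold_length
    block = params.depth_noise_block
    scaffold_names = [f"scf{i + 1}" for i in range(params.n_scaffolds)]
    island_by_scaf: dict[str, list] = {}
    for scaf, s, e in truth.islands:
        island_by_scaf.setdefault(scaf, []).append((s, e))
    tracks = {}
    for lineage in params.lineages:
        depths = {}
        for scaf in scaffold_names:
            lam = np.full(L, params.depth)
            for dscaf, ds, de, dlin in truth.duplications:
                if dscaf == scaf and dlin == lineage:
                    lam[ds - 1 : de] *= 2.0
            n_blocks = (L + block - 1) // block
            sigma = np.full(n_blocks, params.depth_noise_sigma_ldr)
            mids = np.arange(n_blocks) * block + block // 2 + 1
            for s, e in island_by_scaf.get(scaf, []):
                sigma[(mids >= s) & (mids <= e)] = params.depth_noise_sigma_island
            mult = np.exp(rng.normal(0.0, 1.0, size=n_blocks) * sigma)
            lam *= np.repeat(mult, block)[:L]
            depths[scaf] = (
                rng.poisson(lam).astype(np.int32)
                if params.depth > 0
                else np.zeros(L, dtype=np.int32)
            )
        tracks[lineage] = CoverageTrack(lineage=lineage, depths=depths)
    return tracks


def simulate_snvs(
    truth: SyntheticTruth,
    scaffolds: list,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list:
    """Place SNVs and record their true classes in ``truth.snv_classes``.

    Homozygous divergence SNVs fall at region-specific rates (hom_alt in one
    random lineage); background true hets at ``het_snv_rate``; spurious hets
    inside planted duplications at ``dup_het_rate`` in the affected lineage,
    with doubled read depth.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    lin_a, lin_b = params.lineages
    seq_by_scaf = {s.id: s.sequence for s in scaffolds}
    island_by_scaf: dict[str, list] = {}
    for scaf, s, e in truth.islands:
        island_by_scaf.setdefault(scaf, []).append((s, e))
    dup_by_scaf: dict[str, list] = {}
    for scaf, s, e, lin in truth.duplications:
        dup_by_scaf.setdefault(scaf, []).append((s, e, lin))

    snvs: list[SNVRecord] = []
    used: set[tuple[str, int]] = set()

    def _dup_lineage(scaf: str, pos: int) -> str | None:
        for s, e, lin in dup_by_scaf.get(scaf, []):
            if s <= pos <= e:
                return lin
        return None

    def _draw_positions(scaf: str, lo: int, hi: int, rate_per_kb: float) -> np.ndarray:
        n = rng.poisson(rate_per_kb * (hi - lo + 1) / 1000.0)
        if n == 0:
            return np.array([], dtype=np.int64)
        return rng.integers(lo, hi + 1, size=n)

    def _add(scaf: str, pos: int, kind: str, het_lineage: str | None = None) -> None:
        key = (scaf, int(pos))
        if key in used:
            return
        used.add(key)
        ref = seq_by_scaf[scaf][pos - 1]
        alt = "ACGT"["ACGT".index(ref) - int(rng.integers(1, 4))]
        dup_lin = _dup_lineage(scaf, pos)
        # site depth is Poisson around 1x / 2x: the collapsed-duplication
        # signature the classifier is built for
        depths = {}
        for lin in params.lineages:
            lam = params.depth * (2.0 if dup_lin == lin else 1.0)
            depths[lin] = int(rng.poisson(lam)) if lam > 0 else 0
        if kind == "hom":
            carrier = params.lineages[int(rng.integers(0, 2))]
            genotypes = {
                lin: (HOM_ALT if lin == carrier else HOM_REF)
                for lin in params.lineages
            }
        else:
            genotypes = {
                lin: (HET if lin == het_lineage else HOM_REF)
                for lin in params.lineages
            }
        snvs.append(
            SNVRecord(
                scaffold=scaf, pos=int(pos), ref=ref, alt=alt,
                genotypes=genotypes, depths=depths,
            )
        )
        truth.snv_classes[key] = kind

    for scaffold in scaffolds:
        scaf = scaffold.id
        segments: list[tuple[int, int, bool]] = []
        pos = 1
        for s, e in sorted(island_by_scaf.get(scaf, [])):
            if s > pos:
                segments.append((pos, s - 1, False))
            segments.append((s, e, True))
            pos = e + 1
        if pos <= scaffold.length:
            segments.append((pos, scaffold.length, False))
        for lo, hi, is_island in segments:
            rate = (
                params.hom_snv_rate_island if is_island else params.hom_snv_rate_ldr
            )
            for p in _draw_positions(scaf, lo, hi, rate):
                _add(scaf, p, "hom")
            for p in _draw_positions(scaf, lo, hi, params.het_snv_rate):
                _add(
                    scaf, p, "true_het",
                    het_lineage=params.lineages[int(rng.integers(0, 2))],
                )
    for scaf, s, e, lin in truth.duplications:
        for p in _draw_positions(scaf, s, e, params.dup_het_rate):
            _add(scaf, p, "collapsed_duplication", het_lineage=lin)

    snvs.sort(key=lambda v: (v.scaffold, v.pos))
    return snvs


def simulate_counts(
    truth: SyntheticTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Negative-binomial gene counts: island genes down-scaled, queen-group
    effect applied to island genes only, per-sample library-size factors."""
    if rng is None:
        rng = np.random.default_rng(params.seed + 3)
    samples = [f"queen_{i + 1}" for i in range(params.n_queens)] + [
        f"larva_{i + 1}" for i in range(params.n_larvae)
    ]
    groups = {s: ("queen" if s.startswith("queen") else "larva") for s in samples}
    lib = np.exp(rng.normal(0.0, params.library_size_sigma, size=len(samples)))
    gene_ids = sorted(truth.gene_regions)
    data = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    disp = params.nb_dispersion
    for gi, gid in enumerate(gene_ids):
        base = truth.gene_base_means[gid]
        if truth.gene_regions[gid] == "island":
            base *= params.island_down_factor
        for sj, sample in enumerate(samples):
            mu = base * lib[sj]
            if truth.gene_regions[gid] == "island" and groups[sample] == "queen":
                mu *= params.island_queen_factor
            if mu <= 0:
                continue
            if disp > 0:
                n = 1.0 / disp
                p = n / (n + mu)
                data[gi, sj] = rng.negative_binomial(n, p)
            else:
                data[gi, sj] = rng.poisson(mu)
    counts = pd.DataFrame(data, index=gene_ids, columns=samples)
    return CountTable(counts=counts, groups=groups)


def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Run the whole generator in dependency order from one seed."""
    scaffolds, features, genes, truth = simulate_genome(params)
    coverage = simulate_coverage(truth, params)
    snvs = simulate_snvs(truth, scaffolds, params)
    counts = simulate_counts(truth, params)
    return SyntheticDataset(
        scaffolds=scaffolds, features=features, genes=genes, snvs=snvs,
        coverage=coverage, counts=counts, truth=truth,
    )


def substitute_snvs(scaffold: ScaffoldSeq, snvs: list, lineage: str) -> ScaffoldSeq:
    """Lineage consensus: hom_alt positions substituted, hets left as reference."""
    if scaffold.sequence is None:
        raise ValueError("scaffold has no sequence")
    seq = bytearray(scaffold.sequence, "ascii")
    for v in snvs:
        if v.scaffold != scaffold.id:
            continue
        if v.genotypes.get(lineage) == HOM_ALT:
            seq[v.pos - 1] = ord(v.alt)
    return ScaffoldSeq(scaffold.id, scaffold.length, seq.decode("ascii"))


# ---------------------------------------------------------------------------
# file emission (the exact dialects io_model reads)
# ---------------------------------------------------------------------------

_GT_CODE = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}


def write_vcf(
    snvs: list, lineages: tuple, path: str | Path, contigs: dict | None = None
) -> None:
    """Write SNVs as a minimal VCF 4.2 with GT:DP per lineage sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(lineages)
            + "\n"
        )
        for v in snvs:
            cells = [
                f"{_GT_CODE.get(v.genotypes.get(lin), './.')}:{v.depths.get(lin, 0)}"
                for lin in lineages
            ]
            fh.write(
                f"{v.scaffold}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    payload = {
        "islands": [list(x) for x in truth.islands],
        "duplications": [list(x) for x in truth.duplications],
        "gene_regions": truth.gene_regions,
        "snv_classes": {f"{s}:{p}": c for (s, p), c in truth.snv_classes.items()},
        "gene_base_means": truth.gene_base_means,
        "params": truth.params,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    with open(outdir / "truth_islands.bed", "w") as fh:
        for k, (scaf, s, e) in enumerate(sorted(truth.islands), 1):
            fh.write(f"{scaf}\t{s - 1}\t{e}\ttrue_island_{k}\n")


def load_truth(dataset_dir: str | Path) -> SyntheticTruth:
    payload = json.loads((Path(dataset_dir) / "truth.json").read_text())
    return SyntheticTruth(
        islands=[tuple(x) for x in payload["islands"]],
        duplications=[tuple(x) for x in payload["duplications"]],
        gene_regions=payload["gene_regions"],
        snv_classes={
            (k.split(":")[0], int(k.split(":")[1])): v
            for k, v in payload["snv_classes"].items()
        },
        gene_base_means=payload.get("gene_base_means", {}),
        params=payload.get("params", {}),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict:
    """Write every artifact of one dataset; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff": outdir / "annotation.gff3",
        "vcf": outdir / "snvs.vcf",
        "counts": outdir / "counts.tsv",
    }
    write_fasta(ds.scaffolds, paths["fasta"])
    write_gff(ds.features, paths["gff"])
    write_vcf(
        ds.snvs, tuple(ds.coverage), paths["vcf"],
        contigs={s.id: s.length for s in ds.scaffolds},
    )
    write_count_table(ds.counts, paths["counts"])
    for lineage, track in ds.coverage.items():
        p = outdir / f"depth_{lineage}.tsv"
        write_depth_table(track, p)
        paths[f"depth_{lineage}"] = p
    write_truth(ds.truth, outdir)
    paths["truth"] = outdir / "truth.json"
    return paths
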