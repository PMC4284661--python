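"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 1-based inclusive (GFF convention); conversion to
0-based half-open happens only at BED boundaries.  Strand is carried on every
feature but only coding-effect annotation uses it — density computations are
strand-blind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("teislands")

#: zygosity labels used throughout
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"
ZYGOSITIES = (HOM_REF, HOM_ALT, HET, MISSING)

_VALID_BASES = frozenset("ACGTN")


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains the same record id twice."""


@dataclass
class ScaffoldSeq:
    """One assembly scaffold; sequence is optional (length-only workflows)."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.id}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"scaffold {self.id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class AnnotationFeature:
    """A genomic interval: TE copy, gene, exon or CDS (1-based inclusive)."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    kind: str = "te_copy"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.kind} on {self.scaffold}: bad interval "
                f"[{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene with ordered exon and CDS intervals on one scaffold.

    ``exons`` and ``cds`` are lists of (start, end) 1-based inclusive tuples,
    sorted by start.  ``complete`` is False when the summed CDS length is not
    a multiple of three (effect annotation then reports ``unknown``).
    """

    id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] <= prev[1]:
                raise ValueError(f"gene {self.id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0


@dataclass
class SNVRecord:
    """A biallelic SNV with per-lineage zygosity and read depth."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    genotypes: dict  # lineage -> zygosity label
    depths: dict  # lineage -> read depth
    effect: str = "unknown"  # synonymous / nonsynonymous / noncoding / unknown

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"SNV {self.scaffold}:{self.pos}: ref == alt")
        for lineage, depth in self.depths.items():
            if depth < 0:
                raise ValueError(
                    f"SNV {self.scaffold}:{self.pos}: negative depth for {lineage}"
                )


@dataclass
class CoverageTrack:
    """Per-base read depth for one lineage, one array per scaffold.

    Position p (1-based) lives at index p-1.  Positions never reported in the
    source file have depth 0.
    """

    lineage: str
    depths: dict  # scaffold -> np.ndarray of int depth

    def window_means(self, scaffold: str, window: int) -> np.ndarray:
        """Mean depth per non-overlapping window (terminal partial included)."""
        arr = self.depths[scaffold]
        starts = np.arange(0, len(arr), window)
        sums = np.add.reduceat(arr.astype(np.float64), starts)
        eff = np.minimum(window, len(arr) - starts)
        return sums / eff


@dataclass
class CountTable:
    """Gene x sample read counts plus a sample -> group map."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: dict  # sample id -> group label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative counts")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")


class VcfReadResult(NamedTuple):
    snvs: list
    n_skipped: int


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ScaffoldSeq]:
    """Read scaffolds from FASTA; sequences uppercased, ids must be unique.

    Ambiguity codes other than N are rejected so downstream dinucleotide
    counting is well-defined.
    """
    records: list[ScaffoldSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"scaffold {rec.id}: unsupported characters {sorted(bad)}"
            )
        records.append(ScaffoldSeq(rec.id, len(seq), seq))
    return records


def _parse_gff_attrs(col9: str) -> dict:
    attrs = {}
    for chunk in col9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_gff(
    path: str | Path,
    kinds_filter: Iterable[str] = ("te_copy", "gene", "exon", "CDS"),
) -> list[AnnotationFeature]:
    """Read GFF3 features of the requested kinds (column 3 values).

    Lines with start > end are rejected with a logged warning; kinds not in
    ``kinds_filter`` are silently skipped.  Coordinates stay 1-based inclusive.
    """
    kinds = set(kinds_filter)
    feats: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                logger.warning("%s:%d: fewer than 9 columns, skipped", path, lineno)
                continue
            kind = cols[2]
            if kind not in kinds:
                continue
            start, end = int(cols[3]), int(cols[4])
            if start > end:
                logger.warning(
                    "%s:%d: start %d > end %d, line rejected", path, lineno, start, end
                )
                continue
            feats.append(
                AnnotationFeature(
                    scaffold=cols[0],
                    start=start,
                    end=end,
                    strand=cols[6] if cols[6] in "+-" else ".",
                    kind=kind,
                    attrs=_parse_gff_attrs(cols[8]),
                )
            )
    return feats


def build_gene_models(features: list[AnnotationFeature]) -> list[GeneModel]:
    """Assemble GeneModel objects from gene/exon/CDS features (Parent links)."""
    genes: dict[str, AnnotationFeature] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.kind == "gene":
            gid = f.attrs.get("ID")
            if gid:
                genes[gid] = f
        elif f.kind in ("exon", "CDS"):
            parent = f.attrs.get("Parent")
            if parent is None:
                continue
            target = exons if f.kind == "exon" else cds
            target.setdefault(parent, []).append((f.start, f.end))
    models = []
    for gid, g in genes.items():
        if gid not in exons:
            continue
        models.append(
            GeneModel(
                id=gid,
                scaffold=g.scaffold,
                strand=g.strand,
                exons=exons[gid],
                cds=cds.get(gid, []),
            )
        )
    return models


_GT_MAP = {0: HOM_REF, 1: HET, 2: HOM_ALT, 3: MISSING}


def read_vcf_snvs(path: str | Path, lineage_labels: list[str]) -> VcfReadResult:
    """Read biallelic SNVs from a VCF with one sample column per lineage.

    Non-SNV records (indels, multiallelics) are skipped and counted.  Genotypes
    map to zygosity labels; per-sample DP is captured (0 when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for label in lineage_labels:
        if label not in samples:
            raise ValueError(f"sample {label!r} not in VCF (has {samples})")
    idx = {label: samples.index(label) for label in lineage_labels}

    snvs: list[SNVRecord] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt_types = var.gt_types
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        depths = {}
        genotypes = {}
        for label in lineage_labels:
            i = idx[label]
            genotypes[label] = _GT_MAP.get(int(gt_types[i]), MISSING)
            depths[label] = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else 0
        snvs.append(
            SNVRecord(
                scaffold=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                genotypes=genotypes,
                depths=depths,
            )
        )
    return VcfReadResult(snvs, n_skipped)


def read_depth_table(
    path: str | Path, lineage: str, scaffold_lengths: dict | None = None
) -> CoverageTrack:
    """Read a 3-column samtools-depth TSV (scaffold, 1-based pos, depth).

    Positions absent from the file get depth 0.  ``scaffold_lengths`` sizes the
    arrays; without it, arrays extend to the largest observed position.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["scaffold", "pos", "depth"],
            dtype={"scaffold": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["scaffold", "pos", "depth"])
    if len(df) and (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth values")
    depths: dict[str, np.ndarray] = {}
    if scaffold_lengths:
        for name, length in scaffold_lengths.items():
            depths[name] = np.zeros(length, dtype=np.int32)
    for name, sub in df.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if scaffold_lengths is not None:
            if name not in depths:
                raise ValueError(f"{path}: unknown scaffold {name}")
            if pos.max() > len(depths[name]):
                raise ValueError(
                    f"{path}: position beyond scaffold {name} length"
                )
        else:
            depths[name] = np.zeros(int(pos.max()), dtype=np.int32)
        depths[name][pos - 1] = sub["depth"].to_numpy()
    return CoverageTrack(lineage=lineage, depths=depths)


def read_count_table(path: str | Path, groups: dict) -> CountTable:
    """Read a genes x samples TSV (header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(counts=df, groups=dict(groups))


def read_gene_terms(path: str | Path) -> dict:
    """Read a 2-column gene<TAB>term TSV into gene -> set-of-terms."""
    mapping: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, _, term = line.partition("\t")
            if term:
                mapping.setdefault(gene, set()).add(term)
    return mapping


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_partition_bed(partition, path: str | Path, include_ldr: bool = False) -> None:
    """Write islands (and optionally LDR segments) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for isl in sorted(partition.islands, key=lambda i: (i.scaffold, i.start)):
            fh.write(f"{isl.scaffold}\t{isl.start - 1}\t{isl.end}\t{isl.id}\n")
        if include_ldr:
            for k, (scaf, s, e) in enumerate(partition.ldr_intervals(), 1):
                fh.write(f"{scaf}\t{s - 1}\t{e}\tldr_{k}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED lines back to 1-based inclusive (scaffold, start, end, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            name = cols[3] if len(cols) > 3 else ""
            out.append((cols[0], int(cols[1]) + 1, int(cols[2]), name))
    return out


def write_fasta(scaffolds: list[ScaffoldSeq], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in scaffolds:
            if s.sequence is None:
                raise ValueError(f"scaffold {s.id} has no sequence to write")
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.sequence[i : i + width] + "\n")


def write_gff(features: list[AnnotationFeature], path: str | Path) -> None:
    """Write features as GFF3 (attrs joined as key=value;...)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.scaffold, x.start, x.end)):
            attrs = ";".join(f"{k}={v}" for k, v in f.attrs.items())
            fh.write(
                f"{f.scaffold}\tteislands\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_depth_table(track: CoverageTrack, path: str | Path) -> None:
    """Write per-base depth as samtools-depth TSV (all positions, 1-based)."""
    with open(path, "w") as fh:
        for scaf in sorted(track.depths):
            arr = track.depths[scaf]
            df = pd.DataFrame(
                {"s": scaf, "p": np.arange(1, len(arr) + 1), "d": arr}
            )
            df.to_csv(fh, sep="\t", header=False, index=False)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_intersection_bp(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> int:
    """Total bp shared by two interval sets (each internally disjoint)."""
    a = sorted(a)
    b = sorted(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            total += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total
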