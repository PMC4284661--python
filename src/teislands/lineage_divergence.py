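"""Between-lineage divergence statistics.

Covers the pooled-coverage comparison (per-window depth ratio of lineage A to
lineage B, normalized by the genome-wide median ratio), the classification of
heterozygous calls into true heterozygotes vs collapsed duplications (haploid
pools should be homozygous; a het call sitting on ~2x depth marks a collapsed
duplicated locus), coding-effect annotation with per-gene dN/(dN+dS), and the
flagging of copy-number-variant candidate windows.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .composition_stats import mann_whitney_u
from .io_model import HET, HOM_ALT, HOM_REF, CoverageTrack, GeneModel, SNVRecord
from .island_scan import RegionPartition

__all__ = [
    "CoverageRatioWindow",
    "SnvClassification",
    "GeneDnDs",
    "coverage_ratio_windows",
    "region_deviation_summary",
    "classify_het_snvs",
    "snv_region_summary",
    "annotate_snv_effect",
    "gene_dn_ds",
    "flag_cnv_candidates",
]


@dataclass
class CoverageRatioWindow:
    scaffold: str
    start: int
    end: int
    ratio: float  # depth A / depth B; nan when masked
    deviation: float  # |ratio / center - 1|; nan when masked
    masked: bool


@dataclass
class SnvClassification:
    snv: SNVRecord
    label: str  # true_het / collapsed_duplication / hom / masked
    fold: float  # depth / median lineage depth


@dataclass
class GeneDnDs:
    gene_id: str
    dn: int
    ds: int

    @property
    def fraction(self) -> float | None:
        total = self.dn + self.ds
        return self.dn / total if total else None


def coverage_ratio_windows(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    window: int = 1000,
    min_depth: float = 5.0,
    center: str = "median",
) -> list[CoverageRatioWindow]:
    """Per-window depth ratio A/B with normalized deviation.

    Windows with mean depth below ``min_depth`` in either lineage are masked.
    The remaining ratios are centered on their genome-wide median (``center=
    "mean"`` for mean normalization); deviation d = |r/center - 1|.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    scaffolds = sorted(set(track_a.depths) & set(track_b.depths))
    rows = []
    for scaf in scaffolds:
        mean_a = track_a.window_means(scaf, window)
        mean_b = track_b.window_means(scaf, window)
        k = min(len(mean_a), len(mean_b))
        length = min(len(track_a.depths[scaf]), len(track_b.depths[scaf]))
        for i in range(k):
            start = i * window + 1
            end = min(start + window - 1, length)
            a, b = mean_a[i], mean_b[i]
            masked = a < min_depth or b < min_depth
            ratio = a / b if not masked else float("nan")
            rows.append(
                CoverageRatioWindow(scaf, start, end, ratio, float("nan"), masked)
            )
    ratios = np.array([w.ratio for w in rows if not w.masked])
    if ratios.size == 0:
        raise ValueError("no windows pass the depth filter in both lineages")
    c = float(np.median(ratios)) if center == "median" else float(np.mean(ratios))
    for w in rows:
        if not w.masked:
            w.deviation = abs(w.ratio / c - 1.0)
    return rows


def region_deviation_summary(
    ratio_windows: list[CoverageRatioWindow], partition: RegionPartition
) -> dict:
    """Median coverage-ratio deviation in islands vs LDRs plus a U-test.

    Windows are assigned by midpoint; masked windows and windows off the
    eligible scaffolds are ignored.  A region without windows gets an
    undefined (nan) median and the test is skipped.
    """
    isl, ldr = [], []
    for w in ratio_windows:
        if w.masked:
            continue
        label = partition.label(w.scaffold, (w.start + w.end) // 2)
        if label == "island":
            isl.append(w.deviation)
        elif label == "ldr":
            ldr.append(w.deviation)
    out = {
        "median_island": float(np.median(isl)) if isl else float("nan"),
        "median_ldr": float(np.median(ldr)) if ldr else float("nan"),
        "n_island": len(isl),
        "n_ldr": len(ldr),
        "undefined": not isl or not ldr,
    }
    if not out["undefined"]:
        out["U"], out["p"] = mann_whitney_u(isl, ldr)
    return out


def classify_het_snvs(
    snvs: list[SNVRecord],
    lineage: str,
    median_depth: float,
    fold_threshold: float = 1.5,
) -> list[SnvClassification]:
    """Split one lineage's het calls into true heterozygotes vs collapsed
    duplications by depth fold over the lineage median (boundary inclusive).

    Hom calls are labeled ``hom``; zero-depth sites are ``masked``.
    """
    if fold_threshold < 0:
        raise ValueError("fold_threshold must be non-negative")
    if median_depth <= 0:
        raise ValueError("median_depth must be positive")
    out = []
    for v in snvs:
        depth = v.depths.get(lineage, 0)
        fold = depth / median_depth
        gt = v.genotypes.get(lineage)
        if depth == 0:
            label = "masked"
        elif gt == HET:
            label = "collapsed_duplication" if fold >= fold_threshold else "true_het"
        elif gt in (HOM_REF, HOM_ALT):
            label = "hom"
        else:
            label = "masked"
        out.append(SnvClassification(snv=v, label=label, fold=fold))
    return out


def snv_region_summary(snvs: list[SNVRecord], partition: RegionPartition) -> dict:
    """Island/total counts and fractions per lineage and zygosity.

    SNVs on ineligible scaffolds are counted as unassigned and excluded from
    the island shares.  Also reports the overall island share of all assigned
    SNVs.
    """
    per: dict[tuple[str, str], dict] = {}
    total = island_total = unassigned = 0
    for v in snvs:
        label = partition.label(v.scaffold, v.pos)
        if label is None:
            unassigned += 1
            continue
        total += 1
        in_island = label == "island"
        if in_island:
            island_total += 1
        for lineage, zyg in v.genotypes.items():
            rec = per.setdefault((lineage, zyg), {"island": 0, "total": 0})
            rec["total"] += 1
            if in_island:
                rec["island"] += 1
    out = {
        "n_total": total,
        "n_island": island_total,
        "n_unassigned": unassigned,
        "island_share_pct": 100.0 * island_total / total if total else 0.0,
        "by_lineage_zygosity": {
            f"{lineage}:{zyg}": {
                "island": rec["island"],
                "total": rec["total"],
                "island_pct": 100.0 * rec["island"] / rec["total"]
                if rec["total"]
                else 0.0,
            }
            for (lineage, zyg), rec in sorted(per.items())
        },
    }
    return out


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of ``pos`` in the plus-strand CDS concatenation, or None."""
    offset = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            return offset + (pos - s)
        offset += e - s + 1
    return None


def annotate_snv_effect(
    snv: SNVRecord, gene: GeneModel, scaffold_seq: str
) -> str:
    """Label an SNV synonymous/nonsynonymous/noncoding by codon translation.

    The codon containing the site is translated for the reference and the
    alternate allele (standard nuclear code; minus-strand genes are handled on
    the reverse complement).  Incomplete CDS (length not divisible by 3) or N
    within the codon yields ``unknown``.
    """
    plus_off = _cds_offset(gene, snv.pos)
    if plus_off is None:
        return "noncoding"
    if not gene.complete:
        return "unknown"
    total = gene.cds_length

    cds_seq = "".join(scaffold_seq[s - 1 : e] for s, e in gene.cds)
    ref_base, alt_base = snv.ref, snv.alt
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        offset = total - 1 - plus_off
        ref_base = str(Seq(ref_base).reverse_complement())
        alt_base = str(Seq(alt_base).reverse_complement())
    else:
        offset = plus_off

    if cds_seq[offset] != ref_base:
        # reference mismatch: annotation and sequence disagree
        return "unknown"
    codon_start = offset - offset % 3
    codon_ref = cds_seq[codon_start : codon_start + 3]
    if "N" in codon_ref or len(codon_ref) < 3:
        return "unknown"
    codon_alt = (
        codon_ref[: offset % 3] + alt_base + codon_ref[offset % 3 + 1 :]
    )
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


class GeneLocator:
    """Per-scaffold sorted gene lookup by position (gene span containment)."""

    def __init__(self, genes: list[GeneModel]):
        self._by_scaf: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_scaf.setdefault(g.scaffold, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for scaf, gs in self._by_scaf.items():
            gs.sort(key=lambda g: g.start)
            self._starts[scaf] = [g.start for g in gs]

    def genes_at(self, scaffold: str, pos: int) -> list[GeneModel]:
        gs = self._by_scaf.get(scaffold, [])
        starts = self._starts.get(scaffold, [])
        k = bisect_right(starts, pos)
        # genes are short relative to scaffolds; scan back over candidates
        hits = []
        for g in reversed(gs[:k]):
            if g.end >= pos:
                hits.append(g)
            elif pos - g.start > 1_000_000:
                break
        return hits


def gene_dn_ds(
    effects: list[tuple[str, str]],
    genes: list[GeneModel],
    partition: RegionPartition,
) -> tuple[list[GeneDnDs], dict]:
    """Per-gene dN/(dN+dS) and the island-vs-LDR comparison.

    ``effects`` is a list of (gene_id, effect-label) pairs, one per annotated
    coding SNV.  Genes with dN+dS = 0 are excluded from the U-test on
    fractions.  Also reports synonymous SNVs per CDS kb per region.
    """
    counts: dict[str, list[int]] = {g.id: [0, 0] for g in genes}
    for gid, effect in effects:
        if gid not in counts:
            continue
        if effect == "nonsynonymous":
            counts[gid][0] += 1
        elif effect == "synonymous":
            counts[gid][1] += 1
    records = [GeneDnDs(gid, dn, ds) for gid, (dn, ds) in counts.items()]

    by_gene = {g.id: g for g in genes}
    frac_island, frac_ldr = [], []
    ds_bp = {"island": [0, 0], "ldr": [0, 0]}  # region -> [ds_count, cds_bp]
    for rec in records:
        g = by_gene[rec.gene_id]
        region = partition.label(g.scaffold, g.midpoint)
        if region not in ("island", "ldr"):
            continue
        ds_bp[region][0] += rec.ds
        ds_bp[region][1] += g.cds_length
        if rec.fraction is not None:
            (frac_island if region == "island" else frac_ldr).append(rec.fraction)
    comparison = {
        "n_island": len(frac_island),
        "n_ldr": len(frac_ldr),
        "median_fraction_island": float(np.median(frac_island))
        if frac_island
        else float("nan"),
        "median_fraction_ldr": float(np.median(frac_ldr))
        if frac_ldr
        else float("nan"),
        "mean_fraction_island": float(np.mean(frac_island))
        if frac_island
        else float("nan"),
        "mean_fraction_ldr": float(np.mean(frac_ldr))
        if frac_ldr
        else float("nan"),
        "syn_per_cds_kb_island": 1000.0 * ds_bp["island"][0] / ds_bp["island"][1]
        if ds_bp["island"][1]
        else float("nan"),
        "syn_per_cds_kb_ldr": 1000.0 * ds_bp["ldr"][0] / ds_bp["ldr"][1]
        if ds_bp["ldr"][1]
        else float("nan"),
    }
    if frac_island and frac_ldr:
        comparison["U"], comparison["p"] = mann_whitney_u(frac_island, frac_ldr)
    return records, comparison


def flag_cnv_candidates(
    ratio_windows: list[CoverageRatioWindow],
    genes: list[GeneModel],
    deviation_threshold: float = 0.5,
    partition: RegionPartition | None = None,
) -> pd.DataFrame:
    """Rank candidate copy-number loci: unmasked windows with deviation at or
    above the threshold, adjacent qualifying windows merged, annotated with
    overlapping gene ids and (when a partition is given) region label.

    Returns a DataFrame sorted by descending deviation with columns scaffold,
    start, end, deviation (max over merged windows), genes, region.
    """
    locator = GeneLocator(genes)
    qual = [
        w
        for w in ratio_windows
        if not w.masked and w.deviation >= deviation_threshold
    ]
    qual.sort(key=lambda w: (w.scaffold, w.start))
    merged: list[dict] = []
    for w in qual:
        if (
            merged
            and merged[-1]["scaffold"] == w.scaffold
            and w.start == merged[-1]["end"] + 1
        ):
            merged[-1]["end"] = w.end
            merged[-1]["deviation"] = max(merged[-1]["deviation"], w.deviation)
        else:
            merged.append(
                {
                    "scaffold": w.scaffold,
                    "start": w.start,
                    "end": w.end,
                    "deviation": w.deviation,
                }
            )
    for rec in merged:
        hit_ids: set[str] = set()
        for g in locator.genes_at(rec["scaffold"], rec["start"]):
            hit_ids.add(g.id)
        # genes starting within the candidate interval
        for g in locator._by_scaf.get(rec["scaffold"], []):
            if rec["start"] <= g.start <= rec["end"]:
                hit_ids.add(g.id)
        rec["genes"] = ",".join(sorted(hit_ids))
        if partition is not None:
            mid = (rec["start"] + rec["end"]) // 2
            rec["region"] = partition.label(rec["scaffold"], mid) or "unassigned"
        else:
            rec["region"] = "unassigned"
    df = pd.DataFrame(
        merged, columns=["scaffold", "start", "end", "deviation", "genes", "region"]
    )
    return df.sort_values("deviation", ascending=False, ignore_index=True)
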