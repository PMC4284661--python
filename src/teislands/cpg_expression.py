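"""Gene-body CpG observed/expected statistics and expression summaries.

CpG depletion in gene bodies is a proxy for historical germline cytosine
methylation: methylated CpGs deaminate to TpG, so genes methylated over many
generations show o/e CpG well below 1.  The o/e ratio is

    o/e = n_CpG * L / (n_C * n_G)

counted over exon sequence (N excluded from every count and from L; CG pairs
spanning exon junctions are not counted).  Expression values are read counts
normalized by median-of-ratios size factors, summarized as untransformed
per-group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition_stats import mann_whitney_u
from .io_model import CountTable, GeneModel, ScaffoldSeq
from .island_scan import RegionPartition

__all__ = [
    "CpGProfile",
    "ExpressionSummary",
    "cpg_oe",
    "gene_exon_cpg_oe",
    "lineage_oe_ratio_test",
    "size_factors",
    "mean_normalized_expression",
    "expression_rank_curve",
    "compare_region_expression",
]


@dataclass
class CpGProfile:
    """CpG counts over a unit (gene or exon) plus its location."""

    unit_id: str
    scaffold: str
    start: int
    end: int
    cpg_count: int
    c_count: int
    g_count: int
    length: int  # non-N bases counted

    @property
    def oe(self) -> float | None:
        denom = self.c_count * self.g_count
        if denom == 0:
            return None
        return self.cpg_count * self.length / denom

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ExpressionSummary:
    gene_id: str
    group_means: dict  # group label -> untransformed mean normalized count
    overall_mean: float
    rank_percentile: float | None  # 0 (least) .. 100 (most); None if unexpressed


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(cpg, c, g, non-N length) of one sequence, overlapping CG scan."""
    cpg = seq.count("CG")
    c = seq.count("C")
    g = seq.count("G")
    length = len(seq) - seq.count("N")
    return cpg, c, g, length


def cpg_oe(sequence: str) -> float | None:
    """Observed/expected CpG of a sequence; None when undefined.

    Undefined for sequences shorter than 2 informative bases or lacking C or
    G entirely.
    """
    seq = sequence.upper()
    cpg, c, g, length = _counts(seq)
    if length < 2 or c * g == 0:
        return None
    return cpg * length / (c * g)


def gene_exon_cpg_oe(gene: GeneModel, scaffold: ScaffoldSeq) -> CpGProfile:
    """Exon-wide CpG profile of a gene: per-exon scans, summed counts.

    CG pairs spanning exon junctions are deliberately not counted.  Counts are
    strand-symmetric (CG is its own reverse complement and C/G swap leaves the
    product unchanged), so the reference strand is used throughout.
    """
    if scaffold.sequence is None:
        raise ValueError(f"scaffold {scaffold.id} has no sequence")
    cpg = c = g = length = 0
    for s, e in gene.exons:
        if e > scaffold.length:
            raise ValueError(f"gene {gene.id}: exon beyond scaffold end")
        dcpg, dc, dg, dlen = _counts(scaffold.sequence[s - 1 : e])
        cpg += dcpg
        c += dc
        g += dg
        length += dlen
    return CpGProfile(
        unit_id=gene.id,
        scaffold=gene.scaffold,
        start=gene.start,
        end=gene.end,
        cpg_count=cpg,
        c_count=c,
        g_count=g,
        length=length,
    )


def lineage_oe_ratio_test(
    profiles_a: list[CpGProfile],
    profiles_b: list[CpGProfile],
    partition: RegionPartition,
) -> dict:
    """Between-lineage o/e ratio per unit plus an island-vs-LDR variance F-test.

    Units are matched by id; both o/e values must be defined and positive.
    F = var(island ratios) / var(LDR ratios), two-sided p from the F
    distribution with (n_island-1, n_ldr-1) degrees of freedom.  Zero variance
    in both regions is flagged degenerate.
    """
    by_id_b = {p.unit_id: p for p in profiles_b}
    isl, ldr = [], []
    ratios = {}
    for pa in profiles_a:
        pb = by_id_b.get(pa.unit_id)
        if pb is None:
            continue
        oe_a, oe_b = pa.oe, pb.oe
        if not oe_a or not oe_b:
            continue
        r = oe_a / oe_b
        ratios[pa.unit_id] = r
        label = partition.label(pa.scaffold, pa.midpoint)
        if label == "island":
            isl.append(r)
        elif label == "ldr":
            ldr.append(r)
    if len(isl) < 2 or len(ldr) < 2:
        raise ValueError("need at least two ratios per region for the F-test")
    var_i = float(np.var(isl, ddof=1))
    var_l = float(np.var(ldr, ddof=1))
    out = {
        "ratios": ratios,
        "n_island": len(isl),
        "n_ldr": len(ldr),
        "var_island": var_i,
        "var_ldr": var_l,
        "degenerate": var_i == 0.0 and var_l == 0.0,
    }
    if out["degenerate"]:
        out["F"] = float("nan")
        out["p"] = float("nan")
    else:
        f = var_i / var_l if var_l > 0 else float("inf")
        out["F"] = f
        dist = stats.f(len(isl) - 1, len(ldr) - 1)
        out["p"] = float(2 * min(dist.cdf(f), dist.sf(f))) if np.isfinite(f) else 0.0
    return out


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors (one per sample).

    The per-gene reference is the geometric mean across samples over genes
    with no zero count; each sample's factor is the median of its counts over
    those references.
    """
    counts = table.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has a nonzero count in every sample")
    sub = counts[nonzero]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


def mean_normalized_expression(table: CountTable) -> list[ExpressionSummary]:
    """Per-gene untransformed mean normalized expression per group, with rank
    percentile over expressed genes (0 = least expressed).
    """
    groups = set(table.groups.values())
    factors = size_factors(table)
    norm = table.counts / factors
    overall = norm.mean(axis=1)
    group_means = {
        g: norm.loc[:, [s for s in norm.columns if table.groups[s] == g]].mean(axis=1)
        for g in groups
    }
    expressed = overall[norm.sum(axis=1) > 0]
    if len(expressed) > 1:
        ranks = stats.rankdata(expressed.to_numpy())
        pct = pd.Series(
            (ranks - 1) / (len(expressed) - 1) * 100.0, index=expressed.index
        )
    else:
        pct = pd.Series(0.0, index=expressed.index)
    out = []
    for gene in table.counts.index:
        out.append(
            ExpressionSummary(
                gene_id=gene,
                group_means={g: float(group_means[g][gene]) for g in groups},
                overall_mean=float(overall[gene]),
                rank_percentile=float(pct[gene]) if gene in pct.index else None,
            )
        )
    return out


def expression_rank_curve(
    summaries: list[ExpressionSummary],
    profiles: list[CpGProfile],
    partition: RegionPartition,
    bins: int = 100,
) -> pd.DataFrame:
    """Median gene o/e CpG per expression-rank bin, islands and LDRs apart.

    Genes present in both inputs with a defined rank (expressed) and a defined
    o/e are bucketed into ``bins`` equal-width percentile bins.
    """
    by_gene = {p.unit_id: p for p in profiles}
    rows = []
    for s in summaries:
        p = by_gene.get(s.gene_id)
        if p is None or s.rank_percentile is None or p.oe is None:
            continue
        region = partition.label(p.scaffold, p.midpoint)
        if region is None:
            continue
        b = min(int(s.rank_percentile / (100.0 / bins)), bins - 1)
        rows.append((b, region, p.oe))
    if not rows:
        raise ValueError("no genes shared between expression and CpG inputs")
    df = pd.DataFrame(rows, columns=["bin", "region", "oe"])
    return (
        df.groupby(["region", "bin"])["oe"]
        .agg(median_oe="median", n="size")
        .reset_index()
    )


def compare_region_expression(
    summaries: list[ExpressionSummary],
    partition: RegionPartition,
    genes: list[GeneModel],
    group_pair: tuple[str, str] | None = None,
) -> dict:
    """Median expression per region (zeros included) with U-tests.

    Tests island-vs-LDR on overall means, and within each region between the
    two groups of ``group_pair`` when given.  Also counts fully unexpressed
    genes per region.
    """
    region_of = {
        g.id: partition.label(g.scaffold, g.midpoint) for g in genes
    }
    vals: dict[str, list] = {"island": [], "ldr": []}
    group_vals: dict[tuple[str, str], list] = {}
    unexpressed = {"island": 0, "ldr": 0}
    for s in summaries:
        region = region_of.get(s.gene_id)
        if region not in vals:
            continue
        vals[region].append(s.overall_mean)
        if s.rank_percentile is None:
            unexpressed[region] += 1
        for g, m in s.group_means.items():
            group_vals.setdefault((region, g), []).append(m)
    out = {
        "median_island": float(np.median(vals["island"]))
        if vals["island"]
        else float("nan"),
        "median_ldr": float(np.median(vals["ldr"])) if vals["ldr"] else float("nan"),
        "n_island": len(vals["island"]),
        "n_ldr": len(vals["ldr"]),
        "unexpressed": unexpressed,
        "group_medians": {
            f"{region}:{g}": float(np.median(v))
            for (region, g), v in sorted(group_vals.items())
            if v
        },
    }
    if vals["island"] and vals["ldr"]:
        out["U"], out["p"] = mann_whitney_u(vals["island"], vals["ldr"])
    if group_pair is not None:
        g1, g2 = group_pair
        for region in ("island", "ldr"):
            a = group_vals.get((region, g1), [])
            b = group_vals.get((region, g2), [])
            if a and b:
                u, p = mann_whitney_u(a, b)
                out[f"{region}_{g1}_vs_{g2}"] = {"U": u, "p": p}
    return out
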