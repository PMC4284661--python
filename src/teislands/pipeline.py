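"""End-to-end orchestration: windows -> islands -> divergence -> composition
-> CpG/expression, with a machine-readable report.

The analysis path is fully deterministic; all randomness lives in the
synthetic generator.  Stages with missing optional inputs (counts, terms) are
skipped and recorded in the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .composition_stats import (
    length_polymorphism,
    superfamily_enrichment,
    tally_superfamilies,
)
from .cpg_expression import (
    compare_region_expression,
    expression_rank_curve,
    gene_exon_cpg_oe,
    lineage_oe_ratio_test,
    mean_normalized_expression,
    CpGProfile,
)
from .io_model import (
    CountTable,
    build_gene_models,
    read_count_table,
    read_depth_table,
    read_fasta,
    read_gene_terms,
    read_gff,
    read_vcf_snvs,
    write_partition_bed,
)
from .island_scan import (
    aggregate_windows,
    call_te_islands,
    interval_jaccard,
    island_summary,
    tile_windows,
)
from .lineage_divergence import (
    GeneLocator,
    annotate_snv_effect,
    classify_het_snvs,
    coverage_ratio_windows,
    flag_cnv_candidates,
    gene_dn_ds,
    region_deviation_summary,
    snv_region_summary,
)
from .synthetic import SyntheticDataset, substitute_snvs

logger = logging.getLogger("teislands")


@dataclass
class AnalysisParams:
    """Tunable analysis parameters, all exposed in the report's provenance."""

    window_size: int = 1000
    span: int = 200_000
    step: int = 1000
    quantile: float = 0.95
    min_scaffold: int = 200_000
    min_island: int = 10_000
    min_depth: float = 5.0
    fold_threshold: float = 1.5
    deviation_threshold: float = 0.5
    alpha: float = 0.05
    bins: int = 100
    ratio_center: str = "median"
    per_scaffold_quantile: bool = False
    group_pair: tuple = ("queen", "larva")

    def validate(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.window_size < 1 or self.span < self.window_size:
            raise ValueError("bad window sizes")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_threshold < 0 or self.deviation_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_depth < 0 or self.bins < 1:
            raise ValueError("bad min_depth or bins")
        if self.ratio_center not in ("median", "mean"):
            raise ValueError("ratio_center must be 'median' or 'mean'")


@dataclass
class PipelineConfig:
    """Input paths plus analysis parameters for a `run` invocation."""

    fasta: str | None = None
    gff: str | None = None
    vcf: str | None = None
    depth: dict = field(default_factory=dict)  # lineage -> path
    counts: str | None = None
    groups: dict = field(default_factory=dict)  # sample -> group
    terms: str | None = None
    lineages: tuple = ("BR", "JP")
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = AnalysisParams(**raw.pop("params", {}))
        cfg = cls(**{**raw, "params": params})
        if "lineages" in raw:
            cfg.lineages = tuple(raw["lineages"])
        return cfg

    def validate(self, for_run: bool = True) -> None:
        self.params.validate()
        if for_run:
            for label, p in [("fasta", self.fasta), ("gff", self.gff)]:
                if p is None:
                    raise ValueError(f"config missing required input: {label}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} file not found: {p}")
            for p in [self.vcf, self.counts, self.terms, *self.depth.values()]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")


def analyze(
    scaffolds,
    features,
    genes,
    snvs=None,
    coverage=None,
    counts: CountTable | None = None,
    terms: dict | None = None,
    params: AnalysisParams | None = None,
) -> dict:
    """Run every applicable stage on in-memory inputs; returns the report.

    ``coverage`` is a lineage -> CoverageTrack mapping whose insertion order
    fixes the ratio orientation (first/second).  Optional stages (coverage,
    SNVs, expression, terms) are skipped when inputs are absent.
    """
    params = params or AnalysisParams()
    params.validate()
    snvs = snvs or []
    coverage = coverage or {}
    scaffold_lengths = {s.id: s.length for s in scaffolds}
    t0 = time.time()
    report: dict = {"skipped": []}

    logger.info("tiling %d scaffolds into %d bp windows",
                len(scaffolds), params.window_size)
    track1kb = tile_windows(
        features, snvs, list(coverage.values()), scaffold_lengths,
        window_size=params.window_size,
    )
    track200 = aggregate_windows(track1kb, span=params.span, step=params.step)
    partition = call_te_islands(
        track200,
        scaffold_lengths,
        quantile=params.quantile,
        min_scaffold=params.min_scaffold,
        min_island=params.min_island,
        track1kb=track1kb,
        per_scaffold=params.per_scaffold_quantile,
    )
    summary = island_summary(
        partition, features, genes, assembly_len=sum(scaffold_lengths.values())
    )
    report["islands"] = {
        "summary": asdict(summary),
        "intervals": [
            {"id": i.id, "scaffold": i.scaffold, "start": i.start, "end": i.end,
             "te_fraction": i.te_fraction}
            for i in partition.islands
        ],
    }

    # --- coverage-ratio divergence ---------------------------------------
    lineages = list(coverage)
    ratio_windows = None
    if len(lineages) >= 2:
        a, b = lineages[0], lineages[1]
        ratio_windows = coverage_ratio_windows(
            coverage[a], coverage[b],
            window=params.window_size, min_depth=params.min_depth,
            center=params.ratio_center,
        )
        report["coverage"] = {
            "orientation": f"{a}/{b}",
            "deviation": region_deviation_summary(ratio_windows, partition),
        }
        candidates = flag_cnv_candidates(
            ratio_windows, genes,
            deviation_threshold=params.deviation_threshold, partition=partition,
        )
        report["cnv_candidates"] = {
            "n": int(len(candidates)),
            "n_island": int((candidates["region"] == "island").sum()),
            "top": candidates.head(20).to_dict("records"),
        }
        report["_candidates_frame"] = candidates
    else:
        report["skipped"].append("coverage")

    # --- SNV stages -------------------------------------------------------
    if snvs:
        report["snvs"] = {"region_summary": snv_region_summary(snvs, partition)}
        classifications = {}
        median_depths = {}
        for lineage, track in coverage.items():
            alldepth = np.concatenate(list(track.depths.values()))
            med = float(np.median(alldepth))
            median_depths[lineage] = med
            if med > 0:
                cls = classify_het_snvs(
                    snvs, lineage, med, fold_threshold=params.fold_threshold
                )
                tally: dict[str, int] = {}
                for c in cls:
                    tally[c.label] = tally.get(c.label, 0) + 1
                classifications[lineage] = cls
                report["snvs"].setdefault("het_classification", {})[lineage] = tally
        report["snvs"]["median_depths"] = median_depths
        report["_classifications"] = classifications

        # coding effects + dN/(dN+dS)
        seq_by_scaf = {s.id: s.sequence for s in scaffolds}
        locator = GeneLocator(genes)
        effects = []
        effect_counts: dict[str, int] = {}
        for v in snvs:
            seq = seq_by_scaf.get(v.scaffold)
            label = "noncoding"
            gid = None
            if seq is not None:
                for g in locator.genes_at(v.scaffold, v.pos):
                    lab = annotate_snv_effect(v, g, seq)
                    if lab != "noncoding":
                        label, gid = lab, g.id
                        break
            v.effect = label
            effect_counts[label] = effect_counts.get(label, 0) + 1
            if gid is not None and label in ("synonymous", "nonsynonymous"):
                effects.append((gid, label))
        dnds_records, dnds_cmp = gene_dn_ds(effects, genes, partition)
        report["snvs"]["effect_counts"] = effect_counts
        report["dn_ds"] = dnds_cmp
        report["_dnds_records"] = dnds_records
    else:
        report["skipped"].append("snvs")

    # --- composition ------------------------------------------------------
    tallies = tally_superfamilies(features, partition)
    enrich = superfamily_enrichment(tallies, alpha=params.alpha)
    report["superfamilies"] = {
        "tallies": [asdict(t) for t in tallies],
        "enrichment": {
            key: [
                {"unit": r.unit, "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
                 "direction": r.direction, "significant": bool(r.q < params.alpha)}
                for r in res
            ]
            for key, res in enrich.items()
        },
    }
    report["length_polymorphism"] = length_polymorphism(features, partition)

    # --- CpG --------------------------------------------------------------
    with_seq = [s for s in scaffolds if s.sequence is not None]
    if with_seq:
        seq_map = {s.id: s for s in with_seq}
        profiles = [
            gene_exon_cpg_oe(g, seq_map[g.scaffold])
            for g in genes
            if g.scaffold in seq_map
        ]
        oe_island = [
            p.oe for p in profiles
            if p.oe is not None and partition.label(p.scaffold, p.midpoint) == "island"
        ]
        oe_ldr = [
            p.oe for p in profiles
            if p.oe is not None and partition.label(p.scaffold, p.midpoint) == "ldr"
        ]
        report["cpg"] = {
            "median_oe_island": float(np.median(oe_island)) if oe_island else None,
            "median_oe_ldr": float(np.median(oe_ldr)) if oe_ldr else None,
            "n_island": len(oe_island),
            "n_ldr": len(oe_ldr),
        }
        report["_cpg_profiles"] = profiles

        if snvs and len(lineages) >= 2:
            exon_profiles = {}
            for lineage in lineages[:2]:
                consensus = {
                    s.id: substitute_snvs(s, snvs, lineage) for s in with_seq
                }
                plist = []
                for g in genes:
                    if g.scaffold not in consensus:
                        continue
                    seq = consensus[g.scaffold].sequence
                    for k, (es, ee) in enumerate(g.exons, 1):
                        sub = seq[es - 1 : ee]
                        plist.append(
                            CpGProfile(
                                unit_id=f"{g.id}:exon{k}", scaffold=g.scaffold,
                                start=es, end=ee,
                                cpg_count=sub.count("CG"), c_count=sub.count("C"),
                                g_count=sub.count("G"),
                                length=len(sub) - sub.count("N"),
                            )
                        )
                exon_profiles[lineage] = plist
            try:
                ratio = lineage_oe_ratio_test(
                    exon_profiles[lineages[0]], exon_profiles[lineages[1]], partition
                )
                report["cpg"]["lineage_ratio_f_test"] = {
                    k: v for k, v in ratio.items() if k != "ratios"
                }
            except ValueError as err:
                report["cpg"]["lineage_ratio_f_test"] = {"skipped": str(err)}
    else:
        report["skipped"].append("cpg")

    # --- expression -------------------------------------------------------
    if counts is not None:
        summaries = mean_normalized_expression(counts)
        report["expression"] = compare_region_expression(
            summaries, partition, genes, group_pair=params.group_pair
        )
        if with_seq:
            curve = expression_rank_curve(
                summaries, report["_cpg_profiles"], partition, bins=params.bins
            )
            report["_rank_curve"] = curve
        report["_summaries"] = summaries
    else:
        report["skipped"].append("expression")

    # --- term enrichment --------------------------------------------------
    if terms:
        from .composition_stats import term_enrichment_two_tailed

        island_genes = [
            g.id for g in genes if partition.label(g.scaffold, g.midpoint) == "island"
        ]
        res = term_enrichment_two_tailed(
            terms, island_genes, [g.id for g in genes], alpha=params.alpha
        )
        report["term_enrichment"] = [
            {"unit": r.unit, "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
             "direction": r.direction, "significant": bool(r.q < params.alpha)}
            for r in res
        ]
    else:
        report["skipped"].append("term_enrichment")

    report["_partition"] = partition
    report["_track1kb"] = track1kb
    report["provenance"] = {
        "version": __version__,
        "params": asdict(params),
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_scaffolds": len(scaffolds),
        "n_features": len(features),
        "n_genes": len(genes),
        "n_snvs": len(snvs),
    }
    return report


def analyze_dataset(ds: SyntheticDataset, params: AnalysisParams | None = None) -> dict:
    """Convenience wrapper: run `analyze` on an in-memory synthetic dataset."""
    return analyze(
        ds.scaffolds, ds.features, ds.genes, ds.snvs, ds.coverage, ds.counts,
        params=params,
    )


def _strip_private(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Load inputs per config, run the analysis, write report and artifacts."""
    config.validate(for_run=True)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read_fasta"
    try:
        scaffolds = read_fasta(config.fasta)
        stage = "read_gff"
        features = read_gff(config.gff)
        genes = build_gene_models(features)
        lengths = {s.id: s.length for s in scaffolds}
        snvs = []
        if config.vcf:
            stage = "read_vcf"
            snvs = read_vcf_snvs(config.vcf, list(config.lineages)).snvs
        coverage = {}
        for lineage, path in config.depth.items():
            stage = f"read_depth[{lineage}]"
            coverage[lineage] = read_depth_table(path, lineage, lengths)
        counts = None
        if config.counts:
            stage = "read_counts"
            counts = read_count_table(config.counts, config.groups)
        terms = read_gene_terms(config.terms) if config.terms else None
        stage = "analyze"
        report = analyze(
            scaffolds, features, genes, snvs, coverage, counts, terms,
            params=config.params,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    write_outputs(report, outdir)
    return report


def write_outputs(report: dict, outdir: str | Path) -> None:
    """Emit report JSON plus the BED/TSV artifacts of each stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition = report.get("_partition")
    if partition is not None:
        write_partition_bed(partition, outdir / "islands.bed", include_ldr=False)
    track = report.get("_track1kb")
    if track is not None:
        df = track.frame.copy()
        df["start0"] = df["start"] - 1
        df["end"] = df["start0"] + df["effective_len"]
        cols = [c for c in df.columns if c not in ("start", "start0", "end",
                                                   "scaffold", "effective_len")]
        df[["scaffold", "start0", "end"] + cols].to_csv(
            outdir / "windows_1kb.tsv", sep="\t", index=False
        )
    if "_candidates_frame" in report:
        report["_candidates_frame"].to_csv(
            outdir / "cnv_candidates.tsv", sep="\t", index=False
        )
    if "_rank_curve" in report:
        report["_rank_curve"].to_csv(
            outdir / "expression_rank_curve.tsv", sep="\t", index=False
        )
    (outdir / "report.json").write_text(
        json.dumps(_strip_private(report), indent=1, sort_keys=True, default=str)
    )


def evaluate_recovery(ds: SyntheticDataset, report: dict) -> dict:
    """Truth-vs-report comparison for a synthetic dataset.

    Island Jaccard, collapsed-duplication recall/precision, and the planted
    directions of effect (deviation, SNV density, TE length, CpG, expression).
    """
    partition = report["_partition"]
    called = [(i.scaffold, i.start, i.end) for i in partition.islands]
    jac = interval_jaccard(called, ds.truth.islands)

    # duplication recall/precision from per-lineage het classifications
    truth_dup = {
        key for key, cls in ds.truth.snv_classes.items()
        if cls == "collapsed_duplication"
    }
    dup_lineage = {}
    for scaf, s, e, lin in ds.truth.duplications:
        for key in truth_dup:
            if key[0] == scaf and s <= key[1] <= e:
                dup_lineage[key] = lin
    tp = fn = fp = 0
    for lineage, cls_list in report.get("_classifications", {}).items():
        for c in cls_list:
            key = (c.snv.scaffold, c.snv.pos)
            is_true = dup_lineage.get(key) == lineage
            if c.label == "collapsed_duplication":
                if is_true:
                    tp += 1
                else:
                    fp += 1
            elif is_true:
                fn += 1
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")

    directions = {}
    dev = report.get("coverage", {}).get("deviation")
    if dev and not dev.get("undefined"):
        directions["deviation_island_gt_ldr"] = dev["median_island"] > dev["median_ldr"]
    snv_sum = report.get("snvs", {}).get("region_summary")
    if snv_sum and partition.island_bp and partition.ldr_bp:
        isl_density = snv_sum["n_island"] / partition.island_bp
        ldr_density = (snv_sum["n_total"] - snv_sum["n_island"]) / partition.ldr_bp
        directions["snv_density_island_gt_ldr"] = isl_density > ldr_density
    lp = report.get("length_polymorphism", {})
    ok = [
        rec["median_island"] > rec["median_ldr"]
        for rec in lp.values()
        if not rec.get("skipped")
    ]
    if ok:
        directions["te_length_island_gt_ldr"] = all(ok)
    cpg = report.get("cpg", {})
    if cpg.get("median_oe_island") is not None and cpg.get("median_oe_ldr") is not None:
        directions["cpg_oe_island_lt_ldr"] = (
            cpg["median_oe_island"] < cpg["median_oe_ldr"]
        )
    expr = report.get("expression")
    if expr and np.isfinite(expr.get("median_island", np.nan)):
        directions["expression_island_lt_ldr"] = (
            expr["median_island"] < expr["median_ldr"]
        )
    return {
        "island_jaccard": jac,
        "n_islands_called": len(partition.islands),
        "n_islands_true": len(ds.truth.islands),
        "dup_recall": recall,
        "dup_precision": precision,
        "directions": directions,
    }


def check(dataset_dir: str | Path, params: AnalysisParams | None = None) -> dict:
    """Re-run the analysis on a written dataset directory and score it against
    the stored truth.  No-op (with notice) when no truth file is present."""
    dataset_dir = Path(dataset_dir)
    if not (dataset_dir / "truth.json").exists():
        return {"notice": "no truth.json in dataset directory; nothing to check"}
    from .synthetic import load_truth

    truth = load_truth(dataset_dir)
    if not truth.islands and not truth.duplications:
        return {"notice": "empty truth; nothing to check"}
    cfg = PipelineConfig(
        fasta=str(dataset_dir / "genome.fasta"),
        gff=str(dataset_dir / "annotation.gff3"),
        vcf=str(dataset_dir / "snvs.vcf"),
        depth={
            p.stem.replace("depth_", ""): str(p)
            for p in sorted(dataset_dir.glob("depth_*.tsv"))
        },
        counts=str(dataset_dir / "counts.tsv")
        if (dataset_dir / "counts.tsv").exists()
        else None,
        params=params or AnalysisParams(),
    )
    lineages = tuple(truth.params.get("lineages", ("BR", "JP")))
    cfg.lineages = lineages
    if cfg.counts:
        import pandas as pd

        samples = pd.read_csv(cfg.counts, sep="\t", index_col=0, nrows=0).columns
        cfg.groups = {
            s: ("queen" if s.startswith("queen") else "larva") for s in samples
        }
    scaffolds = read_fasta(cfg.fasta)
    features = read_gff(cfg.gff)
    genes = build_gene_models(features)
    lengths = {s.id: s.length for s in scaffolds}
    snvs = read_vcf_snvs(cfg.vcf, list(lineages)).snvs
    coverage = {
        lin: read_depth_table(path, lin, lengths)
        for lin, path in cfg.depth.items()
    }
    counts = None
    if cfg.counts:
        counts = read_count_table(cfg.counts, cfg.groups)
    report = analyze(scaffolds, features, genes, snvs, coverage, counts,
                     params=cfg.params)
    ds = SyntheticDataset(
        scaffolds=scaffolds, features=features, genes=genes, snvs=snvs,
        coverage=coverage, counts=counts, truth=truth,
    )
    return evaluate_recovery(ds, report)
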