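"""Tests on TE composition and generic set enrichment.

Two-sided Fisher exact p-values follow the "probability at most that of the
observed table" rule: with row/column margins fixed, every table whose
hypergeometric probability does not exceed the observed table's contributes to
p.  Conventions for two-sided Fisher tests differ between packages, so the
rule is implemented here explicitly (with a small relative tolerance for
floating-point ties) rather than delegated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import AnnotationFeature, interval_intersection_bp

__all__ = [
    "SuperfamilyTally",
    "EnrichmentResult",
    "tally_superfamilies",
    "fisher_exact_two_sided",
    "bh_fdr",
    "superfamily_enrichment",
    "mann_whitney_u",
    "length_polymorphism",
    "term_enrichment_two_tailed",
]

_TIE_REL_TOL = 1e-12


@dataclass
class SuperfamilyTally:
    superfamily: str
    te_class: str
    copies_in_islands: int
    copies_in_ldr: int
    bp_in_islands: int
    bp_in_ldr: int


@dataclass
class EnrichmentResult:
    unit: str
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float  # conditional MLE; nan when a margin is zero
    p: float
    q: float = float("nan")
    direction: str = "none"  # over / under / none


def tally_superfamilies(
    features: list[AnnotationFeature], partition
) -> list[SuperfamilyTally]:
    """Tally TE copies and bp per superfamily in islands vs LDR.

    A copy is assigned to the region containing its midpoint (non-island and
    off-partition both count as LDR); bp are split exactly at island
    boundaries.  Copies lacking a superfamily attribute tally as
    "unclassified".
    """
    acc: dict[str, dict] = {}
    for f in features:
        if f.kind != "te_copy":
            continue
        sf = f.attrs.get("superfamily", "unclassified")
        cls = f.attrs.get("te_class", "?")
        rec = acc.setdefault(
            sf, {"class": cls, "ci": 0, "cl": 0, "bi": 0, "bl": 0}
        )
        in_island = partition.label(f.scaffold, f.midpoint) == "island"
        rec["ci" if in_island else "cl"] += 1
        bp_isl = interval_intersection_bp(
            [(f.start, f.end)], partition.island_intervals(f.scaffold)
        )
        rec["bi"] += bp_isl
        rec["bl"] += f.length - bp_isl
    return [
        SuperfamilyTally(
            superfamily=sf,
            te_class=rec["class"],
            copies_in_islands=rec["ci"],
            copies_in_ldr=rec["cl"],
            bp_in_islands=rec["bi"],
            bp_in_ldr=rec["bl"],
        )
        for sf, rec in sorted(acc.items())
    ]


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of non-negative integers.

    Returns (conditional-MLE odds ratio, p).  With any zero margin there is a
    single admissible table, so p = 1 and the odds ratio is undefined (nan).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return float("nan"), 1.0

    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1 + _TIE_REL_TOL)
    p = 1.0 if mask.all() else min(1.0, float(np.sum(pmf[mask])))

    odds = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
    return odds, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich(units, tables, alpha) -> list[EnrichmentResult]:
    results = []
    for unit, tbl in zip(units, tables):
        odds, p = fisher_exact_two_sided(tbl)
        (a, b), (c, d) = tbl
        if math.isnan(odds) or odds == 1.0:
            direction = "none"
        else:
            direction = "over" if odds > 1.0 else "under"
        results.append(
            EnrichmentResult(unit=unit, table=((a, b), (c, d)), odds_ratio=odds,
                             p=p, direction=direction)
        )
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def superfamily_enrichment(
    tallies: list[SuperfamilyTally], alpha: float = 0.05
) -> dict:
    """Per-superfamily island enrichment against all other superfamilies.

    Runs a two-sided Fisher test on [[in-island, in-LDR], [rest in-island,
    rest in-LDR]] per superfamily, once on copy counts and once on bp counts,
    with BH correction within each analysis.  Returns
    ``{"copies": [...], "bp": [...]}``; significance is q < alpha.
    """
    if len(tallies) < 2:
        warnings.warn(
            "fewer than two superfamilies: enrichment is degenerate",
            stacklevel=2,
        )
        return {"copies": [], "bp": []}
    out = {}
    for key, fi, fl in (
        ("copies", "copies_in_islands", "copies_in_ldr"),
        ("bp", "bp_in_islands", "bp_in_ldr"),
    ):
        tot_i = sum(getattr(t, fi) for t in tallies)
        tot_l = sum(getattr(t, fl) for t in tallies)
        units, tables = [], []
        for t in tallies:
            a, b = getattr(t, fi), getattr(t, fl)
            units.append(t.superfamily)
            tables.append(((a, b), (tot_i - a, tot_l - b)))
        out[key] = _enrich(units, tables, alpha)
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (midrank ties), i.e. #\\{x_i > y_j\\} + ties/2."""
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def mann_whitney_u(sample_x, sample_y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``method``: "exact" enumerates the permutation distribution (tie-free
    samples use the standard counting distribution; tied samples fall back to
    full enumeration when feasible), "asymptotic" uses the normal
    approximation with tie-corrected variance and continuity correction,
    "auto" picks exact when min(n) <= 20 and enumeration is feasible.
    Returns (U for the first sample, two-sided p).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u = _u_statistic(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n + m

    if method == "auto":
        if min(n, m) > 20:
            method = "asymptotic"
        elif not has_ties:
            method = "exact"
        elif math.comb(n + m, n) <= 200_000:
            method = "exact"
        else:
            method = "asymptotic"

    if method == "exact":
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return u, float(res.pvalue)
        return u, _exact_p_with_ties(x, y, u)

    # normal approximation, tie-corrected variance, continuity correction
    nm = n * m
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    big_n = n + m
    var = nm / 12.0 * (big_n + 1 - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return u, 1.0
    z = (abs(u - nm / 2.0) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u, float(2 * stats.norm.sf(z))


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all label assignments (tied data)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = len(x), len(y)
    nm = n * m
    offset = n * (n + 1) / 2
    u_lo = min(u_obs, nm - u_obs)
    hits = total = 0
    for comb in combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if u <= u_lo + 1e-9 or u >= nm - u_lo - 1e-9:
            hits += 1
    return min(1.0, hits / total)


def length_polymorphism(
    features: list[AnnotationFeature], partition
) -> dict:
    """Per-TE-class (I, II) island-vs-LDR U-test on copy lengths.

    Copies are assigned by midpoint.  Returns per class: median lengths,
    sample sizes, (U, p); classes with fewer than two copies in either region
    are flagged skipped.
    """
    lengths: dict[str, dict[str, list]] = {}
    for f in features:
        if f.kind != "te_copy":
            continue
        cls = f.attrs.get("te_class", "?")
        region = partition.label(f.scaffold, f.midpoint)
        key = "island" if region == "island" else "ldr"
        lengths.setdefault(cls, {"island": [], "ldr": []})[key].append(f.length)
    out = {}
    for cls, d in sorted(lengths.items()):
        isl, ldr = d["island"], d["ldr"]
        rec = {
            "n_island": len(isl),
            "n_ldr": len(ldr),
            "median_island": float(np.median(isl)) if isl else float("nan"),
            "median_ldr": float(np.median(ldr)) if ldr else float("nan"),
            "skipped": len(isl) < 2 or len(ldr) < 2,
        }
        if not rec["skipped"]:
            rec["U"], rec["p"] = mann_whitney_u(isl, ldr)
        out[cls] = rec
    return out


def term_enrichment_two_tailed(
    gene_terms: dict,
    island_gene_ids,
    universe_gene_ids,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Two-tailed term enrichment of island genes against the gene universe.

    Per term: Fisher test on [[island with term, island without], [non-island
    with, non-island without]], BH across terms; both over- and
    under-represented terms are reported (direction field).  Terms never seen
    on a universe gene are skipped.
    """
    universe = set(universe_gene_ids)
    island = set(island_gene_ids)
    if not island <= universe:
        raise ValueError("island genes must be a subset of the universe")
    term_genes: dict[str, set] = {}
    for gene, terms in gene_terms.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    if not term_genes:
        return []
    n_isl = len(island)
    n_rest = len(universe) - n_isl
    units, tables = [], []
    for term in sorted(term_genes):
        genes = term_genes[term]
        a = len(genes & island)
        c = len(genes) - a
        units.append(term)
        tables.append(((a, n_isl - a), (c, n_rest - c)))
    return _enrich(units, tables, alpha)
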