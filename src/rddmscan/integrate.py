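"""Co-localization of DMRs, sRNA clusters, and gene expression.

The RdDM pathway couples the three layers: 24-nt siRNAs produced from a locus
(often a transposable element in a promoter) guide CHH methylation of that
locus; loss of the siRNA signal is expected to travel with promoter CHH
hypomethylation and de-repression of the downstream gene.  This module
quantifies the pairwise association (DMR x DSR odds ratios), links DMRs to
genes through promoter overlap, intersects those targets with DEGs, and
screens for genes showing the full canonical tri-omic pattern.

Term enrichment is a flat hypergeometric over a gene -> term mapping; no
ontology DAG semantics are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .refmodel import GeneModel, RegionSpec, TeAnnotation, overlaps, promoter_of


@dataclass
class AssociationResult:
    """One stratum's DMR-DSR association: 2x2 table, odds ratio, Fisher p."""

    stratum: dict
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p)) if self.p > 0 else float("inf")


def odds_ratio_2x2(table: Sequence[Sequence[float]]) -> float:
    """(a*d)/(b*c) with Haldane-Anscombe +0.5 on every cell iff any cell is 0."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def associate_dmr_dsr(
    dmrs: pd.DataFrame,
    cluster_info: pd.DataFrame,
    dsr: pd.DataFrame,
    dmr_polarity: str,
    dsr_direction: str,
    size_class: str = "all",
    comparison: str | None = None,
) -> AssociationResult:
    """Association between DMRs of one polarity and DSRs of one direction.

    Background = all clusters tested for the given size class (rows of
    ``dsr``).  2x2 rows: cluster's DSR direction equals ``dsr_direction`` or
    not; columns: cluster interval overlaps >= 1 DMR of ``dmr_polarity`` (and
    the DMR table's context/comparison) or not.  Fisher two-sided p on the
    raw table; odds ratio Haldane-corrected when a cell is zero.
    """
    tested = dsr[dsr["size_class"] == size_class] if "size_class" in dsr.columns else dsr
    if comparison is not None and "comparison" in tested.columns:
        tested = tested[tested["comparison"] == comparison]
    if not len(tested):
        raise ValueError("empty background: no tested clusters for this stratum")

    sel_dmrs = dmrs[dmrs["polarity"] == dmr_polarity]
    trees: dict[str, IntervalTree] = {}
    for r in sel_dmrs.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)

    has_dir = (tested["direction"] == dsr_direction).to_numpy()
    has_dmr = np.zeros(len(tested), dtype=bool)
    for i, fid in enumerate(tested["feature_id"]):
        info = cluster_info.loc[fid]
        tree = trees.get(info["chrom"])
        if tree is not None and tree.overlap(int(info["start"]), int(info["end"]) + 1):
            has_dmr[i] = True

    a = int(np.sum(has_dir & has_dmr))
    b = int(np.sum(has_dir & ~has_dmr))
    c = int(np.sum(~has_dir & has_dmr))
    d = int(np.sum(~has_dir & ~has_dmr))
    table = ((a, b), (c, d))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    stratum = {
        "comparison": comparison,
        "context": dmrs["context"].iloc[0] if len(dmrs) else None,
        "dmr_polarity": dmr_polarity,
        "dsr_direction": dsr_direction,
        "size_class": size_class,
    }
    return AssociationResult(stratum=stratum, table=table, odds_ratio=odds_ratio_2x2(table), p=p)


def association_table(
    dmrs: pd.DataFrame,
    cluster_info: pd.DataFrame,
    dsr: pd.DataFrame,
    size_classes: Sequence[str] = ("all", "24nt"),
    comparison: str | None = None,
) -> pd.DataFrame:
    """All polarity x direction strata as one tidy table."""
    rows = []
    for size_class in size_classes:
        for pol in ("hyper", "hypo"):
            for direc in ("up", "down"):
                res = associate_dmr_dsr(
                    dmrs, cluster_info, dsr, dmr_polarity=pol, dsr_direction=direc,
                    size_class=size_class, comparison=comparison,
                )
                (a, b), (c, d) = res.table
                rows.append(
                    {
                        "comparison": comparison,
                        "context": res.stratum["context"],
                        "dmr_polarity": pol,
                        "dsr_direction": direc,
                        "size_class": size_class,
                        "a": a, "b": b, "c": c, "d": d,
                        "odds_ratio": res.odds_ratio,
                        "p": res.p,
                        "neg_log10_p": res.neg_log10_p,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR target genes and DEG intersection
# ---------------------------------------------------------------------------

def dmr_target_genes(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    spec: RegionSpec,
    chrom_lengths: Mapping[str, int],
    degs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Every (gene, DMR) pair whose promoter and DMR share >= 1 bp.

    The promoter is the strand-aware window 2 kb upstream to 500 bp downstream
    of the TSS.  When a DEG table is given, expression log2fc/q/direction are
    joined by gene_id (NaN/absent when the gene was not tested).
    """
    deg_idx = degs.set_index("feature_id") if degs is not None else None
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(dmrs.itertuples()):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, i)
    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom not in chrom_lengths:
            continue
        prom = promoter_of(g, spec, chrom_lengths[g.chrom])
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(prom[0], prom[1] + 1), key=lambda iv: iv.begin):
            r = dmrs.iloc[iv.data]
            ov = min(prom[1], r["end"]) - max(prom[0], r["start"]) + 1
            row = {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "promoter_start": prom[0],
                "promoter_end": prom[1],
                "dmr_start": int(r["start"]),
                "dmr_end": int(r["end"]),
                "context": r["context"],
                "polarity": r["polarity"],
                "overlap_bp": int(ov),
            }
            if deg_idx is not None and g.gene_id in deg_idx.index:
                e = deg_idx.loc[g.gene_id]
                row.update(expr_log2fc=float(e["log2fc"]), expr_q=float(e["q"]), expr_direction=e["direction"])
            rows.append(row)
    cols = ["gene_id", "chrom", "promoter_start", "promoter_end", "dmr_start", "dmr_end",
            "context", "polarity", "overlap_bp", "expr_log2fc", "expr_q", "expr_direction"]
    out = pd.DataFrame(rows)
    return out.reindex(columns=[c for c in cols if degs is not None or not c.startswith("expr_")])


def venn_counts(target_genes: set, degs_up: set, degs_down: set) -> dict[str, int]:
    """Intersection counts between DMR target genes and up/down DEG sets."""
    both = degs_up & degs_down
    if both:
        raise ValueError(f"genes in both up and down DEG sets: {sorted(both)[:5]}")
    return {
        "targets": len(target_genes),
        "degs_up": len(degs_up),
        "degs_down": len(degs_down),
        "targets_and_up": len(target_genes & degs_up),
        "targets_and_down": len(target_genes & degs_down),
        "targets_only": len(target_genes - degs_up - degs_down),
        "up_only": len(degs_up - target_genes),
        "down_only": len(degs_down - target_genes),
    }


# ---------------------------------------------------------------------------
# RdDM candidate screen
# ---------------------------------------------------------------------------

RDDM_COLUMNS = [
    "gene_id", "chrom", "dmr_start", "dmr_end", "dmr_diff", "cluster_id",
    "srna_log2fc", "expr_log2fc", "te_in_promoter", "mode",
]


def screen_rddm(
    dmrs_chh: pd.DataFrame,
    cluster_info: pd.DataFrame,
    dsr24: pd.DataFrame,
    degs: pd.DataFrame,
    genes: Sequence[GeneModel],
    te: TeAnnotation,
    spec: RegionSpec,
    chrom_lengths: Mapping[str, int],
    mode: str = "canonical",
) -> pd.DataFrame:
    """Genes showing the full RdDM co-localization pattern.

    canonical: promoter overlaps a CHH hypo-DMR; a 24-nt cluster overlapping
    that DMR or the promoter is a down-DSR; the gene is an up-DEG.  mirror
    swaps all three polarities.  One row per qualifying (gene, DMR, cluster);
    use drop_duplicates("gene_id") for the gene-level view.
    """
    if mode not in ("canonical", "mirror"):
        raise ValueError(f"unknown mode {mode!r}")
    want_pol, want_dsr, want_deg = ("hypo", "down", "up") if mode == "canonical" else ("hyper", "up", "down")

    comps = set()
    for df in (dmrs_chh, dsr24, degs):
        if "comparison" in df.columns and len(df):
            comps.update(df["comparison"].dropna().unique())
    if len(comps) > 1:
        raise ValueError(f"mismatched comparisons across layers: {sorted(comps)}")

    sel_dmrs = dmrs_chh[(dmrs_chh["polarity"] == want_pol) & (dmrs_chh["context"] == "CHH")]
    deg_dir = degs.set_index("feature_id")
    dsr_dir = dsr24.set_index("feature_id")
    te_trees = te.tree_by_chrom()

    # clusters by chromosome for interval lookup
    cl_trees: dict[str, IntervalTree] = {}
    for cid, info in cluster_info.iterrows():
        cl_trees.setdefault(info["chrom"], IntervalTree()).addi(int(info["start"]), int(info["end"]) + 1, cid)

    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom not in chrom_lengths or g.gene_id not in deg_dir.index:
            continue
        if deg_dir.loc[g.gene_id, "direction"] != want_deg:
            continue
        prom = promoter_of(g, spec, chrom_lengths[g.chrom])
        for r in sel_dmrs.itertuples():
            if r.chrom != g.chrom or not overlaps((r.start, r.end), prom):
                continue
            tree = cl_trees.get(g.chrom)
            if tree is None:
                continue
            hits = tree.overlap(r.start, r.end + 1) | tree.overlap(prom[0], prom[1] + 1)
            for iv in sorted(hits, key=lambda iv: iv.begin):
                cid = iv.data
                if cid not in dsr_dir.index or dsr_dir.loc[cid, "direction"] != want_dsr:
                    continue
                te_tree = te_trees.get(g.chrom)
                te_in_prom = bool(te_tree.overlap(prom[0], prom[1] + 1)) if te_tree is not None else False
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "chrom": g.chrom,
                        "dmr_start": int(r.start),
                        "dmr_end": int(r.end),
                        "dmr_diff": float(r.diff),
                        "cluster_id": cid,
                        "srna_log2fc": float(dsr_dir.loc[cid, "log2fc"]),
                        "expr_log2fc": float(deg_dir.loc[g.gene_id, "log2fc"]),
                        "te_in_promoter": te_in_prom,
                        "mode": mode,
                    }
                )
    out = pd.DataFrame(rows, columns=RDDM_COLUMNS)
    return out.sort_values(["gene_id", "dmr_start", "cluster_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

def term_enrichment(
    selected: set,
    background: set,
    term_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of terms in ``selected`` vs ``background``.

    ``term_map``: gene_id -> iterable of term ids, or a DataFrame with columns
    gene_id, term_id (and optionally term_name).  Genes without terms count
    toward N only.  Only terms with k >= 1 selected carriers are tested; BH
    across tested terms.
    """
    if not selected:
        raise ValueError("empty selection")
    extra = selected - background
    if extra:
        raise ValueError(f"selected genes not in background: {sorted(extra)[:5]}")
    names = dict(term_names or {})
    gene2terms: dict[str, list[str]] = {}
    if isinstance(term_map, pd.DataFrame):
        if "term_name" in term_map.columns:
            names.update(dict(zip(term_map["term_id"], term_map["term_name"])))
        for r in term_map.itertuples():
            gene2terms.setdefault(str(r.gene_id), []).append(str(r.term_id))
    else:
        gene2terms = {g: list(ts) for g, ts in term_map.items()}

    N = len(background)
    n = len(selected)
    carriers: dict[str, set] = {}
    for g in background:
        for t in gene2terms.get(g, ()):
            carriers.setdefault(t, set()).add(g)

    rows = []
    for term in sorted(carriers):
        K = len(carriers[term])
        k = len(carriers[term] & selected)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "term_name": names.get(term, term), "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = []
    return out
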