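"""Methylation levels and DMR calling.

A site's methylation level is the ratio of reads supporting C (methylated) to
total reads covering it.  Global and regional levels are coverage-weighted
pooled ratios (sum of methylated reads over sum of total reads), not means of
per-site fractions.

DMRs are called on non-overlapping genomic tiles (1 kb default): replicate
counts are pooled within each group, windows with pooled coverage below the
minimum in either group are dropped, a two-sided Fisher exact test on the
2x2 methylated/unmethylated table gives p, Benjamini-Hochberg correction is
applied per context per comparison, and a window is a DMR when q <= fdr, the
absolute level difference exceeds min_diff percentage points, and the level
fold change is >= fc_hi or <= fc_lo.  Hyper means higher methylation in the
treatment (later time point) than in the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .refmodel import GeneModel, Genome, RegionIndex, RegionSpec, TeAnnotation

CX_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context", "trinucleotide"]
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class MethylomeSample:
    """One WGBS sample: per-cytosine counts plus timepoint metadata.

    ``sites`` columns: chrom, pos, strand, context, meth, total.
    """

    sample_id: str
    timepoint_dpt: int
    replicate: int
    sites: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.sites):
            if (self.sites["meth"] > self.sites["total"]).any():
                bad = self.sites.loc[self.sites["meth"] > self.sites["total"]].iloc[0]
                raise ValueError(
                    f"{self.sample_id}: methylated count exceeds total at {bad['chrom']}:{bad['pos']}"
                )


def read_cx_report(path, sample_id: str, timepoint_dpt: int, replicate: int = 1) -> MethylomeSample:
    """Read a Bismark-dialect CX cytosine report (TSV, no header).

    Columns: chrom, 1-based pos, strand, count_methylated, count_unmethylated,
    context (CG/CHG/CHH; other values treated as NA context), trinucleotide.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=CX_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "strand": str, "count_methylated": np.int64,
               "count_unmethylated": np.int64, "context": str, "trinucleotide": str},
    )
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        i = int(np.nonzero((df["count_methylated"] < 0) | (df["count_unmethylated"] < 0))[0][0])
        raise ValueError(f"{path}: negative count at line {i + 1}")
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "meth": df["count_methylated"],
            "total": df["count_methylated"] + df["count_unmethylated"],
        }
    )
    return MethylomeSample(sample_id=sample_id, timepoint_dpt=timepoint_dpt, replicate=replicate, sites=sites)


def write_cx_report(sample: MethylomeSample, path, trinucleotides: pd.Series | None = None) -> None:
    s = sample.sites
    out = pd.DataFrame(
        {
            "chrom": s["chrom"],
            "pos": s["pos"],
            "strand": s["strand"],
            "count_methylated": s["meth"],
            "count_unmethylated": s["total"] - s["meth"],
            "context": s["context"],
            "trinucleotide": trinucleotides if trinucleotides is not None else s.get("trinucleotide", "NNN"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def site_level(meth: int, total: int) -> float:
    """Per-site methylation fraction meth/total; NaN when uncovered."""
    if meth > total:
        raise ValueError(f"methylated count {meth} exceeds total {total}")
    if total == 0:
        return float("nan")
    return meth / total


def global_level(sample: MethylomeSample, context: str, pooled: bool = True) -> float:
    """Genome-wide methylation level (percent) for one context.

    Default is the coverage-weighted pooled ratio 100 * sum(meth)/sum(total)
    over covered sites; ``pooled=False`` gives the unweighted mean of per-site
    fractions instead.  NaN when no covered site exists.
    """
    s = sample.sites
    sel = s[(s["context"] == context) & (s["total"] > 0)]
    if not len(sel):
        return float("nan")
    if pooled:
        return 100.0 * sel["meth"].sum() / sel["total"].sum()
    return 100.0 * (sel["meth"] / sel["total"]).mean()


def region_profile(
    sample: MethylomeSample,
    genes: Sequence[GeneModel],
    spec: RegionSpec,
    context: str,
    chrom_lengths: dict[str, int],
    n_bins: int = 20,
) -> dict:
    """Pooled methylation level (percent) per functional region, plus metagene flank curves.

    Returns {"regions": {label: percent-or-NaN}, "upstream_bins": [...],
    "downstream_bins": [...]} where flank bins run 5'->3' in gene orientation,
    each bin pooling sites across all genes.
    """
    s = sample.sites
    sel = s[(s["context"] == context) & (s["total"] > 0)]
    index = RegionIndex(genes, spec, chrom_lengths)
    region_meth = {lab: 0 for lab in _region_labels()}
    region_total = {lab: 0 for lab in _region_labels()}
    for chrom, grp in sel.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            continue
        labs = index.labels(chrom, grp["pos"].to_numpy())
        for lab in _region_labels():
            m = labs == lab
            region_meth[lab] += int(grp["meth"].to_numpy()[m].sum())
            region_total[lab] += int(grp["total"].to_numpy()[m].sum())
    regions = {
        lab: (100.0 * region_meth[lab] / region_total[lab]) if region_total[lab] > 0 else float("nan")
        for lab in _region_labels()
    }

    up_m = np.zeros(n_bins)
    up_t = np.zeros(n_bins)
    dn_m = np.zeros(n_bins)
    dn_t = np.zeros(n_bins)
    by_chrom = {c: g for c, g in sel.groupby("chrom", sort=False)}
    for g in genes:
        grp = by_chrom.get(g.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy()
        tot = grp["total"].to_numpy()
        for (lo, hi, which, flip) in _flank_windows(g, spec):
            m = (pos >= lo) & (pos <= hi)
            if not m.any():
                continue
            offs = (pos[m] - lo) / (hi - lo + 1)  # in [0,1)
            if flip:
                offs = 1.0 - offs - 1e-12
            bins = np.minimum((offs * n_bins).astype(int), n_bins - 1)
            sink = up_m if which == "up" else dn_m
            sinkt = up_t if which == "up" else dn_t
            np.add.at(sink, bins, meth[m])
            np.add.at(sinkt, bins, tot[m])
    with np.errstate(invalid="ignore", divide="ignore"):
        up_curve = np.where(up_t > 0, 100.0 * up_m / np.maximum(up_t, 1), np.nan)
        dn_curve = np.where(dn_t > 0, 100.0 * dn_m / np.maximum(dn_t, 1), np.nan)
    return {"regions": regions, "upstream_bins": up_curve.tolist(), "downstream_bins": dn_curve.tolist()}


def _region_labels():
    return ("upstream2k", "5UTR", "exon", "intron", "3UTR", "downstream2k")


def _flank_windows(g: GeneModel, spec: RegionSpec):
    """(lo, hi, which, flip) windows for the up/downstream flanks of one gene."""
    if g.strand == "+":
        yield (g.tss - spec.upstream_flank, g.tss - 1, "up", False)
        yield (g.tes + 1, g.tes + spec.downstream_flank, "dn", False)
    else:
        yield (g.tss + 1, g.tss + spec.upstream_flank, "up", True)
        yield (g.tes - spec.downstream_flank, g.tes - 1, "dn", True)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DmrParams:
    """Filter cascade for DMR calling.

    min_coverage applies to the pooled read total of a window within each
    group (``per_site=True`` instead requires every covered site to reach it).
    min_diff is in percentage points; fold-change bounds act on the percent
    levels (treatment/control).
    """

    tile_width: int = 1000
    min_coverage: int = 30
    min_diff: float = 15.0
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    fdr: float = 0.05
    per_site: bool = False

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0,1)")
        if self.tile_width <= 0 or self.min_coverage < 0:
            raise ValueError("tile_width must be positive and min_coverage non-negative")


DMR_COLUMNS = [
    "chrom", "start", "end", "context", "level_treat", "level_ctrl",
    "diff", "fold_change", "p", "q", "polarity", "comparison",
]


def _pool_windows(samples: Sequence[MethylomeSample], context: str, tile_width: int) -> pd.DataFrame:
    """Pool replicate counts into (chrom, window) -> (meth, total) for one context."""
    frames = []
    for s in samples:
        df = s.sites
        sel = df[(df["context"] == context) & (df["total"] > 0)]
        frames.append(sel[["chrom", "pos", "meth", "total"]])
    allsites = pd.concat(frames, ignore_index=True)
    if not len(allsites):
        return pd.DataFrame(columns=["chrom", "widx", "meth", "total"])
    allsites = allsites.assign(widx=(allsites["pos"] - 1) // tile_width)
    g = allsites.groupby(["chrom", "widx"], sort=True)[["meth", "total"]].sum().reset_index()
    return g


def call_dmrs(
    treat: Sequence[MethylomeSample],
    ctrl: Sequence[MethylomeSample],
    context: str,
    params: DmrParams = DmrParams(),
    comparison: str = "treat_vs_ctrl",
) -> pd.DataFrame:
    """Call DMRs for one context between two replicate groups.

    Returns a DataFrame with DMR_COLUMNS; levels are percents, diff is
    treatment minus control in percentage points, fold_change is the percent
    ratio treatment/control (inf when control is 0 and treatment positive).
    """
    if not treat or not ctrl:
        raise ValueError("both groups need at least one sample")
    t = _pool_windows(treat, context, params.tile_width).rename(columns={"meth": "meth_t", "total": "total_t"})
    c = _pool_windows(ctrl, context, params.tile_width).rename(columns={"meth": "meth_c", "total": "total_c"})
    merged = t.merge(c, on=["chrom", "widx"], how="inner")
    merged = merged[(merged["total_t"] >= params.min_coverage) & (merged["total_c"] >= params.min_coverage)]
    if params.per_site:
        merged = _apply_per_site_coverage(merged, treat, ctrl, context, params)
    if not len(merged):
        return pd.DataFrame(columns=DMR_COLUMNS)

    meth_t = merged["meth_t"].to_numpy()
    tot_t = merged["total_t"].to_numpy()
    meth_c = merged["meth_c"].to_numpy()
    tot_c = merged["total_c"].to_numpy()
    pvals = np.array(
        [
            stats.fisher_exact([[mt, tt - mt], [mc, tc - mc]], alternative="two-sided")[1]
            for mt, tt, mc, tc in zip(meth_t, tot_t, meth_c, tot_c)
        ]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]

    level_t = 100.0 * meth_t / tot_t
    level_c = 100.0 * meth_c / tot_c
    diff = level_t - level_c
    # FC with zero control level: +inf when treatment is methylated (passes
    # fc_hi); both-zero windows can never be DMRs (NaN fails both bounds).
    fc = np.full(len(level_t), np.nan)
    nz = level_c > 0
    fc[nz] = level_t[nz] / level_c[nz]
    fc[~nz & (level_t > 0)] = np.inf

    fc_safe = np.nan_to_num(fc, nan=1.0)
    keep = (
        (qvals <= params.fdr)
        & (np.abs(diff) > params.min_diff)
        & ((fc_safe >= params.fc_hi) | (fc_safe <= params.fc_lo))
    )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "start": merged["widx"].to_numpy() * params.tile_width + 1,
            "end": (merged["widx"].to_numpy() + 1) * params.tile_width,
            "context": context,
            "level_treat": level_t,
            "level_ctrl": level_c,
            "diff": diff,
            "fold_change": fc,
            "p": pvals,
            "q": qvals,
            "polarity": np.where(diff > 0, "hyper", "hypo"),
            "comparison": comparison,
        }
    )[keep]
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _apply_per_site_coverage(merged, treat, ctrl, context, params):
    """Alternative coverage rule: every covered site in every sample must reach min_coverage."""
    ok_keys = None
    for s in list(treat) + list(ctrl):
        df = s.sites
        sel = df[(df["context"] == context) & (df["total"] > 0)]
        widx = (sel["pos"] - 1) // params.tile_width
        bad = set(zip(sel["chrom"][sel["total"] < params.min_coverage], widx[sel["total"] < params.min_coverage]))
        keys = set(zip(sel["chrom"], widx))
        ok = keys - bad
        ok_keys = ok if ok_keys is None else (ok_keys & ok)
    mask = [((c, w) in ok_keys) for c, w in zip(merged["chrom"], merged["widx"])]
    return merged[np.asarray(mask, dtype=bool)]


def test_window_table(meth_t: int, unmeth_t: int, meth_c: int, unmeth_c: int) -> float:
    """Two-sided Fisher exact p for one window's pooled 2x2 table."""
    return float(stats.fisher_exact([[meth_t, unmeth_t], [meth_c, unmeth_c]], alternative="two-sided")[1])


def dmr_distribution(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    te: TeAnnotation,
    spec: RegionSpec,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Fractions of DMRs by gene/intergenic, TE/non-TE, and functional region, per polarity.

    Gene/intergenic and TE/non-TE membership use >= 1 bp overlap with the DMR
    interval; the functional-region label is taken at the DMR midpoint, with
    the TSS region (tss +/- tss_window) reported as an additional overlay.
    Within each partition the fractions over one polarity sum to 1.
    """
    from intervaltree import IntervalTree

    gene_trees: dict[str, IntervalTree] = {}
    tss_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1)
        tss_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(1, g.tss - spec.tss_window), g.tss + spec.tss_window + 1
        )
    te_trees = te.tree_by_chrom()
    index = RegionIndex(genes, spec, chrom_lengths)

    rows = []
    for r in dmrs.itertuples():
        mid = (r.start + r.end) // 2
        in_gene = bool(gene_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end + 1))
        in_te = bool(te_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end + 1))
        in_tss = bool(tss_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end + 1))
        rows.append(
            {
                "polarity": r.polarity,
                "genic": "gene" if in_gene else "intergenic",
                "te": "TE" if in_te else "non-TE",
                "region": index.label(r.chrom, mid) if r.chrom in chrom_lengths else "intergenic",
                "tss_region": in_tss,
            }
        )
    ann = pd.DataFrame(rows, columns=["polarity", "genic", "te", "region", "tss_region"])
    out = []
    for partition in ("genic", "te", "region"):
        for pol, grp in ann.groupby("polarity"):
            counts = grp[partition].value_counts()
            for value, n in counts.items():
                out.append(
                    {
                        "partition": partition,
                        "polarity": pol,
                        "value": value,
                        "count": int(n),
                        "fraction": float(n / len(grp)),
                    }
                )
    for pol, grp in ann.groupby("polarity"):
        out.append(
            {
                "partition": "tss_region",
                "polarity": pol,
                "value": "TSS",
                "count": int(grp["tss_region"].sum()),
                "fraction": float(grp["tss_region"].mean()),
            }
        )
    return pd.DataFrame(out, columns=["partition", "polarity", "value", "count", "fraction"])
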