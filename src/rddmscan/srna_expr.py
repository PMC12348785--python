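"""sRNA cluster quantification and differential testing of sRNAs and genes.

sRNA reads (18-30 nt after trimming) are assigned to fixed-width genomic bins
by their 5' end; a bin is an "sRNA cluster" identified as
``chrom;start;end`` in 1-based inclusive coordinates (1 kb default width).
Counts are normalized to counts-per-million (CPM) of the per-sample library
total.  Size-class matrices ("20-22 nt" pools lengths 20-22; "24 nt" is
exactly 24) are normalized against the all-length library size, the
convention for size-fractionated sRNA data.

Differential calling — shared by differentially regulated sRNA clusters
(DSRs) and differentially expressed genes (DEGs) — is a Welch two-sample
t-test on log2(CPM + 1) with Benjamini-Hochberg correction per feature
family; a feature is up when q <= 0.05 and log2FC >= 1, down when q <= 0.05
and log2FC <= -1, otherwise ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_SRNA_LEN = 18
MAX_SRNA_LEN = 30
SIZE_CLASSES = ("all", "20-22nt", "24nt")

DIFF_COLUMNS = ["feature_id", "log2fc", "p", "q", "direction", "size_class"]


def read_srna_table(path) -> pd.DataFrame:
    """Read an sRNA read table: chrom, pos5, strand, length, then one count column per sample."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "pos5", "strand", "length"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[(df["length"] < MIN_SRNA_LEN) | (df["length"] > MAX_SRNA_LEN)]
    if len(bad):
        raise ValueError(f"{path}: sRNA length outside [{MIN_SRNA_LEN},{MAX_SRNA_LEN}] at row {bad.index[0]}")
    return df


def sample_columns(reads: pd.DataFrame) -> list[str]:
    return [c for c in reads.columns if c not in ("chrom", "pos5", "strand", "length")]


def length_distribution(reads: pd.DataFrame, sample: str) -> dict[int, float]:
    """Count-weighted proportion of reads per length 18..30 for one sample."""
    if sample not in reads.columns:
        raise ValueError(f"unknown sample {sample!r}")
    totals = reads.groupby("length")[sample].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError(f"sample {sample!r} has zero reads")
    return {int(k): float(v / grand) for k, v in totals.items() if v > 0}


@dataclass
class SrnaClusterSet:
    """Fixed-width sRNA clusters with per-size-class count and CPM matrices.

    ``info``: DataFrame (index cluster_id) with chrom, start, end.
    ``counts``: dict size_class -> DataFrame clusters x samples.
    ``lib_sizes``: all-length per-sample read totals used for CPM.
    """

    bin_width: int
    info: pd.DataFrame
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    lib_sizes: pd.Series | None = None

    def cpm(self, size_class: str = "all") -> pd.DataFrame:
        """CPM against the all-length library size (so size classes are comparable)."""
        if self.lib_sizes is None:
            self.lib_sizes = self.counts["all"].sum(axis=0)
        zero = self.lib_sizes[self.lib_sizes <= 0]
        if len(zero):
            raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
        return self.counts[size_class] * 1e6 / self.lib_sizes


def bin_reads(reads: pd.DataFrame, bin_width: int = 1000) -> SrnaClusterSet:
    """Assign each read to the bin containing its 5' end and accumulate counts.

    Bin k covers [k*w + 1, (k+1)*w], 1-based inclusive; cluster IDs are
    ``chrom;start;end``.  Empty bins are omitted.
    """
    samples = sample_columns(reads)
    widx = (reads["pos5"] - 1) // bin_width
    start = widx * bin_width + 1
    keyed = reads.assign(_start=start)
    groups = {}
    groups["all"] = keyed.groupby(["chrom", "_start"])[samples].sum()
    groups["20-22nt"] = keyed[keyed["length"].between(20, 22)].groupby(["chrom", "_start"])[samples].sum()
    groups["24nt"] = keyed[keyed["length"] == 24].groupby(["chrom", "_start"])[samples].sum()

    base = groups["all"]
    ids = [f"{c};{s};{s + bin_width - 1}" for c, s in base.index]
    info = pd.DataFrame(
        {
            "chrom": [c for c, _ in base.index],
            "start": [int(s) for _, s in base.index],
            "end": [int(s) + bin_width - 1 for _, s in base.index],
        },
        index=pd.Index(ids, name="cluster_id"),
    )
    counts = {}
    for cls, g in groups.items():
        mat = g.reindex(base.index, fill_value=0)
        mat.index = pd.Index(ids, name="cluster_id")
        counts[cls] = mat.astype(np.int64)
    lib = counts["all"].sum(axis=0)
    return SrnaClusterSet(bin_width=bin_width, info=info, counts=counts, lib_sizes=lib)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: value * 1e6 / column total.  Errors on a zero column."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero column total for sample(s): {list(zero.index)}")
    return counts * 1e6 / totals


def read_count_matrix(path) -> pd.DataFrame:
    """Gene count matrix TSV: first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def call_diff(
    treat_cpm: pd.DataFrame,
    ctrl_cpm: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    size_class: str = "n/a",
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Welch t-test on log2(CPM+1) per feature; BH over the family; direction calls.

    treat_cpm/ctrl_cpm: features x replicate-samples, same index.  With fewer
    than 2 replicates in either group the p/q are NaN and the direction is
    decided by the fold change alone (flagged in the ``warning`` column).
    ``use_raw_p`` gates the direction on the unadjusted p instead of q.
    """
    if not treat_cpm.index.equals(ctrl_cpm.index):
        ctrl_cpm = ctrl_cpm.reindex(treat_cpm.index)
    lt = np.log2(treat_cpm.to_numpy(dtype=float) + 1.0)
    lc = np.log2(ctrl_cpm.to_numpy(dtype=float) + 1.0)
    log2fc = lt.mean(axis=1) - lc.mean(axis=1)

    underpowered = lt.shape[1] < 2 or lc.shape[1] < 2
    if underpowered:
        p = np.full(len(log2fc), np.nan)
        q = np.full(len(log2fc), np.nan)
        sig = np.ones(len(log2fc), dtype=bool)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(lt, lc, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
        q = multipletests(p, method="fdr_bh")[1]
        sig = (p if use_raw_p else q) <= alpha
    direction = np.where(
        sig & (log2fc >= min_abs_log2fc), "up", np.where(sig & (log2fc <= -min_abs_log2fc), "down", "ns")
    )
    out = pd.DataFrame(
        {
            "feature_id": treat_cpm.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
            "size_class": size_class,
        }
    ).reset_index(drop=True)
    if underpowered:
        out["warning"] = "fewer than 2 replicates in a group; direction from fold change only"
    return out


def call_dsr(
    clusters: SrnaClusterSet,
    treat_samples: Sequence[str],
    ctrl_samples: Sequence[str],
    size_classes: Sequence[str] = SIZE_CLASSES,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Differential sRNA clusters per size class; one BH family across the classes.

    The size classes are computed on the same clusters, so they share one
    multiple-testing family.
    """
    frames = []
    for cls in size_classes:
        mat = clusters.cpm(cls)
        frames.append(
            call_diff(mat[list(treat_samples)], mat[list(ctrl_samples)], alpha=alpha,
                      min_abs_log2fc=min_abs_log2fc, size_class=cls)
        )
    joint = pd.concat(frames, ignore_index=True)
    if joint["p"].notna().all():
        joint["q"] = multipletests(joint["p"].to_numpy(), method="fdr_bh")[1]
        sig = joint["q"] <= alpha
        joint["direction"] = np.where(
            sig & (joint["log2fc"] >= min_abs_log2fc),
            "up",
            np.where(sig & (joint["log2fc"] <= -min_abs_log2fc), "down", "ns"),
        )
    return joint


def dsr_summary(diff: pd.DataFrame) -> pd.DataFrame:
    """Counts of up/down/ns per size class (and per comparison when present)."""
    if not len(diff):
        return pd.DataFrame(columns=["size_class", "up", "down", "ns", "total"])
    keys = ["size_class"] + (["comparison"] if "comparison" in diff.columns else [])
    rows = []
    for key, grp in diff.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        counts = grp["direction"].value_counts()
        rows.append(
            dict(
                zip(keys, key),
                up=int(counts.get("up", 0)),
                down=int(counts.get("down", 0)),
                ns=int(counts.get("ns", 0)),
                total=int(len(grp)),
            )
        )
    return pd.DataFrame(rows)


def split_samples(sheet: pd.DataFrame, assay: str, timepoint: int) -> list[str]:
    """Sample ids of one assay at one timepoint from a sample sheet
    (columns sample_id, timepoint_dpt, replicate, assay)."""
    sel = sheet[(sheet["assay"] == assay) & (sheet["timepoint_dpt"] == timepoint)]
    return list(sel["sample_id"])
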