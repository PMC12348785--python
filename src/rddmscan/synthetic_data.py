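"""Coupled synthetic tri-omics generator with planted ground truth.

Emulates the study conditions of cold-treated rice microspores sampled at 0,
5, and 10 days of treatment (dpt): a small random genome with gene models and
transposable elements; per-cytosine WGBS counts with beta-binomial replicate
noise around context-specific baselines (CG 57.55%, CHG 30.23%, CHH 4.6%
genome-wide at 0 dpt; TE compartment elevated); negative-binomial sRNA
cluster counts with an 18-30 nt length mixture whose 24-nt fraction rises
with treatment; and negative-binomial gene counts.

Ground truth is planted at the locus level: a planted RdDM locus is one
genomic window that simultaneously carries a TE inside the promoter, a CHH
hypo-DMR, a downregulated 24-nt sRNA cluster, and an upregulated gene, so
recovery is unambiguous.  Planted DMR windows are written as methylation
islands/valleys whose control and treated levels are capped so that the
full effect (dmr_shift_pp) satisfies both the level-difference and the
fold-change filters in every context; treatment effects ramp at half
amplitude at 5 dpt and full amplitude at 10 dpt.

One integer seed determines every file byte-for-byte; the genome, methylome,
sRNA, and expression layers draw from independently spawned streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .refmodel import GeneModel, Genome, RegionSpec, TeAnnotation, enumerate_cytosines, write_gff3
from .methylome import MethylomeSample, write_cx_report

# 18-30 nt length mixture at 0 dpt; the 24-nt weight rises with treatment
# while lengths 20-22 shrink proportionally (cold stress shifts the sRNA pool
# toward the RdDM-associated 24-nt class).
_BASE_LENGTH_WEIGHTS = {
    18: 0.03, 19: 0.04, 20: 0.10, 21: 0.14, 22: 0.10, 23: 0.05, 24: 0.30,
    25: 0.06, 26: 0.05, 27: 0.04, 28: 0.04, 29: 0.03, 30: 0.02,
}
_W24_DRIFT = {0: 0.0, 5: 0.03, 10: 0.06}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_chrom: int = 2
    chrom_len: int = 500_000
    n_genes: int = 500
    n_tes: int = 300
    tile_width: int = 1000
    depth_lambda: float = 30.0
    # percent methylation at 0 dpt, genome-wide and TE compartment
    base_levels: dict = field(default_factory=lambda: {"CG": 57.55, "CHG": 30.23, "CHH": 4.6})
    te_levels: dict = field(default_factory=lambda: {"CG": 85.0, "CHG": 60.0, "CHH": 15.0})
    overdispersion_rho: float = 0.05
    nb_dispersion: float = 0.1
    n_planted_dmr: int = 60
    n_planted_dsr: int = 40
    n_planted_deg: int = 60
    n_planted_rddm: int = 10
    dmr_shift_pp: float = 40.0
    srna_log2fc: float = 2.0
    gene_log2fc: float = 2.0
    timepoints: tuple = (0, 5, 10)
    reps_meth: int = 2
    reps_srna: int = 3
    reps_rna: int = 3
    n_srna_clusters: int = 300
    srna_cluster_mean: float = 150.0
    gene_mean_log: float = 5.7  # lognormal location of gene base means (~300)
    gene_mean_sigma: float = 0.7

    def __post_init__(self):
        if self.chrom_len % self.tile_width:
            raise ValueError("chrom_len must be a multiple of tile_width")
        for lv in (self.base_levels, self.te_levels):
            if any(not (0 <= v <= 100) for v in lv.values()):
                raise ValueError("levels are percents in [0,100]")

    @property
    def genes_per_chrom(self) -> int:
        return -(-self.n_genes // self.n_chrom)

    @property
    def slot_len(self) -> int:
        """Per-gene genomic slot; must hold the promoter tile plus the gene."""
        slot = (self.chrom_len // self.genes_per_chrom) // self.tile_width * self.tile_width
        if slot < 2 * self.tile_width:
            raise ValueError("chromosomes too short for the requested gene count")
        return slot


@dataclass
class TruthSet:
    """Planted features: what the pipeline should recover."""

    dmrs: pd.DataFrame  # chrom, start, end, context, polarity
    dsrs: pd.DataFrame  # cluster_id, chrom, start, end, direction, size_class
    degs: pd.DataFrame  # gene_id, direction
    rddm: pd.DataFrame  # gene_id, cluster_id, chrom, dmr_start, dmr_end


def _amp(dpt: int) -> float:
    """Treatment-effect amplitude ramp: none at 0, half at 5, full at 10 dpt."""
    return {0: 0.0, 5: 0.5, 10: 1.0}.get(dpt, 1.0)


# ---------------------------------------------------------------------------
# Genome, annotation, and planted-locus layout
# ---------------------------------------------------------------------------

def make_genome(cfg: SimConfig, seed) -> tuple[Genome, list[GeneModel], TeAnnotation, TruthSet]:
    """Random genome with slotted gene models, TEs, and planted feature layout.

    Each gene occupies a slot whose first tile is a promoter tile fully inside
    the gene's promoter window; planted DMR/DSR/RdDM features live on the
    promoter tiles of disjoint slots, so planted features never overlap.
    """
    rng = np.random.default_rng(seed)
    n_needed = cfg.n_planted_rddm + cfg.n_planted_dmr + cfg.n_planted_dsr
    if n_needed + cfg.n_planted_deg > cfg.n_genes:
        raise ValueError("planted features do not fit without overlap")

    chroms = []
    for i in range(cfg.n_chrom):
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.chrom_len)
        chroms.append((f"Chr{i + 1}", seq.tobytes().decode("ascii")))
    genome = Genome(chroms)

    # slot assignment
    slots = []  # (chrom, slot_start0) 0-based slot origin
    for i in range(cfg.n_chrom):
        for k in range(cfg.genes_per_chrom):
            if len(slots) < cfg.n_genes:
                slots.append((f"Chr{i + 1}", k * cfg.slot_len))
    order = rng.permutation(len(slots))
    rddm_slots = order[: cfg.n_planted_rddm]
    dmr_slots = order[cfg.n_planted_rddm : cfg.n_planted_rddm + cfg.n_planted_dmr]
    dsr_slots = order[cfg.n_planted_rddm + cfg.n_planted_dmr : n_needed]
    deg_slots = order[n_needed : n_needed + cfg.n_planted_deg]
    # Planted-locus genes are + strand so the slot's first tile is inside
    # their promoter.  A minus-strand gene's promoter extends ~2 kb to the
    # right, into the NEXT slot's first tile — so the gene immediately before
    # any planted tile is forced to + strand, keeping planted tiles out of
    # every non-planted promoter.
    planted_plus = set(int(i) for i in np.concatenate([rddm_slots, dmr_slots, dsr_slots]))
    guard_plus = {
        i - 1
        for i in planted_plus
        if i % cfg.genes_per_chrom != 0  # previous slot exists on the same chromosome
    }

    genes: list[GeneModel] = []
    tw = cfg.tile_width
    for idx, (chrom, s0) in enumerate(slots):
        strand = "+" if (idx in planted_plus or idx in guard_plus) else str(rng.choice(["+", "-"]))
        glen = int(rng.integers(600, min(900, cfg.slot_len - tw - 50)))
        if strand == "+":
            tss = s0 + tw + 1
            gstart, gend = tss, tss + glen - 1
            tes = gend
        else:
            # gene body still to the right of the promoter tile; TSS at its right end
            gstart = s0 + tw + 1
            gend = gstart + glen - 1
            tss, tes = gend, gstart
        exons, futr, tutr = _gene_structure(rng, gstart, gend, strand)
        genes.append(
            GeneModel(
                gene_id=f"gene{idx:04d}", chrom=chrom, strand=strand, tss=tss, tes=tes,
                exons=exons, five_utr=futr, three_utr=tutr,
            )
        )

    # TEs: one inside each RdDM promoter tile, the rest uniform
    te_ivs: list[tuple[str, int, int]] = []
    for si in rddm_slots:
        chrom, s0 = slots[si]
        ts = s0 + int(rng.integers(100, tw - 400))
        te_ivs.append((chrom, ts + 1, ts + 300))
    for _ in range(max(0, cfg.n_tes - cfg.n_planted_rddm)):
        chrom = f"Chr{int(rng.integers(1, cfg.n_chrom + 1))}"
        ln = int(rng.integers(200, 800))
        s = int(rng.integers(0, cfg.chrom_len - ln))
        te_ivs.append((chrom, s + 1, s + ln))
    te = TeAnnotation(sorted(te_ivs))

    # planted features on promoter tiles
    ctx_cycle = ["CG", "CHG", "CHH"]
    pol_cycle = ["hyper", "hypo"]
    dmr_rows = []
    for j, si in enumerate(rddm_slots):
        chrom, s0 = slots[si]
        dmr_rows.append({"chrom": chrom, "start": s0 + 1, "end": s0 + tw,
                         "context": "CHH", "polarity": "hypo"})
    for j, si in enumerate(dmr_slots):
        chrom, s0 = slots[si]
        dmr_rows.append({"chrom": chrom, "start": s0 + 1, "end": s0 + tw,
                         "context": ctx_cycle[j % 3], "polarity": pol_cycle[(j // 3) % 2]})
    dmr_truth = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "context", "polarity"])

    dsr_rows = []
    for j, si in enumerate(rddm_slots):
        chrom, s0 = slots[si]
        cid = f"{chrom};{s0 + 1};{s0 + tw}"
        dsr_rows.append({"cluster_id": cid, "chrom": chrom, "start": s0 + 1, "end": s0 + tw,
                         "direction": "down", "size_class": "24nt"})
    for j, si in enumerate(dsr_slots):
        chrom, s0 = slots[si]
        cid = f"{chrom};{s0 + 1};{s0 + tw}"
        dsr_rows.append({"cluster_id": cid, "chrom": chrom, "start": s0 + 1, "end": s0 + tw,
                         "direction": "down" if j % 2 else "up", "size_class": "24nt"})
    dsr_truth = pd.DataFrame(dsr_rows, columns=["cluster_id", "chrom", "start", "end", "direction", "size_class"])

    deg_rows = [{"gene_id": genes[si].gene_id, "direction": "up"} for si in rddm_slots]
    deg_rows += [
        {"gene_id": genes[si].gene_id, "direction": "down" if j % 2 else "up"}
        for j, si in enumerate(deg_slots)
    ]
    deg_truth = pd.DataFrame(deg_rows, columns=["gene_id", "direction"])

    rddm_rows = []
    for si in rddm_slots:
        chrom, s0 = slots[si]
        rddm_rows.append(
            {"gene_id": genes[si].gene_id, "cluster_id": f"{chrom};{s0 + 1};{s0 + tw}",
             "chrom": chrom, "dmr_start": s0 + 1, "dmr_end": s0 + tw}
        )
    truth = TruthSet(
        dmrs=dmr_truth.sort_values(["chrom", "start"]).reset_index(drop=True),
        dsrs=dsr_truth.sort_values("cluster_id").reset_index(drop=True),
        degs=deg_truth.sort_values("gene_id").reset_index(drop=True),
        rddm=pd.DataFrame(rddm_rows, columns=["gene_id", "cluster_id", "chrom", "dmr_start", "dmr_end"])
        .sort_values("gene_id")
        .reset_index(drop=True),
    )
    return genome, genes, te, truth


def _gene_structure(rng, gstart: int, gend: int, strand: str):
    """2-3 exons with short UTRs at the transcript ends."""
    glen = gend - gstart + 1
    n_exons = int(rng.integers(2, 4))
    cuts = np.sort(rng.choice(np.arange(100, glen - 100, 20), size=(n_exons - 1) * 2, replace=False))
    bounds = [gstart] + [gstart + int(c) for c in cuts] + [gend]
    exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
    utr5_len, utr3_len = 60, 60
    if strand == "+":
        futr = [(exons[0][0], min(exons[0][0] + utr5_len - 1, exons[0][1]))]
        tutr = [(max(exons[-1][1] - utr3_len + 1, exons[-1][0]), exons[-1][1])]
    else:
        futr = [(max(exons[-1][1] - utr5_len + 1, exons[-1][0]), exons[-1][1])]
        tutr = [(exons[0][0], min(exons[0][0] + utr3_len - 1, exons[0][1]))]
    return exons, futr, tutr


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _planted_window_levels(cfg: SimConfig, context: str, polarity: str) -> tuple[float, float]:
    """(control, treated) percent levels for a planted DMR window.

    Caps keep the full-amplitude effect inside both DMR filters: hyper starts
    from at most 30%, hypo ends at at most 30%, so a 40-pp shift always gives
    fold change >= 2.3 or <= 0.43.
    """
    base = cfg.base_levels[context]
    if polarity == "hyper":
        lo = min(base, 30.0)
        return lo, min(lo + cfg.dmr_shift_pp, 97.0)
    hi_end = min(base, 30.0)
    return hi_end + cfg.dmr_shift_pp, hi_end


def simulate_methylome(
    cfg: SimConfig,
    genome: Genome,
    te: TeAnnotation,
    truth: TruthSet,
    seed,
) -> list[MethylomeSample]:
    """Per-sample per-cytosine counts: Poisson depth, beta-binomial methylation.

    Site means come from context x compartment (TE intervals elevated),
    overridden inside planted DMR windows of the site's context; replicate
    draws are independent.
    """
    sites = enumerate_cytosines(genome)
    ss = _seedseq(seed)
    n_samples = len(cfg.timepoints) * cfg.reps_meth
    children = ss.spawn(n_samples)

    # per-chromosome boolean TE masks
    te_mask = {name: np.zeros(genome.length(name), dtype=bool) for name in genome.names}
    for chrom, s, e in te.intervals:
        if chrom in te_mask:
            te_mask[chrom][s - 1 : e] = True

    # baseline mu per site (fraction)
    mu0 = np.zeros(len(sites))
    ctx = sites["context"].to_numpy()
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    in_te = np.zeros(len(sites), dtype=bool)
    for name in genome.names:
        m = chrom_arr == name
        in_te[m] = te_mask[name][pos[m] - 1]
    for context in ("CG", "CHG", "CHH"):
        m = ctx == context
        mu0[m] = np.where(in_te[m], cfg.te_levels[context], cfg.base_levels[context]) / 100.0

    # planted window overrides: (mask, control_mu, treated_mu)
    overrides = []
    for r in truth.dmrs.itertuples():
        m = (chrom_arr == r.chrom) & (pos >= r.start) & (pos <= r.end) & (ctx == r.context)
        c_lvl, t_lvl = _planted_window_levels(cfg, r.context, r.polarity)
        overrides.append((m, c_lvl / 100.0, t_lvl / 100.0))

    samples = []
    si = 0
    for dpt in cfg.timepoints:
        for rep in range(1, cfg.reps_meth + 1):
            rng = np.random.default_rng(children[si])
            si += 1
            mu = mu0.copy()
            a = _amp(dpt)
            for m, c_lvl, t_lvl in overrides:
                mu[m] = c_lvl + a * (t_lvl - c_lvl)
            depth = rng.poisson(cfg.depth_lambda, size=len(mu))
            meth = _beta_binomial(rng, depth, np.clip(mu, 1e-4, 1 - 1e-4), cfg.overdispersion_rho)
            sid = f"meth_{dpt}dpt_r{rep}"
            df = pd.DataFrame(
                {
                    "chrom": chrom_arr,
                    "pos": pos,
                    "strand": sites["strand"].to_numpy(),
                    "context": ctx,
                    "meth": meth,
                    "total": depth,
                    "trinucleotide": sites["trinucleotide"].to_numpy(),
                }
            )
            samples.append(MethylomeSample(sample_id=sid, timepoint_dpt=dpt, replicate=rep, sites=df))
    return samples


def _beta_binomial(rng, depth: np.ndarray, mu: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draw with mean mu and intraclass correlation rho (rho=0 -> binomial)."""
    if rho <= 0:
        return rng.binomial(depth, mu)
    conc = (1.0 - rho) / rho
    p = rng.beta(mu * conc, (1.0 - mu) * conc)
    return rng.binomial(depth, p)


def _seedseq(seed) -> np.random.SeedSequence:
    """Normalize an int or SeedSequence to a SeedSequence (spawn keys preserved)."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


# ---------------------------------------------------------------------------
# sRNA and expression
# ---------------------------------------------------------------------------

def _length_weights(dpt: int) -> dict[int, float]:
    w = dict(_BASE_LENGTH_WEIGHTS)
    delta = _W24_DRIFT.get(dpt, _W24_DRIFT[10])
    pool = w[20] + w[21] + w[22]
    for ln in (20, 21, 22):
        w[ln] -= delta * w[ln] / pool
    w[24] += delta
    return w


def _nb(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_srna(cfg: SimConfig, genome: Genome, truth: TruthSet, seed) -> pd.DataFrame:
    """sRNA read table: planted clusters plus random background clusters.

    Per cluster, sample, and length: NB counts around base * length-mixture
    weight; planted DSR clusters scale their 24-nt mean by 2^(+/- srna_log2fc
    * amplitude) in treated samples.  Rows carry one representative 5'
    position per (cluster, length).
    """
    rng = np.random.default_rng(_seedseq(seed))
    tw = cfg.tile_width
    planted = truth.dsrs.set_index("cluster_id")

    # cluster catalogue: planted first, then random distinct background tiles
    cluster_ids = list(planted.index)
    occupied = {(r.chrom, r.start) for r in truth.dsrs.itertuples()}
    n_bg = max(0, cfg.n_srna_clusters - len(cluster_ids))
    while n_bg > 0:
        chrom = f"Chr{int(rng.integers(1, cfg.n_chrom + 1))}"
        start = int(rng.integers(0, cfg.chrom_len // tw)) * tw + 1
        if (chrom, start) in occupied:
            continue
        occupied.add((chrom, start))
        cluster_ids.append(f"{chrom};{start};{start + tw - 1}")
        n_bg -= 1

    base_mean = rng.lognormal(np.log(cfg.srna_cluster_mean), 0.6, size=len(cluster_ids))
    sample_ids = [f"srna_{dpt}dpt_r{r}" for dpt in cfg.timepoints for r in range(1, cfg.reps_srna + 1)]
    lengths = sorted(_BASE_LENGTH_WEIGHTS)

    counts = {}
    for sid in sample_ids:
        dpt = int(sid.split("_")[1].replace("dpt", ""))
        w = _length_weights(dpt)
        a = _amp(dpt)
        mat = np.zeros((len(cluster_ids), len(lengths)), dtype=np.int64)
        for j, ln in enumerate(lengths):
            mean = base_mean * w[ln]
            if ln == 24:
                scale = np.ones(len(cluster_ids))
                for i, cid in enumerate(cluster_ids):
                    if cid in planted.index:
                        sign = 1.0 if planted.loc[cid, "direction"] == "up" else -1.0
                        scale[i] = 2.0 ** (sign * cfg.srna_log2fc * a)
                mean = mean * scale
            mat[:, j] = _nb(rng, mean, cfg.nb_dispersion)
        counts[sid] = mat

    rows = []
    for i, cid in enumerate(cluster_ids):
        chrom, start, end = cid.split(";")
        start = int(start)
        for j, ln in enumerate(lengths):
            pos5 = start + int(rng.integers(0, tw))
            strand = "+" if rng.random() < 0.5 else "-"
            row = {"chrom": chrom, "pos5": pos5, "strand": strand, "length": ln}
            for sid in sample_ids:
                row[sid] = int(counts[sid][i, j])
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[df[sample_ids].sum(axis=1) > 0].reset_index(drop=True)


def simulate_expression(cfg: SimConfig, genes: list[GeneModel], truth: TruthSet, seed) -> pd.DataFrame:
    """Gene count matrix: NB around lognormal base means; planted DEGs shifted."""
    rng = np.random.default_rng(_seedseq(seed))
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(cfg.gene_mean_log, cfg.gene_mean_sigma, size=len(gene_ids))
    planted = truth.degs.set_index("gene_id")["direction"]
    sign = np.zeros(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if gid in planted.index:
            sign[i] = 1.0 if planted.loc[gid] == "up" else -1.0

    data = {}
    for dpt in cfg.timepoints:
        a = _amp(dpt)
        mean = base * 2.0 ** (sign * cfg.gene_log2fc * a)
        for rep in range(1, cfg.reps_rna + 1):
            data[f"rna_{dpt}dpt_r{rep}"] = _nb(rng, mean, cfg.nb_dispersion)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# Orchestration and truth I/O
# ---------------------------------------------------------------------------

def sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for assay, reps in (("meth", cfg.reps_meth), ("srna", cfg.reps_srna), ("rna", cfg.reps_rna)):
        for dpt in cfg.timepoints:
            for rep in range(1, reps + 1):
                rows.append(
                    {"sample_id": f"{assay}_{dpt}dpt_r{rep}", "timepoint_dpt": dpt,
                     "replicate": rep, "assay": assay}
                )
    return pd.DataFrame(rows)


def write_truth(truth: TruthSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = truth.dmrs.copy()
    bed["start0"] = bed["start"] - 1
    bed["name"] = bed["context"] + ";" + bed["polarity"]
    bed[["chrom", "start0", "end", "name"]].to_csv(outdir / "dmr.bed", sep="\t", header=False, index=False)
    truth.dsrs.to_csv(outdir / "dsr.tsv", sep="\t", index=False)
    truth.degs.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    truth.rddm.to_csv(outdir / "rddm.tsv", sep="\t", index=False)


def read_truth(outdir) -> TruthSet:
    outdir = Path(outdir)
    bed = pd.read_csv(outdir / "dmr.bed", sep="\t", header=None, names=["chrom", "start0", "end", "name"])
    ctx_pol = bed["name"].str.split(";", expand=True)
    dmrs = pd.DataFrame(
        {"chrom": bed["chrom"], "start": bed["start0"] + 1, "end": bed["end"],
         "context": ctx_pol[0], "polarity": ctx_pol[1]}
    )
    return TruthSet(
        dmrs=dmrs,
        dsrs=pd.read_csv(outdir / "dsr.tsv", sep="\t"),
        degs=pd.read_csv(outdir / "deg.tsv", sep="\t"),
        rddm=pd.read_csv(outdir / "rddm.tsv", sep="\t"),
    )


def simulate_all(cfg: SimConfig, seed: int, outdir) -> dict:
    """Generate the full dataset under ``outdir``; returns paths and the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(int(seed))
    s_gen, s_meth, s_srna, s_expr = ss.spawn(4)

    genome, genes, te, truth = make_genome(cfg, s_gen)
    genome.to_fasta(outdir / "genome.fa")
    write_gff3(genes, outdir / "genes.gff3")
    te.to_bed(outdir / "te.bed")
    sheet = sample_sheet(cfg)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    cx_dir = outdir / "cx"
    cx_dir.mkdir(exist_ok=True)
    meth_paths = {}
    for s in simulate_methylome(cfg, genome, te, truth, s_meth):
        p = cx_dir / f"{s.sample_id}.cx.tsv"
        write_cx_report(s, p, trinucleotides=s.sites["trinucleotide"])
        meth_paths[s.sample_id] = str(p)

    srna = simulate_srna(cfg, genome, truth, s_srna)
    srna.to_csv(outdir / "srna.tsv", sep="\t", index=False)
    expr = simulate_expression(cfg, genes, truth, s_expr)
    expr.to_csv(outdir / "gene_counts.tsv", sep="\t")
    write_truth(truth, outdir / "truth")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump({"seed": int(seed), **asdict(cfg)}, fh, indent=1, default=str)
    return {
        "genome": str(outdir / "genome.fa"),
        "gff3": str(outdir / "genes.gff3"),
        "te_bed": str(outdir / "te.bed"),
        "samples": str(outdir / "samples.tsv"),
        "cx": meth_paths,
        "srna": str(outdir / "srna.tsv"),
        "gene_counts": str(outdir / "gene_counts.tsv"),
        "truth_dir": str(outdir / "truth"),
    }
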