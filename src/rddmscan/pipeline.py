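"""End-to-end pipeline: simulate -> DMR -> DSR -> DEG -> integrate -> screen.

``run_all`` executes every stage in order against a run configuration,
writes each intermediate table as TSV, and finishes with a JSON manifest
(parameters, input checksums, per-table row counts).  Rerunning with the
same inputs and seed reproduces byte-identical tables; only the manifest
timestamp differs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import integrate, methylome, refmodel, srna_expr, synthetic_data

STAGES = ("simulate", "annotate", "dmr", "dsr", "deg", "integrate_screen")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    outdir: str = "run"
    seed: int = 0
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    dmr_params: methylome.DmrParams = field(default_factory=methylome.DmrParams)
    region_spec: refmodel.RegionSpec = field(default_factory=refmodel.RegionSpec)
    comparisons: tuple = ((5, 0), (10, 0))
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    contexts: tuple = ("CG", "CHG", "CHH")
    verbose: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = json.load(fh)
        kwargs = dict(obj)
        if "sim" in kwargs:
            kwargs["sim"] = synthetic_data.SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                                        for k, v in kwargs["sim"].items()})
        if "dmr_params" in kwargs:
            kwargs["dmr_params"] = methylome.DmrParams(**kwargs["dmr_params"])
        if "region_spec" in kwargs:
            kwargs["region_spec"] = refmodel.RegionSpec(**kwargs["region_spec"])
        if "comparisons" in kwargs:
            kwargs["comparisons"] = tuple(tuple(c) for c in kwargs["comparisons"])
        if "contexts" in kwargs:
            kwargs["contexts"] = tuple(kwargs["contexts"])
        return cls(**kwargs)


def _log(cfg: RunConfig, stage: str, msg: str) -> None:
    if cfg.verbose:
        print(f"[{stage}] {msg}", file=sys.stderr)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "parameters": {
            "seed": cfg.seed,
            "dmr_params": asdict(cfg.dmr_params),
            "region_spec": asdict(cfg.region_spec),
            "sim": asdict(cfg.sim),
            "alpha": cfg.alpha,
            "min_abs_log2fc": cfg.min_abs_log2fc,
            "comparisons": list(map(list, cfg.comparisons)),
            "tss_region_definition": "tss +/- region_spec.tss_window",
        },
        "tables": {},
        "inputs": {},
    }

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format="%.6g")
        manifest["tables"][name] = int(len(df))

    # --- simulate -----------------------------------------------------
    _log(cfg, "simulate", f"seed={cfg.seed}")
    try:
        paths = synthetic_data.simulate_all(cfg.sim, cfg.seed, out / "sim")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", str(e)) from e
    manifest["stages"].append("simulate")
    for key in ("genome", "gff3", "te_bed", "srna", "gene_counts"):
        manifest["inputs"][key] = {"path": paths[key], "sha256": _sha256(paths[key])}

    # --- annotate -----------------------------------------------------
    try:
        genome = refmodel.Genome.from_fasta(paths["genome"])
        genes = refmodel.read_gff3(paths["gff3"])
        te = refmodel.TeAnnotation.from_bed(paths["te_bed"])
        chrom_lengths = genome.chrom_lengths()
        refmodel.save_refmodel(out / "refmodel.json", genome, genes, te, cfg.region_spec)
    except Exception as e:
        raise StageError("annotate", str(e)) from e
    manifest["stages"].append("annotate")
    _log(cfg, "annotate", f"{len(genes)} genes, {len(te.intervals)} TEs")

    sheet = pd.read_csv(paths["samples"], sep="\t")

    # --- dmr ----------------------------------------------------------
    try:
        meth_samples: dict[int, list] = {}
        for r in sheet[sheet["assay"] == "meth"].itertuples():
            s = methylome.read_cx_report(
                paths["cx"][r.sample_id], r.sample_id, int(r.timepoint_dpt), int(r.replicate)
            )
            meth_samples.setdefault(int(r.timepoint_dpt), []).append(s)
        dmr_frames = []
        level_rows = []
        for dpt, group in sorted(meth_samples.items()):
            for ctx in cfg.contexts:
                for s in group:
                    level_rows.append(
                        {"sample_id": s.sample_id, "timepoint_dpt": dpt, "context": ctx,
                         "global_level_percent": methylome.global_level(s, ctx)}
                    )
        for t_dpt, c_dpt in cfg.comparisons:
            comp = f"{t_dpt}dpt_vs_{c_dpt}dpt"
            for ctx in cfg.contexts:
                dmrs = methylome.call_dmrs(
                    meth_samples[t_dpt], meth_samples[c_dpt], ctx, cfg.dmr_params, comparison=comp
                )
                dmr_frames.append(dmrs)
                _log(cfg, "dmr", f"{comp} {ctx}: {len(dmrs)} DMRs")
        dmr_all = pd.concat(dmr_frames, ignore_index=True)
        save("global_levels.tsv", pd.DataFrame(level_rows))
        save("dmr.tsv", dmr_all)
        dist = methylome.dmr_distribution(dmr_all, genes, te, cfg.region_spec, chrom_lengths)
        save("dmr_distribution.tsv", dist)
    except StageError:
        raise
    except Exception as e:
        raise StageError("dmr", str(e)) from e
    manifest["stages"].append("dmr")

    # --- dsr ----------------------------------------------------------
    try:
        reads = srna_expr.read_srna_table(paths["srna"])
        clusters = srna_expr.bin_reads(reads, cfg.sim.tile_width)
        clusters.info.to_csv(out / "clusters.tsv", sep="\t")
        manifest["tables"]["clusters.tsv"] = int(len(clusters.info))
        dsr_frames = []
        for t_dpt, c_dpt in cfg.comparisons:
            comp = f"{t_dpt}dpt_vs_{c_dpt}dpt"
            treat = srna_expr.split_samples(sheet, "srna", t_dpt)
            ctrl = srna_expr.split_samples(sheet, "srna", c_dpt)
            dsr = srna_expr.call_dsr(clusters, treat, ctrl, alpha=cfg.alpha,
                                     min_abs_log2fc=cfg.min_abs_log2fc)
            dsr["comparison"] = comp
            dsr_frames.append(dsr)
        dsr_all = pd.concat(dsr_frames, ignore_index=True)
        save("dsr.tsv", dsr_all)
        save("dsr_summary.tsv", srna_expr.dsr_summary(dsr_all))
    except StageError:
        raise
    except Exception as e:
        raise StageError("dsr", str(e)) from e
    manifest["stages"].append("dsr")

    # --- deg ----------------------------------------------------------
    try:
        counts = srna_expr.read_count_matrix(paths["gene_counts"])
        gene_cpm = srna_expr.cpm(counts)
        deg_frames = []
        for t_dpt, c_dpt in cfg.comparisons:
            comp = f"{t_dpt}dpt_vs_{c_dpt}dpt"
            treat = srna_expr.split_samples(sheet, "rna", t_dpt)
            ctrl = srna_expr.split_samples(sheet, "rna", c_dpt)
            deg = srna_expr.call_diff(gene_cpm[treat], gene_cpm[ctrl], alpha=cfg.alpha,
                                      min_abs_log2fc=cfg.min_abs_log2fc)
            deg["comparison"] = comp
            deg_frames.append(deg)
        deg_all = pd.concat(deg_frames, ignore_index=True)
        save("deg.tsv", deg_all)
    except StageError:
        raise
    except Exception as e:
        raise StageError("deg", str(e)) from e
    manifest["stages"].append("deg")

    # --- integrate + screen -------------------------------------------
    try:
        assoc_frames, target_frames, venn_rows, screen_frames = [], [], [], []
        for t_dpt, c_dpt in cfg.comparisons:
            comp = f"{t_dpt}dpt_vs_{c_dpt}dpt"
            dsr_c = dsr_all[dsr_all["comparison"] == comp]
            deg_c = deg_all[deg_all["comparison"] == comp]
            for ctx in cfg.contexts:
                dmr_c = dmr_all[(dmr_all["comparison"] == comp) & (dmr_all["context"] == ctx)]
                if len(dmr_c):
                    assoc = integrate.association_table(dmr_c, clusters.info, dsr_c, comparison=comp)
                    assoc["context"] = ctx
                    assoc_frames.append(assoc)
                targets = integrate.dmr_target_genes(dmr_c, genes, cfg.region_spec, chrom_lengths, degs=deg_c)
                if len(targets):
                    targets["comparison"] = comp
                    target_frames.append(targets)
                vc = integrate.venn_counts(
                    set(targets["gene_id"]) if len(targets) else set(),
                    set(deg_c[deg_c["direction"] == "up"]["feature_id"]),
                    set(deg_c[deg_c["direction"] == "down"]["feature_id"]),
                )
                venn_rows.append({"comparison": comp, "context": ctx, **vc})
            dmr_chh = dmr_all[(dmr_all["comparison"] == comp) & (dmr_all["context"] == "CHH")]
            dsr24 = dsr_c[dsr_c["size_class"] == "24nt"]
            cand = integrate.screen_rddm(
                dmr_chh, clusters.info, dsr24, deg_c, genes, te, cfg.region_spec, chrom_lengths
            )
            cand["comparison"] = comp
            screen_frames.append(cand)
        save("association.tsv", pd.concat(assoc_frames, ignore_index=True) if assoc_frames
             else pd.DataFrame())
        save("dmr_target_genes.tsv", pd.concat(target_frames, ignore_index=True) if target_frames
             else pd.DataFrame())
        save("venn.tsv", pd.DataFrame(venn_rows))
        save("rddm_candidates.tsv", pd.concat(screen_frames, ignore_index=True))
    except StageError:
        raise
    except Exception as e:
        raise StageError("integrate_screen", str(e)) from e
    manifest["stages"].append("integrate_screen")

    # self-consistency: manifest row counts vs files on disk
    for name, n in manifest["tables"].items():
        actual = sum(1 for _ in open(out / name)) - 1
        if actual != n:
            raise StageError("manifest", f"{name}: row count mismatch ({actual} != {n})")
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    _log(cfg, "done", f"manifest with {len(manifest['stages'])} stages")
    return manifest
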