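"""Reference model: genome, cytosine contexts, gene annotation, promoters, regions.

Plant cytosine methylation is classified by the two bases 3' of the cytosine
(read 5'->3' on the cytosine's own strand): CG, CHG, and CHH, where H is any
of A, C, or T.  Everything downstream — methylation levels, DMR calling, the
RdDM screen — keys off the context calls and the interval geometry defined
here.

Coordinate convention: every public interface in this package uses 1-based,
inclusive genomic coordinates (the convention visible in sRNA cluster IDs such
as ``Chr6;2121001;2122000``).  BED files are converted from 0-based half-open
on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

# Region labels in precedence order (highest first).  Gene-body labels beat
# flank labels; UTR beats exon; intergenic is the fallback.
REGION_LABELS = (
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "upstream2k",
    "downstream2k",
    "intergenic",
)
_LABEL_PRIORITY = {lab: i for i, lab in enumerate(REGION_LABELS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Genome:
    """An in-memory genome: ordered chromosomes of uppercase A/C/G/T/N text."""

    def __init__(self, chromosomes: Iterable[tuple[str, str]]):
        self.chromosomes: list[tuple[str, str]] = []
        seen = set()
        for name, seq in chromosomes:
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name}")
            seen.add(name)
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: invalid bases {sorted(bad)}")
            self.chromosomes.append((name, seq))
        self._index = {name: seq for name, seq in self.chromosomes}

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def sequence(self, chrom: str) -> str:
        return self._index[chrom]

    def length(self, chrom: str) -> int:
        return len(self._index[chrom])

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def chrom_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class RegionSpec:
    """Window sizes for flanks, promoters, and the TSS region.

    The promoter is 2 kb upstream through 500 bp downstream of the TSS,
    strand-aware.  The "TSS region" used in DMR distribution summaries is
    tss +/- tss_window (no standard definition exists; this one is recorded
    in output metadata).
    """

    upstream_flank: int = 2000
    downstream_flank: int = 2000
    promoter_up: int = 2000
    promoter_down: int = 500
    tss_window: int = 1000

    def __post_init__(self):
        for name in ("upstream_flank", "downstream_flank", "promoter_up", "promoter_down", "tss_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GeneModel:
    """A single gene model (one transcript): strand-aware TSS/TES plus exon and UTR intervals."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int  # 1-based; transcription start
    tes: int  # 1-based; transcription end
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: tss must not exceed tes on + strand")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: tss must not precede tes on - strand")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TeAnnotation:
    """Transposable-element intervals, 1-based inclusive."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path) -> "TeAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"], comment="#")
        # BED is 0-based half-open; convert to 1-based inclusive.
        ivs = [(str(r.chrom), int(r.start) + 1, int(r.end)) for r in df.itertuples()]
        return cls(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    def tree_by_chrom(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, s, e in self.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)  # half-open internal
        return trees


def overlaps(a: tuple[int, int], b: tuple[int, int], chrom_a: str | None = None, chrom_b: str | None = None) -> bool:
    """True iff 1-based inclusive intervals a and b share >= 1 bp.

    If chromosome names are given and differ, returns False.
    """
    if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
        return False
    return a[0] <= b[1] and b[0] <= a[1]


# ---------------------------------------------------------------------------
# Context calling
# ---------------------------------------------------------------------------

def call_context(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at (chrom, pos, strand): CG, CHG, CHH, or NA.

    The base at pos on the given strand must be C.  CG needs one downstream
    base (strand-oriented); CHG/CHH need two; a too-short window or an
    intervening N gives NA.
    """
    seq = genome.sequence(chrom)
    if not (1 <= pos <= len(seq)):
        raise ValueError(f"position {chrom}:{pos} out of bounds")
    if strand == "+":
        base = seq[pos - 1]
        down = seq[pos : pos + 2]
    elif strand == "-":
        base = seq[pos - 1].translate(_COMPLEMENT)
        down = seq[max(0, pos - 3) : pos - 1][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if base != "C":
        raise ValueError(f"base at {chrom}:{pos}({strand}) is {base}, not C")
    return _classify(down)


def _classify(down: str) -> str:
    """Classify from the (strand-oriented) downstream dinucleotide."""
    if len(down) >= 1 and down[0] == "G":
        return "CG"
    if len(down) < 2:
        return "NA"
    b1, b2 = down[0], down[1]
    if b1 == "N" or b2 == "N":
        return "NA"
    # b1 is H (A/C/T) here
    return "CHG" if b2 == "G" else "CHH"


def enumerate_cytosines(genome: Genome, chroms: Sequence[str] | None = None) -> pd.DataFrame:
    """All cytosines of the genome, both strands, with contexts.

    Every C on the + strand, and every G (a C on the - strand), is emitted
    exactly once.  Returns a DataFrame with columns chrom, pos (1-based),
    strand, context, trinucleotide (strand-oriented, N-padded at ends).
    """
    frames = []
    for name, seq in genome.chromosomes:
        if chroms is not None and name not in chroms:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        n = len(arr)
        if n == 0:
            continue
        padded = np.concatenate([np.full(2, b"N"), arr, np.full(2, b"N")])
        # plus strand: C at i (0-based); downstream = i+1, i+2
        plus_idx = np.nonzero(arr == b"C")[0]
        p1 = padded[plus_idx + 3]
        p2 = padded[plus_idx + 4]
        plus_ctx = _classify_vec(p1, p2)
        plus_tri = _tri_vec(arr[plus_idx], p1, p2)
        # minus strand: G at i is a C on -; downstream = complement of i-1, i-2
        minus_idx = np.nonzero(arr == b"G")[0]
        m1 = _comp_vec(padded[minus_idx + 1])
        m2 = _comp_vec(padded[minus_idx + 0])
        minus_ctx = _classify_vec(m1, m2)
        minus_tri = _tri_vec(np.full(len(minus_idx), b"C"), m1, m2)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": np.concatenate([plus_idx, minus_idx]) + 1,
                    "strand": np.repeat(["+", "-"], [len(plus_idx), len(minus_idx)]),
                    "context": np.concatenate([plus_ctx, minus_ctx]),
                    "trinucleotide": np.concatenate([plus_tri, minus_tri]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    return out


def _comp_vec(b: np.ndarray) -> np.ndarray:
    out = np.full_like(b, b"N")
    out[b == b"A"] = b"T"
    out[b == b"T"] = b"A"
    out[b == b"C"] = b"G"
    out[b == b"G"] = b"C"
    return out


def _classify_vec(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Vectorized version of _classify for downstream base arrays."""
    out = np.full(len(b1), "NA", dtype="U3")
    is_g1 = b1 == b"G"
    out[is_g1] = "CG"
    h1 = (b1 == b"A") | (b1 == b"C") | (b1 == b"T")
    out[h1 & (b2 == b"G")] = "CHG"
    h2 = (b2 == b"A") | (b2 == b"C") | (b2 == b"T")
    out[h1 & h2] = "CHH"
    return out


def _tri_vec(b0: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    return np.char.add(np.char.add(b0.astype("U1"), b1.astype("U1")), b2.astype("U1"))


# ---------------------------------------------------------------------------
# Promoters and region assignment
# ---------------------------------------------------------------------------

def promoter_of(gene: GeneModel, spec: RegionSpec, chrom_length: int) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clamped to the chromosome."""
    if gene.strand == "+":
        lo, hi = gene.tss - spec.promoter_up, gene.tss + spec.promoter_down
    else:
        lo, hi = gene.tss - spec.promoter_down, gene.tss + spec.promoter_up
    return (max(1, lo), min(chrom_length, hi))


class RegionIndex:
    """Per-chromosome painted label arrays for O(1) region lookup.

    Labels are painted in reverse precedence order so that the highest-priority
    membership wins; the result is independent of gene-list order.
    """

    def __init__(self, genes: Sequence[GeneModel], spec: RegionSpec, chrom_lengths: dict[str, int]):
        self.spec = spec
        self.chrom_lengths = dict(chrom_lengths)
        self._codes: dict[str, np.ndarray] = {
            chrom: np.full(length, _LABEL_PRIORITY["intergenic"], dtype=np.uint8)
            for chrom, length in chrom_lengths.items()
        }
        for label in reversed(REGION_LABELS[:-1]):  # paint lowest priority first
            code = _LABEL_PRIORITY[label]
            for g in genes:
                arr = self._codes.get(g.chrom)
                if arr is None:
                    continue
                for s, e in self._label_intervals(g, label, len(arr)):
                    if s <= e:
                        arr[s - 1 : e] = code

    def _label_intervals(self, g: GeneModel, label: str, chrom_len: int):
        spec = self.spec
        if label == "exon":
            return [(max(1, s), min(chrom_len, e)) for s, e in g.exons]
        if label == "5UTR":
            return [(max(1, s), min(chrom_len, e)) for s, e in g.five_utr]
        if label == "3UTR":
            return [(max(1, s), min(chrom_len, e)) for s, e in g.three_utr]
        if label == "intron":
            return [(max(1, g.start), min(chrom_len, g.end))]  # overpainted by exon/UTR
        if label == "upstream2k":
            if g.strand == "+":
                iv = (g.tss - spec.upstream_flank, g.tss - 1)
            else:
                iv = (g.tss + 1, g.tss + spec.upstream_flank)
            return [(max(1, iv[0]), min(chrom_len, iv[1]))]
        if label == "downstream2k":
            if g.strand == "+":
                iv = (g.tes + 1, g.tes + spec.downstream_flank)
            else:
                iv = (g.tes - spec.downstream_flank, g.tes - 1)
            return [(max(1, iv[0]), min(chrom_len, iv[1]))]
        raise ValueError(label)

    def label(self, chrom: str, pos: int) -> str:
        arr = self._codes[chrom]
        if not (1 <= pos <= len(arr)):
            raise ValueError(f"position {chrom}:{pos} out of bounds")
        return REGION_LABELS[arr[pos - 1]]

    def labels(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        arr = self._codes[chrom]
        return np.asarray(REGION_LABELS, dtype=object)[arr[np.asarray(positions) - 1]]

    # intron painting above paints the whole gene span then lets exon/UTR
    # overpaint; but upstream/downstream of ANOTHER gene must not overpaint a
    # gene body.  Precedence ordering of the paint loop guarantees this because
    # intron is painted after the flank labels.


def assign_region(genes: Sequence[GeneModel], spec: RegionSpec, chrom: str, pos: int,
                  chrom_lengths: dict[str, int] | None = None) -> str:
    """Single deterministic region label for one position (convenience wrapper)."""
    if chrom_lengths is None:
        end = max([pos] + [g.end + spec.downstream_flank for g in genes if g.chrom == chrom])
        chrom_lengths = {chrom: end}
    idx = RegionIndex([g for g in genes if g.chrom == chrom], spec, {chrom: chrom_lengths[chrom]})
    return idx.label(chrom, pos)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/five_prime_UTR/three_prime_UTR).

    The first mRNA of each gene (by start coordinate, then ID) is used.
    Genes lacking UTR features get empty UTR lists.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        mrnas = sorted(db.children(g, featuretype="mRNA"), key=lambda m: (m.start, m.id))
        parent = mrnas[0] if mrnas else g
        exons = [(e.start, e.end) for e in db.children(parent, featuretype="exon")]
        futr = [(e.start, e.end) for e in db.children(parent, featuretype="five_prime_UTR")]
        tutr = [(e.start, e.end) for e in db.children(parent, featuretype="three_prime_UTR")]
        if not exons:
            exons = [(g.start, g.end)]
        strand = g.strand if g.strand in "+-" else "+"
        tss, tes = (g.start, g.end) if strand == "+" else (g.end, g.start)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=strand,
                tss=tss,
                tes=tes,
                exons=sorted(exons),
                five_utr=sorted(futr),
                three_utr=sorted(tutr),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], path, source: str = "rddmscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            s, e = g.start, g.end
            fh.write(f"{g.chrom}\t{source}\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\t{source}\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\t{source}\texon\t{es}\t{ee}\t.\t{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n")
            for i, (us, ue) in enumerate(g.five_utr, 1):
                fh.write(f"{g.chrom}\t{source}\tfive_prime_UTR\t{us}\t{ue}\t.\t{g.strand}\t.\tID={mid}.5utr{i};Parent={mid}\n")
            for i, (us, ue) in enumerate(g.three_utr, 1):
                fh.write(f"{g.chrom}\t{source}\tthree_prime_UTR\t{us}\t{ue}\t.\t{g.strand}\t.\tID={mid}.3utr{i};Parent={mid}\n")


def save_refmodel(path, genome: Genome, genes: Sequence[GeneModel], te: TeAnnotation, spec: RegionSpec) -> None:
    """Serialize the reference model (lengths, genes, TEs, window spec) to JSON."""
    obj = {
        "coordinate_system": "1-based inclusive",
        "chrom_lengths": genome.chrom_lengths(),
        "region_spec": {
            "upstream_flank": spec.upstream_flank,
            "downstream_flank": spec.downstream_flank,
            "promoter_up": spec.promoter_up,
            "promoter_down": spec.promoter_down,
            "tss_window": spec.tss_window,
            "tss_region_definition": "tss +/- tss_window (no field-standard definition; explicit here)",
        },
        "genes": [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "tes": g.tes,
                "exons": g.exons,
                "five_utr": g.five_utr,
                "three_utr": g.three_utr,
            }
            for g in genes
        ],
        "te_intervals": te.intervals,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_refmodel(path) -> tuple[dict[str, int], list[GeneModel], TeAnnotation, RegionSpec]:
    with open(path) as fh:
        obj = json.load(fh)
    rs = obj["region_spec"]
    spec = RegionSpec(
        upstream_flank=rs["upstream_flank"],
        downstream_flank=rs["downstream_flank"],
        promoter_up=rs["promoter_up"],
        promoter_down=rs["promoter_down"],
        tss_window=rs["tss_window"],
    )
    genes = [
        GeneModel(
            gene_id=g["gene_id"],
            chrom=g["chrom"],
            strand=g["strand"],
            tss=g["tss"],
            tes=g["tes"],
            exons=[tuple(iv) for iv in g["exons"]],
            five_utr=[tuple(iv) for iv in g["five_utr"]],
            three_utr=[tuple(iv) for iv in g["three_utr"]],
        )
        for g in obj["genes"]
    ]
    te = TeAnnotation([(c, int(s), int(e)) for c, s, e in obj["te_intervals"]])
    return obj["chrom_lengths"], genes, te, spec
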