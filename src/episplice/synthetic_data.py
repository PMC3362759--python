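"""Synthetic genome, gene models, methylome and read tracks with planted truth.

The generator emulates the statistical structure of the real study
inputs: multi-isoform coding genes each realising exactly one AS event
type on an internal exon, 147-bp exons (the typical exon length),
terminal exons long enough (>= 2100 bp) that internal exons survive the
2000-bp TSS/PolyA filter, CpG sites with region-dependent methylation
rates, and ChIP-like read tracks whose Poisson rate is multiplied by a
per-feature, per-event-type factor inside +/-500 bp windows around the
planted splice sites. Strands alternate gene by gene. Every planted
event and effect is recorded in the truth tables; all outputs are a pure
function of the configuration and its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transcript_model import Gene, GenomeInterval, Transcript, write_gtf

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_genes",
    "generate_reads",
    "generate_methylome",
    "write_fixture",
    "reads_to_bed",
    "methylome_to_tsv",
    "genome_to_fasta",
]

CHROM = "chrSIM"
ASE_TYPES = ("ES", "ME", "A3SS", "A5SS", "IR")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic fixture.

    ``effects`` maps feature name -> {event type -> read-rate multiplier}
    (1.0 = null); ``methyl_effects`` maps event type -> {side ->
    methylation probability} overriding ``p_methyl_base`` inside the
    corresponding 100-bp splice-site bins.
    """

    seed: int = 0
    n_per_type: int = 10  # genes per AS event type
    n_cne_genes: int = 10
    n_near_tss_genes: int = 0  # ES-like genes planted 1500 bp from the TSS
    exon_length: int = 147
    intron_length: int = 1000
    terminal_exon_length: int = 2100
    alt_shift: int = 40  # A3SS/A5SS alternative-boundary offset
    gene_gap: int = 500
    n_cell_lines: int = 2
    read_rate: float = 0.2  # Poisson read starts per bp (lambda)
    read_length: int = 36  # pre-extension alignment length
    effect_window: int = 500  # +/- bp around planted ASE splice sites
    bin_length: int = 100  # methylation-effect bin size
    effects: dict = field(default_factory=dict)
    p_methyl_base: float = 0.6
    methyl_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.read_rate <= 0:
            raise ValueError("read_rate must be > 0")
        if min(self.exon_length, self.intron_length, self.terminal_exon_length) < 1:
            raise ValueError("lengths must be >= 1")
        if self.alt_shift >= self.exon_length:
            raise ValueError("alt_shift must leave a non-empty alternative exon")
        if self.intron_length <= self.alt_shift:
            raise ValueError("intron too short for alternative boundaries")
        if self.terminal_exon_length + self.intron_length <= 2000 and (
            self.n_per_type or self.n_cne_genes
        ):
            # internal exons must clear the TSS/PolyA filter
            raise ValueError("terminal exon + intron must exceed the 2000-bp filter window")
        for feature, per_type in self.effects.items():
            for etype, m in per_type.items():
                if etype not in ASE_TYPES:
                    raise ValueError(f"unknown event type {etype!r} for {feature}")
                if m <= 0:
                    raise ValueError("effect multipliers must be > 0")


@dataclass
class TruthTable:
    """Planted ground truth: one row per gene and per splice site, plus
    the expected test direction per (feature, event type)."""

    genes: pd.DataFrame  # gene_id, event_type, strand
    sites: pd.DataFrame  # gene_id, event_type, kind, pos, strand
    effects: pd.DataFrame  # feature, event_type, multiplier, direction


def _direction(multiplier: float) -> str:
    if multiplier > 1:
        return "higher_in_ASE"
    if multiplier < 1:
        return "higher_in_CNE"
    return "null"


def _exon_sites(start: int, end: int, strand: str) -> list[tuple[str, int]]:
    if strand == "+":
        return [("acceptor", start), ("donor", end)]
    return [("acceptor", end), ("donor", start)]


def _build_gene(cfg: SimulationConfig, kind: str, gene_id: str, offset: int, strand: str):
    """Exon layouts for one gene; returns (gene, site rows, next offset)."""
    Lt, Le, Li = cfg.terminal_exon_length, cfg.exon_length, cfg.intron_length
    sh = cfg.alt_shift

    def iv(s, e):
        return GenomeInterval(CHROM, offset + s, offset + e, strand)

    sites: list[tuple[str, int]] = []
    if kind in ("ES", "near_tss"):
        lt1 = 1300 if kind == "near_tss" else Lt
        li1 = 200 if kind == "near_tss" else Li
        # the near-TSS variant plants the event exon 1500 bp from the
        # transcript start so the positional filter must remove it
        f1 = iv(0, lt1)
        E = iv(lt1 + li1, lt1 + li1 + Le)
        f2 = iv(E.end - offset + Li, E.end - offset + Li + Lt)
        tA, tB = [f1, E, f2], [f1, f2]
        sites = _exon_sites(E.start, E.end, strand)
    elif kind == "ME":
        f1 = iv(0, Lt)
        E1 = iv(Lt + Li, Lt + Li + Le)
        E2 = iv(E1.end - offset + Li, E1.end - offset + Li + Le)
        f2 = iv(E2.end - offset + Li, E2.end - offset + Li + Lt)
        tA, tB = [f1, E1, f2], [f1, E2, f2]
        sites = _exon_sites(E1.start, E1.end, strand) + _exon_sites(E2.start, E2.end, strand)
    elif kind in ("A3SS", "A5SS"):
        f1 = iv(0, Lt)
        s, e = Lt + Li, Lt + Li + Le
        long_exon = iv(s, e)
        # the alternative boundary must sit on the acceptor side for A3SS
        # and the donor side for A5SS, in transcript orientation
        start_side_differs = (kind == "A3SS") == (strand == "+")
        short_exon = iv(s + sh, e) if start_side_differs else iv(s, e - sh)
        f2 = iv(e + Li, e + Li + Lt)
        tA, tB = [f1, long_exon, f2], [f1, short_exon, f2]
        sites = _exon_sites(long_exon.start, long_exon.end, strand)  # longer-exon rule
    elif kind == "IR":
        f1 = iv(0, Lt)
        A = iv(Lt + Li, Lt + Li + Le)
        B = iv(A.end - offset + Li, A.end - offset + Li + Le)
        f2 = iv(B.end - offset + Li, B.end - offset + Li + Lt)
        tA, tB = [f1, iv(A.start - offset, B.end - offset), f2], [f1, A, B, f2]
        # retained intron (A.end, B.start): donor at its 5', acceptor at its 3'
        if strand == "+":
            sites = [("donor", A.end), ("acceptor", B.start)]
        else:
            sites = [("donor", B.start), ("acceptor", A.end)]
    elif kind == "CNE":
        f1 = iv(0, Lt)
        E = iv(Lt + Li, Lt + Li + Le)
        f2 = iv(E.end - offset + Li, E.end - offset + Li + Lt)
        tA, tB = [f1, E, f2], [f1, E, f2]
        sites = _exon_sites(E.start, E.end, strand)
    else:
        raise ValueError(kind)

    transcripts = [
        Transcript(f"{gene_id}.tA", gene_id, strand, list(tA)),
        Transcript(f"{gene_id}.tB", gene_id, strand, list(tB)),
    ]
    gene = Gene(gene_id, CHROM, strand, transcripts)
    span_end = max(e.end for t in transcripts for e in t.exons)
    return gene, sites, span_end + cfg.gene_gap


def generate_genes(cfg: SimulationConfig):
    """Build the toy genome and gene models.

    Returns ``(genome, genes, truth)`` where ``genome`` maps chromosome
    name -> sequence. Gene order and strand alternation, coordinates and
    sequence are fully determined by the configuration seed.
    """
    rng = np.random.default_rng([cfg.seed, zlib.crc32(b"genes")])
    plan = [(etype, i) for etype in ASE_TYPES for i in range(cfg.n_per_type)]
    plan += [("CNE", i) for i in range(cfg.n_cne_genes)]
    plan += [("near_tss", i) for i in range(cfg.n_near_tss_genes)]

    genes, gene_rows, site_rows = [], [], []
    offset = cfg.gene_gap
    for idx, (kind, i) in enumerate(plan):
        strand = "+" if idx % 2 == 0 else "-"
        label = "ES" if kind == "near_tss" else kind
        gene_id = f"g{idx:05d}_{kind}"
        gene, sites, offset = _build_gene(cfg, kind, gene_id, offset, strand)
        genes.append(gene)
        gene_rows.append((gene_id, label, strand, kind == "near_tss"))
        for skind, pos in sites:
            site_rows.append((gene_id, label, skind, pos, strand))

    length = offset
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    genome = {CHROM: seq.tobytes().decode()}

    effect_rows = [
        (feature, etype, float(m), _direction(m))
        for feature, per_type in cfg.effects.items()
        for etype, m in per_type.items()
    ]
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "event_type", "strand", "near_tss"]),
        sites=pd.DataFrame(site_rows, columns=["gene_id", "event_type", "kind", "pos", "strand"]),
        effects=pd.DataFrame(effect_rows, columns=["feature", "event_type", "multiplier", "direction"]),
    )
    return genome, genes, truth


def _rate_segments(cfg: SimulationConfig, truth: TruthTable, feature: str, length: int):
    """Piecewise-constant read rate: lambda * multiplier inside +/-window
    of planted-type splice sites (non-near-TSS genes), lambda elsewhere."""
    lam = cfg.read_rate
    per_type = cfg.effects.get(feature, {})
    windows: list[tuple[int, int, float]] = []
    analysed = set(truth.genes.loc[~truth.genes["near_tss"], "gene_id"])
    for _, row in truth.sites.iterrows():
        m = per_type.get(row["event_type"], 1.0)
        if m == 1.0 or row["gene_id"] not in analysed:
            continue
        lo = max(0, int(row["pos"]) - cfg.effect_window)
        hi = min(length, int(row["pos"]) + cfg.effect_window)
        windows.append((lo, hi, m))
    windows.sort()
    merged: list[list] = []
    for lo, hi, m in windows:
        if merged and lo <= merged[-1][1] and m == merged[-1][2]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi, m])
    bounds, rates, cur = [], [], 0
    for lo, hi, m in merged:
        if lo > cur:
            bounds.append((cur, lo))
            rates.append(lam)
        bounds.append((lo, hi))
        rates.append(lam * m)
        cur = hi
    if cur < length:
        bounds.append((cur, length))
        rates.append(lam)
    return np.array(bounds, dtype=np.int64), np.array(rates)


def generate_reads(
    cfg: SimulationConfig, truth: TruthTable, feature: str, cell_line: str, length: int
) -> pd.DataFrame:
    """Raw (pre-extension) alignments for one feature in one cell line.

    Read starts follow an exact piecewise-constant Poisson process;
    strands are Bernoulli(0.5). Returns BED6-shaped columns.
    """
    key = zlib.crc32(f"reads|{feature}|{cell_line}".encode())
    rng = np.random.default_rng([cfg.seed, key])
    bounds, rates = _rate_segments(cfg, truth, feature, length)
    seg_len = bounds[:, 1] - bounds[:, 0]
    counts = rng.poisson(rates * seg_len)
    total = int(counts.sum())
    starts = np.concatenate(
        [
            bounds[i, 0] + np.floor(rng.random(c) * seg_len[i]).astype(np.int64)
            for i, c in enumerate(counts)
            if c > 0
        ]
    ) if total else np.empty(0, dtype=np.int64)
    starts.sort()
    strands = np.where(rng.random(total) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": CHROM,
            "start": starts,
            "end": starts + cfg.read_length,
            "name": feature,
            "score": 0,
            "strand": strands,
        }
    )


def _methyl_windows(cfg: SimulationConfig, truth: TruthTable):
    """(start, end, p) bins where the methylation probability differs."""
    out = []
    analysed = set(truth.genes.loc[~truth.genes["near_tss"], "gene_id"])
    for _, row in truth.sites.iterrows():
        per_side = cfg.methyl_effects.get(row["event_type"])
        if not per_side or row["gene_id"] not in analysed:
            continue
        pos, L = int(row["pos"]), cfg.bin_length
        left, right = (pos - L, pos), (pos, pos + L)
        if (row["kind"] == "acceptor") == (row["strand"] == "+"):
            intronic, exonic = left, right
        else:
            exonic, intronic = left, right
        for side, (lo, hi) in (("exonic", exonic), ("intronic", intronic)):
            if side in per_side:
                out.append((lo, hi, float(per_side[side])))
    return out


def generate_methylome(cfg: SimulationConfig, truth: TruthTable, genome: dict[str, str]) -> pd.DataFrame:
    """Both-strand methylation calls for every genomic CpG.

    Each CpG is one functional site emitted as a + and a - strand call
    with a shared Bernoulli state: probability ``p_methyl_base``, or the
    per-type override inside planted splice-site bins.
    """
    rng = np.random.default_rng([cfg.seed, zlib.crc32(b"methylome")])
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        cpg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        p = np.full(len(cpg), cfg.p_methyl_base)
        for lo, hi, pv in _methyl_windows(cfg, truth):
            p[(cpg >= lo) & (cpg < hi)] = pv
        meth = (rng.random(len(cpg)) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.repeat(cpg, 2),
                    "strand": np.tile(["+", "-"], len(cpg)),
                    "methylated": np.repeat(meth, 2),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "methylated"]
    )


# ---------------------------------------------------------------------------
# file emission (plain-text fixtures)


def genome_to_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reads_to_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


def methylome_to_tsv(methylome: pd.DataFrame, path) -> None:
    methylome.to_csv(path, sep="\t", header=False, index=False)


def write_fixture(cfg: SimulationConfig, outdir, features: tuple[str, ...] | None = None,
                  cell_lines: tuple[str, ...] | None = None) -> dict:
    """Emit the complete fixture directory (FASTA, GTF, BEDs, TSVs, truth).

    Returns the path manifest. Deterministic: identical configurations
    produce byte-identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genes(cfg)
    length = len(genome[CHROM])
    manifest = {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "genes.gtf"),
        "methylation": str(outdir / "methylation.tsv"),
        "truth_genes": str(outdir / "truth_genes.tsv"),
        "truth_sites": str(outdir / "truth_sites.tsv"),
        "truth_effects": str(outdir / "truth_effects.tsv"),
        "tracks": {},
    }
    genome_to_fasta(genome, manifest["genome"])
    write_gtf(genes, manifest["gtf"])
    methylome_to_tsv(generate_methylome(cfg, truth, genome), manifest["methylation"])
    truth.genes.to_csv(manifest["truth_genes"], sep="\t", index=False)
    truth.sites.to_csv(manifest["truth_sites"], sep="\t", index=False)
    truth.effects.to_csv(manifest["truth_effects"], sep="\t", index=False)
    features = features if features is not None else tuple(cfg.effects)
    cell_lines = cell_lines if cell_lines is not None else tuple(
        f"cell{i + 1}" for i in range(cfg.n_cell_lines)
    )
    for feature in features:
        manifest["tracks"][feature] = {}
        for line in cell_lines:
            p = outdir / f"reads_{feature}_{line}.bed"
            reads_to_bed(generate_reads(cfg, truth, feature, line, length), p)
            manifest["tracks"][feature][line] = str(p)
    return manifest
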