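"""Signal tracks: genome CpG, strand-combined methylation, extended reads.

Three track kinds share one query surface:

* ``region_level(chrom, start, end)`` — the per-region statistic used for
  the 100-bp splice-site bins (CpG count, percent methylated CpG, or
  overlapping-read count); ``None`` marks an undefined value (a
  methylation percentage over a region with no CpG sites).
* ``position_values(chrom, start, end)`` — one value per bp for
  metaprofiles (read coverage, or 0/1 CpG and methylated-CpG indicators).

All coordinates are 0-based half-open. Overlap means >= 1 bp
intersection. Queries are pure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethylCall",
    "SequenceCpGTrack",
    "MethylationTrack",
    "ReadTrack",
    "count_cpg",
    "read_methylation",
    "methylation_percentage",
    "load_reads",
    "region_read_count",
    "position_coverage",
]

DEFAULT_EXTENSION = 200


@dataclass(frozen=True)
class MethylCall:
    """A strand-combined CpG methylation call (+-strand C coordinate)."""

    chrom: str
    pos: int
    methylated: bool


class SequenceCpGTrack:
    """CpG dinucleotides counted directly from genome sequence.

    ``sequences`` maps chromosome name to its sequence string (as loaded
    from FASTA by e.g. pyfaidx or Bio.SeqIO). Counting is
    case-insensitive; N bases never match.
    """

    kind = "sequence_cpg"

    def __init__(self, sequences: dict[str, str], label: str = "CG"):
        self.label = label
        self._seq = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path, label: str = "CG") -> "SequenceCpGTrack":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, label=label)

    def _bounds(self, chrom: str, start: int, end: int) -> str:
        seq = self._seq.get(chrom)
        if seq is None or start < 0 or end > len(seq) or start >= end:
            raise IndexError(f"region {chrom}:{start}-{end} outside sequence")
        return seq

    def region_level(self, chrom: str, start: int, end: int) -> float:
        """Number of CpG dinucleotides fully inside [start, end)."""
        seq = self._bounds(chrom, start, end)
        # CG cannot overlap itself, so non-overlapping count is exact
        return float(seq.count("CG", start, end))

    def position_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp indicator: 1 where a CpG starts at that position."""
        seq = self._bounds(chrom, start, end)
        out = np.zeros(end - start, dtype=float)
        i = seq.find("CG", start, end + 1)
        while 0 <= i < end:
            out[i - start] = 1.0
            i = seq.find("CG", i + 1, end + 1)
        return out

    def cpg_sites(self, chrom: str) -> np.ndarray:
        """Sorted coordinates of every CpG (C position) on a chromosome."""
        seq = self._seq[chrom]
        pos, i = [], seq.find("CG")
        while i >= 0:
            pos.append(i)
            i = seq.find("CG", i + 1)
        return np.asarray(pos, dtype=np.int64)


class MethylationTrack:
    """Strand-combined CpG methylation calls with percentage queries.

    Sense and antisense calls of one CpG are one functional site; a site
    is methylated when any merged strand call is methylated.
    """

    kind = "methylation"

    def __init__(self, calls: list[MethylCall], label: str = "mCG"):
        self.label = label
        by_chrom: dict[str, dict[int, bool]] = {}
        for c in calls:
            d = by_chrom.setdefault(c.chrom, {})
            if c.pos in d and d[c.pos] != c.methylated:
                logger.debug("conflicting calls at %s:%d; methylated wins", c.chrom, c.pos)
            d[c.pos] = d.get(c.pos, False) or c.methylated
        self._pos: dict[str, np.ndarray] = {}
        self._meth: dict[str, np.ndarray] = {}
        for chrom, d in by_chrom.items():
            pos = np.array(sorted(d), dtype=np.int64)
            self._pos[chrom] = pos
            self._meth[chrom] = np.array([d[p] for p in pos], dtype=bool)

    def site_count(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def region_stats(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """(n_sites, n_methylated) within [start, end)."""
        pos = self._pos.get(chrom)
        if pos is None:
            return 0, 0
        lo, hi = np.searchsorted(pos, (start, end))
        return int(hi - lo), int(self._meth[chrom][lo:hi].sum())

    def region_level(self, chrom: str, start: int, end: int) -> float | None:
        """Percent methylated CpG sites, or None when the region has none."""
        n, m = self.region_stats(chrom, start, end)
        if n == 0:
            return None
        return 100.0 * m / n

    def position_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp indicator: 1 where a methylated CpG site sits."""
        out = np.zeros(end - start, dtype=float)
        pos = self._pos.get(chrom)
        if pos is None:
            return out
        lo, hi = np.searchsorted(pos, (start, end))
        sel = pos[lo:hi][self._meth[chrom][lo:hi]]
        out[sel - start] = 1.0
        return out


class ReadTrack:
    """Strand-extended sequencing-read intervals with overlap queries."""

    kind = "reads"

    def __init__(self, intervals: pd.DataFrame, label: str = "reads"):
        """``intervals``: columns chrom/start/end of already-extended reads."""
        self.label = label
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, sub in intervals.groupby("chrom", sort=False):
            self._starts[str(chrom)] = np.sort(sub["start"].to_numpy(np.int64))
            self._ends[str(chrom)] = np.sort(sub["end"].to_numpy(np.int64))

    def n_reads(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._starts.get(chrom, ()))
        return sum(len(v) for v in self._starts.values())

    def region_level(self, chrom: str, start: int, end: int) -> float:
        """Number of extended reads overlapping [start, end) by >= 1 bp."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0
        ends = self._ends[chrom]
        n = len(starts)
        before = np.searchsorted(ends, start, side="right")  # end <= start
        after = n - np.searchsorted(starts, end, side="left")  # start >= end
        return float(n - before - after)

    def region_levels(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`region_level` over parallel bin arrays."""
        s = self._starts.get(chrom)
        if s is None:
            return np.zeros(len(starts), dtype=float)
        e = self._ends[chrom]
        n = len(s)
        before = np.searchsorted(e, starts, side="right")
        after = n - np.searchsorted(s, ends, side="left")
        return (n - before - after).astype(float)

    def position_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Coverage: reads overlapping each bp of [start, end)."""
        starts = self._starts.get(chrom)
        out_pos = np.arange(start, end, dtype=np.int64)
        if starts is None:
            return np.zeros(end - start, dtype=float)
        ends = self._ends[chrom]
        n_started = np.searchsorted(starts, out_pos, side="right")
        n_ended = np.searchsorted(ends, out_pos, side="right")
        return (n_started - n_ended).astype(float)


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-level API


def count_cpg(track: SequenceCpGTrack, chrom: str, start: int, end: int) -> int:
    return int(track.region_level(chrom, start, end))


def read_methylation(path, label: str = "mCG") -> MethylationTrack:
    """Load the methylation TSV dialect and merge both-strand calls.

    Columns: chrom, pos (0-based, +-strand C of the CpG for either strand
    call), strand_of_call {+,-}, methylated {0,1}. Malformed rows are
    skipped with a warning.
    """
    calls: list[MethylCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                chrom, pos, strand, meth = parts[0], int(parts[1]), parts[2], parts[3]
                if strand not in ("+", "-") or meth not in ("0", "1"):
                    raise ValueError(line)
            except (ValueError, IndexError):
                logger.warning("%s:%d: malformed methylation row skipped", path, lineno)
                continue
            calls.append(MethylCall(chrom, pos, meth == "1"))
    return MethylationTrack(calls, label=label)


def methylation_percentage(
    track: MethylationTrack, chrom: str, start: int, end: int
) -> tuple[float | None, int]:
    """(percent methylated or None, number of CpG sites) in the region."""
    n, m = track.region_stats(chrom, start, end)
    return (None if n == 0 else 100.0 * m / n), n


def load_reads(path, extension: int = DEFAULT_EXTENSION, label: str = "reads") -> ReadTrack:
    """Load BED6 alignments and extend each to ``extension`` bp 3'-ward.

    + reads become [start, start+ext), - reads [end-ext, end); extensions
    running past the chromosome start are clamped at 0 (logged). Rows
    without a +/- strand are skipped. Identical reads are kept (raw-read
    counting, no deduplication).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": [], "start": [], "end": [], "strand": []})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        logger.warning("%s: %d reads without strand skipped", path, int(bad.sum()))
        df = df[~bad]
    return ReadTrack(extend_reads(df, extension), label=label)


def extend_reads(df: pd.DataFrame, extension: int = DEFAULT_EXTENSION) -> pd.DataFrame:
    """Apply the strand-aware fixed-length extension to raw alignments."""
    plus = df["strand"] == "+"
    start = np.where(plus, df["start"], df["end"] - extension)
    end = np.where(plus, df["start"] + extension, df["end"])
    clamped = start < 0
    if clamped.any():
        logger.debug("%d reads clamped at chromosome start", int(clamped.sum()))
        start = np.maximum(start, 0)
    return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "start": start, "end": end})


def region_read_count(track: ReadTrack, chrom: str, start: int, end: int) -> int:
    return int(track.region_level(chrom, start, end))


def position_coverage(track: ReadTrack, chrom: str, start: int, end: int) -> np.ndarray:
    return track.position_values(chrom, start, end).astype(np.int64)
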