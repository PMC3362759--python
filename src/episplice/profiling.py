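"""Splice-site bins, per-region signal levels, and positional metaprofiles.

Each analysed splice site contributes two 100-bp bins, one exonic and one
intronic, anchored at the exon/intron boundary and oriented by transcript
strand; an acceptor/donor pair therefore spans four bins. Signal levels
per bin are collected as one independent observation per
(splice site, bin, feature, cell line) and pooled across cell lines by
the downstream tests.

Metaprofiles average signal per nucleotide position over all splice
sites of an event class, on the window -500..+200 around acceptors and
-200..+500 around donors (transcript orientation; offset 0 is the first
exonic base at an acceptor and the first intronic base at a donor, so
positive acceptor offsets and negative donor offsets are exonic). CpG
and methylated-CpG profiles are percentages and are smoothed with a
147-bp sliding window; read profiles are raw coverage means, never
smoothed (reads are pre-extended to 200 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .as_annotation import ASEvent, SpliceSite
from .signal_io import MethylationTrack

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_IDS",
    "RegionBin",
    "PositionProfile",
    "make_bins",
    "collect_levels",
    "position_profile",
    "smooth_profile",
    "stratify_by_ordinal",
    "ACCEPTOR_OFFSETS",
    "DONOR_OFFSETS",
]

BIN_IDS = ("acceptor_intronic", "acceptor_exonic", "donor_exonic", "donor_intronic")

# metaprofile windows (inclusive offsets, transcript orientation)
ACCEPTOR_OFFSETS = (-500, 200)
DONOR_OFFSETS = (-200, 500)

DEFAULT_BIN_LENGTH = 100
DEFAULT_SMOOTH_WINDOW = 147


@dataclass(frozen=True)
class RegionBin:
    site_kind: str  # acceptor | donor
    side: str  # exonic | intronic
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def bin_id(self) -> str:
        return f"{self.site_kind}_{self.side}"


def make_bins(site: SpliceSite, chrom: str, bin_length: int = DEFAULT_BIN_LENGTH) -> list[RegionBin]:
    """The exonic and intronic bin flanking one splice site.

    For a +-strand acceptor at ``a``: intronic [a-L, a), exonic [a, a+L);
    for a +-strand donor at ``d``: exonic [d-L, d), intronic [d, d+L).
    The minus strand mirrors both. ``bin_length`` 50 reproduces the
    +/-50 nt robustness variant.
    """
    if bin_length < 1:
        raise ValueError("bin_length must be >= 1")
    p, L = site.pos, bin_length
    left = (p - L, p)
    right = (p, p + L)
    if (site.kind == "acceptor") == (site.strand == "+"):
        intronic, exonic = left, right
    else:
        exonic, intronic = left, right
    return [
        RegionBin(site.kind, "intronic", chrom, *intronic, site.strand),
        RegionBin(site.kind, "exonic", chrom, *exonic, site.strand),
    ]


def collect_levels(
    events: list[ASEvent],
    tracks: dict[str, dict[str, object]],
    bin_length: int = DEFAULT_BIN_LENGTH,
) -> pd.DataFrame:
    """Per-bin signal levels for every event splice site.

    ``tracks`` maps feature name -> {cell_line -> SignalTrack}. Returns a
    long table with one row per (splice site, bin, feature, cell line);
    undefined methylation percentages (bins without CpG sites) appear
    with ``missing=True`` and are excluded from downstream tests.
    """
    if not tracks or any(not lines for lines in tracks.values()):
        raise ValueError("every feature needs at least one cell-line track")
    rows = []
    for e in events:
        for s_idx, site in enumerate(e.splice_sites):
            for b in make_bins(site, e.chrom, bin_length):
                for feature, lines in tracks.items():
                    for cell_line, track in lines.items():
                        value = track.region_level(e.chrom, b.start, b.end)
                        rows.append(
                            (
                                e.event_id,
                                e.event_type,
                                s_idx,
                                b.bin_id,
                                feature,
                                cell_line,
                                np.nan if value is None else value,
                                value is None,
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "event_type",
            "site_index",
            "bin",
            "feature",
            "cell_line",
            "value",
            "missing",
        ],
    )


@dataclass
class PositionProfile:
    feature: str
    event_type: str
    site_kind: str
    offsets: np.ndarray  # inclusive, transcript orientation
    values: np.ndarray  # mean level per offset
    n_sites: int


def _site_window_values(track, chrom: str, pos: int, strand: str, site_kind: str) -> np.ndarray:
    """Per-offset track values around one splice site, oriented 5'->3'."""
    lo, hi = ACCEPTOR_OFFSETS if site_kind == "acceptor" else DONOR_OFFSETS
    if strand == "+":
        # offset o -> genomic pos + o (offset 0 = boundary's right bp)
        vals = track.position_values(chrom, pos + lo, pos + hi + 1)
    else:
        # offset o -> genomic pos - 1 - o (mirror of the + convention)
        vals = track.position_values(chrom, pos - 1 - hi, pos - lo)[::-1]
    return vals


def position_profile(
    events: list[ASEvent],
    tracks_by_line: dict[str, object],
    site_kind: str,
    feature: str = "",
    event_type: str | None = None,
) -> PositionProfile:
    """Mean per-position signal across all sites of one event class.

    ``tracks_by_line`` maps cell line -> SignalTrack; per-line profiles
    are averaged with equal weight. CpG/methylation tracks yield
    percentages (indicator mean x 100); read tracks yield mean coverage.
    """
    sites = [
        (e.chrom, s.pos, e.strand)
        for e in events
        if event_type is None or e.event_type == event_type
        for s in e.splice_sites
        if s.kind == site_kind
    ]
    if not sites:
        raise ValueError(f"no {site_kind} sites for event type {event_type}")
    lo, hi = ACCEPTOR_OFFSETS if site_kind == "acceptor" else DONOR_OFFSETS
    offsets = np.arange(lo, hi + 1)
    per_line = []
    for track in tracks_by_line.values():
        acc = np.zeros(len(offsets))
        for chrom, pos, strand in sites:
            acc += _site_window_values(track, chrom, pos, strand, site_kind)
        mean = acc / len(sites)
        if getattr(track, "kind", "reads") in ("sequence_cpg", "methylation"):
            mean = mean * 100.0  # indicator mean -> percent of sites
        per_line.append(mean)
    values = np.mean(per_line, axis=0)
    etype = event_type if event_type is not None else (events[0].event_type if events else "")
    return PositionProfile(feature, etype, site_kind, offsets, values, len(sites))


def smooth_profile(p: PositionProfile, window: int = DEFAULT_SMOOTH_WINDOW) -> PositionProfile:
    """Centred moving average; edges use the truncated available window.

    Intended for CpG/methylated-CpG profiles only; read profiles are
    published unsmoothed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        raise ValueError("window must be odd (centred)")
    if window > len(p.values):
        raise ValueError("window exceeds profile length")
    half = window // 2
    n = len(p.values)
    csum = np.concatenate([[0.0], np.cumsum(p.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return PositionProfile(p.feature, p.event_type, p.site_kind, p.offsets.copy(), smoothed, p.n_sites)


def stratify_by_ordinal(events: list[ASEvent], ordinals: set[int]) -> dict[int, list[ASEvent]]:
    """Partition events by the exon ordinal of their defining exon.

    Used for the positional-control analysis restricted to 2nd-4th exons;
    events with ordinals outside ``ordinals`` are excluded, empty strata
    are dropped with a log message.
    """
    strata: dict[int, list[ASEvent]] = {o: [] for o in sorted(ordinals)}
    for e in events:
        if e.exon_ordinal in strata:
            strata[e.exon_ordinal].append(e)
    for o in list(strata):
        if not strata[o]:
            logger.info("ordinal stratum %d empty; skipped", o)
            del strata[o]
    return strata


def profile_to_frame(p: PositionProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": p.feature,
            "event_type": p.event_type,
            "site_kind": p.site_kind,
            "offset": p.offsets,
            "value": p.values,
            "n_sites": p.n_sites,
        }
    )
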