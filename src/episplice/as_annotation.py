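"""Alternative-splicing event classification from transcript structure.

Events are recognised by comparing the exon-intron junction structure of
every pair of transcripts within a gene. Five event classes are emitted
(exon skipping ES, mutually exclusive exons ME, alternative 3'/5' splice
site A3SS/A5SS, intron retention IR) plus constitutive internal exons
(CNE) as the reference class. Only single-exon skipping is called ES;
cassette-exon super-classes and alternative first/last exons are out of
scope.

The geometric predicates below are the ground truth; the binary/decimal
junction coding (:func:`segment_gene`, :func:`encode_decimal`) is kept as
a bookkeeping representation of the same information.

Acceptor/donor labels follow transcript orientation: the acceptor is the
intron 3' splice site, the donor the intron 5' site, so genomic roles
flip on the minus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .transcript_model import Gene, GenomeInterval, Transcript, internal_exons

logger = logging.getLogger(__name__)

EVENT_TYPES = ("ES", "ME", "A3SS", "A5SS", "IR")
ALL_TYPES = EVENT_TYPES + ("CNE",)

__all__ = [
    "EVENT_TYPES",
    "ALL_TYPES",
    "Segmentation",
    "SpliceSite",
    "ASEvent",
    "segment_gene",
    "encode_decimal",
    "classify_pairwise",
    "annotate_gene",
    "filter_positional",
    "select_splice_sites",
    "events_to_tsv",
    "splice_sites_to_bed",
]


# ---------------------------------------------------------------------------
# binary / decimal junction coding


@dataclass
class Segmentation:
    """Segment-wise exon-inclusion coding of a gene's transcripts.

    ``boundaries`` is the sorted union of all exon starts/ends of all
    transcripts; consecutive boundaries delimit ``segments`` that tile the
    gene span. Each transcript maps to a bit-vector (1 = segment lies
    inside one of its exons); ``decimal_codes`` interprets the bits base-2
    with the most-significant bit at the transcript's 5' end.
    """

    boundaries: list[int]
    segments: list[tuple[int, int]]
    inclusion: dict[str, tuple[int, ...]]
    decimal_codes: dict[str, int]

    def reconstruct(self, transcript_id: str) -> list[tuple[int, int]]:
        """Recover a transcript's exon coordinates from its bit-vector."""
        bits = self.inclusion[transcript_id]
        exons: list[tuple[int, int]] = []
        for (s, e), b in zip(self.segments, bits):
            if not b:
                continue
            if exons and exons[-1][1] == s:
                exons[-1] = (exons[-1][0], e)
            else:
                exons.append((s, e))
        return exons


def encode_decimal(bits) -> int:
    """Base-2 interpretation of a bit-vector (MSB first)."""
    if len(bits) == 0:
        raise ValueError("empty bit-vector")
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


def segment_gene(g: Gene) -> Segmentation:
    """Tile the gene span at every exon boundary and code each transcript."""
    if not g.transcripts:
        raise ValueError(f"{g.gene_id}: no transcripts")
    boundaries = sorted(
        {c for t in g.transcripts for e in t.exons for c in (e.start, e.end)}
    )
    segments = list(zip(boundaries, boundaries[1:]))
    inclusion: dict[str, tuple[int, ...]] = {}
    codes: dict[str, int] = {}
    for t in g.transcripts:
        bits = tuple(
            int(any(e.start <= s and f <= e.end for e in t.exons))
            for s, f in segments
        )
        inclusion[t.transcript_id] = bits
        oriented = bits if t.strand == "+" else bits[::-1]
        codes[t.transcript_id] = encode_decimal(oriented) if oriented else 0
    return Segmentation(boundaries, segments, inclusion, codes)


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class SpliceSite:
    """One analysed splice site (a single exon/intron boundary coordinate)."""

    kind: str  # {"acceptor", "donor"}
    pos: int
    strand: str
    event_id: str = ""


@dataclass
class ASEvent:
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomeInterval, ...]
    evidence: tuple[str, str]
    exon_ordinal: int
    retained_intron: tuple[int, int] | None = None
    evidence_spans: tuple[GenomeInterval, ...] = ()
    event_id: str = ""
    splice_sites: list[SpliceSite] = field(default_factory=list)


def _exon_sites(exon: GenomeInterval, strand: str) -> tuple[int, int]:
    """(acceptor, donor) boundary coordinates of an exon, by strand."""
    if strand == "+":
        return exon.start, exon.end
    return exon.end, exon.start


def _ordinal(t: Transcript, exon: GenomeInterval) -> int:
    """1-based exon position in transcript orientation."""
    idx = t.exons.index(exon)
    return idx + 1 if t.strand == "+" else len(t.exons) - idx


def select_splice_sites(e: ASEvent) -> list[SpliceSite]:
    """Choose the analysed acceptor/donor sites of a classified event.

    ES/CNE use the event exon's own sites. A3SS/A5SS use the sites of the
    longer of the two alternative exons. IR anchors on the retained
    intron: the donor is its 5' boundary, the acceptor its 3' boundary.
    ME contributes the sites of both exons, counted independently.
    """
    strand = e.strand
    sites: list[SpliceSite] = []
    if e.event_type in ("ES", "CNE"):
        a, d = _exon_sites(e.exons[0], strand)
        sites = [SpliceSite("acceptor", a, strand, e.event_id),
                 SpliceSite("donor", d, strand, e.event_id)]
    elif e.event_type in ("A3SS", "A5SS"):
        e1, e2 = e.exons
        if len(e1) != len(e2):
            chosen = e1 if len(e1) > len(e2) else e2
        else:  # defensive: equal lengths cannot arise for distinct exons sharing a boundary
            logger.warning("%s: equal-length alternative exons; keeping 5'-most", e.event_id)
            chosen = min(e1, e2, key=lambda x: x.start if strand == "+" else -x.end)
        a, d = _exon_sites(chosen, strand)
        sites = [SpliceSite("acceptor", a, strand, e.event_id),
                 SpliceSite("donor", d, strand, e.event_id)]
    elif e.event_type == "IR":
        s, t = e.retained_intron  # genomic (start, end) of the retained intron
        donor, acceptor = (s, t) if strand == "+" else (t, s)
        sites = [SpliceSite("acceptor", acceptor, strand, e.event_id),
                 SpliceSite("donor", donor, strand, e.event_id)]
    elif e.event_type == "ME":
        for exon in e.exons:
            a, d = _exon_sites(exon, strand)
            sites.append(SpliceSite("acceptor", a, strand, e.event_id))
            sites.append(SpliceSite("donor", d, strand, e.event_id))
    else:
        raise ValueError(f"unknown event type {e.event_type}")
    return sites


def _flanks(t: Transcript, exon: GenomeInterval) -> tuple[int, int] | None:
    """(left flank end, right flank start) around an internal exon, genomic."""
    i = t.exons.index(exon)
    if i == 0 or i == len(t.exons) - 1:
        return None
    return t.exons[i - 1].end, t.exons[i + 1].start


def _classify_directed(tA: Transcript, tB: Transcript) -> list[ASEvent]:
    """Events defined by an internal exon of ``tA`` against ``tB``."""
    events: list[ASEvent] = []
    b_exons = set(tB.exons)
    b_internal = internal_exons(tB)
    spans = (tA.span, tB.span)

    def mk(etype, exons, ordinal_exon, retained=None):
        return ASEvent(
            event_type=etype,
            gene_id=tA.gene_id,
            chrom=tA.chrom,
            strand=tA.strand,
            exons=tuple(sorted(exons, key=lambda x: x.start)),
            evidence=(tA.transcript_id, tB.transcript_id),
            exon_ordinal=_ordinal(tA, ordinal_exon),
            retained_intron=retained,
            evidence_spans=spans,
        )

    for E in internal_exons(tA):
        u_w = _flanks(tA, E)
        assert u_w is not None
        u, w = u_w

        # ES: tB splices directly from the upstream flank donor to the
        # downstream flank acceptor and nothing in tB overlaps E
        if E not in b_exons:
            has_direct_junction = any(
                p.end == u and q.start == w
                for p, q in zip(tB.exons, tB.exons[1:])
            )
            if has_direct_junction and not any(x.overlaps(E) for x in tB.exons):
                events.append(mk("ES", (E,), E))

        # IR: E spans exactly two consecutive exons of tB plus their intron
        for p, q in zip(tB.exons, tB.exons[1:]):
            if p.start == E.start and q.end == E.end:
                events.append(mk("IR", (E,), E, retained=(p.end, q.start)))

        # A3SS / A5SS: overlapping internal exons sharing one boundary,
        # where the differing boundaries are alternative choices for the
        # same intron (the flanking junction on the differing side is
        # shared) — this keeps intron-retention configurations, whose
        # flanking junctions differ, out of the splice-site-choice classes
        for F in b_internal:
            if F == E or not F.overlaps(E):
                continue
            f_flanks = _flanks(tB, F)
            assert f_flanks is not None
            fu, fw = f_flanks
            if E.end == F.end and E.start != F.start and u == fu:
                # genomic start differs: acceptor side on +, donor side on -
                etype = "A3SS" if tA.strand == "+" else "A5SS"
                events.append(mk(etype, (E, F), E))
            elif E.start == F.start and E.end != F.end and w == fw:
                etype = "A5SS" if tA.strand == "+" else "A3SS"
                events.append(mk(etype, (E, F), E))

        # ME: internal exon of tB between the same flanking junctions,
        # mutually absent and non-overlapping
        if E not in b_exons:
            for F in b_internal:
                if F.overlaps(E) or F in set(tA.exons):
                    continue
                fw = _flanks(tB, F)
                if fw == (u, w):
                    events.append(mk("ME", (E, F), E))
    return events


def _site_key(e: ASEvent) -> tuple:
    sites = select_splice_sites(e)
    return (e.event_type, tuple(sorted((s.kind, s.pos) for s in sites)))


def classify_pairwise(tA: Transcript, tB: Transcript) -> list[ASEvent]:
    """Classify AS events between two transcripts of the same gene.

    The comparison is symmetric: internal exons of each transcript are
    tested against the other, and duplicate discoveries of the same event
    are merged by splice-site identity.
    """
    if tA.gene_id != tB.gene_id or tA.strand != tB.strand:
        raise ValueError("transcripts must share gene and strand")
    seen: dict[tuple, ASEvent] = {}
    for e in _classify_directed(tA, tB) + _classify_directed(tB, tA):
        seen.setdefault(_site_key(e), e)
    return list(seen.values())


def annotate_gene(g: Gene) -> list[ASEvent]:
    """All AS events of a gene plus its constitutive internal exons (CNE).

    Events are the union of pairwise classifications over all transcript
    pairs, de-duplicated by (event type, splice-site tuple). A CNE is an
    internal exon present with identical boundaries (and internal) in
    every transcript whose span covers it, and whose boundaries do not
    coincide with any detected AS event's splice sites.
    """
    transcripts = sorted(g.transcripts, key=lambda t: t.transcript_id)
    seen: dict[tuple, ASEvent] = {}
    for i, tA in enumerate(transcripts):
        for tB in transcripts[i + 1 :]:
            for e in classify_pairwise(tA, tB):
                seen.setdefault(_site_key(e), e)
    events = list(seen.values())

    ase_site_coords = {
        s.pos for e in events for s in select_splice_sites(e)
    }

    cne_seen: set[GenomeInterval] = set()
    for t in transcripts:
        for E in internal_exons(t):
            if E in cne_seen:
                continue
            constitutive = True
            for other in transcripts:
                sp = other.span
                if sp.start <= E.start and E.end <= sp.end:
                    if E not in other.exons or E in (other.exons[0], other.exons[-1]):
                        constitutive = False
                        break
            if not constitutive:
                continue
            if E.start in ase_site_coords or E.end in ase_site_coords:
                continue
            cne_seen.add(E)
            events.append(
                ASEvent(
                    event_type="CNE",
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    strand=g.strand,
                    exons=(E,),
                    evidence=(t.transcript_id, t.transcript_id),
                    exon_ordinal=_ordinal(t, E),
                    evidence_spans=(t.span,),
                )
            )

    # deterministic ids and attached analysed sites
    events.sort(key=lambda e: (_site_key(e)[1], e.event_type))
    out = []
    for i, e in enumerate(events):
        e = replace(e, event_id=f"{g.gene_id}:{e.event_type}:{i}")
        e.splice_sites = select_splice_sites(e)
        out.append(e)
    return out


def filter_positional(events: list[ASEvent], window: int = 2000) -> list[ASEvent]:
    """Drop events whose defining exon lies within ``window`` bp of either
    end of an evidence transcript's genomic span (TSS / terminal site)."""
    if window == 0:
        return list(events)
    kept = []
    for e in events:
        near_end = False
        for sp in e.evidence_spans:
            head = (sp.start, min(sp.end, sp.start + window))
            tail = (max(sp.start, sp.end - window), sp.end)
            for exon in e.exons:
                for s, t in (head, tail):
                    if s < t and exon.start < t and s < exon.end:
                        near_end = True
        if not near_end:
            kept.append(e)
        else:
            logger.debug("%s filtered: within %d bp of transcript end", e.event_id, window)
    return kept


# ---------------------------------------------------------------------------
# output


def events_to_tsv(events: list[ASEvent], path) -> None:
    cols = "event_id\tevent_type\tgene_id\tchrom\tstrand\tacceptor_pos\tdonor_pos\texon_ordinal\tevidence\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for e in events:
            accs = ",".join(str(s.pos) for s in e.splice_sites if s.kind == "acceptor")
            dons = ",".join(str(s.pos) for s in e.splice_sites if s.kind == "donor")
            fh.write(
                f"{e.event_id}\t{e.event_type}\t{e.gene_id}\t{e.chrom}\t{e.strand}\t"
                f"{accs}\t{dons}\t{e.exon_ordinal}\t{e.evidence[0]},{e.evidence[1]}\n"
            )


def splice_sites_to_bed(events: list[ASEvent], path) -> None:
    """BED6 of analysed splice sites, one row per site (1-bp intervals)."""
    with open(path, "w") as fh:
        for e in events:
            for s in e.splice_sites:
                fh.write(
                    f"{e.chrom}\t{s.pos}\t{s.pos + 1}\t{e.event_id}:{s.kind}\t0\t{e.strand}\n"
                )
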