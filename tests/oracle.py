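"""Independent brute-force oracles and random fixtures for the test suite.

Everything here is written from the event definitions directly, without
reusing any code path from the package under test: the classifier oracle
enumerates all exon pairs/triples with explicit index arithmetic, and
the signal oracles are naive per-element loops.
"""

from __future__ import annotations

import numpy as np

from episplice.transcript_model import Gene, GenomeInterval, Transcript

# ---------------------------------------------------------------------------
# brute-force AS classifier


def _ov(a, b):
    return a[0] < b[1] and b[0] < a[1]


def _exon_site_pair(exon, strand):
    """{(kind, pos)} for an exon's own acceptor and donor."""
    s, e = exon
    if strand == "+":
        return {("acceptor", s), ("donor", e)}
    return {("acceptor", e), ("donor", s)}


def _events_one_way(X, Y, strand):
    """Events keyed (type, frozenset sites) defined by X's internal exons vs Y."""
    out = set()
    xe = [(e.start, e.end) for e in X.exons]
    ye = [(e.start, e.end) for e in Y.exons]
    yset = set(ye)
    xset = set(xe)
    for i in range(1, len(xe) - 1):
        E = xe[i]
        up_end, down_start = xe[i - 1][1], xe[i + 1][0]
        # exon skipping: Y joins the flanks directly, nothing in Y touches E
        if E not in yset:
            for j in range(len(ye) - 1):
                if ye[j][1] == up_end and ye[j + 1][0] == down_start:
                    if all(not _ov(E, y) for y in ye):
                        out.add(("ES", frozenset(_exon_site_pair(E, strand))))
        # intron retention: E covers two consecutive Y exons and their intron
        for j in range(len(ye) - 1):
            if ye[j][0] == E[0] and ye[j + 1][1] == E[1]:
                intron = (ye[j][1], ye[j + 1][0])
                if strand == "+":
                    sites = {("donor", intron[0]), ("acceptor", intron[1])}
                else:
                    sites = {("donor", intron[1]), ("acceptor", intron[0])}
                out.add(("IR", frozenset(sites)))
        for j in range(1, len(ye) - 1):
            F = ye[j]
            # mutually exclusive: same flanking junctions, mutually absent
            if (
                not _ov(E, F)
                and E not in yset
                and F not in xset
                and ye[j - 1][1] == up_end
                and ye[j + 1][0] == down_start
            ):
                out.add(("ME", frozenset(_exon_site_pair(E, strand) | _exon_site_pair(F, strand))))
            # alternative splice-site choice for a shared intron
            if F != E and _ov(E, F):
                longer = E if E[1] - E[0] >= F[1] - F[0] else F
                if E[1] == F[1] and E[0] != F[0] and ye[j - 1][1] == up_end:
                    etype = "A3SS" if strand == "+" else "A5SS"
                    out.add((etype, frozenset(_exon_site_pair(longer, strand))))
                if E[0] == F[0] and E[1] != F[1] and ye[j + 1][0] == down_start:
                    etype = "A5SS" if strand == "+" else "A3SS"
                    out.add((etype, frozenset(_exon_site_pair(longer, strand))))
    return out


def brute_force_annotate(gene: Gene) -> set:
    """All (event_type, frozenset of (kind, pos)) keys of a gene, CNE included."""
    out = set()
    ts = gene.transcripts
    for a in range(len(ts)):
        for b in range(len(ts)):
            if a != b:
                out |= _events_one_way(ts[a], ts[b], gene.strand)
    ase_positions = {pos for _, sites in out for _, pos in sites}
    for t in ts:
        exons = [(e.start, e.end) for e in t.exons]
        for i in range(1, len(exons) - 1):
            E = exons[i]
            ok = True
            for u in ts:
                span = (u.exons[0].start, u.exons[-1].end)
                if span[0] <= E[0] and E[1] <= span[1]:
                    ue = [(e.start, e.end) for e in u.exons]
                    if E not in ue or ue.index(E) in (0, len(ue) - 1):
                        ok = False
                        break
            if ok and E[0] not in ase_positions and E[1] not in ase_positions:
                out.add(("CNE", frozenset(_exon_site_pair(E, gene.strand))))
    return out


# ---------------------------------------------------------------------------
# random gene fixtures


def random_gene(rng: np.random.Generator, gene_id: str = "g", n_transcripts=None) -> Gene:
    """A random multi-transcript gene over a shared boundary pool.

    Transcripts pick exons between shared boundaries, so alternative
    configurations (skips, boundary shifts, retained introns) arise by
    chance; all transcript invariants hold by construction.
    """
    n_t = int(n_transcripts if n_transcripts is not None else rng.integers(2, 5))
    n_bound = int(rng.integers(6, 14))
    pool = np.sort(rng.choice(np.arange(0, 4000), size=n_bound, replace=False))
    strand = "+" if rng.random() < 0.5 else "-"
    transcripts = []
    for k in range(n_t):
        exons = []
        idx = int(rng.integers(0, 2))
        while idx < len(pool) - 1:
            nxt = int(rng.integers(idx + 1, min(idx + 3, len(pool))))
            exons.append(GenomeInterval("chr1", int(pool[idx]), int(pool[nxt]), strand))
            idx = nxt + int(rng.integers(1, 3))
        if len(exons) < 2:
            exons = [
                GenomeInterval("chr1", int(pool[0]), int(pool[1]), strand),
                GenomeInterval("chr1", int(pool[-2]), int(pool[-1]), strand),
            ]
        transcripts.append(Transcript(f"{gene_id}.t{k}", gene_id, strand, exons))
    return Gene(gene_id, "chr1", strand, transcripts)


# ---------------------------------------------------------------------------
# naive signal oracles


def naive_read_count(reads, start, end):
    """O(n) overlap count over (start, end) interval pairs."""
    return sum(1 for s, e in reads if s < end and start < e)


def naive_coverage(reads, start, end):
    return np.array(
        [sum(1 for s, e in reads if s <= p < e) for p in range(start, end)]
    )


def naive_methylation_percentage(sites, start, end):
    """sites: list of (pos, methylated). Returns (pct or None, n)."""
    inside = [m for p, m in sites if start <= p < end]
    if not inside:
        return None, 0
    return 100.0 * sum(inside) / len(inside), len(inside)


def naive_moving_average(values, window):
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = sum(values[lo:hi]) / (hi - lo)
    return out


def naive_cpg_count(seq, start, end):
    return sum(
        1
        for p in range(start, end - 1)
        if seq[p : p + 2].upper() == "CG"
    )


def welch_one_tailed_p(a, b):
    """Closed-form Welch statistic and one-tailed p in the direction of
    the observed mean difference (independent of scipy.stats.ttest_ind)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(tdist.sf(abs(tstat), df))
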