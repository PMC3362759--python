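import numpy as np
import pandas as pd
import pytest

from conftest import make_gene
from episplice.as_annotation import SpliceSite, annotate_gene
from episplice.profiling import (
    ACCEPTOR_OFFSETS,
    DONOR_OFFSETS,
    PositionProfile,
    collect_levels,
    make_bins,
    position_profile,
    smooth_profile,
    stratify_by_ordinal,
)
from episplice.signal_io import ReadTrack
from oracle import naive_moving_average


def read_track(intervals, chrom="chr1"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df["chrom"] = chrom
    return ReadTrack(df)


def annotated_es_gene(strand="+", first=3000, intron=1000, exon=150):
    s1 = first + intron
    s2 = s1 + exon + intron
    g = make_gene(
        [
            [(0, first), (s1, s1 + exon), (s2, s2 + first)],
            [(0, first), (s2, s2 + first)],
        ],
        strand=strand,
    )
    return [e for e in annotate_gene(g) if e.event_type == "ES"]


# ---------------------------------------------------------------------------
# bins


def test_plus_strand_bin_layout():
    bins = make_bins(SpliceSite("acceptor", 5000, "+"), "chr1")
    layout = {(b.side, b.start, b.end) for b in bins}
    assert layout == {("intronic", 4900, 5000), ("exonic", 5000, 5100)}
    bins = make_bins(SpliceSite("donor", 5000, "+"), "chr1")
    layout = {(b.side, b.start, b.end) for b in bins}
    assert layout == {("exonic", 4900, 5000), ("intronic", 5000, 5100)}


def test_minus_strand_bins_mirror():
    bins = make_bins(SpliceSite("acceptor", 5000, "-"), "chr1")
    layout = {(b.side, b.start, b.end) for b in bins}
    assert layout == {("exonic", 4900, 5000), ("intronic", 5000, 5100)}


def test_alternate_bin_length_for_robustness_variant():
    bins = make_bins(SpliceSite("acceptor", 5000, "+"), "chr1", bin_length=50)
    assert all(b.end - b.start == 50 for b in bins)


def test_exonic_bin_inside_exon_intronic_outside():
    for strand in "+-":
        for e in annotated_es_gene(strand=strand):
            (exon,) = e.exons
            for site in e.splice_sites:
                for b in make_bins(site, e.chrom):
                    if b.side == "exonic":
                        assert exon.start <= b.start and b.end <= exon.end
                    else:
                        assert b.end <= exon.start or exon.end <= b.start


# ---------------------------------------------------------------------------
# level collection


def test_observation_cardinality_and_requery(rng):
    events = annotated_es_gene()
    tracks = {
        "H3K36me3": {
            "cellA": read_track([(int(s), int(s) + 200) for s in rng.integers(3000, 6000, 500)]),
            "cellB": read_track([(int(s), int(s) + 200) for s in rng.integers(3000, 6000, 500)]),
        }
    }
    obs = collect_levels(events, tracks)
    assert len(obs) == 8  # 4 bins x 2 cell lines x 1 event x 1 feature
    for _, r in obs.iterrows():
        e = events[0]
        site = e.splice_sites[r["site_index"]]
        (b,) = [b for b in make_bins(site, e.chrom) if b.bin_id == r["bin"]]
        assert r["value"] == tracks["H3K36me3"][r["cell_line"]].region_level(e.chrom, b.start, b.end)


def test_methylation_bins_without_sites_flagged_missing():
    from episplice.signal_io import MethylationTrack, MethylCall

    events = annotated_es_gene()
    track = MethylationTrack([MethylCall("chr1", 4020, True)])  # one site, exon side
    obs = collect_levels(events, {"mCG": {"c1": track}})
    assert obs["missing"].sum() == 3
    assert not obs.loc[obs["bin"] == "acceptor_exonic", "missing"].any()


def test_collect_levels_requires_tracks():
    with pytest.raises(ValueError):
        collect_levels(annotated_es_gene(), {"f": {}})


# ---------------------------------------------------------------------------
# metaprofiles


def test_single_site_single_read_profile():
    events = annotated_es_gene()  # acceptor at 4000, + strand
    track = read_track([(4000, 4200)])
    p = position_profile(events, {"c1": track}, "acceptor", event_type="ES")
    assert p.offsets[0] == ACCEPTOR_OFFSETS[0] and p.offsets[-1] == ACCEPTOR_OFFSETS[1]
    assert len(p.values) == 701
    expected = ((p.offsets >= 0) & (p.offsets < 200)).astype(float)
    assert (p.values == expected).all()


def test_profile_of_identical_sites_equals_single_site():
    plus = annotated_es_gene()
    track = read_track([(3900, 4100)])
    single = position_profile(plus, {"c": track}, "acceptor", event_type="ES")
    doubled = position_profile(plus + plus, {"c": track}, "acceptor", event_type="ES")
    assert np.allclose(single.values, doubled.values)


def test_mixed_strand_profile_matches_per_site_extraction(rng):
    reads = [(int(s), int(s) + 200) for s in rng.integers(2000, 8000, 2000)]
    track = read_track(reads)
    plus, minus = annotated_es_gene("+"), annotated_es_gene("-")
    p = position_profile(plus + minus, {"c": track}, "donor", event_type="ES")
    lo, hi = DONOR_OFFSETS
    acc = np.zeros(hi - lo + 1)
    sites = [(e, s) for e in plus + minus for s in e.splice_sites if s.kind == "donor"]
    for e, s in sites:
        if e.strand == "+":
            w = track.position_values("chr1", s.pos + lo, s.pos + hi + 1)
        else:
            w = track.position_values("chr1", s.pos - 1 - hi, s.pos - lo)[::-1]
        acc += w
    assert np.allclose(p.values, acc / len(sites))


def test_profile_and_bin_aggregation_agree(rng):
    # mean coverage over exonic acceptor offsets [0, 100) should equal the
    # mean acceptor-exonic bin count / 100 for fully-contained reads
    events = annotated_es_gene()
    reads = [(int(s), int(s) + 30) for s in rng.integers(4000, 4071, 300)]
    track = read_track(reads)
    p = position_profile(events, {"c": track}, "acceptor", event_type="ES")
    obs = collect_levels(events, {"f": {"c": track}})
    exonic = obs.loc[obs["bin"] == "acceptor_exonic", "value"].mean()
    window = p.values[(p.offsets >= 0) & (p.offsets < 100)]
    # each read of length L contributes L covered positions and 1 count
    assert window.sum() == pytest.approx(exonic * 30)


def test_empty_event_set_raises():
    with pytest.raises(ValueError):
        position_profile([], {"c": read_track([(0, 10)])}, "acceptor")


# ---------------------------------------------------------------------------
# smoothing


def profile_from(values):
    v = np.asarray(values, float)
    return PositionProfile("f", "ES", "acceptor", np.arange(len(v)), v, 1)


def test_constant_profile_unchanged_by_smoothing():
    p = smooth_profile(profile_from(np.full(701, 3.25)), 147)
    assert np.allclose(p.values, 3.25)


def test_impulse_smoothing_closed_form():
    v = np.zeros(701)
    v[350] = 1.0
    p = smooth_profile(profile_from(v), 147)
    inside = (np.arange(701) >= 350 - 73) & (np.arange(701) <= 350 + 73)
    assert np.allclose(p.values[inside], 1 / 147)
    assert np.allclose(p.values[~inside], 0.0)


def test_smoothing_matches_naive_moving_average(rng):
    v = rng.random(701)
    p = smooth_profile(profile_from(v), 147)
    assert np.allclose(p.values, naive_moving_average(v, 147), atol=1e-12)


def test_smoothing_parameter_validation():
    with pytest.raises(ValueError):
        smooth_profile(profile_from(np.zeros(10)), 0)
    with pytest.raises(ValueError):
        smooth_profile(profile_from(np.zeros(10)), 4)  # even
    with pytest.raises(ValueError):
        smooth_profile(profile_from(np.zeros(10)), 11)  # longer than profile


# ---------------------------------------------------------------------------
# stratification


def test_stratification_partitions_and_conserves():
    import dataclasses

    base = annotated_es_gene()[0]
    events = [dataclasses.replace(base, exon_ordinal=o) for o in (2, 3, 7)]
    strata = stratify_by_ordinal(events, {2, 3, 4})
    assert set(strata) == {2, 3}
    assert sum(len(v) for v in strata.values()) == 2
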