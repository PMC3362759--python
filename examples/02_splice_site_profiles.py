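"""Positional metaprofiles of ChIP-like signal around splice sites.

Simulates a study where a feature is 2x enriched around exon-skipping
splice sites, then averages per-position read coverage across all
acceptor sites of each event class on the -500..+200 window (negative
offsets are intronic for an acceptor). The enriched class should sit
clearly above the constitutive baseline.
"""

from episplice.as_annotation import annotate_gene, filter_positional
from episplice.profiling import position_profile
from episplice.signal_io import ReadTrack, extend_reads
from episplice.synthetic_data import CHROM, SimulationConfig, generate_genes, generate_reads

cfg = SimulationConfig(
    seed=2, n_per_type=50, n_cne_genes=50, read_rate=0.2,
    effects={"H3K36me3": {"ES": 2.0}},
)
genome, genes, truth = generate_genes(cfg)
events = filter_positional([e for g in genes for e in annotate_gene(g)])

raw = generate_reads(cfg, truth, "H3K36me3", "cell1", len(genome[CHROM]))
track = ReadTrack(extend_reads(raw, 200))  # 200-bp strand-aware extension

for etype in ("ES", "CNE"):
    p = position_profile(events, {"cell1": track}, "acceptor", feature="H3K36me3",
                         event_type=etype)
    core = p.values[(p.offsets >= -50) & (p.offsets < 50)].mean()
    print(f"{etype:4s} acceptor profile: n_sites={p.n_sites:3d}  "
          f"mean coverage at -50..+50 = {core:6.2f}")
# With lambda = 0.2 reads/bp and 200-bp extension the constitutive
# baseline is ~40 reads per position; the 2x window around ES sites
# doubles it. Read profiles are reported unsmoothed; CpG/methylation
# profiles (percent of sites) would take the 147-bp sliding window.
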