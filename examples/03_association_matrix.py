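"""ASE-vs-CNE association tests and the signed log10-p matrix.

Simulates two cell lines where one feature is enriched (1.5x) around the
splice-site-selection events (A3SS, A5SS, IR) and depleted (0.67x)
around the skipping events (ES, ME), pools per-bin observations across
cell lines, runs the one-tailed Welch t-test per (feature, event type,
100-bp bin) cell with Bonferroni adjustment, and prints the signed
matrix: positive entries mean higher in the AS events, negative higher
in the constitutive exons.
"""

from episplice.as_annotation import annotate_gene, filter_positional
from episplice.association_stats import build_matrix, run_association_tests
from episplice.profiling import collect_levels
from episplice.signal_io import ReadTrack, extend_reads
from episplice.synthetic_data import CHROM, SimulationConfig, generate_genes, generate_reads

cfg = SimulationConfig(
    seed=3, n_per_type=150, n_cne_genes=150, n_cell_lines=2, read_rate=0.2,
    effects={
        "H3K36me3-like": {"A3SS": 1.5, "A5SS": 1.5, "IR": 1.5, "ES": 0.67, "ME": 0.67},
        "null-feature": {},
    },
)
genome, genes, truth = generate_genes(cfg)
L = len(genome[CHROM])
events = filter_positional([e for g in genes for e in annotate_gene(g)])
tracks = {
    f: {line: ReadTrack(extend_reads(generate_reads(cfg, truth, f, line, L)))
        for line in ("cell1", "cell2")}
    for f in cfg.effects
}

obs = collect_levels(events, tracks)
res = run_association_tests(obs)  # Bonferroni family = all populated cells
sig = res[res["significant"]]
print(f"tested cells: {len(res)}   significant at adjusted p < 1e-2: {len(sig)}")
print(sig.groupby(["feature", "event_type"])["direction"].first().to_string())

mat = build_matrix(res)
print("\nsigned log10-p (acceptor-exonic bin):")
print(mat.xs("acceptor_exonic", level="bin", axis=1).round(1).to_string())
# Every significant cell belongs to the planted feature: +values for the
# 1.5x types (higher in ASE), -values for the 0.67x types (higher in
# CNE); the null feature stays near 0 everywhere.
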