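"""Stage orchestration behind a single YAML configuration.

Stages (also exposed as ``episplice`` subcommands): simulate a fixture,
annotate AS events from a GTF, collect per-bin levels and run the
ASE-vs-CNE association tests, compute positional metaprofiles, and
cluster features/AS types from the signed log-p matrix. Every output
TSV starts with a comment header naming the configuration hash and seed
so reruns are auditable; two runs from the same fixture and
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import as_annotation, association_stats, clustering, profiling, signal_io
from .synthetic_data import SimulationConfig, write_fixture
from .transcript_model import read_gtf

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "cmd_simulate",
    "cmd_annotate",
    "cmd_associate",
    "cmd_profile",
    "cmd_cluster",
    "cmd_run_all",
]

SEQUENCE_FEATURES = ("CG",)
METHYLATION_FEATURES = ("mCG",)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``examples/config.yaml``."""

    output_dir: str = "episplice_out"
    genome: str | None = None
    gtf: str | None = None
    manifest: dict = field(default_factory=dict)  # feature -> {cell_line -> path}
    input_tracks: dict = field(default_factory=dict)  # cell_line -> path
    nucleosome_tracks: dict = field(default_factory=dict)  # cell_line -> path
    coding_only: bool = False
    bin_length: int = 100
    smoothing_window: int = 147
    read_extension: int = 200
    tss_buffer: int = 2000
    alpha: float = 1e-2
    correction_mode: str = "none"
    correction_pseudocount: float = 1.0
    bonferroni_m: int | None = None
    k_features: int = 4
    k_types: int = 2
    restarts: int = 25
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bin_length", "smoothing_window", "read_extension"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tss_buffer < 0 or self.alpha < 0:
            raise ValueError("tss_buffer and alpha must be non-negative")
        association_stats.CorrectionSpec(self.correction_mode, self.correction_pseudocount)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self, stage: str) -> None:
        required: list[str] = []
        if stage in ("annotate", "associate", "profile"):
            required.append(self.gtf)
        if stage in ("associate", "profile"):
            paths = [p for lines in self.manifest.values() for p in lines.values()]
            if not paths:
                raise ValueError("manifest: no feature tracks configured")
            required += paths
            if any(f in SEQUENCE_FEATURES for f in self.manifest) or self.genome:
                required.append(self.genome)
        for p in required:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"configured path missing: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# episplice config={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def cmd_simulate(cfg: PipelineConfig) -> dict:
    """Generate the synthetic fixture configured under ``simulate:``."""
    sim = SimulationConfig(seed=cfg.seed, **cfg.simulate)
    out = _outdir(cfg) / "fixture"
    manifest = write_fixture(sim, out)
    logger.info("fixture written to %s", out)
    return manifest


def cmd_annotate(cfg: PipelineConfig) -> list:
    """Annotate, positionally filter and export AS events + CNEs."""
    cfg.validate_paths("annotate")
    genes = read_gtf(cfg.gtf, coding_only=cfg.coding_only)
    if not genes:
        raise ValueError(f"no genes parsed from {cfg.gtf}")
    events = [e for g in genes for e in as_annotation.annotate_gene(g)]
    events = as_annotation.filter_positional(events, window=cfg.tss_buffer)
    counts = pd.Series([e.event_type for e in events]).value_counts()
    logger.info("event counts after filtering: %s", counts.to_dict())
    out = _outdir(cfg)
    rows = [
        {
            "event_id": e.event_id,
            "event_type": e.event_type,
            "gene_id": e.gene_id,
            "chrom": e.chrom,
            "strand": e.strand,
            "acceptor_pos": ",".join(str(s.pos) for s in e.splice_sites if s.kind == "acceptor"),
            "donor_pos": ",".join(str(s.pos) for s in e.splice_sites if s.kind == "donor"),
            "exon_ordinal": e.exon_ordinal,
            "evidence": ",".join(e.evidence),
        }
        for e in events
    ]
    _write_tsv(pd.DataFrame(rows), out / "events.tsv", cfg)
    as_annotation.splice_sites_to_bed(events, out / "splice_sites.bed")
    return events


def _load_tracks(cfg: PipelineConfig) -> dict:
    """Materialise the manifest into SignalTrack objects per cell line."""
    tracks: dict[str, dict[str, object]] = {}
    seq_track = None
    for feature, lines in cfg.manifest.items():
        tracks[feature] = {}
        for cell_line, path in lines.items():
            if feature in SEQUENCE_FEATURES:
                if seq_track is None:
                    seq_track = signal_io.SequenceCpGTrack.from_fasta(cfg.genome)
                tracks[feature][cell_line] = seq_track
            elif feature in METHYLATION_FEATURES:
                tracks[feature][cell_line] = signal_io.read_methylation(path, label=feature)
            else:
                tracks[feature][cell_line] = signal_io.load_reads(
                    path, extension=cfg.read_extension, label=feature
                )
    return tracks


def _reference_tracks(cfg: PipelineConfig) -> dict:
    source = cfg.input_tracks if cfg.correction_mode == "input_subtract" else cfg.nucleosome_tracks
    if not source:
        raise ValueError(f"correction mode {cfg.correction_mode} needs reference tracks")
    return {
        line: signal_io.load_reads(path, extension=cfg.read_extension, label="reference")
        for line, path in source.items()
    }


def cmd_associate(cfg: PipelineConfig, events: list | None = None):
    """Collect bin levels, correct, test and build the signed log-p matrix."""
    cfg.validate_paths("associate")
    if events is None:
        events = cmd_annotate(cfg)
    tracks = _load_tracks(cfg)
    obs = profiling.collect_levels(events, tracks, bin_length=cfg.bin_length)
    if cfg.correction_mode != "none":
        spec = association_stats.CorrectionSpec(cfg.correction_mode, cfg.correction_pseudocount)
        ref_obs = profiling.collect_levels(
            events, {"__ref__": _reference_tracks(cfg)}, bin_length=cfg.bin_length
        )
        # corrections target ChIP-style read features, not CG/mCG
        read_features = [
            f for f in cfg.manifest
            if f not in SEQUENCE_FEATURES + METHYLATION_FEATURES
        ]
        mask = obs["feature"].isin(read_features)
        obs = pd.concat(
            [association_stats.apply_correction(obs[mask], ref_obs, spec), obs[~mask]],
            ignore_index=True,
        )
    results = association_stats.run_association_tests(
        obs, alpha=cfg.alpha, bonferroni_m=cfg.bonferroni_m
    )
    matrix = association_stats.build_matrix(results)
    out = _outdir(cfg)
    _write_tsv(results, out / "results.tsv", cfg)
    flat = matrix.copy()
    flat.columns = [f"{t}:{b}" for t, b in matrix.columns]
    _write_tsv(flat, out / "matrix.tsv", cfg, index=True)
    return results, matrix


def cmd_profile(cfg: PipelineConfig, events: list | None = None) -> pd.DataFrame:
    """Positional metaprofiles per feature, event type and site kind."""
    cfg.validate_paths("profile")
    if events is None:
        events = cmd_annotate(cfg)
    tracks = _load_tracks(cfg)
    present = sorted({e.event_type for e in events})
    frames = []
    for feature, lines in tracks.items():
        smooth = feature in SEQUENCE_FEATURES + METHYLATION_FEATURES
        for etype in present:
            for site_kind in ("acceptor", "donor"):
                try:
                    p = profiling.position_profile(
                        events, lines, site_kind, feature=feature, event_type=etype
                    )
                except ValueError:
                    logger.warning("no %s sites for %s; skipped", site_kind, etype)
                    continue
                if smooth:
                    p = profiling.smooth_profile(p, window=cfg.smoothing_window)
                frames.append(profiling.profile_to_frame(p))
    profiles = pd.concat(frames, ignore_index=True)
    _write_tsv(profiles, _outdir(cfg) / "profiles.tsv", cfg)
    return profiles


def cmd_cluster(cfg: PipelineConfig, matrix: pd.DataFrame | None = None):
    """k-means over features (k=4) and AS types (k=2), plus classical MDS."""
    out = _outdir(cfg)
    if matrix is None:
        flat = _read_tsv(out / "matrix.tsv", index_col=0)
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(":")) for c in flat.columns], names=["event_type", "bin"]
        )
        matrix = flat.set_axis(cols, axis=1)
    feat = clustering.kmeans_cluster(matrix, k=cfg.k_features, seed=cfg.seed, restarts=cfg.restarts)
    types = clustering.cluster_as_types(matrix, k=cfg.k_types, seed=cfg.seed, restarts=cfg.restarts)
    mds = clustering.classical_mds(matrix)
    _write_tsv(feat.to_frame(), out / "clusters_features.tsv", cfg)
    _write_tsv(types.to_frame(), out / "clusters_types.tsv", cfg)
    _write_tsv(mds.reset_index().rename(columns={"index": "item"}), out / "mds.tsv", cfg)
    return feat, types, mds


def cmd_run_all(cfg: PipelineConfig):
    """simulate (when configured) -> annotate -> profile -> associate -> cluster."""
    if cfg.simulate:
        manifest = cmd_simulate(cfg)
        cfg.genome = manifest["genome"]
        cfg.gtf = manifest["gtf"]
        if not cfg.manifest:
            cfg.manifest = dict(manifest["tracks"])
            cfg.manifest["CG"] = {"genome": manifest["genome"]}
            cfg.manifest["mCG"] = {"bsseq": manifest["methylation"]}
    events = cmd_annotate(cfg)
    profiles = cmd_profile(cfg, events)
    results, matrix = cmd_associate(cfg, events)
    clusters = cmd_cluster(cfg, matrix)
    return events, profiles, results, matrix, clusters
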