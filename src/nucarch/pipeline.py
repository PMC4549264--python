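"""End-to-end driver chaining every analysis stage on synthetic data.

``run_pipeline`` executes simulate -> occupancy -> calling -> sequence
periodicity -> metaprofiles/clustering -> methylation geometry -> pattern
scan, writing plain-text outputs plus a manifest (package version, seed,
parameter echo, sha256 checksums).  Rerunning with the same configuration
reproduces the checksums bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, methylation, occupancy, profiles, scan, sequence, simulate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "nucarch_run"
    seed: int = 0
    sim: simulate.SimConfig = None  # type: ignore[assignment]
    scan: scan.ScanConfig = field(default_factory=scan.ScanConfig)
    min_spacing: int = 150
    min_summit: float = 1.0
    normalize_target: float = 100.0
    pcc_bin: int = 10
    tss_flank: int = 1000
    kmeans_k: int = 10
    kmeans_n_init: int = 10
    n_seqfreq_dyads: int = 5000
    stages: tuple[str, ...] = (
        "simulate", "nos", "call", "seqfreq", "phasing", "profiles", "methylation", "scan",
    )

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = simulate.SimConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return [float(x) for x in obj]
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    echo = clean(config)
    echo.pop("outdir", None)  # scientific parameters only: keeps the echo
    # (and hence the run checksums) independent of where the run lives
    return echo


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - name the failing stage
            raise PipelineError(f"stage {name!r} failed: {e}") from e

    def stage_simulate():
        ds = simulate.simulate_dataset(config.sim)
        state["ds"] = ds
        paths = []
        p = outdir / "genome.fa"
        io.write_fasta(ds.genome, p)
        paths.append(p)
        p = outdir / "fragments.bed"
        io.write_bed(ds.fragments[["chrom", "start", "end"]], p)
        paths.append(p)
        p = outdir / "chrom.sizes"
        io.write_chrom_sizes(ds.chrom_sizes, p)
        paths.append(p)
        p = outdir / "genes.bed12"
        io.write_bed(io.genes_to_bed12(ds.truth.genes, ds.features["exons"]), p)
        paths.append(p)
        for strand, tracks in (("plus", ds.rna_plus), ("minus", ds.rna_minus)):
            p = outdir / f"rna_{strand}.bedGraph"
            io.write_bedgraph(tracks, p)
            paths.append(p)
        feat_dir = outdir / "features"
        feat_dir.mkdir(exist_ok=True)
        for name in ("tfbs", "histone_marks", "chromatin_states", "exons"):
            p = feat_dir / f"{name}.bed6"
            io.write_bed(ds.features[name], p)
            paths.append(p)
        p = outdir / "methylation.tsv"
        io.write_methylation(ds.methylation, p)
        paths.append(p)
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name, df in (
            ("nucleosomes", ds.truth.nucleosomes),
            ("genes", ds.truth.genes),
            ("enhancers", ds.truth.enhancers),
        ):
            p = truth_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        p = outdir / "config.yaml"
        p.write_text(yaml.safe_dump(_config_echo(config), sort_keys=True))
        paths.append(p)
        record("simulate", paths)

    def stage_nos():
        ds = state["ds"]
        frags = occupancy.deduplicate_fragments(ds.fragments)
        tracks = occupancy.compute_nos(frags, ds.chrom_sizes)
        state["raw_tracks"] = tracks
        state["norm_tracks"] = occupancy.normalize_tracks(tracks, config.normalize_target)
        p = outdir / "nos.bedGraph"
        io.write_bedgraph(tracks, p)
        w = outdir / "nos.wig"
        io.write_wiggle(tracks, w)
        record("nos", [p, w])

    def stage_call():
        nucs = occupancy.call_nucleosomes(
            state["raw_tracks"], config.min_spacing, config.min_summit
        )
        state["nucleosomes"] = nucs
        p = outdir / "nucleosomes.bed"
        io.write_nucleosomes_bed(nucs, p)
        record("call", [p])

    def stage_seqfreq():
        ds = state["ds"]
        dyads = ds.truth.nucleosomes.head(config.n_seqfreq_dyads)
        prof = sequence.dyad_relative_frequency(ds.genome, dyads, k=2)
        aa = prof["AA"]
        pg = sequence.fft_periodogram(aa)
        p = outdir / "aa_profile.tsv"
        pd.DataFrame({"offset": aa.offsets, "frequency": aa.values}).to_csv(
            p, sep="\t", index=False
        )
        q = outdir / "aa_periodogram.tsv"
        pd.DataFrame({"period": pg.periods, "power": pg.power}).to_csv(q, sep="\t", index=False)
        state["aa_period"] = pg.dominant_period
        record("seqfreq", [p, q])

    def stage_phasing():
        pg = sequence.phasing_periodogram(state["raw_tracks"], seed=config.seed)
        p = outdir / "phasing_periodogram.tsv"
        pd.DataFrame({"period": pg.periods, "power": pg.power}).to_csv(p, sep="\t", index=False)
        state["nrl_estimate"] = pg.dominant_period
        record("phasing", [p])

    def stage_profiles():
        ds = state["ds"]
        mat = profiles.profile_matrix(
            state["norm_tracks"], ds.truth.genes, flank=config.tss_flank
        )
        result = profiles.kmeans_profiles(
            mat, k=config.kmeans_k, n_init=config.kmeans_n_init, seed=config.seed
        )
        p = outdir / "tss_clusters.tsv"
        result.assignments.rename_axis("gene").to_frame().to_csv(p, sep="\t")
        q = outdir / "cluster_max_nos.tsv"
        pd.DataFrame(
            {"cluster": range(result.k), "max_nos_offset": result.max_nos_location}
        ).to_csv(q, sep="\t", index=False)
        rna = profiles.build_rna_signal(ds.rna_plus, ds.rna_minus)
        expr = np.array([profiles.total_expression(g, rna) for _, g in ds.truth.genes.iterrows()])
        quart = profiles.quartile_split(expr)
        r = outdir / "expression_quartiles.tsv"
        pd.DataFrame(
            {"gene": ds.truth.genes["name"], "expression": expr, "quartile": quart}
        ).to_csv(r, sep="\t", index=False)
        record("profiles", [p, q, r])

    def stage_methylation():
        ds = state["ds"]
        sites = methylation.ingest_sites(ds.methylation)
        nucs = state["nucleosomes"]
        assigned = methylation.assign_sites_to_nucleosomes(sites, nucs)
        paths = []
        for ctx in methylation.CONTEXTS:
            hist = methylation.distance_to_nearest_dyad(
                sites, ds.truth.nucleosomes, context=ctx
            )
            p = outdir / f"dyad_distance_{ctx}.tsv"
            pd.DataFrame(
                {"offset": hist.offsets, "frequency_percent": hist.frequency_percent}
            ).to_csv(p, sep="\t", index=False)
            paths.append(p)
        strat = methylation.occupancy_by_count(assigned, "mCG")
        p = outdir / "occupancy_by_mcg_count.tsv"
        strat.table.assign(kw_p=strat.kw_p).to_csv(p, sep="\t", index=False)
        paths.append(p)
        q = outdir / "occupancy_by_mcg_count_pairwise.tsv"
        strat.pairwise.to_csv(q, sep="\t", index=False)
        paths.append(q)
        record("methylation", paths)

    def stage_scan():
        ds = state["ds"]
        hits = scan.find_patterns(state["nucleosomes"], state["raw_tracks"], config.scan)
        p = outdir / "pattern_hits.bed"
        max_score = hits["score"].replace(np.inf, np.nan).max() if len(hits) else 0
        bed = pd.DataFrame(
            {
                "chrom": hits["chrom"],
                "start": hits["window_start"],
                "end": hits["window_end"],
                "name": [f"hit{i}" for i in range(len(hits))],
                "score": (
                    (hits["score"].clip(upper=max_score) / max_score * 1000).fillna(1000).astype(int)
                    if len(hits) and max_score > 0
                    else 0
                ),
                "strand": ".",
            }
        )
        io.write_bed(bed, p)
        q = outdir / "candidates.fa"
        io.write_fasta(scan.extract_hit_sequences(ds.genome, hits), q)
        record("scan", [p, q])

    for name, fn in (
        ("simulate", stage_simulate),
        ("nos", stage_nos),
        ("call", stage_call),
        ("seqfreq", stage_seqfreq),
        ("phasing", stage_phasing),
        ("profiles", stage_profiles),
        ("methylation", stage_methylation),
        ("scan", stage_scan),
    ):
        run_stage(name, fn)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
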