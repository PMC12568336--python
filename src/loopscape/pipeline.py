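"""End-to-end orchestration: pairs -> QC -> matrices -> architecture -> loops
-> promoter-anchored interactions, with a reproducible report bundle.

Every stage logs its input/output record counts (the read-processing
funnel); any stage failure aborts with the stage name while earlier stage
outputs remain on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from . import domains, loops as loopmod, matrixops, pairsio, promoters as promod, significance
from .genome import ConfigError, GenomeSpec
from .io import read_bed, read_pairs, write_bed, write_bedgraph

log = logging.getLogger("loopscape")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; unreferenced annotation paths may be None."""

    pairs: str
    chromsizes: str
    outdir: str
    blacklist: tuple[str, ...] = ()
    resolution: int = 10_000
    chimeric_threshold: int = 2000
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    insulation_window: int = 100_000
    delta_threshold: float = 0.05
    n_strata: int = 100
    loop_q: float = 0.1
    donut_outer: int = 5
    donut_inner: int = 2
    atac: str | None = None
    h3k4me1: str | None = None
    h3k4me3: str | None = None
    h3k27ac: str | None = None
    ctcf: str | None = None
    tss: str | None = None
    deletions: str | None = None
    genes: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")
        if self.chimeric_threshold < 0:
            raise ConfigError("chimeric_threshold must be >= 0")
        if not (0 < self.loop_q < 1):
            raise ConfigError("loop_q must be in (0, 1)")
        if self.delta_threshold < 0:
            raise ConfigError("delta_threshold must be >= 0")
        if self.insulation_window < 2 * self.resolution:
            raise ConfigError("insulation_window must span at least 2 bins")
        for name in ("pairs", "chromsizes", "atac", "h3k4me1", "h3k4me3", "h3k27ac", "ctcf", "tss", "deletions", "genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config path for {name!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.setdefault("blacklist", ())
        data["blacklist"] = tuple(data["blacklist"])
        return cls(**data)


@dataclass
class PipelineReport:
    """In-memory bundle of every stage's headline outputs."""

    summary: pairsio.SummaryReport
    decay_slope: float
    mean_cis_ratio: float
    compartment_tracks: dict[str, comp.CompartmentTrack]
    boundaries: dict[str, list[domains.Boundary]]
    interactions: pd.DataFrame
    loop_calls: list[loopmod.LoopCall]
    loop_histogram: pd.DataFrame
    anchor_summary: pd.DataFrame | None
    variant_overlaps: pd.DataFrame | None
    promoter_interactions: pd.DataFrame | None
    stage_counts: dict[str, int] = field(default_factory=dict)


def bed_bin_density(bed: pd.DataFrame, genome: GenomeSpec, resolution: int) -> dict[str, np.ndarray]:
    """Peak midpoints per bin — a simple 1D activity/signal track."""
    out = {c: np.zeros(genome.n_bins(c, resolution)) for c in genome.analysis_names}
    for row in bed.itertuples():
        if row.chrom not in out:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        b = mid // resolution
        if 0 <= b < len(out[row.chrom]):
            out[row.chrom][b] += 1
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage on the configured inputs; deterministic per seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = GenomeSpec.from_chromsizes(
        Path(config.chromsizes).read_text(), frozenset(config.blacklist)
    )
    counts: dict[str, int] = {}

    # --- pair QC ---------------------------------------------------------
    @_stage("pairsio")
    def _pairs():
        raw = read_pairs(config.pairs)
        counts["input_pairs"] = len(raw)
        parsed, stats = pairsio.parse_pairs(raw, genome)
        counts["parsed"] = stats.n_kept
        counts["dropped_blacklist"] = stats.n_dropped_blacklist
        filtered, n_nonchim = pairsio.filter_chimeric(parsed, config.chimeric_threshold)
        counts["non_chimeric_removed"] = n_nonchim
        deduped, n_dup = pairsio.deduplicate(pairsio.sort_pairs(filtered))
        counts["duplicates"] = n_dup
        classified = pairsio.classify(deduped)
        summary = pairsio.summarize(classified)
        summary.to_tsv(outdir / "summary.tsv")
        log.info("pair funnel: %s", counts)
        return classified, summary

    classified, summary = _pairs()

    # --- matrices --------------------------------------------------------
    @_stage("matrixops")
    def _matrices():
        ms = matrixops.bin_pairs(classified, genome, config.resolution)
        counts["valid_pairs_binned"] = ms.n_pairs
        cov = matrixops.coverage(ms)
        decay = matrixops.contact_decay(ms)
        balanced = {
            c: matrixops.balance(m, tol=config.ice_tol, max_iter=config.ice_max_iter)
            for c, m in ms.cis.items()
        }
        return ms, cov, decay, balanced

    ms, cov, decay, balanced = _matrices()
    slope = decay["all"].slope()

    # --- annotations (optional inputs) -----------------------------------
    beds = {}
    for name in ("atac", "h3k4me1", "h3k4me3", "h3k27ac", "ctcf", "tss", "deletions"):
        p = getattr(config, name)
        if p is not None:
            beds[name] = read_bed(p)

    # --- compartments ----------------------------------------------------
    @_stage("compartments")
    def _compartments():
        if "atac" in beds:
            orient = bed_bin_density(beds["atac"], genome, config.resolution)
        elif "tss" in beds:
            orient = bed_bin_density(beds["tss"], genome, config.resolution)
        else:
            orient = {c: np.ones(genome.n_bins(c, config.resolution)) for c in genome.analysis_names}
        tracks = {}
        for chrom, bm in balanced.items():
            try:
                tracks[chrom] = comp.compartment_eigenvector(bm, orient[chrom])
            except comp.DegenerateMatrixError as exc:
                log.warning("compartments skipped on %s: %s", chrom, exc)
        write_bedgraph(
            {c: t.e1 for c, t in tracks.items()}, config.resolution, outdir / "e1.bedgraph", genome
        )
        return tracks

    tracks = _compartments()

    # --- domains ---------------------------------------------------------
    @_stage("domains")
    def _domains():
        bounds = {}
        ins_tracks = {}
        for chrom, bm in balanced.items():
            tr = domains.insulation(bm, config.insulation_window)
            ins_tracks[chrom] = tr.scores
            bounds[chrom] = domains.call_boundaries(tr, config.delta_threshold)
        write_bedgraph(ins_tracks, config.resolution, outdir / "insulation.bedgraph", genome)
        write_bed(
            pd.DataFrame(
                [
                    (b.chrom, b.start, b.end, f"boundary_{i}", round(b.strength, 4), ".")
                    for i, b in enumerate(x for bl in bounds.values() for x in bl)
                ],
                columns=["chrom", "start", "end", "name", "score", "strand"],
            ),
            outdir / "boundaries.bed",
        )
        counts["boundaries"] = sum(len(v) for v in bounds.values())
        return bounds

    bounds = _domains()

    # --- significance ----------------------------------------------------
    @_stage("significance")
    def _significance():
        frames = []
        for chrom, cm in ms.cis.items():
            if cm.counts.nnz == 0:
                continue
            model = significance.fit_expected(cm, n_strata=config.n_strata)
            frames.append(significance.test_interactions(cm, model))
        inter = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        inter.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        counts["tested_interactions"] = len(inter)
        return inter

    interactions = _significance()

    # --- loops -----------------------------------------------------------
    @_stage("loops")
    def _loops():
        calls: list[loopmod.LoopCall] = []
        for chrom, bm in balanced.items():
            calls.extend(
                loopmod.call_loops(
                    bm,
                    q_threshold=config.loop_q,
                    donut_outer=config.donut_outer,
                    donut_inner=config.donut_inner,
                )
            )
        loopmod.loops_to_bedpe(calls).to_csv(outdir / "loops.bedpe", sep="\t", index=False)
        hist = loopmod.distance_histogram(calls)
        hist.to_csv(outdir / "loop_distance_histogram.tsv", sep="\t", index=False)
        counts["loops"] = len(calls)
        anchor_summary = None
        if "atac" in beds:
            marks = {
                label: beds[key]
                for key, label in (
                    ("h3k4me1", "H3K4me1"),
                    ("h3k4me3", "H3K4me3"),
                    ("h3k27ac", "H3K27ac"),
                    ("ctcf", "CTCF"),
                )
                if key in beds
            }
            _, anchor_summary = loopmod.annotate_anchors(calls, beds["atac"], marks)
            anchor_summary.to_csv(outdir / "anchor_classes.tsv", sep="\t", index=False)
        variant_tbl = None
        if "deletions" in beds:
            variant_tbl, _ = loopmod.overlap_variants(calls, beds["deletions"])
            variant_tbl.to_csv(outdir / "loop_deletion_overlap.tsv", sep="\t", index=False)
        return calls, hist, anchor_summary, variant_tbl

    calls, hist, anchor_summary, variant_tbl = _loops()

    # --- promoters -------------------------------------------------------
    @_stage("promoters")
    def _promoters():
        if "tss" not in beds:
            return None
        proms = promod.build_promoters(
            beds["tss"], beds.get("atac", pd.DataFrame(columns=beds["tss"].columns)), genome=genome
        )
        write_bed(promod.promoters_to_bed(proms), outdir / "promoters.bed")
        pi = promod.subset_promoter_interactions(interactions, proms, config.resolution)
        if config.genes is not None:
            gene_list = [g.strip() for g in Path(config.genes).read_text().splitlines() if g.strip()]
            pi = promod.filter_by_genes(pi, gene_list)
        pi.to_csv(outdir / "promoter_interactions.tsv", sep="\t", index=False)
        counts["promoter_interactions"] = len(pi)
        return pi

    promoter_inter = _promoters()

    report = PipelineReport(
        summary=summary,
        decay_slope=float(slope),
        mean_cis_ratio=float(cov.mean_ratio),
        compartment_tracks=tracks,
        boundaries=bounds,
        interactions=interactions,
        loop_calls=calls,
        loop_histogram=hist,
        anchor_summary=anchor_summary,
        variant_overlaps=variant_tbl,
        promoter_interactions=promoter_inter,
        stage_counts=counts,
    )
    _write_report_json(report, outdir / "report.json")
    return report


def _write_report_json(report: PipelineReport, path: Path) -> None:
    payload = {
        "stage_counts": report.stage_counts,
        "summary": {
            row.Category: [int(row.Count), float(row.Percent)] for row in report.summary.table.itertuples()
        },
        "decay_slope": None if np.isnan(report.decay_slope) else round(report.decay_slope, 6),
        "mean_cis_ratio": None if np.isnan(report.mean_cis_ratio) else round(report.mean_cis_ratio, 6),
        "n_compartment_chroms": len(report.compartment_tracks),
        "n_boundaries": sum(len(v) for v in report.boundaries.values()),
        "n_loops": len(report.loop_calls),
        "loop_histogram": {
            cat: int(ct)
            for cat, ct in zip(report.loop_histogram["category"], report.loop_histogram["count"])
        },
        "n_promoter_interactions": (
            None if report.promoter_interactions is None else len(report.promoter_interactions)
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
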