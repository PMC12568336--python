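"""Plain-text readers and writers for the formats the pipeline exchanges.

Pairs use the 4DN text dialect (``#columns: readID chrom1 pos1 chrom2 pos2
strand1 strand2``); peak/TSS/deletion intervals use BED6 (0-based
half-open); 1D tracks use bedgraph; matrices are exported as a cooler-style
bin table plus a (bin1, bin2, count) triplet table.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .synthgen import PAIR_COLUMNS, AnnotationSet, SyntheticTruth

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_pairs(pairs: pd.DataFrame, path: str | os.PathLike, genome: GenomeSpec | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if genome is not None:
            for nm in genome.names:
                fh.write(f"#chromsize: {nm} {genome.lengths[nm]}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        pairs[PAIR_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=PAIR_COLUMNS,
        dtype={"read_id": str, "chrom1": str, "chrom2": str, "strand1": str, "strand2": str},
    )
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED3/BED6 reader; missing name/score/strand columns get defaults."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid BED interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            score = parts[4] if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bedgraph(track: dict[str, np.ndarray], resolution: int, path: str | os.PathLike,
                   genome: GenomeSpec | None = None) -> None:
    """Per-bin values -> bedgraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for chrom, values in track.items():
            length = genome.lengths[chrom] if genome else None
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                start = i * resolution
                end = (i + 1) * resolution
                if length is not None:
                    end = min(end, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_matrix_text(matrices: dict, genome: GenomeSpec, resolution: int, outdir: str | os.PathLike) -> None:
    """Cooler-style text export: ``bins.tsv`` + per-chromosome ``pixels`` TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bin_rows = []
    for chrom in genome.analysis_names:
        nb = genome.n_bins(chrom, resolution)
        for i in range(nb):
            bin_rows.append((chrom, i * resolution, min((i + 1) * resolution, genome.lengths[chrom])))
    pd.DataFrame(bin_rows, columns=["chrom", "start", "end"]).to_csv(
        outdir / "bins.tsv", sep="\t", index=False
    )
    for key, cm in matrices.items():
        name = key if isinstance(key, str) else "_".join(key)
        coo = cm.counts.tocoo()
        pd.DataFrame({"bin1": coo.row, "bin2": coo.col, "count": coo.data}).sort_values(
            ["bin1", "bin2"]
        ).to_csv(outdir / f"pixels_{name}.tsv", sep="\t", index=False)


def write_truth(truth: SyntheticTruth, outdir: str | os.PathLike) -> None:
    """Tabular truth bundle: compartments/boundaries/loops TSV + params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (chrom, i, lab)
        for chrom, labs in truth.compartment_labels.items()
        for i, lab in enumerate(labs)
    ]
    pd.DataFrame(rows, columns=["chrom", "bin", "label"]).to_csv(
        outdir / "compartments.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(c, p) for c, ps in truth.boundaries.items() for p in ps],
        columns=["chrom", "position"],
    ).to_csv(outdir / "boundaries.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(lp.chrom, lp.pos1, lp.pos2, lp.multiplier) for lp in truth.loops],
        columns=["chrom", "pos1", "pos2", "multiplier"],
    ).to_csv(outdir / "loops.tsv", sep="\t", index=False)
    params = truth.params
    with open(outdir / "params.json", "w") as fh:
        json.dump(
            {
                "n_pairs": params.n_pairs,
                "alpha": params.alpha,
                "trans_fraction": params.trans_fraction,
                "duplicate_rate": params.duplicate_rate,
                "unmapped_rate": params.unmapped_rate,
                "short_fraction": params.short_fraction,
                "compartment_size": params.compartment_size,
                "compartment_strength": params.compartment_strength,
                "tad_boundaries": {k: list(v) for k, v in params.tad_boundaries.items()},
                "tad_strength": params.tad_strength,
                "loops": [[lp.chrom, lp.pos1, lp.pos2, lp.multiplier] for lp in params.loops],
                "bin_size": params.bin_size,
                "seed": params.seed,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def write_annotations(ann: AnnotationSet, outdir: str | os.PathLike) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("atac", "h3k4me1", "h3k4me3", "h3k27ac", "ctcf", "tss", "deletions"):
        p = outdir / f"{name}.bed"
        write_bed(getattr(ann, name), p)
        paths[name] = p
    return paths
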