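"""Plain-text genomics format readers and writers.

BED and bedGraph coordinates are 0-based half-open; fixedStep wiggle is
1-based, per the UCSC conventions.  Writers emit a canonical form
(tab-separated, ``%g`` floats) so that ``write(read(x))`` is
byte-identical for files the package itself produced.  Malformed lines
raise :class:`FormatError` with file and line context.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .occupancy import OccupancyTrack, TrackSet


class FormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, np.ndarray]:
    """Genome as chrom -> uint8 ASCII array (uppercased)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), one_based_attributes=False)
    return {
        name: np.frombuffer(str(fa[name][:]).upper().encode("ascii"), dtype=np.uint8).copy()
        for name in fa.keys()
    }


def write_fasta(genome: dict[str, np.ndarray] | list[tuple[str, str]], path, width: int = 60) -> None:
    items = genome.items() if isinstance(genome, dict) else genome
    with open(path, "w") as fh:
        for name, seq in items:
            if isinstance(seq, np.ndarray):
                seq = bytes(seq).decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: bad size {parts[1]!r}") from e
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# BED


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                "thick_start", "thick_end", "item_rgb",
                "block_count", "block_sizes", "block_starts"]


def read_bed(path, n_fields: int | None = None) -> pd.DataFrame:
    """BED3/6/12 reader with per-line validation."""
    rows = []
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if n_fields is not None and len(parts) < n_fields:
            raise FormatError(f"{path}:{lineno}: expected >= {n_fields} fields")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs at least 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from e
        if start < 0 or start >= end:
            raise FormatError(f"{path}:{lineno}: require 0 <= start < end")
        rows.append(parts)
    if not rows:
        return pd.DataFrame(columns=_BED_COLUMNS[: n_fields or 3])
    width = len(rows[0])
    df = pd.DataFrame(rows, columns=_BED_COLUMNS[:width])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    for col in ("thick_start", "thick_end", "block_count"):
        if col in df.columns:
            try:
                df[col] = df[col].astype(np.int64)
            except ValueError:
                df[col] = df[col].astype(float)  # BED6+2 style extra columns
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in _BED_COLUMNS]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [str(row[c]) for c in cols + extra]
            fh.write("\t".join(fields) + "\n")


def genes_to_bed12(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Gene models plus their exon intervals as BED12 rows."""
    rows = []
    for _, g in genes.iterrows():
        ex = exons[exons["name"] == g["name"]].sort_values("start")
        sizes = ",".join(str(e - s) for s, e in zip(ex["start"], ex["end"])) + ","
        starts = ",".join(str(s - g["start"]) for s in ex["start"]) + ","
        rows.append(
            {
                "chrom": g["chrom"], "start": g["start"], "end": g["end"],
                "name": g["name"], "score": 0, "strand": g["strand"],
                "thick_start": g["start"], "thick_end": g["end"], "item_rgb": "0",
                "block_count": len(ex), "block_sizes": sizes, "block_starts": starts,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bedGraph / wiggle tracks


def write_bedgraph(tracks: TrackSet, path) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in tracks:
            v = tracks[chrom].values
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v[s])}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> TrackSet:
    tracks = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 fields")
        chrom = parts[0]
        if chrom not in tracks:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            s, e, val = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed record") from exc
        if s < 0 or s >= e or e > chrom_sizes[chrom]:
            raise FormatError(f"{path}:{lineno}: interval out of bounds")
        tracks[chrom][s:e] = val
    return {c: OccupancyTrack(c, v) for c, v in tracks.items()}


def write_wiggle(tracks: TrackSet, path) -> None:
    """fixedStep wiggle at 1-bp resolution (1-based starts)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(_fmt(x) for x in tracks[chrom].values) + "\n")


def read_wiggle(path) -> TrackSet:
    tracks: dict[str, list[float]] = {}
    current: list[float] | None = None
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            if fields.get("start") != "1" or fields.get("step") != "1":
                raise FormatError(f"{path}:{lineno}: only start=1 step=1 supported")
            current = tracks.setdefault(fields["chrom"], [])
            continue
        if current is None:
            raise FormatError(f"{path}:{lineno}: data before fixedStep header")
        try:
            current.append(float(line))
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: bad value {line!r}") from e
    return {c: OccupancyTrack(c, np.array(v)) for c, v in tracks.items()}


# ---------------------------------------------------------------------------
# methylation TSV


def read_methylation(path) -> pd.DataFrame:
    """TSV with header: chrom, pos0 (0-based), context."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos0": np.int64, "context": str})
    missing = {"chrom", "pos0", "context"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df.rename(columns={"pos0": "pos"})


def write_methylation(sites: pd.DataFrame, path) -> None:
    out = sites.rename(columns={"pos": "pos0"})[["chrom", "pos0", "context"]]
    out.to_csv(path, sep="\t", index=False)


def write_nucleosomes_bed(nucleosomes: pd.DataFrame, path) -> None:
    """Called nucleosomes as BED6+2: name=nuc{i}, score=round(summit),
    strand '.', then dyad and mean NOS."""
    with open(path, "w") as fh:
        for i, row in nucleosomes.reset_index(drop=True).iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\tnuc{i}\t"
                f"{round(row['summit_nos'])}\t.\t{row['dyad']}\t{_fmt(row['mean_nos'])}\n"
            )


def read_nucleosomes_bed(path) -> pd.DataFrame:
    df = read_bed(path, n_fields=8)
    df = df.rename(columns={"thick_start": "dyad", "thick_end": "mean_nos"})
    df["dyad"] = df["dyad"].astype(np.int64)
    df["mean_nos"] = df["mean_nos"].astype(float)
    df["summit_nos"] = df["score"].astype(float)
    return df[["chrom", "dyad", "start", "end", "summit_nos", "mean_nos"]]
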