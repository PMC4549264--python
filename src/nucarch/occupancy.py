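"""Per-base nucleosome occupancy scores (NOS) and nucleosome calling.

An MNase-protected fragment is evidence for one nucleosome whose dyad sits
at the fragment midpoint.  The NOS of a base is the number of inferred
147-bp core particles (dyad +/- 73 bp) covering it, so a track built from
``n`` fragments sums to ``147 * n`` away from chromosome edges.  Nucleosomes
are called greedily from the track summit down, enforcing a minimum
inter-dyad spacing, which mirrors how occupancy-based callers resolve
overlapping evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

#: Width of the nucleosome core particle in bp.  Odd, so a unique dyad base
#: exists; the caller emits cores of exactly this width.
CORE_WIDTH = 147
CORE_HALF = CORE_WIDTH // 2  # 73


@dataclass
class OccupancyTrack:
    """Per-base NOS values for one chromosome.

    ``depth_factor`` records the cumulative scaling applied by
    :func:`normalize_tracks` (1.0 for raw counts).
    """

    chrom: str
    values: np.ndarray
    depth_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"{self.chrom}: NOS values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)


#: A genome-wide NOS map: chromosome name -> OccupancyTrack.
TrackSet = dict[str, OccupancyTrack]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation has no defined value (too few bins or
    zero variance)."""


def fragment_midpoints(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Inferred dyad of each fragment: floor of the midpoint.

    Even-length fragments have two central bases; the left one is used,
    consistently everywhere in the package.
    """
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    return (start + end - 1) // 2


def deduplicate_fragments(fragments: pd.DataFrame, max_copies: int = 1) -> pd.DataFrame:
    """Collapse clonal fragments (identical chrom/start/end) to at most
    ``max_copies`` occurrences, keeping input order.

    PCR amplifies single ligation events into many identical read pairs;
    capping exact-duplicate intervals removes that bias while leaving
    genuinely re-sampled, non-identical fragments untouched.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    copy_idx = fragments.groupby(["chrom", "start", "end"], sort=False).cumcount()
    return fragments.loc[copy_idx < max_copies].reset_index(drop=True)


def compute_nos(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    core_width: int = CORE_WIDTH,
) -> TrackSet:
    """Build raw (unnormalized) NOS tracks from fragment intervals.

    Each fragment contributes a dyad-centered core of ``core_width`` bp,
    clipped at chromosome ends.  Fragments on unknown chromosomes or outside
    chromosome bounds are rejected with a logged warning.
    """
    if core_width % 2 != 1:
        raise ValueError("core_width must be odd")
    half = core_width // 2
    tracks: TrackSet = {
        chrom: OccupancyTrack(chrom, np.zeros(size)) for chrom, size in chrom_sizes.items()
    }
    n_rejected = 0
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            n_rejected += len(sub)
            continue
        size = chrom_sizes[chrom]
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        ok = (start >= 0) & (end <= size) & (start < end)
        n_rejected += int((~ok).sum())
        dyads = fragment_midpoints(start[ok], end[ok])
        lo = np.clip(dyads - half, 0, size)
        hi = np.clip(dyads + half + 1, 0, size)
        diff = np.zeros(size + 1)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        tracks[chrom].values += np.cumsum(diff[:-1])
    if n_rejected:
        logger.warning("compute_nos: rejected %d out-of-bounds fragments", n_rejected)
    return tracks


def normalize_tracks(tracks: TrackSet, target_mean: float = 100.0) -> TrackSet:
    """Scale a dataset so its genome-wide mean NOS equals ``target_mean``.

    Returns new tracks; ``depth_factor`` accumulates the applied scale so a
    second call is a no-op (scale 1.0).  Raises on an all-zero dataset.
    """
    total = sum(t.values.sum() for t in tracks.values())
    n = sum(len(t) for t in tracks.values())
    if n == 0 or total == 0:
        raise ValueError("cannot normalize an all-zero dataset")
    scale = target_mean / (total / n)
    return {
        chrom: OccupancyTrack(chrom, t.values * scale, t.depth_factor * scale)
        for chrom, t in tracks.items()
    }


def _positioning_scores(
    values: np.ndarray, dyads: np.ndarray, summits: np.ndarray, bg_flank: int = 500
) -> np.ndarray:
    """Summit NOS divided by the mean NOS of the surrounding non-core
    background (dyad +/- bg_flank, excluding the core itself).

    A zero background yields +inf, which ranks above every finite score.
    """
    scores = np.empty(len(dyads))
    n = len(values)
    for i, (d, s) in enumerate(zip(dyads, summits)):
        lo = max(0, d - bg_flank)
        hi = min(n, d + bg_flank + 1)
        core_lo = max(lo, d - CORE_HALF)
        core_hi = min(hi, d + CORE_HALF + 1)
        total = values[lo:hi].sum() - values[core_lo:core_hi].sum()
        count = (hi - lo) - (core_hi - core_lo)
        if count <= 0 or total == 0:
            scores[i] = np.inf
        else:
            scores[i] = s / (total / count)
    return scores


def _call_chrom(
    values: np.ndarray, min_spacing: int, min_summit: float
) -> np.ndarray:
    """Greedy summit selection on one chromosome; returns sorted dyads.

    Repeatedly takes the highest remaining summit as a dyad and excludes
    [d - min_spacing + 1, d + min_spacing - 1] from further summit
    selection.  Distinct summits of equal height resolve leftmost; a flat
    summit plateau (ubiquitous in core-coverage NOS, where every base
    covered by the same fragment set scores identically) yields its
    midpoint, which is the maximum-likelihood dyad for the evidence.
    Implemented as non-maximum suppression over positions sorted by
    (value desc, position asc), which selects exactly the greedy set.
    """
    n = len(values)
    order = np.lexsort((np.arange(n), -values))
    excluded = np.zeros(n, dtype=bool)
    dyads: list[int] = []
    for p in order:
        if values[p] < min_summit:
            break
        if excluded[p]:
            continue
        # expand rightward over the contiguous equal-value plateau
        b = p
        while b + 1 < n and not excluded[b + 1] and values[b + 1] == values[p]:
            b += 1
        d = (p + b) // 2
        if d < CORE_HALF or d > n - CORE_HALF - 1:
            # a full 147-bp core must fit on the chromosome
            excluded[p : b + 1] = True
            continue
        dyads.append(int(d))
        lo = max(0, d - min_spacing + 1)
        hi = min(n, d + min_spacing)
        excluded[lo:hi] = True
        excluded[p : b + 1] = True
    return np.array(sorted(dyads), dtype=np.int64)


def call_nucleosomes(
    tracks: TrackSet | OccupancyTrack,
    min_spacing: int = 150,
    min_summit: float = 1.0,
    bg_flank: int = 500,
) -> pd.DataFrame:
    """Call nucleosomes from an NOS map.

    Returns a DataFrame sorted by (chrom, dyad) with columns ``chrom, dyad,
    start, end, summit_nos, mean_nos, positioning_score``.  Cores are
    ``start = dyad - 73``, ``end = dyad + 74`` (half-open, width 147) and
    consecutive dyads per chromosome are >= ``min_spacing`` apart.
    """
    if isinstance(tracks, OccupancyTrack):
        tracks = {tracks.chrom: tracks}
    if min_spacing < CORE_WIDTH:
        logger.warning(
            "min_spacing=%d < %d: called cores may overlap", min_spacing, CORE_WIDTH
        )
    out = []
    for chrom in tracks:
        values = tracks[chrom].values
        dyads = _call_chrom(values, min_spacing, min_summit)
        if len(dyads) == 0:
            continue
        summits = values[dyads]
        starts = dyads - CORE_HALF
        ends = dyads + CORE_HALF + 1
        csum = np.concatenate([[0.0], np.cumsum(values)])
        means = (csum[ends] - csum[starts]) / CORE_WIDTH
        scores = _positioning_scores(values, dyads, summits, bg_flank)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "dyad": dyads,
                    "start": starts,
                    "end": ends,
                    "summit_nos": summits,
                    "mean_nos": means,
                    "positioning_score": scores,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=[
                "chrom", "dyad", "start", "end",
                "summit_nos", "mean_nos", "positioning_score",
            ]
        )
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["chrom", "dyad"], kind="stable")
        .reset_index(drop=True)
    )


def binned_pcc(
    track_a: TrackSet,
    track_b: TrackSet,
    bin: int = 10,
    mask: pd.DataFrame | None = None,
) -> float:
    """Pearson correlation of two NOS maps after masking and binning.

    Masked bases (``mask``: BED-like DataFrame with chrom/start/end) are
    dropped; the rest are averaged in fixed ``bin``-bp windows anchored at
    coordinate 0, and the correlation is computed over the concatenated
    bins of the shared chromosomes.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    chroms = [c for c in track_a if c in track_b]
    if set(track_a) != set(track_b):
        raise ValueError("track sets cover different chromosomes")
    xs, ys = [], []
    for chrom in chroms:
        a = track_a[chrom].values
        b = track_b[chrom].values
        if len(a) != len(b):
            raise ValueError(f"{chrom}: track lengths differ")
        usable = np.ones(len(a), dtype=bool)
        if mask is not None:
            for _, row in mask[mask["chrom"] == chrom].iterrows():
                usable[max(0, int(row["start"])) : int(row["end"])] = False
        idx = np.arange(len(a)) // bin
        n_bins = int(idx[-1]) + 1 if len(a) else 0
        counts = np.bincount(idx, weights=usable, minlength=n_bins)
        keep = counts > 0
        if not keep.any():
            continue
        sums_a = np.bincount(idx, weights=a * usable, minlength=n_bins)
        sums_b = np.bincount(idx, weights=b * usable, minlength=n_bins)
        xs.append(sums_a[keep] / counts[keep])
        ys.append(sums_b[keep] / counts[keep])
    if not xs:
        raise UndefinedCorrelationError("no usable bins after masking")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: fewer than 2 usable bins or zero variance"
        )
    return float(pearsonr(x, y)[0])
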