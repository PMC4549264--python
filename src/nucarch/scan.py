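"""Enhancer-like nucleosome architecture scanning.

Transcription-factor binding displaces a nucleosome and leaves a
stereotyped footprint in the occupancy map: a depleted trough between two
well-positioned nucleosomes, themselves embedded in a positioned array.
This module scores positioning, scans called nucleosomes for that
pattern, and extracts candidate sequences for downstream motif discovery.
All numeric thresholds are explicit in :class:`ScanConfig`; the pattern
is defined by shape ratios, so the scan is invariant under uniform
scaling of the track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import TrackSet, _positioning_scores

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "chrom", "center", "window_start", "window_end",
    "left_dyad", "right_dyad", "flank_support", "trough_nos", "score",
]


@dataclass
class ScanConfig:
    """Thresholds defining the enhancer-like pattern.

    pos_score_min: minimum positioning score (summit over local non-core
        background) for a nucleosome to count as well-positioned.
    gap_range: allowed inter-dyad distance of the flanking pair, bp.
    trough_frac_max: the gap's minimum NOS must be at most this fraction
        of the smaller flanking summit.
    min_flank_support: additional well-positioned nucleosomes required
        within flank_search_bp on each outer side.
    """

    pos_score_min: float = 2.0
    gap_range: tuple[int, int] = (250, 600)
    trough_frac_max: float = 0.5
    min_flank_support: int = 1
    flank_search_bp: int = 450

    def __post_init__(self) -> None:
        if self.pos_score_min < 1:
            raise ValueError("pos_score_min must be >= 1")
        if self.gap_range[0] <= 147:
            raise ValueError("gap_range minimum must exceed the 147-bp core width")
        if not 0 < self.trough_frac_max <= 1:
            raise ValueError("trough_frac_max must be in (0, 1]")


def positioning_score(
    track: TrackSet, chrom: str, dyad: int, bg_flank: int = 500
) -> float:
    """Summit NOS over the mean non-core NOS within dyad +/- bg_flank.

    1.0 on a flat track; +inf (ranked above all finite scores) when the
    background is empty.  The window is truncated at chromosome ends.
    """
    values = track[chrom].values
    summit = values[dyad]
    return float(
        _positioning_scores(values, np.array([dyad]), np.array([summit]), bg_flank)[0]
    )


def find_patterns(
    nucleosomes: pd.DataFrame, track: TrackSet, config: ScanConfig | None = None
) -> pd.DataFrame:
    """Scan adjacent called-nucleosome pairs for the depleted-region-
    flanked-by-positioned-nucleosomes pattern.

    For each adjacent pair with both positioning scores >=
    ``pos_score_min``, an inter-dyad gap inside ``gap_range`` and a gap
    trough at most ``trough_frac_max`` of the smaller summit, the pattern
    requires ``min_flank_support`` further well-positioned nucleosomes
    within ``flank_search_bp`` on each outer side.  Hits are emitted at
    the trough midpoint with score ``mean(pair scores) * (1 -
    trough/min(summits))``, sorted by score; overlapping 200-bp windows
    are deduplicated keeping the higher score.
    """
    config = config or ScanConfig()
    if len(nucleosomes) == 0:
        return pd.DataFrame(columns=HIT_COLUMNS)
    hits = []
    for chrom, sub in nucleosomes.groupby("chrom", sort=False):
        sub = sub.sort_values("dyad")
        dyads = sub["dyad"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        summits = sub["summit_nos"].to_numpy(float)
        scores = sub["positioning_score"].to_numpy(float)
        values = track[chrom].values
        well = scores >= config.pos_score_min
        well_dyads = dyads[well]
        for i in range(len(sub) - 1):
            gap = dyads[i + 1] - dyads[i]
            if not (config.gap_range[0] <= gap <= config.gap_range[1]):
                continue
            if not (well[i] and well[i + 1]):
                continue
            lo, hi = ends[i], starts[i + 1]
            if hi <= lo:
                continue
            region = values[lo:hi]
            trough = float(region.min())
            min_summit = float(min(summits[i], summits[i + 1]))
            if min_summit <= 0 or trough > config.trough_frac_max * min_summit:
                continue
            left_support = int(
                np.sum((well_dyads >= dyads[i] - config.flank_search_bp) & (well_dyads < dyads[i]))
            )
            right_support = int(
                np.sum((well_dyads > dyads[i + 1]) & (well_dyads <= dyads[i + 1] + config.flank_search_bp))
            )
            if min(left_support, right_support) < config.min_flank_support:
                continue
            at_min = np.flatnonzero(region == trough)
            center = int(lo + (at_min[0] + at_min[-1]) // 2)
            pair_score = float(np.mean([scores[i], scores[i + 1]]))
            score = pair_score * (1.0 - trough / min_summit)
            hits.append(
                {
                    "chrom": chrom,
                    "center": center,
                    "window_start": center - 100,
                    "window_end": center + 100,
                    "left_dyad": int(dyads[i]),
                    "right_dyad": int(dyads[i + 1]),
                    "flank_support": left_support + right_support,
                    "trough_nos": trough,
                    "score": score,
                }
            )
    if not hits:
        return pd.DataFrame(columns=HIT_COLUMNS)
    df = pd.DataFrame(hits).sort_values("score", ascending=False, kind="stable")
    kept: list[int] = []
    kept_windows: dict[str, list[tuple[int, int]]] = {}
    for idx, row in df.iterrows():
        wins = kept_windows.setdefault(row["chrom"], [])
        if any(row["window_start"] < e and row["window_end"] > s for s, e in wins):
            continue
        wins.append((row["window_start"], row["window_end"]))
        kept.append(idx)
    return df.loc[kept].reset_index(drop=True)


def extract_hit_sequences(
    genome: dict[str, np.ndarray], hits: pd.DataFrame, size: int = 200
) -> list[tuple[str, str]]:
    """FASTA-ready (name, sequence) records of ``size`` bp around each hit
    center, named ``chrom:start-end``.  Windows extending past a
    chromosome end are dropped and logged."""
    records = []
    n_dropped = 0
    for _, h in hits.iterrows():
        seq = genome[h["chrom"]]
        start = int(h["center"]) - size // 2
        end = start + size
        if start < 0 or end > len(seq):
            n_dropped += 1
            continue
        window = bytes(seq[start:end]).decode("ascii").upper()
        records.append((f"{h['chrom']}:{start}-{end}", window))
    if n_dropped:
        logger.warning("extract_hit_sequences: dropped %d boundary windows", n_dropped)
    return records
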