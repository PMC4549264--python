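"""Methylation-nucleosome geometry and occupancy stratification.

Covers the per-nucleosome methylation census (how many calls of each
context fall inside each called core), occupancy stratified by that count
with Kruskal-Wallis / pairwise Mann-Whitney rank tests under Bonferroni
correction, signed distance-to-dyad histograms per context, their in-core
periodicity, methylation-centered occupancy profiles, and the
high-occupancy mCG subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .occupancy import CORE_HALF, TrackSet
from .profiles import aggregate_profile
from .sequence import Periodogram, fft_periodogram

logger = logging.getLogger(__name__)

CONTEXTS = ("mCG", "mCHG", "mCHH", "hmC")


@dataclass
class StratifiedOccupancy:
    context: str
    table: pd.DataFrame  # label, n, mean_nos
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, raw_p, bonferroni_p


@dataclass
class DyadDistanceHistogram:
    context: str
    offsets: np.ndarray
    frequency_percent: np.ndarray  # sums to 100 over the reported range
    n_sites: int  # sites inside the range
    n_excluded: int  # sites beyond the range


def ingest_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate contexts and drop mCG calls that were re-called as hmC.

    Bisulfite conversion cannot distinguish 5mC from 5hmC, so a position
    present in both the mCG and hmC sets is kept only as hmC.
    """
    bad = set(sites["context"]) - set(CONTEXTS)
    if bad:
        raise ValueError(f"unknown methylation contexts: {sorted(bad)}")
    hmc = sites.loc[sites["context"] == "hmC", ["chrom", "pos"]]
    key = set(zip(hmc["chrom"], hmc["pos"]))
    shadowed = np.array(
        [(c, p) in key for c, p in zip(sites["chrom"], sites["pos"])], dtype=bool
    )
    drop = (sites["context"] == "mCG").to_numpy() & shadowed
    if drop.any():
        logger.info("ingest_sites: removed %d mCG calls shadowed by hmC", int(drop.sum()))
    return sites[~drop].reset_index(drop=True)


def assign_sites_to_nucleosomes(
    sites: pd.DataFrame, nucleosomes: pd.DataFrame
) -> pd.DataFrame:
    """Per-nucleosome context counts; a site belongs to a nucleosome iff
    its position is inside the half-open core [start, end).

    Cores from a caller with min_spacing >= 147 never overlap, so each
    site lands in at most one nucleosome; linker sites belong to none.
    Returns a copy of ``nucleosomes`` with one count column per context.
    """
    out = nucleosomes.reset_index(drop=True).copy()
    for ctx in CONTEXTS:
        out[f"n_{ctx}"] = 0
    for chrom, nsub in out.groupby("chrom", sort=False):
        starts = nsub["start"].to_numpy()
        ends = nsub["end"].to_numpy()
        ssub = sites[sites["chrom"] == chrom]
        if len(ssub) == 0 or len(nsub) == 0:
            continue
        pos = ssub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        for ctx in CONTEXTS:
            mask = valid & (ssub["context"].to_numpy() == ctx)
            counts = np.bincount(idx[mask], minlength=len(nsub))
            out.loc[nsub.index, f"n_{ctx}"] += counts
    return out


def occupancy_by_count(
    assigned: pd.DataFrame,
    context: str,
    max_bucket: int = 4,
    value_column: str = "mean_nos",
) -> StratifiedOccupancy:
    """Mean occupancy per methylation-count bucket with rank statistics.

    Buckets are 0, 1, ..., max_bucket-1 and ``{max_bucket}+`` (the open
    top bucket keeps the sparse tail testable).  Occupancy is the core
    mean NOS by default.  A Kruskal-Wallis test runs across all nonempty
    buckets, followed by every pairwise two-sided Mann-Whitney test with
    Bonferroni correction over that family.
    """
    col = f"n_{context}"
    if col not in assigned.columns:
        raise ValueError(f"no counts for context {context!r}; run assign_sites_to_nucleosomes")
    counts = assigned[col].to_numpy()
    labels = np.where(
        counts >= max_bucket, f"{max_bucket}+", counts.astype(str)
    )
    order = [str(i) for i in range(max_bucket)] + [f"{max_bucket}+"]
    groups = {
        lab: assigned.loc[labels == lab, value_column].to_numpy()
        for lab in order
        if (labels == lab).any()
    }
    if len(groups) < 2:
        raise ValueError(
            f"degenerate stratification: only bucket(s) {sorted(groups)} are nonempty"
        )
    table = pd.DataFrame(
        {
            "label": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean_nos": [float(v.mean()) for v in groups.values()],
        }
    )
    kw_p = float(kruskal(*groups.values()).pvalue)
    pairs = []
    names = list(groups)
    n_comp = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(
                mannwhitneyu(
                    groups[names[i]], groups[names[j]], alternative="two-sided"
                ).pvalue
            )
            pairs.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "raw_p": p,
                    "bonferroni_p": min(1.0, p * n_comp),
                }
            )
    return StratifiedOccupancy(
        context=context, table=table, kw_p=kw_p, pairwise=pd.DataFrame(pairs)
    )


def distance_to_nearest_dyad(
    sites: pd.DataFrame,
    dyads,
    context: str | None = None,
    range_bp: int = CORE_HALF,
) -> DyadDistanceHistogram:
    """Signed distance from each site to its nearest dyad, as a frequency-
    percent histogram over -range_bp..+range_bp.

    Positive means the site lies downstream (higher coordinate) of the
    dyad.  A site exactly midway between two dyads is assigned to the
    downstream dyad, giving a negative distance.  Sites beyond the range
    are excluded from the histogram but counted.
    """
    from .sequence import _dyads_per_chrom

    by_chrom = _dyads_per_chrom(dyads)
    if not any(len(v) for v in by_chrom.values()):
        raise ValueError("no dyads supplied")
    sub = sites if context is None else sites[sites["context"] == context]
    dists = []
    for chrom, ssub in sub.groupby("chrom", sort=False):
        d = np.sort(by_chrom.get(chrom, np.array([], dtype=np.int64)))
        if len(d) == 0:
            continue
        pos = ssub["pos"].to_numpy(np.int64)
        i = np.searchsorted(d, pos)
        left = d[np.clip(i - 1, 0, len(d) - 1)]
        right = d[np.clip(i, 0, len(d) - 1)]
        dl = np.where(i > 0, pos - left, np.iinfo(np.int64).max)
        dr = np.where(i < len(d), right - pos, np.iinfo(np.int64).max)
        # tie -> the downstream dyad, i.e. the negative signed distance
        use_right = dr <= dl
        signed = np.where(use_right, pos - right, pos - left)
        dists.append(signed)
    signed = np.concatenate(dists) if dists else np.array([], dtype=np.int64)
    offsets = np.arange(-range_bp, range_bp + 1)
    in_range = np.abs(signed) <= range_bp
    n_in = int(in_range.sum())
    counts = np.bincount(signed[in_range] + range_bp, minlength=len(offsets)).astype(float)
    percent = counts / n_in * 100.0 if n_in else counts
    return DyadDistanceHistogram(
        context=context or "all",
        offsets=offsets,
        frequency_percent=percent,
        n_sites=n_in,
        n_excluded=int(len(signed) - n_in),
    )


def methylation_periodogram(
    hist: DyadDistanceHistogram, band: tuple[float, float] = (2.0, 20.0)
) -> Periodogram:
    """In-core periodicity of a methylation placement histogram."""
    return fft_periodogram(hist.frequency_percent, band=band)


def methylation_centered_nos(
    track: TrackSet, sites: pd.DataFrame, context: str, flank: int = 500
) -> np.ndarray:
    """Mean NOS profile around sites of one context (strandless features)."""
    sub = sites[sites["context"] == context]
    feats = [(c, p) for c, p in zip(sub["chrom"], sub["pos"])]
    return aggregate_profile(track, feats, flank=flank)


def high_occupancy_subset(
    sites: pd.DataFrame,
    nucleosomes: pd.DataFrame,
    threshold: float | str = "auto",
    context: str = "mCG",
    range_bp: int = CORE_HALF,
) -> tuple[DyadDistanceHistogram, float]:
    """Distance-to-dyad histogram restricted to sites inside nucleosomes
    whose summit NOS exceeds ``threshold``.

    ``threshold="auto"`` uses the mean summit NOS of all called
    nucleosomes — the dataset-relative version of an absolute "average
    peak signal" cutoff, so it transfers across sequencing depths.
    Returns the histogram and the threshold used.
    """
    if threshold == "auto":
        threshold = float(nucleosomes["summit_nos"].mean())
    high = nucleosomes[nucleosomes["summit_nos"] > threshold]
    if len(high) == 0:
        raise ValueError(f"no nucleosomes above summit threshold {threshold}")
    assigned = assign_sites_to_nucleosomes(sites[sites["context"] == context], high)
    # recompute the per-site signed distances against the retained dyads only,
    # keeping only sites that actually fall inside a retained core
    sub = sites[sites["context"] == context]
    keep = []
    for chrom, ssub in sub.groupby("chrom", sort=False):
        hsub = high[high["chrom"] == chrom]
        if len(hsub) == 0:
            continue
        starts = hsub["start"].to_numpy()
        ends = hsub["end"].to_numpy()
        pos = ssub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        keep.append(ssub[inside])
    if not keep:
        raise ValueError("no in-core sites above the threshold")
    kept = pd.concat(keep)
    hist = distance_to_nearest_dyad(kept, high, context=context, range_bp=range_bp)
    return hist, float(threshold)
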