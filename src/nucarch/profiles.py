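"""Feature-centered occupancy metaprofiles, expression strata and clustering.

Profiles are strand-aware: rows for minus-strand features are reversed
before any averaging so positive offsets always point downstream in the
direction of transcription.  TSS profile matrices are row-max scaled
before k-means so clusters reflect architecture (where the nucleosomes
sit) rather than absolute depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .occupancy import OccupancyTrack, TrackSet

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    ids: list
    offsets: np.ndarray  # -F..+F
    values: np.ndarray  # rows x offsets
    oriented: bool  # True once minus-strand rows have been reversed


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # feature id -> cluster
    centroids: np.ndarray  # k x width, on the row-max-scaled scale
    max_nos_location: np.ndarray  # per cluster, offset of the centroid maximum


def build_rna_signal(plus: TrackSet, minus: TrackSet) -> TrackSet:
    """Total RNA signal: per-base sum of the two strands after scaling each
    nonzero strand to the mean of their totals.

    Transcription is stranded but nucleosomes are not, so both strands are
    pooled; the pre-scaling makes the combination robust to unequal strand
    library depths.  A strand with zero total signal is left untouched.
    """
    if set(plus) != set(minus):
        raise ValueError("plus and minus tracks cover different chromosomes")
    tot_p = sum(t.values.sum() for t in plus.values())
    tot_m = sum(t.values.sum() for t in minus.values())
    nonzero = [t for t in (tot_p, tot_m) if t > 0]
    target = float(np.mean(nonzero)) if nonzero else 0.0
    sp = target / tot_p if tot_p > 0 else 1.0
    sm = target / tot_m if tot_m > 0 else 1.0
    return {
        c: OccupancyTrack(c, plus[c].values * sp + minus[c].values * sm) for c in plus
    }


def total_expression(gene: pd.Series, rna: TrackSet) -> float:
    """Sum of combined RNA signal over the gene span (strand-agnostic)."""
    lo = int(min(gene["tss"], gene["tts"]))
    hi = int(max(gene["tss"], gene["tts"])) + 1
    values = rna[gene["chrom"]].values
    return float(values[max(0, lo) : hi].sum())


def quartile_split(values) -> np.ndarray:
    """Rank-based quartile labels Q1 (lowest) .. Q4, ties broken by stable
    input order."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for quartiles")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(len(values))
    labels = np.array([f"Q{q + 1}" for q in (4 * ranks) // len(values)])
    return labels


def classify_silent(genes: pd.DataFrame, rna: TrackSet, eps: float = 0.0) -> set[str]:
    """Genes whose mean combined signal over the flanked span
    (span +/- 500 bp) is <= eps."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    silent = set()
    for _, g in genes.iterrows():
        lo = int(min(g["tss"], g["tts"])) - 500
        hi = int(max(g["tss"], g["tts"])) + 1 + 500
        values = rna[g["chrom"]].values
        window = values[max(0, lo) : hi]
        if len(window) == 0 or window.mean() <= eps:
            silent.add(g["name"])
    return silent


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        df = features.copy()
        if "pos" not in df.columns:
            if "tss" in df.columns:
                df["pos"] = df["tss"]
            else:
                df["pos"] = (df["start"] + df["end"] - 1) // 2
        if "strand" not in df.columns:
            df["strand"] = "."
        if "name" not in df.columns:
            df["name"] = [f"f{i}" for i in range(len(df))]
        return df[["name", "chrom", "pos", "strand"]]
    rows = []
    for i, feat in enumerate(features):
        chrom, pos = feat[0], feat[1]
        strand = feat[2] if len(feat) > 2 else "."
        rows.append({"name": f"f{i}", "chrom": chrom, "pos": int(pos), "strand": strand})
    return pd.DataFrame(rows)


def profile_matrix(track: TrackSet, features, flank: int = 1000) -> ProfileMatrix:
    """NOS slices of width 2*flank+1 around each feature, minus-strand rows
    reversed.  Features within ``flank`` of a chromosome boundary are
    dropped and counted in the log."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    df = _as_feature_frame(features)
    rows, ids = [], []
    n_dropped = 0
    for _, f in df.iterrows():
        values = track[f["chrom"]].values
        p = int(f["pos"])
        if p - flank < 0 or p + flank + 1 > len(values):
            n_dropped += 1
            continue
        window = values[p - flank : p + flank + 1]
        if f["strand"] == "-":
            window = window[::-1]
        rows.append(window)
        ids.append(f["name"])
    if not rows:
        raise ValueError("no usable features (all within flank of a boundary)")
    if n_dropped:
        logger.warning("profile_matrix: dropped %d boundary-proximal features", n_dropped)
    return ProfileMatrix(
        ids=ids,
        offsets=np.arange(-flank, flank + 1),
        values=np.vstack(rows),
        oriented=True,
    )


def aggregate_profile(track: TrackSet, features, flank: int = 1000) -> np.ndarray:
    """Mean oriented NOS profile over the usable features."""
    return profile_matrix(track, features, flank).values.mean(axis=0)


def normalize_by_reference(
    mat: ProfileMatrix, ref: ProfileMatrix, pseudo: float = 1.0
) -> np.ndarray:
    """Mean per-gene ratio profile (signal + pseudo) / (reference + pseudo).

    Dividing each gene's profile by its sequence-driven reference isolates
    what the cellular machinery changes about the ground state.  Genes
    missing from the reference are dropped with a warning.
    """
    ref_rows = {fid: i for i, fid in enumerate(ref.ids)}
    ratios = []
    n_dropped = 0
    for i, fid in enumerate(mat.ids):
        j = ref_rows.get(fid)
        if j is None:
            n_dropped += 1
            continue
        ratios.append((mat.values[i] + pseudo) / (ref.values[j] + pseudo))
    if n_dropped:
        logger.warning("normalize_by_reference: dropped %d genes absent from reference", n_dropped)
    if not ratios:
        raise ValueError("no genes shared between signal and reference")
    return np.mean(ratios, axis=0)


def kmeans_profiles(
    mat: ProfileMatrix, k: int = 10, n_init: int = 10, seed: int = 0
) -> ClusterResult:
    """Euclidean k-means on row-max-scaled profiles.

    Scaling each row by its own maximum makes clusters group genes by the
    location of their dominant nucleosome rather than by expression-linked
    depth.  All-zero rows cannot be scaled and are dropped with a warning.
    """
    nonzero = mat.values.max(axis=1) > 0
    if int(nonzero.sum()) < k:
        raise ValueError(f"need at least k={k} nonzero rows, have {int(nonzero.sum())}")
    if (~nonzero).any():
        logger.warning("kmeans_profiles: dropped %d all-zero rows", int((~nonzero).sum()))
    X = mat.values[nonzero]
    X = X / X.max(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    ids = [fid for fid, keep in zip(mat.ids, nonzero) if keep]
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=ids, name="cluster"),
        centroids=km.cluster_centers_,
        max_nos_location=mat.offsets[np.argmax(km.cluster_centers_, axis=1)],
    )


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    return np.convolve(values, kernel, mode="same")


def plus_one_location(
    profile: np.ndarray, search: tuple[int, int] = (0, 300), smooth: int = 5
) -> int:
    """Offset of the +1 nucleosome: first local maximum of the smoothed
    profile strictly downstream of the TSS, within ``search``.

    The profile is an oriented TSS metaprofile with offset 0 at the center
    index; a 5-bp moving average suppresses single-base noise before the
    first downturn is located.
    """
    center = len(profile) // 2
    v = _smooth(np.asarray(profile, float), smooth)
    lo, hi = search
    for off in range(max(lo, 0) + 1, hi + 1):
        i = center + off
        if i + 1 >= len(v):
            break
        if v[i] >= v[i - 1] and v[i] > v[i + 1]:
            return off
    raise ValueError(f"no local maximum in ({lo}, {hi}]")


def plus_one_shift(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    search: tuple[int, int] = (0, 300),
    smooth: int = 5,
) -> int:
    """Downstream shift of the +1 nucleosome from profile A to profile B."""
    return plus_one_location(profile_b, search, smooth) - plus_one_location(
        profile_a, search, smooth
    )


def active_site_filter(
    tfbs: pd.DataFrame,
    dnase: TrackSet,
    nos: TrackSet,
    q_dnase: float = 0.75,
    q_nos: float = 0.25,
) -> pd.DataFrame:
    """Bound (active) sites: high accessibility and low occupancy.

    A site is active iff its mean DNase signal is >= the ``q_dnase``
    quantile of per-site means AND its mean NOS is <= the ``q_nos``
    quantile, both thresholds inclusive.  Returns the active subset of
    ``tfbs`` with the per-site means attached.
    """
    if len(tfbs) == 0:
        return tfbs.copy()
    d_means, n_means = [], []
    for _, s in tfbs.iterrows():
        lo, hi = int(s["start"]), int(s["end"])
        d_means.append(float(dnase[s["chrom"]].values[lo:hi].mean()))
        n_means.append(float(nos[s["chrom"]].values[lo:hi].mean()))
    d_means = np.array(d_means)
    n_means = np.array(n_means)
    active = (d_means >= np.quantile(d_means, q_dnase)) & (
        n_means <= np.quantile(n_means, q_nos)
    )
    out = tfbs.copy()
    out["dnase_mean"] = d_means
    out["nos_mean"] = n_means
    return out[active].reset_index(drop=True)
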