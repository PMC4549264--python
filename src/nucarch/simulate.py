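"""Synthetic MNase-seq landscapes with known ground truth.

The generator emulates the observable structure the analysis modules are
built to recover: a genome whose nucleosome cores carry ~10-bp periodic
AA/TT dinucleotides and elevated G+C content, a nucleosome landscape of
well-positioned and fuzzy particles phased at a fixed repeat length with
depleted regions at transcription start sites (TSS) and at planted
enhancer sites, paired-end mononucleosomal fragments sampled around the
true dyads with size jitter and PCR duplicates, cytosine methylation
placed with dyad-coupled geometry, and stranded RNA signal consistent
with assigned expression tiers.

Everything derives deterministically from ``SimConfig.seed`` through named
substreams, so any single stage can be regenerated bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .occupancy import CORE_HALF, CORE_WIDTH, OccupancyTrack, TrackSet

# ASCII codes used for genome arrays throughout the package.
A, C, G, T = 65, 67, 71, 84
_BASES = np.array([A, C, G, T], dtype=np.uint8)

CONTEXTS = ("mCG", "mCHG", "mCHH", "hmC")

# Substream tags: every stage draws from default_rng([seed, tag]).
_S_LAYOUT, _S_GENOME, _S_FRAGMENTS, _S_RNA, _S_METH = 11, 12, 13, 14, 15

#: Dyad offsets spanning the core particle, -73..+73.
CORE_OFFSETS = np.arange(-CORE_HALF, CORE_HALF + 1)


def _gaussian(center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((CORE_OFFSETS - center) / sd) ** 2)


def default_meth_dyad_profiles() -> dict[str, np.ndarray]:
    """Dyad-relative placement densities over offsets -73..+73.

    mCG favors the dyad and +/- 40 bp, the three strongest histone-DNA
    contact regions; mCHG sits further out toward the core edges; mCHH is
    flat in-core (it mostly lives in linkers, controlled separately by the
    linker weight); hmC is a broad central preference.  Each row is
    normalized to sum to 1 over the 147 offsets.
    """
    profiles = {
        "mCG": 0.30 * _gaussian(0, 6) + 0.35 * _gaussian(-40, 6) + 0.35 * _gaussian(40, 6),
        "mCHG": 0.5 * _gaussian(-55, 8) + 0.5 * _gaussian(55, 8),
        "mCHH": np.ones(CORE_WIDTH),
        "hmC": _gaussian(0, 25),
    }
    return {k: v / v.sum() for k, v in profiles.items()}


@dataclass
class SimConfig:
    """Study conditions for the synthetic landscape.

    Scale defaults (2 chromosomes x 1 Mb, ~10,000 nucleosomes implied by
    the repeat length, 200,000 fragments) are large enough for stable FFT
    and clustering estimates while keeping a full run in the minutes
    range.  The 147-bp core, 151-bp mean fragment and 10-bp dinucleotide
    period are the canonical mononucleosome values; the nucleosome repeat
    length of 185 bp is typical for human chromatin.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 2
    gc_background: float = 0.40
    core_gc_boost: float = 0.10
    core_width: int = CORE_WIDTH
    periodic_dinucleotide_period: float = 10.0
    periodic_amplitude: float = 0.6
    periodic_placement_rate: float = 0.2
    nrl: int = 185
    frag_len_mean: float = 151.0
    frag_len_sd: float = 15.0
    jitter_sd_positioned: float = 10.0
    jitter_sd_fuzzy: float = 22.0
    positioned_fraction: float = 0.7
    dup_rate: float = 0.10
    n_fragments: int = 400_000
    domain_bp: int = 50_000
    domain_log_sd: float = 0.6
    n_genes: int = 200
    n_profile_classes: int = 10
    n_enhancers: int = 40
    expression_tiers: tuple[float, ...] = (0.0, 1.0, 4.0, 16.0)
    meth_density_by_context: dict[str, float] = field(
        default_factory=lambda: {"mCG": 0.045, "mCHG": 0.012, "mCHH": 0.012, "hmC": 0.006}
    )
    meth_linker_weight: dict[str, float] = field(
        default_factory=lambda: {"mCG": 0.10, "mCHG": 0.15, "mCHH": 0.85, "hmC": 0.25}
    )
    meth_dyad_profile: dict[str, np.ndarray] = field(default_factory=default_meth_dyad_profiles)
    meth_occupancy_coupling: float = 1.0
    meth_dyad_sharpening: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chroms <= 0 or self.nrl <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.core_width % 2 != 1:
            raise ValueError("core_width must be odd (unique central dyad base)")
        for name in ("gc_background", "periodic_amplitude", "positioned_fraction", "dup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frag_len_mean <= 0 or self.frag_len_sd < 0:
            raise ValueError("fragment length parameters must be nonnegative")
        if self.n_profile_classes > self.n_genes:
            raise ValueError("n_profile_classes cannot exceed n_genes")
        if 0.0 not in self.expression_tiers:
            raise ValueError("expression_tiers must include 0 for silent genes")
        for ctx, prof in self.meth_dyad_profile.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (self.core_width,):
                raise ValueError(f"{ctx}: dyad profile must have {self.core_width} offsets")
            if np.any(prof < 0) or not np.isclose(prof.sum(), 1.0):
                raise ValueError(f"{ctx}: dyad profile must be nonnegative and sum to 1")
            self.meth_dyad_profile[ctx] = prof
        # sizing: each gene slot must hold a gene span plus its flanks
        if self.genome_length * self.n_chroms < self.n_genes * 8_000:
            raise ValueError(
                "genome too small for the requested number of genes "
                f"({self.n_genes} genes need ~{self.n_genes * 8} kb)"
            )


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the synthetic data."""

    nucleosomes: pd.DataFrame  # chrom, dyad, klass, weight, jitter_sd, origin
    genes: pd.DataFrame  # name, chrom, start, end, strand, tss, tts, klass, tier_index, tier
    enhancers: pd.DataFrame  # chrom, start, end, center
    class_offsets: dict[int, int]  # profile class -> signed TSS-relative anchor offset
    methylation_truth: dict


# ---------------------------------------------------------------------------
# landscape layout


#: Signed TSS-relative dyad offsets (transcription direction) of the
#: dominant nucleosome for each of the 10 default architecture classes:
#: five downstream (+1-like) and five upstream (-1-like) placements.
def _class_offsets(n_classes: int) -> dict[int, int]:
    offsets = {}
    for c in range(n_classes):
        rank = c // 2
        side = 1 if c % 2 == 0 else -1
        offsets[c] = side * (60 + 45 * rank)
    return offsets


def _layout(config: SimConfig) -> TruthBundle:
    """Deterministic landscape: genes, enhancers and true nucleosomes.

    Genes occupy disjoint slots along each chromosome so TSSs are unique
    by construction.  Each gene's architecture class fixes the offset of a
    strongly positioned anchor nucleosome relative to its TSS; a weak
    "filler" nucleosome on the opposite side of the TSS shallows or
    deepens the depleted region depending on the expression tier.
    Enhancers are depleted regions flanked by two strongly positioned
    nucleosomes 400 bp apart with one further positioned support on each
    side.  The rest of the genome is tiled at the nucleosome repeat
    length, skipping reserved zones.
    """
    rng = np.random.default_rng([config.seed, _S_LAYOUT])
    L = config.genome_length
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    class_offsets = _class_offsets(config.n_profile_classes)
    n_tiers = len(config.expression_tiers)

    genes_per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        genes_per_chrom[i] += 1
    enh_per_chrom = [config.n_enhancers // config.n_chroms] * config.n_chroms
    for i in range(config.n_enhancers % config.n_chroms):
        enh_per_chrom[i] += 1

    # balanced class and tier assignment, shuffled across genes
    klasses = np.arange(config.n_genes) % config.n_profile_classes
    tiers = np.arange(config.n_genes) % n_tiers
    rng.shuffle(klasses)
    rng.shuffle(tiers)

    gene_rows, enh_rows, nuc_rows = [], [], []
    margin = 2_000
    gi = 0
    for ci, chrom in enumerate(chroms):
        ng = genes_per_chrom[ci]
        slot = (L - 2 * margin) // max(ng, 1)
        if ng and slot < 8_000:
            raise ValueError("genome_length too small to hold the requested genes")
        gene_ends = []
        for s in range(ng):
            slot_start = margin + s * slot
            span = int(rng.integers(2_500, 5_001))
            start = slot_start + int(rng.integers(0, 1_000))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            tts = end - 1 if strand == "+" else start
            klass = int(klasses[gi])
            tier_idx = int(tiers[gi])
            gene_rows.append(
                {
                    "name": f"gene{gi}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": tss,
                    "tts": tts,
                    "klass": klass,
                    "tier_index": tier_idx,
                    "tier": config.expression_tiers[tier_idx],
                }
            )
            sign = 1 if strand == "+" else -1
            off = class_offsets[klass]
            anchor = tss + sign * off
            # weak particle on the opposite side of the TSS from the anchor
            filler = tss - sign * (120 if off > 0 else -120)
            tier_frac = tier_idx / max(n_tiers - 1, 1)
            anchor_w = 1.8 + 1.4 * tier_frac
            anchor_sd = config.jitter_sd_positioned * (1.4 - 0.4 * tier_frac)
            filler_w = 0.8 * 0.5 ** tier_idx
            nuc_rows.append((chrom, anchor, "positioned", anchor_w, anchor_sd, "tss_anchor"))
            nuc_rows.append((chrom, filler, "fuzzy", filler_w, config.jitter_sd_fuzzy, "ndr_filler"))
            gene_ends.append((start, end, tss))
            gi += 1

        # enhancers midway between consecutive gene spans
        n_enh = enh_per_chrom[ci]
        placed = 0
        for s in range(len(gene_ends) - 1):
            if placed >= n_enh:
                break
            gap_lo = gene_ends[s][1] + 800
            gap_hi = gene_ends[s + 1][0] - 800
            if gap_hi - gap_lo < 1_400:
                continue
            center = (gap_lo + gap_hi) // 2
            enh_rows.append({"chrom": chrom, "start": center - 100, "end": center + 100, "center": center})
            # flanking pair around the depleted center, plus one support per
            # side separated by a secondary depleted gap (240 bp inter-dyad)
            for d, w, origin in (
                (center - 250, 2.8, "enh_flank"),
                (center + 250, 2.8, "enh_flank"),
                (center - 490, 2.4, "enh_support"),
                (center + 490, 2.4, "enh_support"),
            ):
                nuc_rows.append(
                    (chrom, d, "positioned", w, 0.5 * config.jitter_sd_positioned, origin)
                )
            placed += 1
        if placed < n_enh:
            raise ValueError("genome_length too small to place the requested enhancers")

    genes = pd.DataFrame(gene_rows)
    enhancers = pd.DataFrame(enh_rows)

    # background tiling at the repeat length, avoiding reserved zones
    explicit = pd.DataFrame(
        nuc_rows, columns=["chrom", "dyad", "klass", "weight", "jitter_sd", "origin"]
    )
    keepout: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _, g in genes.iterrows():
        keepout[g["chrom"]].append((g["tss"] - 350, g["tss"] + 350))
    for _, e in enhancers.iterrows():
        keepout[e["chrom"]].append((e["center"] - 150, e["center"] + 150))

    for chrom in chroms:
        exp_dyads = np.sort(explicit.loc[explicit["chrom"] == chrom, "dyad"].to_numpy())
        zones = keepout[chrom]
        candidates = np.arange(100, L - 100, config.nrl)
        # at least 150 bp from every explicit dyad
        idx = np.searchsorted(exp_dyads, candidates)
        left = np.where(idx > 0, candidates - exp_dyads[np.maximum(idx - 1, 0)], 10**9)
        right = np.where(
            idx < len(exp_dyads), exp_dyads[np.minimum(idx, len(exp_dyads) - 1)] - candidates, 10**9
        )
        ok = (left >= 150) & (right >= 150)
        for lo, hi in zones:
            ok &= ~((candidates >= lo) & (candidates <= hi))
        positioned = rng.random(ok.sum()) < config.positioned_fraction
        for p, is_pos in zip(candidates[ok], positioned):
            if is_pos:
                nuc_rows.append(
                    (chrom, int(p), "positioned", 1.0, config.jitter_sd_positioned, "array")
                )
            else:
                nuc_rows.append((chrom, int(p), "fuzzy", 0.7, config.jitter_sd_fuzzy, "array"))

    nucs = (
        pd.DataFrame(nuc_rows, columns=["chrom", "dyad", "klass", "weight", "jitter_sd", "origin"])
        .sort_values(["chrom", "dyad"], kind="stable")
        .reset_index(drop=True)
    )
    # enforce the >=150 bp inter-dyad contract (construction already
    # guarantees it; drop the later of any violating pair defensively)
    keep = np.ones(len(nucs), dtype=bool)
    dyads = nucs["dyad"].to_numpy()
    same = nucs["chrom"].to_numpy()
    last_kept = {}
    for i in range(len(nucs)):
        c = same[i]
        if c in last_kept and dyads[i] - last_kept[c] < 150:
            keep[i] = False
        else:
            last_kept[c] = dyads[i]
    nucs = nucs[keep].reset_index(drop=True)
    # domain-scale occupancy heterogeneity: one lognormal factor per
    # domain_bp window, applied to every particle in the domain so that
    # positioning scores (ratios of local NOS) are unaffected
    if config.domain_log_sd > 0:
        n_domains = -(-L // config.domain_bp)
        factors = {
            chrom: np.exp(rng.normal(0.0, config.domain_log_sd, n_domains))
            for chrom in chroms
        }
        dom = (nucs["dyad"] // config.domain_bp).to_numpy()
        nucs["weight"] = nucs["weight"].to_numpy() * np.array(
            [factors[c][d] for c, d in zip(nucs["chrom"], dom)]
        )
    return TruthBundle(
        nucleosomes=nucs,
        genes=genes,
        enhancers=enhancers,
        class_offsets=class_offsets,
        methylation_truth={},
    )


# ---------------------------------------------------------------------------
# genome sequence


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    u = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    out[u < gc / 2] = G
    out[(u >= gc / 2) & (u < gc)] = C
    out[(u >= gc) & (u < gc + (1 - gc) / 2)] = A
    out[u >= gc + (1 - gc) / 2] = T
    return out


def generate_genome(config: SimConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Synthesize the genome and return it with the true nucleosome table.

    Linker DNA is background composition; each 147-bp core is re-sampled
    with a GC boost and then seeded with AA/TT dinucleotides whose
    placement probability is sinusoidal in the dyad offset (period
    ``periodic_dinucleotide_period``, phase-locked so maxima fall at the
    dyad), scaled by ``periodic_amplitude``.
    """
    truth = _layout(config)
    rng = np.random.default_rng([config.seed, _S_GENOME])
    genome: dict[str, np.ndarray] = {}
    gc_core = min(1.0, config.gc_background + config.core_gc_boost)
    half = config.core_width // 2
    period = config.periodic_dinucleotide_period

    # placement probability for an AA/TT pair starting at offset p
    pair_offsets = np.arange(-half, half)  # pair must fit inside the core
    q = (
        config.periodic_placement_rate
        * config.periodic_amplitude
        * 0.5
        * (1.0 + np.cos(2 * np.pi * pair_offsets / period))
    )

    for chrom in [f"chr{i + 1}" for i in range(config.n_chroms)]:
        seq = _sample_bases(rng, config.genome_length, config.gc_background)
        dyads = truth.nucleosomes.loc[truth.nucleosomes["chrom"] == chrom, "dyad"].to_numpy()
        if len(dyads) == 0:
            genome[chrom] = seq
            continue
        n = len(dyads)
        core_cols = dyads[:, None] + np.arange(-half, half + 1)[None, :]
        core_bases = _sample_bases(rng, n * config.core_width, gc_core).reshape(n, -1)
        seq[core_cols] = core_bases
        # periodic AA/TT placement, suppressing overlapping starts
        fires = rng.random((n, len(pair_offsets))) < q[None, :]
        prev = np.zeros(n, dtype=bool)
        for j in range(fires.shape[1]):
            fires[:, j] &= ~prev
            prev = fires[:, j]
        is_aa = rng.random(fires.shape) < 0.5
        rows, cols = np.nonzero(fires)
        starts = dyads[rows] + pair_offsets[cols]
        base = np.where(is_aa[rows, cols], A, T).astype(np.uint8)
        seq[starts] = base
        seq[starts + 1] = base
        genome[chrom] = seq
    return genome, truth.nucleosomes


# ---------------------------------------------------------------------------
# fragments


def sample_fragments(
    truth: pd.DataFrame,
    config: SimConfig,
    n_fragments: int | None = None,
    seed_tag: int = _S_FRAGMENTS,
) -> pd.DataFrame:
    """Draw mononucleosomal fragments around the true dyads.

    Source nucleosomes are chosen proportional to ``weight``; the fragment
    midpoint is the dyad plus Gaussian jitter with the nucleosome's own
    jitter sd; lengths are Normal(frag_len_mean, frag_len_sd) truncated to
    [100, 220] bp (mirroring mononucleosomal gel size selection); each
    record is duplicated with probability ``dup_rate``.  Fragments falling
    outside chromosome bounds are redrawn.  Output is sorted.
    """
    if len(truth) == 0:
        raise ValueError("truth nucleosome table is empty")
    n = config.n_fragments if n_fragments is None else n_fragments
    rng = np.random.default_rng([config.seed, seed_tag])
    w = truth["weight"].to_numpy(float)
    idx = rng.choice(len(truth), size=n, p=w / w.sum())
    dyads = truth["dyad"].to_numpy()[idx]
    sds = truth["jitter_sd"].to_numpy(float)[idx]
    chroms = truth["chrom"].to_numpy()[idx]
    mids = dyads + np.rint(rng.normal(0.0, 1.0, n) * sds).astype(np.int64)
    if config.frag_len_sd > 0:
        from scipy.stats import truncnorm

        a = (100 - config.frag_len_mean) / config.frag_len_sd
        b = (220 - config.frag_len_mean) / config.frag_len_sd
        lengths = np.rint(
            truncnorm.rvs(a, b, loc=config.frag_len_mean, scale=config.frag_len_sd,
                          size=n, random_state=rng)
        ).astype(np.int64)
    else:
        lengths = np.full(n, int(round(config.frag_len_mean)), dtype=np.int64)
    starts = mids - (lengths - 1) // 2
    ends = starts + lengths
    # redraw the rare fragments that fall off a chromosome end
    bad = (starts < 0) | (ends > config.genome_length)
    while bad.any():
        k = int(bad.sum())
        mids_k = dyads[bad] + np.rint(rng.normal(0.0, 1.0, k) * sds[bad]).astype(np.int64)
        starts[bad] = mids_k - (lengths[bad] - 1) // 2
        ends[bad] = starts[bad] + lengths[bad]
        bad = (starts < 0) | (ends > config.genome_length)
    frags = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    dup = rng.random(n) < config.dup_rate
    frags = pd.concat([frags, frags[dup]], ignore_index=True)
    return frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotations, RNA signal, features


def generate_annotations(
    config: SimConfig,
) -> tuple[pd.DataFrame, TrackSet, TrackSet, dict[str, pd.DataFrame], TruthBundle]:
    """Gene models, stranded RNA signal, feature intervals and ground truth.

    Returns ``(genes, rna_plus, rna_minus, features, truth)``.  RNA signal
    is per-base Poisson with rate equal to the gene's expression tier over
    the gene body on its own strand, so silent (tier 0) genes emit exactly
    zero.  ``features`` holds TFBS (at enhancer centers), histone-mark and
    chromatin-state intervals consistent with the tiers, plus a synthetic
    DNase-like accessibility track under the key ``"dnase"`` is emitted as
    part of the feature set for site filtering.
    """
    truth = _layout(config)
    rng = np.random.default_rng([config.seed, _S_RNA])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    plus = {c: np.zeros(config.genome_length) for c in chroms}
    minus = {c: np.zeros(config.genome_length) for c in chroms}
    dnase = {c: np.ones(config.genome_length) for c in chroms}

    marks, states, exon_rows = [], [], []
    for _, g in truth.genes.iterrows():
        c, s, e = g["chrom"], int(g["start"]), int(g["end"])
        tier = float(g["tier"])
        target = plus if g["strand"] == "+" else minus
        if tier > 0:
            target[c][s:e] += rng.poisson(tier, e - s)
        # three exons: both ends plus a middle one
        span = e - s
        for xs, xe in ((s, s + 300), (s + span // 2, s + span // 2 + 400), (e - 300, e)):
            exon_rows.append({"chrom": c, "start": xs, "end": xe, "name": g["name"],
                              "score": 0, "strand": g["strand"]})
        tss = int(g["tss"])
        prom = (max(0, tss - 1000), min(config.genome_length, tss + 500))
        tier_idx = int(g["tier_index"])
        if tier_idx == 0:
            mark_names, state = ["H3K27me3"], "ReprPC"
        elif tier_idx == 1:
            mark_names, state = ["H3K4me3", "H3K27me3"], "TssBiv"
        else:
            mark_names, state = ["H3K4me3"], "TssA"
        for m in mark_names:
            marks.append({"chrom": c, "start": prom[0], "end": prom[1], "name": m,
                          "score": 0, "strand": "."})
        states.append({"chrom": c, "start": prom[0], "end": prom[1], "name": state,
                       "score": 0, "strand": "."})
        if tier > 0:
            states.append({"chrom": c, "start": s, "end": e, "name": "Tx", "score": 0,
                           "strand": g["strand"]})
            dnase[c][max(0, tss - 150): tss + 150] += 4.0 * (1 + tier_idx)

    tfbs = []
    for _, enh in truth.enhancers.iterrows():
        c, ctr = enh["chrom"], int(enh["center"])
        tfbs.append({"chrom": c, "start": ctr - 50, "end": ctr + 50, "name": "TFBS",
                     "score": 0, "strand": "."})
        states.append({"chrom": c, "start": ctr - 100, "end": ctr + 100, "name": "Enh",
                       "score": 0, "strand": "."})
        dnase[c][ctr - 150: ctr + 150] += 12.0

    features = {
        "tfbs": pd.DataFrame(tfbs),
        "histone_marks": pd.DataFrame(marks),
        "chromatin_states": pd.DataFrame(states),
        "exons": pd.DataFrame(exon_rows),
    }
    rna_plus = {c: OccupancyTrack(c, v) for c, v in plus.items()}
    rna_minus = {c: OccupancyTrack(c, v) for c, v in minus.items()}
    features["dnase"] = {c: OccupancyTrack(c, v) for c, v in dnase.items()}
    return truth.genes, rna_plus, rna_minus, features, truth


# ---------------------------------------------------------------------------
# methylation


def generate_methylation(
    truth: pd.DataFrame,
    genome: dict[str, np.ndarray],
    config: SimConfig,
    sharpening: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Place methylation calls at C/G positions with dyad-coupled geometry.

    Within each core, a candidate position at offset ``p`` is methylated
    with probability ``rate_i * (1 - lw) * 147 * profile_i[p]`` where the
    per-nucleosome rate scales with ``(weight / mean weight) **
    meth_occupancy_coupling`` (methylated nucleosomes are more occupied)
    and ``profile_i`` mixes the context profile with a narrow dyad bump
    for high-weight nucleosomes (slope ``meth_dyad_sharpening``; pass
    ``sharpening=0`` to disable).  Linker candidates are methylated at the
    uniform floor ``rate * lw``.  Returns the site table (chrom, pos,
    context, sorted) and the parameters actually used.
    """
    if len(truth) == 0:
        raise ValueError("truth nucleosome table is empty")
    for ctx in config.meth_density_by_context:
        if ctx not in config.meth_dyad_profile:
            raise ValueError(f"context {ctx!r} has no dyad placement profile")
    slope = config.meth_dyad_sharpening if sharpening is None else sharpening
    rng = np.random.default_rng([config.seed, _S_METH])
    half = config.core_width // 2
    narrow = _gaussian(0, 8)
    narrow = narrow / narrow.sum()
    rows = []
    used: dict = {"profiles": {}, "densities": {}, "linker_weight": {}, "sharpening": slope}
    w = truth["weight"].to_numpy(float)
    gamma = np.clip(slope * (w - 0.8), 0.0, 0.85)
    rel_rate = (w / w.mean()) ** config.meth_occupancy_coupling

    core_cols = {}
    core_mask = {}
    for chrom, sub in truth.groupby("chrom", sort=False):
        dyads = sub["dyad"].to_numpy()
        cols = dyads[:, None] + np.arange(-half, half + 1)[None, :]
        core_cols[chrom] = (sub.index.to_numpy(), cols)
        covered = np.zeros(len(genome[chrom]), dtype=bool)
        covered[cols.ravel()] = True
        core_mask[chrom] = covered

    for ctx, density in config.meth_density_by_context.items():
        profile = config.meth_dyad_profile[ctx]
        lw = config.meth_linker_weight.get(ctx, 0.1)
        used["profiles"][ctx] = profile
        used["densities"][ctx] = density
        used["linker_weight"][ctx] = lw
        if density == 0:
            continue
        for chrom in core_cols:
            nuc_idx, cols = core_cols[chrom]
            seq = genome[chrom]
            is_cg = (seq[cols] == C) | (seq[cols] == G)
            eff = (1 - gamma[nuc_idx, None]) * profile[None, :] + gamma[nuc_idx, None] * narrow[None, :]
            prob = np.clip(
                density * (1 - lw) * config.core_width * rel_rate[nuc_idx, None] * eff, 0.0, 0.95
            )
            hit = is_cg & (rng.random(cols.shape) < prob)
            pos = cols[hit]
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "context": ctx}))
            # uniform linker floor
            linker = np.flatnonzero(((seq == C) | (seq == G)) & ~core_mask[chrom])
            lhit = rng.random(len(linker)) < density * lw
            rows.append(pd.DataFrame({"chrom": chrom, "pos": linker[lhit], "context": ctx}))
    sites = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "pos", "context"])
    )
    sites = sites.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)
    return sites, used


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, np.ndarray]
    truth: TruthBundle
    fragments: pd.DataFrame
    rna_plus: TrackSet
    rna_minus: TrackSet
    features: dict
    methylation: pd.DataFrame

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every generator stage under one config and bundle the results."""
    genome, nucs = generate_genome(config)
    genes, rna_plus, rna_minus, features, truth = generate_annotations(config)
    truth.nucleosomes = nucs
    fragments = sample_fragments(nucs, config)
    methylation, meth_truth = generate_methylation(nucs, genome, config)
    truth.methylation_truth = meth_truth
    return SimulatedDataset(
        config=config,
        genome=genome,
        truth=truth,
        fragments=fragments,
        rna_plus=rna_plus,
        rna_minus=rna_minus,
        features=features,
        methylation=methylation,
    )
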