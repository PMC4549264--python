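"""Tests of the synthetic-data generator against its own ground truth."""

import numpy as np
import pandas as pd
import pytest

from nucarch.simulate import (
    A,
    C,
    CORE_OFFSETS,
    G,
    T,
    SimConfig,
    default_meth_dyad_profiles,
    generate_genome,
    generate_methylation,
    sample_fragments,
    simulate_dataset,
)

SMALL = dict(genome_length=300_000, n_chroms=1, n_genes=20, n_enhancers=4,
             n_fragments=30_000)


def _aa_profile_by_counting(genome, nucs, half=73):
    """Brute-force dyad-relative AA start frequency (independent of the
    sequence_features module)."""
    counts = np.zeros(2 * half)
    n = 0
    for chrom, sub in nucs.groupby("chrom"):
        seq = genome[chrom]
        for d in sub["dyad"]:
            window = seq[d - half : d + half + 1]
            counts += (window[:-1] == A) & (window[1:] == A)
            n += 1
    return counts / n


# ---------------------------------------------------------------------------
# config validation


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(core_width=146),
        dict(gc_background=1.5),
        dict(n_profile_classes=30, n_genes=20),
        dict(expression_tiers=(1.0, 2.0)),
        dict(genome_length=50_000, n_chroms=1, n_genes=50),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_meth_profile_must_normalize():
    bad = default_meth_dyad_profiles()
    bad["mCG"] = bad["mCG"] * 2
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(meth_dyad_profile=bad)


# ---------------------------------------------------------------------------
# genome generation


def test_zero_amplitude_gives_flat_aa_profile():
    cfg = SimConfig(seed=3, periodic_amplitude=0.0, **SMALL)
    genome, nucs = generate_genome(cfg)
    prof = _aa_profile_by_counting(genome, nucs)
    # flat up to binomial sampling noise: no offset deviates from the
    # overall mean by more than 5 binomial standard errors
    se = np.sqrt(prof.mean() * (1 - prof.mean()) / len(nucs))
    assert np.abs(prof - prof.mean()).max() < 5 * se


def test_pure_gc_background_confines_at_to_placed_motifs():
    cfg = SimConfig(seed=3, gc_background=1.0, **SMALL)
    genome, nucs = generate_genome(cfg)
    seq = genome["chr1"]
    core = np.zeros(len(seq), dtype=bool)
    for d in nucs["dyad"]:
        core[d - 73 : d + 74] = True
    at = (seq == A) | (seq == T)
    assert not (at & ~core).any()  # linkers are pure G/C
    # in-core A/T only occurs as the planted AA/TT dinucleotides
    pos = np.flatnonzero(at)
    neighbor = at[pos - 1] | at[np.minimum(pos + 1, len(seq) - 1)]
    assert neighbor.all()


def test_default_aa_periodicity_peaks_every_10bp(sim):
    prof = _aa_profile_by_counting(sim.genome, sim.truth.nucleosomes.head(5000))
    # local maxima of the smoothed profile should be spaced ~10 bp
    sm = np.convolve(prof, np.ones(3) / 3, mode="same")
    peaks = [
        i for i in range(2, len(sm) - 2) if sm[i] == sm[i - 2 : i + 3].max()
    ]
    spacing = np.diff(peaks)
    assert 9 <= np.median(spacing) <= 11


def test_true_dyads_are_sorted_and_spaced(sim):
    for _, sub in sim.truth.nucleosomes.groupby("chrom"):
        d = sub["dyad"].to_numpy()
        assert (np.diff(d) >= 150).all()


def test_genome_is_reproducible_bit_exactly():
    cfg = dict(seed=11, **SMALL)
    g1, n1 = generate_genome(SimConfig(**cfg))
    g2, n2 = generate_genome(SimConfig(**cfg))
    assert all(np.array_equal(g1[c], g2[c]) for c in g1)
    pd.testing.assert_frame_equal(n1, n2)


# ---------------------------------------------------------------------------
# fragment sampling


def test_zero_noise_fragments_reproduce_dyads_exactly():
    truth = pd.DataFrame(
        {
            "chrom": "c1",
            "dyad": np.arange(50) * 200 + 500,
            "klass": "positioned",
            "weight": 1.0,
            "jitter_sd": 0.0,
        }
    )
    cfg = SimConfig(seed=9, frag_len_sd=0.0, dup_rate=0.0, **SMALL)
    frags = sample_fragments(truth, cfg, n_fragments=5_000)
    mids = (frags["start"] + frags["end"] - 1) // 2
    assert set(mids) == set(truth["dyad"])
    assert (frags["end"] - frags["start"]).eq(round(cfg.frag_len_mean)).all()


def test_fragment_length_distribution_matches_config(sim):
    lengths = sim.fragments["end"] - sim.fragments["start"]
    assert abs(lengths.mean() - sim.config.frag_len_mean) < 1.0
    assert lengths.between(100, 220).all()


def test_duplicate_injection_rate():
    cfg = SimConfig(seed=2, dup_rate=0.5, **SMALL)
    _, nucs = generate_genome(cfg)
    frags = sample_fragments(nucs, cfg, n_fragments=100_000)
    dup_frac = frags.duplicated(keep="first").mean()
    assert dup_frac == pytest.approx(1 / 3, abs=0.02)


def test_fragments_sorted_and_in_bounds(sim):
    f = sim.fragments
    assert (f["start"] >= 0).all()
    assert (f["end"] <= sim.config.genome_length).all()
    for _, sub in f.groupby("chrom"):
        assert sub["start"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# annotations


def test_silent_genes_emit_no_rna(sim):
    genes = sim.truth.genes
    silent = genes[genes["tier"] == 0]
    assert len(silent) > 0
    for _, g in silent.iterrows():
        for tracks in (sim.rna_plus, sim.rna_minus):
            assert tracks[g["chrom"]].values[g["start"] : g["end"]].sum() == 0


def test_class_architecture_is_deterministic(sim):
    """Two genes in the same class share the same TSS-relative anchor offset."""
    genes = sim.truth.genes
    nucs = sim.truth.nucleosomes
    anchors = nucs[nucs["origin"] == "tss_anchor"]
    offsets = {}
    for _, g in genes.iterrows():
        sign = 1 if g["strand"] == "+" else -1
        sub = anchors[anchors["chrom"] == g["chrom"]]
        rel = (sub["dyad"] - g["tss"]) * sign
        near = rel[np.abs(rel) <= 250]
        if len(near) == 1:
            offsets.setdefault(g["klass"], set()).add(int(near.iloc[0]))
    assert offsets and all(len(v) == 1 for v in offsets.values())
    assert len({next(iter(v)) for v in offsets.values()}) == len(offsets)


def test_tss_uniqueness_and_enhancer_count(sim):
    genes = sim.truth.genes
    assert genes.groupby("chrom")["tss"].nunique().sum() == len(genes)
    assert len(sim.truth.enhancers) == sim.config.n_enhancers


def test_all_intervals_within_genome(sim):
    L = sim.config.genome_length
    for df in (sim.truth.genes, sim.truth.enhancers, sim.features["tfbs"]):
        assert (df["start"] >= 0).all() and (df["end"] <= L).all()


# ---------------------------------------------------------------------------
# methylation placement


def test_uniform_profile_places_uniformly():
    profiles = default_meth_dyad_profiles()
    profiles["mCG"] = np.full(147, 1 / 147)
    cfg = SimConfig(seed=4, meth_dyad_profile=profiles, meth_occupancy_coupling=0.0, **SMALL)
    cfg.meth_density_by_context["mCG"] = 0.15  # enough sites for a tight TV bound
    genome, nucs = generate_genome(cfg)
    sites, _ = generate_methylation(nucs, genome, cfg, sharpening=0.0)
    mcg = sites[sites["context"] == "mCG"]
    dyads = {c: s["dyad"].to_numpy() for c, s in nucs.groupby("chrom")}
    rel = []
    for c, s in mcg.groupby("chrom"):
        d = dyads[c]
        pos = s["pos"].to_numpy()
        j = np.searchsorted(d, pos)
        left = d[np.clip(j - 1, 0, len(d) - 1)]
        right = d[np.clip(j, 0, len(d) - 1)]
        rel.append(np.where(np.abs(pos - left) < np.abs(right - pos), pos - left, pos - right))
    rel = np.concatenate(rel)
    in_core = rel[np.abs(rel) <= 73]
    assert len(in_core) > 10_000
    hist, _ = np.histogram(in_core, bins=np.arange(-73.5, 74.5))
    # total-variation distance from the uniform placement density
    tv = 0.5 * np.abs(hist / hist.sum() - 1 / 147).sum()
    assert tv < 0.06  # sampling-noise floor ~0.04 at this site count


def test_zero_density_context_emits_nothing():
    cfg = SimConfig(seed=4, **SMALL)
    cfg.meth_density_by_context["hmC"] = 0.0
    genome, nucs = generate_genome(cfg)
    sites, _ = generate_methylation(nucs, genome, cfg)
    assert (sites["context"] == "hmC").sum() == 0


def test_context_without_profile_rejected():
    cfg = SimConfig(seed=4, **SMALL)
    cfg.meth_density_by_context["mCG2"] = 0.01
    genome, nucs = generate_genome(cfg)
    with pytest.raises(ValueError, match="mCG2"):
        generate_methylation(nucs, genome, cfg)


def test_default_mcg_truth_placement_matches_profile(sim):
    """TV distance between realized mCG in-core placement and the
    configured effective density stays small at >20k sites."""
    mcg = sim.methylation[sim.methylation["context"] == "mCG"]
    assert len(mcg) > 20_000
    # expected aggregate in-core density: the per-nucleosome profile
    # (context profile mixed with the dyad bump for high-weight particles)
    # weighted by each nucleosome's relative placement rate
    cfg = sim.config
    profile = cfg.meth_dyad_profile["mCG"]
    w = sim.truth.nucleosomes["weight"].to_numpy()
    gamma = np.clip(cfg.meth_dyad_sharpening * (w - 0.8), 0.0, 0.85)
    narrow = np.exp(-0.5 * (CORE_OFFSETS / 8.0) ** 2)
    narrow = narrow / narrow.sum()
    rate = (w / w.mean()) ** cfg.meth_occupancy_coupling
    expected = (
        rate[:, None] * ((1 - gamma)[:, None] * profile[None, :] + gamma[:, None] * narrow[None, :])
    ).sum(axis=0)
    expected /= expected.sum()
    rel = []
    for c, s in mcg.groupby("chrom"):
        d = sim.truth.nucleosomes.query("chrom == @c")["dyad"].to_numpy()
        pos = s["pos"].to_numpy()
        j = np.searchsorted(d, pos)
        left = d[np.clip(j - 1, 0, len(d) - 1)]
        right = d[np.clip(j, 0, len(d) - 1)]
        rel.append(np.where(np.abs(pos - left) < np.abs(right - pos), pos - left, pos - right))
    rel = np.concatenate(rel)
    in_core = rel[np.abs(rel) <= 73]
    hist, _ = np.histogram(in_core, bins=np.arange(-73.5, 74.5))
    emp = hist / hist.sum()
    tv = 0.5 * np.abs(emp - expected).sum()
    assert tv < 0.05
    sm = np.convolve(emp, np.ones(3) / 3, mode="same")
    off = CORE_OFFSETS
    left_mode = off[off < -10][np.argmax(sm[off < -10])]
    right_mode = off[off > 10][np.argmax(sm[off > 10])]
    assert abs(abs(left_mode) - 40) <= 3
    assert abs(abs(right_mode) - 40) <= 3


def test_dataset_is_seed_deterministic():
    cfg = dict(seed=13, **SMALL)
    a = simulate_dataset(SimConfig(**cfg))
    b = simulate_dataset(SimConfig(**cfg))
    pd.testing.assert_frame_equal(a.fragments, b.fragments)
    pd.testing.assert_frame_equal(a.methylation, b.methylation)
    assert all(np.array_equal(a.genome[c], b.genome[c]) for c in a.genome)
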