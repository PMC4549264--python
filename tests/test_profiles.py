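"""Metaprofiles, RNA signal, quartiles, clustering, +1 shifts, site filters."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nucarch.occupancy import OccupancyTrack
from nucarch.profiles import (
    active_site_filter,
    aggregate_profile,
    build_rna_signal,
    classify_silent,
    kmeans_profiles,
    normalize_by_reference,
    plus_one_location,
    plus_one_shift,
    profile_matrix,
    quartile_split,
    total_expression,
)
from nucarch.simulate import _class_offsets


def _tracks(values, chrom="c1"):
    return {chrom: OccupancyTrack(chrom, np.asarray(values, float))}


# ---------------------------------------------------------------------------
# RNA signal


def test_zero_minus_strand_passes_plus_through():
    combined = build_rna_signal(_tracks([1, 2, 3]), _tracks([0, 0, 0]))
    assert np.allclose(combined["c1"].values, [1, 2, 3])


def test_equal_strands_double():
    combined = build_rna_signal(_tracks([1, 2]), _tracks([1, 2]))
    assert np.allclose(combined["c1"].values, [2, 4])


def test_strand_depth_normalization():
    combined = build_rna_signal(_tracks([1, 0]), _tracks([0, 3]))
    # each strand scaled to the mean total (2), then summed
    assert np.allclose(combined["c1"].values, [2, 2])


def test_mismatched_chromosomes_rejected():
    with pytest.raises(ValueError):
        build_rna_signal(_tracks([1]), _tracks([1], chrom="c2"))


# ---------------------------------------------------------------------------
# expression and silence


def _gene(chrom="c1", tss=2, tts=5, strand="+", name="g"):
    return pd.Series({"name": name, "chrom": chrom, "tss": tss, "tts": tts, "strand": strand})


def test_expression_is_span_sum():
    rna = _tracks([1.0] * 10)
    assert total_expression(_gene(tss=2, tts=5), rna) == 4.0
    assert total_expression(_gene(tss=5, tts=2, strand="-"), rna) == 4.0


def test_rank_quartiles():
    labels = quartile_split(np.arange(8))
    assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_tied_quartiles_split_by_stable_order():
    labels = quartile_split(np.zeros(8))
    assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_silent_gene_lands_in_q1():
    values = np.array([0.0, 1.0, 2.0, 3.0])
    assert quartile_split(values)[0] == "Q1"


def test_classify_silent_flanks_and_eps():
    genes = pd.DataFrame(
        [
            {"name": "a", "chrom": "c1", "tss": 600, "tts": 700, "strand": "+"},
            {"name": "b", "chrom": "c1", "tss": 2600, "tts": 2700, "strand": "+"},
        ]
    )
    rna = _tracks(np.zeros(4000))
    assert classify_silent(genes, rna) == {"a", "b"}
    rna["c1"].values[150] = 1.0  # one base inside a's 500-bp flank
    assert classify_silent(genes, rna) == {"b"}
    assert classify_silent(genes, rna, eps=0.1) == {"a", "b"}


# ---------------------------------------------------------------------------
# aggregation


def test_plus_feature_profile_is_identity_slice():
    track = _tracks(np.arange(100.0))
    prof = aggregate_profile(track, [("c1", 50, "+")], flank=10)
    assert np.allclose(prof, np.arange(40.0, 61.0))


def test_minus_feature_profile_is_reversed():
    track = _tracks(np.arange(100.0))
    prof = aggregate_profile(track, [("c1", 50, "-")], flank=10)
    assert prof[10 + 10] == 40.0  # +10 offset reads upstream base 40


def test_two_feature_mean():
    track = _tracks(np.arange(100.0))
    prof = aggregate_profile(track, [("c1", 30, "+"), ("c1", 50, "+")], flank=5)
    assert np.allclose(prof, (np.arange(25.0, 36.0) + np.arange(45.0, 56.0)) / 2)


def test_aggregation_is_linear():
    base = np.abs(np.sin(np.arange(300.0)))
    feats = [("c1", 100, "+"), ("c1", 200, "-")]
    one = aggregate_profile(_tracks(base), feats, flank=20)
    three = aggregate_profile(_tracks(3 * base), feats, flank=20)
    assert np.allclose(three, 3 * one)


def test_boundary_features_dropped(caplog):
    track = _tracks(np.arange(100.0))
    with caplog.at_level("WARNING"):
        mat = profile_matrix(track, [("c1", 3, "+"), ("c1", 50, "+")], flank=10)
    assert mat.values.shape == (1, 21)
    with pytest.raises(ValueError):
        profile_matrix(track, [("c1", 3, "+")], flank=10)


# ---------------------------------------------------------------------------
# reference normalization


def test_reference_ratio_identity():
    from nucarch.profiles import ProfileMatrix

    m = ProfileMatrix(["g1"], np.arange(-1, 2), np.array([[2.0, 4.0, 8.0]]), True)
    assert np.allclose(normalize_by_reference(m, m), 1.0)


def test_reference_pseudocount_arithmetic():
    from nucarch.profiles import ProfileMatrix

    a = ProfileMatrix(["g"], np.arange(-1, 2), np.array([[1.0, 1.0, 1.0]]), True)
    ref = ProfileMatrix(["g"], np.arange(-1, 2), np.array([[0.0, 0.0, 0.0]]), True)
    assert np.allclose(normalize_by_reference(a, ref, pseudo=1.0), 2.0)


def test_reference_missing_gene_dropped(caplog):
    from nucarch.profiles import ProfileMatrix

    a = ProfileMatrix(["g", "h"], np.arange(-1, 2), np.ones((2, 3)), True)
    ref = ProfileMatrix(["g"], np.arange(-1, 2), np.ones((1, 3)), True)
    with caplog.at_level("WARNING"):
        out = normalize_by_reference(a, ref)
    assert np.allclose(out, 1.0)
    assert "dropped 1" in caplog.text


# ---------------------------------------------------------------------------
# clustering


def test_single_cluster_centroid_is_scaled_column_mean():
    from nucarch.profiles import ProfileMatrix

    rows = np.array([[1.0, 2.0], [2.0, 8.0]])
    m = ProfileMatrix(["a", "b"], np.array([0, 1]), rows, True)
    res = kmeans_profiles(m, k=1, seed=0)
    scaled = rows / rows.max(axis=1, keepdims=True)
    assert np.allclose(res.centroids[0], scaled.mean(axis=0))


def test_two_planted_profile_classes_fully_recovered():
    rng = np.random.default_rng(0)
    from nucarch.profiles import ProfileMatrix

    offsets = np.arange(-200, 201)
    rows, labels = [], []
    for i in range(40):
        center = -150 if i % 2 == 0 else 150
        rows.append(np.exp(-0.5 * ((offsets - center) / 30) ** 2) + 0.05 * rng.random(401))
        labels.append(i % 2)
    m = ProfileMatrix([f"g{i}" for i in range(40)], offsets, np.array(rows), True)
    res = kmeans_profiles(m, k=2, seed=0)
    assert adjusted_rand_score(labels, res.assignments) == 1.0
    assert sorted(np.abs(res.max_nos_location)) == [150, 150]


def test_ten_planted_tss_classes_recovered(sim, norm_tracks):
    """k=10 clustering of simulated TSS profiles recovers the generator's
    architecture classes (high adjusted Rand index)."""
    mat = profile_matrix(norm_tracks, sim.truth.genes, flank=1000)
    res = kmeans_profiles(mat, k=10, n_init=10, seed=0)
    truth = sim.truth.genes.set_index("name").loc[res.assignments.index, "klass"]
    assert adjusted_rand_score(truth, res.assignments) >= 0.8


def test_all_zero_rows_dropped(caplog):
    from nucarch.profiles import ProfileMatrix

    rows = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
    m = ProfileMatrix(["a", "b", "c"], np.array([0, 1]), rows, True)
    with caplog.at_level("WARNING"):
        res = kmeans_profiles(m, k=2, seed=0)
    assert set(res.assignments.index) == {"a", "c"}


# ---------------------------------------------------------------------------
# +1 nucleosome shift


def _bump(center, width=40, F=400):
    x = np.arange(-F, F + 1)
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def test_identical_profiles_shift_zero():
    p = _bump(60)
    assert plus_one_shift(p, p) == 0


def test_translated_profile_shift():
    assert plus_one_shift(_bump(52), _bump(60)) == 8


def test_constructed_peaks_shift_ten():
    assert plus_one_shift(_bump(50), _bump(60)) == 10


def test_no_downstream_maximum_raises():
    falling = np.linspace(1.0, 0.0, 801)
    with pytest.raises(ValueError):
        plus_one_location(falling)


# ---------------------------------------------------------------------------
# active-site filtering


def _sites(n):
    return pd.DataFrame(
        {
            "chrom": "c1",
            "start": np.arange(n) * 20,
            "end": np.arange(n) * 20 + 10,
        }
    )


def test_single_site_is_active_at_inclusive_thresholds():
    dnase = _tracks(np.ones(100))
    nos = _tracks(np.ones(100))
    out = active_site_filter(_sites(1), dnase, nos)
    assert len(out) == 1


def test_quantile_filter_keeps_extreme_site():
    d = np.zeros(100)
    n = np.zeros(100)
    for i, (dv, nv) in enumerate(zip([1, 2, 3, 4], [4, 3, 2, 1])):
        d[i * 20 : i * 20 + 10] = dv
        n[i * 20 : i * 20 + 10] = nv
    out = active_site_filter(_sites(4), _tracks(d), _tracks(n))
    assert len(out) == 1
    assert out.iloc[0]["dnase_mean"] == 4.0 and out.iloc[0]["nos_mean"] == 1.0


def test_uniform_tracks_leave_all_sites_active():
    out = active_site_filter(_sites(4), _tracks(np.ones(100)), _tracks(np.ones(100)))
    assert len(out) == 4


def test_empty_site_list():
    assert len(active_site_filter(_sites(0), _tracks(np.ones(10)), _tracks(np.ones(10)))) == 0


def test_simulated_active_sites_are_enhancers(sim, norm_tracks):
    out = active_site_filter(sim.features["tfbs"], sim.features["dnase"], norm_tracks)
    assert len(out) > 0
    centers = sim.truth.enhancers.set_index("chrom")
    for _, row in out.iterrows():
        mid = (row["start"] + row["end"]) // 2
        enh = sim.truth.enhancers[sim.truth.enhancers["chrom"] == row["chrom"]]
        assert np.abs(enh["center"] - mid).min() <= 100


# ---------------------------------------------------------------------------
# expression-coupled architecture

def test_expression_quartiles_deepen_ndr_and_strengthen_plus_one(sim, norm_tracks):
    """Higher-expression quartiles show emptier NDRs and taller +1 peaks
    (on genes whose architecture class places the anchor downstream)."""
    genes = sim.truth.genes
    offs = _class_offsets(sim.config.n_profile_classes)
    downstream = genes[genes["klass"].map(offs) > 0].reset_index(drop=True)
    rna = build_rna_signal(sim.rna_plus, sim.rna_minus)
    expr = np.array([total_expression(g, rna) for _, g in downstream.iterrows()])
    quartile = quartile_split(expr)
    mat = profile_matrix(norm_tracks, downstream, flank=1000)
    X = mat.values / mat.values.mean(axis=1, keepdims=True)
    ids = list(downstream["name"])
    qlab = quartile[[ids.index(i) for i in mat.ids]]
    ndr_win = (mat.offsets >= -300) & (mat.offsets <= -60)
    p1_win = (mat.offsets > 0) & (mat.offsets <= 300)
    ndr, p1 = [], []
    for lab in ("Q1", "Q2", "Q3", "Q4"):
        rows = X[qlab == lab]
        ndr.append(rows[:, ndr_win].mean())
        p1.append(rows[:, p1_win].max(axis=1).mean())
    assert all(np.diff(ndr) < 0)
    assert all(np.diff(p1) > 0)


def test_silent_gene_profiles_concord_between_replicates(sim):
    """Ground-state (silent-TSS) profiles from two independent fragment
    samples of the same truth are nearly identical."""
    from scipy.stats import pearsonr

    from nucarch.occupancy import compute_nos, deduplicate_fragments
    from nucarch.simulate import sample_fragments

    rna = build_rna_signal(sim.rna_plus, sim.rna_minus)
    silent = classify_silent(sim.truth.genes, rna)
    sg = sim.truth.genes[sim.truth.genes["name"].isin(silent)]
    profs = []
    for tag in (201, 202):
        f = sample_fragments(sim.truth.nucleosomes, sim.config, n_fragments=200_000, seed_tag=tag)
        t = compute_nos(deduplicate_fragments(f), sim.chrom_sizes)
        profs.append(aggregate_profile(t, sg, flank=1000))
    assert pearsonr(profs[0], profs[1])[0] > 0.95
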