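import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from ctcpheno.clustering import (
    ClusterProfile,
    SomModel,
    best_matching_nodes,
    cluster_profiles,
    concatenate_ctcs,
    elbow_metacluster,
    embed_tsne,
    hierarchical_subgroups,
    label_emt_subgroups,
    subgroup_summary,
    train_som,
)
from ctcpheno.events import EventTable
from ctcpheno.gating import GateResult


def _blob_events(n_per=100, d=8, sep=6.0, seed=0, markers=None):
    rng = np.random.default_rng(seed)
    markers = markers or [f"m{i}" for i in range(d)]
    centres = rng.normal(0, sep, size=(3, d))
    x = np.vstack([c + rng.normal(0, 0.4, size=(n_per, d)) for c in centres])
    labels = np.repeat(["a", "b", "c"], n_per)
    df = pd.DataFrame(x, columns=markers)
    return EventTable(df, transformed=True, truth=pd.Series(labels)), markers


# ---------------------------------------------------------------------------
# SOM training
# ---------------------------------------------------------------------------


def test_som_determinism():
    ev, markers = _blob_events()
    a = train_som(ev, markers, grid=(5, 5), epochs=5, seed=3)
    b = train_som(ev, markers, grid=(5, 5), epochs=5, seed=3)
    np.testing.assert_array_equal(a.codebook, b.codebook)
    c = train_som(ev, markers, grid=(5, 5), epochs=5, seed=4)
    assert not np.array_equal(a.codebook, c.codebook)


def test_som_quantization_error_decreases():
    """QE at the final epoch is no worse than after the first batch update
    (index 0 is the pre-training error of the data-sampled init)."""
    ev, markers = _blob_events()
    model = train_som(ev, markers, grid=(6, 6), epochs=10, seed=0)
    qe = model.quantization_errors
    assert qe[-1] <= qe[1]
    # and the tail of training is non-increasing once the radius is small
    assert qe[-1] <= qe[len(qe) // 2]


def test_som_separates_archetypes_with_high_purity():
    """Node assignments keep the three generated archetypes apart."""
    ev, markers = _blob_events(n_per=150)
    model = train_som(ev, markers, grid=(6, 6), epochs=10, seed=1)
    bmu = best_matching_nodes(model, ev.matrix(markers))
    truth = ev.truth.to_numpy()
    # purity: each node dominated by one archetype
    pure = 0
    for node in np.unique(bmu):
        members = truth[bmu == node]
        pure += pd.Series(members).value_counts().iloc[0]
    assert pure / len(truth) >= 0.95


def test_som_empty_input_rejected():
    ev = EventTable(pd.DataFrame({"m0": []}), transformed=True)
    with pytest.raises(ValueError, match="empty"):
        train_som(ev, ["m0"])


def test_som_nonfinite_rejected():
    ev = EventTable(pd.DataFrame({"m0": [1.0, np.nan]}), transformed=True)
    with pytest.raises(ValueError, match="finite"):
        train_som(ev, ["m0"])


def test_bmu_matches_bruteforce_nearest_centroid():
    """Best-matching-node equals exhaustive nearest-centroid search."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(200, 5))
    codebook = rng.normal(size=(9, 5))
    model = SomModel((3, 3), codebook, [f"m{i}" for i in range(5)], 0, 0)
    got = best_matching_nodes(model, x)
    brute = np.array(
        [int(np.argmin([((xi - c) ** 2).sum() for c in codebook])) for xi in x]
    )
    np.testing.assert_array_equal(got, brute)


# ---------------------------------------------------------------------------
# elbow metaclustering
# ---------------------------------------------------------------------------


def _codebook_model(cb):
    n = len(cb)
    rows = int(np.floor(np.sqrt(n)))
    while n % rows:
        rows -= 1
    return SomModel((rows, n // rows), cb, [f"m{i}" for i in range(cb.shape[1])], 0, 0)


def test_elbow_recovers_three_centres_and_agrees_with_silhouette():
    rng = np.random.default_rng(0)
    centres = rng.normal(0, 5, size=(3, 10))
    cb = np.vstack([c + rng.normal(0, 0.3, size=(33, 10)) for c in centres])
    model = _codebook_model(cb)
    mm = elbow_metacluster(model, (2, 20))
    assert mm.k == 3
    # oracle: exhaustive silhouette over the same range picks the same k
    from scipy.cluster.hierarchy import fcluster, linkage

    z = linkage(cb, method="ward")
    sils = {
        k: silhouette_score(cb, fcluster(z, t=k, criterion="maxclust"))
        for k in range(2, 21)
    }
    assert max(sils, key=sils.get) == mm.k


def test_elbow_single_centre_keeps_smallest_k():
    rng = np.random.default_rng(1)
    cb = rng.normal(0, 1, size=(99, 40))
    mm = elbow_metacluster(_codebook_model(cb), (2, 20))
    assert mm.k == 2


def test_elbow_curve_monotone_nonincreasing():
    rng = np.random.default_rng(2)
    cb = rng.normal(0, 2, size=(64, 6))
    mm = elbow_metacluster(_codebook_model(cb), (2, 20))
    wss = mm.elbow_curve["wss"].to_numpy()
    assert (np.diff(wss) <= 1e-9).all()


def test_elbow_k_range_exceeding_nodes_rejected():
    cb = np.random.default_rng(0).normal(size=(9, 3))
    with pytest.raises(ValueError, match="node count"):
        elbow_metacluster(_codebook_model(cb), (2, 50))


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------


def test_profiles_degenerate_single_cluster_equals_global_median():
    ev, markers = _blob_events(n_per=50)
    model = train_som(ev, markers, grid=(3, 3), epochs=5, seed=0)
    mm = elbow_metacluster(model, (2, 9))
    forced = mm.node_to_meta.copy()
    forced[:] = 1
    mm_single = type(mm)(1, forced, mm.elbow_curve, mm.threshold)
    prof = cluster_profiles(ev, model, mm_single)
    np.testing.assert_allclose(
        prof.medians.iloc[0].to_numpy(), np.median(ev.matrix(markers), axis=0)
    )


def test_profiles_fractions_sum_to_one_and_counts_conserve():
    ev, markers = _blob_events(n_per=80)
    model = train_som(ev, markers, grid=(4, 4), epochs=5, seed=0)
    mm = elbow_metacluster(model, (2, 10))
    prof = cluster_profiles(ev, model, mm)
    assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-12)
    assert int(prof.counts.sum()) == len(ev)


# ---------------------------------------------------------------------------
# parent groups and labels
# ---------------------------------------------------------------------------


def _archetype_profiles(seed=0, n_clusters=13):
    """Cluster medians drawn from three EMT archetype prototypes + noise."""
    rng = np.random.default_rng(seed)
    markers = ["Vimentin", "EpCAM", "E-cadherin", "pCREB", "CD44"]
    prototypes = {
        "epithelial": [0.5, 5.0, 5.0, 1.5, 2.0],
        "early_EMT": [5.0, 3.0, 3.0, 4.0, 4.0],
        "advanced_EMT": [5.0, 1.0, 1.0, 4.0, 4.0],
    }
    owners = [list(prototypes)[i % 3] for i in range(n_clusters)]
    med = pd.DataFrame(
        [np.array(prototypes[o]) + rng.normal(0, 0.15, 5) for o in owners],
        index=pd.Index(range(1, n_clusters + 1), name="metacluster"),
        columns=markers,
    )
    counts = pd.Series(
        rng.integers(20, 100, n_clusters), index=med.index, name="count"
    )
    meta = np.repeat(med.index.to_numpy(), counts.to_numpy())
    prof = ClusterProfile(med, counts, (counts / counts.sum()).rename("fraction"), meta)
    return prof, owners


def test_hierarchical_groups_recover_archetypes():
    prof, owners = _archetype_profiles()
    assign = hierarchical_subgroups(prof)
    groups = assign.cluster_to_group
    # all clusters of one archetype share a group, and archetypes differ
    by_owner = {o: set(groups[np.array(owners) == o]) for o in set(owners)}
    assert all(len(s) == 1 for s in by_owner.values())
    assert len({next(iter(s)) for s in by_owner.values()}) == 3


def test_three_clusters_each_own_group():
    prof, _ = _archetype_profiles(n_clusters=3)
    assign = hierarchical_subgroups(prof)
    assert sorted(assign.cluster_to_group) == [1, 2, 3]


def test_grouping_invariant_to_cluster_order():
    prof, _ = _archetype_profiles(seed=3)
    perm = np.random.default_rng(0).permutation(len(prof.medians))
    med2 = prof.medians.iloc[perm]
    counts2 = prof.counts.iloc[perm]
    prof2 = ClusterProfile(
        med2, counts2, (counts2 / counts2.sum()).rename("fraction"), prof.event_meta
    )
    a = hierarchical_subgroups(prof)
    b = hierarchical_subgroups(prof2)
    # same partition of cluster ids regardless of row order
    def partition(assign):
        inv = {}
        for cl, g in assign.cluster_to_group.items():
            inv.setdefault(g, set()).add(cl)
        return {frozenset(v) for v in inv.values()}

    assert partition(a) == partition(b)


def test_too_few_clusters_rejected():
    prof, _ = _archetype_profiles(n_clusters=2)
    with pytest.raises(ValueError, match=">= 3"):
        hierarchical_subgroups(prof)


def test_emt_labels_follow_generator_truth():
    prof, owners = _archetype_profiles()
    labelled = label_emt_subgroups(hierarchical_subgroups(prof), prof)
    for cluster_id, owner in zip(prof.medians.index, owners):
        assert labelled.cluster_label(cluster_id) == owner


def test_vimentin_low_group_is_epithelial():
    prof, owners = _archetype_profiles(seed=9)
    labelled = label_emt_subgroups(hierarchical_subgroups(prof), prof)
    epi_clusters = [c for c, o in zip(prof.medians.index, owners) if o == "epithelial"]
    assert all(labelled.cluster_label(c) == "epithelial" for c in epi_clusters)


def test_swapping_non_epithelial_profiles_swaps_labels():
    prof, owners = _archetype_profiles()
    labelled = label_emt_subgroups(hierarchical_subgroups(prof), prof)
    med = prof.medians.copy()
    early = [c for c, o in zip(med.index, owners) if o == "early_EMT"]
    adv = [c for c, o in zip(med.index, owners) if o == "advanced_EMT"]
    swapped = med.copy()
    n_swap = min(len(early), len(adv))
    swapped.loc[early[:n_swap]], swapped.loc[adv[:n_swap]] = (
        med.loc[adv[:n_swap]].to_numpy(),
        med.loc[early[:n_swap]].to_numpy(),
    )
    prof2 = ClusterProfile(swapped, prof.counts, prof.fractions, prof.event_meta)
    labelled2 = label_emt_subgroups(hierarchical_subgroups(prof2), prof2)
    for c_e, c_a in zip(early[:n_swap], adv[:n_swap]):
        assert labelled2.cluster_label(c_e) == "advanced_EMT"
        assert labelled2.cluster_label(c_a) == "early_EMT"


def test_subgroup_summary_conserves_counts():
    prof, _ = _archetype_profiles()
    labelled = label_emt_subgroups(hierarchical_subgroups(prof), prof)
    table = subgroup_summary(prof, labelled)
    assert int(table["count"].sum()) == len(prof.event_meta)
    assert table["fraction"].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def _fake_gated(n_ctc, n_other, pid, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n_ctc + n_other, 3)), columns=["a", "b", "c"])
    ev = EventTable(df, sample_id=pid, patient_id=pid, transformed=True)
    labels = pd.Series(["ctc"] * n_ctc + ["enriched_leucocyte"] * n_other)
    return ev, GateResult.from_labels(labels)


def test_concatenate_conserves_counts_and_patient_identity():
    ev1, g1 = _fake_gated(18, 50, "p8", seed=1)
    ev2, g2 = _fake_gated(25, 40, "p10", seed=2)
    out = concatenate_ctcs(
        {"p8": ev1, "p10": ev2},
        {"p8": g1, "p10": g2},
        {"p8": "positive", "p10": "positive"},
    )
    assert len(out) == 43
    assert set(out.data["patient_id"]) == {"p8", "p10"}


def test_concatenate_excludes_negative_patients():
    ev1, g1 = _fake_gated(18, 50, "p8")
    ev2, g2 = _fake_gated(3, 40, "p12")
    out = concatenate_ctcs(
        {"p8": ev1, "p12": ev2},
        {"p8": g1, "p12": g2},
        {"p8": "positive", "p12": "negative"},
    )
    assert len(out) == 18
    assert set(out.data["patient_id"]) == {"p8"}


def test_concatenate_no_positive_patients_is_empty():
    ev, g = _fake_gated(2, 10, "p12")
    out = concatenate_ctcs({"p12": ev}, {"p12": g}, {"p12": "negative"})
    assert len(out) == 0


def test_concatenate_invalid_call_rejected():
    ev, g = _fake_gated(2, 10, "p1")
    with pytest.raises(ValueError, match="positivity"):
        concatenate_ctcs({"p1": ev}, {"p1": g}, {"p1": "maybe"})


# ---------------------------------------------------------------------------
# tSNE plumbing
# ---------------------------------------------------------------------------


def test_tsne_shape_and_determinism():
    ev, markers = _blob_events(n_per=40, d=5)
    a = embed_tsne(ev, markers, seed=0)
    b = embed_tsne(ev, markers, seed=0)
    assert a.shape == (len(ev), 2)
    np.testing.assert_array_equal(a, b)


def test_tsne_separates_archetypes():
    ev, markers = _blob_events(n_per=40, d=5, seed=5)
    emb = embed_tsne(ev, markers, seed=1)
    assert silhouette_score(emb, ev.truth.to_numpy()) > 0


def test_tsne_too_few_events_rejected():
    ev = EventTable(pd.DataFrame({"m0": np.arange(5.0)}), transformed=True)
    with pytest.raises(ValueError, match=">= 10"):
        embed_tsne(ev, ["m0"])
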