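"""SOM clustering of concatenated CTCs and hierarchical EMT subgrouping.

A batch self-organizing map quantizes the concatenated CTC events on the
ArcSinh scale; map nodes are metaclustered by agglomerative (Ward)
clustering with the metacluster count chosen by an explicit elbow rule;
metacluster median profiles are grouped into three parent groups by
average-linkage hierarchical clustering and labelled epithelial / early-EMT
/ advanced-EMT from their vimentin and EpCAM/E-cadherin medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .events import EventTable, concatenate_events
from .gating import GateResult

# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def concatenate_ctcs(
    samples: dict[str, EventTable],
    ctc_gates: dict[str, GateResult],
    positivity: dict[str, str],
) -> EventTable:
    """Pool ctc-labelled events from CTC-positive patients only.

    Event counts are conserved: the output has exactly the sum of the
    positive patients' ctc tallies, with patient identity kept per event.
    """
    for pid, call in positivity.items():
        if call not in ("positive", "negative"):
            raise ValueError(f"invalid positivity call for {pid}: {call}")
    tables = []
    for pid, events in samples.items():
        if positivity.get(pid) != "positive":
            continue
        gate = ctc_gates[pid]
        mask = (gate.labels == "ctc").to_numpy()
        tables.append(events.subset(mask))
    if not tables:
        return EventTable(
            pd.DataFrame(), sample_id="concatenated", transformed=True
        )
    return concatenate_events(tables)


# ---------------------------------------------------------------------------
# batch SOM
# ---------------------------------------------------------------------------


@dataclass
class SomModel:
    """Trained batch SOM: grid, codebook and training metadata."""

    grid: tuple[int, int]
    codebook: np.ndarray  # nodes x markers, ArcSinh scale
    markers: list[str]
    epochs: int
    seed: int
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def node_coords(self) -> np.ndarray:
        rows, cols = self.grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def best_matching_nodes(model: SomModel, x: np.ndarray) -> np.ndarray:
    """Index of the nearest codebook vector for each event (euclidean)."""
    return np.argmin(cdist(np.asarray(x, dtype=float), model.codebook), axis=1)


def train_som(
    ctcs: EventTable,
    markers: list[str],
    grid: tuple[int, int] = (10, 10),
    epochs: int = 10,
    seed: int = 0,
) -> SomModel:
    """Train a batch SOM on the given markers.

    Nodes are initialized from a random event sample; each batch epoch
    reassigns best-matching nodes and replaces every codebook vector with
    the neighbourhood-weighted mean of its events.  The Gaussian
    neighbourhood radius shrinks linearly from max(grid)/2 to 0.5, so late
    epochs approach plain k-means on the grid nodes.  Identical seeds give
    identical codebooks.
    """
    if len(ctcs) == 0:
        raise ValueError("cannot train a SOM on an empty event table")
    x = ctcs.matrix(markers)
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensities in training data")
    rng = np.random.default_rng(int(seed))
    n_nodes = grid[0] * grid[1]
    if len(x) >= n_nodes:
        init_idx = rng.choice(len(x), size=n_nodes, replace=False)
    else:
        init_idx = rng.choice(len(x), size=n_nodes, replace=True)
    codebook = x[init_idx].astype(float).copy()

    coords = np.column_stack(
        [np.repeat(np.arange(grid[0]), grid[1]), np.tile(np.arange(grid[1]), grid[0])]
    ).astype(float)
    grid_d2 = cdist(coords, coords) ** 2

    sigma_start, sigma_end = max(grid) / 2.0, 0.5
    qes: list[float] = []
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * t
        d = cdist(x, codebook)
        bmu = np.argmin(d, axis=1)
        qes.append(float(d[np.arange(len(x)), bmu].mean()))
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # nodes x nodes
        # accumulate per-BMU sums, then smooth over the grid neighbourhood
        sums = np.zeros_like(codebook)
        counts = np.zeros(n_nodes)
        np.add.at(sums, bmu, x)
        np.add.at(counts, bmu, 1.0)
        num = h @ sums
        den = (h @ counts)[:, None]
        nonzero = den[:, 0] > 1e-12
        codebook[nonzero] = num[nonzero] / den[nonzero]
    # final quantization error after the last update
    d = cdist(x, codebook)
    qes.append(float(d.min(axis=1).mean()))
    return SomModel(grid, codebook, list(markers), epochs, int(seed), qes)


# ---------------------------------------------------------------------------
# elbow metaclustering
# ---------------------------------------------------------------------------


@dataclass
class MetaclusterMap:
    k: int
    node_to_meta: np.ndarray  # node index -> metacluster id in 1..k
    elbow_curve: pd.DataFrame  # columns: k, wss
    threshold: float

    def __post_init__(self) -> None:
        ids = set(np.unique(self.node_to_meta))
        if ids != set(range(1, self.k + 1)):
            raise ValueError("node assignment must be surjective onto 1..k")


def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        total += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return total


def elbow_metacluster(
    model: SomModel,
    k_range: tuple[int, int] = (2, 20),
    threshold: float = 0.05,
) -> MetaclusterMap:
    """Agglomerative metaclustering of codebook vectors with elbow-chosen k.

    Ward linkage over the codebook gives nested partitions for every k in
    the range; k is the smallest value whose incremental decrease in
    within-metacluster sum of squares, relative to the total sum of squares
    of the codebook, falls below ``threshold``.  A flat curve (degenerate
    codebook) yields the smallest k; if no k qualifies, the largest is
    kept.  The full elbow curve is returned.
    """
    k_min, k_max = k_range
    if k_max > model.n_nodes:
        raise ValueError("k_range exceeds the node count")
    if k_min < 1 or k_min > k_max:
        raise ValueError("invalid k_range")
    x = model.codebook
    z = linkage(x, method="ward")
    tss = float(((x - x.mean(axis=0)) ** 2).sum())
    ks = list(range(k_min, k_max + 1))
    partitions = {k: fcluster(z, t=k, criterion="maxclust") for k in ks + [k_max + 1]}
    wss = {k: _wss(x, partitions[k]) for k in partitions}
    curve = pd.DataFrame({"k": ks, "wss": [wss[k] for k in ks]})
    if tss <= 1e-12:
        chosen = k_min
    else:
        chosen = k_max
        for k in ks:
            if (wss[k] - wss[k + 1]) / tss < threshold:
                chosen = k
                break
    labels = partitions[chosen]
    # relabel to a dense 1..k in first-appearance order (k may exceed the
    # number of distinct merges for degenerate codebooks)
    _, dense = np.unique(labels, return_inverse=True)
    return MetaclusterMap(
        int(dense.max() + 1), dense + 1, curve, threshold
    )


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------


@dataclass
class ClusterProfile:
    """Per-metacluster marker medians, counts and fractions."""

    medians: pd.DataFrame  # metacluster x marker, ArcSinh scale
    counts: pd.Series
    fractions: pd.Series
    event_meta: np.ndarray  # per-event metacluster id

    def __post_init__(self) -> None:
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if int(self.counts.sum()) != len(self.event_meta):
            raise ValueError("counts must sum to the concatenated event count")


def cluster_profiles(
    ctcs: EventTable, model: SomModel, meta_map: MetaclusterMap
) -> ClusterProfile:
    """Median ArcSinh profile, count and fraction of every metacluster."""
    if len(ctcs) == 0:
        raise ValueError("no events to profile")
    x = ctcs.matrix(model.markers)
    bmu = best_matching_nodes(model, x)
    meta = meta_map.node_to_meta[bmu]
    ids = np.unique(meta)
    med = pd.DataFrame(
        [np.median(x[meta == m], axis=0) for m in ids],
        index=pd.Index(ids, name="metacluster"),
        columns=model.markers,
    )
    counts = pd.Series({m: int((meta == m).sum()) for m in ids}, name="count")
    fractions = counts / counts.sum()
    return ClusterProfile(med, counts, fractions.rename("fraction"), meta)


# ---------------------------------------------------------------------------
# parent groups and EMT labels
# ---------------------------------------------------------------------------

SUBGROUP_LABELS = ("epithelial", "early_EMT", "advanced_EMT")


@dataclass
class SubgroupAssignment:
    """Metacluster -> parent group -> EMT subgroup labels."""

    cluster_to_group: pd.Series  # metacluster id -> group id (1..3)
    group_labels: dict[int, str] = field(default_factory=dict)  # group id -> label
    dendrogram: str = ""  # Newick text of the cluster-median tree

    def cluster_label(self, metacluster: int) -> str:
        return self.group_labels[int(self.cluster_to_group.loc[metacluster])]

    def labels_for_events(self, event_meta: np.ndarray) -> np.ndarray:
        lut = {
            m: self.group_labels[int(g)] if self.group_labels else str(g)
            for m, g in self.cluster_to_group.items()
        }
        return np.array([lut[m] for m in event_meta])


def _newick(z: np.ndarray, names: list[str]) -> str:
    tree = to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.4g}"

    return walk(tree) + ";"


def hierarchical_subgroups(
    profile: ClusterProfile, n_groups: int = 3, method: str = "average"
) -> SubgroupAssignment:
    """Cut the cluster-median tree (euclidean, average linkage) into 3 groups."""
    n = len(profile.medians)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} metaclusters, got {n}")
    x = profile.medians.to_numpy()
    z = linkage(x, method=method, metric="euclidean")
    groups = fcluster(z, t=n_groups, criterion="maxclust")
    names = [f"c{m}" for m in profile.medians.index]
    return SubgroupAssignment(
        pd.Series(groups, index=profile.medians.index, name="group"),
        dendrogram=_newick(z, names),
    )


def label_emt_subgroups(
    assignment: SubgroupAssignment, profile: ClusterProfile
) -> SubgroupAssignment:
    """Name the three parent groups from their EMT marker medians.

    The group with the lowest mean vimentin median is epithelial; of the
    remaining two, the one with the higher mean EpCAM/E-cadherin median is
    early-EMT, the other advanced-EMT.  Exact ties on a deciding statistic
    are reported as an error rather than silently broken.
    """
    med = profile.medians
    for marker in ("Vimentin", "EpCAM", "E-cadherin"):
        if marker not in med.columns:
            raise KeyError(f"profiles lack required marker {marker}")
    groups = sorted(assignment.cluster_to_group.unique())
    if len(groups) != 3:
        raise ValueError("labelling requires exactly three parent groups")
    vim = {
        g: float(med.loc[assignment.cluster_to_group == g, "Vimentin"].mean())
        for g in groups
    }
    ranked = sorted(groups, key=lambda g: vim[g])
    if vim[ranked[0]] == vim[ranked[1]]:
        raise ValueError("tie on vimentin medians between candidate epithelial groups")
    epithelial = ranked[0]
    rest = ranked[1:]
    epi_score = {
        g: float(
            med.loc[assignment.cluster_to_group == g, ["EpCAM", "E-cadherin"]]
            .mean(axis=1)
            .mean()
        )
        for g in rest
    }
    if epi_score[rest[0]] == epi_score[rest[1]]:
        raise ValueError("tie on EpCAM/E-cadherin between candidate EMT groups")
    early = max(rest, key=lambda g: epi_score[g])
    advanced = min(rest, key=lambda g: epi_score[g])
    labels = {int(epithelial): "epithelial", int(early): "early_EMT", int(advanced): "advanced_EMT"}
    return SubgroupAssignment(
        assignment.cluster_to_group, labels, assignment.dendrogram
    )


def subgroup_summary(
    profile: ClusterProfile, labelled: SubgroupAssignment
) -> pd.DataFrame:
    """Per-subgroup cell counts and fractions of the concatenated set."""
    ev_labels = labelled.labels_for_events(profile.event_meta)
    counts = pd.Series(ev_labels).value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(lab, 0)) for lab in SUBGROUP_LABELS],
            "fraction": [counts.get(lab, 0) / len(ev_labels) for lab in SUBGROUP_LABELS],
        },
        index=pd.Index(SUBGROUP_LABELS, name="subgroup"),
    )
    return out


# ---------------------------------------------------------------------------
# tSNE plumbing
# ---------------------------------------------------------------------------


def embed_tsne(ctcs: EventTable, markers: list[str], seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of events for plotting; nothing downstream uses it."""
    if len(ctcs) < 10:
        raise ValueError("need >= 10 events for an embedding")
    x = ctcs.matrix(markers)
    perplexity = min(30.0, (len(x) - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
        max_iter=500,
    )
    return ts.fit_transform(x)


# convenience used by the pipeline and tests ---------------------------------


def truth_subgroup_of(events: EventTable) -> np.ndarray:
    """Map synthetic truth labels onto subgroup names (ctc_* events only)."""
    if events.truth is None:
        raise ValueError("event table has no truth labels")
    lut = {
        "ctc_epithelial": "epithelial",
        "ctc_early_emt": "early_EMT",
        "ctc_advanced_emt": "advanced_EMT",
    }
    return np.array([lut.get(t, "other") for t in events.truth])
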