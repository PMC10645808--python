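"""Rank tests, composition PCA and clinical association statistics.

The subgroup comparisons use a two-sided Mann-Whitney U test on ArcSinh
intensities: exact by full enumeration of label assignments for small
samples, tie-corrected normal approximation otherwise.  Patient-level
cluster compositions feed a centred PCA whose scores are partitioned by
k-means with silhouette-selected k (the paper-style patient grouping made
explicit).  Clinical associations are univariate logistic regressions
(Wald), a Welch t-test and a one-way ANOVA; raw p values are reported
without multiplicity claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_LIMIT = 12  # largest n1+n2 for which the permutation null is enumerated


@dataclass
class TestResult:
    marker: str
    groups: tuple[str, str]
    u_statistic: float
    p_value: float
    medians: tuple[float, float]
    n: tuple[int, int]
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        n1, n2 = self.n
        if not 0 <= self.u_statistic <= n1 * n2:
            raise ValueError("U must lie in [0, n1*n2]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p must lie in (0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairs with a_i > b_j, halves for ties."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(
    a, b, marker: str = "", groups: tuple[str, str] = ("a", "b")
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For pooled sizes up to 12 the permutation null is fully enumerated
    (ties permitted; the p value is the doubled smaller tail of the exact U
    distribution, capped at 1).  Larger samples use the normal approximation
    with midranks, tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)

    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        idx = np.arange(n1 + n2)
        us = []
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        lo = float((us <= u + 1e-12).mean())
        hi = float((us >= u - 1e-12).mean())
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        ranks = sps.rankdata(np.concatenate([a, b]))
        r1 = ranks[:n1].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0  # equals the pair-count U with midranks
        mean_u = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var_u <= 0:
            return TestResult(
                marker, groups, u, 1.0,
                (float(np.median(a)), float(np.median(b))), (n1, n2), "normal_approx",
            )
        z = (u1 - mean_u - np.sign(u1 - mean_u) * 0.5) / np.sqrt(var_u)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        p = max(p, np.finfo(float).tiny)
        method = "normal_approx"
    return TestResult(
        marker, groups, u, p, (float(np.median(a)), float(np.median(b))), (n1, n2), method
    )


# ---------------------------------------------------------------------------
# subgroup comparisons
# ---------------------------------------------------------------------------


def compare_subgroups(
    values: pd.DataFrame,
    subgroup: pd.Series | np.ndarray,
    markers: list[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests per marker between subgroups.

    ``values`` holds ArcSinh intensities (rows = observations: events, or
    per-cluster medians for a cluster-level comparison); ``subgroup`` the
    matching labels.  Returns one row per (marker, pair).  Benjamini-
    Hochberg adjusted p values are appended only when ``adjust`` is set,
    mirroring reporting of raw p by default.
    """
    labels = pd.Series(np.asarray(subgroup), index=values.index)
    if labels.isna().any():
        raise ValueError("unlabelled observations")
    present = [g for g in labels.unique()]
    if len(present) < 2:
        raise ValueError("need >= 2 subgroups to compare")
    markers = markers or list(values.columns)
    rows = []
    for marker in markers:
        for g1, g2 in combinations(present, 2):
            res = mann_whitney_u(
                values.loc[labels == g1, marker],
                values.loc[labels == g2, marker],
                marker=marker,
                groups=(str(g1), str(g2)),
            )
            rows.append(
                {
                    "marker": marker,
                    "group1": g1,
                    "group2": g2,
                    "n1": res.n[0],
                    "n2": res.n[1],
                    "median1": res.medians[0],
                    "median2": res.medians[1],
                    "U": res.u_statistic,
                    "p": res.p_value,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# composition matrix and PCA
# ---------------------------------------------------------------------------


def composition_matrix(
    event_meta: dict[str, np.ndarray], all_clusters: list[int] | None = None
) -> pd.DataFrame:
    """Row-normalized metacluster fractions per patient.

    ``event_meta[patient] = per-event metacluster ids`` for the patient's
    CTCs.  Patients with zero CTCs are rejected (only positivity-positive
    patients belong here).
    """
    for pid, meta in event_meta.items():
        if len(meta) == 0:
            raise ValueError(f"patient {pid} has zero CTC events")
    clusters = all_clusters or sorted(
        set(int(c) for meta in event_meta.values() for c in meta)
    )
    rows = {}
    for pid, meta in event_meta.items():
        counts = pd.Series(meta).value_counts()
        rows[pid] = [counts.get(c, 0) / len(meta) for c in clusters]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"c{c}" for c in clusters]
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    patient_groups: pd.Series = field(default_factory=pd.Series)
    chosen_k: int = 0


def pca_composition(
    comp: pd.DataFrame,
    n_components: int | None = None,
    group_k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> PcaResult:
    """Centred PCA of the composition matrix plus score-space grouping.

    Patient groups are found by k-means on the scores with k selected by
    mean silhouette over ``group_k_range`` (capped at n-1).
    """
    n_patients = len(comp)
    if n_patients < 2:
        raise ValueError("need >= 2 patients")
    max_comp = min(n_patients, comp.shape[1])
    n_components = n_components or max_comp
    if n_components > max_comp:
        raise ValueError("fewer patients/clusters than components requested")
    pca = PCA(n_components=n_components, random_state=int(seed))
    scores = pca.fit_transform(comp.to_numpy())
    ratio = pca.explained_variance_ratio_
    scores_df = pd.DataFrame(
        scores, index=comp.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    loadings = pd.DataFrame(
        pca.components_.T, index=comp.columns, columns=scores_df.columns
    )

    best_k, best_sil, best_labels = 0, -np.inf, None
    lo, hi = group_k_range
    for k in range(lo, min(hi, n_patients - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(scores)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(scores, km.labels_)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, km.labels_
    groups = pd.Series(
        best_labels if best_labels is not None else np.zeros(n_patients, dtype=int),
        index=comp.index,
        name="group",
    )
    return PcaResult(scores_df, loadings, ratio, groups, best_k)


# ---------------------------------------------------------------------------
# clinical associations
# ---------------------------------------------------------------------------


def _logistic_wald(outcome: np.ndarray, x: np.ndarray) -> dict:
    """Univariate logistic fit of a binary outcome on one covariate."""
    design = sm.add_constant(np.asarray(x, dtype=float))
    try:
        fit = sm.Logit(np.asarray(outcome, dtype=float), design).fit(disp=0)
        converged = bool(fit.mle_retvals.get("converged", True))
        # enormous standard errors signal (quasi-)separation
        separated = bool(np.any(np.asarray(fit.bse) > 1e3))
        return {
            "coef": float(fit.params[1]),
            "p": float(fit.pvalues[1]),
            "converged": converged and not separated,
        }
    except Exception:  # perfect separation raises inside statsmodels
        return {"coef": np.nan, "p": np.nan, "converged": False}


def clinical_associations(
    clinical: pd.DataFrame,
    ctc_totals: pd.Series,
    emt_fraction: pd.Series | None = None,
    tumour_class: pd.Series | None = None,
) -> dict:
    """The study's clinical association tests.

    * univariate logistic regressions of T-stage (T3/4), nodal positivity
      and advanced overall stage (III/IV) on total CTC count (Wald p);
    * Welch t-test of the per-patient EMT CTC fraction by nodal status;
    * one-way ANOVA of CTC count across tumour expression classes.

    Statistics and p values are reported descriptively; non-convergent or
    separated logistic fits are flagged, not raised.
    """
    df = clinical.copy()
    counts = ctc_totals.reindex(df.index).astype(float)
    outcomes = {
        "t_stage_high": df["t_stage"].astype(str).str.startswith(("3", "4")).astype(int),
        "node_positive": (~df["n_stage"].astype(str).isin(["0"])).astype(int),
        "stage_advanced": df["stage"].astype(str).isin(["III", "IV"]).astype(int),
    }
    logistic = {
        name: _logistic_wald(y.to_numpy(), counts.to_numpy())
        for name, y in outcomes.items()
    }

    report: dict = {"logistic": logistic}

    if emt_fraction is not None:
        node = outcomes["node_positive"].reindex(emt_fraction.index)
        g1 = emt_fraction[node == 1].dropna()
        g0 = emt_fraction[node == 0].dropna()
        if len(g1) >= 2 and len(g0) >= 2:
            t, p = sps.ttest_ind(g1, g0, equal_var=False)
            if np.isnan(t):  # both groups constant and equal
                t, p = 0.0, 1.0
            report["emt_by_node_ttest"] = {"t": float(t), "p": float(p)}

    if tumour_class is not None:
        groups = [
            counts.reindex(tumour_class.index)[tumour_class == c].dropna().to_numpy()
            for c in tumour_class.unique()
        ]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 tumour classes")
        f, p = sps.f_oneway(*groups)
        report["count_by_tumour_class_anova"] = {"F": float(f), "p": float(p)}
    return report
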