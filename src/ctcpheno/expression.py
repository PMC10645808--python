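"""Gene-expression comparators for the CTC pipeline.

Two simplified bulk comparators sit alongside the mass-cytometry analysis:

* a median-of-ratios count normalization plus negative-binomial Wald
  differential expression (method-of-moments dispersion, Benjamini-Hochberg
  adjustment) — a deliberately simplified re-implementation of the standard
  RNA-seq workflow, sufficient for the paired enriched-vs-PBMC contrast;
* hierarchical classification of tumour samples on an epithelial/
  mesenchymal signature (log-normalized, gene-wise z-scored, euclidean
  complete-linkage tree cut at three classes);
* projection of per-patient differential expression onto the antibody
  panel and a descriptive concordance report against the cytometry calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .countmatrix import CountMatrix
from .genes import MARKER_GENE_MAP
from .panel import PanelDefinition
from .stats import benjamini_hochberg

# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-gene geometric mean over samples, computed on
    genes with nonzero counts in every sample; each sample's size factor is
    the median ratio of its counts to the reference, standardized so the
    factors have geometric mean 1 (which makes the operation idempotent).
    Raises when no gene is nonzero everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in all samples")
    ref = mat[all_nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    log_factors = np.median(np.log(ref) - log_geo_mean[:, None], axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return size_factors, normalized


# ---------------------------------------------------------------------------
# NB Wald differential expression
# ---------------------------------------------------------------------------

DISPERSION_FLOOR = 1e-8


@dataclass
class DEResult:
    """Per-gene differential-expression table plus metadata."""

    table: pd.DataFrame  # mean_a, mean_b, log2_fc, stat, p, p_adj, significant
    groups: tuple[str, str]
    fdr: float

    def significant_genes(self, elevated_only: bool = False) -> list[str]:
        t = self.table
        mask = t["significant"]
        if elevated_only:
            mask = mask & (t["log2_fc"] > 0)
        return list(t.index[mask])


def nb_wald_de(
    counts: pd.DataFrame,
    group_labels: pd.Series | dict[str, str],
    contrast: tuple[str, str] | None = None,
    fdr: float = 0.05,
    prior_dispersion: float = 0.1,
    prior_df: int = 6,
    shrink_weight: float = 0.5,
) -> DEResult:
    """Negative-binomial Wald test between two sample groups.

    After median-of-ratios normalization, each gene gets a method-of-moments
    dispersion (floored at 1e-8; pooled across groups and shrunk
    geometrically toward the gene-wise median with ``shrink_weight``), a
    log2 fold change of normalized group means, a Wald statistic from the
    delta-method standard error of the log-mean difference, and a
    BH-adjusted p value.  The reference distribution is a moderated t with
    ``n1 + n2 - 2 + prior_df`` degrees of freedom: the shrinkage prior is
    estimated from all genes, so it contributes information beyond the
    residual degrees of freedom while the finite tail still absorbs the
    remaining dispersion uncertainty.  When both groups have a single
    sample — the per-patient enriched vs matched-PBMC design — the
    configured ``prior_dispersion`` stands in for the inestimable per-gene
    value.
    """
    labels = pd.Series(group_labels)
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    ga, gb = contrast or (uniq[0], uniq[1])
    cols_a = labels.index[labels == ga]
    cols_b = labels.index[labels == gb]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both contrast groups need >= 1 sample")

    _, norm = median_of_ratios_normalize(counts)
    xa = norm[cols_a].to_numpy(dtype=float)
    xb = norm[cols_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)

    # method-of-moments dispersion pooled over the two groups, shrunk
    # toward the gene-wise median (the moderation prior)
    if na >= 2 or nb >= 2:
        disp_parts, weights = [], []
        for x, mu, n in ((xa, mean_a, na), (xb, mean_b, nb)):
            if n >= 2:
                var = x.var(axis=1, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = (var - mu) / np.where(mu > 0, mu**2, np.nan)
                disp_parts.append(np.nan_to_num(d, nan=0.0))
                weights.append(n - 1)
        disp = np.average(disp_parts, axis=0, weights=weights)
        disp = np.clip(disp, DISPERSION_FLOOR, None)
        prior = max(float(np.median(disp)), DISPERSION_FLOOR)
        disp = np.exp(
            shrink_weight * np.log(disp) + (1.0 - shrink_weight) * np.log(prior)
        )
    else:
        disp = np.full(len(counts), prior_dispersion)
    disp = np.clip(disp, DISPERSION_FLOOR, None)

    pseudo = 0.5
    log2_fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    # delta method: Var[log2 mean] = Var[mean] / (mean^2 ln(2)^2)
    var_a = (mean_a + disp * mean_a**2) / na
    var_b = (mean_b + disp * mean_b**2) / nb
    se = np.sqrt(
        var_a / np.maximum(mean_a + pseudo, 1e-12) ** 2
        + var_b / np.maximum(mean_b + pseudo, 1e-12) ** 2
    ) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2_fc / se, 0.0)
    df_total = max(na + nb - 2, 0) + prior_df
    p = 2.0 * sps.t.sf(np.abs(stat), df=df_total)
    identical = (se == 0) & (log2_fc == 0)
    p = np.where(identical, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "dispersion": disp,
            "stat": stat,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= fdr,
        },
        index=counts.index,
    )
    return DEResult(table, (str(ga), str(gb)), fdr)


# ---------------------------------------------------------------------------
# panel projection
# ---------------------------------------------------------------------------


def panel_dge_map(
    de_results: dict[str, DEResult],
    panel: PanelDefinition,
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """Binary marker x patient map of significant elevation in enriched RNA.

    For each panel marker with a mapped gene, 1 iff the gene is
    significantly elevated in the patient's enriched sample versus the
    matched PBMC control.  Markers without a mapped gene are skipped and
    recorded in ``warn`` when a list is supplied.
    """
    rows = {}
    for marker in panel.analytical_markers:
        gene, _flagged = MARKER_GENE_MAP.get(marker, (None, False))
        if gene is None:
            if warn is not None:
                warn.append(marker)
            continue
        row = {}
        for patient, de in de_results.items():
            if gene in de.table.index:
                row[patient] = int(gene in de.significant_genes(elevated_only=True))
            else:
                row[patient] = 0
        rows[marker] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def paired_dge_by_patient(
    bulk: CountMatrix, fdr: float = 0.05, prior_dispersion: float = 0.05
) -> dict[str, DEResult]:
    """Run enriched-vs-matched-PBMC DE per patient from a paired matrix."""
    meta = bulk.sample_meta
    out = {}
    for pid in meta["patient_id"].unique():
        cols = meta.index[meta["patient_id"] == pid]
        roles = meta.loc[cols, "role"]
        if set(roles) != {"enriched", "matched_pbmc"}:
            raise ValueError(f"patient {pid} lacks a matched enriched/PBMC pair")
        de = nb_wald_de(
            bulk.counts[cols],
            roles,
            contrast=("matched_pbmc", "enriched"),
            fdr=fdr,
            prior_dispersion=prior_dispersion,
        )
        out[pid] = de
    return out


# ---------------------------------------------------------------------------
# tumour EMT-signature classification
# ---------------------------------------------------------------------------


@dataclass
class TumourClassAssignment:
    classes: pd.Series  # sample -> {epithelial, mesenchymal, mixed}
    scores: pd.DataFrame  # per-sample mean epithelial / mesenchymal z-scores
    linkage_matrix: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))


def emt_signature_cluster(
    tumour: CountMatrix,
    signature: dict[str, list[str]] | None = None,
) -> TumourClassAssignment:
    """Classify tumours as epithelial / mesenchymal / mixed.

    The signature submatrix is log-normalized (log1p of median-of-ratios
    counts), z-scored per gene, and samples are joined by a euclidean
    complete-linkage tree cut at three branches.  A branch whose mean
    epithelial and mesenchymal scores are both above 0 is mixed; otherwise
    the branch takes the arm with the higher score.
    """
    signature = signature or {
        "signature_epithelial": tumour.gene_sets.get("signature_epithelial", []),
        "signature_mesenchymal": tumour.gene_sets.get("signature_mesenchymal", []),
    }
    epi = [g for g in signature["signature_epithelial"] if g in tumour.counts.index]
    mes = [g for g in signature["signature_mesenchymal"] if g in tumour.counts.index]
    if not epi or not mes:
        raise ValueError("signature genes missing from the count matrix")
    if tumour.counts.shape[1] < 3:
        raise ValueError("need >= 3 samples to cut three classes")

    _, norm = median_of_ratios_normalize(tumour.counts)
    sub = np.log1p(norm.loc[epi + mes])
    sd = sub.std(axis=1, ddof=0)
    if (sd < 1e-12).all():
        raise ValueError("degenerate distances: all samples identical on the signature")
    keep = sd > 1e-12
    z = sub[keep].sub(sub[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)

    samples = list(tumour.counts.columns)
    zmat = z.to_numpy().T  # samples x genes
    lm = linkage(zmat, method="complete", metric="euclidean")
    branches = fcluster(lm, t=3, criterion="maxclust")

    epi_kept = [g for g in epi if keep.get(g, False)]
    mes_kept = [g for g in mes if keep.get(g, False)]
    scores = pd.DataFrame(
        {
            "epithelial_score": z.loc[epi_kept].mean(axis=0),
            "mesenchymal_score": z.loc[mes_kept].mean(axis=0),
        },
        index=samples,
    )
    classes = {}
    for b in np.unique(branches):
        members = [s for s, br in zip(samples, branches) if br == b]
        e = scores.loc[members, "epithelial_score"].mean()
        m = scores.loc[members, "mesenchymal_score"].mean()
        if e > 0 and m > 0:
            label = "mixed"
        elif e >= m:
            label = "epithelial"
        else:
            label = "mesenchymal"
        for s in members:
            classes[s] = label
    return TumourClassAssignment(
        pd.Series(classes, name="tumour_class").reindex(samples), scores, lm
    )


# ---------------------------------------------------------------------------
# concordance report
# ---------------------------------------------------------------------------

EPITHELIAL_DETECTION_MARKERS = ("EpCAM", "Pan-cytokeratin", "E-cadherin")


def concordance_report(
    cytometry_positive: pd.Series,
    cytometry_emt_fraction: pd.Series,
    dge_map: pd.DataFrame,
    tumour_classes: pd.Series | None = None,
    ctc_totals: pd.Series | None = None,
    emt_detect_floor: float = 0.0,
) -> dict:
    """Descriptive agreement between cytometry and bulk expression calls.

    Per patient: does bulk epithelial-transcript detection agree with the
    cytometry positivity call, and does bulk vimentin detection agree with
    the presence of EMT CTCs (fraction above ``emt_detect_floor``)?  When
    tumour classes are supplied, one-way ANOVAs of CTC count and EMT
    fraction across classes are appended.  All quantities are reported
    descriptively; no significance claim is made.
    """
    patients = [p for p in dge_map.columns if p in cytometry_positive.index]
    missing = [p for p in dge_map.columns if p not in cytometry_positive.index]
    if missing:
        raise ValueError(f"unmatched patient identifiers: {missing}")

    epi_rows = [m for m in EPITHELIAL_DETECTION_MARKERS if m in dge_map.index]
    rows = []
    for p in patients:
        bulk_pos = bool(dge_map.loc[epi_rows, p].any()) if epi_rows else False
        cyto_pos = bool(cytometry_positive.loc[p])
        bulk_emt = (
            bool(dge_map.loc["Vimentin", p]) if "Vimentin" in dge_map.index else False
        )
        cyto_emt = bool(cytometry_emt_fraction.get(p, 0.0) > emt_detect_floor)
        ki67 = bool(dge_map.loc["Ki67", p]) if "Ki67" in dge_map.index else False
        rows.append(
            {
                "patient": p,
                "cytometry_positive": cyto_pos,
                "bulk_positive": bulk_pos,
                "positivity_agrees": bulk_pos == cyto_pos,
                "cytometry_emt": cyto_emt,
                "bulk_emt": bulk_emt,
                "emt_agrees": bulk_emt == cyto_emt,
                "bulk_ki67": ki67,
            }
        )
    per_patient = pd.DataFrame(rows).set_index("patient")
    report: dict = {
        "per_patient": per_patient,
        "n_patients": len(patients),
        "positivity_agreement": int(per_patient["positivity_agrees"].sum()),
        "emt_agreement": int(per_patient["emt_agrees"].sum()),
        "bulk_emt_detected": int(per_patient["bulk_emt"].sum()),
    }
    if tumour_classes is not None:
        shared = [p for p in patients if p in tumour_classes.index]
        groups = tumour_classes.loc[shared]
        anovas = {}
        for name, series in (
            ("ctc_count", ctc_totals),
            ("emt_fraction", cytometry_emt_fraction),
        ):
            if series is None:
                continue
            vals = series.reindex(shared).astype(float)
            parts = [vals[groups == c].dropna() for c in groups.unique()]
            parts = [p_ for p_ in parts if len(p_) > 0]
            if len(parts) >= 2:
                f, pv = sps.f_oneway(*parts)
                anovas[name] = {"F": float(f), "p": float(pv)}
        report["anova_by_tumour_class"] = anovas
    return report
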