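"""Event transform, clean-up gating, population deconvolution and CTC calling.

The stage order mirrors routine mass-cytometry practice: ArcSinh transform
of the antibody channels; removal of debris and fused events by the
acquisition Gaussian discrimination parameters (Center, Offset, Width,
Residual, Event_length); deconvolution of barcoded carrier PBMCs,
osmium-labelled control PBMCs and the enriched fraction; and rule-based CTC
identification within the enriched fraction (CD45-low AND all immune
lineage markers low AND pan-cytokeratin intermediate/high).  A patient is
scored CTC-positive when the tally exceeds the healthy-donor background
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .events import EventTable, acquisition_columns
from .panel import (
    ACQUISITION_CHANNELS,
    CTC_EXCLUSION_MARKERS,
    CTC_INCLUSION_MARKER,
    PanelDefinition,
)

# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


@dataclass
class TransformSpec:
    """ArcSinh transform x -> asinh(x / cofactor) for antibody channels."""

    cofactor: float = 5.0
    channels: list[str] | None = None  # None = all non-acquisition channels

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")


def arcsinh_transform(events: EventTable, spec: TransformSpec | None = None) -> EventTable:
    """ArcSinh-transform analytical channels; acquisition channels untouched.

    Monotone and order-preserving per channel. Re-application is refused via
    the table's ``transformed`` flag.
    """
    spec = spec or TransformSpec()
    if events.transformed:
        raise ValueError("event table is already ArcSinh-transformed")
    channels = spec.channels
    if channels is None:
        skip = set(ACQUISITION_CHANNELS) | {"Time"}
        channels = [c for c in events.data.columns if c not in skip]
    bad = [c for c in channels if c in ACQUISITION_CHANNELS]
    if bad:
        raise ValueError(f"acquisition channels must not be transformed: {bad}")
    out = events.data.copy()
    out[channels] = np.arcsinh(out[channels].to_numpy(dtype=float) / spec.cofactor)
    return replace(events, data=out, transformed=True)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


@dataclass
class GateThresholds:
    """Cut points and windows for every gating stage.

    Clean-up windows default to Tukey fences (Q1 - k*IQR, Q3 + k*IQR) per
    acquisition channel, which adapt to the sample while tolerating a
    contaminating debris mode; plain quantile windows or fixed bounds can be
    supplied instead.  Marker cut points set to ``None`` are resolved
    data-driven (valley between the two modes of the ArcSinh distribution,
    anchored by carrier PBMCs where available) with a fixed fallback.
    """

    cleanup_mode: str = "tukey"  # "tukey" | "quantile" | "fixed"
    tukey_k: float = 3.0
    quantile_window: tuple[float, float] = (0.01, 0.99)
    fixed_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    barcode_high: float | None = None
    osmium_high: float | None = None
    cd45_low: float | None = None
    lineage_low: dict[str, float] = field(default_factory=dict)
    panck_min: float | None = None
    fallback_cut: float | None = 2.0

    background_ctc_threshold: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.quantile_window
        if not (0 <= lo < hi <= 1):
            raise ValueError("quantile window must satisfy 0 <= lo < hi <= 1")
        for ch, (lo, hi) in self.fixed_windows.items():
            if lo >= hi:
                raise ValueError(f"window for {ch} must have lower < upper")
        if self.background_ctc_threshold < 0:
            raise ValueError("background_ctc_threshold must be >= 0")


@dataclass
class GateResult:
    """Per-event labels for one gating stage plus tallies and provenance."""

    labels: pd.Series
    tallies: dict[str, int]
    thresholds_used: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.labels.value_counts().to_dict()
        for k, v in self.tallies.items():
            if counts.get(k, 0) != v:
                raise ValueError("tallies must equal label counts")

    @classmethod
    def from_labels(cls, labels: pd.Series, thresholds: dict | None = None) -> "GateResult":
        labels = labels.reset_index(drop=True)
        return cls(labels, labels.value_counts().to_dict(), thresholds or {})


# ---------------------------------------------------------------------------
# clean-up gating
# ---------------------------------------------------------------------------


def _resolve_window(
    values: np.ndarray, channel: str, thresholds: GateThresholds
) -> tuple[float, float]:
    if channel in thresholds.fixed_windows:
        return thresholds.fixed_windows[channel]
    if thresholds.cleanup_mode == "fixed":
        raise ValueError(f"fixed clean-up requested but no window for {channel}")
    if thresholds.cleanup_mode == "quantile":
        lo, hi = thresholds.quantile_window
        return float(np.quantile(values, lo)), float(np.quantile(values, hi))
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    k = thresholds.tukey_k
    return float(q1 - k * iqr), float(q3 + k * iqr)


def gaussian_cleanup(events: EventTable, thresholds: GateThresholds | None = None) -> GateResult:
    """Label events outside the acquisition-parameter windows as debris.

    An event is debris if it falls outside the retention window on any of
    the Gaussian discrimination channels; all other events are retained.
    Resolved windows are recorded in the result's provenance.
    """
    thresholds = thresholds or GateThresholds()
    acq = acquisition_columns(events)
    missing = [c for c in ACQUISITION_CHANNELS if c not in acq]
    if missing:
        raise KeyError(f"missing acquisition channels: {missing}")
    keep = np.ones(len(events), dtype=bool)
    used: dict[str, object] = {"cleanup_mode": thresholds.cleanup_mode}
    for ch in acq:
        v = events.data[ch].to_numpy(dtype=float)
        lo, hi = _resolve_window(v, ch, thresholds)
        used[ch] = (lo, hi)
        keep &= (v >= lo) & (v <= hi)
    labels = pd.Series(np.where(keep, "retained", "debris"), name="cleanup")
    return GateResult.from_labels(labels, used)


# ---------------------------------------------------------------------------
# valley-seeking threshold resolution
# ---------------------------------------------------------------------------


def valley_cut(values: np.ndarray, min_mode_frac: float = 0.05) -> float | None:
    """Find the density valley between the two dominant modes of ``values``.

    Returns None when the distribution is effectively unimodal (fewer than
    two modes above ``min_mode_frac`` of the peak density).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 20 or np.ptp(v) < 1e-9:
        return None
    if len(v) > 20000:
        v = v[:: len(v) // 20000 + 1]
    grid = np.linspace(v.min(), v.max(), 512)
    try:
        dens = gaussian_kde(v)(grid)
    except np.linalg.LinAlgError:
        return None
    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[dens[peaks] >= min_mode_frac * dens.max()]
    # collapse plateaus / adjacent ripples into distinct modes
    modes: list[int] = []
    for p in peaks:
        if modes and (grid[p] - grid[modes[-1]]) < 0.05 * np.ptp(grid):
            if dens[p] > dens[modes[-1]]:
                modes[-1] = p
        else:
            modes.append(p)
    if len(modes) < 2:
        return None
    top2 = sorted(sorted(modes, key=lambda i: -dens[i])[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def _resolve_cut(
    configured: float | None,
    values: np.ndarray,
    fallback: float | None,
) -> tuple[float, str]:
    if configured is not None:
        return float(configured), "configured"
    cut = valley_cut(values)
    if cut is not None:
        return cut, "valley"
    if fallback is None:
        raise ValueError(
            "channel distribution is unimodal and no configured fallback cut is set"
        )
    return float(fallback), "fallback"


# ---------------------------------------------------------------------------
# deconvolution and CTC identification
# ---------------------------------------------------------------------------


def deconvolute_populations(
    events: EventTable, panel: PanelDefinition, thresholds: GateThresholds | None = None
) -> GateResult:
    """Separate carrier, control and enriched populations.

    Barcode-high events are carriers, osmium-high events are controls, and
    double-negative events form the enriched fraction.  Cut points are
    sought as the valley between the two modes of each channel's ArcSinh
    distribution, falling back to a configured fixed cut.
    """
    thresholds = thresholds or GateThresholds()
    if not events.transformed:
        raise ValueError("deconvolution expects ArcSinh-transformed events")
    barcode = panel.barcode_marker
    osmium = panel.control_marker
    for ch in (barcode, osmium):
        if ch not in events.data.columns:
            raise KeyError(f"missing channel: {ch}")
    b = events.data[barcode].to_numpy(dtype=float)
    o = events.data[osmium].to_numpy(dtype=float)
    b_cut, b_src = _resolve_cut(thresholds.barcode_high, b, thresholds.fallback_cut)
    o_cut, o_src = _resolve_cut(thresholds.osmium_high, o, thresholds.fallback_cut)
    labels = np.where(b > b_cut, "carrier", np.where(o > o_cut, "control", "enriched"))
    return GateResult.from_labels(
        pd.Series(labels, name="population"),
        {"barcode_high": (b_cut, b_src), "osmium_high": (o_cut, o_src)},
    )


def identify_ctcs(
    enriched: EventTable,
    panel: PanelDefinition,
    thresholds: GateThresholds | None = None,
    anchor: EventTable | None = None,
) -> GateResult:
    """Apply the CTC rule within the enriched fraction.

    An event is a CTC iff CD45 is below ``cd45_low`` AND every immune
    lineage marker (CD3, CD4, CD8, CD19, CD14, CD56, CD66b) is below its
    ``lineage_low`` AND pan-cytokeratin is at or above ``panck_min``.  All
    other enriched events are labelled ``enriched_leucocyte``.  When cut
    points are unset they are resolved as the valley of the marker's
    distribution over the enriched events pooled with the optional carrier
    ``anchor`` (whose PBMCs pin the marker-positive mode).
    """
    thresholds = thresholds or GateThresholds()
    if not enriched.transformed:
        raise ValueError("CTC identification expects ArcSinh-transformed events")
    panel.require(list(CTC_EXCLUSION_MARKERS) + [CTC_INCLUSION_MARKER])
    missing = [
        m
        for m in list(CTC_EXCLUSION_MARKERS) + [CTC_INCLUSION_MARKER]
        if m not in enriched.data.columns
    ]
    if missing:
        raise KeyError(f"enriched events missing markers: {missing}")

    def pooled(marker: str) -> np.ndarray:
        v = enriched.data[marker].to_numpy(dtype=float)
        if anchor is not None and marker in anchor.data.columns:
            v = np.concatenate([v, anchor.data[marker].to_numpy(dtype=float)])
        return v

    used: dict[str, object] = {}
    cd45_cut, src = _resolve_cut(thresholds.cd45_low, pooled("CD45"), thresholds.fallback_cut)
    used["cd45_low"] = (cd45_cut, src)
    is_ctc = enriched.data["CD45"].to_numpy(dtype=float) < cd45_cut
    for m in CTC_EXCLUSION_MARKERS[1:]:
        cut, src = _resolve_cut(
            thresholds.lineage_low.get(m), pooled(m), thresholds.fallback_cut
        )
        used[f"lineage_low:{m}"] = (cut, src)
        is_ctc &= enriched.data[m].to_numpy(dtype=float) < cut
    panck_cut, src = _resolve_cut(
        thresholds.panck_min, pooled(CTC_INCLUSION_MARKER), thresholds.fallback_cut
    )
    used["panck_min"] = (panck_cut, src)
    is_ctc &= enriched.data[CTC_INCLUSION_MARKER].to_numpy(dtype=float) >= panck_cut
    labels = pd.Series(np.where(is_ctc, "ctc", "enriched_leucocyte"), name="ctc_gate")
    return GateResult.from_labels(labels, used)


# ---------------------------------------------------------------------------
# positivity scoring
# ---------------------------------------------------------------------------


def score_positivity(ctc_total: int, thresholds: GateThresholds | None = None) -> str:
    """'negative' iff the tally is at or below the healthy-donor background."""
    thresholds = thresholds or GateThresholds()
    if ctc_total < 0:
        raise ValueError("ctc_total must be >= 0")
    return "negative" if ctc_total <= thresholds.background_ctc_threshold else "positive"


def per_ml(ctc_total: int, volume_ml: float = 9.0) -> int:
    """Cells/ml as round-half-up of total / volume."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    if ctc_total < 0:
        raise ValueError("ctc_total must be >= 0")
    return int(np.floor(ctc_total / volume_ml + 0.5))
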