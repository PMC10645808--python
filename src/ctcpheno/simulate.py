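"""Synthetic cohort generator for the CTC mass-cytometry pipeline.

Emulates the structure of a head-and-neck cancer CTC study: per patient, a
stained sample containing barcoded autologous PBMC carrier cells,
osmium-labelled stimulated control PBMCs, a microfluidically enriched
fraction (CTCs plus contaminating leucocytes) and a debris/doublet fraction
with aberrant acquisition Gaussian parameters.  Three CTC archetypes are
generated — epithelial, early-EMT and advanced-EMT — whose marker
co-patterns encode the study's phenotype structure (EpCAM/E-cadherin falling
and vimentin rising along the EMT axis; pCREB up in both EMT groups, pERK up
in early EMT, pSTAT1 down in advanced EMT, CD44 up in EMT groups).

Channel intensities follow a zero-inflated lognormal: with probability
``zero_p`` the ion count is zero, otherwise LogNormal(mu, sigma) with
``mu = log(cofactor * sinh(level))`` so that the ArcSinh-transformed median
equals the configured archetype ``level``.

Companion negative-binomial count matrices carry (a) a synthetic
epithelial/mesenchymal tumour signature and (b) bulk enriched-vs-PBMC
profiles whose panel-marker genes are elevated proportionally to the
abundance of protein-expressing cells, so low-frequency EMT CTCs can fall
below bulk detectability.

Every output is a pure function of (config, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .events import EventTable
from .genes import mapped_markers
from .panel import ACQUISITION_CHANNELS, PanelDefinition, make_default_panel

# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


@dataclass
class PatientEntry:
    patient_id: str
    age: int
    sex: str
    t_stage: str
    n_stage: str
    m_stage: str
    stage: str
    site: str
    treatment: str
    true_ctc_total: int
    draw_volume_ml: float = 9.0
    #: simplex weights over (epithelial, early_EMT, advanced_EMT)
    mixture: tuple[float, float, float] = (0.2, 0.5, 0.3)

    def __post_init__(self) -> None:
        if self.true_ctc_total < 0:
            raise ValueError("true_ctc_total must be >= 0")
        if self.draw_volume_ml <= 0:
            raise ValueError("draw_volume_ml must be > 0")
        w = np.asarray(self.mixture, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be a simplex")


@dataclass
class DonorEntry:
    donor_id: str
    true_ctc_total: int = 0
    draw_volume_ml: float = 9.0
    mixture: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    """Study cohort plus per-sample composition settings (scaled down)."""

    patients: list[PatientEntry]
    healthy_donors: list[DonorEntry] = field(default_factory=list)
    carrier_count: int = 9000
    control_count: int = 1000
    enriched_count: int = 1000
    debris_fraction: float = 0.05

    def __post_init__(self) -> None:
        for n in (self.carrier_count, self.control_count, self.enriched_count):
            if n < 0:
                raise ValueError("cell counts must be >= 0")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris_fraction must be in [0, 1)")
        for p in self.patients:
            if self.enriched_count < p.true_ctc_total:
                raise ValueError(
                    f"enriched_count {self.enriched_count} < true_ctc_total "
                    f"of patient {p.patient_id}"
                )

    def entry(self, sample_id: str) -> PatientEntry | DonorEntry:
        for p in self.patients:
            if p.patient_id == sample_id:
                return p
        for d in self.healthy_donors:
            if d.donor_id == sample_id:
                return d
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients] + [
            d.donor_id for d in self.healthy_donors
        ]


# patient rows of the study cohort table: id, age, sex, T, N, M, stage, site,
# treatment, total CTC count per 9 ml draw, default subgroup mixture.
_COHORT_ROWS = [
    ("1", 77, "M", "4a", "1", "0", "IV", "Oral", "S+CRT", 97, (0.20, 0.50, 0.30)),
    ("2", 65, "M", "4a", "0", "0", "IV", "Larynx", "S", 40, (0.35, 0.45, 0.20)),
    ("3", 73, "M", "3", "2b", "0", "IV", "Oral", "S+RT", 54, (0.15, 0.55, 0.30)),
    ("4", 75, "M", "3", "2b", "0", "IV", "Oral", "S+RT", 98, (0.10, 0.50, 0.40)),
    ("5", 53, "M", "3", "0", "0", "III", "Oral", "S+CRT", 58, (0.30, 0.50, 0.20)),
    ("6", 63, "M", "4a", "0", "0", "IV", "Oral", "S+RT", 167, (0.20, 0.55, 0.25)),
    ("7", 43, "F", "4a", "2b", "0", "IV", "Oral", "S+CRT", 86, (0.20, 0.45, 0.35)),
    ("8", 66, "F", "4a", "2b", "0", "IV", "Oral", "S+RT", 18, (0.30, 0.40, 0.30)),
    ("9", 57, "M", "3", "0", "0", "III", "Oral", "S", 39, (0.25, 0.45, 0.30)),
    ("10", 52, "F", "2", "0", "0", "II", "Oral", "S", 25, (0.40, 0.60, 0.00)),
    ("11", 73, "M", "4a", "0", "0", "IV", "Oral", "S+RT", 183, (0.00, 0.50, 0.50)),
    ("12", 76, "F", "1", "0", "0", "I", "Oral", "S", 0, (0.20, 0.50, 0.30)),
    ("13", 61, "M", "4a", "0", "0", "IV", "Oral", "S+RT", 61, (0.20, 0.50, 0.30)),
    ("14", 62, "M", "4a", "2b", "0", "IV", "Oral", "S+RT", 218, (0.25, 0.50, 0.25)),
]


def default_cohort(patient12_alternate: bool = False) -> CohortConfig:
    """The 14-patient study cohort plus six healthy donors.

    Patient 12's printed total is 0; the running text instead describes 4
    background-level cells for this stage-I patient. ``patient12_alternate``
    exposes the second reading.  Two of the six healthy donors carry
    background CTC-like cells (totals 2 and 3 per draw).
    """
    patients = []
    for pid, age, sex, t, n, m, stage, site, rx, total, mix in _COHORT_ROWS:
        if pid == "12" and patient12_alternate:
            total = 4
        patients.append(
            PatientEntry(pid, age, sex, t, n, m, stage, site, rx, total, mixture=mix)
        )
    donors = [
        DonorEntry("HD1", 2),
        DonorEntry("HD2", 3),
        DonorEntry("HD3", 0),
        DonorEntry("HD4", 0),
        DonorEntry("HD5", 0),
        DonorEntry("HD6", 0),
    ]
    return CohortConfig(patients=patients, healthy_donors=donors)


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

# (level on the ArcSinh scale, zero-inflation probability)
_OFF = (0.15, 0.50)
_LOW = (1.0, 0.20)
_MID = (3.0, 0.05)
_MIDHI = (4.0, 0.02)
_HI = (5.0, 0.01)

# shared PBMC profile; carriers/controls/leucocytes derive from it
_PBMC = {
    "CD45": _HI,
    "CD3": (3.0, 0.40),
    "CD4": (2.5, 0.50),
    "CD8": (2.0, 0.60),
    "CD25": (1.0, 0.60),
    "CD14": (2.0, 0.60),
    "CD86": (1.5, 0.60),
    "CD163": (1.0, 0.70),
    "CD19": (1.5, 0.70),
    "CD56": (1.5, 0.70),
    "CD66b": (1.0, 0.70),
    "HLA-ABC": _MIDHI,
    "HLA-DR": (3.0, 0.30),
    "CD31": (1.0, 0.50),
    "Vimentin": (1.5, 0.30),
    "CD24": (2.0, 0.40),
    "CD44": (3.5, 0.05),
    "Ki67": (0.5, 0.60),
    "CD47": (3.0, 0.10),
    "PD-1": (1.5, 0.50),
    "CD39": (1.5, 0.50),
    "CD73": (1.5, 0.50),
    "pSTAT1": (1.2, 0.30),
    "pSTAT3": (1.2, 0.30),
    "pSTAT5": (1.2, 0.30),
    "pPARP": (1.0, 0.30),
    "pAKT": (1.2, 0.30),
    "pERK": (1.2, 0.30),
    "pCREB": (1.2, 0.30),
    "p38": (1.2, 0.30),
}

# CTC base: everything immune off, CD45 low
_CTC_BASE = {
    "CD45": (0.3, 0.40),
    "HLA-ABC": _MID,
}

_CTC_EPITHELIAL = {
    **_CTC_BASE,
    "EpCAM": _HI,
    # CTCs are identified as pan-cytokeratin intermediate/high, so the
    # archetypes carry no zero inflation on this channel
    "Pan-cytokeratin": (5.0, 0.0),
    "E-cadherin": _HI,
    "EGFR": _MIDHI,
    "Vimentin": (0.5, 0.30),
    "Snail1": _LOW,
    "Twist": _LOW,
    "CD133": (3.5, 0.05),
    "CD24": (3.5, 0.05),
    "CD44": (2.0, 0.10),
    "Ki67": _MID,
    "CD47": (3.5, 0.05),
    "PD-1": (3.0, 0.05),
    "PD-L1": (3.5, 0.05),
    "PD-L2": (3.0, 0.05),
    "CTLA4": (3.0, 0.05),
    "CD39": (3.5, 0.05),
    "CD73": (3.0, 0.05),
    "pSTAT1": (3.5, 0.05),
    "pSTAT3": (3.5, 0.05),
    "pSTAT5": (3.5, 0.05),
    "pPARP": (3.5, 0.05),
    "pAKT": (3.5, 0.05),
    "pERK": (1.5, 0.10),
    "pCREB": (1.5, 0.10),
    "p38": (2.5, 0.05),
}

_CTC_EARLY_EMT = {
    **_CTC_BASE,
    "EpCAM": _MID,
    "Pan-cytokeratin": (4.0, 0.0),
    "E-cadherin": _MID,
    "EGFR": _MID,
    "Vimentin": _HI,
    "Snail1": _MID,
    "Twist": (3.5, 0.05),
    "CD133": _LOW,
    "CD24": _LOW,
    "CD44": (4.0, 0.02),
    "Ki67": (3.5, 0.05),
    "CD47": (2.0, 0.10),
    "PD-1": (1.5, 0.20),
    "PD-L1": (1.5, 0.20),
    "PD-L2": (1.5, 0.20),
    "CTLA4": (1.5, 0.20),
    "CD39": (1.5, 0.20),
    "CD73": (1.5, 0.20),
    "pSTAT1": _MID,
    "pSTAT3": (2.5, 0.05),
    "pSTAT5": (2.5, 0.05),
    "pPARP": (2.5, 0.05),
    "pAKT": (2.5, 0.05),
    "pERK": (4.5, 0.02),
    "pCREB": (4.0, 0.02),
    "p38": (2.5, 0.05),
}

_CTC_ADVANCED_EMT = {
    **_CTC_BASE,
    "EpCAM": _LOW,
    "Pan-cytokeratin": (3.5, 0.0),
    "E-cadherin": _LOW,
    "EGFR": (2.0, 0.10),
    "Vimentin": _HI,
    "Snail1": (4.0, 0.02),
    "Twist": (1.5, 0.15),
    "CD133": _LOW,
    "CD24": _LOW,
    "CD44": (4.0, 0.02),
    "Ki67": (1.0, 0.30),
    "CD47": (2.0, 0.10),
    "PD-1": (1.5, 0.20),
    "PD-L1": (1.5, 0.20),
    "PD-L2": (1.5, 0.20),
    "CTLA4": (1.5, 0.20),
    "CD39": (1.5, 0.20),
    "CD73": (1.5, 0.20),
    "pSTAT1": (1.0, 0.30),
    "pSTAT3": (2.0, 0.10),
    "pSTAT5": (2.0, 0.10),
    "pPARP": (2.0, 0.10),
    "pAKT": (2.0, 0.10),
    "pERK": (2.0, 0.10),
    "pCREB": (4.0, 0.02),
    "p38": (2.0, 0.10),
}

# stimulated positive-control PBMCs: phospho pathways upregulated
_CONTROL_EXTRA = {m: (4.5, 0.02) for m in (
    "pSTAT1", "pSTAT3", "pSTAT5", "pPARP", "pAKT", "pERK", "pCREB", "p38",
)}

#: acquisition Gaussian parameters: channel -> (mean, sd) for intact singlets
_ACQ_INTACT = {
    "Event_length": (25.0, 3.0),
    "Center": (600.0, 50.0),
    "Offset": (80.0, 10.0),
    "Width": (100.0, 10.0),
    "Residual": (60.0, 15.0),
}

#: debris/doublets: Residual and Offset inflated, Width broadened
_ACQ_DEBRIS = {
    "Event_length": (25.0, 6.0),
    "Center": (600.0, 80.0),
    "Offset": (160.0, 30.0),
    "Width": (200.0, 40.0),
    "Residual": (250.0, 60.0),
}


def _population_profiles() -> dict[str, dict[str, tuple[float, float]]]:
    barcode_on = {"B2M-ATPase-barcode": _HI}
    osmium_on = {"Osmium": (5.5, 0.005)}
    return {
        "carrier": {**_PBMC, **barcode_on},
        "control": {**_PBMC, **_CONTROL_EXTRA, **osmium_on},
        "leucocyte": dict(_PBMC),
        "ctc_epithelial": dict(_CTC_EPITHELIAL),
        "ctc_early_emt": dict(_CTC_EARLY_EMT),
        "ctc_advanced_emt": dict(_CTC_ADVANCED_EMT),
        "debris": {},  # all markers at the off level
    }


@dataclass
class GeneratorParams:
    """Zero-inflated lognormal intensity model plus acquisition parameters.

    ``profiles[pop][marker] = (level, zero_p)`` where ``level`` is the target
    ArcSinh-scale median and ``zero_p`` the zero-inflation probability.
    Markers absent from a profile sit at the off level. ``sigma`` is the
    lognormal log-scale dispersion shared by all channels.
    """

    sigma: float = 0.35
    cofactor: float = 5.0
    off_level: tuple[float, float] = _OFF
    profiles: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_population_profiles
    )
    acq_intact: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_ACQ_INTACT)
    )
    acq_debris: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_ACQ_DEBRIS)
    )
    #: ArcSinh level above which a population counts as expressing a protein
    express_level: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for prof in self.profiles.values():
            for level, zp in prof.values():
                if not 0.0 <= zp <= 1.0:
                    raise ValueError("zero-inflation probabilities must be in [0,1]")
                if level <= 0:
                    raise ValueError("levels must be > 0")

    # -- model helpers ----------------------------------------------------
    def level_of(self, pop: str, marker: str) -> tuple[float, float]:
        return self.profiles.get(pop, {}).get(marker, self.off_level)

    def _mu(self, level: float) -> float:
        return float(np.log(self.cofactor * np.sinh(level)))

    def sample_intensities(
        self, pop: str, marker: str, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        level, zero_p = self.level_of(pop, marker)
        x = rng.lognormal(self._mu(level), self.sigma, size=n)
        x[rng.random(n) < zero_p] = 0.0
        return x

    def expected_arcsinh_mean(self, pop: str, marker: str, order: int = 60) -> float:
        """E[asinh(X / cofactor)] under the zero-inflated lognormal.

        Computed by Gauss-Hermite quadrature; used by the moment-fidelity
        checks as the configured archetype value.
        """
        level, zero_p = self.level_of(pop, marker)
        nodes, weights = np.polynomial.hermite.hermgauss(order)
        z = np.sqrt(2.0) * nodes
        vals = np.arcsinh(np.exp(self._mu(level) + self.sigma * z) / self.cofactor)
        mean_pos = float((weights / np.sqrt(np.pi)) @ vals)
        return (1.0 - zero_p) * mean_pos

    def expressing_fraction(self, pop: str, marker: str) -> float:
        """Fraction of cells of ``pop`` expressing ``marker`` above background."""
        level, zero_p = self.level_of(pop, marker)
        return (1.0 - zero_p) if level >= self.express_level else 0.0


# ---------------------------------------------------------------------------
# event-level simulation
# ---------------------------------------------------------------------------


def subgroup_counts(total: int, mixture: tuple[float, float, float]) -> tuple[int, int, int]:
    """Split a CTC total over the three archetypes by largest remainder."""
    w = np.asarray(mixture, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be a simplex")
    if total < 0:
        raise ValueError("total must be >= 0")
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def _sample_population(
    pop: str,
    n: int,
    panel: PanelDefinition,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    non_acq = [
        m for m in panel.markers() if m not in ACQUISITION_CHANNELS
    ]
    cols = {m: params.sample_intensities(pop, m, n, rng) for m in non_acq}
    acq = params.acq_debris if pop == "debris" else params.acq_intact
    for ch in ACQUISITION_CHANNELS:
        mean, sd = acq[ch]
        cols[ch] = np.clip(rng.normal(mean, sd, size=n), 0.0, None)
    return pd.DataFrame(cols)


def simulate_sample(
    entry: PatientEntry | DonorEntry,
    cohort: CohortConfig,
    panel: PanelDefinition | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> EventTable:
    """Simulate one stained sample with ground-truth labels.

    The table contains carrier, control, enriched (CTC + leucocyte) and
    debris populations; the barcode channel is elevated only in carriers and
    the osmium channel only in controls.  The number of ``ctc_*`` events
    equals ``entry.true_ctc_total`` exactly.  Identical seeds give
    bit-identical tables.
    """
    panel = panel or make_default_panel()
    params = params or GeneratorParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _stable_id(entry)]))

    n_epi, n_early, n_adv = subgroup_counts(entry.true_ctc_total, entry.mixture)
    n_leuco = cohort.enriched_count - entry.true_ctc_total
    if n_leuco < 0:
        raise ValueError("enriched_count smaller than true_ctc_total")
    blocks = [
        ("carrier", cohort.carrier_count),
        ("control", cohort.control_count),
        ("ctc_epithelial", n_epi),
        ("ctc_early_emt", n_early),
        ("ctc_advanced_emt", n_adv),
        ("leucocyte", n_leuco),
    ]
    n_cells = sum(n for _, n in blocks)
    n_debris = int(round(cohort.debris_fraction * n_cells / (1.0 - cohort.debris_fraction)))
    blocks.append(("debris", n_debris))

    frames, labels = [], []
    for pop, n in blocks:
        if n == 0:
            continue
        frames.append(_sample_population(pop, n, panel, params, rng))
        labels.extend([pop] * n)
    data = pd.concat(frames, ignore_index=True)
    truth = pd.Series(labels, name="truth")

    perm = rng.permutation(len(data))
    data = data.iloc[perm].reset_index(drop=True)
    truth = truth.iloc[perm].reset_index(drop=True)
    data["Time"] = np.arange(len(data)) / 500.0  # acquisition at ~500 events/s

    sid = entry.patient_id if isinstance(entry, PatientEntry) else entry.donor_id
    return EventTable(data, sample_id=sid, patient_id=sid, truth=truth)


def _stable_id(entry: PatientEntry | DonorEntry) -> int:
    sid = entry.patient_id if isinstance(entry, PatientEntry) else entry.donor_id
    return sum((i + 1) * ord(c) for i, c in enumerate(sid)) % (2**31)


def simulate_cohort(
    cohort: CohortConfig,
    panel: PanelDefinition | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
    include_donors: bool = True,
) -> dict[str, EventTable]:
    """Simulate every sample of the cohort; keyed by sample id."""
    panel = panel or make_default_panel()
    params = params or GeneratorParams()
    entries: list[PatientEntry | DonorEntry] = list(cohort.patients)
    if include_donors:
        entries += list(cohort.healthy_donors)
    return {
        (e.patient_id if isinstance(e, PatientEntry) else e.donor_id): simulate_sample(
            e, cohort, panel, params, seed
        )
        for e in entries
    }


# ---------------------------------------------------------------------------
# count-matrix simulation
# ---------------------------------------------------------------------------

N_SIGNATURE_GENES = 25  # per arm of the synthetic EMT signature

EPITHELIAL_SIGNATURE = [f"EPI_SIG_{i:02d}" for i in range(1, N_SIGNATURE_GENES + 1)]
MESENCHYMAL_SIGNATURE = [f"MES_SIG_{i:02d}" for i in range(1, N_SIGNATURE_GENES + 1)]


@dataclass
class TumourExpressionParams:
    """Negative-binomial model for the tumour EMT-signature comparator."""

    n_background: int = 150
    dispersion: float = 0.2
    base_mean_range: tuple[float, float] = (50.0, 2000.0)
    #: fold elevation of the matching signature arm in pure classes
    class_fold: float = 4.0
    #: fold elevation of both arms in mixed (EMT-profile) samples
    mixed_fold: float = 3.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_r = 1.0 / dispersion
    p = size_r / (size_r + mean)
    return rng.negative_binomial(size_r, p)


def simulate_tumour_counts(
    design: tuple[int, int, int],
    params: TumourExpressionParams | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Simulate tumour count matrices with an EMT signature structure.

    ``design = (n_epithelial, n_mesenchymal, n_mixed)``. Epithelial-class
    samples elevate the epithelial signature arm, mesenchymal-class samples
    the mesenchymal arm, and mixed-class samples co-express both arms at a
    moderately high level (the EMT profile).
    """
    params = params or TumourExpressionParams()
    n_epi, n_mes, n_mix = design
    if min(design) < 0:
        raise ValueError("class sizes must be >= 0")
    if sum(design) == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(int(seed))

    background = [f"BG_{i:03d}" for i in range(1, params.n_background + 1)]
    genes = EPITHELIAL_SIGNATURE + MESENCHYMAL_SIGNATURE + background
    lo, hi = params.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    classes = ["epithelial"] * n_epi + ["mesenchymal"] * n_mes + ["mixed"] * n_mix
    sample_ids = [f"T{i + 1:02d}" for i in range(len(classes))]
    fold = {
        "epithelial": (params.class_fold, 1.0),
        "mesenchymal": (1.0, params.class_fold),
        "mixed": (params.mixed_fold, params.mixed_fold),
    }
    is_epi = np.array([g in EPITHELIAL_SIGNATURE for g in genes])
    is_mes = np.array([g in MESENCHYMAL_SIGNATURE for g in genes])

    cols = {}
    for sid, cls in zip(sample_ids, classes):
        f_epi, f_mes = fold[cls]
        mean = base * np.where(is_epi, f_epi, 1.0) * np.where(is_mes, f_mes, 1.0)
        cols[sid] = _nb_draw(rng, mean, params.dispersion)
    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame({"truth_class": classes}, index=sample_ids)
    return CountMatrix(
        counts,
        sample_meta=meta,
        gene_sets={
            "signature_epithelial": EPITHELIAL_SIGNATURE,
            "signature_mesenchymal": MESENCHYMAL_SIGNATURE,
        },
    )


@dataclass
class BulkExpressionParams:
    """Enriched-vs-matched-PBMC bulk profile model.

    The mean of a panel-marker gene in a sample scales with the fraction of
    cells in that sample expressing the corresponding protein:
    ``mean = noise_floor + expression_scale * expressing_fraction``.
    Transcripts absent from blood (epithelial genes in the PBMC control)
    sit at the noise floor, so abundant CTC populations produce clear
    differential expression while a handful of EMT CTCs among ~1000
    enriched cells stays within noise — the bulk sensitivity gap.
    """

    n_background: int = 60
    dispersion: float = 0.05
    noise_floor: float = 3.0
    expression_scale: float = 4000.0
    background_mean: float = 300.0


def enriched_composition(
    entry: PatientEntry | DonorEntry, cohort: CohortConfig
) -> dict[str, int]:
    """Cell composition of the enriched (Parsortix) fraction for one sample."""
    n_epi, n_early, n_adv = subgroup_counts(entry.true_ctc_total, entry.mixture)
    return {
        "ctc_epithelial": n_epi,
        "ctc_early_emt": n_early,
        "ctc_advanced_emt": n_adv,
        "leucocyte": cohort.enriched_count - entry.true_ctc_total,
    }


def simulate_bulk_ctc_counts(
    cohort: CohortConfig,
    truth_compositions: dict[str, dict[str, int]] | None = None,
    params: BulkExpressionParams | None = None,
    gen_params: GeneratorParams | None = None,
    seed: int = 0,
    patient_ids: list[str] | None = None,
) -> CountMatrix:
    """Simulate paired enriched / matched-PBMC bulk count profiles.

    One ``<pid>_enriched`` and one ``<pid>_pbmc`` column per patient.
    Panel-marker genes are elevated in the enriched sample proportionally to
    the abundance of protein-expressing cells in its composition.
    """
    params = params or BulkExpressionParams()
    gen_params = gen_params or GeneratorParams()
    pids = patient_ids or [p.patient_id for p in cohort.patients]
    if truth_compositions is None:
        truth_compositions = {
            pid: enriched_composition(cohort.entry(pid), cohort) for pid in pids
        }
    missing = [pid for pid in pids if pid not in truth_compositions]
    if missing:
        raise ValueError(f"patients without a matched composition: {missing}")
    rng = np.random.default_rng(int(seed))

    marker_gene = mapped_markers()
    genes = list(marker_gene.values()) + [
        f"BG_{i:03d}" for i in range(1, params.n_background + 1)
    ]
    gene_markers = {g: m for m, g in marker_gene.items()}
    background_base = params.background_mean * np.exp(
        rng.uniform(-0.5, 0.5, size=len(genes))
    )

    def mean_profile(composition: dict[str, float]) -> np.ndarray:
        total = sum(composition.values())
        means = background_base.copy()
        for i, g in enumerate(genes):
            marker = gene_markers.get(g)
            if marker is None:
                continue
            f = sum(
                n * gen_params.expressing_fraction(pop, marker)
                for pop, n in composition.items()
            ) / max(total, 1)
            means[i] = params.noise_floor + params.expression_scale * f
        return means

    cols, roles, owners = {}, [], []
    for pid in pids:
        comp = truth_compositions[pid]
        pbmc_comp = {"leucocyte": sum(comp.values())}
        for role, c in (("enriched", comp), ("pbmc", pbmc_comp)):
            cols[f"{pid}_{role}"] = _nb_draw(rng, mean_profile(c), params.dispersion)
            roles.append("enriched" if role == "enriched" else "matched_pbmc")
            owners.append(pid)
    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame({"role": roles, "patient_id": owners}, index=list(cols))
    return CountMatrix(counts, sample_meta=meta, gene_markers=gene_markers)


# ---------------------------------------------------------------------------
# composition archetypes (patient-level PCA fixture)
# ---------------------------------------------------------------------------


def simulate_composition_archetypes(
    n_patients: int = 20,
    n_clusters: int = 8,
    seed: int = 0,
    concentration: float = 40.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Patient x cluster composition fractions drawn from four archetypes.

    Archetypes mirror the patient groupings the composition PCA is meant to
    recover: epithelial-dominant, advanced-EMT-dominant, and two early-EMT
    archetypes that load on disjoint cluster subsets (the checkpoint-high /
    checkpoint-low split). Returns (composition matrix, truth labels).
    """
    if n_clusters < 4:
        raise ValueError("need >= 4 clusters for four archetypes")
    rng = np.random.default_rng(int(seed))
    groups = np.array_split(np.arange(n_clusters), 4)
    names = ["epithelial", "advanced_emt", "early_emt_A", "early_emt_B"]
    base = np.full(n_clusters, 0.5)
    archetype_alphas = []
    for g in groups:
        a = base.copy()
        a[g] = concentration / len(g)
        archetype_alphas.append(a)
    labels = [names[i % 4] for i in range(n_patients)]
    rows = [rng.dirichlet(archetype_alphas[names.index(lab)]) for lab in labels]
    comp = pd.DataFrame(
        rows,
        index=[f"P{i + 1:02d}" for i in range(n_patients)],
        columns=[f"c{j + 1}" for j in range(n_clusters)],
    )
    return comp, pd.Series(labels, index=comp.index, name="archetype")
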