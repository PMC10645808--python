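"""End-to-end orchestration: simulate -> gate -> cluster -> stats -> expression.

The pipeline is a sequence of pure library calls with every stage's outputs
written under a run directory, the resolved configuration and seed recorded
in a provenance block, and deterministic stages bit-identical on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterProfile,
    MetaclusterMap,
    SomModel,
    SubgroupAssignment,
    cluster_profiles,
    concatenate_ctcs,
    elbow_metacluster,
    hierarchical_subgroups,
    label_emt_subgroups,
    subgroup_summary,
    train_som,
)
from .events import EventTable
from .gating import (
    GateThresholds,
    TransformSpec,
    arcsinh_transform,
    deconvolute_populations,
    gaussian_cleanup,
    identify_ctcs,
    per_ml,
    score_positivity,
)
from .panel import PanelDefinition, make_default_panel
from .simulate import (
    CohortConfig,
    GeneratorParams,
    default_cohort,
    simulate_cohort,
)
from .stats import clinical_associations, compare_subgroups, composition_matrix, pca_composition

log = logging.getLogger("ctcpheno")


@dataclass
class PipelineConfig:
    """Resolved settings for a full run."""

    output_dir: str = "ctcpheno_run"
    simulate: bool = True
    input_dir: str | None = None  # event CSVs when simulate is off
    seed: int = 0
    cofactor: float = 5.0
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 10
    k_range: tuple[int, int] = (2, 20)
    elbow_threshold: float = 0.05
    include_donors: bool = True
    patient12_alternate: bool = False
    thresholds: GateThresholds = field(default_factory=GateThresholds)

    def config_hash(self) -> str:
        blob = json.dumps(_to_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = GateThresholds(**raw.pop("thresholds", {}))
        for key in ("som_grid", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(asdict(self))))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PipelineResult:
    run_dir: Path
    positivity: dict[str, str]
    ctc_tallies: dict[str, int]
    per_ml: dict[str, int]
    som: SomModel | None
    meta_map: MetaclusterMap | None
    profile: ClusterProfile | None
    subgroups: SubgroupAssignment | None
    subgroup_table: pd.DataFrame | None
    composition: pd.DataFrame | None
    contrasts: pd.DataFrame | None
    clinical: dict | None
    concatenated: EventTable | None


def _provenance(config: PipelineConfig) -> dict:
    return {
        "tool": "ctcpheno",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    path.write_text(
        json.dumps({"provenance": _provenance(config), **_to_plain(payload)}, indent=2)
    )


def run_pipeline(
    config: PipelineConfig,
    cohort: CohortConfig | None = None,
    panel: PanelDefinition | None = None,
    params: GeneratorParams | None = None,
    dry_run: bool = False,
) -> PipelineResult:
    """Execute the full analysis and write per-stage outputs.

    Stage errors abort with the stage name attached; partial outputs from
    completed stages are retained in the run directory.
    """
    panel = panel or make_default_panel()
    params = params or GeneratorParams()
    if not config.simulate and config.input_dir is None:
        raise ValueError("configuration error: no input_dir and simulate disabled")
    run_dir = Path(config.output_dir)
    if dry_run:
        log.info("dry run: configuration valid")
        return PipelineResult(
            run_dir, {}, {}, {}, None, None, None, None, None, None, None, None, None
        )
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    stage = "simulate"
    try:
        if config.simulate:
            cohort = cohort or default_cohort(config.patient12_alternate)
            samples = simulate_cohort(
                cohort, panel, params, config.seed, include_donors=config.include_donors
            )
        else:
            samples = {}
            for f in sorted(Path(config.input_dir).glob("*.csv")):
                t = EventTable.from_csv(f)
                samples[t.sample_id] = t
            if not samples:
                raise ValueError(f"no event CSVs under {config.input_dir}")
            cohort = cohort or default_cohort()
        log.info("stage simulate: %d samples", len(samples))

        stage = "gate"
        spec = TransformSpec(cofactor=config.cofactor)
        thr = config.thresholds
        positivity: dict[str, str] = {}
        tallies: dict[str, int] = {}
        conc: dict[str, int] = {}
        ctc_tables: dict[str, EventTable] = {}
        ctc_gates = {}
        tally_rows = []
        for sid, raw in samples.items():
            transformed = arcsinh_transform(raw, spec)
            cleanup = gaussian_cleanup(transformed, thr)
            retained = transformed.subset((cleanup.labels == "retained").to_numpy())
            pops = deconvolute_populations(retained, panel, thr)
            enriched = retained.subset((pops.labels == "enriched").to_numpy())
            carrier = retained.subset((pops.labels == "carrier").to_numpy())
            gate = identify_ctcs(enriched, panel, thr, anchor=carrier)
            n_ctc = int(gate.tallies.get("ctc", 0))
            entry = cohort.entry(sid) if cohort else None
            volume = entry.draw_volume_ml if entry is not None else 9.0
            positivity[sid] = score_positivity(n_ctc, thr)
            tallies[sid] = n_ctc
            conc[sid] = per_ml(n_ctc, volume)
            ctc_tables[sid] = enriched
            ctc_gates[sid] = gate
            tally_rows.append(
                {
                    "sample_id": sid,
                    "ctc_total": n_ctc,
                    "ctc_per_ml": conc[sid],
                    "positivity": positivity[sid],
                    "n_debris": int(cleanup.tallies.get("debris", 0)),
                    "n_carrier": int(pops.tallies.get("carrier", 0)),
                    "n_control": int(pops.tallies.get("control", 0)),
                    "n_enriched": int(pops.tallies.get("enriched", 0)),
                }
            )
        pd.DataFrame(tally_rows).to_csv(run_dir / "gate_tallies.csv", index=False)
        _write_json(run_dir / "positivity.json", {"positivity": positivity, "tallies": tallies}, config)
        log.info("stage gate: %d/%d positive", sum(v == "positive" for v in positivity.values()), len(positivity))

        stage = "cluster"
        patient_ids = [p.patient_id for p in cohort.patients]
        patient_samples = {sid: t for sid, t in ctc_tables.items() if sid in patient_ids}
        patient_gates = {sid: g for sid, g in ctc_gates.items() if sid in patient_ids}
        patient_pos = {sid: positivity[sid] for sid in patient_samples}
        ctcs = concatenate_ctcs(patient_samples, patient_gates, patient_pos)
        if len(ctcs) == 0:
            raise ValueError("no CTC-positive patients: downstream stages refuse")
        markers = panel.analytical_markers
        som = train_som(ctcs, markers, config.som_grid, config.som_epochs, config.seed)
        k_hi = min(config.k_range[1], som.n_nodes)
        meta_map = elbow_metacluster(som, (config.k_range[0], k_hi), config.elbow_threshold)
        profile = cluster_profiles(ctcs, som, meta_map)
        subgroups = label_emt_subgroups(hierarchical_subgroups(profile), profile)
        sub_table = subgroup_summary(profile, subgroups)
        profile.medians.to_csv(run_dir / "cluster_medians.csv")
        sub_table.to_csv(run_dir / "subgroups.csv")
        (run_dir / "dendrogram.nwk").write_text(subgroups.dendrogram + "\n")
        log.info("stage cluster: k=%d, subgroups %s", meta_map.k, sub_table["count"].to_dict())

        stage = "stats"
        ev_subgroup = subgroups.labels_for_events(profile.event_meta)
        values = pd.DataFrame(ctcs.matrix(markers), columns=markers)
        contrasts = compare_subgroups(values, ev_subgroup, markers)
        contrasts.to_csv(run_dir / "subgroup_contrasts.csv", index=False)
        event_meta_by_patient = {}
        pid_per_event = ctcs.data["patient_id"].to_numpy()
        for pid in np.unique(pid_per_event):
            event_meta_by_patient[str(pid)] = profile.event_meta[pid_per_event == pid]
        composition = composition_matrix(
            event_meta_by_patient, sorted(profile.medians.index)
        )
        composition.to_csv(run_dir / "composition.csv")
        pca = pca_composition(composition, seed=config.seed)
        clinical_df = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "t_stage": p.t_stage,
                    "n_stage": p.n_stage,
                    "stage": p.stage,
                }
                for p in cohort.patients
            ]
        ).set_index("patient_id")
        emt_frac = pd.Series(
            {
                pid: float(np.isin(ev_subgroup[pid_per_event == pid], ["early_EMT", "advanced_EMT"]).mean())
                for pid in composition.index
            }
        )
        clin = clinical_associations(
            clinical_df,
            pd.Series(tallies).reindex(clinical_df.index).fillna(0),
            emt_fraction=emt_frac,
        )
        _write_json(
            run_dir / "stats.json",
            {"clinical": clin, "pca_groups": pca.patient_groups.to_dict(), "pca_k": pca.chosen_k},
            config,
        )
        log.info("stage stats: %d contrasts", len(contrasts))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    return PipelineResult(
        run_dir,
        positivity,
        tallies,
        conc,
        som,
        meta_map,
        profile,
        subgroups,
        sub_table,
        composition,
        contrasts,
        clin,
        ctcs,
    )
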