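"""End-to-end orchestration: simulate -> preprocess -> connect -> report.

Stages communicate through files under the output directory so each can be
re-run in isolation; every source of randomness flows from the single master
seed recorded in ``config.json``.  The bundle mirrors the analysis products
of the emulated study: a per-network deficit table (per-patient reduced-link
counts with a one-sample t-test), an inter-network correlation matrix of
deficit counts, a link-frequency map, a volumetry group table (GM/WM
fractions and thalamus asymmetry index), and per-patient FA statistic maps.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .connectivity import correlation_matrix, extract_roi_signals
from .fa_compare import SINGLE_CASE, exceedance_fraction, singlecase_map
from .morphometry import compute_volumes, group_compare
from .networks import load_networks
from .normative import (
    calibrated_null_mean,
    deficit_ttest,
    fit_normative,
    flag_abnormal,
    frequency_map,
    network_correlations,
)
from .preprocess import lowpass, regress_physio
from .synthetic import (
    CONTROL,
    PATIENT,
    SimulationConfig,
    cohort_sex,
    generate_bold,
    generate_fa_skeleton,
    generate_label_map,
    iter_subjects,
)

logger = logging.getLogger("cognet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs, plus the analysis flags."""

    sim: SimulationConfig
    out_dir: Path
    networks_path: str | None = None
    stratify_by_sex: bool = True
    reduced_only: bool = True
    null_mean_mode: str = "zero"  # "zero" | "calibrated"
    fisher_z: bool = False
    signed_ai: bool = False
    fa_method: str = SINGLE_CASE
    lowpass_cutoff_hz: float = 0.08
    p_threshold: float = 0.01

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.null_mean_mode not in ("zero", "calibrated"):
            raise PipelineError(
                f"null_mean_mode must be 'zero' or 'calibrated', "
                f"got {self.null_mean_mode!r}"
            )

    def networks(self):
        return load_networks(self.networks_path, parcellation=self.sim.parcellation)

    def flags(self) -> dict:
        d = dataclasses.asdict(self)
        del d["sim"], d["out_dir"]
        return d


def _manifest_path(cfg: RunConfig) -> Path:
    return cfg.out_dir / "subjects.json"


def _load_manifest(cfg: RunConfig, stage: str) -> list[dict]:
    path = _manifest_path(cfg)
    if not path.exists():
        raise PipelineError(f"stage {stage}: missing {path}; run simulate first")
    return json.loads(path.read_text())["subjects"]


def _dump_json(doc, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig) -> list[dict]:
    """Generate the whole cohort to disk and write the manifest + sidecar."""
    sim = cfg.sim
    out = cfg.out_dir
    (out / "sim").mkdir(parents=True, exist_ok=True)
    sim.to_json(out / "config.json")
    _dump_json({"seed": sim.seed, "flags": cfg.flags()}, out / "run_sidecar.json")
    sex = cohort_sex(sim)
    subjects = []
    for sid, kind, index in iter_subjects(sim):
        sdir = out / "sim" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        labels = generate_label_map(sim, kind, index)
        bold, physio = generate_bold(sim, labels, kind, index)
        fa = generate_fa_skeleton(sim, kind, index)
        cio.save_labels(labels, sdir / "labels.nii")
        cio.save_bold(bold, sdir / "bold.nii")
        cio.save_physio(physio, sdir / "physio.tsv")
        cio.save_fa(fa, sdir / "fa.nii")
        subjects.append(
            {"id": sid, "kind": kind, "index": index, "sex": sex[sid],
             "dir": f"sim/{sid}"}
        )
        logger.info("simulated %s", sid)
    _dump_json({"subjects": subjects}, _manifest_path(cfg))
    return subjects


def stage_preprocess(cfg: RunConfig) -> None:
    """Physio regression then low-pass, per subject."""
    (cfg.out_dir / "preproc").mkdir(parents=True, exist_ok=True)
    for sub in _load_manifest(cfg, "preprocess"):
        sdir = cfg.out_dir / sub["dir"]
        bold = cio.load_bold(sdir / "bold.nii")
        physio = cio.load_physio(sdir / "physio.tsv")
        clean = lowpass(regress_physio(bold, physio), cfg.lowpass_cutoff_hz)
        cio.save_bold(clean, cfg.out_dir / "preproc" / f"{sub['id']}.nii")
        logger.info("preprocessed %s", sub["id"])


def stage_connect(cfg: RunConfig) -> None:
    """ROI extraction and per-network correlation matrices, per subject."""
    nets = cfg.networks()
    (cfg.out_dir / "connectivity").mkdir(parents=True, exist_ok=True)
    for sub in _load_manifest(cfg, "connect"):
        labels = cio.load_labels(cfg.out_dir / sub["dir"] / "labels.nii")
        bold = cio.load_bold(cfg.out_dir / "preproc" / f"{sub['id']}.nii")
        for net in nets:
            ts = extract_roi_signals(bold, labels, net, subject_id=sub["id"])
            cm = correlation_matrix(ts, network_name=net.name,
                                    fisher_z=cfg.fisher_z)
            cio.save_matrix(
                cm, cfg.out_dir / "connectivity" / f"{sub['id']}_{net.name}.tsv"
            )
        logger.info("connectivity for %s", sub["id"])


def stage_normative(cfg: RunConfig) -> dict:
    """Normative bands, abnormal-link reports, frequency maps, group stats."""
    nets = cfg.networks()
    subjects = _load_manifest(cfg, "normative")
    controls = [s for s in subjects if s["kind"] == CONTROL]
    patients = [s for s in subjects if s["kind"] == PATIENT]
    sex_labels = {s["id"]: s["sex"] for s in subjects}
    ndir = cfg.out_dir / "normative"
    ndir.mkdir(parents=True, exist_ok=True)

    def matrix(sub, net):
        return cio.load_matrix(
            cfg.out_dir / "connectivity" / f"{sub['id']}_{net.name}.tsv",
            subject_id=sub["id"], network_name=net.name,
        )

    stats_doc: dict = {"networks": {}}
    reports_by_network: dict[str, list] = {}
    for net in nets:
        ctrl_mats = [matrix(s, net) for s in controls]
        if cfg.stratify_by_sex:
            models = fit_normative(ctrl_mats, stratify_by_sex=True,
                                   sex_labels=sex_labels)
            for sexlab, model in models.items():
                cio.save_normative_model(
                    model, ndir / f"{net.name}_model_{sexlab}.tsv"
                )
        else:
            model = fit_normative(ctrl_mats)
            models = None
            cio.save_normative_model(model, ndir / f"{net.name}_model.tsv")

        reports = []
        for sub in patients:
            m = models[sex_labels[sub["id"]]] if models else model
            reports.append(flag_abnormal(matrix(sub, net), m))
        reports_by_network[net.name] = reports
        if reports:
            cio.save_reports(reports, ndir / f"{net.name}_patient_links.tsv")
            for reduced_only in (True, False):
                fmap = frequency_map(reports, reduced_only=reduced_only)
                tag = "reduced" if reduced_only else "abnormal"
                cio.save_frequency_map(fmap, ndir / f"{net.name}_frequency_{tag}.tsv")

        ref_model = next(iter(models.values())) if models else model
        entry: dict = {"n_links": len(ref_model.links)}
        if len(reports) >= 2:
            null_mean = (
                0.0 if cfg.null_mean_mode == "zero"
                else calibrated_null_mean(ref_model, reduced_only=cfg.reduced_only)
            )
            test = deficit_ttest(
                reports, null_mean=null_mean,
                use="reduced" if cfg.reduced_only else "abnormal",
            )
            entry.update(
                null_mean=null_mean,
                counts=[int(c) for c in test.counts],
                mean=test.mean, sd=test.sd, t=test.t, p=test.p,
                zero_variance=test.zero_variance,
            )
        else:
            warnings.warn(f"{net.name}: fewer than 2 patients; deficit t-test skipped")
        stats_doc["networks"][net.name] = entry

    if len(patients) >= 3:
        names, r, p = network_correlations(
            reports_by_network, use="reduced" if cfg.reduced_only else "abnormal"
        )
        stats_doc["network_correlations"] = {
            "names": names, "r": r.tolist(), "p": p.tolist()
        }
    _dump_json(stats_doc, ndir / "group_stats.json")
    return stats_doc


def stage_volumes(cfg: RunConfig) -> dict:
    """Per-subject volumetry and the group comparison table."""
    import pandas as pd

    sim = cfg.sim
    subjects = _load_manifest(cfg, "volumes")
    vdir = cfg.out_dir / "morphometry"
    vdir.mkdir(parents=True, exist_ok=True)
    tissue = sim.tissue_by_label()
    names = sim.region_names_by_label()
    spec = sim.parcellation.get(sim.asymmetry_region)
    pairs = (
        {sim.asymmetry_region: (spec["labels"]["L"], spec["labels"]["R"])}
        if spec else {}
    )
    records = {CONTROL: [], PATIENT: []}
    rows = []
    for sub in subjects:
        labels = cio.load_labels(cfg.out_dir / sub["dir"] / "labels.nii")
        rec = compute_volumes(labels, tissue, subject_id=sub["id"],
                              region_names=names, pairs=pairs,
                              signed_ai=cfg.signed_ai)
        records[sub["kind"]].append(rec)
        row = {"subject": sub["id"], "kind": sub["kind"],
               **{f"frac_{k}": v for k, v in rec.group_fractions.items()}}
        row.update({f"AI_{k}": v for k, v in rec.ai.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(vdir / "subjects.tsv", sep="\t", index=False,
                              float_format="%.10g")

    doc: dict = {}
    measures = ["GM", "WM"] + ([f"{sim.asymmetry_region}_AI"] if pairs else [])
    if len(records[PATIENT]) >= 2 and len(records[CONTROL]) >= 2:
        for measure in measures:
            gc = group_compare(records[PATIENT], records[CONTROL], measure)
            doc[measure] = {
                "patients_mean": gc.mean_patients, "patients_sd": gc.sd_patients,
                "controls_mean": gc.mean_controls, "controls_sd": gc.sd_controls,
                "t": gc.t, "p": gc.p,
            }
    else:
        warnings.warn("volumetry group comparison skipped: a group has < 2 subjects")
    _dump_json(doc, vdir / "group_table.json")
    return doc


def stage_fa(cfg: RunConfig) -> dict:
    """Per-patient voxelwise single-case FA comparison against controls."""
    subjects = _load_manifest(cfg, "fa")
    controls = [s for s in subjects if s["kind"] == CONTROL]
    patients = [s for s in subjects if s["kind"] == PATIENT]
    fdir = cfg.out_dir / "fa"
    fdir.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    if len(controls) < 3:
        warnings.warn("FA comparison skipped: fewer than 3 controls")
        _dump_json(doc, fdir / "summary.json")
        return doc
    ctrl_maps = [cio.load_fa(cfg.out_dir / s["dir"] / "fa.nii") for s in controls]
    import nibabel as nib

    for sub in patients:
        patient = cio.load_fa(cfg.out_dir / sub["dir"] / "fa.nii")
        # stored maps keep only the nonzero support; lesions can push FA near
        # zero, so impose the union support as the common skeleton
        mask = np.zeros(patient.fa.shape, dtype=bool)
        for m in ctrl_maps + [patient]:
            mask |= m.skeleton_mask
        patient.skeleton_mask = mask
        for m in ctrl_maps:
            m.skeleton_mask = mask
        smap = singlecase_map(patient, ctrl_maps, method=cfg.fa_method)
        nib.save(
            nib.Nifti1Image(np.nan_to_num(smap.t).astype(np.float32), smap.affine),
            fdir / f"{sub['id']}_tmap.nii",
        )
        sig = np.isfinite(smap.p) & (smap.p < cfg.p_threshold)
        doc[sub["id"]] = {
            "n_mask_voxels": int(smap.mask.sum()),
            "n_significant": int(sig.sum()),
            "exceedance_fraction_5pct": exceedance_fraction(smap, alpha=0.05),
        }
        logger.info("FA map for %s", sub["id"])
    _dump_json(doc, fdir / "summary.json")
    return doc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the machine-readable ``summary.json``."""
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("connect", stage_connect),
        ("normative", stage_normative),
        ("volumes", stage_volumes),
        ("fa", stage_fa),
    ]
    results: dict = {}
    for name, fn in stages:
        try:
            out = fn(cfg)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the user
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        if isinstance(out, dict):
            results[name] = out
    summary = {
        "seed": cfg.sim.seed,
        "n_controls": cfg.sim.n_controls,
        "n_patients": cfg.sim.n_patients,
        "flags": cfg.flags(),
        "deficits": results.get("normative", {}),
        "volumetry": results.get("volumes", {}),
        "fa": results.get("fa", {}),
    }
    _dump_json(summary, cfg.out_dir / "summary.json")
    return summary
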