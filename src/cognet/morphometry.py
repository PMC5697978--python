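"""Regional volumetry: normalized volumes, tissue groups, asymmetry index.

Raw regional volume is voxel count times voxel volume (|det| of the affine's
3x3 block).  Volumes are normalized to the total brain volume, defined as
the sum of all labeled segments — gray matter, white matter *and* CSF spaces
— so GM + WM + CSF fractions sum to one by construction.  Paired structures
get an asymmetry index

    AI = |V_L − V_R| / ((V_L + V_R) / 2),

a unitless value in [0, 2].  The magnitude form is the default: across a
cohort in which either hemisphere may be the affected one, only |AI| has a
coherent group mean.  A signed variant is available.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synthetic import LabelVolume


class MorphometryError(ValueError):
    pass


@dataclass
class MorphometryRecord:
    """Per-subject normalized volumes, tissue-group fractions and AIs."""

    subject_id: str
    voxel_volume_mm3: float
    raw_mm3: dict[str, float]  # region node -> mm^3
    normalized: dict[str, float]  # region node -> fraction of brain volume
    group_fractions: dict[str, float]  # GM / WM / CSF
    ai: dict[str, float] = field(default_factory=dict)  # paired structure -> AI

    @property
    def total_brain_mm3(self) -> float:
        return sum(self.raw_mm3.values())


def asymmetry_index(v_left: float, v_right: float, signed: bool = False) -> float:
    """AI of a paired structure; 0 for symmetric, 2 when one side vanishes."""
    denom = (v_left + v_right) / 2.0
    if denom <= 0:
        raise MorphometryError("asymmetry index undefined: both volumes are zero")
    ai = (v_left - v_right) / denom
    return float(ai if signed else abs(ai))


def compute_volumes(
    labels: LabelVolume,
    tissue_by_label: dict[int, str],
    subject_id: str = "subject",
    region_names: dict[int, str] | None = None,
    pairs: dict[str, tuple[int, int]] | None = None,
    signed_ai: bool = False,
) -> MorphometryRecord:
    """Volumetry of one labeled volume.

    ``tissue_by_label`` must cover every nonzero label (GM/WM/CSF).
    ``pairs`` maps a structure name to its (left label, right label) for
    asymmetry indices.  ``region_names`` supplies display names; labels
    without one are named ``label_<k>``.
    """
    counts = labels.voxel_counts()
    unassigned = sorted(set(counts) - set(tissue_by_label))
    if unassigned:
        raise MorphometryError(
            f"labels without a tissue-group assignment: {unassigned}"
        )
    voxel_volume = float(abs(np.linalg.det(labels.affine[:3, :3])))
    names = region_names or {}
    raw = {
        names.get(lab, f"label_{lab}"): counts[lab] * voxel_volume for lab in counts
    }
    total = sum(raw.values())
    if total <= 0:
        raise MorphometryError("volume contains no labeled voxels")
    normalized = {k: v / total for k, v in raw.items()}
    groups = {"GM": 0.0, "WM": 0.0, "CSF": 0.0}
    for lab, c in counts.items():
        groups[tissue_by_label[lab]] += c * voxel_volume / total
    ai = {}
    for structure, (lab_l, lab_r) in (pairs or {}).items():
        v_l = counts.get(lab_l, 0) * voxel_volume
        v_r = counts.get(lab_r, 0) * voxel_volume
        ai[structure] = asymmetry_index(v_l, v_r, signed=signed_ai)
    return MorphometryRecord(
        subject_id=subject_id,
        voxel_volume_mm3=voxel_volume,
        raw_mm3=raw,
        normalized=normalized,
        group_fractions=groups,
        ai=ai,
    )


@dataclass
class GroupComparison:
    """Welch two-sample t-test between patient and control measures."""

    measure: str
    mean_patients: float
    sd_patients: float
    n_patients: int
    mean_controls: float
    sd_controls: float
    n_controls: int
    t: float
    p: float

    def table_row(self) -> str:
        return (
            f"{self.mean_patients:.3f} (±{self.sd_patients:.3f})\t"
            f"{self.mean_controls:.3f} (±{self.sd_controls:.3f})\t"
            f"p={self.p:.4g}"
        )


def _measure_values(records: list[MorphometryRecord], measure: str) -> np.ndarray:
    if measure in ("GM", "WM", "CSF"):
        return np.array([r.group_fractions[measure] for r in records])
    if measure.endswith("_AI"):
        structure = measure[:-3]
        try:
            return np.array([r.ai[structure] for r in records])
        except KeyError:
            raise MorphometryError(f"no asymmetry index for {structure!r}")
    try:
        return np.array([r.normalized[measure] for r in records])
    except KeyError:
        raise MorphometryError(f"unknown measure {measure!r}")


def group_compare(
    patients: list[MorphometryRecord],
    controls: list[MorphometryRecord],
    measure: str,
) -> GroupComparison:
    """Welch (unequal-variance) two-sided t-test on a volumetric measure.

    ``measure`` is a tissue group (``GM``/``WM``/``CSF``), a paired-structure
    AI (``thalamus_AI``) or a region node name (normalized volume).
    """
    if len(patients) < 2 or len(controls) < 2:
        raise MorphometryError("each group needs at least 2 subjects")
    x = _measure_values(patients, measure)
    y = _measure_values(controls, measure)
    if np.array_equal(x, y) or (x.std(ddof=1) == 0 and y.std(ddof=1) == 0):
        t, p = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        measure=measure,
        mean_patients=float(x.mean()),
        sd_patients=float(x.std(ddof=1)),
        n_patients=len(x),
        mean_controls=float(y.mean()),
        sd_controls=float(y.std(ddof=1)),
        n_controls=len(y),
        t=t,
        p=p,
    )
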