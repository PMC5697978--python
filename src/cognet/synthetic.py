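"""Synthetic cohort generator for the connectivity / volumetry / FA pipeline.

Generates every input the analysis consumes, with the statistical structure
the analysis assumes and nothing more:

* integer label maps whose paired thalami realize a planted asymmetry index
  and whose tissue-group voxel fractions are drawn around planted group
  means (controls vs patients);
* 4-D BOLD runs in which all voxels of a region share a latent regional
  signal drawn from a stationary multivariate Gaussian with a planted
  inter-regional correlation structure (selected links weakened in
  patients), plus independent voxel noise and sinusoidal cardiac /
  respiratory confounds whose exact time courses are returned as the
  physiological trace;
* skeletonized FA maps drawn around a control mean, with a contiguous
  lesional patch of reduced FA in patients.

Randomness is fully seeded: each subject owns an independent stream derived
from ``(master seed, stream id, subject kind, subject index)``, so cohorts
are extensible without perturbing earlier subjects and identical
(seed, config) pairs reproduce every array bit for bit.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .networks import (
    HEMISPHERES,
    enumerate_links,
    load_networks,
    load_parcellation,
    node_name,
)

CONTROL = "control"
PATIENT = "patient"
_KIND_CODE = {CONTROL: 0, PATIENT: 1}

# stream ids: one purpose per id so draw orders never interleave
_STREAM_BOLD = 0
_STREAM_LABELS = 1
_STREAM_FA = 2
_STREAM_WEAKEN = 3


class ConfigError(ValueError):
    """Simulation configuration is unusable."""


class SizingError(ConfigError):
    """Grid too small to host the requested regions."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 20 controls vs 10 relapsing-remitting
    MS patients, 150 BOLD volumes at TR = 2 s, tissue-fraction and thalamus
    asymmetry-index group statistics matching the reported volumetry, and
    roughly three weakened links per cognitive network per patient.
    """

    n_controls: int = 20
    n_patients: int = 10
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = (22, 22, 18)
    voxel_size_mm: tuple[float, float, float] = (3.4375, 3.4375, 3.5)
    total_labeled_voxels: int = 6000
    parcellation: dict[str, dict] = field(default_factory=load_parcellation)
    # link -> planted correlation; None builds the default (all within-network
    # links of the packaged five networks at base_r)
    base_connectivity: dict[tuple[str, str], float] | None = None
    base_r: float = 0.45
    # explicit per-patient weakened links {patient_index: [(node_a, node_b, r)]};
    # None draws n_weakened_per_network links per network per patient
    weakened_links: dict[int, list[tuple[str, str, float]]] | None = None
    n_weakened_per_network: int = 3
    weakened_r: float = 0.0
    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.3
    confound_amplitude: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    # fixed planted AI; None draws |N(ai_mean, ai_sd)| per subject by group
    thalamus_asymmetry: float | None = None
    asymmetry_region: str = "thalamus"
    ai_mean: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.089, PATIENT: 0.188}
    )
    ai_sd: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.057, PATIENT: 0.172}
    )
    tissue_fraction_mean: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            CONTROL: {"GM": 0.453, "WM": 0.281},
            PATIENT: {"GM": 0.435, "WM": 0.297},
        }
    )
    tissue_fraction_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            CONTROL: {"GM": 0.011, "WM": 0.0168},
            PATIENT: {"GM": 0.021, "WM": 0.048},
        }
    )
    # explicit combined (L+R) voxel count per region; bypasses the
    # tissue-fraction allocation when given
    region_voxel_counts: dict[str, int] | None = None
    fa_mean: float = 0.5
    fa_sd: float = 0.03
    fa_floor: float = 0.2
    lesion_depth: float = 0.15
    lesion_radius: int = 3
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.grid_shape) != 3 or any(v <= 0 for v in self.grid_shape):
            raise ConfigError("grid_shape must be three positive voxel counts")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be at least 2")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        if self.n_controls < 0 or self.n_patients < 0:
            raise ConfigError("cohort sizes must be non-negative")
        for (a, b), r in (self.base_connectivity or {}).items():
            if not (-1.0 < r < 1.0):
                raise ConfigError(
                    f"planted correlation for ({a}, {b}) must lie in (-1, 1)"
                )

    # -- derived node bookkeeping ------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(
            node_name(region, h)
            for region in self.parcellation
            for h in HEMISPHERES
        )

    @property
    def node_labels(self) -> dict[str, int]:
        return {
            node_name(region, h): spec["labels"][h]
            for region, spec in self.parcellation.items()
            for h in HEMISPHERES
        }

    def tissue_by_label(self) -> dict[int, str]:
        return {
            spec["labels"][h]: spec["tissue"]
            for spec in self.parcellation.values()
            for h in HEMISPHERES
        }

    def region_names_by_label(self) -> dict[int, str]:
        return {
            spec["labels"][h]: node_name(region, h)
            for region, spec in self.parcellation.items()
            for h in HEMISPHERES
        }

    # -- (de)serialization --------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        if doc["base_connectivity"] is not None:
            doc["base_connectivity"] = {
                f"{a}|{b}": r for (a, b), r in doc["base_connectivity"].items()
            }
        if doc["weakened_links"] is not None:
            doc["weakened_links"] = {
                str(k): [list(t) for t in v] for k, v in doc["weakened_links"].items()
            }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        if doc.get("base_connectivity") is not None:
            doc["base_connectivity"] = {
                tuple(k.split("|")): float(r)
                for k, r in doc["base_connectivity"].items()
            }
        if doc.get("weakened_links") is not None:
            doc["weakened_links"] = {
                int(k): [(a, b, float(r)) for a, b, r in v]
                for k, v in doc["weakened_links"].items()
            }
        for key in ("grid_shape", "voxel_size_mm"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


# ---------------------------------------------------------------------------
# Volumes (dataclasses shared with downstream modules)


@dataclass
class LabelVolume:
    """Integer parcellation volume; label 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError("label volume must be 3-D")

    def voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.data, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts) if l != 0}


@dataclass
class FASkeletonMap:
    """Skeletonized fractional-anisotropy map (zero off the skeleton)."""

    fa: np.ndarray
    skeleton_mask: np.ndarray
    affine: np.ndarray
    lesion_mask: np.ndarray | None = None


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def subject_rng(config: SimulationConfig, stream: int, kind: str, index: int):
    """Independent per-subject random stream."""
    if kind not in _KIND_CODE:
        raise ConfigError(f"subject kind must be 'control' or 'patient', got {kind!r}")
    return np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, stream, _KIND_CODE[kind], int(index)]
    )


# ---------------------------------------------------------------------------
# Planted correlation structure


def default_connectivity(config: SimulationConfig) -> dict[tuple[str, str], float]:
    """All within-network links of the packaged networks at ``base_r``.

    Networks whose regions are absent from the configured parcellation are
    skipped, so reduced parcellations remain usable.
    """
    out: dict[tuple[str, str], float] = {}
    for net in load_networks(parcellation=config.parcellation, skip_unresolvable=True):
        ls = enumerate_links(net)
        for a, b in ls.link_names():
            out[tuple(sorted((a, b)))] = config.base_r
    return out


def weakened_links_for(
    config: SimulationConfig, subject_index: int
) -> list[tuple[str, str, float]]:
    """Links weakened in one patient (explicit, or drawn from a seeded stream)."""
    if config.weakened_links is not None:
        return list(config.weakened_links.get(subject_index, []))
    if config.n_weakened_per_network <= 0:
        return []
    rng = subject_rng(config, _STREAM_WEAKEN, PATIENT, subject_index)
    chosen: list[tuple[str, str, float]] = []
    for net in load_networks(parcellation=config.parcellation, skip_unresolvable=True):
        names = enumerate_links(net).link_names()
        k = min(config.n_weakened_per_network, len(names))
        for idx in rng.choice(len(names), size=k, replace=False):
            a, b = names[int(idx)]
            chosen.append((a, b, config.weakened_r))
    return chosen


def nearest_psd_correlation(c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues at zero and renormalize to unit diagonal."""
    c = np.asarray(c, dtype=float)
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w.min() >= -tol:
        return c
    w = np.clip(w, 0.0, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    if np.any(d <= 0):
        raise ConfigError("planted covariance degenerate after PSD repair")
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def planted_correlation_matrix(
    config: SimulationConfig, subject_kind: str = CONTROL, subject_index: int = 0
) -> np.ndarray:
    """Target node-by-node correlation matrix for one subject (PSD-repaired)."""
    nodes = config.node_names
    idx = {nd: i for i, nd in enumerate(nodes)}
    base = config.base_connectivity
    if base is None:
        base = default_connectivity(config)
    c = np.eye(len(nodes))
    for (a, b), r in base.items():
        if a not in idx or b not in idx:
            raise ConfigError(f"connectivity link ({a}, {b}) not in parcellation")
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    if subject_kind == PATIENT:
        for a, b, r in weakened_links_for(config, subject_index):
            c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    c = nearest_psd_correlation(c)
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-8:
        raise ConfigError("planted covariance not PSD after repair")
    return c


def _correlated_factor(c: np.ndarray) -> np.ndarray:
    """Factor A with A @ A.T = c, tolerant of singular targets."""
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_node_signals(
    config: SimulationConfig,
    subject_kind: str = CONTROL,
    subject_index: int = 0,
    rng=None,
):
    """Latent regional signals (nodes x timepoints) plus confound phases.

    Draw order (phases, then the Gaussian block) is fixed so that
    :func:`generate_bold` can continue the same stream for voxel noise.
    """
    if rng is None:
        rng = subject_rng(config, _STREAM_BOLD, subject_kind, subject_index)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    c = planted_correlation_matrix(config, subject_kind, subject_index)
    z = rng.standard_normal((config.n_timepoints, c.shape[0]))
    latent = z @ _correlated_factor(c).T  # (t, nodes)
    return latent.T.copy(), phases, rng


# ---------------------------------------------------------------------------
# Label maps


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _split_pair(total: int, ai: float) -> tuple[int, int]:
    """Voxel counts (left, right) realizing AI = (V_L - V_R) / ((V_L + V_R)/2)."""
    v_right = int(round(total * (2.0 - ai) / 4.0))
    return total - v_right, v_right


def generate_label_map(
    config: SimulationConfig,
    subject_kind: str = CONTROL,
    subject_index: int = 0,
) -> LabelVolume:
    """Parcellation volume with planted tissue fractions and thalamus AI.

    Regions occupy contiguous runs of the flattened grid; label 0 is
    background.  The left/right voxel counts of ``config.asymmetry_region``
    realize the planted asymmetry index up to one-voxel quantization.
    """
    rng = subject_rng(config, _STREAM_LABELS, subject_kind, subject_index)
    regions = list(config.parcellation)
    if not regions:
        raise ConfigError("parcellation defines no regions")

    if config.thalamus_asymmetry is not None:
        ai = float(config.thalamus_asymmetry)
    else:
        mu, sd = config.ai_mean[subject_kind], config.ai_sd[subject_kind]
        ai = float(np.clip(abs(rng.normal(mu, sd)), 0.0, 1.8))
    if not (0.0 <= ai <= 2.0):
        raise ConfigError(f"asymmetry index must lie in [0, 2], got {ai}")

    # combined (L+R) voxel count per region
    if config.region_voxel_counts is not None:
        combined = {r: int(config.region_voxel_counts[r]) for r in regions}
    else:
        frac_mu = config.tissue_fraction_mean[subject_kind]
        frac_sd = config.tissue_fraction_sd[subject_kind]
        f = {
            t: float(np.clip(rng.normal(frac_mu[t], frac_sd[t]), 0.05, 0.9))
            for t in ("GM", "WM")
        }
        f["CSF"] = 1.0 - f["GM"] - f["WM"]
        if f["CSF"] < 0.05:  # keep all three compartments non-trivial
            scale = 0.95 / (f["GM"] + f["WM"])
            f["GM"] *= scale
            f["WM"] *= scale
            f["CSF"] = 0.05
        combined = {}
        for tissue in ("GM", "WM", "CSF"):
            members = [r for r in regions if config.parcellation[r]["tissue"] == tissue]
            if not members:
                continue
            n_t = int(round(f[tissue] * config.total_labeled_voxels))
            w = np.array([config.parcellation[r]["weight"] for r in members])
            for r, c in zip(members, _largest_remainder(w, n_t)):
                combined[r] = int(c)

    total = sum(combined.values())
    if total > int(np.prod(config.grid_shape)):
        raise SizingError(
            f"grid {config.grid_shape} holds {int(np.prod(config.grid_shape))} "
            f"voxels but {total} are requested"
        )

    # per-node counts; the asymmetric pair realizes the planted AI
    counts: dict[int, int] = {}
    for region in regions:
        spec = config.parcellation[region]
        c = combined[region]
        if region == config.asymmetry_region:
            v_l, v_r = _split_pair(c, ai)
        else:
            v_l, v_r = c - c // 2, c // 2
        counts[spec["labels"]["L"]] = v_l
        counts[spec["labels"]["R"]] = v_r

    flat = np.zeros(int(np.prod(config.grid_shape)), dtype=np.int16)
    pos = 0
    for lab in sorted(counts):
        flat[pos : pos + counts[lab]] = lab
        pos += counts[lab]
    return LabelVolume(
        data=flat.reshape(config.grid_shape), affine=_affine(config.voxel_size_mm)
    )


# ---------------------------------------------------------------------------
# BOLD


@dataclass
class PhysioTrace:
    """Recorded cardiac / respiratory traces on a strictly increasing grid."""

    time_s: np.ndarray
    cardiac: np.ndarray
    respiratory: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ConfigError("physio time_s must be strictly increasing")


def generate_bold(
    config: SimulationConfig,
    labels: LabelVolume,
    subject_kind: str = CONTROL,
    subject_index: int = 0,
):
    """One subject's 4-D BOLD run plus its exact physiological confounds.

    Voxels of a region share the region's latent multivariate-Gaussian
    signal; independent Gaussian voxel noise and subject-phase sinusoidal
    cardiac/respiratory confounds are added on top of a constant baseline.
    Returns ``(Bold4D, PhysioTrace)``.
    """
    from .preprocess import Bold4D  # local import to avoid a cycle

    if tuple(labels.data.shape) != tuple(config.grid_shape):
        raise ConfigError(
            f"label map shape {labels.data.shape} does not match "
            f"grid_shape {config.grid_shape}"
        )
    rng = subject_rng(config, _STREAM_BOLD, subject_kind, subject_index)
    signals, phases, rng = simulate_node_signals(
        config, subject_kind, subject_index, rng=rng
    )
    t = np.arange(config.n_timepoints) * config.tr_seconds
    cardiac = np.sin(2.0 * np.pi * config.cardiac_hz * t + phases[0])
    respiratory = np.sin(2.0 * np.pi * config.respiratory_hz * t + phases[1])
    confound = config.confound_amplitude * (cardiac + respiratory)

    shape = tuple(config.grid_shape) + (config.n_timepoints,)
    data = np.zeros(shape, dtype=float)
    labs = labels.data
    for node, lab in config.node_labels.items():
        mask = labs == lab
        if not mask.any():
            continue
        i = config.node_names.index(node)
        data[mask] = config.baseline + signals[i] + confound
    brain = labs > 0
    if config.noise_sd > 0 and brain.any():
        data[brain] += config.noise_sd * rng.standard_normal(
            (int(brain.sum()), config.n_timepoints)
        )
    bold = Bold4D(data=data, tr_seconds=config.tr_seconds, affine=labels.affine)
    physio = PhysioTrace(time_s=t, cardiac=cardiac, respiratory=respiratory)
    return bold, physio


# ---------------------------------------------------------------------------
# FA skeletons


def skeleton_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Fixed synthetic tract skeleton: two coronal and two axial sheets."""
    nx, ny, nz = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)
    for y in (ny // 3, (2 * ny) // 3):
        mask[:, y, :] = True
    for z in (nz // 3, (2 * nz) // 3):
        mask[:, :, z] = True
    return mask


def generate_fa_skeleton(
    config: SimulationConfig,
    subject_kind: str = CONTROL,
    subject_index: int = 0,
) -> FASkeletonMap:
    """Skeletonized FA map; patients carry a contiguous lesional patch.

    Control values are Gaussian around ``fa_mean`` truncated to
    ``[fa_floor, 1]`` (the white-matter threshold); lesion voxels are reduced
    by ``lesion_depth`` and may fall below the threshold, as lesional white
    matter does.
    """
    rng = subject_rng(config, _STREAM_FA, subject_kind, subject_index)
    mask = skeleton_mask(config.grid_shape)
    fa = np.zeros(config.grid_shape, dtype=float)
    fa[mask] = np.clip(
        rng.normal(config.fa_mean, config.fa_sd, size=int(mask.sum())),
        config.fa_floor,
        1.0,
    )
    lesion = None
    if subject_kind == PATIENT and config.lesion_depth > 0:
        coords = np.argwhere(mask)
        center = coords[int(rng.integers(len(coords)))]
        dist2 = ((np.indices(config.grid_shape).reshape(3, -1).T - center) ** 2).sum(
            axis=1
        )
        ball = (dist2 <= config.lesion_radius**2).reshape(config.grid_shape)
        lesion = ball & mask
        fa[lesion] = np.clip(fa[lesion] - config.lesion_depth, 0.01, 1.0)
    return FASkeletonMap(
        fa=fa,
        skeleton_mask=mask,
        affine=_affine(config.voxel_size_mm),
        lesion_mask=lesion,
    )


# ---------------------------------------------------------------------------
# Cohort conveniences


def cohort_sex(config: SimulationConfig) -> dict[str, str]:
    """Subject id -> sex; mirrors the emulated cohort (controls balanced,
    patients 9:1 female:male)."""
    out = {}
    for i in range(config.n_controls):
        out[subject_id(CONTROL, i)] = "F" if i < (config.n_controls + 1) // 2 else "M"
    n_female = int(np.ceil(0.9 * config.n_patients))
    for i in range(config.n_patients):
        out[subject_id(PATIENT, i)] = "F" if i < n_female else "M"
    return out


def subject_id(kind: str, index: int) -> str:
    return f"{'ctrl' if kind == CONTROL else 'pat'}{index:02d}"


def iter_subjects(config: SimulationConfig):
    """Yield (subject_id, kind, index) for the whole cohort, controls first."""
    for i in range(config.n_controls):
        yield subject_id(CONTROL, i), CONTROL, i
    for i in range(config.n_patients):
        yield subject_id(PATIENT, i), PATIENT, i
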