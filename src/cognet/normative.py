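"""Normative link bands, abnormal-link detection and group statistics.

The control cohort defines, per link, a normative band mean ± 2 SD (sample
SD, denominator n−1), optionally stratified by sex.  A patient's link is
*reduced* below the band, *elevated* above it, *abnormal* either way.  The
headline per-patient statistic is the reduced-link count per network; group
inference is a one-sample t-test of those counts and Pearson correlations of
counts between networks.

Under a Gaussian null the two-sided ±2 SD rule flags a fraction tending to
2·Φ(−2) ≈ 4.55% of links as the control cohort grows; with a finite cohort
the rate is somewhat inflated because the band itself is estimated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix
from .networks import LinkSet

NORMAL = "normal"
REDUCED = "reduced"
ELEVATED = "elevated"
UNDEFINED = "undefined"

# two-sided Gaussian tail mass outside +/- 2 SD
GAUSSIAN_TWO_SIDED_2SD = float(2.0 * stats.norm.sf(2.0))


class NormativeError(ValueError):
    pass


def _links_for(node_order: tuple[str, ...]) -> tuple[tuple[int, int], ...]:
    n = len(node_order)
    return tuple((i, j) for i in range(n) for j in range(i + 1, n))


@dataclass
class NormativeLinkModel:
    """Per-link control mean and SD defining the ±2 SD band."""

    network_name: str
    node_order: tuple[str, ...]
    links: tuple[tuple[int, int], ...]
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_per_link: np.ndarray
    n_controls: int
    stratum: str | None = None

    @property
    def unmodelable(self) -> np.ndarray:
        return self.n_per_link < 2

    def band(self, n_sd: float = 2.0):
        return self.mean_r - n_sd * self.sd_r, self.mean_r + n_sd * self.sd_r

    def _with_stratum(self, stratum: str) -> "NormativeLinkModel":
        self.stratum = stratum
        return self


@dataclass
class AbnormalLinkReport:
    """Per-link status of one patient against a normative model."""

    subject_id: str
    network_name: str
    links: tuple[tuple[int, int], ...]
    node_order: tuple[str, ...]
    r: np.ndarray
    status: list[str]
    reduced_count: int = field(init=False)
    elevated_count: int = field(init=False)
    abnormal_count: int = field(init=False)
    n_defined: int = field(init=False)

    def __post_init__(self):
        self.reduced_count = self.status.count(REDUCED)
        self.elevated_count = self.status.count(ELEVATED)
        self.abnormal_count = self.reduced_count + self.elevated_count
        self.n_defined = len(self.status) - self.status.count(UNDEFINED)


@dataclass
class FrequencyMap:
    """Per-link count of patients flagged, across a cohort (Figure-2 style)."""

    network_name: str
    links: tuple[tuple[int, int], ...]
    node_order: tuple[str, ...]
    counts: np.ndarray
    n_patients: int
    reduced_only: bool


def fit_normative(
    controls: list[ConnectivityMatrix],
    stratify_by_sex: bool = False,
    sex_labels: dict[str, str] | None = None,
):
    """Per-link sample mean/SD across controls.

    Returns one :class:`NormativeLinkModel`, or a ``{sex: model}`` dict when
    ``stratify_by_sex``.  NaN link values are dropped per link with the
    per-link n recorded; links with fewer than 2 usable controls are
    unmodelable (NaN band).
    """
    if stratify_by_sex:
        if not sex_labels:
            raise NormativeError("stratify_by_sex requires sex labels")
        strata: dict[str, list[ConnectivityMatrix]] = {}
        for cm in controls:
            try:
                strata.setdefault(sex_labels[cm.subject_id], []).append(cm)
            except KeyError:
                raise NormativeError(f"no sex label for control {cm.subject_id!r}")
        return {
            sex: fit_normative(members)._with_stratum(sex)
            for sex, members in sorted(strata.items())
        }

    if len(controls) < 2:
        raise NormativeError(
            f"need at least 2 controls, got {len(controls)}: every link unmodelable"
        )
    first = controls[0]
    for cm in controls[1:]:
        if cm.network_name != first.network_name or cm.node_order != first.node_order:
            raise NormativeError("controls mix networks or node orders")
    links = _links_for(first.node_order)
    values = np.array([cm.link_values(links) for cm in controls])  # (subjects, L)
    finite = np.isfinite(values)
    n = finite.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(finite, values, np.nan), axis=0)
        sd = np.nanstd(np.where(finite, values, np.nan), axis=0, ddof=1)
    mean[n < 2] = np.nan
    sd[n < 2] = np.nan
    return NormativeLinkModel(
        network_name=first.network_name,
        node_order=first.node_order,
        links=links,
        mean_r=mean,
        sd_r=sd,
        n_per_link=n,
        n_controls=len(controls),
    )


def flag_abnormal(
    patient: ConnectivityMatrix, model: NormativeLinkModel, n_sd: float = 2.0
) -> AbnormalLinkReport:
    """Mark each patient link against the model's mean ± ``n_sd``·SD band."""
    if (
        patient.network_name != model.network_name
        or patient.node_order != model.node_order
    ):
        raise NormativeError(
            f"patient {patient.subject_id!r} does not match the normative model "
            f"({patient.network_name!r} vs {model.network_name!r})"
        )
    r = patient.link_values(model.links)
    lo, hi = model.band(n_sd)
    status = []
    for k, value in enumerate(r):
        if not np.isfinite(value) or model.n_per_link[k] < 2:
            status.append(UNDEFINED)
        elif value < lo[k]:
            status.append(REDUCED)
        elif value > hi[k]:
            status.append(ELEVATED)
        else:
            status.append(NORMAL)
    return AbnormalLinkReport(
        subject_id=patient.subject_id,
        network_name=model.network_name,
        links=model.links,
        node_order=model.node_order,
        r=r,
        status=status,
    )


def frequency_map(
    reports: list[AbnormalLinkReport], reduced_only: bool = False
) -> FrequencyMap:
    """How many patients are flagged on each link (Figure-2 aggregation)."""
    if reports:
        first = reports[0]
        name, links, node_order = first.network_name, first.links, first.node_order
        for rep in reports[1:]:
            if rep.network_name != name or rep.links != links:
                raise NormativeError("reports mix networks")
    else:
        name, links, node_order = "", (), ()
    flagged = (REDUCED,) if reduced_only else (REDUCED, ELEVATED)
    counts = np.zeros(len(links), dtype=int)
    for rep in reports:
        counts += np.array([s in flagged for s in rep.status], dtype=int)
    return FrequencyMap(
        network_name=name,
        links=links,
        node_order=node_order,
        counts=counts,
        n_patients=len(reports),
        reduced_only=reduced_only,
    )


@dataclass
class DeficitTest:
    """One-sample t-test of per-patient link-deficit counts."""

    network_name: str
    counts: np.ndarray
    null_mean: float
    mean: float
    sd: float
    t: float
    p: float
    n: int
    zero_variance: bool = False

    def table_row(self) -> str:
        return f"{self.mean:.3f} (±{self.sd:.3f})"


def calibrated_null_mean(model: NormativeLinkModel, reduced_only: bool = True) -> float:
    """Expected false-flag count per patient under the Gaussian null."""
    L = int((model.n_per_link >= 2).sum())
    rate = GAUSSIAN_TWO_SIDED_2SD / 2.0 if reduced_only else GAUSSIAN_TWO_SIDED_2SD
    return rate * L


def deficit_ttest(
    reports: list[AbnormalLinkReport],
    null_mean: float = 0.0,
    use: str = REDUCED,
) -> DeficitTest:
    """Two-sided one-sample t-test of per-patient counts against ``null_mean``.

    ``use`` selects the counted statistic: ``"reduced"`` (the headline
    deficit count) or ``"abnormal"`` (two-sided flags).
    """
    if len(reports) < 2:
        raise NormativeError("deficit t-test needs at least 2 patients")
    if use == REDUCED:
        counts = np.array([r.reduced_count for r in reports], dtype=float)
    elif use == "abnormal":
        counts = np.array([r.abnormal_count for r in reports], dtype=float)
    else:
        raise NormativeError(f"use must be 'reduced' or 'abnormal', got {use!r}")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    if sd == 0.0:
        return DeficitTest(
            network_name=reports[0].network_name,
            counts=counts,
            null_mean=null_mean,
            mean=mean,
            sd=0.0,
            t=0.0 if mean == null_mean else np.inf * np.sign(mean - null_mean),
            p=float("nan"),
            n=len(counts),
            zero_variance=True,
        )
    res = stats.ttest_1samp(counts, popmean=null_mean)
    return DeficitTest(
        network_name=reports[0].network_name,
        counts=counts,
        null_mean=null_mean,
        mean=mean,
        sd=sd,
        t=float(res.statistic),
        p=float(res.pvalue),
        n=len(counts),
    )


def network_correlations(
    reports_by_network: dict[str, list[AbnormalLinkReport]],
    use: str = REDUCED,
):
    """Pearson correlations of per-patient deficit counts between networks.

    Returns ``(network_names, r, p)`` with symmetric unit-diagonal ``r``.
    Requires the same patients (by id, in order) in every network group and
    at least 3 patients.
    """
    names = list(reports_by_network)
    if not names:
        raise NormativeError("no networks given")
    ids = [r.subject_id for r in reports_by_network[names[0]]]
    if len(ids) < 3:
        raise NormativeError("network correlations need at least 3 patients")
    vectors = {}
    for name in names:
        reps = reports_by_network[name]
        if [r.subject_id for r in reps] != ids:
            raise NormativeError(f"network {name!r} has a different patient set")
        attr = "reduced_count" if use == REDUCED else "abnormal_count"
        vectors[name] = np.array([getattr(r, attr) for r in reps], dtype=float)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = vectors[names[i]], vectors[names[j]]
            if xi.std() == 0 or xj.std() == 0:
                rij, pij = float("nan"), float("nan")
            else:
                res = stats.pearsonr(xi, xj)
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return names, r, p
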