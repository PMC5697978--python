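"""File formats: NIfTI volumes, physio TSV, connectivity and report tables.

Images are written as uncompressed ``.nii`` (float32 for BOLD/FA, int16 for
labels) so outputs are byte-reproducible; tables are TSV via pandas.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .normative import AbnormalLinkReport, FrequencyMap, NormativeLinkModel
from .preprocess import Bold4D
from .synthetic import FASkeletonMap, LabelVolume, PhysioTrace


def save_bold(bold: Bold4D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (bold.tr_seconds,))
    nib.save(img, path)
    return path

def load_bold(path: str | Path) -> Bold4D:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return Bold4D(data=np.asarray(img.dataobj, dtype=float), tr_seconds=tr,
                  affine=img.affine)


def save_labels(labels: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.data.astype(np.int16), labels.affine), path)
    return path

def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(data=np.asarray(img.dataobj, dtype=np.int16),
                       affine=img.affine)


def save_fa(fa_map: FASkeletonMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(fa_map.fa.astype(np.float32), fa_map.affine), path)
    return path

def load_fa(path: str | Path) -> FASkeletonMap:
    """Skeleton mask is recovered as the nonzero support of the stored map."""
    img = nib.load(str(path))
    fa = np.asarray(img.dataobj, dtype=float)
    return FASkeletonMap(fa=fa, skeleton_mask=fa > 0, affine=img.affine)


def save_physio(trace: PhysioTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time_s, "cardiac": trace.cardiac,
         "respiratory": trace.respiratory}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path

def load_physio(path: str | Path) -> PhysioTrace:
    df = pd.read_csv(path, sep="\t")
    return PhysioTrace(time_s=df["time_s"].to_numpy(),
                       cardiac=df["cardiac"].to_numpy(),
                       respiratory=df["respiratory"].to_numpy())


def save_matrix(cm: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(cm.r, index=cm.node_order, columns=cm.node_order).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    return path

def load_matrix(path: str | Path, subject_id: str, network_name: str
                ) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(subject_id=subject_id, network_name=network_name,
                              r=df.to_numpy(), node_order=tuple(df.columns))


def save_normative_model(model: NormativeLinkModel, path: str | Path) -> Path:
    rows = []
    for k, (i, j) in enumerate(model.links):
        rows.append({
            "node_i": model.node_order[i], "node_j": model.node_order[j],
            "mean_r": model.mean_r[k], "sd_r": model.sd_r[k],
            "n": int(model.n_per_link[k]),
        })
    df = pd.DataFrame(rows)
    df.insert(0, "network", model.network_name)
    if model.stratum is not None:
        df.insert(1, "stratum", model.stratum)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def save_reports(reports: list[AbnormalLinkReport], path: str | Path) -> Path:
    rows = []
    for rep in reports:
        for k, (i, j) in enumerate(rep.links):
            rows.append({
                "subject": rep.subject_id, "network": rep.network_name,
                "node_i": rep.node_order[i], "node_j": rep.node_order[j],
                "r": rep.r[k], "status": rep.status[k],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def save_frequency_map(fmap: FrequencyMap, path: str | Path) -> Path:
    rows = []
    for k, (i, j) in enumerate(fmap.links):
        rows.append({
            "network": fmap.network_name,
            "node_i": fmap.node_order[i], "node_j": fmap.node_order[j],
            "count": int(fmap.counts[k]),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
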