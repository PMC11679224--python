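"""Readers and writers for cohort, feature, and report artifacts.

Formats: NIfTI 4D volumes (one per subject, synthetic line-of-voxels
geometry mapped to an (V, 1, 1, T) image with a 1 mm isotropic affine),
CSV tables for labels / features / fused vectors / predictions, JSON
manifests and reports, and an .npz checkpoint for trained models.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import afgru
from .ica import SubjectFeatureSet
from .stfa import ConvBankParams, FusedFeature
from .synth import RSNAtlas, SubjectScan

__all__ = [
    "save_cohort", "load_cohort", "save_atlas", "load_atlas",
    "save_feature_sets", "load_feature_sets", "save_fused", "load_fused",
    "save_model", "load_model", "save_json", "load_json",
]


def save_json(obj: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


# --- cohort -----------------------------------------------------------------


def save_cohort(scans: list[SubjectScan], out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        vol = scan.data.T.reshape(scan.n_voxels, 1, 1, scan.n_timepoints)
        img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
        nib.save(img, out / f"{scan.subject_id}.nii")
        rows.append({"subject_id": scan.subject_id, "label": scan.label})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def load_cohort(in_dir: Path | str) -> list[SubjectScan]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    scans = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        path = in_dir / f"{sid}.nii"
        if not path.exists():
            path = in_dir / f"{sid}.nii.gz"
        img = nib.load(path)
        vol = np.asarray(img.dataobj, dtype=float)
        data = vol.reshape(-1, vol.shape[-1]).T  # (T, V)
        scans.append(SubjectScan(subject_id=sid, data=data, label=int(row["label"])))
    return scans


def save_atlas(atlas: RSNAtlas, path: Path | str) -> None:
    pd.DataFrame(atlas.maps, columns=atlas.names).to_csv(path, index=False)


def load_atlas(path: Path | str) -> RSNAtlas:
    df = pd.read_csv(path)
    return RSNAtlas(maps=df.to_numpy(dtype=float), names=list(df.columns))


# --- per-subject feature sets ----------------------------------------------


def save_feature_sets(
    feature_sets: list[SubjectFeatureSet], out_dir: Path | str, manifest_extra: dict | None = None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fs in feature_sets:
        pd.DataFrame(fs.timecourses).to_csv(out / f"{fs.subject_id}_timecourses.csv", index=False)
        pd.DataFrame(fs.spatial_features).to_csv(out / f"{fs.subject_id}_spatial.csv", index=False)
    manifest = {
        "subjects": [{"subject_id": fs.subject_id, "label": fs.label} for fs in feature_sets],
        "T_prime": int(feature_sets[0].timecourses.shape[0]),
        "n_components": int(feature_sets[0].timecourses.shape[1]),
        "n_networks": int(feature_sets[0].spatial_features.shape[0]),
    }
    manifest.update(manifest_extra or {})
    save_json(manifest, out / "manifest.json")


def load_feature_sets(in_dir: Path | str) -> list[SubjectFeatureSet]:
    in_dir = Path(in_dir)
    manifest = load_json(in_dir / "manifest.json")
    out = []
    for rec in manifest["subjects"]:
        sid = rec["subject_id"]
        tc = pd.read_csv(in_dir / f"{sid}_timecourses.csv").to_numpy(dtype=float)
        sp = pd.read_csv(in_dir / f"{sid}_spatial.csv").to_numpy(dtype=float)
        out.append(SubjectFeatureSet(subject_id=sid, timecourses=tc,
                                     spatial_features=sp, label=int(rec["label"])))
    return out


# --- fused vectors ----------------------------------------------------------


def save_fused(fused: list[FusedFeature], path: Path | str) -> None:
    """One CSV row per subject plus a sidecar JSON with the layout."""
    path = Path(path)
    vecs = np.stack([f.vector for f in fused])
    df = pd.DataFrame(vecs, columns=[f"f{i:05d}" for i in range(vecs.shape[1])])
    df.insert(0, "subject_id", [f.subject_id for f in fused])
    df.insert(1, "label", [f.label for f in fused])
    df.to_csv(path, index=False)
    save_json({"layout": fused[0].layout}, path.with_suffix(".layout.json"))


def load_fused(path: Path | str) -> list[FusedFeature]:
    path = Path(path)
    layout = load_json(path.with_suffix(".layout.json"))["layout"]
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        vec = row.drop(["subject_id", "label"]).to_numpy(dtype=float)
        out.append(FusedFeature(subject_id=str(row["subject_id"]),
                                vector=vec, label=int(row["label"]), layout=layout))
    return out


# --- model checkpoint -------------------------------------------------------


def save_model(model: afgru.AFGRUModel, path: Path | str) -> None:
    header = {
        "version": 1,
        "config": vars(model.config),
        "seq_shape": list(model.seq_shape),
        "layout": model.layout,
        "trained": model.trained,
        "branch_lr": model.branch_weights.lr,
        "branch_rounds": model.branch_weights.rounds,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["branch_w"] = model.branch_weights.w
    arrays["feature_mean"] = model.feature_mean
    arrays["feature_std"] = model.feature_std
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path: Path | str) -> afgru.AFGRUModel:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                 allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        weights = afgru.BranchWeights(
            w=data["branch_w"], lr=header["branch_lr"], rounds=header["branch_rounds"]
        )
        model = afgru.AFGRUModel(
            config=afgru.AFGRUConfig(**header["config"]),
            params=params,
            branch_weights=weights,
            seq_shape=tuple(header["seq_shape"]),
            layout=header["layout"],
            feature_mean=data["feature_mean"],
            feature_std=data["feature_std"],
            trained=header["trained"],
        )
    return model


def conv_params_from_config(kernel_sizes, n_filters, pool, seed) -> ConvBankParams:
    return ConvBankParams(
        kernel_sizes=tuple(kernel_sizes), n_filters=n_filters, pool_size=pool, seed=seed
    )
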