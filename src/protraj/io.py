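"""Formats, configuration and pipeline orchestration.

Tables travel as delimited text (CSV), volumes as NIfTI-1 (affines
preserved), fitted models and reports as JSON.  All floats are serialised
at full precision so write-then-read round-trips are exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .gmlvq import GMLVQ, GMLVQResults
from .pls_rfe import PLSRFE, VoxelMatrix, VoxelWeightMap, gm_score
from .simulate import SimulationConfig, simulate_cohort
from .validation import (classification_metrics, kfold_cv, pearson_ci,
                         random_resampling, rate_of_change)

__all__ = [
    "read_cohort", "write_cohort",
    "read_voxel_matrix", "write_voxel_matrix",
    "read_voxel_niftis", "write_voxel_niftis",
    "write_weight_map", "read_weight_map",
    "load_config", "run_pipeline",
]

COHORT_NUMERIC = ["gds", "adni_mem", "adni_ef", "amyloid_suvr", "apoe4"]


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort(path, required=("subject_id",), numeric=COHORT_NUMERIC,
                longitudinal_path=None) -> pd.DataFrame:
    """Read and validate a per-subject table; optionally join visit series.

    Errors name offending ids/cells; rows with missing values in the
    numeric model features are dropped with a recorded count
    (``df.attrs['n_dropped']``).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    dupes = df.loc[df.subject_id.duplicated(), "subject_id"].tolist()
    if dupes:
        raise ValueError(f"duplicate subject id(s): {dupes}")
    for col in numeric:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as e:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                         & df[col].notna()].index.tolist()
                raise ValueError(f"unparseable cells in column {col!r}, rows {bad}") from e
    present = [c for c in numeric if c in df.columns]
    n_before = len(df)
    # canonical subject order so downstream seeded fits are independent of
    # the file's row order
    df = df.dropna(subset=present).sort_values("subject_id").reset_index(drop=True)
    df.attrs["n_dropped"] = n_before - len(df)
    if longitudinal_path is not None:
        series = pd.read_csv(longitudinal_path, float_precision="round_trip")
        unknown = set(series.subject_id) - set(df.subject_id)
        if unknown:
            raise ValueError(f"longitudinal series for unknown id(s): {sorted(unknown)[:5]}")
        df.attrs["longitudinal"] = series
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# voxel matrices


def write_voxel_matrix(voxels: VoxelMatrix, values_path, index_path) -> None:
    """Dense matrix + (i,j,k) sidecar as delimited text."""
    pd.DataFrame(voxels.values).to_csv(values_path, index=False, float_format="%.17g")
    idx = pd.DataFrame(voxels.voxel_index, columns=["i", "j", "k"])
    idx.attrs = {}
    header = ",".join(map(str, voxels.grid_shape))
    with open(index_path, "w") as fh:
        fh.write(f"# grid_shape={header}\n")
        idx.to_csv(fh, index=False)


def read_voxel_matrix(values_path, index_path) -> VoxelMatrix:
    with open(index_path) as fh:
        first = fh.readline()
        if not first.startswith("# grid_shape="):
            raise ValueError(f"{index_path} lacks a grid_shape header line")
        grid_shape = tuple(int(v) for v in first.split("=", 1)[1].split(","))
        idx = pd.read_csv(fh, float_precision="round_trip")
    values = pd.read_csv(values_path, float_precision="round_trip").to_numpy(float)
    return VoxelMatrix(values, idx[["i", "j", "k"]].to_numpy(int), grid_shape)


def write_voxel_niftis(voxels: VoxelMatrix, out_dir, subject_ids) -> list[Path]:
    """One NIfTI-1 volume per subject on the common grid."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = voxels.affine if voxels.affine is not None else np.eye(4)
    paths = []
    lin = voxels.linear_index()
    for row, sid in zip(voxels.values, subject_ids):
        vol = np.zeros(voxels.grid_shape)
        vol.ravel()[lin] = row
        p = out_dir / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths.append(p)
    return paths


def read_voxel_niftis(paths) -> VoxelMatrix:
    """Stack per-subject volumes (identical grids) into a voxel matrix."""
    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape, affine = data.shape, img.affine
        elif data.shape != shape or not np.allclose(img.affine, affine):
            raise ValueError(f"{p} is not on the common grid")
        vols.append(data.ravel())
    index = np.argwhere(np.ones(shape, dtype=bool))
    return VoxelMatrix(np.vstack(vols), index, shape, affine=affine)


def write_weight_map(wmap: VoxelWeightMap, table_path, nifti_path=None) -> None:
    wmap.to_frame().to_csv(table_path, index=False, float_format="%.17g")
    meta = {"grid_shape": list(wmap.grid_shape)}
    with open(str(table_path) + ".json", "w") as fh:
        json.dump(meta, fh)
    if nifti_path is not None:
        affine = wmap.affine if wmap.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(wmap.to_volume(), affine), str(nifti_path))


def read_weight_map(table_path) -> VoxelWeightMap:
    df = pd.read_csv(table_path, float_precision="round_trip")
    with open(str(table_path) + ".json") as fh:
        meta = json.load(fh)
    z = df["zstat"].to_numpy(float)
    return VoxelWeightMap(
        voxel_index=df[["i", "j", "k"]].to_numpy(int),
        weights=df["weight"].to_numpy(float),
        grid_shape=tuple(meta["grid_shape"]),
        centers=df["center"].to_numpy(float),
        zstats=None if np.all(np.isnan(z)) else z,
    )


# ---------------------------------------------------------------------------
# configuration and pipeline


def load_config(path) -> SimulationConfig:
    """YAML key/value config overriding the simulation defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimulationConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, tuple):
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def _config_hash(cfg: SimulationConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: SimulationConfig | None = None, out_dir=None,
                 seed: int | None = None, n_resamples: int = 100, cv_folds: int = 5,
                 pls_folds: int = 5, stages=("simulate", "pls", "gmlvq", "validate"),
                 verbose: bool = False) -> dict:
    """Run simulate -> fit-pls -> score-gm -> fit-gmlvq -> project -> validate.

    Returns a report dict (also written as JSON when ``out_dir`` is given)
    containing exclusion counts, CV metrics for cognitive and biological
    models, resampling medians, and the projection/decline correlations.
    Every artifact is stamped with the config hash and seed.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    stages = list(stages)
    known = {"simulate", "pls", "gmlvq", "validate"}
    if set(stages) - known:
        raise ValueError(f"unknown stage(s): {set(stages) - known}")
    for pre, post in (("simulate", "pls"), ("pls", "gmlvq"), ("gmlvq", "validate")):
        if post in stages and pre not in stages:
            raise ValueError(f"stage {post!r} requires stage {pre!r}")
    report: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed, "timings": {}}

    def _log(msg):
        if verbose:
            print(msg, flush=True)

    t0 = time.perf_counter()
    cohort = simulate_cohort(cfg)
    report["timings"]["simulate"] = time.perf_counter() - t0
    labelled = cohort.labelled
    report["n_subjects"] = len(cohort.table)
    report["n_labelled_mci"] = len(labelled)
    report["n_excluded"] = int((cohort.table.label == "excluded").sum())
    _log(f"simulated {len(cohort.table)} subjects ({len(labelled)} labelled MCI)")
    out = {"cohort": cohort, "report": report}
    if "pls" not in stages:
        return _finish(report, out, out_dir, cohort)

    # grey-matter biomarker from density -> memory regression
    t0 = time.perf_counter()
    plsrfe = PLSRFE(cohort.voxels, cohort.table.adni_mem.to_numpy())
    pls_res = plsrfe.fit(folds=pls_folds, seed=cfg.seed)
    report["timings"]["pls"] = time.perf_counter() - t0
    gm = pls_res.score(cohort.voxels)
    cohort.table["gm_score"] = gm
    report["pls"] = {"n_retained": pls_res.weight_map.n_retained,
                     "held_out_r2": pls_res.held_out_r2()}
    out["pls"] = pls_res
    _log(f"PLS-RFE retained {pls_res.weight_map.n_retained} voxels "
         f"(held-out r2 {report['pls']['held_out_r2']:.3f})")
    if "gmlvq" not in stages:
        return _finish(report, out, out_dir, cohort)

    # classifiers and projections on the labelled MCI subsample
    t0 = time.perf_counter()
    feature_sets = {
        "cognitive": ["gds", "adni_mem", "adni_ef"],
        "biological": ["gm_score", "amyloid_suvr", "apoe4"],
    }
    models = {}
    for name, feats in feature_sets.items():
        model = GMLVQ.from_dataframe(cohort.table.loc[labelled.index], feats, "label")
        models[name] = model.fit(seed=cfg.seed)
    report["timings"]["gmlvq"] = time.perf_counter() - t0
    out["gmlvq"] = models
    if "validate" not in stages:
        return _finish(report, out, out_dir, cohort, models=models)

    t0 = time.perf_counter()
    slopes = {}
    for sid, grp in cohort.longitudinal.groupby("subject_id"):
        slopes[sid] = rate_of_change(grp.time_years, grp.adni_mem).slope
    lab = cohort.table.loc[labelled.index]
    report["validation"] = {}
    for name, feats in feature_sets.items():
        Xl = lab[feats].to_numpy(float)
        yl = lab["label"].to_numpy()
        cv = kfold_cv(Xl, yl, _gmlvq_factory(feats), k=cv_folds, seed=cfg.seed)
        sl = lab.subject_id.map(slopes).to_numpy(float)
        resamp = random_resampling(Xl, yl, sl, n_resamples=n_resamples,
                                   train_size=min(52, len(lab) - 10), seed=cfg.seed,
                                   feature_names=feats)
        proj = models[name].project(Xl)
        corr = pearson_ci(proj, sl)
        report["validation"][name] = {
            "cv": cv.mean_metrics.round().as_dict(),
            "resampling_median_r": resamp.median_r,
            "resampling_ci95": list(resamp.ci95),
            "projection_slope_r": corr.r,
            "projection_slope_ci95": list(corr.ci95),
            "projection_slope_p": corr.p,
        }
        _log(f"{name}: {cv.summary()}; projection-slope {corr.summary()}")
    report["timings"]["validate"] = time.perf_counter() - t0
    return _finish(report, out, out_dir, cohort, models=models)


def _gmlvq_factory(feats):
    from .gmlvq import GMLVQClassifier

    def factory(**params):
        return GMLVQClassifier(**params)

    return factory


def _finish(report, out, out_dir, cohort, models=None):
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort.table, out_dir / "cohort.csv")
        write_cohort(cohort.longitudinal, out_dir / "longitudinal.csv")
        write_cohort(cohort.tau, out_dir / "tau.csv")
        if "pls" in out:
            write_weight_map(out["pls"].weight_map, out_dir / "weight_map.csv",
                             out_dir / "weight_map.nii.gz")
        for name, res in (models or {}).items():
            res.to_json(out_dir / f"gmlvq_{name}.json")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    out["report"] = report
    return out
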