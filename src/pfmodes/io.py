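"""Readers and writers: NIfTI-1 and HDF5 datasets, model states, reports.

Conventions: voxel ordering is raster (C) order of the mask; indexing is
0-based throughout; every HDF5 file embeds a JSON config echo.  Simulated
1-D data can be written as NIfTI with a V x 1 x 1 grid for interoperability
with standard tools, alongside the native HDF5 container.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .engine import (
    ModelState,
    MultiRunDataset,
)
from .hrf import HRFKernel
from .noise import NoisePosterior
from .spatial import GroupSpatialPosterior, SubjectMapPosterior
from .temporal import TemporalPrecisionPosterior, TimeCoursePosterior

__all__ = [
    "RunHeader",
    "read_dataset",
    "write_dataset",
    "write_state",
    "read_state",
    "write_report",
    "write_hrf_csv",
    "read_hrf_csv",
    "write_mode_maps_nifti",
    "checksum_manifest",
]


@dataclass
class RunHeader:
    """Provenance of one loaded run."""

    subject: str
    run: str
    V: int
    T: int
    tr: float
    source: str
    grid_shape: tuple[int, int, int] | None = None
    mask_indices: np.ndarray | None = None


def _load_run_matrix(path: Path, mask_indices: np.ndarray | None):
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"], dtype=float)
        return data, None, None
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D NIfTI volume, got shape {vol.shape}")
    grid_shape = vol.shape[:3]
    flat = vol.reshape(-1, vol.shape[3])  # raster (C) order
    if mask_indices is None:
        mask_indices = np.arange(flat.shape[0])
    return flat[mask_indices], grid_shape, mask_indices


def read_dataset(manifest_path: str | Path) -> tuple[MultiRunDataset, list[RunHeader]]:
    """Load a dataset from a JSON manifest listing run files.

    Manifest schema::

        {"tr": 0.72, "mask": "mask.nii.gz",     # mask optional, NIfTI only
         "runs": [{"subject": "s1", "run": "r1", "path": "s1_r1.nii.gz"}, ...]}

    Paths are resolved relative to the manifest.  NIfTI 4-D volumes are
    reshaped to V x T in raster order of the mask; HDF5 files must carry a
    ``data`` dataset of shape V x T.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    tr = float(manifest["tr"])

    mask_indices = None
    if manifest.get("mask"):
        mask_img = nib.load(str(base / manifest["mask"]))
        mask = np.asarray(mask_img.dataobj) > 0
        mask_indices = np.flatnonzero(mask.reshape(-1))

    runs: dict[tuple[str, str], np.ndarray] = {}
    headers: list[RunHeader] = []
    shapes: dict[tuple[str, str], int] = {}
    for entry in manifest["runs"]:
        key = (entry["subject"], entry["run"])
        path = base / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"run {key}: file not found: {path}")
        try:
            data, grid_shape, used_mask = _load_run_matrix(path, mask_indices)
        except Exception as exc:  # noqa: BLE001 - reattach run identity
            raise type(exc)(f"run {key}: {exc}") from exc
        if key in runs:
            raise ValueError(f"duplicate run entry {key}")
        runs[key] = data
        shapes[key] = data.shape[0]
        headers.append(
            RunHeader(
                subject=entry["subject"],
                run=entry["run"],
                V=data.shape[0],
                T=data.shape[1],
                tr=tr,
                source=str(path),
                grid_shape=grid_shape,
                mask_indices=used_mask,
            )
        )
    distinct = sorted(set(shapes.values()))
    if len(distinct) > 1:
        offenders = {k: v for k, v in shapes.items()}
        raise ValueError(f"runs disagree on voxel count V: {offenders}")
    return MultiRunDataset(runs=runs, tr=tr), headers


def write_dataset(
    data: MultiRunDataset,
    path: str | Path,
    config: dict | None = None,
) -> Path:
    """Write all runs to one HDF5 file under /runs/<subject>__<run>/data."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["tr"] = data.tr
        f.attrs["config"] = json.dumps(config or {})
        grp = f.create_group("runs")
        for (s, r), mat in sorted(data.runs.items()):
            g = grp.create_group(f"{s}__{r}")
            g.create_dataset("data", data=mat)
            g.attrs["subject"] = s
            g.attrs["run"] = r
    return path


def read_dataset_h5(path: str | Path) -> MultiRunDataset:
    with h5py.File(path, "r") as f:
        tr = float(f.attrs["tr"])
        runs = {}
        for name, g in f["runs"].items():
            runs[(g.attrs["subject"], g.attrs["run"])] = np.asarray(g["data"], dtype=float)
    return MultiRunDataset(runs=runs, tr=tr)


def write_mode_maps_nifti(
    maps: np.ndarray,
    path: str | Path,
    grid_shape: tuple[int, int, int] | None = None,
    mask_indices: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> Path:
    """Write V x M mode maps as a 4-D NIfTI (one volume per mode).

    Without a grid mapping a synthetic V x 1 x 1 grid is used.
    """
    maps = np.asarray(maps, dtype=float)
    V, M = maps.shape
    if grid_shape is None:
        grid_shape = (V, 1, 1)
        mask_indices = np.arange(V)
    if mask_indices is None:
        mask_indices = np.arange(int(np.prod(grid_shape)))
    vol = np.zeros((int(np.prod(grid_shape)), M))
    vol[mask_indices] = maps
    vol = vol.reshape(*grid_shape, M)
    img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    return Path(path)


def read_mode_maps_nifti(
    path: str | Path, mask_indices: np.ndarray | None = None
) -> np.ndarray:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    flat = vol.reshape(-1, vol.shape[3])
    if mask_indices is None:
        mask_indices = np.arange(flat.shape[0])
    return flat[mask_indices]


def write_run_nifti(run: np.ndarray, path: str | Path, tr: float) -> Path:
    """Write a V x T run as a V x 1 x 1 x T NIfTI-1 volume."""
    run = np.asarray(run, dtype=float)
    img = nib.Nifti1Image(run[:, None, None, :], np.eye(4))
    img.header["pixdim"][4] = tr
    nib.save(img, str(path))
    return Path(path)


# ----------------------------------------------------------------------------
# Model state
# ----------------------------------------------------------------------------

def write_state(state: ModelState, path: str | Path, config: dict | None = None) -> Path:
    """Serialise a ModelState to HDF5.

    Layout: /group_maps (point estimate), /group/<param>, /subjects/<id>/<param>,
    /runs/<subject>__<run>/{tc_mean,tc_cov,psi_shape,...}, /elbo, /config.
    """
    path = Path(path)
    g = state.group
    with h5py.File(path, "w") as f:
        f.attrs["M"] = state.M
        f.attrs["rng_seed"] = state.rng_seed
        f.attrs["config"] = json.dumps(config or {})
        f.attrs["lambda_sparsity"] = g.lambda_sparsity
        f.create_dataset("group_maps", data=state.group_maps())
        f.create_dataset("elbo", data=np.asarray(state.elbo_trace, dtype=float))
        gg = f.create_group("group")
        for name in ("pi_a", "pi_b", "rho_prob", "mu_mean", "mu_var",
                     "sigma_shape", "sigma_rate", "gamma_prec"):
            gg.create_dataset(name, data=getattr(g, name))
        gs = f.create_group("subjects")
        for sid, subj in state.subjects.items():
            sg = gs.create_group(sid)
            sg.create_dataset("slab_mean", data=subj.slab_mean)
            sg.create_dataset("slab_var", data=subj.slab_var)
            sg.create_dataset("q_prob", data=subj.q_prob)
        gr = f.create_group("runs")
        for (s, r), tc in state.timecourses.items():
            rg = gr.create_group(f"{s}__{r}")
            rg.attrs["subject"] = s
            rg.attrs["run"] = r
            rg.create_dataset("tc_mean", data=tc.mean)
            rg.create_dataset("tc_cov", data=tc.cov)
            nz = state.noise[(s, r)]
            rg.attrs["psi_shape"] = nz.psi_shape
            rg.attrs["psi_rate"] = nz.psi_rate
            rg.create_dataset("nu_mean", data=nz.nu_mean)
            rg.create_dataset("nu_var", data=nz.nu_var)
        f.attrs["alpha_shape"] = state.alpha.shape
        f.attrs["alpha_rate"] = state.alpha.rate
        priors = f.create_group("priors")
        for T, prior in state.priors.items():
            pg = priors.create_group(str(T))
            pg.create_dataset("covariance", data=prior.covariance)
            pg.attrs["tr"] = prior.tr
    return path


def read_state(path: str | Path) -> ModelState:
    from .hrf import TemporalPrior

    with h5py.File(path, "r") as f:
        group = GroupSpatialPosterior(
            pi_a=f["group/pi_a"][...],
            pi_b=f["group/pi_b"][...],
            rho_prob=f["group/rho_prob"][...],
            mu_mean=f["group/mu_mean"][...],
            mu_var=f["group/mu_var"][...],
            sigma_shape=f["group/sigma_shape"][...],
            sigma_rate=f["group/sigma_rate"][...],
            gamma_prec=f["group/gamma_prec"][...],
            lambda_sparsity=float(f.attrs["lambda_sparsity"]),
        )
        subjects = {
            sid: SubjectMapPosterior(
                slab_mean=sg["slab_mean"][...],
                slab_var=sg["slab_var"][...],
                q_prob=sg["q_prob"][...],
            )
            for sid, sg in f["subjects"].items()
        }
        timecourses = {}
        noise = {}
        for _, rg in f["runs"].items():
            key = (rg.attrs["subject"], rg.attrs["run"])
            timecourses[key] = TimeCoursePosterior(
                mean=rg["tc_mean"][...], cov=rg["tc_cov"][...]
            )
            noise[key] = NoisePosterior(
                psi_shape=float(rg.attrs["psi_shape"]),
                psi_rate=float(rg.attrs["psi_rate"]),
                nu_mean=rg["nu_mean"][...],
                nu_var=rg["nu_var"][...],
            )
        priors = {
            int(T): TemporalPrior(
                covariance=pg["covariance"][...],
                tr=float(pg.attrs["tr"]),
                T=int(T),
            )
            for T, pg in f["priors"].items()
        }
        return ModelState(
            M=int(f.attrs["M"]),
            group=group,
            subjects=subjects,
            timecourses=timecourses,
            alpha=TemporalPrecisionPosterior(
                shape=float(f.attrs["alpha_shape"]), rate=float(f.attrs["alpha_rate"])
            ),
            noise=noise,
            priors=priors,
            elbo_trace=list(np.asarray(f["elbo"][...], dtype=float)),
            rng_seed=int(f.attrs["rng_seed"]),
        )


# ----------------------------------------------------------------------------
# Reports and small text formats
# ----------------------------------------------------------------------------

REPORT_REQUIRED_KEYS = {
    "spatial_accuracy",
    "temporal_accuracy",
    "spatial_netmat_rmse",
    "temporal_netmat_rmse",
}


def write_report(report: dict, path: str | Path, csv_path: str | Path | None = None) -> Path:
    """Write a score report as JSON (and optionally a per-mode CSV table)."""
    path = Path(path)

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, float) and np.isnan(obj):
            return None
        return obj

    path.write_text(json.dumps(_clean(report), indent=2, allow_nan=False))
    if csv_path is not None and "spatial_accuracy" in report:
        sa = report["spatial_accuracy"]
        ta = report.get("temporal_accuracy", {})
        rows = [
            {"mode": int(k), "spatial_accuracy": sa[k], "temporal_accuracy": ta.get(k)}
            for k in sorted(sa, key=lambda x: int(x))
        ]
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    return path


def validate_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing required keys: {sorted(missing)}")
    return report


def write_hrf_csv(kernel: HRFKernel, path: str | Path) -> Path:
    """Dump an HRF kernel as a two-column CSV (time_s, amplitude)."""
    t = np.arange(len(kernel)) * kernel.dt
    pd.DataFrame({"time_s": t, "amplitude": kernel.samples}).to_csv(path, index=False)
    return Path(path)


def read_hrf_csv(path: str | Path) -> HRFKernel:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = float(t[1] - t[0])
    return HRFKernel(samples=df["amplitude"].to_numpy(), dt=dt, duration=dt * len(df))


def checksum_manifest(paths: list[str | Path], out_path: str | Path) -> Path:
    """Emit a JSON manifest of sha256 checksums for the given files."""
    entries = {}
    for p in paths:
        p = Path(p)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    out = Path(out_path)
    out.write_text(json.dumps(entries, indent=2, sort_keys=True))
    return out
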