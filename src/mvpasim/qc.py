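"""Quality-control metrics: integrated head motion and temporal SNR.

The integrated motion metric condenses six rigid-body realignment
parameters into a single rate.  Rotations (radians) are converted to
arc-length displacements on a sphere of radius 5.7 cm (a typical adult
head radius), the six parameters are differenced between consecutive
volumes, and the root-sum-of-squares of each difference vector, divided
by the inter-volume interval and averaged over the scan, gives a
scalar in mm/s.

tSNR is the voxelwise timecourse mean divided by its standard
deviation; zero-variance voxels are flagged as undefined rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionTrace",
    "TsnrMap",
    "read_realignment_params",
    "read_pose_log",
    "integrated_motion_metric",
    "compute_tsnr",
    "tsnr_from_nifti",
    "save_tsnr_nifti",
]

DEFAULT_ROTATION_RADIUS_MM = 57.0


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters over a scan.

    ``samples`` is (volumes, 6): x/y/z translations in mm then
    pitch/roll/yaw rotations in radians.
    """

    samples: np.ndarray
    sample_interval_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("samples must be (volumes, 6)")
        if self.samples.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")

    @property
    def n_volumes(self) -> int:
        return self.samples.shape[0]


@dataclass
class TsnrMap:
    """Per-voxel tSNR with undefined voxels flagged as NaN."""

    per_voxel: np.ndarray
    median: float
    n_undefined: int


def read_realignment_params(path,
                            sample_interval_s: float,
                            rotations_in_degrees: bool = False
                            ) -> MotionTrace:
    """Read an SPM-style 6-column whitespace-delimited ``rp_*.txt`` file.

    SPM stores rotations in radians; pass ``rotations_in_degrees=True``
    for sources using the degree dialect (converted on read).
    """
    params = np.loadtxt(path, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 realignment columns, got {params.shape[1]}")
    if rotations_in_degrees:
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    return MotionTrace(samples=params, sample_interval_s=sample_interval_s)


def read_pose_log(path, rotations_in_degrees: bool = False) -> MotionTrace:
    """Read a tracker pose log: CSV with timestamp followed by 6 DOF.

    The sampling interval is taken as the median timestamp difference.
    Lines starting with '#' are ignored.
    """
    table = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if table.shape[1] != 7:
        raise ValueError(
            f"{path}: expected timestamp + 6 DOF columns, got {table.shape[1]}")
    dt = float(np.median(np.diff(table[:, 0])))
    params = table[:, 1:].copy()
    if rotations_in_degrees:
        params[:, 3:] = np.deg2rad(params[:, 3:])
    return MotionTrace(samples=params, sample_interval_s=dt)


def integrated_motion_metric(trace: MotionTrace,
                             radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
                             ) -> float:
    """Scalar head-motion rate in mm/s.

    Rotations become arc lengths ``radius_mm * angle``; the framewise
    differences of the six displacement parameters are combined by
    root-sum-of-squares per volume pair, divided by the inter-volume
    interval, and averaged over the scan.
    """
    disp = trace.samples.copy()
    disp[:, 3:] *= radius_mm
    deltas = np.diff(disp, axis=0)
    framewise = np.sqrt((deltas ** 2).sum(axis=1))
    return float(framewise.mean() / trace.sample_interval_s)


def compute_tsnr(timeseries: np.ndarray) -> TsnrMap:
    """Per-voxel mean/SD of a (timepoints, voxels) matrix."""
    X = np.asarray(timeseries, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    sd = X.std(axis=0, ddof=1)
    defined = sd > 0
    tsnr = np.full(X.shape[1], np.nan)
    tsnr[defined] = X.mean(axis=0)[defined] / sd[defined]
    median = float(np.nanmedian(tsnr)) if defined.any() else float("nan")
    return TsnrMap(per_voxel=tsnr, median=median,
                   n_undefined=int((~defined).sum()))


def tsnr_from_nifti(path, mask: np.ndarray | None = None) -> TsnrMap:
    """tSNR of a 4D NIfTI timeseries, optionally within a boolean mask."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D timeseries")
    vox = data.reshape(-1, data.shape[3]).T  # (time, voxels)
    if mask is not None:
        vox = vox[:, np.asarray(mask, dtype=bool).reshape(-1)]
    return compute_tsnr(vox)


def save_tsnr_nifti(tsnr: TsnrMap, shape3d, path, affine=None) -> None:
    """Write a per-voxel tSNR map back to a 3D NIfTI volume."""
    import nibabel as nib

    vol = np.asarray(tsnr.per_voxel, dtype=float).reshape(shape3d)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vol, affine), str(path))
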