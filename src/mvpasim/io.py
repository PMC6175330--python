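"""On-disk layout for simulated datasets, NIfTI export, config loading.

A simulated cohort is written as one ``.npy`` matrix per participant
per subrun plus a JSON manifest carrying the design geometry, noise
levels, seeds and per-participant ground truths, so a dataset can be
regenerated or audited without the generating process.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .design import BlockDesign, make_block_design
from .synth import GroundTruth, NoiseSpec, SimulatedDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "export_nifti",
    "load_config",
]


def _matrix_name(participant: int, subrun: int) -> str:
    return f"sub-{participant:03d}_subrun-{subrun:02d}.npy"


def save_dataset(dataset: SimulatedDataset, out_dir) -> Path:
    """Write a cohort to ``out_dir`` (matrix files + manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(dataset.n_participants):
        for s in range(dataset.design.n_subruns):
            np.save(out / _matrix_name(i, s), dataset.data[i, s])
    manifest = {
        "design": {
            "block_duration_s": dataset.design.block_duration_s,
            "blocks_per_subrun": dataset.design.blocks_per_subrun,
            "n_subruns": dataset.design.n_subruns,
            "sample_period_s": dataset.design.sample_period_s,
            "inter_block_gap_s": dataset.design.inter_block_gap_s,
        },
        "noise": asdict(dataset.noise),
        "seed": dataset.seed,
        "n_participants": dataset.n_participants,
        "n_voxels": dataset.n_voxels,
        "truths": [t.condition_means.tolist() for t in dataset.truths],
    }
    (out / "manifest.json").write_text(json.dumps(manifest))
    return out


def load_dataset(in_dir) -> SimulatedDataset:
    """Load a cohort previously written by :func:`save_dataset`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    design = make_block_design(**manifest["design"])
    noise = NoiseSpec(**manifest["noise"])
    n_p = manifest["n_participants"]
    truths = [GroundTruth(condition_means=np.array(t))
              for t in manifest["truths"]]
    data = np.stack([
        np.stack([np.load(root / _matrix_name(i, s))
                  for s in range(design.n_subruns)])
        for i in range(n_p)
    ])
    return SimulatedDataset(data=data, design=design, truths=truths,
                            noise=noise, seed=manifest["seed"])


def export_nifti(data_subruns: np.ndarray, path, sample_period_s: float = 2.0
                 ) -> None:
    """Export one participant's (subruns, timepoints, voxels) matrix as a
    4D NIfTI, voxels reshaped onto a dummy cubic grid (zero-padded).

    Subruns are concatenated along time.  Intended for integration
    tests of NIfTI-consuming pipelines, not for anatomical realism.
    """
    import nibabel as nib

    data = np.asarray(data_subruns, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n_sub, n_t, n_vox = data.shape
    side = int(np.ceil(n_vox ** (1 / 3)))
    flat = np.zeros((n_sub * n_t, side ** 3))
    flat[:, :n_vox] = data.reshape(n_sub * n_t, n_vox)
    vol = flat.T.reshape(side, side, side, n_sub * n_t)
    img = nib.Nifti1Image(vol, np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, sample_period_s))
    nib.save(img, str(path))


def load_config(path) -> dict:
    """Read a JSON or YAML experiment/generator config into a dict."""
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
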