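"""File formats and run configuration.

Conventions: DW volumes are 4-D NIfTI (x, y, z, b-index) with an FSL-dialect
whitespace-separated ``.bval`` text file; parameter maps are 3-D NIfTI with
the input's affine copied; phantoms are written as a NIfTI bundle plus a
JSON sidecar.  b-values are kept in file order — silent reordering would
corrupt the pairing with volumes — with an opt-in ``sort`` flag that
reorders volumes and b-values together.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .core import AcquisitionScheme

__all__ = [
    "read_bvals",
    "write_bvals",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "write_phantom",
    "RunConfig",
]

logger = logging.getLogger(__name__)

#: in-plane voxel size (mm) written by the simulator, mirroring a typical
#: preclinical SE-EPI protocol.
SIM_VOXEL_MM = 0.282

MAP_SUFFIXES = ("_D", "_f", "_Dstar")


def read_bvals(path) -> np.ndarray:
    """Whitespace-separated b-values (FSL dialect, one line or one column)."""
    text = Path(path).read_text().split()
    if not text:
        raise ValueError(f"empty bval file: {path}")
    return np.array([float(x) for x in text])


def write_bvals(b_values, path) -> Path:
    path = Path(path)
    path.write_text(" ".join(f"{b:g}" for b in np.asarray(b_values)) + "\n")
    return path


def _sim_affine() -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = SIM_VOXEL_MM
    return aff


def read_dwi(path, bval_path, sort: bool = False):
    """Load a 4-D DW volume and its b-values.

    Returns ``(data, scheme, img)`` where ``img`` is the nibabel image
    (affine/header source for writing maps).  Errors if the bval count does
    not match the 4th dimension.  Non-increasing b-values raise unless
    ``sort=True``, which reorders b-values and volumes together.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D DW volume, got shape {data.shape}")
    bvals = read_bvals(bval_path)
    if bvals.size != data.shape[-1]:
        raise ValueError(f"bval count {bvals.size} does not match "
                         f"{data.shape[-1]} volumes in {path}")
    if np.any(np.diff(bvals) <= 0):
        if not sort:
            raise ValueError("b-values are not strictly increasing; pass "
                             "sort=True to reorder volumes and b-values together")
        order = np.argsort(bvals, kind="stable")
        logger.warning("reordering %d volumes into ascending-b order", bvals.size)
        bvals = bvals[order]
        data = data[..., order]
    return data, AcquisitionScheme(tuple(bvals)), img


def write_dwi(data: np.ndarray, b_values, path, bval_path=None,
              affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    affine = _sim_affine() if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    if bval_path is not None:
        write_bvals(b_values, bval_path)
    return path


def write_maps(maps: dict[str, np.ndarray] | tuple, prefix,
               ref_img=None) -> list[Path]:
    """Write (D, f, Dstar) maps as ``<prefix>_D.nii.gz`` etc.

    ``ref_img`` (a nibabel image) supplies the affine/header; NaN background
    is preserved (maps are float32).
    """
    if not isinstance(maps, dict):
        maps = dict(zip(("D", "f", "Dstar"), maps))
    affine = _sim_affine() if ref_img is None else ref_img.affine
    header = None if ref_img is None else ref_img.header.copy()
    Path(str(prefix)).parent.mkdir(parents=True, exist_ok=True)
    out = []
    for name in ("D", "f", "Dstar"):
        arr = np.asarray(maps[name], dtype=np.float32)
        img = nib.Nifti1Image(arr, affine, header=header)
        p = Path(f"{prefix}_{name}.nii.gz")
        nib.save(img, str(p))
        out.append(p)
    return out


def write_phantom(inst, b_values, out_dir, stem: str) -> dict[str, Path]:
    """Write one phantom as a NIfTI bundle + JSON sidecar.

    Files: ``<stem>_dwi.nii.gz`` (noisy 4-D), ``<stem>.bval``, ground-truth
    maps ``<stem>_truth_{D,f,Dstar}.nii.gz``, label map ``<stem>_roi.nii.gz``
    and ``<stem>.json`` (SNR, seed, per-ROI triplets and b0 levels).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nb = inst.noisy.shape[-1]
    paths: dict[str, Path] = {}
    paths["bval"] = out_dir / f"{stem}.bval"
    paths["dwi"] = write_dwi(inst.noisy[:, :, None, :], b_values,
                             out_dir / f"{stem}_dwi.nii.gz", paths["bval"])
    paths["roi"] = out_dir / f"{stem}_roi.nii.gz"
    nib.save(nib.Nifti1Image(inst.roi_labels.astype(np.int16)[:, :, None],
                             _sim_affine()), str(paths["roi"]))
    for name, arr in (("D", inst.truth_D), ("f", inst.truth_f),
                      ("Dstar", inst.truth_Dstar)):
        p = out_dir / f"{stem}_truth_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32)[:, :, None],
                                 _sim_affine()), str(p))
        paths[f"truth_{name}"] = p
    sidecar = {
        "snr": inst.snr,
        "seed": list(inst.seed) if inst.seed is not None else None,
        "n_b": nb,
        "roi_params": {str(k): [v.D, v.f, v.Dstar] for k, v in inst.roi_params.items()},
        "roi_b0": {str(k): v for k, v in inst.roi_b0.items()},
    }
    paths["json"] = out_dir / f"{stem}.json"
    paths["json"].write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return paths


def read_phantom(directory, stem: str):
    """Re-read a phantom bundle written by :func:`write_phantom`.

    Returns a :class:`~ivimdnn.phantom.PhantomInstance` (the noiseless stack
    is not stored on disk and comes back as None) plus the acquisition
    scheme.
    """
    from .phantom import PhantomInstance

    directory = Path(directory)
    dwi, scheme, _ = read_dwi(directory / f"{stem}_dwi.nii.gz",
                              directory / f"{stem}.bval")
    truth = {}
    for name in ("D", "f", "Dstar"):
        img = nib.load(str(directory / f"{stem}_truth_{name}.nii.gz"))
        truth[name] = np.asarray(img.dataobj, dtype=float)[:, :, 0]
    roi = np.asarray(nib.load(str(directory / f"{stem}_roi.nii.gz")).dataobj)[:, :, 0]
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    noisy = dwi[:, :, 0, :]
    b0_map = np.zeros(roi.shape)
    for label, b0 in sidecar["roi_b0"].items():
        b0_map[roi == int(label)] = b0
    inst = PhantomInstance(
        noiseless=None, noisy=noisy, truth_D=truth["D"], truth_f=truth["f"],
        truth_Dstar=truth["Dstar"], b0_map=b0_map,
        noise_sigma=np.where(roi > 0, b0_map, np.median(b0_map[roi > 0])) / sidecar["snr"],
        roi_labels=roi.astype(np.int16), snr=float(sidecar["snr"]),
        seed=tuple(sidecar["seed"]) if sidecar["seed"] else None,
        roi_b0={int(k): v for k, v in sidecar["roi_b0"].items()},
    )
    return inst, scheme


def list_phantom_stems(directory) -> list[str]:
    """Stems of every phantom bundle in a directory, sorted."""
    return sorted(p.name[:-len("_dwi.nii.gz")]
                  for p in Path(directory).glob("*_dwi.nii.gz"))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Section):
    snr_levels: list[float] = [10, 15, 20, 25, 50, 75, 100]
    phantoms_per_snr: int = 2000
    shape: list[int] = [64, 64]
    b_values: list[float] = [0, 25, 50, 75, 100, 150, 300, 800, 1000]
    b0_range: list[float] = [0.5, 1.5]


class FeatureSection(_Section):
    log_features: bool = True
    normalize_to_b0: bool = True
    log_floor: float = 1e-6


class NetworkSection(_Section):
    hidden_layers: int = 3
    hidden_width: int = 32
    standardize_targets: bool = True


class TrainingSection(_Section):
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    lr_decrease: float = 0.1
    lr_increase: float = 10.0
    max_iterations: int = 5000
    min_gradient: float = 1e-7
    validation_patience: int = 6
    validation_fraction: float = 0.2
    batch_size: int = 2048
    max_voxels: int | None = None


class FitSection(_Section):
    mode: str = "full_biexp"
    b_threshold: float = 300.0


class MetricsSection(_Section):
    snr_aggregate: str = "median"
    fr_threshold: float = 0.5


class RunConfig(_Section):
    """Schema-validated nested run configuration; unknown keys rejected."""

    grid: GridSection = GridSection()
    features: FeatureSection = FeatureSection()
    network: NetworkSection = NetworkSection()
    training: TrainingSection = TrainingSection()
    fit: FitSection = FitSection()
    metrics: MetricsSection = MetricsSection()
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)

    def write_resolved(self, out_dir) -> Path:
        """Persist the fully resolved config next to a run's outputs."""
        p = Path(out_dir) / "resolved_config.yaml"
        p.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return p
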