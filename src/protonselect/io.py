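"""Volume, table and configuration I/O.

Volumes travel as NIfTI with the voxel spacing encoded in the affine
diagonal (array axes map directly to affine axes, so a ``(z, y, x)`` grid
round-trips unchanged). Phantoms are written as one intensity volume, one
unsigned-integer label volume whose bits flag ROI membership (masks may
overlap: a PTV contains its CTV), and a JSON sidecar with the ROI bit
table, spacing, anticoagulant flag and prescription assignment. Pipeline
configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .decision import DecisionThresholds
from .dosimetry import FractionationParams
from .engine import BeamConfig, DoseMap, EngineSettings
from .ntcp import LKBParams, LogisticNTCPParams
from .phantoms import CohortSpec, Phantom
from .predictor import PredictorConfig

__all__ = [
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "write_dose",
    "read_dose",
    "save_phantom",
    "load_phantom",
    "PipelineConfig",
]


class VolumeFormatError(ValueError):
    """A volume file could not be read."""


def write_volume(grid: np.ndarray, spacing, path) -> None:
    """Write a 3-D grid as NIfTI; spacing (per array axis, mm) goes into
    the affine diagonal."""
    affine = np.diag([float(spacing[0]), float(spacing[1]), float(spacing[2]), 1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (grid, spacing). Inverse of
    :func:`write_volume` to float32 precision."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    if grid.ndim != 3:
        raise VolumeFormatError(f"expected a 3-D volume in {path}, got shape {grid.shape}")
    return grid, spacing


def write_dose(dose: DoseMap, path) -> None:
    write_volume(dose.grid, dose.spacing, path)


def read_dose(path, modality: str = "unknown") -> DoseMap:
    grid, spacing = read_volume(path)
    return DoseMap(grid=np.asarray(grid, dtype=float), spacing=spacing,
                   modality=modality, provenance="file")


def save_phantom(phantom: Phantom, directory) -> None:
    """Write intensity + bit-packed label volume + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.intensity, phantom.spacing, directory / "intensity.nii.gz")
    rois = sorted(phantom.masks)
    if len(rois) > 32:
        raise ValueError("more ROIs than label bits")
    labels = np.zeros(phantom.shape, dtype=np.uint32)
    for bit, roi in enumerate(rois):
        labels |= phantom.masks[roi].astype(np.uint32) << bit
    img = nib.Nifti1Image(labels, np.diag([*phantom.spacing, 1.0]))
    nib.save(img, str(directory / "labels.nii.gz"))
    sidecar = {
        "patient_id": phantom.patient_id,
        "spacing_mm": list(phantom.spacing),
        "roi_bits": {roi: bit for bit, roi in enumerate(rois)},
        "anticoagulant_use": int(phantom.anticoagulant_use),
        "dual_gradient": bool(phantom.dual_gradient),
        "ptv2_dose_cgy": phantom.ptv2_dose,
    }
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(directory) -> Phantom:
    directory = Path(directory)
    sidecar = json.loads((directory / "phantom.json").read_text())
    intensity, spacing = read_volume(directory / "intensity.nii.gz")
    labels = np.asarray(nib.load(str(directory / "labels.nii.gz")).dataobj).astype(np.uint32)
    masks = {roi: (labels >> bit) & 1 for roi, bit in sidecar["roi_bits"].items()}
    phantom = Phantom(
        intensity=intensity,
        masks={roi: m.astype(bool) for roi, m in masks.items()},
        spacing=tuple(sidecar["spacing_mm"]),
        patient_id=sidecar["patient_id"],
        anticoagulant_use=int(sidecar["anticoagulant_use"]),
        dual_gradient=bool(sidecar["dual_gradient"]),
        ptv2_dose=sidecar["ptv2_dose_cgy"],
    )
    phantom.validate()
    return phantom


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    engine: EngineSettings = field(default_factory=EngineSettings)
    photon_beams: BeamConfig = field(default_factory=BeamConfig.photon)
    proton_beams: BeamConfig = field(default_factory=BeamConfig.proton)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    predictor_enabled: bool = True
    cv_folds: int = 5
    fractionation: FractionationParams = field(default_factory=FractionationParams)
    logistic_params: LogisticNTCPParams = field(default_factory=LogisticNTCPParams)
    lkb_params: LKBParams = field(default_factory=LKBParams)
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)
    output_dir: str = "protonselect_out"
    seed: int = 0
    write_volumes: bool = False
    cache: bool = True

    def to_yaml(self, path=None) -> str:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        payload = {f.name: convert(getattr(self, f.name))
                   for f in dataclasses.fields(self)}
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)

        def build(tp, payload):
            if payload is None:
                return None
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in payload:
                    continue
                v = payload[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return tp(**kwargs)

        return cls(
            cohort=build(CohortSpec, data.get("cohort", {})),
            engine=build(EngineSettings, data.get("engine", {})),
            photon_beams=build(BeamConfig, data.get("photon_beams", {"modality": "photon"})),
            proton_beams=build(BeamConfig, data.get("proton_beams", {"modality": "proton"})),
            predictor=build(PredictorConfig, data.get("predictor", {})),
            predictor_enabled=bool(data.get("predictor_enabled", True)),
            cv_folds=int(data.get("cv_folds", 5)),
            fractionation=build(FractionationParams, data.get("fractionation", {})),
            logistic_params=build(LogisticNTCPParams, data.get("logistic_params", {})),
            lkb_params=build(LKBParams, data.get("lkb_params", {})),
            thresholds=build(DecisionThresholds, data.get("thresholds", {})),
            output_dir=str(data.get("output_dir", "protonselect_out")),
            seed=int(data.get("seed", 0)),
            write_volumes=bool(data.get("write_volumes", False)),
            cache=bool(data.get("cache", True)),
        )
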