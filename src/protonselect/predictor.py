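"""Learned image-to-dose regression (encoder–decoder, slice-wise).

The model maps a three-channel axial slice — normalised CT, an integer-coded
structure map, and a DPTV map (the prescription dose painted into the
planning-target masks, normalised by the PTV1 level) — to the corresponding
dose slice. The encoder is a 7×7 convolutional stem with 2×2 max-pooling
followed by four stages of residual bottleneck blocks (1×1, 3×3, 1×1
convolutions); two of the stages halve resolution so the deepest feature map
sits at 1/8 of the input resolution. The decoder restores full resolution
with three fractionally-strided deconvolutions and a final 1×1 convolution,
with interpolation as a last step whenever internal padding leaves a shape
mismatch. One model is trained per treatment modality; the full-depth
configuration uses (3, 4, 23, 5) bottleneck blocks per stage, while tests
and the desk-scale pipeline use a narrow variant of the same architecture.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import nn
from .engine import DoseMap, Prescription
from .phantoms import Phantom

__all__ = [
    "PredictorConfig",
    "TrainingCase",
    "DosePredictionNet",
    "make_input_channels",
    "build_model",
    "train_model",
    "predict_dose",
    "crossvalidate",
    "save_model",
    "load_model",
]

#: Fixed ROI coding order of the structure-map channel (later entries
#: overwrite earlier ones where masks overlap, so the most specific
#: structure wins).
STRUCTURE_ORDER = ("body", "intestine", "colon", "femur_R", "femur_L",
                   "bladder", "rectum", "rectum_wall", "PTV2", "CTV2",
                   "PTV1", "CTV1")


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training hyperparameters.

    ``block_counts`` gives the number of bottleneck blocks in each of the
    four encoder stages; (3, 4, 23, 5) is the full-depth configuration.
    ``downscale_factor`` is fixed at 8: the deepest stage runs at 1/8 of the
    input resolution before upsampling.
    """

    block_counts: tuple[int, int, int, int] = (1, 1, 2, 1)
    base_filters: int = 8
    input_channels: int = 3
    downscale_factor: int = 8
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-2
    #: cosine-decay floor as a fraction of the initial rate (1.0 = constant)
    lr_decay_floor: float = 0.05
    seed: int = 0
    loss: str = "mse"
    #: crop this many voxels off each in-plane edge for training/prediction
    #: (0 = full slices); the periphery of a pelvic slice carries no target
    #: and little dose, so a central window concentrates compute on it
    train_crop_margin: int = 8
    #: width of the 3x3 bottleneck convolution = stage_channels // divisor;
    #: 4 is the canonical deep-residual ratio, 2 gives narrow desk-scale
    #: variants more spatial capacity
    bottleneck_mid_divisor: int = 2

    def __post_init__(self) -> None:
        if len(self.block_counts) != 4 or any(b < 1 for b in self.block_counts):
            raise ValueError("block_counts must be 4 positive integers")
        if self.downscale_factor != 8:
            raise ValueError("downscale_factor is fixed at 8")
        if self.input_channels != 3:
            raise ValueError("the model takes exactly 3 input channels")
        if self.loss != "mse":
            raise ValueError(f"unknown loss {self.loss!r}")

    @classmethod
    def paper_scale(cls, **kw) -> "PredictorConfig":
        """Full-depth configuration: (3, 4, 23, 5) blocks, 64 base filters,
        canonical bottleneck width ratio."""
        kw.setdefault("bottleneck_mid_divisor", 4)
        return cls(block_counts=(3, 4, 23, 5), base_filters=64, **kw)


@dataclass
class TrainingCase:
    """One axial slice: 3-channel input stack and a normalised dose target."""

    input_stack: np.ndarray   # (3, H, W)
    target: np.ndarray        # (H, W), dose / ptv1_dose
    case_id: str
    slice_index: int


def _crop_window(shape_hw: tuple[int, int], margin: int) -> tuple[slice, slice]:
    if margin <= 0:
        return slice(None), slice(None)
    h, w = shape_hw
    if 2 * margin >= min(h, w):
        raise ValueError(f"crop margin {margin} too large for in-plane shape {shape_hw}")
    return slice(margin, h - margin), slice(margin, w - margin)


def make_input_channels(phantom: Phantom, prescription: Prescription,
                        dose: DoseMap | None = None,
                        slice_selection: str = "body",
                        crop_margin: int = 0,
                        slice_margin: int = 3) -> list[TrainingCase]:
    """Build per-slice three-channel training inputs for one phantom.

    The CT channel is min-max normalised to [0, 1]; the structure channel
    codes each ROI as a distinct level scaled to [0, 1]; the DPTV channel
    carries prescription/ptv1_dose inside each PTV (1.0 in PTV1, e.g. 0.667
    in a 4500-in-6750 PTV2) and 0 elsewhere. ``slice_selection`` picks the
    axial slices: every slice intersecting the body (default) or only those
    intersecting a target ("target").
    """
    if "PTV1" not in phantom.masks:
        raise ValueError("phantom lacks the PTV1 mask")
    ct = phantom.intensity.astype(float)
    lo, hi = ct.min(), ct.max()
    ct_norm = (ct - lo) / (hi - lo) if hi > lo else np.zeros_like(ct)

    present = [r for r in STRUCTURE_ORDER if r in phantom.masks]
    struct = np.zeros(phantom.shape, dtype=float)
    for level, roi in enumerate(present, start=1):
        struct[phantom.masks[roi]] = level / len(present)

    dptv = np.zeros(phantom.shape, dtype=float)
    if prescription.ptv2_dose is not None and "PTV2" in phantom.masks:
        dptv[phantom.masks["PTV2"]] = prescription.ptv2_dose / prescription.ptv1_dose
    dptv[phantom.masks["PTV1"]] = 1.0

    if slice_selection == "target":
        sel = phantom.masks["PTV1"].copy()
        if "PTV2" in phantom.masks:
            sel |= phantom.masks["PTV2"]
        has = np.array([sel[z].any() for z in range(phantom.shape[0])])
        # include the dose transition zone just beyond the target ends
        for _ in range(max(slice_margin, 0)):
            has[1:] |= has[:-1].copy()
            has[:-1] |= has[1:].copy()
        slice_ids = [z for z in range(phantom.shape[0]) if has[z]]
    else:
        sel = phantom.masks.get("body", np.ones(phantom.shape, dtype=bool))
        slice_ids = [z for z in range(phantom.shape[0]) if sel[z].any()]

    target_vol = None
    if dose is not None:
        target_vol = np.asarray(dose.grid, dtype=float) / prescription.ptv1_dose

    sy, sx = _crop_window(phantom.shape[1:], crop_margin)
    cases = []
    for z in slice_ids:
        stack = np.stack([ct_norm[z][sy, sx], struct[z][sy, sx], dptv[z][sy, sx]])
        tgt = target_vol[z][sy, sx] if target_vol is not None \
            else np.zeros_like(stack[0])
        cases.append(TrainingCase(input_stack=stack.astype(np.float32),
                                  target=tgt.astype(np.float32),
                                  case_id=phantom.patient_id, slice_index=z))
    return cases


class DosePredictionNet:
    """Encoder–decoder dose-regression network (see module docstring)."""

    def __init__(self, config: PredictorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        F = config.base_filters
        b1, b2, b3, b4 = config.block_counts

        self.stem = nn.Conv2D(rng, config.input_channels, F, 7, stride=1)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2()

        div = config.bottleneck_mid_divisor

        def stage(c_in, c_out, n_blocks, stride):
            mid = max(c_out // div, 4)
            blocks = [nn.Bottleneck(rng, c_in, c_out, stride=stride, mid=mid)]
            blocks += [nn.Bottleneck(rng, c_out, c_out, mid=mid)
                       for _ in range(n_blocks - 1)]
            return blocks

        self.stages = (stage(F, F, b1, 1)
                       + stage(F, 2 * F, b2, 2)
                       + stage(2 * F, 4 * F, b3, 2)
                       + stage(4 * F, 4 * F, b4, 1))

        self.decoder = [
            nn.ConvTranspose2D(rng, 4 * F, 2 * F), nn.ReLU(),
            nn.ConvTranspose2D(rng, 2 * F, F), nn.ReLU(),
            nn.ConvTranspose2D(rng, F, F), nn.ReLU(),
        ]
        self.head = nn.Conv2D(rng, F, 1, 1)
        self.trained_input_hw: tuple[int, int] | None = None
        self.modality: str | None = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.stem.params()
        for b in self.stages:
            ps += b.params()
        for layer in self.decoder:
            ps += layer.params()
        ps += self.head.params()
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _pad_to8(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        h, w = x.shape[2:]
        ph = (-h) % 8
        pw = (-w) % 8
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) -> (N, 1, H, W); pads internally to multiples of 8."""
        xp, (h, w) = self._pad_to8(x)
        y = self.pool.forward(self.stem_relu.forward(self.stem.forward(xp)))
        for b in self.stages:
            y = b.forward(y)
        for layer in self.decoder:
            y = layer.forward(y)
        y = self.head.forward(y)
        self._pad_hw = (h, w)
        if y.shape[2:] != xp.shape[2:]:  # defensive: interpolate to input grid
            zoom = (1, 1, xp.shape[2] / y.shape[2], xp.shape[3] / y.shape[3])
            y = ndimage.zoom(y, zoom, order=1)
        return y[:, :, :h, :w]

    def backward(self, dy: np.ndarray) -> None:
        h, w = self._pad_hw
        ph = (-h) % 8
        pw = (-w) % 8
        if ph or pw:
            dy = np.pad(dy, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = self.head.backward(dy)
        for layer in reversed(self.decoder):
            d = layer.backward(d)
        for b in reversed(self.stages):
            d = b.backward(d)
        d = self.pool.backward(d)
        d = self.stem_relu.backward(d)
        self.stem.backward(d)


def build_model(config: PredictorConfig) -> DosePredictionNet:
    """Construct the network with seeded initial weights."""
    return DosePredictionNet(config)


def train_model(cases: list[TrainingCase], config: PredictorConfig,
                model: DosePredictionNet | None = None,
                ) -> tuple[DosePredictionNet, list[float]]:
    """Train with Adam on mean-squared error of normalised dose.

    Returns the trained model and the per-epoch mean training loss. Fully
    deterministic for a fixed config seed.
    """
    if len(cases) < 2:
        raise ValueError("training requires at least 2 cases")
    model = model if model is not None else build_model(config)
    model.trained_input_hw = cases[0].input_stack.shape[1:]
    x = np.stack([c.input_stack for c in cases]).astype(np.float32)
    t = np.stack([c.target for c in cases])[:, None].astype(np.float32)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(cases)
    history = []
    lr0 = config.learning_rate
    lr_min = config.lr_decay_floor * lr0
    for epoch in range(config.epochs):
        if config.epochs > 1:
            cos = 0.5 * (1.0 + np.cos(np.pi * epoch / (config.epochs - 1)))
            opt.lr = lr_min + (lr0 - lr_min) * cos
        order = rng.permutation(n)
        sq_sum = 0.0
        n_elem = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb = x[idx], t[idx]
            pred = model.forward(xb)
            err = pred - tb
            sq_sum += float(np.sum(err.astype(np.float64) ** 2))
            n_elem += err.size
            opt.zero_grad()
            model.backward(2.0 * err / err.size)
            opt.step()
        history.append(sq_sum / n_elem)
    return model, history


def predict_dose(model: DosePredictionNet, phantom: Phantom,
                 prescription: Prescription) -> DoseMap:
    """Predict the full 3-D dose map (cGy) for a phantom, slice by slice.

    When the model was trained on a central crop window, prediction runs on
    the same window and the periphery (outside the window) is left at zero.
    """
    margin = model.config.train_crop_margin
    sy, sx = _crop_window(phantom.shape[1:], margin)
    hw = (phantom.shape[1] - 2 * max(margin, 0), phantom.shape[2] - 2 * max(margin, 0)) \
        if margin > 0 else phantom.shape[1:]
    if model.trained_input_hw is not None and tuple(model.trained_input_hw) != tuple(hw):
        raise ValueError(f"phantom in-plane shape {phantom.shape[1:]} (window {hw}) does "
                         f"not match the training resolution {tuple(model.trained_input_hw)}")
    cases = make_input_channels(phantom, prescription, slice_selection="body",
                                crop_margin=margin)
    grid = np.zeros(phantom.shape, dtype=float)
    batch = np.stack([c.input_stack for c in cases]).astype(np.float32)
    out = model.forward(batch)[:, 0]
    for c, sl in zip(cases, out):
        grid[c.slice_index][sy, sx] = sl
    grid = np.clip(grid * prescription.ptv1_dose, 0.0, None)
    return DoseMap(grid=grid, spacing=phantom.spacing,
                   modality=model.modality or "unknown", provenance="predicted")


def kfold_partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random split of range(n) into k near-equal disjoint folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def crossvalidate(cohort: list[Phantom], gt_doses: list[DoseMap],
                  prescriptions: list[Prescription],
                  config: PredictorConfig, k: int = 5,
                  rois: tuple[str, ...] = ("PTV1", "rectum_wall", "rectum", "bladder"),
                  slice_selection: str = "target",
                  include_baseline: bool = True,
                  return_predictions: bool = False):
    """k-fold cross-validation of the dose predictor against engine doses.

    Each case appears in exactly one test fold. Reports the per-fold and
    pooled prescription-normalised MAE per ROI; with ``include_baseline``
    the MAE of predicting the training-set voxelwise mean dose is reported
    alongside, as a trivial reference any learned model must beat.
    Returns a pandas DataFrame (one row per fold × ROI, fold -1 = pooled).
    """
    import pandas as pd
    from .dosimetry import mae as _mae

    n = len(cohort)
    if not (n == len(gt_doses) == len(prescriptions)):
        raise ValueError("cohort, gt_doses and prescriptions must align")
    folds = kfold_partition(n, k, config.seed)

    per_case: dict[str, dict[int, float]] = {r: {} for r in rois}
    per_case_base: dict[str, dict[int, float]] = {r: {} for r in rois}
    fold_of = {}
    predictions: dict[int, DoseMap] = {}
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train_cases = []
        for i in train_idx:
            train_cases += make_input_channels(cohort[i], prescriptions[i],
                                               dose=gt_doses[i],
                                               slice_selection=slice_selection,
                                               crop_margin=config.train_crop_margin)
        model, _ = train_model(train_cases, config)
        mean_grid = np.mean([gt_doses[i].grid for i in train_idx], axis=0)
        for i in test_idx:
            fold_of[i] = fold_id
            pred = predict_dose(model, cohort[i], prescriptions[i])
            predictions[i] = pred
            presc = prescriptions[i].ptv1_dose
            for roi in rois:
                if roi not in cohort[i].masks:
                    continue
                mask = cohort[i].masks[roi]
                per_case[roi][i] = _mae(pred, gt_doses[i], mask, presc)
                if include_baseline:
                    per_case_base[roi][i] = _mae(mean_grid, gt_doses[i], mask, presc)

    rows = []
    for roi in rois:
        for fold_id in range(k):
            ids = [i for i in per_case[roi] if fold_of[i] == fold_id]
            if not ids:
                continue
            row = {"fold": fold_id, "roi": roi,
                   "mae": float(np.mean([per_case[roi][i] for i in ids])),
                   "n_cases": len(ids)}
            if include_baseline:
                row["mae_baseline"] = float(np.mean([per_case_base[roi][i] for i in ids]))
            rows.append(row)
        ids = sorted(per_case[roi])
        if ids:
            row = {"fold": -1, "roi": roi,
                   "mae": float(np.mean([per_case[roi][i] for i in ids])),
                   "n_cases": len(ids)}
            if include_baseline:
                row["mae_baseline"] = float(np.mean([per_case_base[roi][i] for i in ids]))
            rows.append(row)
    df = pd.DataFrame(rows)
    if return_predictions:
        return df, predictions
    return df


def save_model(model: DosePredictionNet, path) -> None:
    """Single-file checkpoint: config, weights, training metadata."""
    state = {
        "config": asdict(model.config),
        "weights": [p.value for p in model.params()],
        "trained_input_hw": model.trained_input_hw,
        "modality": model.modality,
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_model(path) -> DosePredictionNet:
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    cfg = state["config"]
    cfg["block_counts"] = tuple(cfg["block_counts"])
    model = DosePredictionNet(PredictorConfig(**cfg))
    for p, w in zip(model.params(), state["weights"]):
        p.value[...] = w
    model.trained_input_hw = tuple(state["trained_input_hw"]) \
        if state["trained_input_hw"] else None
    model.modality = state["modality"]
    return model
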