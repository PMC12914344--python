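"""Normal-tissue complication probability models.

Two model families are provided:

* a logistic model whose linear predictor is

      S = -3.07 + 0.79 * anticoagulant_use + 0.12 * rectum-wall V6300cGy [%]

  with NTCP = 1 / (1 + exp(-S)) — the operative model for rectal bleeding
  after prostate radiotherapy (coefficients from the Pedersen et al.
  rectum-wall model);
* the Lyman–Kutcher–Burman (LKB) probit model NTCP = Phi(u) with
  u = (EUD - TD50) / (m * TD50), fed by the generalised equivalent uniform
  dose gEUD_a = (mean(D^a))^(1/a).

ΔNTCP = 100 * (NTCP_photon - NTCP_proton) in percentage points is the
patient-selection statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "LogisticNTCPParams",
    "LKBParams",
    "NTCPRecord",
    "logistic_s",
    "logistic_ntcp",
    "lkb_ntcp",
    "generalized_eud",
    "delta_ntcp",
]


@dataclass(frozen=True)
class LogisticNTCPParams:
    """Coefficients of the logistic rectal-bleeding model (per-% V6300 slope)."""

    intercept: float = -3.07
    coef_anticoagulant: float = 0.79
    coef_v6300: float = 0.12

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_anticoagulant", "coef_v6300"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class LKBParams:
    """LKB parameters: TD50 (Gy), slope m, and gEUD volume exponent a.

    The defaults are literature-style placeholder values for late rectal
    toxicity; the logistic model above is the operative selector.
    """

    td50: float = 76.9
    m: float = 0.13
    a: float = 8.33

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValueError("TD50 must be > 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")


@dataclass
class NTCPRecord:
    """Per-case, per-modality complication summary."""

    case_id: str
    modality: str
    v6300_percent: float
    anticoagulant: int
    s: float
    ntcp: float  # probability in [0, 1]


def logistic_s(v6300: float, anticoagulant: int,
               params: LogisticNTCPParams = LogisticNTCPParams()) -> float:
    """Linear predictor S of the logistic rectal-bleeding model."""
    v = np.asarray(v6300, dtype=float)
    if np.any(v < 0) or np.any(v > 100):
        raise ValueError(f"V6300 must lie in [0, 100] percent, got {v6300}")
    if np.any(~np.isin(np.asarray(anticoagulant), (0, 1))):
        raise ValueError("anticoagulant flag must be 0 or 1")
    s = params.intercept + params.coef_anticoagulant * np.asarray(anticoagulant) \
        + params.coef_v6300 * v
    return float(s) if s.ndim == 0 else s


def logistic_ntcp(s, as_printed: bool = False):
    """Logistic NTCP = 1 / (1 + e^(-S)).

    ``as_printed=True`` evaluates 1 / (1 - e^(-S)) instead, an audit-only
    variant that is not a probability (it leaves [0, 1]); the default is the
    standard logistic.
    """
    s = np.asarray(s, dtype=float)
    if as_printed:
        out = 1.0 / (1.0 - np.exp(-s))
    else:
        out = 1.0 / (1.0 + np.exp(-s))
    return float(out) if out.ndim == 0 else out


def generalized_eud(dose, mask, a: float) -> float:
    """gEUD in Gy: (mean over ROI voxels of D^a)^(1/a), dose map in cGy."""
    if a == 0:
        raise ValueError("a must be nonzero (use an explicit geometric mean for a -> 0)")
    grid = np.asarray(getattr(dose, "grid", dose), dtype=float) / 100.0  # Gy
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("ROI mask is empty")
    vals = grid[m]
    return float(np.mean(vals ** a) ** (1.0 / a))


def lkb_ntcp(eud: float, params: LKBParams = LKBParams()) -> float:
    """LKB NTCP: standard normal CDF of u = (EUD - TD50) / (m * TD50)."""
    u = (np.asarray(eud, dtype=float) - params.td50) / (params.m * params.td50)
    out = ndtr(u)
    return float(out) if out.ndim == 0 else out


def delta_ntcp(ntcp_photon: float, ntcp_proton: float) -> float:
    """Photon-minus-proton NTCP difference in percentage points."""
    for name, p in (("ntcp_photon", ntcp_photon), ("ntcp_proton", ntcp_proton)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
    return 100.0 * (ntcp_photon - ntcp_proton)
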