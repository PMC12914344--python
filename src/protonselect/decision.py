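"""Two-step proton/photon modality selection.

Step 1 evaluates the photon NTCP: if it does not exceed the step-1 threshold
(10% by default) photon therapy is selected outright and the proton plan is
never evaluated. Otherwise step 2 computes the proton NTCP and the
difference ΔNTCP = NTCP_photon - NTCP_proton (percentage points): photon is
kept when ΔNTCP does not exceed the step-2 threshold (10 points by default),
proton is chosen when it does.

Both comparators are strict "exceeds" tests by default and can be flipped to
inclusive ones for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

__all__ = ["DecisionThresholds", "DecisionRecord", "decide"]


@dataclass(frozen=True)
class DecisionThresholds:
    """Thresholds in percent (step 1) and percentage points (step 2)."""

    step1_ntcp_threshold: float = 10.0
    step2_delta_threshold: float = 10.0
    step1_strict: bool = True   # proceed to step 2 only if NTCP_ph > threshold
    step2_strict: bool = True   # choose proton only if delta > threshold

    def __post_init__(self) -> None:
        if self.step1_ntcp_threshold < 0 or self.step2_delta_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class DecisionRecord:
    """Outcome of the two-step rule for one case."""

    case_id: str
    ntcp_photon: float                # percent
    ntcp_proton: float | None         # percent; None when step 1 decided
    delta_ntcp: float | None          # percentage points; None when step 1 decided
    modality: str                     # "photon" | "proton"
    deciding_step: int                # 1 | 2


def decide(ntcp_photon: float,
           ntcp_proton_provider: Callable[[], float],
           thresholds: DecisionThresholds = DecisionThresholds(),
           case_id: str = "") -> DecisionRecord:
    """Apply the two-step rule; the proton NTCP is computed lazily.

    ``ntcp_photon`` and the provider's return value are percentages in
    [0, 100]. The provider is only invoked when step 1 does not already
    select photon therapy, mirroring a workflow in which the proton plan is
    only produced for candidate patients.
    """
    if not 0.0 <= ntcp_photon <= 100.0:
        raise ValueError(f"photon NTCP must lie in [0, 100] percent, got {ntcp_photon}")

    t1 = thresholds.step1_ntcp_threshold
    proceed = ntcp_photon > t1 if thresholds.step1_strict else ntcp_photon >= t1
    if not proceed:
        return DecisionRecord(case_id=case_id, ntcp_photon=ntcp_photon,
                              ntcp_proton=None, delta_ntcp=None,
                              modality="photon", deciding_step=1)

    try:
        ntcp_proton = float(ntcp_proton_provider())
    except Exception as exc:  # annotate with case context, then re-raise
        raise RuntimeError(f"proton NTCP evaluation failed for case {case_id!r}") from exc
    if not 0.0 <= ntcp_proton <= 100.0:
        raise ValueError(f"proton NTCP must lie in [0, 100] percent, got {ntcp_proton}")

    delta = ntcp_photon - ntcp_proton
    t2 = thresholds.step2_delta_threshold
    proton = delta > t2 if thresholds.step2_strict else delta >= t2
    return DecisionRecord(case_id=case_id, ntcp_photon=ntcp_photon,
                          ntcp_proton=ntcp_proton, delta_ntcp=delta,
                          modality="proton" if proton else "photon",
                          deciding_step=2)
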