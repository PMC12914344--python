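"""From dose maps to the two-step proton/photon decision.

Computes the rectum-wall V6300cGy on the fractionation-corrected (EQD2)
dose, evaluates the logistic complication model
S = -3.07 + 0.79·anticoagulant + 0.12·V6300, NTCP = 1/(1+e^-S), and applies
the two-step rule: photon NTCP <= 10% selects photon outright; otherwise
proton therapy is chosen when the NTCP reduction ΔNTCP exceeds 10 points.
"""

from protonselect import (BeamConfig, CaseParams, FractionationParams,
                          Prescription, decide, generate_phantom, logistic_ntcp,
                          logistic_s, plan_dose, v6300_rectum_wall)

phantom = generate_phantom(CaseParams(patient_id="demo", anticoagulant_use=0),
                           seed=21)
prescription = Prescription.for_phantom(phantom)
frac = FractionationParams(n_fractions=prescription.n_fractions)

ntcp = {}
for beams in (BeamConfig.photon(), BeamConfig.proton()):
    dose = plan_dose(phantom, prescription, beams, seed=3)
    v63 = v6300_rectum_wall(dose, phantom, frac)
    s = logistic_s(v63, phantom.anticoagulant_use)
    ntcp[beams.modality] = 100.0 * logistic_ntcp(s)
    print(f"{beams.modality}: V6300(EQD2, rectum wall) = {v63:.1f}%  "
          f"S = {s:+.2f}  NTCP = {ntcp[beams.modality]:.1f}%")

record = decide(ntcp["photon"], lambda: ntcp["proton"],
                case_id=phantom.patient_id)
print(f"\ndecision: {record.modality} (step {record.deciding_step})")
if record.deciding_step == 1:
    print("photon NTCP did not exceed 10%, so the proton plan was never needed")
else:
    print(f"ΔNTCP = {record.delta_ntcp:.1f} points "
          f"({'>' if record.modality == 'proton' else '<='} 10-point threshold)")
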