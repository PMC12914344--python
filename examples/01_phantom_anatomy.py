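"""Generate one synthetic pelvic phantom and inspect its anatomy.

Builds the default phantom (prostate + seminal-vesicle CTV, rectum with a
3 mm wall shell, bladder, femoral heads), expands the CTV to the PTV with
the clinical margins (1.0 cm everywhere except 0.5 cm posterior) and prints
structure volumes and the PTV–rectum overlap that places the dose gradient
across the anterior rectum wall.
"""

import numpy as np

from protonselect import CaseParams, generate_phantom

phantom = generate_phantom(CaseParams(patient_id="demo"), seed=1)

print(f"grid {phantom.shape} at {phantom.spacing} mm, "
      f"anticoagulant use = {phantom.anticoagulant_use}")
print(f"{'ROI':12s} {'voxels':>8s} {'volume [cc]':>12s}")
for roi, mask in sorted(phantom.masks.items()):
    print(f"{roi:12s} {mask.sum():8d} {mask.sum() * phantom.voxel_volume_cc:12.1f}")

overlap = np.sum(phantom.masks["PTV1"] & phantom.masks["rectum"])
print(f"\nPTV1 ∩ rectum: {overlap} voxels "
      f"({overlap * phantom.voxel_volume_cc:.1f} cc) — the 0.5 cm posterior "
      "margin reaches into the anterior rectum wall, so the treatment dose "
      "gradient crosses the wall exactly where the complication model looks.")
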