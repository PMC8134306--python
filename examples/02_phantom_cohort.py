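"""Generate a small phantom cohort and inspect its bending statistics.

Each case owns a labeled head volume (T1-like intensity + cortex/white/
deep-grey tissue codes) and electrodes that deviate from their bolt axis
mainly where they cross tissue interfaces.
"""

import numpy as np

from seegbend import generate_dataset, compute_labels, trajectory_mse

cohort = generate_dataset(n_cases=3, electrodes_per_case=6, seed=7)

print(f"{len(cohort)} cases, {cohort.n_electrodes()} electrodes")
for case, electrode in cohort.iter_electrodes():
    labels = compute_labels(electrode.implanted, electrode.rigid)
    gu_target = np.linalg.norm(labels.gu[-1])
    baseline = trajectory_mse(electrode.rigid, electrode.implanted)
    print(f"{case.case_id}/{electrode.electrode_id} group={electrode.group:4} "
          f"depth={len(electrode.implanted)-1:2d} mm  "
          f"|gu| at target={gu_target:5.2f} mm  rigid-vs-implanted "
          f"MSE={baseline:5.2f} mm^2")

# |gu| at the target is how far the electrode tip ended from its straight
# bolt line; the rigid-vs-implanted MSE is the error a no-bending
# predictor would incur — the baseline any useful model must beat.
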