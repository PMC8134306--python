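"""Train a small image-based bending model and roll out a trajectory.

A reduced version of the full experiment: a few phantom cases, one
E2E model (electrode direction + 9x9x9 tissue window -> local
displacement), trained briefly, then used to iteratively extend an
unseen electrode 1 mm at a time from its 5-point rigid seed.
"""

from seegbend import generate_dataset
from seegbend.experiment import build_point_dataset, make_splits
from seegbend.inference import infer_trajectory
from seegbend.models import TrainConfig, TrainedModel, build_e2e_model, train_model

cohort = generate_dataset(n_cases=6, electrodes_per_case=4, seed=3)
split = make_splits(cohort.case_ids, seed=3, n_folds=2, holdout_frac=0.2)

train = build_point_dataset(cohort, split.train_case_ids(0), "e2e",
                            source="tissue", label_kind="lu")
val = build_point_dataset(cohort, split.val_case_ids(0), "e2e",
                          source="tissue", label_kind="lu")
print(f"training on {len(train['y'])} interior points "
      f"from {len(split.train_case_ids(0))} cases")

net = build_e2e_model(seed=3)
net, history = train_model(net, train, val,
                           TrainConfig(epochs=15, label_kind="lu", seed=3))
print(f"best validation MSE: {history.attrs['best_val_loss']:.2e} mm^2")

model = TrainedModel(net=net, label_kind="lu", family="e2e", source="tissue")
case = next(c for c in cohort.cases if c.case_id in split.holdout_case_ids)
electrode = case.electrodes[0]
result = infer_trajectory(model, electrode, case.volume)
from seegbend import trajectory_mse
baseline = trajectory_mse(electrode.rigid, electrode.implanted)
print(f"hold-out electrode {case.case_id}/{electrode.electrode_id}: "
      f"rollout MSE_i = {result.mse_i:.3f} mm^2 "
      f"(rigid baseline {baseline:.3f} mm^2)")

# MSE_i below the baseline means the model predicted bending in the right
# direction; MSE_i <= 1 mm^2 is the conventional reporting threshold.
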