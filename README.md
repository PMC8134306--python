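# seegbend

Patient-specific prediction of SEEG depth-electrode bending.

In stereo-electroencephalography (SEEG), depth electrodes are implanted
through skull-mounted bolts along planned straight trajectories, but the
implanted electrode bends as it interacts with brain tissue. Planning and
quality-assessment tools that assume straight ("rigid") trajectories
therefore mislocate contacts by millimetres. `seegbend` predicts, point by
point at 1 mm steps, where an electrode inserted along a given bolt axis
will actually travel through a 3D brain image, with Monte-Carlo-dropout
uncertainty, and evaluates predictions with a stratified hold-out +
k-fold protocol. A phantom generator supplies labeled brain volumes and
bent electrodes so the whole pipeline is trainable and testable without
patient data.

## The model

An electrode is an ordered point sequence **x**₀ … **x**_{I−1} at 1 mm
spacing (entry to target). At an interior point, with travel direction

&nbsp;&nbsp; **v̂**ᵢ = (**x**ᵢ − **x**ᵢ₋₁) / |**x**ᵢ − **x**ᵢ₋₁|,

bending is described by either the **local displacement**
**lu** = **x**ᵢ₊₁ − (**x**ᵢ + 1·**v̂**ᵢ) — the mm offset of the next point
from a 1 mm straight-ahead projection — or the **bending direction**
**êb** = (**x**ᵢ₊₁ − **x**ᵢ)/|**x**ᵢ₊₁ − **x**ᵢ|, a unit vector. For 1 mm
spacing the two are equivalent: **v̂** + **lu** = **êb**. The per-point
offset from the index-matched rigid trajectory is the global displacement
**gu**.

Two regression networks map per-point inputs to a 3-dof label:

* **HcF** — 96 handcrafted features (implantation geometry, bending
  history, tissue structure, collision proximity, plus 18 one-hot
  categorical dims) through a dense-5/PReLU/dropout stack;
* **E2E** — the electrode direction **v̂** and a one-channel 9×9×9 image
  window (T1-like intensity or cortex/white/deep tissue codes) through a
  3×3×3 conv + max-pool branch and two dense blocks (32, 8 units) with
  leaky ReLU, batch norm and dropout.

Training minimizes the MSE loss with Adam (lr 10⁻³, weight decay 10⁻³),
200 epochs, validation every 5 epochs, learning rate reduced tenfold on a
training-loss plateau. Inference *rolls out* a trajectory: starting from
the first five rigid points, the model regresses the label at the tip
(optionally averaging T = 200 dropout-active forward passes, p = 0.1, for
an epistemic mean and variance), the tip advances 1 mm, and the loop
repeats to the target depth. Rollouts are scored by MSE_i, the mean
squared point-to-point distance (mm²) to the implanted ground truth, with
MSE_i ≤ 1 as the conventional reporting threshold; cross-validated label
errors are reported as MSE_t.

## Worked example

`python examples/01_bending_labels.py` computes the labels of a one-step
bend:

```
travel direction v : [0. 0. 1.]
local displacement lu (mm): [ 0.   0.6 -0.2]
bending direction eb: [0.  0.6 0.8] | norm 1.0
identity |v + lu - eb| = 0.0
```

The electrode was heading along +z; the next point sits 0.6 mm laterally
and 0.2 mm short of the straight-ahead projection, and the unit bending
direction (0, 0.6, 0.8) reproduces **v̂** + **lu** exactly.

`python examples/03_train_and_rollout.py` trains a small E2E-tissue model
on a phantom cohort and rolls out an unseen electrode:

```
best validation MSE: 2.40e-05 mm^2
hold-out electrode case002/E00: rollout MSE_i = 0.048 mm^2 (rigid baseline 0.134 mm^2)
```

MSE_i below the rigid baseline means the model bent the trajectory toward
the truth. See `examples/02_phantom_cohort.py` (cohort statistics) and
`examples/04_mc_uncertainty.py` (MC-dropout variance and its 1/√T
stabilisation).

## Command line

The same pipeline is scriptable via the `seegbend` CLI:

```bash
seegbend simulate --seed 1 --out runs/data           # phantom cohort
seegbend train    --data runs/data --label lu --model e2e --image tissue \
                  --seed 1 --out runs/ckpt           # per-fold models
seegbend infer    --data runs/data --checkpoint runs/ckpt/fold00.npz \
                  --case case000 --electrode E00 --out runs/pred.json
seegbend evaluate --data runs/data --checkpoints runs/ckpt --out runs/msei.csv
seegbend report   --metrics runs/ckpt/mse_t.csv
```

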