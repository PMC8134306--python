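"""Iterative trajectory rollout.

Inference starts from the first 5 points (5 mm) of the rigid trajectory
and repeatedly: computes the current direction from the last two points,
builds the model input at the tip (96 handcrafted features, or direction
plus a one-channel 9x9x9 image window centred on the tip's nearest
voxel), regresses the bending label — averaging T stochastic passes in
MC-dropout mode — and advances the tip 1 mm, until the requested number
of points is reached.  Handcrafted features are recomputed from the
*predicted* history, so prediction errors feed back into the inputs, as
they would in deployment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Trajectory, advance_point, trajectory_mse, unit
from .models import MCConfig, TrainedModel, predict
from .phantom import ElectrodeCase, LabeledVolume
from . import features as feat

logger = logging.getLogger(__name__)

__all__ = ["RolloutResult", "init_rollout", "infer_trajectory", "extract_window",
           "SEED_POINTS"]

SEED_POINTS = 5


@dataclass
class RolloutResult:
    """A predicted trajectory with its per-point uncertainty and score."""

    predicted: Trajectory
    mse_i: float
    n_points: int
    per_point_variance: list = field(default_factory=list)
    out_of_volume_events: int = 0

    def __post_init__(self):
        if self.mse_i < 0:
            raise ValueError("mse_i must be nonnegative")


def init_rollout(rigid: Trajectory) -> np.ndarray:
    """The 5-point (5 mm) seed: the first five rigid-trajectory points."""
    if len(rigid) < SEED_POINTS:
        raise ValueError(
            f"rigid trajectory has {len(rigid)} points; "
            f"need at least {SEED_POINTS} for the rollout seed"
        )
    return rigid.points[:SEED_POINTS].copy()


def extract_window(volume: LabeledVolume, point, size: int = 9,
                   source: str = "intensity") -> np.ndarray:
    """``size^3`` image window centred on the voxel nearest a world point.

    Out-of-volume entries are zero.  ``source='tissue'`` returns the
    integer tissue codes scaled to [0, 1] by a fixed /3 (preserving their
    categorical meaning across windows); ``source='intensity'`` returns
    the T1-like values unchanged.
    """
    if size % 2 != 1:
        raise ValueError("window size must be odd")
    if source == "intensity":
        grid = volume.intensity
        scale = 1.0
    elif source == "tissue":
        grid = volume.tissue
        scale = 1.0 / 3.0
    else:
        raise ValueError("source must be 'intensity' or 'tissue'")
    center = np.rint(volume.world_to_voxel(np.asarray(point, float))).astype(int)
    half = size // 2
    out = np.zeros((size, size, size))
    lo = center - half
    hi = center + half + 1
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, np.asarray(volume.shape))
    if np.all(src_lo < src_hi):
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = (
            np.asarray(
                grid[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))],
                dtype=float,
            )
            * scale
        )
    return out


def _model_inputs(model: TrainedModel, history: np.ndarray,
                  case: ElectrodeCase, volume: LabeledVolume,
                  n_points: int, v_hat: np.ndarray) -> dict:
    tip = history[-1]
    if model.family == "e2e":
        window = extract_window(volume, tip, source=model.source)
        return {"direction": v_hat[None], "window": window[None]}
    meta = {"stylet": case.stylet, "entry_lobe": case.entry_lobe,
            "target_region": case.target_region}
    fv = feat.point_features_from_history(
        history,
        rigid_entry=case.rigid.points[0],
        bolt_direction=case.bolt_direction,
        n_total=n_points,
        meta=meta,
        volume=volume,
    )
    x = fv.values
    if model.normalizer is not None:
        x = model.normalizer.transform(x)
    return {"features": x[None]}


def infer_trajectory(
    model: TrainedModel,
    case: ElectrodeCase,
    volume: LabeledVolume,
    n_points: int | None = None,
    mode: str = "direct",
    mc_cfg: MCConfig | None = None,
) -> RolloutResult:
    """Roll out a predicted trajectory and score it against the implant.

    ``n_points`` defaults to the implanted trajectory's point count so
    MSE_i is index-matched.  If the tip leaves the volume the window is
    zero-padded (and features see background), the rollout continues,
    and the event is counted and logged.
    """
    if n_points is None:
        n_points = len(case.implanted)
    if n_points < SEED_POINTS + 1:
        raise ValueError(f"n_points must be at least {SEED_POINTS + 1}")
    pts = list(init_rollout(case.rigid))
    variances = []
    oov = 0
    bounds_lo = volume.voxel_to_world(np.zeros(3))
    bounds_hi = volume.voxel_to_world(np.asarray(volume.shape) - 1)

    while len(pts) < n_points:
        history = np.asarray(pts)
        v_hat = unit(history[-1] - history[-2])
        inputs = _model_inputs(model, history, case, volume, n_points, v_hat)
        pred = predict(model.net, inputs, mode=mode, mc_cfg=mc_cfg)
        label = np.asarray(pred.mean, dtype=float).reshape(3)
        if pred.variance is not None:
            variances.append(np.asarray(pred.variance, dtype=float).reshape(3))
        nxt = advance_point(history[-1], v_hat, label,
                            label_kind=model.label_kind)
        if np.any(nxt < bounds_lo) or np.any(nxt > bounds_hi):
            oov += 1
            logger.info(
                "%s/%s: predicted tip left the volume at point %d",
                case.case_id, case.electrode_id, len(pts),
            )
        pts.append(nxt)

    predicted = Trajectory(np.asarray(pts), kind="predicted")
    truth = case.implanted
    if len(truth) > n_points:
        truth = Trajectory(truth.points[:n_points], kind="implanted")
    mse = trajectory_mse(predicted, truth)
    return RolloutResult(predicted=predicted, mse_i=mse, n_points=n_points,
                         per_point_variance=variances,
                         out_of_volume_events=oov)
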