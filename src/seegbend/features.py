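"""Handcrafted per-point features for the HcF regression model.

Each interpolated point of an electrode is described by 96 features: 78
continuous features in four categories — *implantation* (where the point
sits relative to entry, bolt axis and target), *bending* (trailing
history of local/global displacement and step angles), *structure*
(tissue context of the local image neighbourhood and along the travel
direction), *collision* (proximity to the brain and volume boundaries) —
followed by 18 one-hot dimensions for the categorical metadata (stylet
use 3, tissue region at the point 3, entry lobe 5, target region 7).

The roster is a versioned stand-in (schema ``v1``) with the documented
category structure and the exact total of 96; it is frozen in
``FEATURE_SCHEMA`` so an alternative roster can be swapped in without
touching the model code.  Features use only the trajectory history up to
the current point (never the regression target ``x_{i+1}``), so the same
code serves training-label generation and predicted-history rollout;
trailing-history entries at early indices are zero-padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import unit
from .phantom import (
    BACKGROUND, CORTEX, DEEP, WHITE,
    ENTRY_LOBES, STYLET_LEVELS, TARGET_REGIONS, ElectrodeCase, LabeledVolume,
)

__all__ = [
    "FeatureVector", "FeatureNormalizer", "FEATURE_SCHEMA",
    "SCHEMA_VERSION", "N_CONTINUOUS", "N_CATEGORICAL", "N_FEATURES",
    "encode_categoricals", "compute_point_features",
    "point_features_from_history", "fit_normalizer", "write_feature_schema",
]

SCHEMA_VERSION = "v1"
N_CONTINUOUS = 78
N_CATEGORICAL = 18
N_FEATURES = N_CONTINUOUS + N_CATEGORICAL

POINT_REGIONS = ("cortex", "white", "deep")
_HIST = 5          # trailing-history window, points
_RAY_CAP = 20.0    # mm, ray-march cap


def _continuous_schema():
    s = []

    def add(name, category, units="mm"):
        s.append({"index": len(s), "name": name, "category": category,
                  "units": units})

    # implantation
    add("depth_from_entry", "implantation")
    add("remaining_depth", "implantation")
    add("frac_along", "implantation", "1")
    add("cos_v_bolt", "implantation", "1")
    add("angle_v_bolt", "implantation", "deg")
    for ax in "123":
        add(f"v_in_bolt_frame_e{ax}", "implantation", "1")
    add("axial_position_along_bolt", "implantation")
    add("lateral_offset_from_bolt", "implantation")
    add("dist_to_rigid_target", "implantation")
    add("dist_from_entry", "implantation")
    # bending
    for k in range(1, _HIST + 1):
        add(f"lu_mag_hist_{k}", "bending")
    for k in range(1, _HIST + 1):
        add(f"gu_mag_hist_{k}", "bending")
    for k in range(1, _HIST + 1):
        add(f"step_angle_hist_{k}", "bending", "deg")
    add("cum_curvature", "bending", "deg")
    add("mean_lu_mag", "bending")
    add("max_lu_mag", "bending")
    add("gu_mag_current", "bending")
    add("gu_mag_rate", "bending", "mm/step")
    # structure
    add("dist_interface_ahead", "structure")
    add("dist_interface_behind", "structure")
    for tis in ("bg", "cortex", "white", "deep"):
        add(f"occ3_{tis}", "structure", "1")
    for tis in ("bg", "cortex", "white", "deep"):
        add(f"occ5_{tis}", "structure", "1")
    add("int3_mean", "structure", "1")
    add("int3_sd", "structure", "1")
    add("int5_mean", "structure", "1")
    add("int5_sd", "structure", "1")
    add("int_at_point", "structure", "1")
    add("int_grad_mag", "structure", "1/mm")
    for tis in ("bg", "cortex", "white", "deep"):
        add(f"dist_ahead_to_{tis}", "structure")
    for tis in ("bg", "cortex", "white", "deep"):
        add(f"frac_ahead5_{tis}", "structure", "1")
    add("int5_min", "structure", "1")
    add("int5_max", "structure", "1")
    add("tissue_code_ahead2", "structure", "1")
    add("tissue_code_behind2", "structure", "1")
    add("boundary_within2_ahead", "structure", "1")
    add("boundary_within2_behind", "structure", "1")
    add("tissue3_mean_code", "structure", "1")
    add("tissue3_n_distinct", "structure", "count")
    add("int_ahead5_mean", "structure", "1")
    add("int_behind5_mean", "structure", "1")
    # collision
    add("dist_brain_boundary_ahead", "collision")
    add("dist_brain_boundary_behind", "collision")
    add("dist_volume_edge_ahead", "collision")
    add("dist_brain_radial", "collision")
    add("cos_v_normal", "collision", "1")
    add("angle_v_normal", "collision", "deg")
    add("min_bg_dist_axes", "collision")
    add("steps_since_interface", "collision", "steps")
    add("remaining_in_brain_along_bolt", "collision")
    add("entry_incidence_cos", "collision", "1")
    add("exit_margin_ahead", "collision")
    add("outside_brain_flag", "collision", "1")
    return s


def _categorical_schema():
    s = []
    idx = N_CONTINUOUS
    for block, levels in (
        ("stylet", STYLET_LEVELS),
        ("region", POINT_REGIONS),
        ("entry_lobe", ENTRY_LOBES),
        ("target_region", TARGET_REGIONS),
    ):
        for lvl in levels:
            s.append({"index": idx, "name": f"{block}={lvl}",
                      "category": "categorical", "units": "onehot"})
            idx += 1
    return s


FEATURE_SCHEMA = _continuous_schema() + _categorical_schema()
assert len(FEATURE_SCHEMA) == N_FEATURES
FEATURE_NAMES = [f["name"] for f in FEATURE_SCHEMA]

CATEGORICAL_BLOCKS = {
    "stylet": STYLET_LEVELS,
    "region": POINT_REGIONS,
    "entry_lobe": ENTRY_LOBES,
    "target_region": TARGET_REGIONS,
}


@dataclass
class FeatureVector:
    """96 ordered scalars plus their schema identity."""

    values: np.ndarray
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != N_FEATURES:
            raise ValueError(
                f"feature vector must have {N_FEATURES} entries, "
                f"got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    @property
    def names(self):
        return FEATURE_NAMES

    def __len__(self):
        return len(self.values)


def encode_categoricals(case_meta: dict) -> np.ndarray:
    """18-dim one-hot block for (stylet, region-at-point, entry lobe, target).

    ``case_meta`` needs keys ``stylet``, ``region``, ``entry_lobe``,
    ``target_region``; an unknown level raises with the valid levels listed.
    """
    parts = []
    for block, levels in CATEGORICAL_BLOCKS.items():
        value = case_meta[block]
        if value not in levels:
            raise ValueError(
                f"unknown {block} value {value!r}; valid levels: {levels}"
            )
        onehot = np.zeros(len(levels))
        onehot[levels.index(value)] = 1.0
        parts.append(onehot)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# geometry / image probes


def _march(volume, x, direction, stop, cap=_RAY_CAP):
    """Distance (1 mm nearest-voxel steps) until ``stop(code)``; cap if never."""
    t = 1.0
    while t <= cap:
        if stop(volume.tissue_at(x + t * direction)):
            return t
        t += 1.0
    return cap


def _neighborhood(volume, x, radius):
    """Tissue codes and intensities of the (2r+1)^3 cube, clipped at bounds."""
    ijk = np.rint(volume.world_to_voxel(x)).astype(int)
    lo = np.maximum(ijk - radius, 0)
    hi = np.minimum(ijk + radius + 1, np.asarray(volume.shape))
    if np.any(lo >= hi):
        return np.array([BACKGROUND]), np.array([0.0])
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume.tissue[sl].ravel(), volume.intensity[sl].ravel().astype(float)


def _dist_to_box_edge(x, direction, volume):
    """Analytic distance along ``direction`` to the volume bounding box."""
    lo = volume.voxel_to_world(np.zeros(3))
    hi = volume.voxel_to_world(np.asarray(volume.shape) - 1)
    tmax = 50.0
    for d in range(3):
        if abs(direction[d]) > 1e-9:
            for bound in (lo[d], hi[d]):
                t = (bound - x[d]) / direction[d]
                if t > 1e-9:
                    tmax = min(tmax, t)
    return tmax


def _bolt_frame(b_hat):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(b_hat, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = unit(ref - np.dot(ref, b_hat) * b_hat)
    e3 = np.cross(b_hat, e2)
    return b_hat, e2, e3


def point_features_from_history(
    history: np.ndarray,
    rigid_entry: np.ndarray,
    bolt_direction: np.ndarray,
    n_total: int,
    meta: dict,
    volume: LabeledVolume,
    spacing: float = 1.0,
) -> FeatureVector:
    """Feature vector at the last point of ``history``.

    ``history`` is the (i+1, 3) array of trajectory points up to and
    including the current index ``i`` — ground-truth points during
    training-set construction, predicted points during rollout.  The
    rigid reference is reconstructed analytically from the entry and
    bolt direction, so the history may be longer than any stored rigid
    trajectory.
    """
    hist = np.atleast_2d(np.asarray(history, dtype=float))
    i = len(hist) - 1
    x = hist[-1]
    b_hat = unit(bolt_direction)
    entry = np.asarray(rigid_entry, dtype=float)
    e1, e2, e3 = _bolt_frame(b_hat)
    v_hat = unit(hist[-1] - hist[-2]) if i >= 1 else b_hat.copy()

    # trailing histories (zero-padded)
    dirs = np.zeros((i + 1, 3))
    for j in range(1, i + 1):
        dirs[j] = unit(hist[j] - hist[j - 1])
    lu_mags, gu_mags, angles = [], [], []
    for j in range(1, i):
        lu_j = hist[j + 1] - (hist[j] + spacing * dirs[j])
        lu_mags.append(np.linalg.norm(lu_j))
    for j in range(0, i + 1):
        gu_mags.append(np.linalg.norm(hist[j] - (entry + j * spacing * b_hat)))
    for j in range(2, i + 1):
        c = np.clip(np.dot(dirs[j], dirs[j - 1]), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(c)))

    def tail(seq, k=_HIST):
        out = list(seq[-k:])
        return [0.0] * (k - len(out)) + out

    f = {}
    # implantation
    f["depth_from_entry"] = i * spacing
    f["remaining_depth"] = (n_total - 1 - i) * spacing
    f["frac_along"] = i / max(n_total - 1, 1)
    cosvb = float(np.clip(np.dot(v_hat, b_hat), -1.0, 1.0))
    f["cos_v_bolt"] = cosvb
    f["angle_v_bolt"] = float(np.degrees(np.arccos(cosvb)))
    f["v_in_bolt_frame_e1"] = float(np.dot(v_hat, e1))
    f["v_in_bolt_frame_e2"] = float(np.dot(v_hat, e2))
    f["v_in_bolt_frame_e3"] = float(np.dot(v_hat, e3))
    rel = x - entry
    axial = float(np.dot(rel, e1))
    f["axial_position_along_bolt"] = axial
    f["lateral_offset_from_bolt"] = float(np.linalg.norm(rel - axial * e1))
    rigid_target = entry + (n_total - 1) * spacing * b_hat
    f["dist_to_rigid_target"] = float(np.linalg.norm(x - rigid_target))
    f["dist_from_entry"] = float(np.linalg.norm(rel))
    # bending
    for k, v in enumerate(reversed(tail(lu_mags)), start=1):
        f[f"lu_mag_hist_{k}"] = v
    for k, v in enumerate(reversed(tail(gu_mags)), start=1):
        f[f"gu_mag_hist_{k}"] = v
    for k, v in enumerate(reversed(tail(angles)), start=1):
        f[f"step_angle_hist_{k}"] = v
    f["cum_curvature"] = float(np.sum(angles)) if angles else 0.0
    f["mean_lu_mag"] = float(np.mean(lu_mags)) if lu_mags else 0.0
    f["max_lu_mag"] = float(np.max(lu_mags)) if lu_mags else 0.0
    f["gu_mag_current"] = gu_mags[-1]
    f["gu_mag_rate"] = (gu_mags[-1] - gu_mags[-2]) if i >= 1 else 0.0
    # structure
    code_here = volume.tissue_at(x)
    f["dist_interface_ahead"] = _march(volume, x, v_hat,
                                       lambda c: c != code_here)
    f["dist_interface_behind"] = _march(volume, x, -v_hat,
                                        lambda c: c != code_here)
    codes3, int3 = _neighborhood(volume, x, 1)
    codes5, int5 = _neighborhood(volume, x, 2)
    for tis, code in (("bg", BACKGROUND), ("cortex", CORTEX),
                      ("white", WHITE), ("deep", DEEP)):
        f[f"occ3_{tis}"] = float(np.mean(codes3 == code))
        f[f"occ5_{tis}"] = float(np.mean(codes5 == code))
    f["int3_mean"] = float(int3.mean())
    f["int3_sd"] = float(int3.std())
    f["int5_mean"] = float(int5.mean())
    f["int5_sd"] = float(int5.std())
    f["int_at_point"] = volume.intensity_at(x)
    g = np.array([
        volume.intensity_at(x + ax) - volume.intensity_at(x - ax)
        for ax in np.eye(3)
    ]) / 2.0
    f["int_grad_mag"] = float(np.linalg.norm(g))
    for tis, code in (("bg", BACKGROUND), ("cortex", CORTEX),
                      ("white", WHITE), ("deep", DEEP)):
        if code_here == code:
            f[f"dist_ahead_to_{tis}"] = 0.0
        else:
            f[f"dist_ahead_to_{tis}"] = _march(volume, x, v_hat,
                                               lambda c, cc=code: c == cc)
    ahead_codes = [volume.tissue_at(x + t * v_hat) for t in range(1, 6)]
    for tis, code in (("bg", BACKGROUND), ("cortex", CORTEX),
                      ("white", WHITE), ("deep", DEEP)):
        f[f"frac_ahead5_{tis}"] = float(np.mean([c == code for c in ahead_codes]))
    f["int5_min"] = float(int5.min())
    f["int5_max"] = float(int5.max())
    f["tissue_code_ahead2"] = volume.tissue_at(x + 2 * v_hat) / 3.0
    f["tissue_code_behind2"] = volume.tissue_at(x - 2 * v_hat) / 3.0
    f["boundary_within2_ahead"] = float(f["dist_interface_ahead"] <= 2.0)
    f["boundary_within2_behind"] = float(f["dist_interface_behind"] <= 2.0)
    f["tissue3_mean_code"] = float(codes3.mean() / 3.0)
    f["tissue3_n_distinct"] = float(len(np.unique(codes3)))
    f["int_ahead5_mean"] = float(np.mean(
        [volume.intensity_at(x + t * v_hat) for t in range(1, 6)]))
    f["int_behind5_mean"] = float(np.mean(
        [volume.intensity_at(x - t * v_hat) for t in range(1, 6)]))
    # collision
    f["dist_brain_boundary_ahead"] = _march(volume, x, v_hat,
                                            lambda c: c == BACKGROUND)
    f["dist_brain_boundary_behind"] = _march(volume, x, -v_hat,
                                             lambda c: c == BACKGROUND)
    f["dist_volume_edge_ahead"] = float(_dist_to_box_edge(x, v_hat, volume))
    center = volume.center_world
    radial = x - center
    rn = np.linalg.norm(radial)
    radial = radial / rn if rn > 1e-9 else e1
    f["dist_brain_radial"] = _march(volume, x, radial, lambda c: c == BACKGROUND)
    n_hat = volume.interface_normal(x)
    cosvn = float(abs(np.dot(v_hat, n_hat))) if np.linalg.norm(n_hat) > 0 else 0.0
    f["cos_v_normal"] = cosvn
    f["angle_v_normal"] = float(np.degrees(np.arccos(np.clip(cosvn, -1, 1))))
    f["min_bg_dist_axes"] = min(
        _march(volume, x, ax * sgn, lambda c: c == BACKGROUND)
        for ax in np.eye(3) for sgn in (1.0, -1.0)
    )
    hist_codes = [volume.tissue_at(p) for p in hist[-int(_RAY_CAP):]]
    steps_since = 0.0
    for a, b in zip(reversed(hist_codes[:-1]), reversed(hist_codes[1:])):
        if a != b:
            break
        steps_since += 1.0
    f["steps_since_interface"] = min(steps_since, _RAY_CAP)
    f["remaining_in_brain_along_bolt"] = _march(volume, x, b_hat,
                                                lambda c: c == BACKGROUND)
    n_entry = volume.interface_normal(entry)
    f["entry_incidence_cos"] = (
        float(abs(np.dot(b_hat, n_entry)))
        if np.linalg.norm(n_entry) > 0 else 0.0
    )
    f["exit_margin_ahead"] = (
        f["dist_brain_boundary_ahead"] - f["remaining_depth"]
    )
    f["outside_brain_flag"] = float(code_here == BACKGROUND)

    cont = np.array([f[s["name"]] for s in FEATURE_SCHEMA[:N_CONTINUOUS]])
    region = {CORTEX: "cortex", WHITE: "white", DEEP: "deep"}.get(
        code_here, "cortex"
    )
    cat = encode_categoricals({
        "stylet": meta.get("stylet", "no-information"),
        "region": region,
        "entry_lobe": meta.get("entry_lobe", "frontal"),
        "target_region": meta.get("target_region", "frontal"),
    })
    return FeatureVector(np.concatenate([cont, cat]))


def compute_point_features(case: ElectrodeCase, i: int,
                           volume: LabeledVolume) -> FeatureVector:
    """Features at interior index ``i`` of an electrode's implanted path."""
    n_total = len(case.implanted)
    if not 1 <= i <= n_total - 2:
        raise IndexError(
            f"index {i} outside the label range [1, {n_total - 2}]"
        )
    meta = {"stylet": case.stylet, "entry_lobe": case.entry_lobe,
            "target_region": case.target_region}
    return point_features_from_history(
        case.implanted.points[: i + 1],
        rigid_entry=case.rigid.points[0],
        bolt_direction=case.bolt_direction,
        n_total=n_total,
        meta=meta,
        volume=volume,
        spacing=case.implanted.spacing_mm,
    )


# ---------------------------------------------------------------------------
# normalization


class FeatureNormalizer:
    """Z-score normalizer for the continuous block; one-hot passthrough.

    Fit on the training split only.  Constant features get a guarded
    scale of 1 (their transformed value is exactly 0).
    """

    def __init__(self):
        self.center = None
        self.scale = None

    @property
    def fitted(self) -> bool:
        return self.center is not None

    def fit(self, X: np.ndarray) -> "FeatureNormalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(X) < 2:
            raise ValueError("need at least 2 training points to fit")
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} columns, got {X.shape[1]}")
        center = np.zeros(N_FEATURES)
        scale = np.ones(N_FEATURES)
        mu = X[:, :N_CONTINUOUS].mean(axis=0)
        sd = X[:, :N_CONTINUOUS].std(axis=0)
        center[:N_CONTINUOUS] = mu
        scale[:N_CONTINUOUS] = np.where(sd < 1e-12, 1.0, sd)
        self.center, self.scale = center, scale
        return self

    def transform(self, X) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer has not been fitted")
        if isinstance(X, FeatureVector):
            X = X.values
        X = np.asarray(X, dtype=float)
        return (X - self.center) / self.scale

    def state_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_state_dict(cls, state: dict) -> "FeatureNormalizer":
        norm = cls()
        norm.center = np.asarray(state["center"], dtype=float)
        norm.scale = np.asarray(state["scale"], dtype=float)
        return norm


def fit_normalizer(train_points: np.ndarray) -> FeatureNormalizer:
    """Fit a z-score normalizer on a (N, 96) training feature matrix."""
    return FeatureNormalizer().fit(train_points)


def write_feature_schema(path) -> None:
    """Emit the machine-readable feature schema sidecar (JSON)."""
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION,
                   "features": FEATURE_SCHEMA}, fh, indent=1)
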