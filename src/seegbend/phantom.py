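"""Synthetic phantom brains and bent-electrode simulation.

Stands in for the patient cohort: nested ellipsoidal tissue geometry
(cortex shell, white-matter interior, deep-grey blobs) rendered as a
T1-like intensity volume plus a CWD-style tissue-label volume, and an
electrode insertion model in which the tip advances 1 mm per step,
wanders with a small angular random walk, and is deflected where it
crosses a tissue interface.  The deflection acts in the plane of
incidence (about the axis ``v × n``, with ``n`` the smoothed interface
normal), so bending is predictable from the local image content — the
structure the regression models are meant to exploit — while the drift
term injects unpredictable noise.

The first few millimetres of travel are kept straight: physically the
guide bolt constrains the electrode near the entry, and it makes the
5-point rollout seed exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    AffineTransform,
    Trajectory,
    rigid_trajectory,
    unit,
)

__all__ = [
    "PhantomConfig",
    "BendingModel",
    "LabeledVolume",
    "ElectrodeCase",
    "PhantomCase",
    "CaseSet",
    "generate_phantom",
    "simulate_implantation",
    "generate_dataset",
    "GROUPS",
    "ENTRY_LOBES",
    "TARGET_REGIONS",
    "STYLET_LEVELS",
    "group_from_metadata",
    "sample_electrode_metadata",
]

# Six anatomical strata (entry/target-structure based), five entry lobes,
# seven target regions — the categorical vocabulary of the cohort.
GROUPS = ("sfg", "mfg", "ifog", "tg", "apcg", "po")
ENTRY_LOBES = ("frontal", "central", "temporal", "parietal", "occipital")
TARGET_REGIONS = (
    "frontal", "central", "temporal", "parietal", "occipital", "insula", "cingulum",
)
STYLET_LEVELS = ("yes", "no", "no-information")

BACKGROUND, CORTEX, WHITE, DEEP = 0, 1, 2, 3
TISSUE_NAMES = {BACKGROUND: "background", CORTEX: "cortex", WHITE: "white", DEEP: "deep"}


@dataclass
class PhantomConfig:
    """Geometry and appearance of a synthetic head volume.

    Semi-axes are in voxels of the default 96^3 / 1 mm grid; tissue means
    are T1-like (white matter brightest, grey darker).
    """

    shape: tuple = (96, 96, 96)
    voxel_size: float = 1.0
    cortex_semiaxes: tuple = (42.0, 40.0, 38.0)
    white_semiaxes: tuple = (33.0, 31.0, 29.0)
    n_deep_blobs: int = 3
    deep_radius_range: tuple = (5.0, 9.0)
    tissue_means: tuple = (0.0, 0.45, 0.75, 0.55)  # background, cortex, white, deep
    bias_amplitude: float = 0.05
    noise_sd: float = 0.02


@dataclass
class BendingModel:
    """Stochastic model of electrode deviation from the bolt axis.

    drift_sd_deg : per-step SD of the angular random walk (degrees).
    interface_deflection_mean_deg / _sd_deg : deflection angle applied when
        the tip crosses a tissue boundary, in the plane of incidence.
    seed_steps : leading steps kept perfectly straight (bolt-constrained).
    """

    drift_sd_deg: float = 0.15
    interface_deflection_mean_deg: float = 4.0
    interface_deflection_sd_deg: float = 1.5
    deflection_ramp_steps: int = 4
    seed_steps: int = 5

    def __post_init__(self):
        if self.drift_sd_deg < 0 or self.interface_deflection_sd_deg < 0:
            raise ValueError("angular SDs must be nonnegative")
        if not (0 <= self.interface_deflection_mean_deg < 45):
            raise ValueError("interface deflection mean must be in [0, 45) degrees")
        if self.deflection_ramp_steps < 1:
            raise ValueError("deflection_ramp_steps must be >= 1")


@dataclass
class LabeledVolume:
    """Co-registered T1-like intensity and tissue-label grids.

    intensity in [0, 1]; tissue codes {0 background, 1 cortex, 2 white,
    3 deep grey}; ``affine`` maps voxel indices to world mm.
    """

    intensity: np.ndarray
    tissue: np.ndarray
    affine: AffineTransform
    voxel_size: float = 1.0
    _normals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.intensity.shape != self.tissue.shape:
            raise ValueError("intensity and tissue grids must share a shape")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple:
        return self.intensity.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates for world-mm points."""
        return self.affine.inverse().apply(points)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.affine.apply(np.asarray(ijk, dtype=float))

    def tissue_at(self, point) -> int:
        """Tissue code at the voxel nearest a world point (0 outside the grid)."""
        ijk = np.rint(self.world_to_voxel(np.asarray(point, float))).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(self.shape)):
            return BACKGROUND
        return int(self.tissue[tuple(ijk)])

    def intensity_at(self, point) -> float:
        ijk = np.rint(self.world_to_voxel(np.asarray(point, float))).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(self.shape)):
            return 0.0
        return float(self.intensity[tuple(ijk)])

    def interface_normal(self, point) -> np.ndarray:
        """Unit normal of the nearest tissue interface (zero vector if flat).

        Computed as the gradient of a Gaussian-smoothed copy of the tissue
        code field, cached per volume.
        """
        if self._normals is None:
            smoothed = ndimage.gaussian_filter(self.tissue.astype(float), sigma=2.0)
            self._normals = np.stack(np.gradient(smoothed), axis=-1)
        ijk = np.rint(self.world_to_voxel(np.asarray(point, float))).astype(int)
        ijk = np.clip(ijk, 0, np.asarray(self.shape) - 1)
        g = self._normals[tuple(ijk)]
        n = np.linalg.norm(g)
        if n < 1e-9:
            return np.zeros(3)
        # gradient is in voxel index space; for an axis-aligned isotropic
        # affine this is parallel to the world-space normal
        return g / n

    @property
    def center_world(self) -> np.ndarray:
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)


@dataclass
class ElectrodeCase:
    """One electrode: paired rigid/implanted trajectories plus metadata."""

    case_id: str
    electrode_id: str
    rigid: Trajectory
    implanted: Trajectory
    group: str
    stylet: str = "no-information"
    entry_lobe: str = "frontal"
    target_region: str = "frontal"

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; valid: {GROUPS}")
        if self.stylet not in STYLET_LEVELS:
            raise ValueError(f"unknown stylet level {self.stylet!r}")
        if self.entry_lobe not in ENTRY_LOBES:
            raise ValueError(f"unknown entry lobe {self.entry_lobe!r}")
        if self.target_region not in TARGET_REGIONS:
            raise ValueError(f"unknown target region {self.target_region!r}")

    @property
    def bolt_direction(self) -> np.ndarray:
        return unit(self.rigid.points[1] - self.rigid.points[0])


@dataclass
class PhantomCase:
    case_id: str
    volume: LabeledVolume
    electrodes: list
    seed: int = 0


@dataclass
class CaseSet:
    cases: list
    seed: int = 0

    def __len__(self) -> int:
        return len(self.cases)

    def iter_electrodes(self):
        for case in self.cases:
            for e in case.electrodes:
                yield case, e

    @property
    def case_ids(self) -> list:
        return [c.case_id for c in self.cases]

    def volume_for(self, case_id: str) -> LabeledVolume:
        for c in self.cases:
            if c.case_id == case_id:
                return c.volume
        raise KeyError(case_id)

    def n_electrodes(self) -> int:
        return sum(len(c.electrodes) for c in self.cases)


# ---------------------------------------------------------------------------
# volume synthesis


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _smooth_bias(shape, amplitude, rng) -> np.ndarray:
    """Multiplicative low-frequency bias field in [1-a, 1+a]."""
    coarse = rng.standard_normal((4, 4, 4))
    f = ndimage.zoom(coarse, [s / 4 for s in shape], order=3)
    f = f[: shape[0], : shape[1], : shape[2]]
    span = np.abs(f).max()
    if span < 1e-12:
        return np.ones(shape)
    return 1.0 + amplitude * f / span


def generate_phantom(
    shape=(96, 96, 96),
    voxel_size: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> LabeledVolume:
    """Build a labeled phantom head: nested ellipsoids + bias + noise.

    Deterministic per seed.  Intensity = per-tissue mean x smooth
    multiplicative bias + Gaussian noise, clipped to [0, 1].
    """
    if config is None:
        config = PhantomConfig(shape=tuple(shape), voxel_size=voxel_size,
                               noise_sd=noise_sd)
    shape = tuple(int(s) for s in config.shape)
    if min(shape) < 32:
        raise ValueError("phantom shape must be at least 32 voxels per axis")
    if config.voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    rng = np.random.default_rng(seed)
    center = (np.asarray(shape) - 1) / 2.0

    tissue = np.zeros(shape, dtype=np.int8)
    tissue[_ellipsoid_mask(shape, center, config.cortex_semiaxes)] = CORTEX
    white_mask = _ellipsoid_mask(shape, center, config.white_semiaxes)
    tissue[white_mask] = WHITE

    n_blobs = int(rng.integers(max(2, config.n_deep_blobs - 1),
                               min(4, config.n_deep_blobs + 1) + 1))
    lo, hi = config.deep_radius_range
    for _ in range(n_blobs):
        r = rng.uniform(lo, hi)
        # blob centres inside the white interior, biased toward the middle
        offset = rng.uniform(-0.45, 0.45, size=3) * np.asarray(
            config.white_semiaxes
        )
        blob = _ellipsoid_mask(shape, center + offset, (r, r, r))
        tissue[blob & white_mask] = DEEP

    means = np.asarray(config.tissue_means, dtype=float)
    intensity = means[tissue]
    intensity = intensity * _smooth_bias(shape, config.bias_amplitude, rng)
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=shape)
    intensity = np.clip(intensity, 0.0, 1.0).astype(np.float32)

    aff = np.eye(4)
    aff[:3, :3] *= config.voxel_size
    return LabeledVolume(
        intensity=intensity,
        tissue=tissue,
        affine=AffineTransform(aff),
        voxel_size=config.voxel_size,
    )


# ---------------------------------------------------------------------------
# electrode simulation


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))


def _random_perpendicular(v: np.ndarray, rng) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-9:
            return p / n


def simulate_implantation(
    volume: LabeledVolume,
    entry,
    bolt_direction,
    depth: float,
    model: BendingModel | None = None,
    seed: int = 0,
    case_id: str = "case",
    electrode_id: str = "E00",
    metadata: dict | None = None,
) -> ElectrodeCase:
    """Advance an electrode tip 1 mm per step through a labeled volume.

    Per step the direction receives an angular random-walk perturbation
    (SD ``drift_sd_deg``); when the tissue code under the tip changes, a
    total deflection angle (mean/SD from the model) is sampled and then
    develops as a ramp over ``deflection_ramp_steps`` subsequent steps —
    electrodes bend smoothly over a few millimetres rather than kinking
    instantaneously — about the axis ``v x n`` with ``n`` the local
    interface normal, bending the tip in the plane of incidence.
    ``deflection_ramp_steps=1`` reproduces an instantaneous kink.
    Returns the paired straight (rigid) and bent (implanted)
    trajectories; both are truncated together (with a warning) if the
    tip leaves the volume.
    """
    if model is None:
        model = BendingModel()
    rng = np.random.default_rng(seed)
    entry = np.asarray(entry, dtype=float).reshape(3)
    b_hat = unit(bolt_direction)
    n_steps = int(np.floor(depth + 1e-9))
    if n_steps < 1:
        raise ValueError("depth must be at least 1 mm")

    rigid = rigid_trajectory(entry, b_hat, depth=n_steps, spacing=1.0)

    pts = [entry.copy()]
    direction = b_hat.copy()
    prev_tissue = volume.tissue_at(entry)
    bounds_lo = volume.voxel_to_world(np.zeros(3))
    bounds_hi = volume.voxel_to_world(np.asarray(volume.shape) - 1)
    truncated = False

    # pending deflection: remaining per-step rotations about a fixed axis
    pending_axis = None
    pending_per_step = 0.0
    pending_steps = 0

    for k in range(1, n_steps + 1):
        free = k > model.seed_steps  # bolt constrains the first millimetres
        if free and model.drift_sd_deg > 0:
            axis = _random_perpendicular(direction, rng)
            ang = np.deg2rad(rng.normal(0.0, model.drift_sd_deg))
            direction = unit(_rotate_about(direction, axis, ang))
        if pending_steps > 0:
            direction = unit(
                _rotate_about(direction, pending_axis, pending_per_step)
            )
            pending_steps -= 1
        nxt = pts[-1] + direction
        if np.any(nxt < bounds_lo) or np.any(nxt > bounds_hi):
            truncated = True
            break
        tis = volume.tissue_at(nxt)
        if free and tis != prev_tissue:
            ang = np.deg2rad(
                rng.normal(
                    model.interface_deflection_mean_deg,
                    model.interface_deflection_sd_deg,
                )
            )
            normal = volume.interface_normal(nxt)
            axis = np.cross(direction, normal)
            a_norm = np.linalg.norm(axis)
            if a_norm > 1e-9 and abs(ang) > 1e-12:
                pending_axis = axis / a_norm
                pending_per_step = ang / model.deflection_ramp_steps
                pending_steps = model.deflection_ramp_steps
        prev_tissue = tis
        pts.append(nxt)

    if truncated:
        warnings.warn(
            f"{case_id}/{electrode_id}: trajectory left the volume after "
            f"{len(pts) - 1} of {n_steps} steps; truncating",
            stacklevel=2,
        )
        rigid = Trajectory(rigid.points[: len(pts)], kind="rigid")
    if len(pts) < 3:
        raise ValueError("trajectory truncated below 3 points; move the entry")

    implanted = Trajectory(np.asarray(pts), kind="implanted")
    meta = metadata or {}
    return ElectrodeCase(
        case_id=case_id,
        electrode_id=electrode_id,
        rigid=rigid,
        implanted=implanted,
        group=meta.get("group", "sfg"),
        stylet=meta.get("stylet", "no-information"),
        entry_lobe=meta.get("entry_lobe", "frontal"),
        target_region=meta.get("target_region", "frontal"),
    )


# ---------------------------------------------------------------------------
# cohort metadata


def group_from_metadata(entry_lobe: str, target_region: str) -> str:
    """Deterministic mapping (entry lobe, target region) -> anatomical stratum.

    Temporal entries form ``tg``; parietal/occipital entries form ``po``;
    anterior entries split by target: cingulum -> ``apcg``, insula ->
    ``ifog``, frontal target from a frontal entry -> ``sfg``, everything
    else anterior -> ``mfg``.
    """
    if entry_lobe == "temporal":
        return "tg"
    if entry_lobe in ("parietal", "occipital"):
        return "po"
    # frontal or central entry
    if target_region == "cingulum":
        return "apcg"
    if target_region == "insula":
        return "ifog"
    if entry_lobe == "frontal" and target_region == "frontal":
        return "sfg"
    return "mfg"


# valid (entry_lobe, target_region) pre-images of each group
_GROUP_PREIMAGE = {
    g: [
        (e, t)
        for e in ENTRY_LOBES
        for t in TARGET_REGIONS
        if group_from_metadata(e, t) == g
    ]
    for g in GROUPS
}

# roughly the cohort's per-group electrode imbalance (ifog/apcg smallest,
# tg largest), normalized
DEFAULT_GROUP_PROBS = {
    "sfg": 0.18, "mfg": 0.18, "ifog": 0.11, "tg": 0.28, "apcg": 0.11, "po": 0.14,
}


def sample_electrode_metadata(rng, group_probs: dict | None = None) -> dict:
    """Draw (group, entry lobe, target region, stylet) for one electrode."""
    probs = dict(DEFAULT_GROUP_PROBS if group_probs is None else group_probs)
    groups = list(probs)
    p = np.asarray([probs[g] for g in groups], dtype=float)
    p = p / p.sum()
    group = groups[rng.choice(len(groups), p=p)]
    entry_lobe, target_region = _GROUP_PREIMAGE[group][
        rng.integers(len(_GROUP_PREIMAGE[group]))
    ]
    stylet = STYLET_LEVELS[rng.choice(3, p=[0.45, 0.45, 0.10])]
    return {
        "group": group,
        "entry_lobe": entry_lobe,
        "target_region": target_region,
        "stylet": stylet,
    }


_LOBE_AZIMUTH = {  # degrees, sector centres in the x-y plane
    "frontal": 0.0,
    "central": 72.0,
    "temporal": 144.0,
    "parietal": 216.0,
    "occipital": 288.0,
}


def _sample_entry_and_target(volume, config, meta, rng):
    """Entry point on the cortex shell + inward bolt direction + depth."""
    center = volume.center_world
    az = np.deg2rad(
        _LOBE_AZIMUTH[meta["entry_lobe"]] + rng.uniform(-30.0, 30.0)
    )
    el = np.deg2rad(rng.uniform(15.0, 60.0))  # upper hemisphere
    u = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    semi = np.asarray(config.cortex_semiaxes) * volume.voxel_size
    # point on the ellipsoid surface along direction u from the centre
    scale = 1.0 / np.sqrt(np.sum((u / semi) ** 2))
    entry = center + 0.995 * scale * u

    deep_target = meta["target_region"] in ("insula", "cingulum")
    if deep_target:
        jitter = rng.uniform(-6.0, 6.0, size=3)
        target = center + jitter
    else:
        # mid-depth target below the entry, pulled toward the centre
        frac = rng.uniform(0.35, 0.6)
        target = entry + frac * (center - entry) + rng.uniform(-8.0, 8.0, size=3)

    direction = unit(target - entry)
    depth = float(np.linalg.norm(target - entry))
    depth = float(np.clip(np.round(depth + rng.uniform(0.0, 6.0)), 25, 55))
    return entry, direction, depth


def generate_dataset(
    n_cases: int = 10,
    electrodes_per_case: int = 10,
    phantom_cfg: PhantomConfig | None = None,
    bending_cfg: BendingModel | None = None,
    seed: int = 0,
    group_probs: dict | None = None,
    max_retries: int = 50,
) -> CaseSet:
    """Generate a cohort of phantom cases with bent electrodes.

    Each case owns one phantom volume and ``electrodes_per_case``
    electrodes whose metadata spans the six strata.  Fully reproducible
    per seed: the master seed fans out to per-case and per-electrode
    streams via :class:`numpy.random.SeedSequence`.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    phantom_cfg = phantom_cfg or PhantomConfig()
    bending_cfg = bending_cfg or BendingModel()
    master = np.random.SeedSequence(seed)
    case_seeds = master.generate_state(2 * n_cases) % (2**31)

    cases = []
    for c in range(n_cases):
        case_id = f"case{c:03d}"
        vol_seed = int(case_seeds[2 * c])
        volume = generate_phantom(seed=vol_seed, config=phantom_cfg)
        rng = np.random.default_rng(int(case_seeds[2 * c + 1]))
        electrodes = []
        for e in range(electrodes_per_case):
            meta = sample_electrode_metadata(rng, group_probs)
            ec = None
            for attempt in range(max_retries):
                entry, direction, depth = _sample_entry_and_target(
                    volume, phantom_cfg, meta, rng
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("error")  # reject truncated draws
                        ec = simulate_implantation(
                            volume, entry, direction, depth,
                            model=bending_cfg,
                            seed=int(rng.integers(2**31)),
                            case_id=case_id,
                            electrode_id=f"E{e:02d}",
                            metadata=meta,
                        )
                    break
                except (UserWarning, Warning, ValueError):
                    ec = None
            if ec is None:
                raise RuntimeError(
                    f"could not place electrode {case_id}/E{e:02d} after "
                    f"{max_retries} retries"
                )
            electrodes.append(ec)
        cases.append(PhantomCase(case_id=case_id, volume=volume,
                                 electrodes=electrodes, seed=vol_seed))
    return CaseSet(cases=cases, seed=seed)
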