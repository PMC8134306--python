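"""Shared fixtures: small phantom volumes/cohorts and stub regressors."""

import numpy as np
import pytest

from seegbend import models as md
from seegbend import phantom as ph
from seegbend.geometry import AffineTransform


def small_phantom_config(**kw):
    """48^3 phantom geometry scaled down from the 96^3 default."""
    defaults = dict(
        shape=(48, 48, 48),
        cortex_semiaxes=(20.0, 19.0, 18.0),
        white_semiaxes=(15.0, 14.0, 13.0),
        deep_radius_range=(3.5, 5.5),
        n_deep_blobs=2,
    )
    defaults.update(kw)
    return ph.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def volume48():
    return ph.generate_phantom(seed=7, config=small_phantom_config())


@pytest.fixture(scope="session")
def halfspace_volume():
    """Flat cortex/white interface at z = 24.5 voxels, noise-free."""
    shape = (48, 48, 48)
    tissue = np.ones(shape, dtype=np.int8)
    tissue[:, :, 25:] = 2
    intensity = np.where(tissue == 1, 0.45, 0.75).astype(np.float32)
    return ph.LabeledVolume(
        intensity=intensity, tissue=tissue,
        affine=AffineTransform.identity(), voxel_size=1.0,
    )


@pytest.fixture(scope="session")
def caseset():
    """Six-case phantom cohort covering all six anatomical strata."""
    cs = ph.generate_dataset(
        n_cases=6, electrodes_per_case=5,
        phantom_cfg=small_phantom_config(), seed=13,
    )
    groups = {e.group for _, e in cs.iter_electrodes()}
    assert groups == set(ph.GROUPS), f"fixture misses groups: {groups}"
    return cs


class StubNet(md._Net):
    """Regressor returning a fixed 3-vector (default zero) for any input."""

    family = "hcf"

    def __init__(self, output=(0.0, 0.0, 0.0)):
        self.output = np.asarray(output, dtype=float)

    def _all_layers(self):
        return []

    def params(self):
        return []

    def forward(self, inputs, **kw):
        key = next(iter(inputs))
        n = len(np.atleast_2d(inputs[key]))
        return np.tile(self.output, (n, 1))

    def backward(self, dy):
        pass

    def extra_state(self):
        return {}

    def load_extra_state(self, state):
        pass


class OracleNet(md._Net):
    """Teacher regressor replaying ground-truth labels step by step.

    A rollout queries the model once per extension step, starting at the
    seed tip (interior index 4); the oracle replays the matching
    ground-truth label sequence.
    """

    family = "hcf"

    def __init__(self, labels: np.ndarray, first_index: int = 4):
        self.labels = np.asarray(labels, dtype=float)
        self.cursor = first_index

    def _all_layers(self):
        return []

    def params(self):
        return []

    def forward(self, inputs, **kw):
        out = self.labels[self.cursor]
        self.cursor += 1
        return out[None, :]

    def backward(self, dy):
        pass

    def extra_state(self):
        return {}

    def load_extra_state(self, state):
        pass


@pytest.fixture
def stub_model_factory():
    def make(output=(0.0, 0.0, 0.0), label_kind="lu"):
        return md.TrainedModel(net=StubNet(output), label_kind=label_kind,
                               family="hcf")
    return make


@pytest.fixture
def oracle_model_factory():
    def make(case, label_kind="lu"):
        from seegbend.geometry import compute_labels

        labels = compute_labels(case.implanted, case.rigid)
        arr = labels.lu if label_kind == "lu" else labels.eb_hat
        # label at interior index i lives at array position i-1; the
        # rollout's first query is at tip index 4
        net = OracleNet(arr, first_index=3)
        return md.TrainedModel(net=net, label_kind=label_kind, family="hcf")
    return make
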