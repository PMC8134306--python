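"""Handcrafted feature roster, one-hot encodings and normalization."""

import numpy as np
import pytest

from seegbend import features as ft
from seegbend import phantom as ph
from seegbend.geometry import AffineTransform, rigid_trajectory


def uniform_white_volume(shape=(48, 48, 48)):
    tissue = np.full(shape, ph.WHITE, dtype=np.int8)
    intensity = np.full(shape, 0.75, dtype=np.float32)
    return ph.LabeledVolume(intensity=intensity, tissue=tissue,
                            affine=AffineTransform.identity())


def straight_case(depth=20):
    rigid = rigid_trajectory((24, 24, 10), (0, 0, 1), depth=depth)
    return ph.ElectrodeCase(
        case_id="c", electrode_id="e",
        rigid=rigid, implanted=rigid.replace(kind="implanted"),
        group="sfg", stylet="yes", entry_lobe="frontal",
        target_region="frontal",
    )


class TestEncodeCategoricals:
    def test_exactly_one_hot_per_block(self):
        v = ft.encode_categoricals({
            "stylet": "yes", "region": "white",
            "entry_lobe": "frontal", "target_region": "insula",
        })
        assert v.shape == (18,)
        assert v.sum() == 4
        assert set(np.unique(v)) == {0.0, 1.0}

    def test_no_information_maps_to_third_stylet_slot(self):
        v = ft.encode_categoricals({
            "stylet": "no-information", "region": "cortex",
            "entry_lobe": "frontal", "target_region": "frontal",
        })
        assert v[2] == 1.0 and v[0] == 0.0 and v[1] == 0.0

    def test_unknown_level_lists_valid_values(self):
        with pytest.raises(ValueError, match="valid levels"):
            ft.encode_categoricals({
                "stylet": "maybe", "region": "white",
                "entry_lobe": "frontal", "target_region": "frontal",
            })

    def test_block_sums_one_for_random_draws(self):
        rng = np.random.default_rng(0)
        blocks = list(ft.CATEGORICAL_BLOCKS.items())
        for _ in range(1000):
            meta = {name: levels[rng.integers(len(levels))]
                    for name, levels in blocks}
            v = ft.encode_categoricals(meta)
            start = 0
            for _, levels in blocks:
                assert v[start : start + len(levels)].sum() == 1.0
                start += len(levels)


class TestComputePointFeatures:
    def test_vector_length_and_finiteness(self, caseset):
        case = caseset.cases[0]
        e = case.electrodes[0]
        for i in (1, 5, len(e.implanted) - 2):
            fv = ft.compute_point_features(e, i, case.volume)
            assert len(fv) == 96
            assert np.all(np.isfinite(fv.values))

    def test_schema_is_frozen_at_96(self):
        assert len(ft.FEATURE_SCHEMA) == 96
        cats = {f["category"] for f in ft.FEATURE_SCHEMA}
        assert cats == {"implantation", "bending", "structure", "collision",
                        "categorical"}

    def test_straight_electrode_has_zero_bending_features(self):
        case = straight_case()
        vol = uniform_white_volume()
        names = [f["name"] for f in ft.FEATURE_SCHEMA]
        bending_idx = [i for i, f in enumerate(ft.FEATURE_SCHEMA)
                       if f["category"] == "bending"]
        for i in (1, 8, 18):
            fv = ft.compute_point_features(case, i, vol)
            np.testing.assert_allclose(fv.values[bending_idx], 0.0, atol=1e-9,
                                       err_msg=str([names[j] for j in bending_idx]))

    def test_interface_distance_matches_ray_march_oracle(self):
        # cortex below z=10, white above: point at z=7 sees the boundary
        # 3 mm ahead along +z (nearest-voxel stepping)
        tissue = np.full((48, 48, 48), ph.CORTEX, dtype=np.int8)
        tissue[:, :, 10:] = ph.WHITE
        vol = ph.LabeledVolume(
            intensity=np.full((48, 48, 48), 0.5, dtype=np.float32),
            tissue=tissue, affine=AffineTransform.identity(),
        )
        rigid = rigid_trajectory((24, 24, 2), (0, 0, 1), depth=20)
        case = straight_case()
        case = ph.ElectrodeCase(
            case_id="c", electrode_id="e", rigid=rigid,
            implanted=rigid.replace(kind="implanted"), group="sfg",
        )
        fv = ft.compute_point_features(case, 5, vol)  # point at z = 7
        idx = [f["name"] for f in ft.FEATURE_SCHEMA].index(
            "dist_interface_ahead"
        )
        assert fv.values[idx] == 3.0

    def test_out_of_range_index_rejected(self, caseset):
        case = caseset.cases[0]
        e = case.electrodes[0]
        with pytest.raises(IndexError):
            ft.compute_point_features(e, 0, case.volume)
        with pytest.raises(IndexError):
            ft.compute_point_features(e, len(e.implanted) - 1, case.volume)

    def test_invariant_to_global_translation(self, caseset):
        case = caseset.cases[0]
        e = case.electrodes[0]
        base = ft.compute_point_features(e, 6, case.volume).values
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.uniform(-30, 30, 3)
            shift = AffineTransform.from_translation(t)
            moved_vol = ph.LabeledVolume(
                intensity=case.volume.intensity, tissue=case.volume.tissue,
                affine=shift.compose(case.volume.affine),
            )
            moved = ph.ElectrodeCase(
                case_id="c", electrode_id="e",
                rigid=e.rigid.replace(points=e.rigid.points + t),
                implanted=e.implanted.replace(points=e.implanted.points + t),
                group=e.group, stylet=e.stylet, entry_lobe=e.entry_lobe,
                target_region=e.target_region,
            )
            fv = ft.compute_point_features(moved, 6, moved_vol).values
            np.testing.assert_allclose(fv, base, atol=1e-5)

    def test_no_leakage_of_next_point(self, caseset):
        """Features at i do not depend on x_{i+1} (the regression target)."""
        case = caseset.cases[0]
        e = case.electrodes[0]
        i = 8
        base = ft.compute_point_features(e, i, case.volume).values
        perturbed_points = e.implanted.points.copy()
        perturbed_points[i + 1 :] += 5.0
        perturbed = ph.ElectrodeCase(
            case_id="c", electrode_id="e", rigid=e.rigid,
            implanted=e.implanted.replace(points=perturbed_points),
            group=e.group, stylet=e.stylet, entry_lobe=e.entry_lobe,
            target_region=e.target_region,
        )
        fv = ft.compute_point_features(perturbed, i, case.volume).values
        np.testing.assert_allclose(fv, base, atol=1e-12)


class TestNormalizer:
    def make_matrix(self, rng, n=50):
        X = rng.standard_normal((n, 96))
        X[:, 40] = 7.0  # constant feature
        X[:, ft.N_CONTINUOUS :] = 0.0
        X[:, ft.N_CONTINUOUS] = 1.0  # fake one-hot
        return X

    def test_train_set_standardized(self):
        rng = np.random.default_rng(2)
        X = self.make_matrix(rng)
        norm = ft.fit_normalizer(X)
        Z = norm.transform(X)
        cont = Z[:, : ft.N_CONTINUOUS]
        np.testing.assert_allclose(cont.mean(axis=0), 0.0, atol=1e-6)
        sd = cont.std(axis=0)
        varying = np.where(X[:, : ft.N_CONTINUOUS].std(axis=0) > 1e-12)[0]
        np.testing.assert_allclose(sd[varying], 1.0, atol=1e-6)

    def test_constant_feature_guarded_to_zero(self):
        rng = np.random.default_rng(3)
        Z = ft.fit_normalizer(self.make_matrix(rng)).transform(
            self.make_matrix(rng)
        )
        np.testing.assert_allclose(Z[:, 40], 0.0, atol=1e-9)

    def test_one_hot_block_passthrough(self):
        rng = np.random.default_rng(4)
        X = self.make_matrix(rng)
        Z = ft.fit_normalizer(X).transform(X)
        np.testing.assert_array_equal(Z[:, ft.N_CONTINUOUS :],
                                      X[:, ft.N_CONTINUOUS :])

    def test_unfitted_rejected(self):
        with pytest.raises(RuntimeError):
            ft.FeatureNormalizer().transform(np.zeros(96))

    def test_state_roundtrip(self):
        rng = np.random.default_rng(5)
        X = self.make_matrix(rng)
        norm = ft.fit_normalizer(X)
        clone = ft.FeatureNormalizer.from_state_dict(norm.state_dict())
        np.testing.assert_allclose(clone.transform(X), norm.transform(X),
                                   atol=1e-12)

    def test_schema_sidecar_written(self, tmp_path):
        path = tmp_path / "schema.json"
        ft.write_feature_schema(path)
        import json

        doc = json.loads(path.read_text())
        assert doc["schema_version"] == ft.SCHEMA_VERSION
        assert len(doc["features"]) == 96
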