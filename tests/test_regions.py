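import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.morphology import disk

from spineqct.calibration import CalibrationModel
from spineqct.errors import MeasurementError, ValidationError
from spineqct.regions import (compute_bone_metrics, extract_trabecular_mask,
                              partition_regions, slab_counts)
from spineqct.volume import CTVolume

IDENTITY = CalibrationModel(1.0, 0.0, 1.0, 3)


def _cylinder(radius=20, height=20, shape=(48, 48, 24)):
    x, y = np.meshgrid(np.arange(shape[0]) - shape[0] / 2 + 0.5,
                       np.arange(shape[1]) - shape[1] / 2 + 0.5, indexing="ij")
    circ = x**2 + y**2 <= radius**2
    mask = np.zeros(shape, dtype=bool)
    z0 = (shape[2] - height) // 2
    mask[:, :, z0:z0 + height] = circ[..., None]
    return CTVolume(mask.astype(np.uint8), (1.0, 1.0, 1.0))


class TestSlabCounts:
    @pytest.mark.parametrize(
        "n,fractions,expected",
        [
            (30, (1 / 3, 1 / 3, 1 / 3), (10, 10, 10)),
            (31, (1 / 3, 1 / 3, 1 / 3), (10, 11, 10)),  # remainder -> transverse
            (20, (0.5, 0.25, 0.25), (10, 5, 5)),
        ],
    )
    def test_slice_allocation(self, n, fractions, expected):
        assert slab_counts(n, fractions) == expected

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            slab_counts(10, (0.5, 0.5, 0.5))


class TestExtractTrabecularMask:
    def test_zero_margins_is_identity(self):
        body = _cylinder()
        trab = extract_trabecular_mask(body, 0.0, 0.0)
        assert np.array_equal(trab.mask.data, body.data.astype(bool))

    def test_erosion_matches_brute_force_morphology(self):
        # independent oracle: slice-wise 2-D erosion + explicit slice trim
        body = _cylinder(radius=20, height=20)
        trab = extract_trabecular_mask(body, 2.0, 2.0)
        expect = np.stack(
            [ndimage.binary_erosion(body.data[:, :, k].astype(bool), disk(2))
             for k in range(body.shape[2])], axis=-1,
        )
        occ = np.flatnonzero(expect.any(axis=(0, 1)))
        expect[:, :, occ[:2]] = False
        expect[:, :, occ[-2:]] = False
        assert np.array_equal(trab.mask.data, expect)

    def test_margin_excludes_generator_cortex(self, noiseless_scene):
        # shell is 2 mm; a 3 mm margin must leave zero cortical voxels inside
        _, labels, _ = noiseless_scene
        body = labels.like(np.isin(labels.data, (1, 2, 3)))
        trab = extract_trabecular_mask(body, 3.0, 6.0)
        inside = labels.data[trab.mask.data.astype(bool)]
        assert np.count_nonzero(inside == 2) == 0  # no cortical label
        assert np.count_nonzero(inside == 3) == 0  # no endplate label

    def test_margins_consuming_body_raise(self):
        body = _cylinder(radius=5, height=4)
        with pytest.raises(MeasurementError, match="0"):
            extract_trabecular_mask(body, 10.0, 0.0)


class TestPartitionRegions:
    def test_partition_is_exact_tiling(self):
        body = _cylinder()
        trab = extract_trabecular_mask(body, 2.0, 2.0)
        part = partition_regions(trab)
        union = part.union()
        assert np.array_equal(union, trab.mask.data.astype(bool))
        counts = part.voxel_counts()
        assert sum(counts.values()) == trab.voxel_count
        # pairwise disjoint
        overlap = (part.superior.data.astype(int) + part.transverse.data.astype(int)
                   + part.inferior.data.astype(int))
        assert overlap.max() == 1

    def test_too_few_slices_rejected(self):
        body = _cylinder(height=2)
        with pytest.raises(MeasurementError, match="3"):
            partition_regions(body)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_conservation_on_random_masks(self, data):
        # property: |sup| + |trans| + |inf| == |mask| on any mask
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        mask = rng.random((12, 12, data.draw(st.integers(3, 15)))) < 0.4
        if mask.sum() == 0 or mask.any(axis=(0, 1)).sum() < 3:
            return
        vol = CTVolume(mask.astype(np.uint8), (1, 1, 3))
        fr = data.draw(st.sampled_from([(1/3, 1/3, 1/3), (0.5, 0.25, 0.25), (0.2, 0.6, 0.2)]))
        part = partition_regions(vol, fr)
        assert sum(part.voxel_counts().values()) == mask.sum()
        assert np.array_equal(part.union(), mask)


class TestComputeBoneMetrics:
    def test_uniform_phantom_all_metrics_equal(self):
        body = _cylinder()
        vol = body.like(np.full(body.shape, 150.0))
        part = partition_regions(extract_trabecular_mask(body, 2.0, 2.0))
        bm = compute_bone_metrics(vol, part, IDENTITY)
        for v in (bm.global_tb_vbmd, *bm.regional().values()):
            assert v == pytest.approx(150.0)

    def test_recovers_injected_regional_densities(self, noiseless_scene):
        vol, labels, _ = noiseless_scene
        body = labels.like(np.isin(labels.data, (1, 2, 3)))
        part = partition_regions(extract_trabecular_mask(body, 3.0, 6.0))
        bm = compute_bone_metrics(vol, part, IDENTITY)
        assert bm.rbmd_superior == pytest.approx(178.9, abs=0.5)
        assert bm.rbmd_transverse == pytest.approx(177.5, abs=0.5)
        assert bm.rbmd_inferior == pytest.approx(196.5, abs=0.5)

    def test_global_equals_weighted_regional_mean(self, noisy_scene):
        vol, labels, _ = noisy_scene
        body = labels.like(np.isin(labels.data, (1, 2, 3)))
        part = partition_regions(extract_trabecular_mask(body, 3.0, 6.0))
        bm = compute_bone_metrics(vol, part, CalibrationModel(0.78, -3.2, 1.0, 3))
        c = bm.voxel_counts
        weighted = sum(c[r] * bm.regional()[r] for r in c) / sum(c.values())
        assert bm.global_tb_vbmd == pytest.approx(weighted, rel=1e-9)

    def test_raising_one_region_leaves_others_unchanged(self, grid):
        # monotonicity: +10 mg/cm^3 in the superior region raises superior
        # and global, leaves transverse/inferior untouched
        from dataclasses import replace

        from spineqct.synthetic import (LinearHUMap, PhantomSpec, VertebraSpec,
                                        default_muscles, render_session)

        base = VertebraSpec()
        bumped = replace(
            base,
            regional_trabecular_density={**base.regional_trabecular_density,
                                         "superior": 188.9},
        )
        out = {}
        for name, vert in (("base", base), ("bumped", bumped)):
            rng = np.random.default_rng(0)
            vol, labels, _ = render_session(
                vert, default_muscles(), PhantomSpec(), LinearHUMap(1.0, 0.0),
                0.0, rng, grid)
            body = labels.like(np.isin(labels.data, (1, 2, 3)))
            part = partition_regions(extract_trabecular_mask(body, 3.0, 6.0))
            out[name] = compute_bone_metrics(vol, part, IDENTITY)
        assert out["bumped"].rbmd_superior > out["base"].rbmd_superior
        assert out["bumped"].global_tb_vbmd > out["base"].global_tb_vbmd
        assert out["bumped"].rbmd_transverse == pytest.approx(
            out["base"].rbmd_transverse, abs=1e-9)
        assert out["bumped"].rbmd_inferior == pytest.approx(
            out["base"].rbmd_inferior, abs=1e-9)

    def test_empty_region_raises_with_name(self):
        body = _cylinder()
        part = partition_regions(extract_trabecular_mask(body, 2.0, 2.0))
        part.superior.data[:] = 0
        vol = body.like(np.zeros(body.shape))
        with pytest.raises(MeasurementError, match="superior"):
            compute_bone_metrics(vol, part, IDENTITY)
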