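"""The seven biomarkers: maps, the loss percentage, volume summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralmark.biomarkers import (
    BiomarkerMaps,
    compute_all,
    epithelial_depth_map,
    loss_of_boundary_pct,
    stratification,
    volume_summary,
)
from oralmark.regions import EnFaceMaskSet, SurfaceSet, build_region_masks
from oralmark.volume_io import EnFaceMap


def _region_masks(top, bnd, bottom, n_depth=100):
    surfaces = SurfaceSet(
        epi_top=np.asarray(top, dtype=float), boundary=np.asarray(bnd, dtype=float)
    )
    return build_region_masks(surfaces, np.asarray(bottom, dtype=float), n_depth)


class TestDepthMap:
    def test_sixteen_pixels_is_160_um(self):
        masks = _region_masks([[10.0]], [[26.0]], [[60.0]])
        assert epithelial_depth_map(masks).values[0, 0] == 160.0

    def test_loss_aline_spans_visualized_depth(self):
        """Missing boundary, top 10, bottom 60: depth is the full 500 um."""
        masks = _region_masks([[10.0]], [[np.nan]], [[60.0]])
        assert epithelial_depth_map(masks).values[0, 0] == 500.0

    def test_no_tissue_is_missing(self):
        masks = _region_masks([[np.nan]], [[np.nan]], [[np.nan]])
        assert np.isnan(epithelial_depth_map(masks).values[0, 0])


class TestLossPct:
    def _enface(self, n, artifact_cols=()):
        artifact = np.zeros((1, n), bool)
        artifact[0, list(artifact_cols)] = True
        return EnFaceMaskSet(
            contact=np.ones((1, n), bool), artifact=artifact, lesion=np.zeros((1, n), bool)
        )

    def test_no_loss(self):
        masks = _region_masks([[10.0] * 4], [[30.0] * 4], [[60.0] * 4])
        assert loss_of_boundary_pct(masks, self._enface(4)) == 0.0

    def test_half_loss(self):
        bnd = [[30.0] * 50 + [np.nan] * 50]
        masks = _region_masks([[10.0] * 100], bnd, [[60.0] * 100])
        assert loss_of_boundary_pct(masks, self._enface(100)) == 50.0

    def test_artifacts_excluded_from_both_counts(self):
        """10 flagged of 100 tissue A-lines; 5 of them lie in artifacts and
        artifacts cover 15 A-lines: 100 x 5 / 85."""
        bnd = np.full((1, 100), 30.0)
        bnd[0, :10] = np.nan  # 10 loss A-lines
        masks = _region_masks([[10.0] * 100], bnd, [[60.0] * 100])
        artifact_cols = list(range(5, 20))  # overlaps 5 loss A-lines
        enface = self._enface(100, artifact_cols)
        assert loss_of_boundary_pct(masks, enface) == pytest.approx(100 * 5 / 85)

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(0)
        bnd = np.where(rng.random((6, 20)) < 0.3, np.nan, 30.0)
        top = np.full((6, 20), 10.0)
        bottom = np.full((6, 20), 60.0)
        enface = EnFaceMaskSet(
            contact=np.ones((6, 20), bool),
            artifact=np.zeros((6, 20), bool),
            lesion=np.zeros((6, 20), bool),
        )
        a = loss_of_boundary_pct(_region_masks(top, bnd, bottom), enface)
        perm = rng.permutation(6)
        b = loss_of_boundary_pct(_region_masks(top[perm], bnd[perm], bottom[perm]), enface)
        assert a == b

    def test_all_artifact_raises(self):
        masks = _region_masks([[10.0]], [[30.0]], [[60.0]])
        enface = self._enface(1, artifact_cols=[0])
        with pytest.raises(ValueError, match="artifact-free"):
            loss_of_boundary_pct(masks, enface)


class TestStratification:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.22, 3.71, -0.51), (1.15, 4.21, -0.57), (0.95, 4.95, -0.68), (1.36, 4.52, -0.54)],
    )
    def test_contralateral_worked_examples(self, a, b, expected):
        """Printed epithelium/stroma median pairs reproduce the printed
        stratification medians at two decimals."""
        assert round(stratification(a, b), 2) == expected

    def test_symmetry_and_bounds(self):
        assert stratification(2.0, 2.0) == 0.0
        assert stratification(1.5, 0.0) == 1.0
        assert np.isnan(stratification(0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0.0, 50.0, allow_nan=False),
        st.floats(0.0, 50.0, allow_nan=False),
    )
    def test_range_and_antisymmetry(self, a, b):
        """Outputs lie in [-1, 1] and negate under argument swap."""
        if a + b == 0:
            return
        s = stratification(a, b)
        assert -1.0 <= s <= 1.0
        assert stratification(b, a) == pytest.approx(-s, abs=1e-12)


class TestComputeAll:
    def test_noiseless_phantom_truth_recovery(self, tiny_noiseless):
        vol, truth = tiny_noiseless
        maps = compute_all(vol, truth.surfaces, truth.masks)
        contact = truth.masks.contact
        np.testing.assert_allclose(maps.depth_um.values[contact], 160.0)
        assert maps.loss_pct == 0.0
        np.testing.assert_allclose(maps.mu_epi.values[contact], 1.2, rtol=0.02)
        np.testing.assert_allclose(maps.mu_stroma.values[contact], 3.97, rtol=0.02)
        expected_es = (1.2 - 3.97) / (1.2 + 3.97)
        np.testing.assert_allclose(maps.es_strat.values[contact], expected_es, atol=0.02)
        # uniform attenuation within the epithelium: halves agree
        np.testing.assert_allclose(maps.ie_strat.values[contact], 0.0, atol=0.02)

    def test_artifact_columns_missing_everywhere(self, tiny_noiseless):
        vol, truth = tiny_noiseless
        enface = EnFaceMaskSet(
            contact=truth.masks.contact,
            artifact=np.zeros_like(truth.masks.artifact),
            lesion=truth.masks.lesion,
        )
        enface.artifact[:, 3] = True
        maps = compute_all(vol, truth.surfaces, enface)
        for _, emap in maps.map_items():
            assert np.all(np.isnan(emap.values[:, 3]))

    def test_requires_isotropic_volume(self, tiny_noiseless):
        from dataclasses import replace

        vol, truth = tiny_noiseless
        stretched = replace(vol, z_spacing_optical_um=20.0)
        with pytest.raises(ValueError, match="10 um"):
            compute_all(stretched, truth.surfaces, truth.masks)


def _maps_from(values_by_name, loss_pct=0.0):
    shape = next(iter(values_by_name.values())).shape
    kwargs = {
        name: EnFaceMap(values_by_name.get(name, np.ones(shape)))
        for name in ("depth_um", "mu_overall", "mu_epi", "mu_stroma", "es_strat", "ie_strat")
    }
    return BiomarkerMaps(
        **kwargs, loss_pct=loss_pct, loss_mask=np.zeros(shape, dtype=bool)
    )


class TestVolumeSummary:
    def test_uniform_maps(self):
        shape = (8, 10)
        maps = _maps_from({"depth_um": np.full(shape, 230.0)}, loss_pct=4.5)
        enface = EnFaceMaskSet(
            contact=np.ones(shape, bool),
            artifact=np.zeros(shape, bool),
            lesion=np.zeros(shape, bool),
        )
        summary = volume_summary(maps, enface)
        assert summary.medians["depth_um"] == 230.0
        assert summary.medians["loss_pct"] == 4.5

    def test_odd_count_median(self):
        depth = np.full((4, 3), np.nan)
        depth[1, :] = [100.0, 160.0, 700.0]  # central (retained) frame row
        maps = _maps_from({"depth_um": depth})
        enface = EnFaceMaskSet(
            contact=np.ones((4, 3), bool),
            artifact=np.zeros((4, 3), bool),
            lesion=np.zeros((4, 3), bool),
        )
        assert volume_summary(maps, enface).medians["depth_um"] == 160.0

    def test_artifact_extremes_do_not_move_medians(self):
        """Extreme values confined to artifact A-lines leave medians fixed."""
        rng = np.random.default_rng(1)
        shape = (16, 20)
        depth = rng.normal(160, 20, shape)
        enface = EnFaceMaskSet(
            contact=np.ones(shape, bool),
            artifact=np.zeros(shape, bool),
            lesion=np.zeros(shape, bool),
        )
        base = volume_summary(_maps_from({"depth_um": depth}), enface)
        enface.artifact[:, 5] = True
        depth2 = depth.copy()
        depth2[:, 5] = 1e6
        perturbed = volume_summary(_maps_from({"depth_um": depth2}), enface)
        assert perturbed.medians["depth_um"] == pytest.approx(
            volume_summary(_maps_from({"depth_um": depth}), enface).medians["depth_um"]
        )
        del base

    def test_lesion_restriction(self):
        shape = (8, 10)
        depth = np.full(shape, 100.0)
        lesion = np.zeros(shape, bool)
        lesion[:, :5] = True
        depth[:, :5] = 400.0
        maps = _maps_from({"depth_um": depth})
        enface = EnFaceMaskSet(
            contact=np.ones(shape, bool), artifact=np.zeros(shape, bool), lesion=lesion
        )
        assert volume_summary(maps, enface, restrict_to_lesion=True).medians["depth_um"] == 400.0

    def test_empty_retained_set_raises(self):
        shape = (4, 4)
        maps = _maps_from({"depth_um": np.ones(shape)})
        enface = EnFaceMaskSet(
            contact=np.ones(shape, bool), artifact=np.ones(shape, bool),
            lesion=np.zeros(shape, bool),
        )
        with pytest.raises(ValueError, match="retained"):
            volume_summary(maps, enface)
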