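"""LCN segmentation, lacuna/canaliculi split and morphometric descriptors."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from skimage.measure import label as cc_label
from skimage.morphology import ball

import lcnpipe as lp
from lcnpipe.core import BONE, Volume3D
from lcnpipe.lcn import mesh_area, smoothness_from_vs, sphericity_from_vs
from lcnpipe.skeleton import skeleton_graph
from .conftest import make_ellipsoid, make_tube


def ellipsoid_surface_area(a, b, c):
    """Numerical (quadrature) surface area of an ellipsoid — the oracle."""

    def integrand(u, v):
        return np.sqrt(
            (b * c * np.sin(v) ** 2 * np.cos(u)) ** 2
            + (a * c * np.sin(v) ** 2 * np.sin(u)) ** 2
            + (a * b * np.sin(v) * np.cos(v)) ** 2
        )

    val, _ = dblquad(integrand, 0, np.pi, 0, 2 * np.pi)
    return val


class TestSegmentLCN:
    def test_bimodal_exact(self):
        data = np.full((16, 16, 16), 200.0)
        data[4:8, 4:8, 4:8] = 50.0
        mask = lp.segment_lcn(Volume3D(data, 1.0), threshold=125, polarity="dark")
        np.testing.assert_array_equal(mask, data == 50.0)

    def test_threshold_above_max_marks_everything(self):
        data = np.random.default_rng(0).uniform(0, 100, (8, 8, 8))
        mask = lp.segment_lcn(Volume3D(data, 1.0), threshold=1000, polarity="dark")
        assert mask.all()

    def test_noisy_phantom_dice(self, nano_phantom, nano_split):
        _, truth = nano_phantom
        mask = nano_split[0]
        true_mask = truth.label_volume.data != BONE
        dice = 2 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum())
        assert dice >= 0.9


class TestSplitLCN:
    def test_lacuna_count_after_split(self):
        shape = (60, 60, 60)
        lcn = (
            make_ellipsoid((7.0, 6.0, 6.0), shape, (20, 20, 20))
            | make_ellipsoid((7.0, 6.0, 6.0), shape, (40, 40, 40))
            | make_tube((20, 20, 20), (40, 40, 40), 2.0, shape)
        )
        lacunae, canaliculi = lp.split_lcn(lcn, open_radius=3)
        assert cc_label(lacunae, connectivity=3).max() == 2
        assert canaliculi.any()

    def test_union_and_disjointness_identity(self, nano_split):
        mask, lacunae, canaliculi, _ = nano_split
        np.testing.assert_array_equal(lacunae | canaliculi, mask)
        assert not (lacunae & canaliculi).any()

    def test_vanishing_lacuna_warns(self):
        lcn = make_ellipsoid((2.0, 2.0, 2.0), (20, 20, 20), (10, 10, 10))
        with pytest.warns(UserWarning, match="vanished"):
            lacunae, _ = lp.split_lcn(lcn, open_radius=5, expected_lacunae=1)
        assert not lacunae.any()


class TestShapeDescriptors:
    def test_digitized_sphere_near_unity(self):
        rec = lp.shape_descriptors(ball(20).astype(np.int32), spacing=1.0)[0]
        assert rec.sphericity == pytest.approx(1.0, abs=0.03)
        assert rec.smoothness == pytest.approx(1.0, abs=0.09)

    def test_cube_closed_form(self):
        # analytic V = a³ and SA = 6a² straight into the shape formulas
        a = 7.0
        assert sphericity_from_vs(a**3, 6 * a**2) == pytest.approx((np.pi / 6) ** (1 / 3))
        assert smoothness_from_vs(a**3, 6 * a**2) == pytest.approx(6 / np.pi)

    def test_smoothness_sphericity_identity(self, nano_split):
        _, _, _, labelled = nano_split
        for rec in lp.shape_descriptors(labelled, 0.3):
            assert abs(rec.smoothness * rec.sphericity**3 - 1.0) < 1e-9

    def test_sphericity_monotone_in_aspect_ratio(self):
        """At fixed volume, sphericity falls with elongation; measured values
        track a quadrature surface-area oracle within 5%."""
        v0 = 4 / 3 * np.pi * 1000.0
        measured, oracle = [], []
        for ar in (1.0, 2.0, 3.0, 4.0):
            s = (v0 * 3 / (4 * np.pi) / ar) ** (1 / 3)
            a, b, c = ar * s, s, s
            rec = lp.shape_descriptors(make_ellipsoid((a, b, c)).astype(np.int32), 1.0)[0]
            measured.append(rec.sphericity)
            oracle.append(sphericity_from_vs(v0, ellipsoid_surface_area(a, b, c)))
        assert np.all(np.diff(measured) < 0)
        assert np.all(np.diff(oracle) < 0)
        assert np.abs(np.array(measured) / np.array(oracle) - 1).max() < 0.05

    def test_tiny_component_excluded_with_warning(self):
        lab = np.zeros((8, 8, 8), np.int32)
        lab[2, 2, 2] = 1
        lab[4:7, 4:7, 4:7] = 2
        with pytest.warns(UserWarning, match="excluded"):
            recs = lp.shape_descriptors(lab, 1.0)
        assert [r.id for r in recs] == [2]


class TestCanaliculiPerLacuna:
    def _one_lacuna_four_tubes(self, offset=(0, 0, 0)):
        shape = (50, 50, 50)
        c = tuple(25 + o for o in offset)
        lac = make_ellipsoid((8.0, 8.0, 8.0), shape, c)
        tubes = np.zeros(shape, bool)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, 0, 1)):
            end = tuple(np.clip(c[i] + 22 * d[i], 1, 48) for i in range(3))
            tubes |= make_tube(c, end, 1.5, shape)
        tubes &= ~lac
        return lac, tubes

    def test_four_attached_tubes(self):
        lac, tubes = self._one_lacuna_four_tubes()
        labelled = cc_label(lac, connectivity=3)
        recs = lp.shape_descriptors(labelled, 1.0)
        sk = skeleton_graph(tubes, 1.0, prune_length=3.0)
        out = lp.lcn.canaliculi_per_lacuna(sk, labelled, recs)
        assert out[1] == pytest.approx(4.0 / recs[0].surface_area_um2)

    def test_isolated_lacuna_zero(self):
        lac, _ = self._one_lacuna_four_tubes()
        labelled = cc_label(lac, connectivity=3)
        recs = lp.shape_descriptors(labelled, 1.0)
        sk = skeleton_graph(np.zeros_like(lac), 1.0)
        assert lp.lcn.canaliculi_per_lacuna(sk, labelled, recs)[1] == 0.0

    def test_translation_invariant(self):
        results = []
        for off in ((0, 0, 0), (3, -2, 4)):
            lac, tubes = self._one_lacuna_four_tubes(off)
            labelled = cc_label(lac, connectivity=3)
            recs = lp.shape_descriptors(labelled, 1.0)
            sk = skeleton_graph(tubes, 1.0, prune_length=3.0)
            results.append(lp.lcn.canaliculi_per_lacuna(sk, labelled, recs)[1])
        assert results[0] == pytest.approx(results[1], rel=1e-6)


class TestJunctionAndPorosity:
    def test_junction_density_examples(self):
        shape = (50, 40, 40)
        y = (
            make_tube((5, 20, 20), (25, 20, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 10, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 30, 20), 3.0, shape)
        )
        sk = skeleton_graph(y, 1.0, prune_length=6.0)
        assert lp.lcn.junction_density(sk, 1.0e5) == pytest.approx(1.0e-5)
        sk0 = skeleton_graph(make_tube((5, 7, 7), (40, 7, 7), 3.0, (50, 15, 15)), 1.0, 6.0)
        assert lp.lcn.junction_density(sk0, 1.0e5) == 0.0
        with pytest.raises(ValueError):
            lp.lcn.junction_density(sk, 0.0)

    def test_two_disjoint_junctions(self):
        shape = (50, 40, 80)
        y1 = (
            make_tube((5, 20, 20), (25, 20, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 10, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 30, 20), 3.0, shape)
        )
        y2 = np.roll(y1, 40, axis=2)
        sk = skeleton_graph(y1 | y2, 1.0, prune_length=6.0)
        assert lp.lcn.junction_density(sk, 1.0e5) == pytest.approx(2.0e-5)

    def test_lcn_porosity_ratio_and_guard(self):
        bone = np.zeros((30, 30, 30), bool)
        bone[:, :, :] = True
        lcn_mask = np.zeros_like(bone)
        lcn_mask.ravel()[:500] = True
        assert lp.lcn_porosity(lcn_mask, bone) == pytest.approx(500 / 27000)
        assert lp.lcn_porosity(np.zeros_like(bone), bone) == 0.0
        with pytest.raises(ValueError, match="outside"):
            lp.lcn_porosity(lcn_mask, ~bone)

    def test_split_then_shapes_recovers_ground_truth(self, nano_phantom, nano_split):
        _, truth = nano_phantom
        _, _, _, labelled = nano_split
        recs = lp.shape_descriptors(labelled, 0.3)
        assert len(recs) == truth.n_lacunae
        got = np.sort([r.volume_um3 for r in recs])
        want = np.sort(truth.lacuna_table.volume_voxel_um3.to_numpy())
        assert np.abs(got / want - 1).max() <= 0.10

    def test_mean_canalicular_values_are_per_branch(self):
        lac = make_ellipsoid((8.0, 8.0, 8.0), (50, 50, 50), (25, 25, 25))
        tubes = make_tube((25, 25, 25), (25, 25, 48), 1.5, (50, 50, 50)) & ~lac
        bone = np.ones((50, 50, 50), bool)
        metrics, sk = lp.compute_lcn_metrics(lac, tubes, bone, 1.0, prune_length=3.0)
        assert metrics.n_canaliculi == sk.n_branches
        total_sa = mesh_area(tubes, 1.0, smooth_sigma=0.5)
        assert metrics.mean_ca_sa_um2 == pytest.approx(total_sa / sk.n_branches)
        assert metrics.mean_ca_v_um3 == pytest.approx(tubes.sum() / sk.n_branches)
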