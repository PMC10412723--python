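"""Micro-scale porosity: extraction, classification, VOI, densities, skeleton."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import lcnpipe as lp
from lcnpipe.core import BONE
from lcnpipe.skeleton import skeleton_graph
from .conftest import make_ellipsoid, make_tube


class TestExtractPorosity:
    def test_internal_cavity_recovered_exactly(self):
        bone = np.zeros((20, 20, 20), bool)
        bone[2:18, 2:18, 2:18] = True
        bone[8:13, 8:13, 8:13] = False  # 5³ cavity
        pores = lp.extract_porosity(bone, open_radius=1, close_radius=3)
        oracle = ndi.binary_fill_holes(bone) & ~bone
        np.testing.assert_array_equal(pores, oracle)

    def test_solid_bone_gives_empty_pores(self):
        bone = np.ones((12, 12, 12), bool)
        assert not lp.extract_porosity(bone, 1, 3).any()

    def test_cavity_open_to_exterior_excluded(self):
        bone = np.zeros((24, 24, 24), bool)
        bone[2:22, 2:22, 2:22] = True
        # 9-voxel-wide blind channel to the outside, wider than the closing
        # ball; its open lumen must not come back as porosity (the closing
        # legitimately rounds the sharp corner lines and the concave floor
        # of the blind end, so assert on the open core)
        bone[8:17, 8:17, 0:12] = False
        pores = lp.extract_porosity(bone, open_radius=1, close_radius=3)
        assert not pores[10:15, 10:15, 0:10].any()

    def test_result_depends_only_on_opened_bone(self):
        rng = np.random.default_rng(5)
        bone = np.zeros((28, 28, 28), bool)
        bone[2:26, 2:26, 2:26] = True
        for c in rng.integers(6, 22, size=(5, 3)):
            bone[tuple(slice(int(v) - 1, int(v) + 2) for v in c)] = False
        from lcnpipe.core import ball_opening

        p1 = lp.extract_porosity(bone, 1, 3)
        p2 = lp.extract_porosity(ball_opening(bone, 1), 1, 3)
        np.testing.assert_array_equal(p1, p2)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lp.extract_porosity(np.full((4, 4, 4), 2), 1, 3)


class TestClassifyPores:
    def test_ellipsoids_vs_tube(self):
        # three ~230 µm³ lacunae and one ~1.5e4 µm³ canal at 2 µm spacing
        # (semiaxes below are in voxels: 4×3×3 µm and tube radius 7 µm)
        shape = (60, 60, 60)
        pores = np.zeros(shape, bool)
        for c in ((12, 12, 12), (12, 40, 40), (40, 12, 40)):
            pores |= make_ellipsoid((2.0, 1.5, 1.5), shape, c, spacing=1.0)
        pores |= make_tube((5, 50, 20), (55, 50, 20), 3.5, shape)
        comps, lac, vas = lp.classify_pores(pores, spacing=2.0, vol_thresh_um3=1000.0)
        classes = sorted(c.pore_class for c in comps)
        assert classes == ["lacunar", "lacunar", "lacunar", "vascular"]
        assert (lac | vas).sum() == pores.sum() and not (lac & vas).any()

    def test_empty_mask(self):
        comps, lac, vas = lp.classify_pores(np.zeros((8, 8, 8), bool), 2.0)
        assert comps == [] and not lac.any() and not vas.any()

    def test_volume_exactly_at_threshold_is_vascular(self):
        pores = np.zeros((20, 20, 20), bool)
        pores[5:10, 5:10, 5:10] = True  # 125 voxels × 8 µm³ = 1000 µm³
        comps, _, _ = lp.classify_pores(
            pores, spacing=2.0, vol_thresh_um3=1000.0, elongation_thresh=100.0
        )
        assert comps[0].pore_class == "vascular"


class TestBuildVOI:
    @pytest.fixture()
    def implant(self):
        mask = np.zeros((20, 120, 120), bool)
        yy, xx = np.mgrid[0:120, 0:120]
        mask[:, (yy - 60) ** 2 + (xx - 60) ** 2 <= 15**2] = True
        return mask

    def test_forty_dilations_at_5um_is_200um_shell(self, implant):
        voi = lp.build_voi(implant, n_dilations=40, spacing=5.0)
        assert voi.nominal_thickness_um == pytest.approx(200.0)
        # measured along +x from the implant boundary: exactly 40 shell voxels
        row_imp = implant[10, 60, :]
        row_shell = voi.mask[10, 60, :]
        x_edge = np.where(row_imp)[0].max()
        assert row_shell[x_edge + 1 : x_edge + 41].all()
        assert not row_shell[x_edge + 41]

    def test_zero_dilations_empty_shell(self, implant):
        assert not lp.build_voi(implant, 0, 5.0).mask.any()

    def test_shell_disjoint_from_implant(self, implant):
        voi = lp.build_voi(implant, 10, 5.0)
        assert not (voi.mask & implant).any()

    def test_euclidean_mode_bounded_by_distance(self, implant):
        voi = lp.build_voi(implant, 10, 5.0, mode="euclidean")
        dist = ndi.distance_transform_edt(~implant, sampling=5.0)
        assert dist[voi.mask].max() <= 50.0 + 1e-9

    def test_empty_implant_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lp.build_voi(np.zeros((4, 4, 4), bool), 5, 5.0)


class TestDensities:
    def test_bone_volume_arithmetic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:1000] = True
        assert lp.bone_volume(mask, 5.0) == pytest.approx(1.25e5)
        assert lp.bone_volume(np.zeros((4, 4, 4), bool), 5.0) == 0.0
        assert lp.bone_volume(np.ones((64, 64, 64), bool), 1.0) == pytest.approx(262144.0)

    def test_number_density_and_inverse(self):
        assert lp.number_density(8, 1.0e6) == pytest.approx(8000.0)  # 0.001 mm³
        assert lp.number_density(0, 1.0e6) == 0.0
        # density × BV reproduces the count
        for n, bv in ((3, 12345.6), (17, 9.9e5)):
            assert lp.number_density(n, bv) * bv * 1e-9 == pytest.approx(n)

    def test_zero_bv_rejected(self):
        with pytest.raises(ValueError):
            lp.number_density(1, 0.0)


class TestSkeleton:
    def test_straight_tube_single_branch(self):
        tube = make_tube((5, 7, 7), (54, 7, 7), 3.0, (60, 15, 15))
        sk = skeleton_graph(tube, spacing=1.0, prune_length=6.0)
        assert sk.n_branches == 1
        assert sk.n_endpoints == 2
        assert sk.n_junctions == 0
        # total branch length within 5% of the 49-voxel axial length
        assert sk.total_length == pytest.approx(49.0, rel=0.05)

    def test_y_union_single_degree3_junction(self):
        shape = (50, 40, 40)
        y = (
            make_tube((5, 20, 20), (25, 20, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 10, 20), 3.0, shape)
            | make_tube((25, 20, 20), (45, 30, 20), 3.0, shape)
        )
        sk = skeleton_graph(y, spacing=1.0, prune_length=6.0)
        assert sk.n_junctions == 1
        assert sk.graph.degree(sk.junction_positions[0]) == 3
        assert sk.n_branches == 3

    def test_empty_mask_empty_graph(self):
        sk = skeleton_graph(np.zeros((6, 6, 6), bool), 1.0)
        assert sk.n_branches == 0 and sk.graph.number_of_nodes() == 0


class TestPipelineRecovery:
    def test_counts_exact_volumes_within_10pct(self):
        # well-separated lacunae with min semiaxis >= 5 voxels
        spec = lp.PhantomSpec(
            grid_shape=(96, 96, 96), spacing=1.0, n_lacunae=6,
            lacuna_semiaxes_range=((7.0, 5.0, 5.0), (9.0, 6.0, 6.0)),
            n_vascular=0, min_gap_voxels=4.0, seed=3,
        )
        _, truth = lp.generate_phantom(spec)
        bone = truth.label_volume.data == BONE
        pores = lp.extract_porosity(bone, open_radius=1, close_radius=7)
        comps, _, _ = lp.classify_pores(pores, 1.0, vol_thresh_um3=2000.0)
        lacs = [c for c in comps if c.pore_class == "lacunar"]
        assert len(lacs) == truth.n_lacunae
        got = np.sort([c.volume_um3 for c in lacs])
        want = np.sort(truth.lacuna_table.volume_voxel_um3.to_numpy())
        assert np.abs(got / want - 1).max() <= 0.10

    def test_micro_phantom_classification_matches_truth(self, micro_phantom):
        _, truth = micro_phantom
        bone = truth.label_volume.data == BONE
        pores = lp.extract_porosity(bone, open_radius=1, close_radius=6)
        comps, _, _ = lp.classify_pores(pores, truth.label_volume.spacing)
        n_lac = sum(1 for c in comps if c.pore_class == "lacunar")
        n_vas = len(comps) - n_lac
        assert n_lac == truth.n_lacunae
        assert n_vas == len(truth.vascular_table)
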