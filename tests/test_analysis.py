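"""Shell partition, radial distribution functions, contacts and LAC profiles."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from sxtseg import (
    BinaryMask,
    InstanceMap,
    Volume,
    detect_contacts,
    distance_fields,
    functional_regions,
    lac_radial_profile,
    rdf_contacts,
    rdf_points,
    rdf_voxels,
    shell_partition,
)


def _ball(shape, center, radius):
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


@pytest.fixture(scope="module")
def sphere_shells():
    """Concentric-sphere cell (R=22) and nucleus (R=8) with 8 shells."""
    shape = (50, 50, 50)
    cell = BinaryMask(_ball(shape, (25, 25, 25), 22), class_name="cell")
    nucleus = BinaryMask(_ball(shape, (25, 25, 25), 8), class_name="nucleus")
    d_nuc, d_pm = distance_fields(cell, nucleus)
    shells = shell_partition(d_nuc, d_pm)
    return cell, nucleus, shells


class TestDistanceFields:
    def test_adjacent_voxel_distance_one(self):
        shape = (9, 9, 9)
        cell = BinaryMask(np.ones(shape, bool))
        nuc = np.zeros(shape, bool)
        nuc[4, 4, 4] = True
        d_nuc, _ = distance_fields(cell, BinaryMask(nuc))
        assert d_nuc[4, 4, 5] == 1.0

    def test_matches_brute_force_nearest_neighbor(self, rng):
        shape = (15, 15, 15)
        cell = rng.random(shape) > 0.2
        nuc = cell & (rng.random(shape) > 0.8)
        if not nuc.any():
            nuc[tuple(np.argwhere(cell)[0])] = True
        d_nuc, d_pm = distance_fields(BinaryMask(cell), BinaryMask(nuc))
        nuc_pts = np.argwhere(nuc)
        out_pts = np.argwhere(~cell)
        for idx in np.argwhere(cell & ~nuc)[::17]:
            bf_nuc = np.sqrt(((nuc_pts - idx) ** 2).sum(axis=1)).min()
            assert d_nuc[tuple(idx)] == pytest.approx(bf_nuc)
            if out_pts.size:
                bf_pm = np.sqrt(((out_pts - idx) ** 2).sum(axis=1)).min()
                assert d_pm[tuple(idx)] == pytest.approx(bf_pm)

    def test_nucleus_outside_cell_warns_and_intersects(self):
        shape = (8, 8, 8)
        cell = np.zeros(shape, bool)
        cell[:4] = True
        nuc = np.zeros(shape, bool)
        nuc[3:6] = True
        with pytest.warns(UserWarning, match="outside the cell"):
            d_nuc, _ = distance_fields(BinaryMask(cell), BinaryMask(nuc))
        assert d_nuc[3, 0, 0] == 0.0   # kept: inside both
        assert d_nuc[5, 0, 0] > 0.0    # dropped: outside cell

    def test_empty_masks_rejected(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool))
        full = BinaryMask(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError):
            distance_fields(empty, full)
        with pytest.raises(ValueError):
            distance_fields(full, empty)


class TestShellPartition:
    def test_bin_edges_on_synthetic_depths(self):
        # direct control of lambda through hand-built distance fields
        shape = (1, 1, 4)
        cytosol = np.ones(shape, bool)
        d_nuc = np.array([0.0, 0.999, 0.5, 1.0]).reshape(shape)
        d_pm = np.array([1.0, 0.001, 0.5, 0.0]).reshape(shape)
        shells = shell_partition(d_nuc, d_pm, n_shells=8, cytosol=cytosol)
        assert shells.shell_index[0, 0, 0] == 1   # lambda = 0
        assert shells.shell_index[0, 0, 1] == 8   # lambda = 0.999
        assert shells.shell_index[0, 0, 2] == 5   # lambda = 0.5
        assert shells.shell_index[0, 0, 3] == 8   # lambda = 1 -> last shell

    def test_partitions_cytosol_exactly(self, sphere_shells):
        cell, nucleus, shells = sphere_shells
        cytosol = cell.data & ~nucleus.data
        assert shells.shell_volumes.sum() == cytosol.sum()
        assert np.all((shells.shell_index > 0) == cytosol)

    def test_concentric_spheres_give_equal_relative_annuli(self, sphere_shells):
        cell, nucleus, shells = sphere_shells
        # along a radial ray the shell id follows floor(8*lambda)+1 with
        # lambda the analytic relative depth between the two spheres
        center, r_nuc, r_cell = 25, 8.0, 22.0
        for z in range(int(center + r_nuc) + 2, int(center + r_cell) - 1):
            radial = z - center
            lam = (radial - r_nuc) / (r_cell - r_nuc)
            expected = min(int(lam * 8) + 1, 8)
            assert abs(shells.shell_index[25, 25, z] - expected) <= 1

    def test_matches_brute_force_distances_on_small_grid(self, rng):
        shape = (12, 12, 12)
        cell = _ball(shape, (6, 6, 6), 5)
        nuc = _ball(shape, (6, 6, 6), 2)
        d_nuc, d_pm = distance_fields(BinaryMask(cell), BinaryMask(nuc))
        shells = shell_partition(d_nuc, d_pm, n_shells=4)
        nuc_pts = np.argwhere(nuc)
        out_pts = np.argwhere(~cell)
        for idx in np.argwhere(cell & ~nuc):
            dn = np.sqrt(((nuc_pts - idx) ** 2).sum(axis=1)).min()
            dp = np.sqrt(((out_pts - idx) ** 2).sum(axis=1)).min()
            lam = dn / (dn + dp)
            expected = min(int(lam * 4) + 1, 4)
            assert shells.shell_index[tuple(idx)] == expected

    def test_zero_total_distance_rejected(self):
        shape = (2, 2, 2)
        with pytest.raises(ValueError, match="zero"):
            shell_partition(np.zeros(shape), np.zeros(shape),
                            cytosol=np.ones(shape, bool))


class TestRDF:
    def test_single_shell_population(self, sphere_shells):
        _, _, shells = sphere_shells
        sel = np.argwhere(shells.shell_index == 3)[:50]
        profile = rdf_points([c.astype(float) for c in sel], shells)
        expected = (shells.cytosol_volume / shells.shell_volumes[2]) * 1.0
        assert profile.g[2] == pytest.approx(expected)
        assert np.all(profile.g[[0, 1, 3, 4, 5, 6, 7]] == 0)

    def test_counts_conserved_for_single_center(self, sphere_shells):
        _, _, shells = sphere_shells
        center = np.argwhere(shells.shell_index == 5)[0].astype(float)
        profile = rdf_points([center], shells)
        assert profile.counts.sum() == 1

    def test_uniform_centers_give_unit_g_within_3_sigma(self, sphere_shells, rng):
        _, _, shells = sphere_shells
        coords = np.argwhere(shells.shell_index > 0)
        n = 800
        picks = coords[rng.choice(len(coords), n, replace=False)].astype(float)
        profile = rdf_points(list(picks), shells)
        for k in range(8):
            frac = shells.shell_volumes[k] / shells.cytosol_volume
            sigma_g = np.sqrt(frac * (1 - frac) / n) / frac
            assert abs(profile.g[k] - 1.0) <= 3 * sigma_g

    def test_volume_weighted_mean_is_one(self, sphere_shells, rng):
        _, _, shells = sphere_shells
        coords = np.argwhere(shells.shell_index > 0)
        picks = coords[rng.choice(len(coords), 100, replace=False)].astype(float)
        profile = rdf_points(list(picks), shells)
        wmean = (profile.g * shells.shell_volumes).sum() / shells.cytosol_volume
        assert wmean == pytest.approx(1.0)

    def test_centers_in_nucleus_discarded_with_warning(self, sphere_shells):
        _, nucleus, shells = sphere_shells
        inside = np.argwhere(shells.shell_index > 0)[0].astype(float)
        in_nuc = np.argwhere(nucleus.data)[0].astype(float)
        with pytest.warns(UserWarning, match="discarded"):
            profile = rdf_points([inside, in_nuc], shells)
        assert profile.counts.sum() == 1

    def test_voxel_rdf_of_entire_cytosol_is_flat_one(self, sphere_shells):
        cell, nucleus, shells = sphere_shells
        cytosol = BinaryMask(cell.data & ~nucleus.data)
        np.testing.assert_allclose(rdf_voxels(cytosol, shells).g, 1.0)

    def test_voxel_rdf_confined_to_one_shell(self, sphere_shells):
        _, _, shells = sphere_shells
        mask = BinaryMask(shells.shell_index == 8)
        g = rdf_voxels(mask, shells).g
        assert g[7] > 0 and np.all(g[:7] == 0)

    def test_voxel_counts_match_brute_force_tally(self, sphere_shells, rng):
        _, _, shells = sphere_shells
        blob = (rng.random(shells.shell_index.shape) > 0.9) & (shells.shell_index > 0)
        profile = rdf_voxels(BinaryMask(blob), shells)
        tally = np.zeros(8, int)
        for idx in np.argwhere(blob):
            tally[shells.shell_index[tuple(idx)] - 1] += 1
        np.testing.assert_array_equal(profile.counts, tally)

    def test_empty_population_rejected(self, sphere_shells):
        _, _, shells = sphere_shells
        with pytest.raises(ValueError):
            rdf_points([], shells)
        with pytest.raises(ValueError):
            rdf_voxels(BinaryMask(np.zeros(shells.shell_index.shape, bool)), shells)


class TestContacts:
    def test_face_adjacent_voxel_is_contact(self):
        shape = (6, 6, 6)
        ves = np.zeros(shape, np.int32)
        mito = np.zeros(shape, bool)
        ves[2, 2, 2] = 1
        mito[2, 2, 3] = True  # distance 1 < 1.5
        contacts = detect_contacts(InstanceMap(ves), BinaryMask(mito))
        assert contacts.n_contacts == 1
        np.testing.assert_allclose(contacts.centers[0], [2, 2, 2])

    def test_distance_two_is_not_a_contact(self):
        shape = (6, 6, 6)
        ves = np.zeros(shape, np.int32)
        mito = np.zeros(shape, bool)
        ves[2, 2, 2] = 1
        mito[2, 2, 4] = True
        assert detect_contacts(InstanceMap(ves), BinaryMask(mito)).n_contacts == 0

    def test_matches_all_pairs_distance_scan(self, rng):
        shape = (12, 12, 12)
        ves = InstanceMap.from_labels(
            np.where(rng.random(shape) > 0.85, 1, 0))
        mito = rng.random(shape) > 0.9
        contacts = detect_contacts(ves, BinaryMask(mito), cutoff=1.5)
        mito_pts = np.argwhere(mito)
        expected = np.zeros(shape, bool)
        if mito_pts.size:
            for idx in np.argwhere(ves.data > 0):
                d = np.sqrt(((mito_pts - idx) ** 2).sum(axis=1)).min()
                expected[tuple(idx)] = d < 1.5
        np.testing.assert_array_equal(contacts.contacts.data > 0, expected)

    def test_monotone_in_cutoff(self, rng):
        shape = (14, 14, 14)
        ves = InstanceMap.from_labels(np.where(rng.random(shape) > 0.8, 1, 0))
        mito = BinaryMask(rng.random(shape) > 0.9)
        small = detect_contacts(ves, mito, cutoff=1.0).contacts.data > 0
        large = detect_contacts(ves, mito, cutoff=2.5).contacts.data > 0
        assert np.all(small <= large)

    def test_no_mitochondria_gives_empty_set(self):
        ves = InstanceMap.from_labels(np.ones((4, 4, 4), np.int32))
        contacts = detect_contacts(ves, BinaryMask(np.zeros((4, 4, 4), bool)))
        assert contacts.n_contacts == 0
        with pytest.raises(ValueError, match="empty"):
            rdf_contacts(contacts, None)

    def test_contact_rdf_conserves_counts(self, sphere_shells):
        cell, nucleus, shells = sphere_shells
        ves = np.zeros(cell.shape, np.int32)
        mito = np.zeros(cell.shape, bool)
        spot = np.argwhere(shells.shell_index == 4)[0]
        ves[tuple(spot)] = 1
        mito[spot[0], spot[1], spot[2] + 1] = True
        contacts = detect_contacts(InstanceMap(ves), BinaryMask(mito))
        profile = rdf_contacts(contacts, shells)
        assert profile.counts.sum() == 1


class TestLACProfile:
    def test_single_voxel_instance(self):
        vol = Volume(np.full((3, 3, 3), 0.4, np.float32))
        inst = np.zeros((3, 3, 3), bool)
        inst[1, 1, 1] = True
        profile = lac_radial_profile(vol, inst)
        assert len(profile.boundary_distance_bins) == 1
        assert profile.mean_lac[0] == pytest.approx(0.4)
        np.testing.assert_array_equal(profile.center_voxel, [1, 1, 1])

    def test_uniform_sphere_has_equal_bins(self):
        shape = (15, 15, 15)
        inst = _ball(shape, (7, 7, 7), 5)
        vol = Volume(np.where(inst, 0.45, 0.1).astype(np.float32))
        profile = lac_radial_profile(vol, inst)
        valid = profile.bin_counts > 0
        np.testing.assert_allclose(profile.mean_lac[valid], 0.45, rtol=1e-6)

    def test_bin_counts_sum_to_instance_volume(self, small_phantom):
        inst = small_phantom.gt_vesicles.data == 1
        profile = lac_radial_profile(small_phantom.volume, inst)
        assert profile.bin_counts.sum() == inst.sum()

    def test_dense_core_profile_is_non_decreasing(self, small_phantom_clean):
        p = small_phantom_clean
        for lab in range(1, p.gt_vesicles.n_instances + 1):
            profile = lac_radial_profile(p.volume, p.gt_vesicles.data == lab)
            means = profile.mean_lac[profile.bin_counts > 0]
            assert np.all(np.diff(means) >= -1e-6)

    def test_center_voxel_is_max_lac(self, small_phantom_clean):
        p = small_phantom_clean
        inst = p.gt_vesicles.data == 3
        profile = lac_radial_profile(p.volume, inst)
        assert p.volume.data[tuple(profile.center_voxel)] == p.volume.data[inst].max()

    def test_empty_instance_rejected(self):
        with pytest.raises(ValueError):
            lac_radial_profile(Volume(np.zeros((3, 3, 3))),
                               np.zeros((3, 3, 3), bool))


class TestFunctionalRegions:
    @pytest.mark.parametrize("shell,region", [
        (1, "perinuclear"), (2, "maturation"), (3, "maturation"),
        (4, "transportation"), (5, "transportation"), (6, "transportation"),
        (7, "secretion"), (8, "secretion"),
    ])
    def test_mapping(self, shell, region):
        assert functional_regions(shell) == region

    @pytest.mark.parametrize("bad", [0, 9, -1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            functional_regions(bad)
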