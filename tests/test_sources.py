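"""Sphere forward model, LCMV beamformer, ASI and region assignment."""

import numpy as np
import pytest

import ictalmeg as im
from ictalmeg.exceptions import (
    ConfigurationError,
    GeometryError,
    NoSourceError,
)
from ictalmeg.sources import AsiMap, accumulate_source_imaging

from conftest import tangential


class TestGridAndAtlas:
    def test_default_grid_scans_whole_brain_scale(self):
        grid = im.make_source_grid()
        assert 15000 <= grid.n_voxels <= 19000
        assert np.all(np.linalg.norm(grid.voxel_centres_mm, axis=1) < 96.0)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            im.make_source_grid(spacing_mm=0.0)

    def test_every_voxel_gets_exactly_one_label(self, coarse_grid, atlas):
        labels = atlas.label_of(coarse_grid.voxel_centres_mm)
        assert len(labels) == coarse_grid.n_voxels
        assert set(labels) <= set(atlas.CANONICAL_LABELS)

    def test_mfc_nested_in_frontal_territory(self, atlas):
        # Every MFC voxel sits in the anterior (y > 0) frontal volume.
        grid = im.make_source_grid(spacing_mm=12.0)
        labels = atlas.label_of(grid.voxel_centres_mm)
        mfc = grid.voxel_centres_mm[labels == "MFC"]
        assert mfc.size > 0
        assert np.all(mfc[:, 1] >= 20.0)


class TestSphereLeadfield:
    def test_radial_dipole_is_silent(self, mid_leadfield, mid_grid):
        rng = np.random.default_rng(0)
        scale = np.abs(mid_leadfield.gains).max()
        for _ in range(10):
            v = int(rng.integers(0, mid_grid.n_voxels))
            loc = mid_grid.voxel_centres_mm[v]
            if np.linalg.norm(loc) < 1e-9:
                continue
            g = mid_leadfield.gains[:, v, :] @ (loc / np.linalg.norm(loc))
            assert np.abs(g).max() < 1e-12 * scale

    def test_dipole_at_sphere_centre_is_silent(self, mid_leadfield, mid_grid):
        v = int(mid_grid.nearest_voxel(np.zeros((1, 3)))[0])
        assert np.allclose(mid_grid.voxel_centres_mm[v], 0.0)
        assert np.abs(mid_leadfield.gains[:, v, :]).max() == 0.0

    def test_gains_linear_in_dipole_moment(self, mid_leadfield, mid_grid):
        rng = np.random.default_rng(1)
        v = int(mid_grid.nearest_voxel(np.array([[30.0, 30.0, 30.0]]))[0])
        u = tangential(mid_grid.voxel_centres_mm[v], rng)
        g1 = mid_leadfield.gain_for(v, u)
        g2 = mid_leadfield.gains[:, v, :] @ (2.0 * u)
        assert np.allclose(g2, 2.0 * g1)

    def test_voxel_outside_sphere_is_rejected(self, small_array):
        bad = im.SourceGrid(np.array([[0.0, 0.0, 99.0]]), 6.0, 96.0, (0, 0, 0))
        with pytest.raises(GeometryError):
            im.sphere_leadfield(small_array, bad)

    def test_sensor_inside_sphere_is_rejected(self, coarse_grid):
        arr = im.make_sensor_array(10, helmet_radius_mm=50.0, seed=0)
        with pytest.raises(GeometryError):
            im.sphere_leadfield(arr, coarse_grid)


class TestBeamformer:
    def _single_source_data(self, lf, grid, v, rng, snr=np.inf, n=1500):
        u = tangential(grid.voxel_centres_mm[v], rng)
        gain = lf.gains[:, v, :] @ u
        sig = np.sin(2 * np.pi * 10 * np.arange(n) / 1000.0)
        clean = gain[:, None] * sig[None, :]
        if np.isfinite(snr):
            sd = np.sqrt(np.mean(clean**2)) / snr
            return clean + sd * rng.standard_normal(clean.shape)
        return clean

    def test_unit_gain_constraint(self, mid_leadfield, mid_grid):
        rng = np.random.default_rng(2)
        data = self._single_source_data(mid_leadfield, mid_grid, 500, rng, snr=10)
        Q, W = im.beamform(data, mid_leadfield, 0.05, return_weights=True)
        L = mid_leadfield.gains
        live = np.abs(W).sum(axis=1) > 0
        # For the selected orientation u, w = C^-1 L u / (u^T M u) with u an
        # eigenvector of M, hence w^T L recovers u itself (a unit vector) and
        # the gain w^T (L u) is exactly 1.
        wl = np.einsum("vs,svi->vi", W, L)
        norms = np.linalg.norm(wl[live], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        u = wl[live] / norms[:, None]
        gains = np.einsum("vs,svi,vi->v", W[live], L[:, live, :], u)
        assert np.allclose(gains, 1.0, atol=1e-9)

    def test_single_source_recovered_within_one_voxel(
        self, mid_leadfield, mid_grid
    ):
        rng = np.random.default_rng(3)
        radii = np.linalg.norm(mid_grid.voxel_centres_mm, axis=1)
        eligible = np.flatnonzero(radii >= 15.0)
        for _ in range(5):
            v = int(rng.choice(eligible))
            data = self._single_source_data(mid_leadfield, mid_grid, v, rng, snr=10)
            Q = im.beamform(data, mid_leadfield, 0.05)
            est = int(np.argmax(im.accumulate_source_imaging(Q).strength))
            err = np.linalg.norm(
                mid_grid.voxel_centres_mm[est] - mid_grid.voxel_centres_mm[v]
            )
            assert err <= mid_grid.spacing_mm

    def test_two_uncorrelated_sources_recovered(self, mid_leadfield, mid_grid):
        rng = np.random.default_rng(4)
        va = int(mid_grid.nearest_voxel(np.array([[0.0, 48.0, 36.0]]))[0])
        vb = int(mid_grid.nearest_voxel(np.array([[0.0, -48.0, 36.0]]))[0])
        n = 2000
        t = np.arange(n) / 1000.0
        sa = np.sin(2 * np.pi * 10 * t)
        sb = np.sign(np.sin(2 * np.pi * 7 * t + 1.0))  # uncorrelated waveform
        ga = mid_leadfield.gains[:, va, :] @ tangential(mid_grid.voxel_centres_mm[va], rng)
        gb = mid_leadfield.gains[:, vb, :] @ tangential(mid_grid.voxel_centres_mm[vb], rng)
        clean = ga[:, None] * sa + gb[:, None] * sb
        sd = np.sqrt(np.mean(clean**2)) / 10.0
        data = clean + sd * rng.standard_normal(clean.shape)
        strength = im.accumulate_source_imaging(im.beamform(data, mid_leadfield, 0.05)).strength
        # the two strongest well-separated peaks must bracket the truth
        order = np.argsort(strength)[::-1]
        found = {va: False, vb: False}
        for cand in order[:40]:
            for v in (va, vb):
                d = np.linalg.norm(
                    mid_grid.voxel_centres_mm[cand] - mid_grid.voxel_centres_mm[v]
                )
                if d <= 2 * mid_grid.spacing_mm:
                    found[v] = True
        assert all(found.values())

    def test_asi_invariant_to_channel_permutation(self, coarse_leadfield, coarse_grid):
        rng = np.random.default_rng(5)
        data = self._single_source_data(coarse_leadfield, coarse_grid, 40, rng, snr=10)
        perm = rng.permutation(data.shape[0])
        lf_perm = im.LeadField(coarse_leadfield.gains[perm])
        s1 = im.accumulate_source_imaging(im.beamform(data, coarse_leadfield, 0.05)).strength
        s2 = im.accumulate_source_imaging(im.beamform(data[perm], lf_perm, 0.05)).strength
        assert np.allclose(s1, s2, rtol=1e-8, atol=1e-30)

    def test_strength_homogeneous_in_data_scale(self, coarse_leadfield, coarse_grid):
        rng = np.random.default_rng(6)
        data = self._single_source_data(coarse_leadfield, coarse_grid, 40, rng, snr=10)
        s1 = im.accumulate_source_imaging(im.beamform(data, coarse_leadfield, 0.05)).strength
        s2 = im.accumulate_source_imaging(im.beamform(-3.0 * data, coarse_leadfield, 0.05)).strength
        assert np.allclose(s2, 3.0 * s1, rtol=1e-8, atol=1e-30)

    def test_short_unregularized_segment_rejected(self, coarse_leadfield):
        data = np.random.default_rng(7).standard_normal((30, 20))
        with pytest.raises(ConfigurationError):
            im.beamform(data, coarse_leadfield, regularization=0.0)


class TestAccumulatedSourceImaging:
    def test_constant_unit_activity_sums_to_n(self):
        Q = np.zeros((5, 100))
        Q[2] = 1.0
        asi = accumulate_source_imaging(Q)
        assert asi.strength[2] == 100.0
        assert asi.n_timepoints == 100

    def test_signed_mode_cancels_zero_mean_oscillation(self):
        t = np.arange(1000)
        Q = np.sin(2 * np.pi * 5 * t / 1000.0)[None, :]
        signed = accumulate_source_imaging(Q, mode="signed")
        magnitude = accumulate_source_imaging(Q, mode="magnitude")
        assert abs(signed.strength[0]) < 1e-9
        assert magnitude.strength[0] > 100.0

    def test_accumulation_additive_over_concatenated_segments(self):
        rng = np.random.default_rng(8)
        qa, qb = rng.standard_normal((3, 50)), rng.standard_normal((3, 70))
        whole = accumulate_source_imaging(np.concatenate([qa, qb], axis=1))
        parts = accumulate_source_imaging(qa).strength + accumulate_source_imaging(qb).strength
        assert np.allclose(whole.strength, parts)

    def test_empty_segment_rejected(self):
        with pytest.raises(ConfigurationError):
            accumulate_source_imaging(np.zeros((3, 0)))


class TestPredominantRegion:
    def test_simulated_mfc_source_labelled_mfc(
        self, mid_array, mid_grid, mid_leadfield, atlas
    ):
        rng = np.random.default_rng(9)
        labels = atlas.label_of(mid_grid.voxel_centres_mm)
        v = int(np.flatnonzero(labels == "MFC")[3])
        u = tangential(mid_grid.voxel_centres_mm[v], rng)
        gain = mid_leadfield.gains[:, v, :] @ u
        sig = np.sin(2 * np.pi * 10 * np.arange(1500) / 1000.0)
        clean = gain[:, None] * sig[None, :]
        sd = np.sqrt(np.mean(clean**2)) / 10.0
        data = clean + sd * rng.standard_normal(clean.shape)
        asi = im.accumulate_source_imaging(im.beamform(data, mid_leadfield, 0.05))
        label, peak = im.predominant_region(asi, atlas, mid_grid)
        assert label == "MFC"

    def test_all_zero_map_raises(self, coarse_grid, atlas):
        asi = AsiMap(np.zeros(coarse_grid.n_voxels), 10)
        with pytest.raises(NoSourceError):
            im.predominant_region(asi, atlas, coarse_grid)

    def test_tie_broken_by_atlas_priority(self, coarse_grid, atlas):
        labels = atlas.label_of(coarse_grid.voxel_centres_mm)
        v_fc = int(np.flatnonzero(labels == "FC")[0])
        v_th = int(np.flatnonzero(labels == "TH")[0])
        s = np.zeros(coarse_grid.n_voxels)
        s[v_fc] = s[v_th] = 1.0
        label, peak = im.predominant_region(AsiMap(s, 1), atlas, coarse_grid)
        assert label == "FC"  # FC boxes precede TH in priority order
        assert peak == v_fc
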