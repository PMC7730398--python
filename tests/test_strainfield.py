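"""Strain fields, ray affine strain, Poisson ratios, correlations, CNR."""

import numpy as np
import pandas as pd
import pytest

from ict.strainfield import (
    cnr_planes,
    correlate_parameters,
    displacement_for_strain,
    poisson_ratio,
    profile_by_position,
    ray_affine_strain,
    smooth_strain,
)


def _scatter_samples(u_fn, ncell=60, nz=120, voxel=1.62, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(ncell):
        x0, y0 = rng.uniform(0, 400, 2)
        z = np.arange(nz) * voxel
        ux, uy, uz = u_fn(x0, y0, z)
        frames.append(pd.DataFrame(dict(
            cell_id=c, x=x0, y=y0, z=z,
            u_x=np.broadcast_to(ux, z.shape).copy(),
            u_y=np.broadcast_to(uy, z.shape).copy(),
            u_z=np.broadcast_to(uz, z.shape).copy(),
        )))
    return pd.concat(frames, ignore_index=True)


class TestSmoothStrain:
    def test_affine_field_recovered_everywhere(self):
        df = _scatter_samples(lambda x, y, z: (8e-3 * (x - 200), 0.0, 0.0))
        sf = smooth_strain(df, resolution=50, voxel_size=1.62)
        s = sf.samples
        assert np.abs(s.eps_RR - 8e-3).max() < 5e-5
        assert np.abs(s.eps_TT).max() < 5e-5
        assert np.abs(s.eps_LL).max() < 5e-5

    def test_zero_displacement_zero_strain(self):
        df = _scatter_samples(lambda x, y, z: (0.0, 0.0, 0.0))
        sf = smooth_strain(df, resolution=50, voxel_size=1.62)
        assert np.nanmax(np.abs(sf.samples[["eps_RR", "eps_TT", "eps_LL",
                                            "eps_RT"]].to_numpy())) < 1e-12

    def test_pure_shear_definition(self):
        gamma = 1e-2
        df = _scatter_samples(lambda x, y, z: (gamma * z, 0.0, 0.0))
        sf = smooth_strain(df, resolution=50, voxel_size=1.62)
        s = sf.samples
        assert np.nanmedian(s.eps_RL) == pytest.approx(gamma / 2, rel=1e-6)
        assert np.nanmax(np.abs(s.eps_RR)) < 1e-8
        assert np.nanmax(np.abs(s.eps_LL)) < 1e-8

    def test_symmetry_by_construction(self):
        # eps_ij = eps_ji holds because only the symmetric combination is
        # ever formed; check the shear of a transposed field matches
        g = 2e-3
        df_a = _scatter_samples(lambda x, y, z: (0.0, 0.0, g * x))
        df_b = _scatter_samples(lambda x, y, z: (g * z, 0.0, 0.0))
        sa = smooth_strain(df_a, resolution=50, voxel_size=1.62).samples
        sb = smooth_strain(df_b, resolution=50, voxel_size=1.62).samples
        assert np.nanmedian(sa.eps_RL) == pytest.approx(g / 2, rel=1e-3)
        assert np.nanmedian(sb.eps_RL) == pytest.approx(g / 2, rel=1e-3)

    def test_too_few_samples_rejected(self):
        df = _scatter_samples(lambda x, y, z: (0, 0, 0), ncell=1, nz=5)
        with pytest.raises(ValueError):
            smooth_strain(df, resolution=50)


class TestRayAffineStrain:
    _lattice = np.array([[0, 0], [12, 0], [0, 10], [12, 10], [6, 5],
                         [6, 15], [0, 20]], dtype=float)

    def test_rigid_translation_zero_strain(self):
        rs = ray_affine_strain(self._lattice, self._lattice + [3.0, -2.0])
        assert np.abs(rs.eps_ray).max() < 1e-12
        assert rs.u_ray.max() < 1e-9

    def test_axial_compression_exact(self):
        test = self._lattice * np.array([1.0, 0.98])
        rs = ray_affine_strain(self._lattice, test)
        assert rs.eps_ray[1, 1] == pytest.approx(-0.02, abs=1e-12)
        assert rs.eps_ray[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_lumen_is_nonaffine(self):
        # a dense lattice localizes a single off-lattice displacement in the
        # residual while the affine part stays small
        gy, gz = np.meshgrid(np.arange(4) * 10.0, np.arange(5) * 10.0)
        ref = np.stack([gy.ravel(), gz.ravel()], axis=1)
        test = ref.copy()
        test[7] += [0.0, 2.0]
        rs = ray_affine_strain(ref, test)
        # least squares absorbs the leverage share (~1/n) of the outlier
        assert rs.u_ray[7] == pytest.approx(2.0, rel=0.25)
        assert rs.u_ray[np.arange(len(ref)) != 7].max() < 0.5
        assert np.abs(rs.eps_ray).max() < 0.01

    def test_collinear_lattice_flagged(self):
        line = np.stack([np.zeros(5), np.arange(5.0)], axis=1)
        rs = ray_affine_strain(line, line * np.array([1.0, 1.01]))
        assert rs.collinear
        assert rs.eps_ray[1, 1] == pytest.approx(0.01, abs=1e-9)

    def test_too_few_lumens_rejected(self):
        with pytest.raises(ValueError):
            ray_affine_strain(self._lattice[:2], self._lattice[:2])


class TestPoissonRatio:
    def test_printed_arithmetic(self):
        _, avg = poisson_ratio(np.array([-0.00752]), np.array([0.008]))
        assert avg == pytest.approx(0.94)

    def test_zero_numerator(self):
        _, avg = poisson_ratio(np.zeros(5), np.full(5, 0.008))
        assert avg == 0.0

    def test_imposed_unit_ratio_recovered(self):
        rng = np.random.default_rng(1)
        den = rng.uniform(5e-3, 1e-2, 500)
        num = -den + rng.normal(0, 5e-5, 500)
        _, avg = poisson_ratio(num, den)
        assert avg == pytest.approx(1.0, abs=0.02)

    def test_fully_masked_warns(self):
        with pytest.warns(UserWarning):
            _, avg = poisson_ratio(np.ones(3), np.full(3, 1e-9))
        assert np.isnan(avg)


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=2000)
        df = pd.DataFrame({"a": a, "b": -a, "c": rng.normal(size=2000)})
        r = correlate_parameters(df)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert abs(r.loc["a", "c"]) < 0.05
        p = r.attrs["p_values"]
        assert p.loc["a", "b"] < 1e-10

    def test_null_correlation_bound_large_n(self):
        rng = np.random.default_rng(3)
        n = 1_000_000
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        r = correlate_parameters(df)
        # null sd is 1/sqrt(n) = 1e-3; 4 sd covers the 95% band amply
        assert abs(r.loc["a", "b"]) < 0.004

    def test_constant_field_missing(self):
        df = pd.DataFrame({"a": np.ones(100), "b": np.arange(100.0)})
        r = correlate_parameters(df)
        assert np.isnan(r.loc["a", "b"])


class TestCNR:
    def test_bump_height_measured_in_noise_units(self):
        rng = np.random.default_rng(0)
        pos = np.arange(2000.0)
        prof = rng.normal(0, 1, 2000)
        prof[np.abs(pos - 1000.0) <= 20.0] += 10.0
        out = cnr_planes(pos, prof, [1000.0], band_width=40.0)
        assert out.cnr.iloc[0] == pytest.approx(10.0, abs=0.5)

    def test_flat_profile_near_zero(self):
        rng = np.random.default_rng(1)
        pos = np.arange(1000.0)
        out = cnr_planes(pos, rng.normal(0, 1, 1000), [300.0, 700.0])
        assert np.all(out.cnr < 1.0)

    def test_offset_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(2)
        pos = np.arange(1500.0)
        prof = rng.normal(0, 1, 1500)
        prof[(pos > 700) & (pos < 760)] += 6.0
        base = cnr_planes(pos, prof, [730.0], band_width=60.0).cnr.iloc[0]
        shifted = cnr_planes(pos, prof + 123.0, [730.0],
                             band_width=60.0).cnr.iloc[0]
        doubled = cnr_planes(pos, prof * 2, [730.0],
                             band_width=60.0).cnr.iloc[0]
        assert shifted == pytest.approx(base, rel=1e-9)
        assert doubled == pytest.approx(base, rel=1e-9)  # sd doubles too
        amp = prof.copy()
        amp[(pos > 700) & (pos < 760)] += 6.0  # bump now 2x over same noise
        assert cnr_planes(pos, amp, [730.0], band_width=60.0).cnr.iloc[0] == \
            pytest.approx(2 * base, rel=0.15)

    def test_band_on_true_compression_plane_wins(self, tiny_phantom):
        from ict.phantom import apply_compression_band

        vol, gt = tiny_phantom
        ext_z = vol.shape[2] * vol.voxel_size
        center = ext_z / 2
        _, gt2 = apply_compression_band(vol, gt, center, 80.0, -0.3)
        band = gt2.deformations[0]
        z = np.linspace(0, ext_z, 400)
        profile = band.strain_zz(z)
        cands = [center, center - 90, center + 90, 30.0, ext_z - 30.0]
        out = cnr_planes(z, profile, cands, band_width=50.0)
        assert out.cnr.idxmax() == 0  # the true plane position


class TestProfiles:
    def test_single_cell_profile_is_its_channel(self):
        df = pd.DataFrame({"z": [5.0, 15.0, 25.0], "v": [1.0, 2.0, 3.0]})
        out = profile_by_position(df, "z", ["v"], bin_width=10.0)
        assert list(out.v.dropna()) == [1.0, 2.0, 3.0]

    def test_constant_channel_flat(self):
        df = pd.DataFrame({"z": np.linspace(0, 100, 50), "v": 7.0})
        out = profile_by_position(df, "z", ["v"], bin_width=20.0)
        assert np.allclose(out.v.dropna(), 7.0)

    def test_empty_bins_missing_not_zero(self):
        df = pd.DataFrame({"z": [5.0, 95.0], "v": [1.0, 2.0]})
        out = profile_by_position(df, "z", ["v"], bin_width=10.0)
        assert out.v.isna().sum() >= 7

    def test_ring_major_axis_decreases_earlywood_to_latewood(
            self, segmented_tiny):
        from ict.cellparam import parameterize_all

        _, gt, _, lv = segmented_tiny
        profs = parameterize_all(lv, cell_ids=lv.ids_of("tracheid"),
                                 min_length=82)
        rows = []
        for p in profs.values():
            tab = p.table[p.table.valid]
            rows.append({"x": tab.c_X.mean(), "e_a": tab.e_a.mean()})
        df = pd.DataFrame(rows)
        prof = profile_by_position(df, "x", ["e_a"], bin_width=40.0)
        ok = prof.dropna()
        slope = np.polyfit(ok.position, ok.e_a, 1)[0]
        assert slope < 0  # lumens shrink towards latewood


def test_displacement_equivalents():
    # a 5e-5 strain over a 35 um lumen is a nanometre-scale displacement
    assert displacement_for_strain(35.0, 5e-5) == pytest.approx(1.75)
    assert displacement_for_strain(3.5, 0.008) == pytest.approx(28.0)
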