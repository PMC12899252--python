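"""Unit tests for the crystallographic data model and transforms."""

import numpy as np
import pytest

from hdmphase import core
from hdmphase.core import (
    ComplexSF,
    DensityMap,
    GridContext,
    ReflectionSet,
    SpaceGroupInfo,
    Status,
    UnitCell,
    assign_flags,
    choose_grid,
    fft_density_to_sf,
    read_reflections,
    reduce_to_asu,
    rng_for,
    sf_to_density,
    write_reflections,
)


class TestUnitCell:
    def test_orthogonal_d_spacing_closed_form(self):
        cell = UnitCell(10.0, 10.0, 10.0)
        hkl = np.array([[1, 0, 0], [1, 1, 0], [2, 1, 2]])
        expect = 1.0 / np.sqrt((hkl**2).sum(axis=1) / 100.0)
        np.testing.assert_allclose(cell.d(hkl), expect, rtol=1e-12)

    def test_volume_triclinic(self):
        cell = UnitCell(10, 12, 14, 80, 95, 100)
        g = cell.metric()
        np.testing.assert_allclose(cell.volume, np.sqrt(np.linalg.det(g)), rtol=1e-10)

    @pytest.mark.parametrize("bad", [dict(a=-1), dict(alpha=0.0), dict(gamma=180.0)])
    def test_invalid_cells_rejected(self, bad):
        kw = dict(a=10, b=10, c=10, alpha=90, beta=90, gamma=90)
        kw.update(bad)
        with pytest.raises(ValueError):
            UnitCell(**kw)


class TestSpaceGroup:
    def test_unknown_symbol(self):
        with pytest.raises(ValueError, match="unknown space group"):
            SpaceGroupInfo.from_symbol("Z 9 9 9")

    def test_p1_properties(self):
        sg = SpaceGroupInfo.from_symbol("P 1")
        assert sg.n_ops == 1
        assert sg.polar_axes == (True, True, True)
        assert sg.has_inversion_ambiguity

    def test_p212121_symops_closed_and_shifts(self):
        sg = SpaceGroupInfo.from_symbol("P 21 21 21")
        assert sg.n_ops == 4
        # identity present
        assert any(
            np.array_equal(r, np.eye(3, dtype=int)) and np.allclose(t, 0)
            for r, t in sg.symops
        )
        # closure under composition modulo lattice translations
        keys = {
            (tuple(r.ravel()), tuple(np.round(t * 24).astype(int) % 24))
            for r, t in sg.symops
        }
        for r1, t1 in sg.symops:
            for r2, t2 in sg.symops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                assert (tuple(r.ravel()), tuple(np.round(t * 24).astype(int) % 24)) in keys
        # origin shifts: all half-cell translations
        assert set(sg.allowed_origin_shifts) == {
            (x, y, z) for x in (0, 0.5) for y in (0, 0.5) for z in (0, 0.5)
        }
        assert sg.polar_axes == (False, False, False)

    def test_centric_reflections_p21(self):
        sg = SpaceGroupInfo.from_symbol("P 1 21 1")
        # h0l reflections are centric in P21 (b unique)
        assert sg.centric(np.array([[1, 0, 3]]))[0]
        assert not sg.centric(np.array([[1, 1, 3]]))[0]

    def test_asu_reduction_identifies_mates(self):
        sg = SpaceGroupInfo.from_symbol("P 21 21 21")
        h = np.array([[1, 2, 3]])
        mates = [h[0] @ r for r, _ in sg.symops] + [-h[0] @ r for r, _ in sg.symops]
        reps = reduce_to_asu(np.array(mates), sg)
        assert (reps == reps[0]).all()


class TestReflectionIO:
    def test_text_file_parse_and_d(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text(
            "CELL 10 10 10 90 90 90\nSPACEGROUP P 1\nDMIN 2.0\n"
            "1 0 0 5.0 0.1\n2 1 0 4.0 0.1\n2 2 2 3.0 0.1\n"
        )
        rs = read_reflections(p)
        assert len(rs) == 3
        np.testing.assert_allclose(rs.d, [10.0, 10 / np.sqrt(5), 10 / np.sqrt(12)])
        assert (rs.status == Status.WORK).all()

    def test_duplicate_after_reduction_rejected(self, tmp_path):
        p = tmp_path / "r.txt"
        # (1,0,0) and (-1,0,0) are Friedel mates -> same unique reflection
        p.write_text(
            "CELL 10 10 10 90 90 90\nSPACEGROUP P 21 21 21\n"
            "1 0 0 5.0 0.1\n-1 0 0 5.0 0.1\n"
        )
        with pytest.raises(ValueError, match="reduces to|duplicate"):
            read_reflections(p)

    def test_unknown_space_group_in_file(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("CELL 10 10 10 90 90 90\nSPACEGROUP Q 5\n1 0 0 5 0.1\n")
        with pytest.raises(ValueError, match="unknown space group"):
            read_reflections(p)

    def test_text_round_trip_bit_exact(self, tmp_path, random_refls):
        rs = assign_flags(random_refls, free_frac=0.05, seed=3)
        p = tmp_path / "rt.txt"
        write_reflections(p, rs)
        back = read_reflections(p)
        np.testing.assert_array_equal(back.hkl, rs.hkl)
        np.testing.assert_array_equal(back.f_obs, rs.f_obs)
        np.testing.assert_array_equal(back.sig_f, rs.sig_f)
        np.testing.assert_array_equal(back.status, rs.status)
        assert back.cell == rs.cell
        assert back.sg.symbol == rs.sg.symbol

    def test_mtz_round_trip(self, tmp_path, random_refls):
        rs = assign_flags(random_refls, free_frac=0.05, seed=3)
        p = tmp_path / "rt.mtz"
        write_reflections(p, rs)
        back = read_reflections(p)
        order = np.lexsort(back.hkl.T)
        order_ref = np.lexsort(rs.hkl.T)
        np.testing.assert_array_equal(back.hkl[order], rs.hkl[order_ref])
        np.testing.assert_allclose(back.f_obs[order], rs.f_obs[order_ref], rtol=1e-6)
        assert (back.status == Status.FREE).sum() == (rs.status == Status.FREE).sum()


class TestAssignFlags:
    def test_free_fraction_count_exact(self, random_refls):
        # pad to exactly 1000 reflections is overkill; use the real count
        rs = random_refls
        out = assign_flags(rs, free_frac=0.01, sig_ratio=np.inf, d_low_cut=np.inf, seed=1)
        assert (out.status == Status.FREE).sum() == round(len(rs) * 0.01)

    def test_large_error_rule(self, random_refls):
        rs = random_refls.copy()
        rs.sig_f = rs.sig_f.copy()
        rs.sig_f[5] = 3.0 * rs.f_obs[5]
        out = assign_flags(rs, free_frac=0.0, sig_ratio=2.0, d_low_cut=np.inf)
        assert out.status[5] == Status.LARGE_ERROR
        assert (out.status == Status.LARGE_ERROR).sum() >= 1

    def test_low_res_rule_and_precedence(self, random_refls):
        rs = random_refls.copy()
        rs.sig_f = np.zeros(len(rs))
        rs.sig_f[0] = 10 * rs.f_obs[0]  # (0,*) low-res candidates too
        out = assign_flags(rs, free_frac=0.0, sig_ratio=2.0, d_low_cut=10.0)
        low = (rs.d > 10.0) & ~(rs.sig_f > 2 * rs.f_obs)
        assert (out.status[low] == Status.LOW_RES).all()
        # large_error wins over low_res
        assert out.status[0] == Status.LARGE_ERROR

    def test_zero_fraction_identity(self, random_refls):
        out = assign_flags(random_refls, free_frac=0.0, sig_ratio=np.inf, d_low_cut=np.inf)
        assert (out.status == Status.WORK).all()

    def test_pure_function_of_seed(self, random_refls):
        a = assign_flags(random_refls, free_frac=0.05, seed=7)
        b = assign_flags(random_refls, free_frac=0.05, seed=7)
        c = assign_flags(random_refls, free_frac=0.05, seed=8)
        np.testing.assert_array_equal(a.status, b.status)
        assert not np.array_equal(a.status, c.status)


def _direct_dft(values, hkl):
    """Brute-force DFT oracle: F(h) = sum_x rho(x) exp(-2 pi i h.x)."""
    grid = values.shape
    out = np.zeros(len(hkl), dtype=complex)
    idx = np.indices(grid).reshape(3, -1).T / np.array(grid)
    flat = values.ravel()
    for i, h in enumerate(hkl):
        out[i] = (flat * np.exp(-2j * np.pi * (idx @ h))).sum()
    return out


class TestFourier:
    def test_constant_map_dc_only(self, random_refls):
        cell = random_refls.cell
        dmap = DensityMap(np.full((8, 8, 8), 3.7), cell)
        sf = fft_density_to_sf(dmap, random_refls)
        np.testing.assert_allclose(sf.amplitude, 0.0, atol=1e-9)

    def test_impulse_flat_spectrum(self, random_refls):
        vals = np.zeros((8, 8, 8))
        vals[2, 3, 4] = 2.5
        sf = fft_density_to_sf(DensityMap(vals, random_refls.cell), random_refls)
        np.testing.assert_allclose(sf.amplitude, 2.5, rtol=1e-12)

    def test_matches_direct_dft_oracle(self, random_refls):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((8, 8, 8))
        sf = fft_density_to_sf(DensityMap(vals, random_refls.cell), random_refls)
        oracle = _direct_dft(vals, random_refls.hkl)
        np.testing.assert_allclose(sf.f, oracle, atol=1e-9)

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((16, 16, 16))
        F = np.fft.fftn(vals)
        lhs = (np.abs(F) ** 2).sum() / vals.size
        rhs = (vals**2).sum()
        assert abs(lhs - rhs) / rhs < 1e-10

    def test_round_trip_band_limited_map(self, p1_toy):
        """Forward then inverse with unchanged coefficients reproduces the map."""
        rs, truth = p1_toy.rs, p1_toy.truth
        ctx = p1_toy.ctx
        dmap = sf_to_density(truth, rs, ctx.grid, ctx=ctx)
        sf2 = fft_density_to_sf(dmap, rs, ctx=ctx)
        np.testing.assert_allclose(sf2.f, truth.f, atol=1e-8 * np.abs(truth.f).max())

    def test_grid_too_coarse_rejected(self):
        cell = UnitCell(20, 20, 20)
        sg = SpaceGroupInfo.from_symbol("P 1")
        with pytest.raises(ValueError, match="too coarse"):
            choose_grid(cell, sg, spacing=1.5, d_min=2.0)

    def test_symmetrized_map_has_equal_mate_amplitudes(self, p212121_toy):
        ctx = p212121_toy.ctx
        rs = p212121_toy.rs
        rng = np.random.default_rng(2)
        vals = ctx.symmetrize(rng.random(ctx.grid))
        F = np.fft.fftn(vals)
        # compare each reflection's amplitude with one symmetry mate
        for i in range(0, len(rs), 97):
            h = rs.hkl[i]
            rot, _ = rs.sg.symops[1]
            mate = h @ rot
            a1 = np.abs(F[tuple(h % ctx.grid)])
            a2 = np.abs(F[tuple(mate % np.array(ctx.grid))])
            assert a2 == pytest.approx(a1, rel=1e-8)

    def test_half_spectrum_gather_matches_full(self, p212121_toy):
        ctx = p212121_toy.ctx
        rng = np.random.default_rng(3)
        vals = rng.random(ctx.grid)
        full = ctx.gather(ctx.sf_grid(vals))
        half = ctx.rgather(ctx.rsf_grid(vals))
        np.testing.assert_allclose(half, full, atol=1e-9)


class TestRng:
    def test_stream_splitting_reproducible_and_independent(self):
        a = rng_for(3, "init", 0).random(5)
        b = rng_for(3, "init", 0).random(5)
        c = rng_for(3, "init", 1).random(5)
        d = rng_for(3, "flags", 0).random(5)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert not np.array_equal(a, d)

    def test_unknown_purpose_rejected(self):
        with pytest.raises(ValueError):
            rng_for(3, "nope")


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            core.PhasingConfig(algorithm="hdm_f9")
        with pytest.raises(ValueError):
            core.PhasingConfig(scheme="magic")
        with pytest.raises(ValueError):
            core.PhasingConfig(solvent_fraction=1.5)
        with pytest.raises(ValueError):
            core.PhasingConfig(n_iter=100, n_finish=200)
        # degenerate n_finish == n_iter is allowed (pure PA/PB alternation)
        core.PhasingConfig(n_iter=100, n_finish=100)
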