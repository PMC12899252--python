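"""Projector laws: PB amplitude replacement, PA histogram matching."""

import numpy as np
import pytest

from hdmphase.core import (
    ComplexSF,
    DensityMap,
    GridContext,
    Mask,
    ReflectionSet,
    SpaceGroupInfo,
    Status,
    UnitCell,
)
from hdmphase.projections import (
    HistogramRef,
    fill_missing,
    make_reference_histogram,
    project_fourier,
    project_fourier_grid,
    project_real,
    scale_factor,
)


def _sf(rs, amps, phases_deg=None):
    ph = np.zeros(len(rs)) if phases_deg is None else np.asarray(phases_deg)
    return ComplexSF(rs.hkl, np.asarray(amps) * np.exp(1j * np.radians(ph)))


class TestScaleFactor:
    def test_identity_when_equal(self, random_refls):
        sf = _sf(random_refls, random_refls.f_obs)
        assert scale_factor(random_refls, sf) == pytest.approx(1.0)

    def test_half_when_doubled(self, random_refls):
        sf = _sf(random_refls, 2.0 * random_refls.f_obs)
        assert scale_factor(random_refls, sf) == pytest.approx(0.5)

    def test_hand_arithmetic_small_table(self):
        cell = UnitCell(10, 10, 10)
        sg = SpaceGroupInfo.from_symbol("P 1")
        hkl = np.array([[1, 0, 0], [2, 0, 0], [2, 1, 0], [3, 0, 0], [3, 2, 1]])
        fobs = np.array([10.0, 20.0, 5.0, 8.0, 7.0])
        rs = ReflectionSet(cell, sg, 2.0, hkl, fobs, np.zeros(5), np.zeros(5, np.int8))
        fcal = np.array([4.0, 10.0, 2.0, 3.0, 6.0])
        # by hand: 50 / 25 = 2
        assert scale_factor(rs, _sf(rs, fcal)) == pytest.approx(50.0 / 25.0)

    def test_degenerate_all_zero_fcal(self, random_refls):
        with pytest.raises(ValueError, match="degenerate"):
            scale_factor(random_refls, _sf(random_refls, np.zeros(len(random_refls))))


class TestFillMissing:
    def test_ratio_one_returns_fcal(self, random_refls):
        rs = random_refls.copy()
        rs.status[3] = Status.FREE
        sf = _sf(rs, rs.f_obs)
        filled = fill_missing(rs, sf)
        assert filled[3] == pytest.approx(rs.f_obs[3])

    def test_plug_in_ratio_two(self):
        cell = UnitCell(10, 10, 10)
        sg = SpaceGroupInfo.from_symbol("P 1")
        hkl = np.array([[1, 0, 0], [2, 0, 0], [2, 1, 0]])
        # work sums: obs 100, cal 50 -> ratio 2; missing fcal 3 -> 6
        rs = ReflectionSet(
            cell, sg, 2.0, hkl,
            np.array([60.0, 40.0, 0.0]), np.zeros(3),
            np.array([Status.WORK, Status.WORK, Status.MISSING], np.int8),
        )
        sf = _sf(rs, np.array([30.0, 20.0, 3.0]))
        assert fill_missing(rs, sf)[2] == pytest.approx(6.0)

    def test_matches_independent_recomputation(self, random_refls):
        rng = np.random.default_rng(5)
        rs = random_refls.copy()
        rs.status[rng.choice(len(rs), 10, replace=False)] = Status.MISSING
        fcal = rng.uniform(1, 50, len(rs))
        sf = _sf(rs, fcal)
        filled = fill_missing(rs, sf)
        work = rs.status == Status.WORK
        ratio = rs.f_obs[work].sum() / fcal[work].sum()
        expect = np.where(work, rs.f_obs, ratio * fcal)
        np.testing.assert_allclose(filled, expect, rtol=1e-12)

    def test_scale_equivariance(self, random_refls):
        rs = random_refls.copy()
        rs.status[1] = Status.MISSING
        sf = _sf(rs, np.linspace(1, 60, len(rs)))
        a = fill_missing(rs, sf)
        rs2 = rs.copy()
        rs2.f_obs = 3.0 * rs2.f_obs
        b = fill_missing(rs2, sf)
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)


class TestProjectFourier:
    def test_fixed_point_of_consistent_map(self, p1_toy):
        out = project_fourier(p1_toy.true_map, p1_toy.rs, ctx=p1_toy.ctx)
        np.testing.assert_allclose(
            out.values, p1_toy.true_map.values, atol=1e-8 * np.abs(p1_toy.true_map.values).max()
        )

    def test_idempotent_on_random_maps(self, p1_toy):
        rng = np.random.default_rng(7)
        vals = rng.random(p1_toy.ctx.grid)
        once, _ = project_fourier_grid(vals, p1_toy.ctx)
        twice, _ = project_fourier_grid(once, p1_toy.ctx)
        assert np.abs(twice - once).max() < 1e-8 * np.abs(once).max()

    def test_idempotent_with_weights(self, p1_toy):
        rng = np.random.default_rng(8)
        vals = rng.random(p1_toy.ctx.grid)
        w = np.exp(-2 * (np.pi * 0.5 * p1_toy.rs.s) ** 2)
        once, _ = project_fourier_grid(vals, p1_toy.ctx, w)
        twice, _ = project_fourier_grid(once, p1_toy.ctx, w)
        assert np.abs(twice - once).max() < 1e-8 * np.abs(once).max()

    def test_preserves_work_phases_and_sets_amplitudes(self, p1_toy):
        rng = np.random.default_rng(9)
        ctx = p1_toy.ctx
        rs = p1_toy.rs
        vals = rng.random(ctx.grid)
        out, cache = project_fourier_grid(vals, ctx)
        f_in = cache["fcal"].f
        f_out = ctx.rgather(ctx.rsf_grid(out))
        # phases retained
        dphi = np.angle(f_out * np.conj(f_in))
        np.testing.assert_allclose(dphi, 0.0, atol=1e-8)
        # amplitudes equal lambda^-1 |Fobs|
        lam = cache["lambda_pb"]
        np.testing.assert_allclose(np.abs(f_out), rs.f_obs / lam, rtol=1e-9)

    def test_brute_force_oracle_replacement(self, p1_toy):
        """PB equals DFT -> amplitude replacement -> inverse DFT, coefficient
        by coefficient, on the full grid."""
        rng = np.random.default_rng(10)
        ctx = p1_toy.ctx
        rs = p1_toy.rs
        vals = rng.random(ctx.grid)
        out, cache = project_fourier_grid(vals, ctx)
        # oracle: full-spectrum manual replacement; unmeasured coefficients
        # are zeroed (band-limited model) except the F(000) offset
        F = np.fft.fftn(vals)
        lam = cache["lambda_pb"]
        Fo = F.copy().ravel()
        cid = ctx.coeff_refl_id
        unmapped = np.nonzero(cid < 0)[0]
        Fo[unmapped] = 0.0
        Fo[0] = F.ravel()[0]
        for i in np.nonzero(cid >= 0)[0]:
            r = cid[i]
            target = rs.f_obs[r] / lam if rs.status[r] == Status.WORK else np.abs(Fo[i])
            a = np.abs(Fo[i])
            Fo[i] = Fo[i] / a * target if a > 0 else target
        oracle = np.fft.ifftn(Fo.reshape(ctx.grid)).real
        np.testing.assert_allclose(out, oracle, atol=1e-9 * np.abs(oracle).max())

    def test_free_reflections_keep_calculated_amplitude(self, p1_toy):
        rng = np.random.default_rng(11)
        ctx = p1_toy.ctx
        rs = p1_toy.rs.copy()
        rs.status[4] = Status.FREE
        ctx2 = GridContext(rs, ctx.grid)
        vals = rng.random(ctx.grid)
        out, cache = project_fourier_grid(vals, ctx2)
        f_out = ctx2.rgather(ctx2.rsf_grid(out))
        assert np.abs(f_out[4]) == pytest.approx(cache["fcal"].amplitude[4], rel=1e-9)

    def test_all_zero_map_degenerate(self, p1_toy):
        with pytest.raises(ValueError, match="degenerate"):
            project_fourier_grid(np.zeros(p1_toy.ctx.grid), p1_toy.ctx)


class TestProjectReal:
    def _setup(self, n=4):
        cell = UnitCell(8, 8, 8)
        vals = np.zeros((n, n, n))
        inside = np.zeros((n, n, n), dtype=bool)
        return cell, vals, inside

    def test_rank_mapping_oracle_8_voxels(self):
        cell, vals, inside = self._setup()
        flat_idx = [0, 3, 9, 17, 22, 41, 50, 63]
        values = [5.0, -2.0, 7.5, 0.3, 12.0, -8.0, 1.0, 3.3]
        for i, v in zip(flat_idx, values):
            vals.ravel()[i] = v
            inside.ravel()[i] = True
        href = HistogramRef(2.0, (np.arange(8) + 0.5) / 8)
        out = project_real(
            DensityMap(vals, cell), Mask(inside, cell), href
        )
        ranks = np.argsort(np.argsort(values))
        expect = (ranks + 0.5) / 8
        np.testing.assert_allclose(out.values.ravel()[flat_idx], expect, rtol=1e-12)

    def test_solvent_exactly_zero(self, p1_toy):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal(p1_toy.ctx.grid)
        out = project_real(
            DensityMap(vals, p1_toy.rs.cell), p1_toy.true_mask, p1_toy.href
        )
        assert (out.values[~p1_toy.true_mask.inside] == 0.0).all()

    def test_idempotent(self, p1_toy):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(p1_toy.ctx.grid)
        m, h = p1_toy.true_mask, p1_toy.href
        once = project_real(DensityMap(vals, p1_toy.rs.cell), m, h)
        twice = project_real(once, m, h)
        assert np.abs(twice.values - once.values).max() < 1e-8

    def test_idempotent_with_few_quantiles_and_ties(self):
        cell, vals, inside = self._setup(6)
        rng = np.random.default_rng(14)
        inside[:3] = True
        vals[:] = rng.random(vals.shape)
        href = HistogramRef(2.0, np.array([0.0, 1.0, 1.0, 2.0]))
        m = Mask(inside, cell)
        once = project_real(DensityMap(vals, cell), m, href)
        twice = project_real(once, m, href)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_output_histogram_matches_reference(self, p1_toy):
        rng = np.random.default_rng(15)
        vals = rng.standard_normal(p1_toy.ctx.grid)
        m = p1_toy.true_mask
        href = p1_toy.href
        out = project_real(DensityMap(vals, p1_toy.rs.cell), m, href)
        got = np.sort(out.values[m.inside])
        n_q = len(href.quantiles)
        # Kolmogorov distance between achieved and reference CDFs
        grid_q = np.quantile(got, (np.arange(n_q) + 0.5) / n_q)
        ks = np.abs(np.searchsorted(got, href.quantiles) / len(got)
                    - (np.arange(n_q) + 0.5) / n_q).max()
        assert ks < 1.0 / n_q + 0.01

    def test_empty_protein_region_rejected(self):
        cell, vals, inside = self._setup()
        href = HistogramRef(2.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="empty protein region"):
            project_real(DensityMap(vals, cell), Mask(inside, cell), href)


class TestReferenceHistogram:
    def test_constant_model(self, p1_toy):
        vals = np.full(p1_toy.ctx.grid, 2.5)
        href = make_reference_histogram(
            DensityMap(vals, p1_toy.rs.cell), p1_toy.true_mask, 16
        )
        np.testing.assert_allclose(href.quantiles, 2.5)

    def test_two_quantiles_of_1234(self):
        cell = UnitCell(8, 8, 8)
        vals = np.zeros((4, 4, 4))
        inside = np.zeros((4, 4, 4), dtype=bool)
        vals.ravel()[:4] = [1.0, 2.0, 3.0, 4.0]
        inside.ravel()[:4] = True
        href = make_reference_histogram(DensityMap(vals, cell), Mask(inside, cell), 2)
        # documented rule: inverse-CDF interpolation -> lower/upper medians
        np.testing.assert_allclose(href.quantiles, [1.5, 3.5])

    def test_monotone_and_serialization(self, p1_toy, tmp_path):
        href = make_reference_histogram(p1_toy.true_map, p1_toy.true_mask, 64)
        assert (np.diff(href.quantiles) >= 0).all()
        p = tmp_path / "h.txt"
        href.save(p)
        back = HistogramRef.load(p)
        np.testing.assert_allclose(back.quantiles, href.quantiles)

    def test_too_few_quantiles(self, p1_toy):
        with pytest.raises(ValueError):
            make_reference_histogram(p1_toy.true_map, p1_toy.true_mask, 1)
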