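"""Preprocessing, grid fit (against a brute-force oracle), search, filters."""

import numpy as np
import pytest

from prfclust import (
    GridSpec,
    PRFFit,
    PRFParams,
    Run,
    SheetDataset,
    filter_voxels,
    grid_fit,
    make_cluster_sheet,
    search_fit,
    simulate_timeseries,
    spatial_blur,
    temporal_decimate,
    variance_explained,
)
from prfclust.fitting import _demean, blur_weight
from prfclust.prf_model import HRFSpec, convolve_hrf, css_neural_response


def _flat_dataset(series_by_site, coords=None, tr=2.0):
    series = np.asarray(series_by_site, dtype=float)
    if coords is None:
        coords = np.column_stack([np.arange(len(series)), np.zeros(len(series))])
    return SheetDataset(coords, (Run(1.0, series, "r0"),), tr_s=tr)


class TestSpatialBlur:
    def test_constant_field_unchanged(self):
        ds = _flat_dataset(np.ones((5, 10)) * 3.7)
        out = spatial_blur(ds, fwhm_mm=5.0)
        np.testing.assert_allclose(out.runs[0].series, 3.7)

    def test_global_mean_preserved_on_uniform_grid(self):
        rng = np.random.default_rng(0)
        xx, yy = np.meshgrid(np.arange(30), np.arange(30))
        coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        series = rng.standard_normal((900, 8))
        out = spatial_blur(SheetDataset(coords, (Run(1.0, series),)), 5.0)
        # symmetric normalized smoothing nearly preserves the spatial mean
        np.testing.assert_allclose(
            out.runs[0].series.mean(0), series.mean(0), atol=0.01
        )

    def test_impulse_half_maximum_at_half_fwhm(self):
        # the Gaussian weight profile drops to half at fwhm/2
        assert blur_weight(2.5, 5.0) == pytest.approx(0.5, rel=1e-12)
        assert blur_weight(0.0, 5.0) == 1.0

    def test_impulse_spread_follows_weight_profile(self):
        n = 41
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        series = np.zeros((n, 1))
        series[n // 2, 0] = 1.0
        out = spatial_blur(_flat_dataset(series, coords), fwhm_mm=5.0)
        prof = out.runs[0].series[:, 0]
        ratio = prof[n // 2 + 2] / prof[n // 2]  # 2 mm off-center... fwhm 5
        assert ratio == pytest.approx(blur_weight(2.0, 5.0), rel=1e-6)

    def test_missing_coordinates_rejected(self):
        ds = _flat_dataset(np.ones((3, 4)))
        object.__setattr__(ds, "coords_mm", np.empty((0, 2)))
        with pytest.raises(ValueError):
            spatial_blur(ds)


class TestTemporalDecimate:
    def test_hand_block_average(self):
        np.testing.assert_allclose(
            temporal_decimate(np.array([1.0, 3.0, 2.0, 4.0]), 2), [2.0, 3.0]
        )

    def test_factor_one_is_identity(self):
        x = np.arange(7, dtype=float)
        np.testing.assert_array_equal(temporal_decimate(x, 1), x)

    def test_constant_series_stays_constant_at_half_length(self):
        out = temporal_decimate(np.full(10, 2.5), 2)
        assert out.shape == (5,)
        np.testing.assert_allclose(out, 2.5)

    def test_odd_tail_dropped(self):
        np.testing.assert_allclose(temporal_decimate(np.array([1.0, 3.0, 9.0]), 2), [2.0])

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            temporal_decimate(np.arange(4.0), 0)


class TestGridFit:
    def test_exact_recovery_of_on_grid_truth(
        self, snapped_layout, noiseless_dataset, run_apertures, default_grid
    ):
        fits = grid_fit(
            noiseless_dataset, run_apertures, default_grid, decimate_factor=2
        )
        for f, truth in zip(fits, snapped_layout.params):
            assert (f.params.x0, f.params.y0) == (truth.x0, truth.y0)
            assert f.params.sigma == truth.sigma
            assert f.params.n == truth.n
            assert f.params.beta == pytest.approx(truth.beta, abs=1e-9)
            assert f.variance_explained == pytest.approx(1.0, abs=1e-9)
            assert f.retained

    def test_matches_brute_force_exhaustive_argmax(
        self, reduced_grid, run_apertures
    ):
        """The vectorized grid fit must pick the same candidate as an
        independently coded per-candidate loop (prediction built through the
        public forward model, beta by lstsq, Eq.-style score)."""
        layout = make_cluster_sheet(
            n_clusters=1, maps_per_cluster=2, rows_per_map=5, n_ecc_cols=5,
            snap_to_grid=None, seed=4,
        )
        ds = simulate_timeseries(layout, run_apertures, noise_sd=0.7, seed=9)
        fits = grid_fit(ds, run_apertures, reduced_grid, decimate_factor=2)
        hrf = HRFSpec(dt_s=ds.tr_s)
        widths = sorted(run_apertures)

        # ----- independent oracle -----
        cands = []
        for cx, cy in reduced_grid.centers_deg:
            for s in reduced_grid.sigmas_deg:
                for n in reduced_grid.exponents:
                    cands.append((cx, cy, s, n))
        pred_cache = {}
        for c in cands:
            blocks = []
            for w in widths:
                neural = css_neural_response(
                    run_apertures[w], PRFParams(c[0], c[1], c[2], c[3])
                )
                bold = temporal_decimate(convolve_hrf(neural, hrf), 2)
                blocks.append(bold - bold.mean())
            pred_cache[c] = {w: b for w, b in zip(widths, blocks)}

        for site in range(0, ds.n_sites, 3):
            data = np.concatenate(
                [
                    _demean(temporal_decimate(r.series[site], 2))
                    for r in ds.runs
                ]
            )
            best, best_ve = None, -np.inf
            for c in cands:
                pred = np.concatenate(
                    [pred_cache[c][r.width_deg] for r in ds.runs]
                )
                beta = max(
                    float(np.linalg.lstsq(pred[:, None], data, rcond=None)[0][0]),
                    0.0,
                )
                ve = variance_explained(beta * pred, data)
                # same tie-break: smaller sigma, then smaller n
                key = (ve, -c[2], -c[3])
                if best is None or key > (best_ve, -best[2], -best[3]):
                    best, best_ve = c, ve
            f = fits[site]
            assert (f.params.x0, f.params.y0, f.params.sigma, f.params.n) == best
            assert f.variance_explained == pytest.approx(best_ve, abs=1e-9)

    def test_constant_series_not_retained(self, run_apertures, reduced_grid):
        n_t = len(run_apertures[1.0])
        ds = _flat_dataset(np.zeros((3, n_t)))
        fits = grid_fit(ds, run_apertures, reduced_grid)
        for f in fits:
            assert f.variance_explained <= 0.0
            assert not f.retained

    def test_deterministic(self, noiseless_dataset, run_apertures, reduced_grid):
        f1 = grid_fit(noiseless_dataset, run_apertures, reduced_grid, decimate_factor=2)
        f2 = grid_fit(noiseless_dataset, run_apertures, reduced_grid, decimate_factor=2)
        for a, b in zip(f1, f2):
            assert a.params == b.params
            assert a.variance_explained == b.variance_explained


class TestSearchFit:
    @pytest.fixture(scope="class")
    def offgrid(self, run_apertures, reduced_grid):
        layout = make_cluster_sheet(
            n_clusters=1, maps_per_cluster=1, rows_per_map=4, n_ecc_cols=4, seed=3
        )
        ds = simulate_timeseries(layout, run_apertures, noise_sd=0.2, seed=3)
        fits = grid_fit(ds, run_apertures, reduced_grid, decimate_factor=2)
        return layout, ds, fits

    def test_never_worse_than_seed_in_sample(self, offgrid, run_apertures):
        layout, ds, fits = offgrid
        for i in (0, 5, 11):
            sf = search_fit(fits[i], ds, run_apertures)
            # compare on the same unprocessed series the search used
            seed_params = fits[i].params
            seeded = search_fit(
                PRFFit(seed_params, -np.inf, site_id=fits[i].site_id),
                ds,
                run_apertures,
                maxiter=0,
            )
            assert sf.variance_explained >= seeded.variance_explained - 1e-12

    def test_seeding_at_truth_stays_at_truth(self, run_apertures):
        layout = make_cluster_sheet(
            n_clusters=1, maps_per_cluster=1, rows_per_map=4, n_ecc_cols=4, seed=6
        )
        ds = simulate_timeseries(layout, run_apertures, noise_sd=0.0, seed=6)
        truth = layout.params[7]
        seed = PRFFit(truth, 1.0, site_id=7)
        sf = search_fit(seed, ds, run_apertures)
        assert sf.params.x0 == pytest.approx(truth.x0, abs=0.05)
        assert sf.params.y0 == pytest.approx(truth.y0, abs=0.05)
        assert sf.params.sigma == pytest.approx(truth.sigma, rel=0.05)
        assert sf.variance_explained == pytest.approx(1.0, abs=1e-6)

    def test_search_beats_grid_on_offgrid_truth(self, offgrid, run_apertures):
        layout, ds, fits = offgrid
        gerr, serr = [], []
        for i in range(0, ds.n_sites, 2):
            t = layout.params[i]
            sf = search_fit(fits[i], ds, run_apertures)
            gerr.append(np.hypot(fits[i].params.x0 - t.x0, fits[i].params.y0 - t.y0))
            serr.append(np.hypot(sf.params.x0 - t.x0, sf.params.y0 - t.y0))
        assert np.median(serr) < np.median(gerr)


class TestFilterVoxels:
    def _fit(self, ve, ecc):
        return PRFFit(PRFParams(ecc, 0.0, 1.0, 0.5), ve, site_id=0)

    @pytest.mark.parametrize(
        "ve,ecc,kept",
        [
            (0.09, 3.0, False),
            (0.10, 3.0, True),
            (0.50, 12.5, False),
            (0.50, 12.0, True),
            (0.50, 3.0, True),
            (0.099999, 0.0, False),
        ],
    )
    def test_boundaries(self, ve, ecc, kept):
        out = filter_voxels([self._fit(ve, ecc)])
        assert out[0].retained is kept

    def test_fine_sweeps_transition_exactly_at_thresholds(self):
        ves = np.linspace(0.0, 0.3, 301)
        kept = [
            filter_voxels([self._fit(v, 1.0)])[0].retained for v in ves
        ]
        assert kept == [v >= 0.10 for v in ves]
        eccs = np.linspace(10.0, 14.0, 201)
        kept = [
            filter_voxels([self._fit(0.5, e)])[0].retained for e in eccs
        ]
        assert kept == [e <= 12.0 for e in eccs]
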