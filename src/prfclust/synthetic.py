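"""Ground-truth clustered retinotopic sheets and simulated BOLD runs.

The generator lays out visual field map *clusters* on a flat 2D sheet (mm
coordinates standing in for a flattened cortical patch).  Within a cluster,
adjacent maps are mirrored polar-angle gradients — angle sweeps from the
lower vertical meridian (-90 deg) to the upper vertical meridian (+90 deg)
along the sheet, then reverses back in the next map — while all maps share
one eccentricity gradient running orthogonally, whose minimum (the
confluent fovea) sits on the maps' common border.  pRF size grows linearly
with eccentricity, and the compressive exponent is set per map.

Every site carries its generating :class:`~prfclust.prf_model.PRFParams`,
so fits can be scored against exact ground truth.  Simulated BOLD series
are the CSS forward model (HRF-convolved) plus seeded additive white
Gaussian noise scaled to each site's signal SD; an AR(1) option provides
temporally correlated noise for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Run, SheetDataset
from .fitting import GRID_EXPONENTS, GridSpec, grid_fit, temporal_decimate
from .prf_model import HRFSpec, PRFParams, css_prediction, effective_size
from .stimulus import ApertureSequence


@dataclass(frozen=True)
class ClusterLayout:
    """A generated retinotopic sheet with per-site ground truth.

    ``coords_mm`` indexes sites row-major over a (n_v, n_u) sheet grid: the
    v axis carries the stacked polar-angle gradients (maps), the u axis the
    shared eccentricity gradient (fovea at u = 0).  ``map_boundaries_v``
    holds the v indices of the planted borders between adjacent maps, where
    the angle progression reverses.
    """

    coords_mm: np.ndarray
    params: tuple[PRFParams, ...]
    region_labels: np.ndarray
    angles_deg: np.ndarray
    eccs_deg: np.ndarray
    sheet_shape: tuple[int, int]  # (n_v, n_u)
    map_boundaries_v: tuple[int, ...]
    hemisphere: str = "left"
    n_clusters: int = 1
    maps_per_cluster: int = 2

    @property
    def n_sites(self) -> int:
        return len(self.params)

    def site_index(self, v: int, u: int) -> int:
        return v * self.sheet_shape[1] + u

    def angle_path(self, u: int = 0) -> np.ndarray:
        """Polar angles along one constant-u column of the sheet (the path
        crossing every map border)."""
        n_v, n_u = self.sheet_shape
        return self.angles_deg[[self.site_index(v, u) for v in range(n_v)]]


def make_cluster_sheet(
    n_clusters: int = 2,
    maps_per_cluster: int = 2,
    rows_per_map: int = 12,
    n_ecc_cols: int = 10,
    ecc_range: tuple[float, float] = (0.5, 10.0),
    sigma_intercept: float = 0.5,
    sigma_slope: float = 0.25,
    exponent_by_map: tuple[float, ...] | float = 0.5,
    beta: float = 1.0,
    hemisphere: str = "left",
    spacing_mm: float = 1.0,
    seed: int = 0,
    angle_jitter_deg: float = 0.0,
    snap_to_grid: GridSpec | None = None,
) -> ClusterLayout:
    """Build a clustered retinotopic sheet with known pRF parameters.

    Parameters mirror the study conditions: centers stay within 12 deg
    eccentricity, sigma grows with eccentricity
    (``sigma = intercept + slope * ecc``), exponents come from
    {0.25, 0.5, 0.75, 1} (one per map, or a single shared value), and each
    map spans the full contralateral hemifield in polar angle.  With
    ``snap_to_grid`` the ground truth is snapped to the fitting grid's
    candidate values so grid-fit recovery can be exact; without it the
    truth is continuous (for testing the search refinement).
    ``angle_jitter_deg`` adds seeded angular scatter for less idealized
    sheets.  The layout is deterministic given its arguments and seed.
    """
    if n_clusters < 1 or maps_per_cluster < 1:
        raise ValueError("need at least one cluster with at least one map")
    if not 0 < ecc_range[0] < ecc_range[1] <= 12.0:
        raise ValueError("eccentricity range must satisfy 0 < lo < hi <= 12")
    n_maps = n_clusters * maps_per_cluster
    if np.isscalar(exponent_by_map):
        exponents = (float(exponent_by_map),) * n_maps
    else:
        exponents = tuple(float(e) for e in exponent_by_map)
        if len(exponents) != n_maps:
            raise ValueError(
                f"exponent_by_map must have one entry per map ({n_maps})"
            )
    for e in exponents:
        if not 0 < e <= 1:
            raise ValueError("exponents must lie in (0, 1]")
    n_v = n_maps * rows_per_map
    n_u = n_ecc_cols
    if n_v < 2 * n_maps or n_u < 2:
        raise ValueError("sheet too small for the requested layout")

    rng = np.random.default_rng(seed)
    eccs_u = np.geomspace(ecc_range[0], ecc_range[1], n_u)
    max_ecc = 12.0 if snap_to_grid is None else float(
        np.hypot(*snap_to_grid.centers_deg.T).max()
    )

    coords = np.empty((n_v * n_u, 2))
    params: list[PRFParams] = []
    labels = np.empty(n_v * n_u, dtype=object)
    angles = np.empty(n_v * n_u)
    eccs = np.empty(n_v * n_u)

    # angle ramp within one map: LVM (-90) to UVM (+90); mirrored in the next
    ramp = np.linspace(-90.0, 90.0, rows_per_map)
    for v in range(n_v):
        m, r = divmod(v, rows_per_map)
        cluster, map_in_cluster = divmod(m, maps_per_cluster)
        ang = ramp[r] if map_in_cluster % 2 == 0 else ramp[::-1][r]
        for u in range(n_u):
            i = v * n_u + u
            coords[i] = (u * spacing_mm, v * spacing_mm)
            a = ang + (rng.normal(0.0, angle_jitter_deg) if angle_jitter_deg else 0.0)
            a = float(np.clip(a, -90.0, 90.0))
            e = float(eccs_u[u])
            sig = sigma_intercept + sigma_slope * e
            n_exp = exponents[m]
            theta = np.radians(a)
            x0 = e * np.cos(theta)
            y0 = e * np.sin(theta)
            if hemisphere == "right":
                x0 = -x0
            if snap_to_grid is not None:
                x0, y0, sig, n_exp = _snap(
                    x0, y0, sig, n_exp, snap_to_grid
                )
                e = float(np.hypot(x0, y0))
                ax = -x0 if hemisphere == "right" else x0
                a = float(np.degrees(np.arctan2(y0, ax))) if e > 0 else 0.0
            if np.hypot(x0, y0) > max_ecc + 1e-9:
                raise ValueError("layout places a center beyond the 12-deg limit")
            params.append(PRFParams(x0, y0, sig, n_exp, beta))
            labels[i] = f"c{cluster}m{map_in_cluster}"
            angles[i] = a
            eccs[i] = e

    boundaries = tuple(m * rows_per_map for m in range(1, n_maps))
    layout = ClusterLayout(
        coords_mm=coords,
        params=tuple(params),
        region_labels=labels,
        angles_deg=angles,
        eccs_deg=eccs,
        sheet_shape=(n_v, n_u),
        map_boundaries_v=boundaries,
        hemisphere=hemisphere,
        n_clusters=n_clusters,
        maps_per_cluster=maps_per_cluster,
    )
    validate_layout(layout)
    return layout


def _snap(
    x0: float, y0: float, sig: float, n_exp: float, grid: GridSpec
) -> tuple[float, float, float, float]:
    d2 = (grid.centers_deg[:, 0] - x0) ** 2 + (grid.centers_deg[:, 1] - y0) ** 2
    cx, cy = grid.centers_deg[int(np.argmin(d2))]
    s = grid.sigmas_deg[int(np.argmin(np.abs(grid.sigmas_deg - sig)))]
    exps = np.asarray(grid.exponents)
    n = float(exps[int(np.argmin(np.abs(exps - n_exp)))])
    return float(cx), float(cy), float(s), n


def validate_layout(layout: ClusterLayout) -> None:
    """Explicit post-generation checks of the layout invariants.

    Raises ``ValueError`` if any map fails to span the contralateral
    hemifield, if sigma does not increase with eccentricity, if maps within
    a cluster do not share their eccentricity minimum (the confluent
    fovea), or if any center exceeds 12 deg eccentricity.
    """
    n_v, n_u = layout.sheet_shape
    rows_per_map = n_v // (layout.n_clusters * layout.maps_per_cluster)
    eccs = layout.eccs_deg.reshape(n_v, n_u)
    angles = layout.angles_deg.reshape(n_v, n_u)
    if np.hypot(*np.array([(p.x0, p.y0) for p in layout.params]).T).max() > 12 + 1e-9:
        raise ValueError("a pRF center lies beyond 12 deg eccentricity")
    n_maps = layout.n_clusters * layout.maps_per_cluster
    fovea_cols = []
    for m in range(n_maps):
        rows = slice(m * rows_per_map, (m + 1) * rows_per_map)
        a = angles[rows]
        if a.min() > -80.0 or a.max() < 80.0:
            raise ValueError(f"map {m} does not span the contralateral hemifield")
        # sigma vs ecc: within a map, mean sigma per distinct eccentricity
        # level must be non-decreasing (tolerates grid snapping ties)
        sig = np.array([p.sigma for p in layout.params]).reshape(n_v, n_u)[rows]
        e_flat, s_flat = eccs[rows].ravel(), sig.ravel()
        levels = np.unique(np.round(e_flat, 6))
        means = [s_flat[np.round(e_flat, 6) == lv].mean() for lv in levels]
        if np.any(np.diff(means) < -1e-9):
            raise ValueError(f"sigma does not increase with eccentricity in map {m}")
        fovea_cols.append(int(np.argmin(eccs[rows].mean(axis=0))))
    if len(set(fovea_cols)) != 1:
        raise ValueError("maps do not share a confluent fovea column")


def simulate_timeseries(
    layout: ClusterLayout,
    apertures_by_width: dict[float, ApertureSequence],
    noise_sd: float = 0.5,
    seed: int = 0,
    runs_per_width: int = 2,
    hrf: HRFSpec | None = None,
    ar_coef: float = 0.0,
) -> SheetDataset:
    """Simulate noisy BOLD runs for every site of a layout.

    Each run is the CSS forward prediction for one bar width's aperture
    sequence plus additive noise with SD equal to ``noise_sd`` times that
    site's noiseless signal SD (pooled over widths).  White Gaussian noise
    by default; ``ar_coef`` in (0, 1) switches to an AR(1) process with the
    same marginal SD.  Reproducible given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not apertures_by_width:
        raise ValueError("need at least one aperture sequence")
    if hrf is None:
        hrf = HRFSpec(dt_s=next(iter(apertures_by_width.values())).tr_s)
    rng = np.random.default_rng(seed)
    widths = sorted(apertures_by_width)
    n_sites = layout.n_sites

    clean: dict[float, np.ndarray] = {}
    for w in widths:
        ap = apertures_by_width[w]
        block = np.empty((n_sites, len(ap)))
        for s, p in enumerate(layout.params):
            block[s] = css_prediction(ap, p, hrf)
        clean[w] = block
    signal_sd = np.hstack([clean[w] for w in widths]).std(axis=1)
    signal_sd = np.where(signal_sd > 0, signal_sd, 1.0)

    runs = []
    for w in widths:
        for rep in range(runs_per_width):
            t_len = clean[w].shape[1]
            eps = rng.standard_normal((n_sites, t_len))
            if ar_coef:
                if not 0 < ar_coef < 1:
                    raise ValueError("ar_coef must lie in (0, 1)")
                ar = np.empty_like(eps)
                ar[:, 0] = eps[:, 0]
                innov = np.sqrt(1.0 - ar_coef**2)
                for t in range(1, t_len):
                    ar[:, t] = ar_coef * ar[:, t - 1] + innov * eps[:, t]
                eps = ar
            noise = noise_sd * signal_sd[:, None] * eps
            runs.append(
                Run(
                    width_deg=w,
                    series=clean[w] + noise,
                    run_id=f"w{w:g}r{rep}",
                )
            )
    return SheetDataset(
        coords_mm=layout.coords_mm,
        runs=tuple(runs),
        tr_s=next(iter(apertures_by_width.values())).tr_s,
        hemisphere=layout.hemisphere,
        ground_truth=layout.params,
        region_labels=layout.region_labels,
    )


def center_tolerance(grid: GridSpec, params: PRFParams) -> float:
    """One grid spacing at a given true center: distance from the nearest
    candidate center to *its* nearest distinct neighbor."""
    c = grid.centers_deg
    d2 = (c[:, 0] - params.x0) ** 2 + (c[:, 1] - params.y0) ** 2
    i = int(np.argmin(d2))
    dd = np.hypot(c[:, 0] - c[i, 0], c[:, 1] - c[i, 1])
    dd[i] = np.inf
    return float(dd.min())


def recovery_experiment(
    layout: ClusterLayout,
    apertures_by_width: dict[float, ApertureSequence],
    noise_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    grid: GridSpec | None = None,
    seed: int = 0,
    runs_per_width: int = 2,
    decimate_factor: int = 2,
    blur_fwhm_mm: float | None = None,
    hrf: HRFSpec | None = None,
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Simulate, fit, and score parameter recovery across noise levels.

    Returns a summary frame (one row per noise level: center RMSE, fraction
    of sites recovered within one grid spacing, median relative error of
    the effective size sigma/n, exponent hit rate) and a dict of exponent
    confusion matrices (true x fitted, row-indexed by true exponent).

    Spatial blurring is off by default here: blurring mixes neighbouring
    sites' distinct ground truths, so exact noiseless recovery is only
    well-defined on unblurred series.  Pass ``blur_fwhm_mm`` to include it.
    """
    if grid is None:
        grid = GridSpec.default()
    if hrf is None:
        hrf = HRFSpec(dt_s=next(iter(apertures_by_width.values())).tr_s)
    from .fitting import spatial_blur  # local to avoid cycle at import time

    exps = list(grid.exponents)
    rows = []
    confusions: dict[float, pd.DataFrame] = {}
    for k, noise in enumerate(noise_levels):
        ds = simulate_timeseries(
            layout,
            apertures_by_width,
            noise_sd=noise,
            seed=seed + k,
            runs_per_width=runs_per_width,
            hrf=hrf,
        )
        if blur_fwhm_mm:
            ds = spatial_blur(ds, fwhm_mm=blur_fwhm_mm)
        fits = grid_fit(
            ds, apertures_by_width, grid, model="css", hrf=hrf,
            decimate_factor=decimate_factor,
        )
        cerr = np.array(
            [
                np.hypot(f.params.x0 - p.x0, f.params.y0 - p.y0)
                for f, p in zip(fits, layout.params)
            ]
        )
        tol = np.array([center_tolerance(grid, p) for p in layout.params])
        eff_true = np.array([effective_size(p) for p in layout.params])
        eff_hat = np.array([f.effective_size_deg for f in fits])
        conf = pd.DataFrame(0, index=exps, columns=exps)
        for f, p in zip(fits, layout.params):
            if p.n in exps and f.params.n in exps:
                conf.loc[p.n, f.params.n] += 1
        confusions[noise] = conf
        rows.append(
            {
                "noise_sd": noise,
                "center_rmse_deg": float(np.sqrt(np.mean(cerr**2))),
                "center_within_one_step": float(np.mean(cerr <= tol + 1e-9)),
                "median_eff_size_rel_err": float(
                    np.median(np.abs(eff_hat - eff_true) / eff_true)
                ),
                "exponent_hit_rate": float(
                    np.mean([f.params.n == p.n for f, p in zip(fits, layout.params)])
                ),
                "mean_ve": float(np.mean([f.variance_explained for f in fits])),
                "n_sites": layout.n_sites,
            }
        )
    return pd.DataFrame(rows), confusions
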