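"""Preprocessing and pRF fitting.

The coarse-to-fine strategy: time series are spatially blurred on the sheet
(Gaussian kernel, 5 mm full width at half maximum by default) and temporally
decimated (2x block averaging), then fit by exhaustive evaluation of a
parameter grid — every (x0, y0, sigma, n) candidate's prediction is built
once, its amplitude solved in closed form by least squares, and the
candidate with the highest variance explained wins.  A continuous search
refinement seeded by the grid solution, applied to the unblurred series, is
available as a second stage.  Voxel filters drop sites with poor fits
(variance explained < 10%) or centers beyond the display limit (12 deg).

Before fitting, each run's series (data and predictions alike) is converted
to fluctuation units by removing its mean, so the sum of squared data in the
variance-explained denominator behaves as a variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .dataset import Run, SheetDataset
from .prf_model import (
    HRFSpec,
    PRFParams,
    convolve_hrf,
    css_neural_response,
    effective_size,
)
from .stimulus import ApertureSequence

logger = logging.getLogger(__name__)

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_VE_MIN = 0.10
DEFAULT_ECC_MAX_DEG = 12.0
GRID_EXPONENTS = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Candidate values for the exhaustive grid fit.

    ``centers_deg`` is an (n, 2) array of (x0, y0) candidates; ``sigmas_deg``
    and ``exponents`` are 1D.  The default layout places centers on a polar
    lattice (8 angles x 12 log-spaced eccentricities from 0.5 to 12 deg,
    plus the origin), 10 log-spaced sigmas from 0.25 to 12 deg, and the
    exponent set {0.25, 0.5, 0.75, 1}.
    """

    centers_deg: np.ndarray
    sigmas_deg: np.ndarray
    exponents: tuple[float, ...] = GRID_EXPONENTS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centers_deg", np.atleast_2d(np.asarray(self.centers_deg, float))
        )
        object.__setattr__(
            self, "sigmas_deg", np.asarray(self.sigmas_deg, dtype=float)
        )
        object.__setattr__(self, "exponents", tuple(self.exponents))

    @classmethod
    def default(
        cls,
        n_angles: int = 8,
        n_ecc: int = 12,
        ecc_range: tuple[float, float] = (0.5, 12.0),
        n_sigma: int = 10,
        sigma_range: tuple[float, float] = (0.25, 12.0),
        exponents: tuple[float, ...] = GRID_EXPONENTS,
        hemifield: str | None = None,
    ) -> "GridSpec":
        """Standard polar grid covering eccentricity <= 12 deg.

        With ``hemifield`` set to 'left' or 'right', angle candidates are
        restricted to that hemisphere's contralateral hemifield (useful for
        reduced grids in simulations; the full default spans 360 deg).
        """
        angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
        if hemifield == "left":  # contralateral field is x > 0
            angles = np.linspace(-np.pi / 2, np.pi / 2, n_angles)
        elif hemifield == "right":
            angles = np.linspace(np.pi / 2, 3 * np.pi / 2, n_angles)
        eccs = np.geomspace(*ecc_range, n_ecc)
        centers = [(0.0, 0.0)]
        for e in eccs:
            for a in angles:
                centers.append((e * np.cos(a), e * np.sin(a)))
        sigmas = np.geomspace(*sigma_range, n_sigma)
        return cls(np.array(centers), sigmas, exponents)

    @property
    def n_candidates(self) -> int:
        return len(self.centers_deg) * len(self.sigmas_deg) * len(self.exponents)

    def candidate_table(self) -> np.ndarray:
        """All (x0, y0, sigma, n) rows in canonical order: center-major,
        then sigma, then exponent."""
        rows = np.empty((self.n_candidates, 4))
        i = 0
        for cx, cy in self.centers_deg:
            for s in self.sigmas_deg:
                for n in self.exponents:
                    rows[i] = (cx, cy, s, n)
                    i += 1
        return rows


@dataclass
class PRFFit:
    """A fitted pRF for one site with its goodness of fit and filter flag."""

    params: PRFParams
    variance_explained: float
    site_id: int = -1
    retained: bool = False
    fit_stage: str = "grid"

    @property
    def effective_size_deg(self) -> float:
        return effective_size(self.params)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def spatial_blur(
    dataset: SheetDataset, fwhm_mm: float = 5.0, mm_per_sheet_unit: float = 1.0
) -> SheetDataset:
    """Gaussian-blur every run's series across the sheet.

    Each site's series becomes a normalized Gaussian-weighted average of all
    sites' series, with weights determined by pairwise sheet distance and
    the given full width at half maximum.
    """
    if dataset.coords_mm is None or len(dataset.coords_mm) == 0:
        raise ValueError("dataset has no sheet coordinates")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    coords = dataset.coords_mm * mm_per_sheet_unit
    sd = fwhm_mm / _FWHM_TO_SD
    d2 = cdist(coords, coords, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * sd**2))
    w /= w.sum(axis=1, keepdims=True)
    runs = [replace(r, series=w @ r.series) for r in dataset.runs]
    return dataset.with_runs(runs)


def blur_weight(distance_mm: float, fwhm_mm: float) -> float:
    """Unnormalized Gaussian blur weight at a given sheet distance."""
    sd = fwhm_mm / _FWHM_TO_SD
    return float(np.exp(-(distance_mm**2) / (2.0 * sd**2)))


def temporal_decimate(series: np.ndarray, factor: int = 2) -> np.ndarray:
    """Average adjacent non-overlapping blocks of ``factor`` samples
    (last axis); a trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    factor = int(factor)
    series = np.asarray(series, dtype=float)
    if factor == 1:
        return series.copy()
    n = (series.shape[-1] // factor) * factor
    trimmed = series[..., :n]
    shape = trimmed.shape[:-1] + (n // factor, factor)
    return trimmed.reshape(shape).mean(axis=-1)


def _demean(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# grid fit
# ---------------------------------------------------------------------------

def _width_predictions(
    aperture: ApertureSequence,
    grid: GridSpec,
    model: str,
    hrf: HRFSpec,
    decimate_factor: int,
) -> np.ndarray:
    """Prediction matrix (n_timepoints_decimated, n_candidates) for one run
    aperture, mean-removed, in :meth:`GridSpec.candidate_table` order."""
    field = aperture.field
    X, Y = field.meshgrid()
    px = np.column_stack([X.ravel(), Y.ravel()])
    d2 = cdist(px, grid.centers_deg, "sqeuclidean")  # (P, C)
    flat = aperture.masks.reshape(len(aperture), -1).astype(float)  # (T, P)
    kernel = hrf.kernel()

    n_cen, n_sig = len(grid.centers_deg), len(grid.sigmas_deg)
    n_exp = len(grid.exponents)
    t_dec = temporal_decimate(np.zeros(len(aperture)), decimate_factor).shape[-1]
    out = np.empty((t_dec, grid.n_candidates))
    for j, sig in enumerate(grid.sigmas_deg):
        G = np.exp(-d2 / (2.0 * sig**2))  # (P, C)
        overlap = (flat @ G) / G.sum(axis=0)  # (T, C), unit-integral normalized
        for k, n in enumerate(grid.exponents):
            neural = np.power(overlap, n)
            bold = np.apply_along_axis(
                lambda col: np.convolve(col, kernel)[: len(col)], 0, neural
            )
            dec = temporal_decimate(bold.T, decimate_factor).T  # (t_dec, C)
            dec = dec - dec.mean(axis=0, keepdims=True)
            # candidate order: center-major, sigma, exponent
            idx = np.arange(n_cen) * (n_sig * n_exp) + j * n_exp + k
            out[:, idx] = dec
    return out


def grid_predictions(
    apertures_by_width: dict[float, ApertureSequence],
    runs: Sequence[Run],
    grid: GridSpec,
    model: str,
    hrf: HRFSpec | None = None,
    decimate_factor: int = 1,
) -> np.ndarray:
    """Concatenated (over runs) mean-removed prediction matrix for a grid."""
    if model not in ("css", "linear"):
        raise ValueError("model must be 'css' or 'linear'")
    if model == "linear":
        grid = replace(grid, exponents=(1.0,))
    if hrf is None:
        hrf = HRFSpec(dt_s=next(iter(apertures_by_width.values())).tr_s)
    per_width: dict[float, np.ndarray] = {}
    blocks = []
    for r in runs:
        if r.width_deg not in apertures_by_width:
            raise ValueError(f"no aperture sequence for bar width {r.width_deg}")
        if r.width_deg not in per_width:
            per_width[r.width_deg] = _width_predictions(
                apertures_by_width[r.width_deg], grid, model, hrf, decimate_factor
            )
        blocks.append(per_width[r.width_deg])
    return np.vstack(blocks)


def _stack_data(runs: Sequence[Run], decimate_factor: int) -> np.ndarray:
    """(n_timepoints_total, n_sites) decimated, per-run mean-removed data."""
    blocks = [_demean(temporal_decimate(r.series, decimate_factor)) for r in runs]
    return np.hstack(blocks).T


def grid_fit(
    dataset: SheetDataset,
    apertures_by_width: dict[float, ApertureSequence],
    grid: GridSpec | None = None,
    model: str = "css",
    hrf: HRFSpec | None = None,
    decimate_factor: int = 1,
    nonnegative_beta: bool = True,
    ve_min: float = DEFAULT_VE_MIN,
    ecc_max_deg: float = DEFAULT_ECC_MAX_DEG,
) -> list[PRFFit]:
    """Exhaustive grid fit of the pRF model at every site.

    For every candidate (x0, y0, sigma, n) the predicted series is built
    once (concatenated across runs, HRF-convolved, decimated, mean-removed);
    beta is the closed-form least-squares amplitude (clipped at zero by
    default, since responses are modeled as positive); the winning candidate
    maximizes variance explained.  Exact ties go to the smaller sigma, then
    the smaller exponent, then candidate order.  The fit is deterministic.

    Note ``dataset`` should already be spatially blurred if the coarse-fit
    convention is wanted; decimation is applied here to both data and
    predictions so they stay consistent.
    """
    if grid is None:
        grid = GridSpec.default()
    if model == "linear":
        grid = replace(grid, exponents=(1.0,))
    if hrf is None:
        hrf = HRFSpec(dt_s=dataset.tr_s)

    P = grid_predictions(
        apertures_by_width, dataset.runs, grid, model, hrf, decimate_factor
    )  # (T, C)
    D = _stack_data(dataset.runs, decimate_factor)  # (T, S)
    cand = grid.candidate_table()

    # tie-break order: sort candidates by (sigma, n, original index) so the
    # first argmax hit is the preferred one
    order = np.lexsort((np.arange(len(cand)), cand[:, 3], cand[:, 2]))
    P_ord, cand_ord = P[:, order], cand[order]

    pp = np.einsum("tc,tc->c", P_ord, P_ord)  # (C,)
    num = P_ord.T @ D  # (C, S)
    dd = np.einsum("ts,ts->s", D, D)  # (S,)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / pp[:, None]
    if nonnegative_beta:
        beta = np.clip(beta, 0.0, None)
    beta = np.nan_to_num(beta)
    # ve = (2*beta*num - beta^2*pp) / dd   (residual expansion, mean-removed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = (2.0 * beta * num - beta**2 * pp[:, None]) / dd[None, :]

    fits: list[PRFFit] = []
    for s in range(dataset.n_sites):
        if dd[s] <= 1e-12:  # flat series: nothing to explain
            params = PRFParams(*cand_ord[0, :2], cand_ord[0, 2], cand_ord[0, 3], 0.0)
            fits.append(
                PRFFit(params, 0.0, site_id=int(dataset.site_ids[s]), retained=False)
            )
            continue
        best = int(np.argmax(ve[:, s]))
        x0, y0, sig, n = cand_ord[best]
        params = PRFParams(x0, y0, sig, n, float(beta[best, s]))
        fits.append(
            PRFFit(params, float(ve[best, s]), site_id=int(dataset.site_ids[s]))
        )
    return filter_voxels(fits, ve_min=ve_min, ecc_max_deg=ecc_max_deg)


# ---------------------------------------------------------------------------
# search refinement
# ---------------------------------------------------------------------------

def _site_prediction(
    params: PRFParams,
    apertures_by_width: dict[float, ApertureSequence],
    runs: Sequence[Run],
    hrf: HRFSpec,
) -> np.ndarray:
    per_width: dict[float, np.ndarray] = {}
    blocks = []
    for r in runs:
        if r.width_deg not in per_width:
            neural = css_neural_response(apertures_by_width[r.width_deg], params)
            per_width[r.width_deg] = _demean(convolve_hrf(neural, hrf))
        blocks.append(per_width[r.width_deg])
    return np.concatenate(blocks)


def _ve_for(pred: np.ndarray, data: np.ndarray, nonnegative_beta: bool) -> tuple[float, float]:
    pp = float(pred @ pred)
    if pp <= 1e-300:
        return 0.0, 0.0
    b = float(pred @ data) / pp
    if nonnegative_beta:
        b = max(b, 0.0)
    dd = float(data @ data)
    if dd <= 1e-12:
        return 0.0, b
    return (2.0 * b * (pred @ data) - b * b * pp) / dd, b


def search_fit(
    seed: PRFFit,
    dataset: SheetDataset,
    apertures_by_width: dict[float, ApertureSequence],
    hrf: HRFSpec | None = None,
    ecc_max_deg: float = DEFAULT_ECC_MAX_DEG,
    sigma_bounds: tuple[float, float] = (0.05, 12.0),
    nonnegative_beta: bool = True,
    maxiter: int = 300,
) -> PRFFit:
    """Continuous refinement of a grid-fit seed on the unblurred series.

    Nelder-Mead over (x0, y0, log sigma, n) with beta profiled out in closed
    form; parameters are kept inside the grid limits by a barrier.  If the
    optimizer fails to improve on the seed, the seed is returned (with its
    variance explained recomputed on the same unprocessed series).
    """
    if hrf is None:
        hrf = HRFSpec(dt_s=dataset.tr_s)
    s_idx = int(np.nonzero(dataset.site_ids == seed.site_id)[0][0])
    data = _demean(
        np.hstack([_demean(r.series[s_idx]) for r in dataset.runs])
    )

    def unpack(v: np.ndarray) -> PRFParams | None:
        x0, y0, logsig, n = v
        sig = float(np.exp(logsig))
        if not (sigma_bounds[0] <= sig <= sigma_bounds[1]):
            return None
        if not (0.01 <= n <= 1.0):
            return None
        if np.hypot(x0, y0) > ecc_max_deg:
            return None
        return PRFParams(float(x0), float(y0), sig, float(n), 1.0)

    def objective(v: np.ndarray) -> float:
        p = unpack(v)
        if p is None:
            return 1e6
        pred = _site_prediction(p, apertures_by_width, dataset.runs, hrf)
        ve, _ = _ve_for(pred, data, nonnegative_beta)
        return -ve

    v0 = np.array(
        [seed.params.x0, seed.params.y0, np.log(seed.params.sigma), seed.params.n]
    )
    seed_ve = -objective(v0)
    res = minimize(
        objective, v0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8},
    )
    if not res.success and -res.fun <= seed_ve:
        warnings.warn("search_fit did not converge; returning grid seed")
    if -res.fun < seed_ve or unpack(res.x) is None:
        params = seed.params
        best_ve = seed_ve
    else:
        params = unpack(res.x)
        best_ve = -res.fun
    pred = _site_prediction(params, apertures_by_width, dataset.runs, hrf)
    _, beta = _ve_for(pred, data, nonnegative_beta)
    params = PRFParams(params.x0, params.y0, params.sigma, params.n, beta)
    return PRFFit(params, float(best_ve), site_id=seed.site_id, fit_stage="search")


# ---------------------------------------------------------------------------
# voxel filters
# ---------------------------------------------------------------------------

def filter_voxels(
    fits: Sequence[PRFFit],
    ve_min: float = DEFAULT_VE_MIN,
    ecc_max_deg: float = DEFAULT_ECC_MAX_DEG,
) -> list[PRFFit]:
    """Flag fits to retain: variance explained >= ve_min and center
    eccentricity <= ecc_max_deg; everything else is excluded."""
    out = []
    for f in fits:
        keep = (
            f.variance_explained >= ve_min
            and f.params.eccentricity <= ecc_max_deg
        )
        out.append(
            PRFFit(f.params, f.variance_explained, f.site_id, keep, f.fit_stage)
        )
    n_keep = sum(f.retained for f in out)
    logger.info("filter_voxels: %d of %d sites retained", n_keep, len(out))
    return out
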