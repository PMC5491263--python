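"""Forward models from aperture sequences to predicted BOLD time series.

Three predictors are provided:

* the compressive spatial summation (CSS) pRF model,
  ``r(t) = beta * [ integral S(x,y) G(x,y) dx dy ]^n``,
  with ``G`` an isotropic 2D Gaussian and ``0 < n <= 1`` a static power-law
  nonlinearity applied to the neural signal before hemodynamic convolution;
* its linear special case (``n = 1``);
* a spatially untuned contralateral predictor that responds whenever any
  part of the stimulus enters the hemifield opposite the recording site's
  hemisphere.

A voxel's *effective* pRF size is ``sigma / n``: the compressive exponent
broadens the region of space over which stimuli produce near-equal
responses, so sigma alone understates spatial pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .stimulus import ApertureSequence, FieldSpec

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class PRFParams:
    """One site's pRF model: center (x0, y0), size sigma, exponent n, amplitude beta.

    Units: degrees of visual angle for position and size; n is unitless in
    (0, 1]; beta is in arbitrary BOLD response units.
    """

    x0: float
    y0: float
    sigma: float
    n: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("exponent n must lie in (0, 1]")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle_deg(self) -> float:
        """Polar angle, 0 = right horizontal meridian, +90 = upper vertical."""
        return float(np.degrees(np.arctan2(self.y0, self.x0)))


def effective_size(params: PRFParams) -> float:
    """Effective pRF size sigma/n in degrees."""
    if params.n <= 0:
        raise ValueError("exponent n must be positive")
    return params.sigma / params.n


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic impulse response.

    Difference of two gamma densities: a positive lobe peaking around
    ``peak_s`` (default 5 s) and an undershoot around ``undershoot_s``
    (default 15 s) scaled by ``undershoot_ratio``.  ``dt_s`` is the sampling
    interval (match the TR) and ``duration_s`` the finite kernel support.
    The kernel is normalized to unit sum so convolution preserves the scale
    of a sustained neural response.
    """

    peak_s: float = 5.0
    undershoot_s: float = 15.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dt_s: float = 2.0
    duration_s: float = 32.0

    def kernel(self) -> np.ndarray:
        t = np.arange(0.0, self.duration_s + 1e-9, self.dt_s)
        pos = gamma_dist.pdf(t, self.peak_s / self.peak_disp, scale=self.peak_disp)
        neg = gamma_dist.pdf(
            t, self.undershoot_s / self.undershoot_disp, scale=self.undershoot_disp
        )
        h = pos - self.undershoot_ratio * neg
        s = h.sum()
        if s <= 0:
            raise ValueError("HRF kernel must integrate to a positive constant")
        return h / s


def gaussian_field(params: PRFParams, field: FieldSpec) -> np.ndarray:
    """Isotropic Gaussian G(x, y) on the field raster; peak value 1 at (x0, y0)."""
    X, Y = field.meshgrid()
    return np.exp(
        -((X - params.x0) ** 2 + (Y - params.y0) ** 2) / (2.0 * params.sigma**2)
    )


def overlap_series(
    aperture: ApertureSequence, params: PRFParams, normalize: bool = True
) -> np.ndarray:
    """Per-step overlap integral of the stimulus mask with the pRF Gaussian.

    With ``normalize`` the Gaussian is scaled to unit (discrete) integral, so
    a full-field stimulus yields exactly 1 and beta has consistent units
    across sigma.  Without it the raw peak-1 Gaussian is integrated (the
    overlap then carries units of deg^2).
    """
    G = gaussian_field(params, aperture.field)
    flat = aperture.masks.reshape(len(aperture), -1).astype(float)
    raw = flat @ G.ravel()
    if normalize:
        return raw / G.sum()
    return raw * aperture.field.pixel_area


def css_neural_response(
    aperture: ApertureSequence, params: PRFParams, normalize: bool = True
) -> np.ndarray:
    """CSS neural response r(t): (overlap integral)^n scaled by beta."""
    ov = overlap_series(aperture, params, normalize=normalize)
    return params.beta * np.power(ov, params.n)


def convolve_hrf(neural: np.ndarray, hrf: HRFSpec) -> np.ndarray:
    """Causal convolution of a neural time series with the HRF, truncated to input length."""
    neural = np.asarray(neural, dtype=float)
    if neural.size == 0:
        raise ValueError("cannot convolve an empty series")
    return np.convolve(neural, hrf.kernel())[: neural.size]


def css_prediction(
    aperture: ApertureSequence,
    params: PRFParams,
    hrf: HRFSpec | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Predicted BOLD series: CSS neural response convolved with the HRF."""
    if hrf is None:
        hrf = HRFSpec(dt_s=aperture.tr_s)
    if abs(hrf.dt_s - aperture.tr_s) > 1e-9:
        raise ValueError("HRF sampling interval must match the aperture TR")
    return convolve_hrf(css_neural_response(aperture, params, normalize), hrf)


def linear_prediction(
    aperture: ApertureSequence,
    params: PRFParams,
    hrf: HRFSpec | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Linear pRF prediction: the CSS pipeline with the exponent fixed at 1."""
    lin = PRFParams(params.x0, params.y0, params.sigma, n=1.0, beta=params.beta)
    return css_prediction(aperture, lin, hrf, normalize)


def contralateral_regressor(
    aperture: ApertureSequence, hemisphere: str
) -> np.ndarray:
    """Binary regressor: 1 whenever any stimulus pixel lies strictly in the
    hemifield contralateral to ``hemisphere`` (x > 0 for left-hemisphere
    sites, x < 0 for right), else 0."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}; use 'left' or 'right'")
    x = aperture.field.pixel_centers()
    cols = x > 0 if hemisphere == "left" else x < 0
    # masks are (t, y, x): any active pixel in a contralateral column
    return (aperture.masks[:, :, cols].any(axis=(1, 2))).astype(float)


def contralateral_prediction(
    aperture: ApertureSequence,
    hemisphere: str,
    hrf: HRFSpec | None = None,
    beta: float = 1.0,
) -> np.ndarray:
    """Contralateral-only predicted BOLD series (uniform amplitude, no spatial tuning)."""
    if hrf is None:
        hrf = HRFSpec(dt_s=aperture.tr_s)
    return beta * convolve_hrf(contralateral_regressor(aperture, hemisphere), hrf)
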