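"""Map-level summaries of fitted pRFs.

* **Laterality index** — the fraction of a pRF's Gaussian mass (with SD
  equal to the effective size sigma/n) lying in the hemifield contralateral
  to the site's hemisphere.  0 means completely ipsilateral, 0.5 no lateral
  bias, 1 completely contralateral.  Because the Gaussian is isotropic and
  separable, the 2D half-plane mass reduces to the 1D normal CDF
  Phi(x0 / (sigma/n)) for a left-hemisphere site (contralateral field
  x > 0), mirrored for the right hemisphere.
* **Coverage density** — the pointwise *mean* (not envelope) of an ROI's
  peak-normalized pRFs over visual space, so the map reflects both where
  pRFs cover and how densely their centers sample each location.
* **Size vs. eccentricity** — binned mean +/- SEM of effective pRF size.
* **Polar-angle reversal detection** — boundaries between adjacent maps
  show up as sign changes in the polar-angle progression along a sheet
  path.

Polar angle convention: 0 deg = contralateral horizontal meridian,
+90/-90 deg = upper/lower vertical meridian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .fitting import PRFFit
from .prf_model import HEMISPHERES, PRFParams, effective_size, gaussian_field
from .stimulus import FieldSpec


def laterality_index(fit: PRFFit | PRFParams, hemisphere: str) -> float:
    """Contralateral Gaussian mass of one pRF, using effective size sigma/n.

    Closed form: Phi(x0 / (sigma/n)) for a left-hemisphere site, where Phi
    is the standard normal CDF; the mirrored value for the right hemisphere
    (equivalently, one minus the left-hemisphere bookkeeping).
    """
    params = fit.params if isinstance(fit, PRFFit) else fit
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    if params.sigma <= 0 or params.n <= 0:
        raise ValueError("laterality requires sigma > 0 and n > 0")
    size = effective_size(params)
    z = params.x0 / size
    if hemisphere == "right":  # contralateral field is x < 0
        z = -z
    return float(ndtr(z))


@dataclass(frozen=True)
class CoverageMap:
    """Mean of peak-normalized pRFs over visual space, values in [0, 1]."""

    density: np.ndarray
    field: FieldSpec
    roi: str = ""
    n_sites: int = 0

    def peak_location(self) -> tuple[float, float]:
        """(x, y) in degrees of the density maximum."""
        iy, ix = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        c = self.field.pixel_centers()
        return float(c[ix]), float(c[iy])


def coverage_density(
    fits: Sequence[PRFFit],
    field: FieldSpec | None = None,
    roi: str = "",
    beta_weighted: bool = False,
    retained_only: bool = True,
) -> CoverageMap:
    """Pointwise mean of the ROI's pRFs, each a peak-1 Gaussian with
    SD = effective size sigma/n.

    With ``beta_weighted`` each pRF is scaled by its amplitude before
    averaging (then renormalized by the max so values stay in [0, 1]).
    """
    if field is None:
        field = FieldSpec()
    use = [f for f in fits if f.retained] if retained_only else list(fits)
    if not use:
        raise ValueError("coverage density is undefined with zero retained fits")
    acc = np.zeros((field.n_pixels, field.n_pixels))
    wsum = 0.0
    for f in use:
        p = f.params
        eff = PRFParams(p.x0, p.y0, effective_size(p), 1.0, p.beta)
        g = gaussian_field(eff, field)
        w = p.beta if beta_weighted else 1.0
        acc += w * g
        wsum += w
    if wsum <= 0:
        raise ValueError("total weight is zero; cannot average pRFs")
    density = acc / wsum
    if beta_weighted and density.max() > 0:
        density = density / density.max()
    return CoverageMap(density=density, field=field, roi=roi, n_sites=len(use))


def size_vs_eccentricity(
    fits: Sequence[PRFFit],
    ecc_bin_edges: Sequence[float] | np.ndarray = None,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Binned mean +/- SEM of effective pRF size against center eccentricity.

    Returns one row per bin with columns (ecc_lo, ecc_hi, ecc_mid, n,
    mean_size, sem_size); empty bins carry NaN, not zero.
    """
    if ecc_bin_edges is None:
        ecc_bin_edges = np.linspace(0.0, 12.0, 7)
    edges = np.asarray(ecc_bin_edges, dtype=float)
    use = [f for f in fits if f.retained] if retained_only else list(fits)
    if not use:
        raise ValueError("no retained fits to bin")
    ecc = np.array([f.params.eccentricity for f in use])
    size = np.array([f.effective_size_deg for f in use])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inbin = (ecc > lo) & (ecc <= hi) if lo > 0 else (ecc >= lo) & (ecc <= hi)
        vals = size[inbin]
        rows.append(
            {
                "ecc_lo": lo,
                "ecc_hi": hi,
                "ecc_mid": (lo + hi) / 2,
                "n": int(inbin.sum()),
                "mean_size": float(vals.mean()) if vals.size else np.nan,
                "sem_size": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else (0.0 if vals.size == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows)


def detect_angle_reversals(
    angle_sequence: Sequence[float] | np.ndarray,
    smooth_window: int = 3,
    min_run: int = 3,
) -> list[int]:
    """Indices where the polar-angle progression along a sheet path reverses.

    The angle sequence is smoothed with a moving average of ``smooth_window``
    samples; its first difference is signed, and a reversal is declared where
    the sign flips and both the preceding and following sign persist for at
    least ``min_run`` steps (the guard against noise-driven flips).  Returned
    indices locate the extremum (peak or trough) of the progression.
    """
    a = np.asarray(angle_sequence, dtype=float)
    if smooth_window < 1 or min_run < 1:
        raise ValueError("smooth_window and min_run must be >= 1")
    if a.size < max(2 * min_run + 1, smooth_window + 1):
        raise ValueError("path shorter than the reversal guard window")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(a, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")[: a.size]
    else:
        sm = a
    d = np.diff(sm)
    signs = np.sign(d)
    signs[signs == 0] = 0

    # collapse into runs of constant nonzero sign (zero-diff plateaus extend
    # the current run but do not count toward its length)
    runs: list[list[int]] = []  # [sign, first_idx, last_idx, count]
    for i, s in enumerate(signs):
        if s == 0:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][2] = i
            runs[-1][3] += 1
        else:
            runs.append([int(s), i, i, 1])

    reversals = []
    for r1, r2 in zip(runs[:-1], runs[1:]):
        if r1[0] != r2[0] and r1[3] >= min_run and r2[3] >= min_run:
            lo, hi = r1[1], r2[2] + 1
            seg = a[lo : hi + 1]
            ext = int(np.argmax(seg) if r1[0] > 0 else np.argmin(seg))
            reversals.append(lo + ext)
    return reversals
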