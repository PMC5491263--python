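"""Variance explained and leave-one-bar-width-out model comparison.

Goodness of fit is the coefficient of determination

    ve = 1 - sum((prediction - data)^2) / sum(data^2),

computed here on mean-removed (fluctuation-unit) series by the fitting
path, so the denominator behaves as a variance; a raw mode is exposed.

Model comparison cross-validates three predictors — the nonlinear CSS pRF,
the linear pRF, and the spatially untuned contralateral model — by holding
out one bar width at a time: each model is fully solved on the runs of the
two remaining widths and scored on the held-out width's runs.  Because
every model is scored on data it never saw, extra parameters earn no
advantage.  Per-site accuracy is the mean over the three folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SheetDataset
from .fitting import (
    GridSpec,
    PRFFit,
    _demean,
    _stack_data,
    grid_fit,
    grid_predictions,
    temporal_decimate,
)
from .prf_model import HRFSpec, contralateral_regressor, convolve_hrf
from .stimulus import ApertureSequence

MODELS = ("nonlinear", "linear", "contralateral")


def variance_explained(
    prediction: np.ndarray, data: np.ndarray, demean: bool = False
) -> float:
    """Fraction of the data's energy explained by the prediction.

    May be negative when the prediction is worse than predicting zero.
    With ``demean`` both series are mean-removed first.
    """
    prediction = np.asarray(prediction, dtype=float)
    data = np.asarray(data, dtype=float)
    if prediction.shape != data.shape:
        raise ValueError("prediction and data must have equal length")
    if demean:
        prediction = prediction - prediction.mean()
        data = data - data.mean()
    denom = float(np.sum(data**2))
    if denom <= 0:
        raise ValueError("data has zero energy; variance explained undefined")
    return 1.0 - float(np.sum((prediction - data) ** 2)) / denom


@dataclass(frozen=True)
class Fold:
    """Bookkeeping for one cross-validation fold."""

    test_width: float
    train_widths: tuple[float, ...]
    train_run_ids: tuple[str, ...]
    test_run_ids: tuple[str, ...]


@dataclass
class ModelComparisonResult:
    """Cross-validated accuracy per site and model.

    ``per_site`` is a tidy frame with columns (site_id, model, fold
    [= held-out width], ve); ``folds`` records which runs trained and
    tested each fold.
    """

    per_site: pd.DataFrame
    folds: tuple[Fold, ...]
    region_labels: np.ndarray | None = None
    site_ids: np.ndarray | None = None

    def site_means(self) -> pd.DataFrame:
        """Per-site cv accuracy: mean over folds, one row per (site, model)."""
        return (
            self.per_site.groupby(["site_id", "model"], as_index=False)["ve"]
            .mean()
        )

    def summary(self) -> pd.DataFrame:
        """Per-model (optionally per-region) mean +/- SEM of per-site cv accuracy."""
        m = self.site_means()
        if self.region_labels is not None:
            ids = (
                self.site_ids
                if self.site_ids is not None
                else np.arange(len(self.region_labels))
            )
            lab = pd.DataFrame({"site_id": ids, "region": self.region_labels})
            m = m.merge(lab, on="site_id")
            group = ["region", "model"]
        else:
            m = m.assign(region="all")
            group = ["region", "model"]
        out = m.groupby(group)["ve"].agg(
            mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count"
        )
        return out.reset_index()


def _candidate_index(grid: GridSpec) -> dict[tuple, int]:
    table = grid.candidate_table()
    return {tuple(np.round(row, 9)): i for i, row in enumerate(table)}


def _score_fits_on_runs(
    fits: Sequence[PRFFit],
    dataset: SheetDataset,
    apertures_by_width: dict[float, ApertureSequence],
    grid: GridSpec,
    model: str,
    hrf: HRFSpec,
    decimate_factor: int,
) -> np.ndarray:
    """Held-out ve per site for grid-fit solutions (amplitude from training)."""
    P = grid_predictions(
        apertures_by_width, dataset.runs, grid, model, hrf, decimate_factor
    )
    if model == "linear":
        grid = replace(grid, exponents=(1.0,))
    index = _candidate_index(grid)
    D = _stack_data(dataset.runs, decimate_factor)  # (T, S)
    ves = np.empty(len(fits))
    for s, f in enumerate(fits):
        key = tuple(
            np.round((f.params.x0, f.params.y0, f.params.sigma, f.params.n), 9)
        )
        pred = f.params.beta * P[:, index[key]]
        d = D[:, s]
        dd = float(d @ d)
        ves[s] = 0.0 if dd <= 1e-12 else 1.0 - float(
            np.sum((pred - d) ** 2)
        ) / dd
    return ves


def _contralateral_design(
    dataset: SheetDataset,
    apertures_by_width: dict[float, ApertureSequence],
    hrf: HRFSpec,
    decimate_factor: int,
) -> np.ndarray:
    """Concatenated mean-removed contralateral regressor over runs, (T,)."""
    per_width: dict[float, np.ndarray] = {}
    blocks = []
    for r in dataset.runs:
        if r.width_deg not in per_width:
            reg = contralateral_regressor(
                apertures_by_width[r.width_deg], dataset.hemisphere
            )
            bold = convolve_hrf(reg, hrf)
            per_width[r.width_deg] = _demean(
                temporal_decimate(bold, decimate_factor)
            )
        blocks.append(per_width[r.width_deg])
    return np.concatenate(blocks)


def crossval_compare(
    dataset: SheetDataset,
    apertures_by_width: dict[float, ApertureSequence],
    models: Sequence[str] = MODELS,
    grid: GridSpec | None = None,
    hrf: HRFSpec | None = None,
    decimate_factor: int = 1,
    nonnegative_beta: bool = True,
) -> ModelComparisonResult:
    """Leave-one-bar-width-out comparison of the three models.

    For each of the three folds every model is fully solved on the training
    runs (the contralateral model fits only its amplitude — its shape is
    fixed by construction) and scored by variance explained on the held-out
    width's runs.  Training and test runs never overlap.
    """
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}; choose from {MODELS}")
    widths = dataset.widths
    if len(widths) < 2:
        raise ValueError("cross-validation needs at least two bar widths")
    for w in widths:
        if w not in apertures_by_width:
            raise ValueError(f"no aperture sequence for bar width {w}")
    if grid is None:
        grid = GridSpec.default()
    if hrf is None:
        hrf = HRFSpec(dt_s=dataset.tr_s)

    rows = []
    folds = []
    for test_w in widths:
        train_w = tuple(w for w in widths if w != test_w)
        train = dataset.runs_for_widths(train_w)
        test = dataset.runs_for_widths([test_w])
        folds.append(
            Fold(
                test_width=test_w,
                train_widths=train_w,
                train_run_ids=tuple(r.run_id for r in train.runs),
                test_run_ids=tuple(r.run_id for r in test.runs),
            )
        )
        for model in models:
            if model == "contralateral":
                x_tr = _contralateral_design(
                    train, apertures_by_width, hrf, decimate_factor
                )
                x_te = _contralateral_design(
                    test, apertures_by_width, hrf, decimate_factor
                )
                D_tr = _stack_data(train.runs, decimate_factor)
                D_te = _stack_data(test.runs, decimate_factor)
                xx = float(x_tr @ x_tr)
                beta = (x_tr @ D_tr) / xx if xx > 0 else np.zeros(dataset.n_sites)
                if nonnegative_beta:
                    beta = np.clip(beta, 0.0, None)
                resid = D_te - x_te[:, None] * beta[None, :]
                dd = np.einsum("ts,ts->s", D_te, D_te)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ves = 1.0 - np.einsum("ts,ts->s", resid, resid) / dd
                ves = np.where(dd <= 1e-12, 0.0, ves)
            else:
                fit_model = "css" if model == "nonlinear" else "linear"
                fits = grid_fit(
                    train,
                    apertures_by_width,
                    grid,
                    model=fit_model,
                    hrf=hrf,
                    decimate_factor=decimate_factor,
                    nonnegative_beta=nonnegative_beta,
                )
                ves = _score_fits_on_runs(
                    fits, test, apertures_by_width, grid, fit_model, hrf,
                    decimate_factor,
                )
            for s in range(dataset.n_sites):
                rows.append(
                    {
                        "site_id": int(dataset.site_ids[s]),
                        "model": model,
                        "fold": test_w,
                        "ve": float(ves[s]),
                    }
                )
    return ModelComparisonResult(
        per_site=pd.DataFrame(rows),
        folds=tuple(folds),
        region_labels=dataset.region_labels,
        site_ids=np.asarray(dataset.site_ids),
    )
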