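"""Repeat filtration, run pooling, calibration curves, aggregate spectra and
drift summaries.

*Repeat filtration* aggregates technical repeats of the same well by keeping,
per well, the reading that deviates least from the data-set trendline —
rather than a median — so transient excursions (wells that wander off trend
for a few readings before regressing back) are suppressed instead of
averaged in.  The filtered plates from several runs are then pooled on an
absolute concentration scale and a final robust calibration curve is fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .assess import PolynomialResponseModel
from .errors import FitError, PlatecalError
from .plate import PlateMap
from .simulate import PlateReading


@dataclass
class FilteredPlate:
    """Per-well outcome of repeat filtration."""

    table: pd.DataFrame  # well, target, selected_value, selected_repeat, deviation
    trend: PolynomialResponseModel
    n_repeats: int
    wavelength: float
    warning: str | None = None

    def values(self) -> dict[str, float]:
        return dict(zip(self.table["well"], self.table["selected_value"]))

    def rmse_to_trend(self) -> float:
        """Plate RMSE of selected values about the trendline (sample wells)."""
        t = self.table[self.table["target"] > 0]
        return float(np.sqrt(np.mean((t["selected_value"] - self.trend.predict(t["target"])) ** 2)))


def _pooled_frame(repeats: list[PlateReading], plate_map: PlateMap, wavelength: float):
    rows = []
    for r, reading in enumerate(repeats):
        vals = reading.at_wavelength(wavelength)
        for well, v in vals.items():
            rows.append((well, r, plate_map[well].target_ratio, plate_map[well].role, v))
    return pd.DataFrame(rows, columns=["well", "repeat", "target", "role", "value"])


def rmse_to_trend(values: dict[str, float], plate_map: PlateMap,
                  trend: PolynomialResponseModel) -> float:
    """RMSE of per-well values about a trendline, over sample wells."""
    t = np.array([plate_map[w].target_ratio for w in values])
    v = np.array(list(values.values()))
    keep = t > 0
    return float(np.sqrt(np.mean((v[keep] - trend.predict(t[keep])) ** 2)))


def repeat_filtration(
    repeats: list[PlateReading],
    plate_map: PlateMap,
    wavelength: float = 524.0,
    degree: int = 1,
    robust: bool = True,
    iterate: bool = False,
) -> FilteredPlate:
    """Keep, per well, the repeat value deviating least from the trendline.

    The trendline is a (robust, by default) response model fitted on all
    (target, value) pairs pooled across repeats; ties in deviation go to the
    lowest repeat index.  With ``iterate=True`` the trend is refit on the
    selected values and the selection repeated until stable (at most 10
    passes).  A single repeat is passed through with a warning flag.
    """
    if not repeats:
        raise PlatecalError("repeat_filtration needs at least one reading")
    grids = {tuple(r.wavelengths) for r in repeats}
    if len(grids) > 1:
        raise PlatecalError("repeats must share one wavelength grid")
    df = _pooled_frame(repeats, plate_map, wavelength)
    samples = df[df["role"] == "sample"]
    trend = PolynomialResponseModel(degree=degree, robust=robust).fit(
        samples["target"].to_numpy(), samples["value"].to_numpy()
    )
    warning = None
    if len(repeats) == 1:
        warning = "single repeat: filtration is a no-op"

    def select(trend_model):
        dev = (df["value"] - trend_model.predict(df["target"].to_numpy())).abs()
        tmp = df.assign(deviation=dev)
        # stable sort keeps the lowest repeat index on ties
        tmp = tmp.sort_values(["well", "deviation", "repeat"], kind="stable")
        return tmp.groupby("well", sort=False).first().reset_index()

    chosen = select(trend)
    if iterate and len(repeats) > 1:
        for _ in range(10):
            sel_samples = chosen[chosen["role"] == "sample"]
            new_trend = PolynomialResponseModel(degree=degree, robust=robust).fit(
                sel_samples["target"].to_numpy(), sel_samples["value"].to_numpy()
            )
            new_chosen = select(new_trend)
            trend = new_trend
            if new_chosen["repeat"].equals(chosen["repeat"]):
                chosen = new_chosen
                break
            chosen = new_chosen

    order = {w: i for i, w in enumerate(repeats[0].wells)}
    chosen = chosen.sort_values("well", key=lambda s: s.map(order))
    table = pd.DataFrame(
        {
            "well": chosen["well"].to_numpy(),
            "target": chosen["target"].to_numpy(),
            "selected_value": chosen["value"].to_numpy(),
            "selected_repeat": chosen["repeat"].to_numpy(),
            "deviation": chosen["deviation"].to_numpy(),
        }
    )
    return FilteredPlate(table, trend, len(repeats), wavelength, warning)


@dataclass(frozen=True)
class RunMetadata:
    """Stock bookkeeping tying a run's dilution ratios to concentrations.

    ``concentration = stock_concentration * working_factor * target_ratio``;
    e.g. a 4/100 working dilution of a 0.5 mg/mL stock gives
    0.02 mg/mL at ratio 1.
    """

    run_id: str
    stock_concentration: float  # C_0, mg/mL
    working_factor: float = 1.0  # dilution factor of the working mix
    instrument_id: str = ""
    mix_age_days: float = 0.0


def combine_runs(
    filtered_plates: list[FilteredPlate],
    run_metadata: list[RunMetadata],
) -> pd.DataFrame:
    """Pool runs' per-well values onto an absolute concentration scale."""
    if len(filtered_plates) != len(run_metadata):
        raise PlatecalError("one RunMetadata per filtered plate is required")
    frames = []
    for fp, meta in zip(filtered_plates, run_metadata):
        if meta is None:
            raise PlatecalError("missing run metadata")
        conc = meta.stock_concentration * meta.working_factor * fp.table["target"]
        frames.append(
            pd.DataFrame(
                {
                    "run_id": meta.run_id,
                    "well": fp.table["well"],
                    "concentration": conc,
                    "value": fp.table["selected_value"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class CalibrationCurve:
    """Final calibration curve OD = f(concentration) with quality metrics."""

    model: PolynomialResponseModel
    points: pd.DataFrame
    pearson: float
    spearman: float
    rmse: float
    wavelength: float | None = None

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength,
            "degree": self.model.degree,
            "robust": self.model.robust,
            "a": self.model.a_,
            "b": self.model.b_,
            "c": self.model.c_,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "rmse": self.rmse,
            "n_points": int(len(self.points)),
        }


def build_calibration(
    points: pd.DataFrame,
    degree: int = 1,
    robust: bool = True,
    wavelength: float | None = None,
) -> CalibrationCurve:
    """Fit the final calibration curve on pooled (concentration, value) points.

    Metrics follow the inversion workflow: the fitted model is inverted on
    every value and Pearson/Spearman/RMSE are computed between estimated and
    known concentrations (blank points enter the fit at concentration 0 but
    are excluded from RMSE's relative framing only — RMSE here is absolute
    on the concentration scale, over all points).
    """
    conc = points["concentration"].to_numpy(dtype=float)
    vals = points["value"].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise FitError("concentrations must be nonnegative")
    model = PolynomialResponseModel(degree=degree, robust=robust).fit(conc, vals)
    est = np.asarray(model.inverse_predict(vals), dtype=float)
    pearson = float(stats.pearsonr(conc, est).statistic)
    spearman = float(stats.spearmanr(conc, est).statistic)
    rmse = float(np.sqrt(np.mean((est - conc) ** 2)))
    return CalibrationCurve(model, points.copy(), pearson, spearman, rmse, wavelength)


def aggregate_spectrum(
    spectra: list[np.ndarray],
    wavelengths: np.ndarray,
    normalization_wavelength: float | None = None,
    prominence_fraction: float = 0.05,
    min_separation_nm: float = 10.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Mean of normalized spectra plus detected peaks.

    Each spectrum is scaled to 1 at ``normalization_wavelength`` (its global
    maximum when None) before averaging.  Peaks are local maxima with
    prominence above ``prominence_fraction`` of the aggregate's maximum,
    separated by at least ``min_separation_nm``.  A flat spectrum yields an
    empty peak list.
    """
    if not spectra:
        raise PlatecalError("aggregate_spectrum needs at least one spectrum")
    wavelengths = np.asarray(wavelengths, dtype=float)
    normed = []
    for s in spectra:
        s = np.asarray(s, dtype=float)
        if s.shape != wavelengths.shape:
            raise PlatecalError("spectrum/grid length mismatch")
        if normalization_wavelength is None:
            k = s.max()
        else:
            k = s[int(np.argmin(np.abs(wavelengths - normalization_wavelength)))]
        normed.append(s / k if k > 0 else s)
    mean = np.mean(normed, axis=0)
    step = float(np.median(np.diff(wavelengths)))
    distance = max(1, int(round(min_separation_nm / step)))
    prominence = prominence_fraction * mean.max() if mean.max() > 0 else None
    if prominence and prominence > 0:
        locs, _ = signal.find_peaks(mean, prominence=prominence, distance=distance)
    else:
        locs = np.array([], dtype=int)
    peaks = [(float(wavelengths[i]), float(mean[i])) for i in locs]
    return mean, peaks


@dataclass
class DriftSummary:
    """Spectral stability of a plate over a measurement time series."""

    table: pd.DataFrame  # timepoint, similarity, peak_retention
    peak_wavelength: float


def spectral_drift(time_series: list[PlateReading]) -> DriftSummary:
    """Similarity and peak retention of plate-mean spectra versus timepoint 0.

    Similarity is the Pearson correlation of each timepoint's plate-mean
    spectrum with the first; retention is the mean-spectrum height at the
    first timepoint's peak wavelength, relative to its initial height.
    """
    if len(time_series) < 2:
        raise PlatecalError("spectral_drift needs >= 2 timepoints")
    grid = time_series[0].wavelengths
    for r in time_series[1:]:
        if len(r.wavelengths) != len(grid) or not np.allclose(r.wavelengths, grid):
            raise PlatecalError("timepoints must share one wavelength grid")
    means = [r.absorbance.mean(axis=0) for r in time_series]
    j = int(np.argmax(means[0]))
    rows = []
    for t, m in enumerate(means):
        sim = 1.0 if t == 0 else float(stats.pearsonr(means[0], m).statistic)
        retention = float(m[j] / means[0][j]) if means[0][j] != 0 else np.nan
        rows.append((t, sim, retention))
    table = pd.DataFrame(rows, columns=["timepoint", "similarity", "peak_retention"])
    return DriftSummary(table, float(grid[j]))
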