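"""Regression–inversion error assessment of a dilution plate.

The three-step workflow: (1) fit a degree-1 or degree-2 response model of
absorbance (or spectrum-model abundance) on targeted dilution ratio;
(2) invert the model to estimate the realized ratio of every sample well;
(3) map residuals and relative errors across the plate and summarize them
with Pearson/Spearman correlations and RMSE on the ratio scale.  Also
provides per-wavelength correlation scans and column/row-stratified trend
analysis with jump flagging against the global prediction band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError, InversionError
from .plate import ROWS, PlateMap
from .simulate import PlateReading
from .spectral import SpectrumFit

logger = logging.getLogger(__name__)


class PolynomialResponseModel(RegressorMixin, BaseEstimator):
    """Degree-1/2 response model ``f(X) = a X^2 + b X + c`` with inversion.

    ``robust=False`` fits ordinary least squares (with classical prediction
    intervals); ``robust=True`` fits iteratively reweighted least squares
    with Huber weights (tuning constant 1.345 on an MAD scale) to damp
    outliers.  ``inverse_predict`` maps a response back to the dilution
    ratio / concentration on the monotone branch covering the calibration
    range.

    Attributes after fit: ``a_``, ``b_``, ``c_`` (``a_ = 0`` for degree 1),
    ``residual_scale_``, ``x_range_``.
    """

    def __init__(self, degree: int = 1, robust: bool = False):
        self.degree = degree
        self.robust = robust

    def fit(self, X, y) -> "PolynomialResponseModel":
        if self.degree not in (1, 2):
            raise FitError(f"degree must be 1 or 2, got {self.degree}")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise FitError("x and y must have equal length")
        n_distinct = len(np.unique(x))
        if n_distinct < max(3, self.degree + 1):
            raise FitError(
                f"need >= {max(3, self.degree + 1)} distinct x values, got {n_distinct}"
            )
        cols = [np.ones_like(x), x] + ([x**2] if self.degree == 2 else [])
        design = np.column_stack(cols)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FitError("rank-deficient design matrix")
        ols = sm.OLS(y, design).fit()
        if self.robust:
            rlm = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=1.345)).fit(
                scale_est="mad"
            )
            params = rlm.params
            self.residual_scale_ = float(rlm.scale)
        else:
            params = ols.params
            self.residual_scale_ = float(np.sqrt(ols.scale))
        self.c_ = float(params[0])
        self.b_ = float(params[1])
        self.a_ = float(params[2]) if self.degree == 2 else 0.0
        self._ols_result = ols  # classical intervals even for robust fits
        self.x_range_ = (float(x.min()), float(x.max()))
        self.n_obs_ = len(x)
        return self

    # -- prediction -------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return self.a_ * x**2 + self.b_ * x + self.c_

    def prediction_interval(self, X, alpha: float = 0.05):
        """Classical OLS prediction band (lower, upper) at new points."""
        frame = self._interval_frame(X, alpha)
        return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()

    def confidence_interval(self, X, alpha: float = 0.05):
        """Classical OLS mean-confidence band (lower, upper) at new points."""
        frame = self._interval_frame(X, alpha)
        return frame["mean_ci_lower"].to_numpy(), frame["mean_ci_upper"].to_numpy()

    def _interval_frame(self, X, alpha: float):
        x = np.asarray(X, dtype=float).reshape(-1)
        cols = [np.ones_like(x), x] + ([x**2] if self.degree == 2 else [])
        return self._ols_result.get_prediction(np.column_stack(cols)).summary_frame(
            alpha=alpha
        )

    # -- inversion --------------------------------------------------------
    def inverse_predict(self, y) -> np.ndarray:
        """Estimated x for each response y (degree-2: monotone branch)."""
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 0
        y = np.atleast_1d(y)
        if self.degree == 1 or self.a_ == 0.0:
            if self.b_ == 0.0:
                raise InversionError("slope b is zero: model is not invertible")
            out = (y - self.c_) / self.b_
        else:
            out = np.array([self._invert_quadratic(float(v)) for v in y])
        return float(out[0]) if scalar else out

    def _invert_quadratic(self, y: float) -> float:
        a, b, c = self.a_, self.b_, self.c_
        x_lo, x_hi = 0.0, max(self.x_range_[1], 0.0)
        vertex = -b / (2 * a)
        if x_lo < vertex < x_hi:
            raise InversionError(
                f"fitted quadratic is not monotone over [0, {x_hi:g}] "
                f"(vertex at x = {vertex:g})"
            )
        disc = b * b - 4 * a * (c - y)
        if disc < 0:
            raise InversionError(f"no real root for response y = {y:g}")
        sq = np.sqrt(disc)
        roots = ((-b - sq) / (2 * a), (-b + sq) / (2 * a))
        # the monotone branch covering [0, x_hi] lies on one side of the vertex
        on_branch = [r for r in roots if (r >= vertex) == (x_lo >= vertex)]
        if not on_branch:
            raise InversionError(f"no root on the calibration branch for y = {y:g}")
        # closest to the calibration interval if both qualify
        return min(on_branch, key=lambda r: max(x_lo - r, r - x_hi, 0.0))

    def out_of_range(self, x_hat, margin: float = 0.1) -> np.ndarray:
        """Flag estimates outside [-margin, (1+margin)*x_max] (not clipped)."""
        x_hat = np.atleast_1d(np.asarray(x_hat, dtype=float))
        hi = (1.0 + margin) * self.x_range_[1]
        return (x_hat < -margin) | (x_hat > hi)


def fit_response_model(x, y, degree: int = 1, robust: bool = False) -> PolynomialResponseModel:
    """Thin functional wrapper over :class:`PolynomialResponseModel`."""
    return PolynomialResponseModel(degree=degree, robust=robust).fit(x, y)


def invert_model(model: PolynomialResponseModel, y):
    """Estimate the ratio/concentration producing response ``y``."""
    return model.inverse_predict(y)


@dataclass
class AssessmentResult:
    """Per-well and global outcome of the regression–inversion workflow."""

    table: pd.DataFrame  # well, target, response, estimated, residual, relative_error, flagged
    model: PolynomialResponseModel
    pearson: float
    spearman: float
    rmse: float
    wavelength: float | None = None
    per_well_errors: dict[str, str] = field(default_factory=dict)

    def error_map(self, value: str = "relative_error") -> pd.DataFrame:
        """8 x 12 plate-shaped map of a per-well column."""
        grid = pd.DataFrame(
            np.full((8, 12), np.nan), index=list(ROWS), columns=range(1, 13)
        )
        for _, row in self.table.iterrows():
            well = row["well"]
            grid.loc[well[0], int(well[1:])] = row[value]
        return grid

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "rmse": self.rmse,
            "model": {
                "degree": self.model.degree,
                "robust": self.model.robust,
                "a": self.model.a_,
                "b": self.model.b_,
                "c": self.model.c_,
            },
            "wells": self.table.where(pd.notna(self.table), None).to_dict("records"),
        }


def _responses_from_source(reading_or_fit, plate_map, response_source):
    """Per-well response values plus the wavelength used (None for alphas)."""
    if isinstance(reading_or_fit, SpectrumFit):
        if response_source not in (None, "spectrum"):
            raise ValueError("a SpectrumFit input implies response_source='spectrum'")
        return dict(reading_or_fit.alpha), None
    reading: PlateReading = reading_or_fit
    if response_source == "spectrum":
        raise ValueError("response_source='spectrum' requires a SpectrumFit input")
    wavelength = float(response_source)
    return reading.at_wavelength(wavelength), wavelength


def assess_plate(
    reading_or_fit: PlateReading | SpectrumFit,
    plate_map: PlateMap,
    response_source: float | str = 524.0,
    degree: int = 1,
    robust: bool = False,
    metrics_on: str = "estimated",
) -> AssessmentResult:
    """Run the full fit → invert → residual-map workflow on one plate.

    ``response_source`` is a wavelength in nm, or ``"spectrum"`` together
    with a :class:`SpectrumFit` input to use the decomposition's abundance
    coefficients.  Blanks are excluded from the fit and from RMSE; their
    estimated ratios are still reported (with no relative error).
    ``metrics_on`` selects whether the global correlations pair the targets
    with the ``"estimated"`` ratios (default) or the raw ``"response"``.
    """
    responses, wavelength = _responses_from_source(reading_or_fit, plate_map, response_source)
    rows = []
    for well, resp in responses.items():
        spec = plate_map[well]
        rows.append((well, spec.role, spec.target_ratio, resp))
    df = pd.DataFrame(rows, columns=["well", "role", "target", "response"])
    samples = df[df["role"] == "sample"]
    if samples["target"].nunique() < 3:
        raise FitError("assessment requires >= 3 distinct sample targets")
    model = PolynomialResponseModel(degree=degree, robust=robust).fit(
        samples["target"].to_numpy(), samples["response"].to_numpy()
    )
    estimated = np.full(len(df), np.nan)
    errors: dict[str, str] = {}
    for i, resp in enumerate(df["response"]):
        try:
            estimated[i] = model.inverse_predict(resp)
        except InversionError as exc:  # collect, keep going
            errors[df["well"].iloc[i]] = str(exc)
    df["estimated"] = estimated
    df["residual"] = df["estimated"] - df["target"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = df["residual"] / df["target"]
    df["relative_error"] = rel.where(df["target"] > 0)
    df["flagged"] = model.out_of_range(df["estimated"].fillna(0.0)) & df["estimated"].notna()

    s = df[(df["role"] == "sample") & df["estimated"].notna()]
    pair = s["estimated"] if metrics_on == "estimated" else s["response"]
    pearson = float(stats.pearsonr(s["target"], pair).statistic)
    spearman = float(stats.spearmanr(s["target"], pair).statistic)
    rmse = float(np.sqrt(np.mean((s["estimated"] - s["target"]) ** 2)))
    table = df.drop(columns="role")
    return AssessmentResult(table, model, pearson, spearman, rmse, wavelength, errors)


def implied_solute_gain(estimated_ratio, target_ratio):
    """Solute-volume gain implied by an estimated vs targeted dilution ratio.

    A multiplicative bias ``g`` on the solute transfer volume realizes
    ``r' = g r / (1 + (g - 1) r)`` instead of the target ``r`` (the solvent
    volume is unchanged, so the total grows).  Inverting the mass balance,
    ``g = r' (1 - r) / (r (1 - r'))``; wells at ``r = 1`` carry no solvent
    and give no leverage on ``g`` (returned as NaN).
    """
    r = np.asarray(target_ratio, dtype=float)
    rp = np.asarray(estimated_ratio, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = rp * (1 - r) / (r * (1 - rp))
    return np.where((r > 0) & (r < 1) & (rp < 1), g, np.nan)


def correlation_scan(
    reading: PlateReading,
    plate_map: PlateMap,
    metrics: tuple[str, ...] = ("pearson", "spearman", "kendall"),
) -> pd.DataFrame:
    """Correlation between target ratio and absorbance at every wavelength.

    Kendall uses the tau-b formula.  ``"phik"`` is honoured only when the
    optional phik package is importable; otherwise it is omitted with a log
    note.  Wavelengths where the measurement is constant yield NaN.
    """
    idx = [i for i, w in enumerate(reading.wells) if plate_map[w].role == "sample"]
    targets = np.array([plate_map[reading.wells[i]].target_ratio for i in idx])
    if len(np.unique(targets)) < 3:
        raise FitError("correlation scan requires >= 3 distinct targets")
    M = reading.absorbance[idx]
    metrics = tuple(metrics)
    phik_fn = None
    if "phik" in metrics:
        try:  # pragma: no cover - optional dependency
            from phik import phik_matrix  # noqa: F401
            import phik as _phik

            phik_fn = _phik
        except ImportError:
            logger.info("phik not installed; omitting phik from the correlation scan")
            metrics = tuple(m for m in metrics if m != "phik")
    out = {m: np.full(len(reading.wavelengths), np.nan) for m in metrics}
    for j in range(len(reading.wavelengths)):
        y = M[:, j]
        if np.ptp(y) == 0:
            continue
        for m in metrics:
            if m == "pearson":
                out[m][j] = stats.pearsonr(targets, y).statistic
            elif m == "spearman":
                out[m][j] = stats.spearmanr(targets, y).statistic
            elif m == "kendall":
                out[m][j] = stats.kendalltau(targets, y, variant="b").statistic
            elif m == "phik" and phik_fn is not None:  # pragma: no cover
                df = pd.DataFrame({"x": targets, "y": y})
                out[m][j] = df.phik_matrix(interval_cols=["x", "y"]).loc["x", "y"]
    return pd.DataFrame(out, index=pd.Index(reading.wavelengths, name="wavelength_nm"))


@dataclass
class StratumTrend:
    stratum: str
    model: PolynomialResponseModel | None
    n_points: int
    outside_fraction: float
    jump: bool
    note: str = ""


@dataclass
class StratifiedTrends:
    global_model: PolynomialResponseModel
    strata: list[StratumTrend]

    @property
    def flagged(self) -> list[str]:
        return [s.stratum for s in self.strata if s.jump]


def stratified_trends(
    reading: PlateReading,
    plate_map: PlateMap,
    by: str = "column",
    wavelength: float = 524.0,
    degree: int = 1,
    band_alpha: float = 0.05,
    jump_threshold: float = 0.5,
) -> StratifiedTrends:
    """Per-column (or per-row) response trends versus the plate-wide trend.

    A stratum is flagged as a *jump* when more than ``jump_threshold`` of its
    points sit where the stratum fit's ``1 - band_alpha`` confidence band
    does not overlap the global model's confidence band — the stratum's
    trend has exited the plate-wide trend by more than both uncertainties
    allow.  This is the signature of a correlated (e.g. carryover) error
    confined to part of the plate: within such a stratum the trend is tight,
    yet displaced from the plate-wide band; under independent well noise the
    stratum band is wide and overlap is retained.  Strata with fewer than
    two distinct targets are skipped with a note.
    """
    if by not in ("column", "row"):
        raise ValueError("by must be 'column' or 'row'")
    responses = reading.at_wavelength(wavelength)
    recs = [
        (w, plate_map[w].target_ratio, responses[w])
        for w in reading.wells
        if plate_map[w].role == "sample"
    ]
    df = pd.DataFrame(recs, columns=["well", "target", "response"])
    df["stratum"] = [w[1:] if by == "column" else w[0] for w in df["well"]]
    global_model = PolynomialResponseModel(degree=degree).fit(
        df["target"].to_numpy(), df["response"].to_numpy()
    )
    # separation tolerance against exactly-deterministic (zero-residual) data
    eps = 1e-9 * max(float(np.abs(df["response"]).max()), 1.0)
    strata = []
    for name, grp in df.groupby("stratum", sort=True):
        x = grp["target"].to_numpy()
        y = grp["response"].to_numpy()
        glo, ghi = global_model.confidence_interval(x, alpha=band_alpha)
        if grp["target"].nunique() < 2:
            strata.append(
                StratumTrend(str(name), None, len(grp), 0.0, False,
                             note="skipped: fewer than 2 distinct targets")
            )
            continue
        try:
            m = PolynomialResponseModel(degree=1).fit(x, y)
        except FitError:
            m = None
        if m is None:
            slo, shi = y, y  # fall back to raw points with no uncertainty
        else:
            slo, shi = m.confidence_interval(x, alpha=band_alpha)
        disjoint = (slo > ghi + eps) | (shi < glo - eps)
        frac = float(np.mean(disjoint))
        strata.append(StratumTrend(str(name), m, len(grp), frac, frac > jump_threshold))
    return StratifiedTrends(global_model, strata)
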