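"""Constrained spectrum decomposition of a plate scan.

The spectrum model explains every sample well's scan as a per-well multiple
of one shared solute spectrum ``S`` on top of a plate baseline ``B``:

    M[i, lam] ~ alpha[i] * S[lam] + B[lam]

with ``S >= 0``, ``B >= 0``, ``alpha >= 0`` elementwise, and a quadratic
penalty ``w * sum_lam (B[lam] - blank_mean[lam])^2`` anchoring the baseline
to the plate's blank wells.  The fit alternates exact nonnegative
(clipped closed-form) updates of ``alpha``, ``S`` and ``B``, each of which
cannot increase the objective, until the relative objective change drops
below ``tol``.  Because ``(S, alpha) -> (S/k, k*alpha)`` leaves the data
term unchanged, the reported ``S`` is normalized to 1 at a reference
wavelength (the spectrum maximum by default) and ``alpha`` rescaled to
compensate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import FitError
from .plate import PlateMap
from .simulate import PlateReading


@dataclass
class SpectrumFit:
    """Result of a spectrum-model decomposition."""

    wavelengths: np.ndarray
    S: np.ndarray
    B: np.ndarray
    alpha: dict[str, float]
    lambda_ref: float
    penalty_weight: float
    objective_trace: list[float]
    converged: bool
    n_iter: int

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def to_dict(self) -> dict:
        return {
            "lambda_ref_nm": float(self.lambda_ref),
            "wavelengths_nm": [float(v) for v in self.wavelengths],
            "S": [float(v) for v in self.S],
            "B": [float(v) for v in self.B],
            "alpha": {k: float(v) for k, v in self.alpha.items()},
            "objective": float(self.objective),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def spectrum_model_objective(
    M: np.ndarray,
    alpha: np.ndarray,
    S: np.ndarray,
    B: np.ndarray,
    blank_mean: np.ndarray,
    penalty_weight: float,
) -> float:
    """Penalized least-squares objective of the spectrum model."""
    resid = M - np.outer(alpha, S) - B[None, :]
    return float(np.sum(resid**2) + penalty_weight * np.sum((B - blank_mean) ** 2))


class SpectrumModel(BaseEstimator):
    """Nonnegative shared-spectrum + baseline decomposition of a plate scan.

    Parameters
    ----------
    penalty_weight : float
        Weight ``w`` of the quadratic pull of the baseline toward the blank
        mean spectrum.
    wavelength_range : tuple (lo, hi) in nm, or None
        Restrict the fit to this wavelength window.
    reference_wavelength : float or None
        Where to normalize ``S`` to 1; ``None`` uses the spectrum maximum.
    tol, max_iter
        Relative-objective-change stopping rule for the alternating updates.

    Attributes (after :meth:`fit`)
    ------------------------------
    S_, B_ : arrays over ``wavelengths_``; alpha_ : per-well coefficients
    aligned with ``wells_``; objective_trace_ (nonincreasing), n_iter_,
    converged_, lambda_ref_.
    """

    def __init__(
        self,
        penalty_weight: float = 1.0,
        wavelength_range: tuple[float, float] | None = None,
        reference_wavelength: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.penalty_weight = penalty_weight
        self.wavelength_range = wavelength_range
        self.reference_wavelength = reference_wavelength
        self.tol = tol
        self.max_iter = max_iter

    def fit(
        self,
        reading: PlateReading,
        plate_map: PlateMap | None = None,
        blank_wells: list[str] | None = None,
    ) -> "SpectrumModel":
        """Decompose ``reading``; blanks come from ``plate_map`` or are
        listed explicitly via ``blank_wells``."""
        lam = reading.wavelengths
        mask = np.ones(len(lam), dtype=bool)
        if self.wavelength_range is not None:
            lo, hi = self.wavelength_range
            mask = (lam >= lo) & (lam <= hi)
            if not mask.any():
                raise FitError("wavelength_range excludes the entire grid")
        lam = lam[mask]
        M = reading.absorbance[:, mask]
        wells = list(reading.wells)
        if blank_wells is not None:
            blanks = set(blank_wells)
        elif plate_map is not None:
            blanks = {w for w in wells if plate_map[w].role == "blank"}
        else:
            raise FitError("either plate_map or blank_wells must be given")
        blank_idx = [i for i, w in enumerate(wells) if w in blanks]
        if not blank_idx:
            raise FitError("spectrum model requires at least one blank well")
        if not np.any(M > 0):
            raise FitError("all-zero plate: spectrum model is degenerate")
        blank_mean = M[blank_idx].mean(axis=0)
        w = float(self.penalty_weight)
        n = M.shape[0]

        # warm start: baseline from blanks, S from the strongest well
        B = np.clip(blank_mean, 0.0, None)
        if plate_map is not None:
            targets = np.array([plate_map[well].target_ratio for well in wells])
        else:
            targets = M.sum(axis=1)  # strongest scan stands in for the top target
        top = int(np.argmax(targets))
        S = np.clip(M[top] - B, 0.0, None)
        if not np.any(S > 0):
            S = np.clip(M.max(axis=0) - B, 0.0, None)
        alpha = self._update_alpha(M, S, B)

        trace = [spectrum_model_objective(M, alpha, S, B, blank_mean, w)]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            alpha = self._update_alpha(M, S, B)
            S = self._update_S(M, alpha, B)
            B = self._update_B(M, alpha, S, blank_mean, w, n)
            obj = spectrum_model_objective(M, alpha, S, B, blank_mean, w)
            trace.append(obj)
            prev = trace[-2]
            if prev - obj <= self.tol * max(prev, 1e-300):
                converged = True
                break

        # fix the (S, alpha) scale at the reference wavelength
        if self.reference_wavelength is None:
            ref_j = int(np.argmax(S))
        else:
            ref_j = int(np.argmin(np.abs(lam - self.reference_wavelength)))
        k = S[ref_j]
        if k > 0:
            S = S / k
            alpha = alpha * k

        self.wavelengths_ = lam
        self.wells_ = wells
        self.S_ = S
        self.B_ = B
        self.alpha_ = alpha
        self.lambda_ref_ = float(lam[ref_j])
        self.blank_mean_ = blank_mean
        self.objective_trace_ = trace
        self.n_iter_ = it
        self.converged_ = converged
        return self

    @staticmethod
    def _update_alpha(M: np.ndarray, S: np.ndarray, B: np.ndarray) -> np.ndarray:
        denom = float(S @ S)
        if denom <= 0:
            return np.zeros(M.shape[0])
        return np.clip((M - B[None, :]) @ S / denom, 0.0, None)

    @staticmethod
    def _update_S(M: np.ndarray, alpha: np.ndarray, B: np.ndarray) -> np.ndarray:
        denom = float(alpha @ alpha)
        if denom <= 0:
            return np.zeros(M.shape[1])
        return np.clip(alpha @ (M - B[None, :]) / denom, 0.0, None)

    @staticmethod
    def _update_B(
        M: np.ndarray, alpha: np.ndarray, S: np.ndarray,
        blank_mean: np.ndarray, w: float, n: int,
    ) -> np.ndarray:
        num = (M - np.outer(alpha, S)).sum(axis=0) + w * blank_mean
        return np.clip(num / (n + w), 0.0, None)

    def result(self) -> SpectrumFit:
        """Package the fitted decomposition for serialization."""
        return SpectrumFit(
            wavelengths=self.wavelengths_,
            S=self.S_,
            B=self.B_,
            alpha={w: float(a) for w, a in zip(self.wells_, self.alpha_)},
            lambda_ref=self.lambda_ref_,
            penalty_weight=self.penalty_weight,
            objective_trace=self.objective_trace_,
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


def fit_spectrum_model(
    reading: PlateReading,
    plate_map: PlateMap,
    wavelength_range: tuple[float, float] | None = None,
    penalty_weight: float = 1.0,
    reference_wavelength: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SpectrumFit:
    """Fit the spectrum model and return a serializable :class:`SpectrumFit`."""
    model = SpectrumModel(
        penalty_weight=penalty_weight,
        wavelength_range=wavelength_range,
        reference_wavelength=reference_wavelength,
        tol=tol,
        max_iter=max_iter,
    ).fit(reading, plate_map)
    return model.result()
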