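"""Synthetic plate generator: instruction execution under pipetting error
models, and absorbance rendering with a carotenoid-like spectrum.

The executor keeps exact mass/volume bookkeeping per well while perturbing
every transfer volume with the configured error classes (independent noise,
constant offset, multiplicative gain, reservoir concentration error,
column-to-column carryover, contamination droplets).  The renderer turns the
resulting per-well concentration fractions into wells x wavelengths
absorbance matrices via a Beer–Lambert response with optional saturation
curvature, a blank baseline, read noise, and per-repeat transient
excursions that decay back toward the trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, SimulationError
from .plate import (
    DISCARD,
    SOLUTE_RESERVOIR,
    SOLVENT_RESERVOIR,
    PlateMap,
    TransferInstruction,
    WellAddress,
    all_addresses,
)

DEFAULT_WAVELENGTHS = np.arange(350.0, 651.0, 2.0)  # 350–650 nm, 2 nm steps

#: Three-peak carotenoid-like solute spectrum: (center nm, Gaussian sd nm,
#: height).  Centers follow the lycopene-in-DMSO triplet; widths/heights are
#: chosen so the triplet stays resolved on the 2 nm grid.
DEFAULT_PEAKS = ((458.0, 11.0, 0.70), (488.0, 11.0, 1.00), (524.0, 12.0, 0.82))


@dataclass
class SpectrumConfig:
    """Solute spectrum, baseline and aging model for the renderer."""

    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    peaks: Sequence[tuple[float, float, float]] = DEFAULT_PEAKS
    aging_flatness: float = 0.0
    baseline_level: float = 0.04
    baseline_tilt: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if any(h < 0 for _, _, h in self.peaks):
            raise ConfigurationError("peak heights must be nonnegative")
        if not 0 <= self.aging_flatness <= 1:
            raise ConfigurationError("aging_flatness must be in [0, 1]")

    def solute_spectrum(self) -> np.ndarray:
        """Peaked spectrum mixed toward a broad background by aging."""
        lam = self.wavelengths
        peaked = np.zeros_like(lam)
        for center, sd, height in self.peaks:
            peaked += height * np.exp(-0.5 * ((lam - center) / sd) ** 2)
        broad_center = float(np.mean([c for c, _, _ in self.peaks])) if self.peaks else 480.0
        broad = np.exp(-0.5 * ((lam - broad_center) / 80.0) ** 2)
        if peaked.max() > 0:
            broad *= peaked.max()
        a = self.aging_flatness
        return (1 - a) * peaked + a * broad

    def baseline(self) -> np.ndarray:
        lam = self.wavelengths
        span = lam[-1] - lam[0] if lam[-1] > lam[0] else 1.0
        b = self.baseline_level + self.baseline_tilt * (lam - lam[0]) / span
        return np.clip(b, 0.0, None)


@dataclass
class ErrorConfig:
    """Liquid-handling and measurement error parameters.

    All-zero (the default) gives an ideal, deterministic execution.  Volume
    units are uL, absorbance units OD.
    """

    independent_cv: float = 0.0         # sd of transfer volume, fraction of v
    constant_offset: float = 0.0        # additive uL on every transfer
    systematic_gain: float = 1.0        # multiplicative bias on volumes
    systematic_gain_scope: str = "all"  # all | solute | solvent
    reservoir_concentration_error: float = 0.0  # fractional stock mis-make
    carryover_excess: float = 0.0       # extra uL on each column transfer
    contamination_prob: float = 0.0     # per travel
    droplet_volume: float = 0.0         # uL lost to a random well per event
    transient_prob: float = 0.0         # per-well per-repeat excursion trigger
    transient_scale: float = 0.0        # excursion magnitude (multiplicative)
    transient_decay: float = 0.5        # geometric decay per repeat
    measurement_noise_sd: float = 0.0   # OD read noise
    curvature: float = 0.0              # gamma in g(c) = c / (1 + gamma c)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contamination_prob", "transient_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.systematic_gain_scope not in ("all", "solute", "solvent"):
            raise ConfigurationError(
                f"systematic_gain_scope must be all|solute|solvent, "
                f"got {self.systematic_gain_scope!r}"
            )
        if not 0 < self.transient_decay <= 1:
            raise ConfigurationError("transient_decay must be in (0, 1]")


@dataclass
class PlateReading:
    """One wells x wavelengths absorbance scan with run metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray  # shape (96, n_wavelengths)
    wells: list[str] = field(default_factory=lambda: [str(a) for a in all_addresses()])
    run_id: str = "sim"
    plate_id: str = "01"
    instrument_id: str = "synthetic"
    repeat_index: int = 0
    timestamp: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != (len(self.wells), len(self.wavelengths)):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.wells)} wells x {len(self.wavelengths)} wavelengths"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def at_wavelength(self, wavelength: float) -> dict[str, float]:
        """Per-well absorbance at the grid point nearest ``wavelength``."""
        j = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return {w: float(self.absorbance[i, j]) for i, w in enumerate(self.wells)}

    def well_index(self, well: str) -> int:
        return self.wells.index(well)


@dataclass
class PlateComposition:
    """Ground-truth contents of every well after executing an instruction list."""

    wells: list[str]
    solute_volume: np.ndarray   # uL of stock liquid per well
    solvent_volume: np.ndarray  # uL of diluent per well
    true_ratio: np.ndarray      # concentration fraction of nominal stock
    realized_volumes: list[tuple[int, float]]  # (step, realized uL)

    @property
    def total_volume(self) -> np.ndarray:
        return self.solute_volume + self.solvent_volume


@dataclass
class SimulatedPlate:
    """A simulated experiment: composition ground truth plus its readings."""

    composition: PlateComposition
    readings: list[PlateReading]
    plate_map: PlateMap

    @property
    def reading(self) -> PlateReading:
        return self.readings[0]


def _well_order_index() -> dict[str, int]:
    return {str(a): i for i, a in enumerate(all_addresses())}


def execute_instructions(
    instructions: Sequence[TransferInstruction],
    plate_map: PlateMap,
    error: ErrorConfig | None = None,
) -> PlateComposition:
    """Execute a transfer list with perturbed volumes and exact bookkeeping.

    Each transfer volume ``v`` is realized as ``gain*v + N(0, (cv*v)^2) +
    offset`` (clipped at zero); column transfers additionally receive the
    carryover excess.  Contamination events divert a droplet of the carried
    liquid to a uniformly chosen well.  Wells are assumed perfectly mixed, so
    aspiration from a well removes solute and solvent proportionally.
    """
    error = error or ErrorConfig()
    idx = _well_order_index()
    wells = list(idx)
    n = len(wells)
    solute = np.zeros(n)
    solvent = np.zeros(n)
    stock_concentration = 1.0 + error.reservoir_concentration_error
    child_seeds = np.random.SeedSequence(error.seed).spawn(len(instructions))
    log: list[tuple[int, float]] = []

    for inst, seed in zip(instructions, child_seeds):
        rng = np.random.default_rng(seed)
        if inst.phase == "mix":
            log.append((inst.step, inst.volume))
            continue
        gain = 1.0
        if error.systematic_gain_scope == "all":
            gain = error.systematic_gain
        elif error.systematic_gain_scope == "solute" and inst.source == SOLUTE_RESERVOIR:
            gain = error.systematic_gain
        elif error.systematic_gain_scope == "solvent" and inst.source == SOLVENT_RESERVOIR:
            gain = error.systematic_gain
        v = gain * inst.volume + error.constant_offset
        if error.independent_cv > 0:
            v += rng.normal(0.0, error.independent_cv * inst.volume)
        if inst.phase == "column_transfer":
            v += error.carryover_excess
        v = max(v, 0.0)
        log.append((inst.step, v))

        # aspirate
        if inst.source == SOLUTE_RESERVOIR:
            d_solute, d_solvent = v, 0.0
        elif inst.source == SOLVENT_RESERVOIR:
            d_solute, d_solvent = 0.0, v
        else:
            i = idx[str(WellAddress.from_string(inst.source))]
            total = solute[i] + solvent[i]
            if v > total + 1e-9:
                raise SimulationError(
                    f"step {inst.step}: aspirating {v:.3f} uL from {inst.source} "
                    f"holding only {total:.3f} uL"
                )
            frac = 0.0 if total <= 0 else v / total
            d_solute, d_solvent = solute[i] * frac, solvent[i] * frac
            solute[i] -= d_solute
            solvent[i] -= d_solvent

        # contamination: a droplet of the carried liquid lands elsewhere
        if error.contamination_prob > 0 and error.droplet_volume > 0:
            if rng.random() < error.contamination_prob:
                carried = d_solute + d_solvent
                drop = min(error.droplet_volume, carried)
                if carried > 0 and drop > 0:
                    f = drop / carried
                    j = int(rng.integers(0, n))
                    solute[j] += d_solute * f
                    solvent[j] += d_solvent * f
                    d_solute *= 1 - f
                    d_solvent *= 1 - f

        # dispense
        if inst.destination == DISCARD:
            continue
        i = idx[str(WellAddress.from_string(inst.destination))]
        solute[i] += d_solute
        solvent[i] += d_solvent

    total = solute + solvent
    if np.any(total < -1e-9):
        raise SimulationError("negative well volume after execution")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, solute * stock_concentration / np.maximum(total, 1e-300), 0.0)
    return PlateComposition(wells, solute, solvent, ratio, log)


def render_absorbance(
    composition: PlateComposition,
    spectrum: SpectrumConfig | None = None,
    error: ErrorConfig | None = None,
    n_repeats: int = 1,
) -> list[PlateReading]:
    """Render technical-repeat absorbance scans from a plate composition.

    The response is ``A_i(lam) = (1 + e_it) g(c_i) S(lam) + B(lam) + noise``
    with ``g(c) = c / (1 + gamma c)`` (``gamma = 0`` recovers Beer–Lambert
    linearity).  ``e_it`` is the transient-excursion excess of well ``i`` at
    repeat ``t``: triggers with probability proportional to concentration,
    then decays geometrically, mimicking transient solubility artifacts that
    regress toward the trend over successive readings.
    """
    spectrum = spectrum or SpectrumConfig()
    error = error or ErrorConfig()
    S = spectrum.solute_spectrum()
    B = spectrum.baseline()
    c = np.asarray(composition.true_ratio, dtype=float)
    g = c / (1.0 + error.curvature * c)
    rng = np.random.default_rng(np.random.SeedSequence([error.seed, 7]))
    c_max = c.max() if c.max() > 0 else 1.0
    trigger_p = error.transient_prob * (c / c_max)
    excess = np.zeros(len(c))
    readings = []
    for t in range(n_repeats):
        if error.transient_prob > 0:
            excess *= error.transient_decay
            hits = rng.random(len(c)) < trigger_p
            excess[hits] += error.transient_scale * np.abs(rng.standard_normal(hits.sum()))
        A = np.outer((1.0 + excess) * g, S) + B[None, :]
        if error.measurement_noise_sd > 0:
            A = A + rng.normal(0.0, error.measurement_noise_sd, size=A.shape)
        readings.append(
            PlateReading(
                wavelengths=spectrum.wavelengths.copy(),
                absorbance=A,
                wells=list(composition.wells),
                repeat_index=t,
            )
        )
    return readings


def simulate_plate(
    plate_map: PlateMap,
    instructions: Sequence[TransferInstruction],
    spectrum: SpectrumConfig | None = None,
    error: ErrorConfig | None = None,
    n_repeats: int = 1,
) -> SimulatedPlate:
    """Execute instructions and render repeats in one call."""
    composition = execute_instructions(instructions, plate_map, error)
    readings = render_absorbance(composition, spectrum, error, n_repeats)
    return SimulatedPlate(composition, readings, plate_map)
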