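"""Plate maps and transfer instructions for the two built-in dilution schemes.

A 96-well plate (rows A–H, columns 1–12) is laid out either with the
*geometric* (serial, column-to-column 1:2) dilution scheme or the *linear*
(direct, reservoir-to-well) scheme.  Both reserve columns 11–12 for blanks
(pure diluent) and duplicate every dilution ratio in adjacent row pairs
(A=B, C=D, E=F, G=H) as technical repeats.  Every well ends up holding the
same total volume (200 uL by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError, InstructionError

ROWS = "ABCDEFGH"
N_COLUMNS = 12
BLANK_COLUMNS = (11, 12)

SOLUTE_RESERVOIR = "solute_reservoir"
SOLVENT_RESERVOIR = "solvent_reservoir"
DISCARD = "discard"

_WELL_RE = re.compile(r"^([A-Ha-h])0?([1-9]|1[0-2])$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well coordinate, row letter A–H and 1-based column 1–12."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"row must be one of {ROWS!r}, got {self.row!r}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ValueError(f"column must be in [1, {N_COLUMNS}], got {self.column}")

    @classmethod
    def from_string(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(text.strip())
        if m is None:
            raise ValueError(f"invalid well address {text!r}")
        return cls(row=m.group(1).upper(), column=int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


def all_addresses() -> list[WellAddress]:
    """All 96 addresses in row-major order (A1..A12, B1..B12, ...)."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLUMNS + 1)]


@dataclass(frozen=True)
class WellSpec:
    """Role and dilution target of one well.

    ``target_ratio`` is the fraction of the stock concentration intended for
    the well (1 = undiluted stock, 0 = pure diluent).  ``replicate_group``
    identifies wells sharing a target within the plate.
    """

    address: WellAddress
    role: str  # "sample" | "blank"
    target_ratio: float
    block: int | None = None
    replicate_group: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("sample", "blank"):
            raise ValueError(f"role must be 'sample' or 'blank', got {self.role!r}")
        if self.role == "blank" and self.target_ratio != 0:
            raise ValueError("blank wells must have target_ratio 0")
        if self.role == "sample" and not 0 < self.target_ratio <= 1:
            raise ValueError("sample wells must have target_ratio in (0, 1]")


@dataclass
class PlateMap:
    """A full 96-well plate layout for one dilution scheme."""

    scheme: str  # "geometric" | "linear"
    wells: list[WellSpec]
    total_volume: float = 200.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wells) != 96:
            raise ValueError(f"a plate map needs exactly 96 wells, got {len(self.wells)}")
        addrs = [w.address for w in self.wells]
        if len(set(addrs)) != 96:
            raise ValueError("duplicate well addresses in plate map")
        self._by_address = {w.address: w for w in self.wells}

    def __getitem__(self, address: WellAddress | str) -> WellSpec:
        if isinstance(address, str):
            address = WellAddress.from_string(address)
        return self._by_address[address]

    @property
    def n_sample_wells(self) -> int:
        return sum(1 for w in self.wells if w.role == "sample")

    def sample_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.role == "sample"]

    def blank_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.role == "blank"]

    def target_ratios(self) -> dict[str, float]:
        return {str(w.address): w.target_ratio for w in self.wells}


@dataclass(frozen=True)
class TransferInstruction:
    """One aspirate/dispense step.

    ``source`` is a reservoir name or a well; ``destination`` a well or
    ``"discard"``.  Aspirated and dispensed volumes are equal here, so a
    single ``volume`` field carries both.
    """

    step: int
    phase: str  # prefill | direct | column_transfer | mix | discard
    source: str
    destination: str
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("transfer volume must be positive")
        if self.phase not in ("prefill", "direct", "column_transfer", "mix", "discard"):
            raise ValueError(f"unknown phase {self.phase!r}")


def _pair_rows() -> list[tuple[str, str]]:
    """Technical-repeat row pairs: (A,B), (C,D), (E,F), (G,H)."""
    return [(ROWS[i], ROWS[i + 1]) for i in range(0, 8, 2)]


def _blank_specs(start_group: int) -> list[WellSpec]:
    specs = []
    for col in BLANK_COLUMNS:
        for row in ROWS:
            specs.append(
                WellSpec(WellAddress(row, col), "blank", 0.0, block=None,
                         replicate_group=start_group)
            )
    return specs


def build_linear_map(step: float = 0.05, total_volume: float = 200.0) -> PlateMap:
    """Linear (direct) dilution scheme: Fig-1B style plate map.

    Two identical blocks (columns 1–5 and 6–10) each hold the 20 ratios
    {1.00, 0.95, ..., 0.05} descending column-major over the distinct row
    pairs; columns 11–12 are blanks.
    """
    if step <= 0 or step > 1:
        raise ConfigurationError(f"step must be in (0, 1], got {step}")
    inv = 1.0 / step
    if abs(inv - round(inv)) > 1e-9:
        raise ConfigurationError(f"1/step must be an integer, got step={step}")
    n_values = int(round(inv))
    if step * total_volume <= 0:
        raise ConfigurationError("step*total_volume must be a positive volume")
    pairs = _pair_rows()
    n_slots = len(pairs) * 5  # 4 row pairs x 5 columns per block
    if n_values != n_slots:
        raise ConfigurationError(
            f"step {step} yields {n_values} ratios but a block holds {n_slots} slots"
        )
    values = [round((n_values - k) * step, 12) for k in range(n_values)]  # 1.00 .. step
    wells: list[WellSpec] = []
    for block, col0 in ((1, 1), (2, 6)):
        k = 0
        for col in range(col0, col0 + 5):
            for top, bottom in pairs:
                ratio = values[k]
                for row in (top, bottom):
                    wells.append(
                        WellSpec(WellAddress(row, col), "sample", ratio,
                                 block=block, replicate_group=k)
                    )
                k += 1
    wells.extend(_blank_specs(start_group=n_values))
    return PlateMap("linear", wells, total_volume, meta={"step": step})


def build_geometric_map(
    first_column: Sequence[float] = (1.0, 7 / 8, 3 / 4, 5 / 8),
    fold: float = 2.0,
    total_volume: float = 200.0,
) -> PlateMap:
    """Geometric (serial) dilution scheme: Fig-1A style plate map.

    Column 1 carries ``first_column`` on rows A, C, E, G (duplicated below);
    each subsequent column 2..10 divides the previous by ``fold``.
    """
    if fold <= 1:
        raise ConfigurationError(f"fold must exceed 1, got {fold}")
    fc = list(first_column)
    if len(fc) != 4:
        raise ConfigurationError("first_column needs 4 values (rows A, C, E, G)")
    if any(not 0 < v <= 1 for v in fc):
        raise ConfigurationError("first_column values must be in (0, 1]")
    if any(fc[i] <= fc[i + 1] for i in range(3)):
        raise ConfigurationError("first_column must be strictly decreasing")
    wells: list[WellSpec] = []
    group = 0
    for p, (top, bottom) in enumerate(_pair_rows()):
        for col in range(1, 11):
            ratio = fc[p] / fold ** (col - 1)
            for row in (top, bottom):
                wells.append(
                    WellSpec(WellAddress(row, col), "sample", ratio,
                             block=None, replicate_group=group)
                )
            group += 1
    wells.extend(_blank_specs(start_group=group))
    return PlateMap("geometric", wells, total_volume,
                    meta={"fold": fold, "first_column": fc})


def _check_multiple(volume: float, increment: float) -> bool:
    if volume < 0:
        return False
    ratio = volume / increment
    return abs(ratio - round(ratio)) < 1e-9


def linear_transfer_instructions(
    plate_map: PlateMap, min_increment: float = 10.0
) -> list[TransferInstruction]:
    """Direct-transfer list realizing a linear map: reservoirs to wells only.

    Per well one solvent transfer of ``(1-ratio)*V`` followed (globally) by
    one solute transfer of ``ratio*V``; solvent is dispensed first.  All
    reservoir volumes must be multiples of ``min_increment``.
    """
    solvent_steps: list[tuple[str, float]] = []
    solute_steps: list[tuple[str, float]] = []
    V = plate_map.total_volume
    for w in plate_map.wells:
        v_solute = w.target_ratio * V
        v_solvent = V - v_solute
        for v, name in ((v_solute, "solute"), (v_solvent, "solvent")):
            if v > 1e-12 and not _check_multiple(v, min_increment):
                raise InstructionError(
                    f"well {w.address}: {name} volume {v:g} uL is not a "
                    f"multiple of {min_increment:g} uL"
                )
        # snap float dust to the increment grid (validated above)
        v_solute = round(v_solute / min_increment) * min_increment
        v_solvent = V - v_solute
        if v_solvent > 1e-12:
            solvent_steps.append((str(w.address), v_solvent))
        if v_solute > 1e-12:
            solute_steps.append((str(w.address), v_solute))
    instructions = []
    step = 1
    for dest, v in solvent_steps:
        instructions.append(TransferInstruction(step, "direct", SOLVENT_RESERVOIR, dest, v))
        step += 1
    for dest, v in solute_steps:
        instructions.append(TransferInstruction(step, "direct", SOLUTE_RESERVOIR, dest, v))
        step += 1
    return instructions


def geometric_transfer_instructions(
    plate_map: PlateMap, transfer_volume: float | None = None
) -> list[TransferInstruction]:
    """Iterative-transfer list realizing a geometric map.

    Columns 2–10 are prefilled with solvent (``V_p = total_volume``), column 1
    is built by direct dilution at volume ``total_volume + V_t``, then ``V_t``
    is carried column to column (with a mix step at each destination) and
    finally discarded from column 10.  ``V_t`` solves
    ``V_t / (V_t + V_p) = 1/fold``.
    """
    fold = plate_map.meta.get("fold")
    if fold is None:
        raise ConfigurationError("plate map does not define a dilution fold")
    if fold <= 1:
        raise ConfigurationError(f"fold must exceed 1, got {fold}")
    V = plate_map.total_volume
    v_p = V
    v_t = v_p / (fold - 1.0)
    if transfer_volume is not None:
        if abs(transfer_volume - v_t) > 1e-9:
            raise ConfigurationError(
                f"transfer_volume {transfer_volume:g} uL inconsistent with fold "
                f"{fold:g} and total volume {V:g} uL (requires {v_t:g} uL)"
            )
        v_t = transfer_volume
    instructions: list[TransferInstruction] = []
    step = 1
    # prefill solvent into columns 2..10, and blanks (11..12) to full volume
    for col in range(2, 11):
        for row in ROWS:
            instructions.append(
                TransferInstruction(step, "prefill", SOLVENT_RESERVOIR, f"{row}{col}", v_p)
            )
            step += 1
    for col in BLANK_COLUMNS:
        for row in ROWS:
            instructions.append(
                TransferInstruction(step, "prefill", SOLVENT_RESERVOIR, f"{row}{col}", V)
            )
            step += 1
    # column 1 by direct dilution at working volume V + V_t, solvent first
    v1 = V + v_t
    col1 = [plate_map[f"{row}1"] for row in ROWS]
    for w in col1:
        v_solvent = (1 - w.target_ratio) * v1
        if v_solvent > 1e-12:
            instructions.append(
                TransferInstruction(step, "direct", SOLVENT_RESERVOIR, str(w.address), v_solvent)
            )
            step += 1
    for w in col1:
        v_solute = w.target_ratio * v1
        if v_solute > 1e-12:
            instructions.append(
                TransferInstruction(step, "direct", SOLUTE_RESERVOIR, str(w.address), v_solute)
            )
            step += 1
    # serial transfers with mixing
    for col in range(2, 11):
        for row in ROWS:
            src, dst = f"{row}{col - 1}", f"{row}{col}"
            instructions.append(
                TransferInstruction(step, "column_transfer", src, dst, v_t)
            )
            step += 1
            instructions.append(TransferInstruction(step, "mix", dst, dst, v_t))
            step += 1
    # discard the residual transfer volume from column 10
    for row in ROWS:
        instructions.append(
            TransferInstruction(step, "discard", f"{row}10", DISCARD, v_t)
        )
        step += 1
    return instructions
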