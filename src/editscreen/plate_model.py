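"""Data model and I/O for 384-well dual-channel luminescence plates.

A screen is stored as two long-format CSV tables:

* measurements: ``plate_id,well,channel,value`` with channel in {FFL, Nluc}
* plate map:    ``plate_id,well,role,compound_id,dose_uM``

Wells are addressed row-letter + 1-based column (``A1`` .. ``P24``), the
convention used by essentially every plate-reader export. The default layout
places compounds in columns 1-22 and the DMSO-vehicle / Nluc-inhibitor
controls in columns 23 and 24.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLUMNS = 24
NEG_CONTROL_COLUMN = 23
POS_CONTROL_COLUMN = 24
COMPOUND_COLUMNS = tuple(range(1, 23))
WELLS_PER_PLATE = N_ROWS * N_COLUMNS

CHANNELS = ("FFL", "Nluc")

MEASUREMENT_COLUMNS = ["plate_id", "well", "channel", "value"]
PLATEMAP_COLUMNS = ["plate_id", "well", "role", "compound_id", "dose_uM"]

_ADDRESS_RE = re.compile(r"^([A-P])([1-9][0-9]?)$")


class Role(str, enum.Enum):
    """What a well holds: a library compound, a control, or nothing usable."""

    COMPOUND = "compound"
    NEG_CONTROL = "neg_control"
    POS_CONTROL = "pos_control"
    EMPTY = "empty"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A 384-well position: row letter A-P, column 1-24."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise ValueError(f"row {self.row!r} outside A-{ROW_LETTERS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ValueError(f"column {self.column} outside 1-{N_COLUMNS}")

    @classmethod
    def from_string(cls, text: str) -> "WellAddress":
        m = _ADDRESS_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed well address {text!r}")
        return cls(row=m.group(1), column=int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


def all_addresses() -> Iterator[WellAddress]:
    """All 384 addresses in row-major order (A1..A24, B1.., .., P24)."""
    for row in ROW_LETTERS:
        for col in range(1, N_COLUMNS + 1):
            yield WellAddress(row, col)


@dataclass
class Well:
    """One well's identity plus its two luminescence channel values.

    ``ffl``/``nluc`` are ``None`` for wells with no usable measurement
    (role ``empty``); otherwise they are finite non-negative counts.
    """

    address: WellAddress
    role: Role
    compound_id: str | None = None
    dose: float = 0.0  # uM; 0 for vehicle controls
    ffl: float | None = None
    nluc: float | None = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if self.role is Role.COMPOUND and not self.compound_id:
            raise ValueError(f"compound well {self.address} lacks a compound_id")
        for name, value in (("ffl", self.ffl), ("nluc", self.nluc)):
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(
                    f"well {self.address}: {name}={value!r} is not a finite "
                    "non-negative count"
                )


@dataclass
class Plate:
    """A complete 384-well plate keyed by address."""

    plate_id: str
    wells: dict[WellAddress, Well] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(all_addresses())
        got = set(self.wells)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            raise ValueError(
                f"plate {self.plate_id}: needs exactly one well per address "
                f"(missing e.g. {missing}, unexpected e.g. {extra})"
            )

    def __iter__(self) -> Iterator[Well]:
        return iter(self.wells[a] for a in sorted(self.wells))

    def wells_with_role(self, role: Role) -> list[Well]:
        return [w for w in self if w.role is role]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-well table (one row per well) for downstream analysis."""
        rows = [
            {
                "plate_id": self.plate_id,
                "well": str(w.address),
                "role": w.role.value,
                "compound_id": w.compound_id,
                "dose_uM": w.dose,
                "ffl": w.ffl,
                "nluc": w.nluc,
            }
            for w in self
        ]
        return pd.DataFrame(rows)


def default_layout() -> dict[WellAddress, Role]:
    """The screen's plate layout: columns 1-22 compound, 23 neg, 24 pos."""
    layout: dict[WellAddress, Role] = {}
    for addr in all_addresses():
        if addr.column == NEG_CONTROL_COLUMN:
            layout[addr] = Role.NEG_CONTROL
        elif addr.column == POS_CONTROL_COLUMN:
            layout[addr] = Role.POS_CONTROL
        else:
            layout[addr] = Role.COMPOUND
    return layout


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path_or_df: str | Path | pd.DataFrame, required: list[str]) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks required column(s) {missing}")
    return df


def read_plate_table(
    measurements: str | Path | pd.DataFrame,
    plate_map: str | Path | pd.DataFrame,
) -> list[Plate]:
    """Assemble plates from a long measurement table and a plate map.

    A mapped well missing one or both channel values is kept but demoted to
    role ``empty`` (and logged) so a single bad read does not void the other
    383 wells. Duplicate measurement rows, unknown channel labels and
    malformed well addresses are hard errors.
    """
    meas = _read_csv(measurements, MEASUREMENT_COLUMNS)
    pmap = _read_csv(plate_map, PLATEMAP_COLUMNS)

    bad = set(meas["channel"]) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channel label(s) {sorted(bad)}; expected {CHANNELS}")

    dup = meas.duplicated(subset=["plate_id", "well", "channel"], keep=False)
    if dup.any():
        first = meas[dup].iloc[0]
        raise ValueError(
            "duplicate measurement row for "
            f"(plate={first['plate_id']}, well={first['well']}, "
            f"channel={first['channel']})"
        )
    dup_map = pmap.duplicated(subset=["plate_id", "well"], keep=False)
    if dup_map.any():
        first = pmap[dup_map].iloc[0]
        raise ValueError(
            f"duplicate plate-map row for (plate={first['plate_id']}, "
            f"well={first['well']})"
        )

    values: dict[tuple[str, str], dict[str, float]] = {}
    for row in meas.itertuples(index=False):
        WellAddress.from_string(str(row.well))  # validate early
        values.setdefault((str(row.plate_id), str(row.well)), {})[row.channel] = float(
            row.value
        )

    plates: list[Plate] = []
    for plate_id, group in pmap.groupby("plate_id", sort=True):
        wells: dict[WellAddress, Well] = {}
        for row in group.itertuples(index=False):
            addr = WellAddress.from_string(str(row.well))
            role = Role(str(row.role))
            chan = values.get((str(plate_id), str(row.well)), {})
            ffl, nluc = chan.get("FFL"), chan.get("Nluc")
            if role is not Role.EMPTY and (ffl is None or nluc is None):
                logger.warning(
                    "plate %s well %s: missing %s value(s); marking empty",
                    plate_id,
                    addr,
                    [c for c in CHANNELS if c not in chan],
                )
                role, ffl, nluc = Role.EMPTY, None, None
            compound = None
            if role is Role.COMPOUND:
                compound = None if pd.isna(row.compound_id) else str(row.compound_id)
            dose = 0.0 if pd.isna(row.dose_uM) else float(row.dose_uM)
            wells[addr] = Well(addr, role, compound, dose, ffl, nluc)
        for addr in all_addresses():  # unmapped positions are empty
            wells.setdefault(addr, Well(addr, Role.EMPTY))
        plates.append(Plate(str(plate_id), wells))
    return plates


def write_plate_table(plates: Iterable[Plate]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`read_plate_table`: long measurement + plate-map tables."""
    meas_rows, map_rows = [], []
    for plate in plates:
        for w in plate:
            map_rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": str(w.address),
                    "role": w.role.value,
                    "compound_id": w.compound_id,
                    "dose_uM": w.dose,
                }
            )
            if w.ffl is not None and w.nluc is not None:
                for channel, value in (("FFL", w.ffl), ("Nluc", w.nluc)):
                    meas_rows.append(
                        {
                            "plate_id": plate.plate_id,
                            "well": str(w.address),
                            "channel": channel,
                            "value": value,
                        }
                    )
    return (
        pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS),
        pd.DataFrame(map_rows, columns=PLATEMAP_COLUMNS),
    )


def write_plate_csvs(
    plates: Iterable[Plate], measurements_path: str | Path, platemap_path: str | Path
) -> None:
    meas, pmap = write_plate_table(plates)
    meas.to_csv(measurements_path, index=False)
    pmap.to_csv(platemap_path, index=False)


# ---------------------------------------------------------------------------
# Acoustic-dispense dilution arithmetic


@dataclass(frozen=True)
class DispensePlan:
    """The two-step dilution used to dose the screen.

    A nanolitre compound droplet (``dispensed_vol_nl`` of ``stock_conc_mM``
    stock in pure DMSO) is dispensed into ``diluent_vol_ul`` of medium;
    ``transfer_vol_ul`` of that intermediate is then added to cells growing
    in ``recipient_vol_ul``.
    """

    stock_conc_mM: float
    dispensed_vol_nl: float
    diluent_vol_ul: float
    transfer_vol_ul: float
    recipient_vol_ul: float

    def __post_init__(self) -> None:
        if self.stock_conc_mM < 0 or self.dispensed_vol_nl < 0:
            raise ValueError("stock concentration and dispensed volume must be >= 0")
        for name in ("diluent_vol_ul", "transfer_vol_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.recipient_vol_ul < 0:
            raise ValueError("recipient_vol_ul must be >= 0")


def final_concentration(plan: DispensePlan) -> tuple[float, float]:
    """Final assay-well compound concentration (uM) and DMSO fraction (% v/v).

    Compound mass is conserved through the chain; DMSO is tracked as a
    volume fraction (the stock solvent is pure DMSO). Volumes are converted
    to litres internally.
    """
    dispensed_l = plan.dispensed_vol_nl * 1e-9
    diluent_l = plan.diluent_vol_ul * 1e-6
    transfer_l = plan.transfer_vol_ul * 1e-6
    recipient_l = plan.recipient_vol_ul * 1e-6

    intermediate_l = dispensed_l + diluent_l
    if intermediate_l <= 0:
        raise ValueError("intermediate volume is zero")
    stock_uM = plan.stock_conc_mM * 1e3
    intermediate_uM = stock_uM * dispensed_l / intermediate_l
    intermediate_dmso = dispensed_l / intermediate_l

    final_l = transfer_l + recipient_l
    if final_l <= 0:
        raise ValueError("final well volume is zero")
    final_uM = intermediate_uM * transfer_l / final_l
    final_dmso_pct = 100.0 * intermediate_dmso * transfer_l / final_l
    return final_uM, final_dmso_pct


#: The published screening protocol: 60 nl of 10 mM stock into 20 ul medium,
#: 10 ul of that onto cells in 20 ul -> 10 uM compound, 0.1% DMSO.
SCREEN_DISPENSE_PLAN = DispensePlan(
    stock_conc_mM=10.0,
    dispensed_vol_nl=60.0,
    diluent_vol_ul=20.0,
    transfer_vol_ul=10.0,
    recipient_vol_ul=20.0,
)
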