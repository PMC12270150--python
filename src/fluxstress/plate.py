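"""Plate-run domain model and canonical CSV I/O.

An extracellular flux analyzer run is represented at the instrument's
"level-2" output: per-well, per-measurement-cycle oxygen consumption rates
(OCR, pmol O2/min) and extracellular acidification rates (ECAR, mpH/min),
plus per-well metadata (condition, arm, cell count, blank flag) and the
injection protocol that divides the measurement cycles into phases.

Raw O2-tension / pH transients and proprietary instrument exports are out
of scope; rates are the inputs.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Selection",
    "ProtocolKind",
    "Arm",
    "PhaseDef",
    "Protocol",
    "ConversionConstants",
    "PlateRun",
    "PlateValidationError",
    "default_protocol",
    "read_plate_run",
    "write_plate_run",
    "MITO_PHASES",
    "GLYCO_PHASES",
    "WELL_COLUMNS",
    "CYCLE_COLUMNS",
]


class Selection(str, Enum):
    """Which cycles of a phase feed parameter computation."""

    ALL = "ALL"
    LAST_2 = "LAST_2"
    FIRST_1 = "FIRST_1"


class ProtocolKind(str, Enum):
    MITO = "MITO"
    GLYCO = "GLYCO"


class Arm(str, Enum):
    """Whether ATP synthase (complex V) was inhibited with oligomycin."""

    CV_INHIBITED = "CV_INHIBITED"
    CV_FREE = "CV_FREE"


MITO_PHASES = ("pre", "post_inj1", "post_fccp", "post_raa")
GLYCO_PHASES = ("pre_glucose", "post_glucose", "post_raa", "post_monensin_fccp", "post_2dg")

WELL_COLUMNS = [
    "plate_id", "well", "role", "experiment_id",
    "substance", "dose", "dose_unit", "arm", "cell_count",
]
CYCLE_COLUMNS = [
    "plate_id", "well", "cycle_index", "phase", "time_min",
    "ocr_pmol_per_min", "ecar_mpH_per_min",
]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class PlateValidationError(ValueError):
    """A plate run violated a structural invariant; message names the culprit."""


@dataclass(frozen=True)
class PhaseDef:
    """One injection phase: its cycles and the cycle-selection rule."""

    name: str
    injections: tuple[tuple[str, str], ...]  # (compound, final concentration) — metadata only
    n_cycles: int
    selection: Selection

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise PlateValidationError(f"phase {self.name!r}: n_cycles must be >= 1")
        if self.selection is Selection.LAST_2 and self.n_cycles < 2:
            raise PlateValidationError(f"phase {self.name!r}: LAST_2 needs >= 2 cycles")

    def selected_offsets(self) -> list[int]:
        """0-based offsets, within the phase, of the cycles used downstream."""
        if self.selection is Selection.ALL:
            return list(range(self.n_cycles))
        if self.selection is Selection.LAST_2:
            return [self.n_cycles - 2, self.n_cycles - 1]
        return [0]


@dataclass(frozen=True)
class Protocol:
    kind: ProtocolKind
    phases: tuple[PhaseDef, ...]
    cycle_interval: float = 6.0  # minutes

    def __post_init__(self) -> None:
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise PlateValidationError("phase names must be unique within a protocol")

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.phases)

    @property
    def n_cycles(self) -> int:
        return sum(p.n_cycles for p in self.phases)

    def cycle_phase(self) -> pd.Series:
        """Map global 1-based cycle_index -> phase name."""
        labels: list[str] = []
        for p in self.phases:
            labels.extend([p.name] * p.n_cycles)
        return pd.Series(labels, index=np.arange(1, self.n_cycles + 1), name="phase")


@dataclass(frozen=True)
class ConversionConstants:
    """Assay constants converting ECAR to proton efflux and OCR to ATP.

    buffering_factor : mmol H+/L per pH unit of the assay medium
        (experimentally determined per medium; the default is the value
        measured for the supplemented DMEM used here).
    chamber_volume : transient measurement microchamber volume, uL (96-well).
    kvol : dimensionless volume scaling applied by the vendor's PER formula.
    ccf : CO2 contribution factor — fraction of mitochondrial OCR appearing
        as medium acidification via CO2/bicarbonate.
    po_ratio : ATP per O (P/O); 2 O per O2 times P/O converts coupled OCR to
        ATP production rate.
    """

    buffering_factor: float = 2.4
    chamber_volume: float = 2.28
    kvol: float = 1.6
    ccf: float = 0.61
    po_ratio: float = 2.75

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise PlateValidationError(f"conversion constant {f.name} must be > 0")

    @property
    def per_scale(self) -> float:
        """mpH/min -> pmol H+/min multiplier: BF * V * Kvol."""
        return self.buffering_factor * self.chamber_volume * self.kvol


@dataclass
class PlateRun:
    """One instrument run: protocol + well metadata + per-cycle records.

    ``wells`` columns follow :data:`WELL_COLUMNS`; ``records`` holds
    plate_id, well, cycle_index, phase, time_min, ocr, ecar (ecar may be
    all-NaN for MITO runs).
    """

    protocol: Protocol
    wells: pd.DataFrame
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "SAMPLE"]

    def blank_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "BLANK"]

    def copy(self) -> "PlateRun":
        return PlateRun(self.protocol, self.wells.copy(), self.records.copy(), dict(self.meta))

    def validate(self) -> "PlateRun":
        validate_run(self)
        return self


def default_protocol(kind: ProtocolKind | str) -> Protocol:
    """The study's injection schedules.

    MITO: 3/3/3/2 cycles at 6-min intervals around oligomycin (or medium),
    FCCP, and rotenone+antimycin A injections; analysis uses the last two
    cycles pre- and post-first-injection, the first cycle post-FCCP, and
    both cycles post-rot/AA.

    GLYCO: 2/3/3/3/3 cycles around glucose, rot/AA, monensin+FCCP, and 2-DG
    injections; analysis uses all cycles except post-monensin/FCCP, where
    the last two are used.
    """
    kind = ProtocolKind(kind)
    if kind is ProtocolKind.MITO:
        phases = (
            PhaseDef("pre", (), 3, Selection.LAST_2),
            PhaseDef("post_inj1", (("oligomycin A (or medium)", "1 uM"),), 3, Selection.LAST_2),
            PhaseDef("post_fccp", (("FCCP", "2 uM (CV_INHIBITED) / 3 uM (CV_FREE)"),), 3, Selection.FIRST_1),
            PhaseDef("post_raa", (("rotenone", "0.5 uM"), ("antimycin A", "0.5 uM")), 2, Selection.ALL),
        )
        return Protocol(kind, phases)
    phases = (
        PhaseDef("pre_glucose", (), 2, Selection.ALL),
        PhaseDef("post_glucose", (("D-glucose", "10 mM"),), 3, Selection.ALL),
        PhaseDef("post_raa", (("rotenone", "0.5 uM"), ("antimycin A", "0.5 uM")), 3, Selection.ALL),
        PhaseDef("post_monensin_fccp", (("monensin", "10 uM"), ("FCCP", "3 uM")), 3, Selection.LAST_2),
        PhaseDef("post_2dg", (("2-deoxy-D-glucose", "50 mM"),), 3, Selection.ALL),
    )
    return Protocol(kind, phases)


def validate_run(run: PlateRun) -> None:
    wells, records, protocol = run.wells, run.records, run.protocol

    missing_cols = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing_cols:
        raise PlateValidationError(f"wells table missing columns: {missing_cols}")
    for c in ("plate_id", "well", "cycle_index", "phase", "time_min", "ocr"):
        if c not in records.columns:
            raise PlateValidationError(f"records table missing column: {c}")

    bad_coord = wells.loc[~wells["well"].astype(str).str.match(_WELL_RE), "well"]
    if len(bad_coord):
        raise PlateValidationError(f"invalid well coordinates: {sorted(bad_coord)}")
    if wells["well"].duplicated().any():
        dupes = sorted(wells.loc[wells["well"].duplicated(), "well"])
        raise PlateValidationError(f"duplicate wells in metadata: {dupes}")

    blanks = run.blank_wells()
    if len(blanks) == 0:
        raise PlateValidationError("plate run has no BLANK wells")
    if (blanks["cell_count"] != 0).any():
        raise PlateValidationError("BLANK wells must have cell_count 0")
    samples = run.sample_wells()
    neg = samples.loc[samples["cell_count"] < 0, "well"]
    if len(neg):
        raise PlateValidationError(f"negative cell_count in wells: {sorted(neg)}")
    zero = samples.loc[samples["cell_count"] == 0, "well"]
    if len(zero):
        raise PlateValidationError(f"SAMPLE wells with cell_count 0: {sorted(zero)}")

    # phase labels must agree with the protocol's cycle -> phase map
    cp = protocol.cycle_phase()
    unknown = set(records["phase"]) - set(protocol.phase_names)
    if unknown:
        raise PlateValidationError(
            f"unknown phase labels for {protocol.kind.value} protocol: {sorted(unknown)}"
        )
    rec = records[["well", "cycle_index", "phase"]]
    expected = rec["cycle_index"].map(cp)
    mismatch = rec[expected.isna() | (rec["phase"] != expected)]
    if len(mismatch):
        first = mismatch.iloc[0]
        raise PlateValidationError(
            f"phase mismatch with protocol: well {first['well']} cycle {first['cycle_index']} "
            f"labelled {first['phase']!r}"
        )

    # every well must carry every cycle
    counts = records.groupby("well")["cycle_index"].agg(["size", "nunique"])
    all_cycles = set(range(1, protocol.n_cycles + 1))
    gaps = []
    for w in wells["well"]:
        if w not in counts.index:
            gaps.append((w, sorted(all_cycles)))
            continue
        have = set(records.loc[records["well"] == w, "cycle_index"])
        if have != all_cycles:
            gaps.append((w, sorted(all_cycles - have)))
    if gaps:
        desc = "; ".join(f"well {w} missing cycles {m}" for w, m in gaps[:5])
        raise PlateValidationError(f"incomplete cycle coverage: {desc}")

    # time strictly increasing per well
    t = records.sort_values(["well", "cycle_index"]).groupby("well")["time_min"].diff()
    if (t.dropna() <= 0).any():
        bad = records.sort_values(["well", "cycle_index"]).loc[t <= 0, "well"].iloc[0]
        raise PlateValidationError(f"time not strictly increasing in well {bad}")


def read_plate_run(cycles_path, wells_path, protocol: Protocol) -> PlateRun:
    """Read the canonical long-format CSVs and validate against ``protocol``."""
    wells = pd.read_csv(wells_path, dtype={"plate_id": str, "well": str, "experiment_id": str})
    cycles = pd.read_csv(cycles_path, dtype={"plate_id": str, "well": str})
    missing = [c for c in CYCLE_COLUMNS if c not in cycles.columns]
    if missing:
        raise PlateValidationError(f"cycles CSV missing columns: {missing}")
    records = cycles.rename(
        columns={"ocr_pmol_per_min": "ocr", "ecar_mpH_per_min": "ecar"}
    )
    if "ecar" not in records.columns:
        records["ecar"] = np.nan
    wells["cell_count"] = wells["cell_count"].fillna(0).astype(int)
    wells["dose"] = pd.to_numeric(wells["dose"], errors="coerce")
    for c in ("substance", "dose_unit", "arm"):
        wells[c] = wells[c].fillna("")
    run = PlateRun(protocol, wells, records)
    validate_run(run)
    return run


def write_plate_run(run: PlateRun, cycles_path, wells_path) -> None:
    """Write the canonical CSVs; numeric fields keep 6 significant digits."""
    if len(run.records) == 0:
        raise PlateValidationError("refusing to write a run with no records")
    validate_run(run)
    wells = run.wells[WELL_COLUMNS]
    records = run.records.rename(
        columns={"ocr": "ocr_pmol_per_min", "ecar": "ecar_mpH_per_min"}
    )[CYCLE_COLUMNS]
    wells.to_csv(wells_path, index=False)
    records.to_csv(cycles_path, index=False, float_format="%.6g")
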