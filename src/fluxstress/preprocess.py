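"""Blank correction, per-cell normalization, and phase-representative rates.

The order of operations follows the assay convention: per-cycle blank
subtraction first (instrument drift is shared between cell-free and sample
wells), then scaling to a common cell number, then reduction of each
injection phase to a single representative rate via the protocol's
cycle-selection rule.  Negative corrected rates are never clamped here;
a QC helper flags wells whose post-rot/AA OCR is implausibly negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .plate import PlateRun, PlateValidationError

__all__ = ["blank_correct", "normalize_per_cell", "phase_rates", "qc_flags", "preprocess"]

_CHANNELS = ("ocr", "ecar")


def blank_correct(run: PlateRun, robust: bool = False) -> PlateRun:
    """Subtract, per cycle and channel, the blank-well mean (median if
    ``robust``) from every SAMPLE well.  BLANK records are kept unchanged."""
    blanks = set(run.blank_wells()["well"])
    if not blanks:
        raise PlateValidationError("blank correction requires >= 1 BLANK well")
    out = run.copy()
    rec = out.records
    is_blank = rec["well"].isin(blanks)
    agg = "median" if robust else "mean"
    for ch in _CHANNELS:
        if ch not in rec.columns or rec[ch].isna().all():
            continue
        ref = rec[is_blank].groupby("cycle_index")[ch].agg(agg)
        rec.loc[~is_blank, ch] = rec.loc[~is_blank, ch] - rec.loc[~is_blank, "cycle_index"].map(ref)
    out.meta["blank_corrected"] = True
    return out


def normalize_per_cell(run: PlateRun) -> PlateRun:
    """Scale every SAMPLE value by 1e4/cell_count; units become per-1e4-cells."""
    out = run.copy()
    samples = out.sample_wells()
    zero = samples.loc[samples["cell_count"] <= 0, "well"]
    if len(zero):
        raise PlateValidationError(f"cannot normalize: cell_count <= 0 in wells {sorted(zero)}")
    factor = (1e4 / samples.set_index("well")["cell_count"])
    rec = out.records
    f = rec["well"].map(factor)  # NaN for blanks -> leave unchanged
    for ch in _CHANNELS:
        if ch in rec.columns:
            rec[ch] = np.where(f.notna(), rec[ch] * f, rec[ch])
    out.meta["normalized"] = True
    return out


def phase_rates(run: PlateRun, channel: str = "ocr") -> pd.DataFrame:
    """Representative rate per (sample well, phase): the arithmetic mean of
    the cycles picked by each phase's selection rule.

    Returns a DataFrame indexed by well with one column per protocol phase,
    in protocol order.
    """
    if channel not in _CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    rec = run.records
    if channel not in rec.columns or rec[channel].isna().all():
        raise PlateValidationError(f"channel {channel!r} absent from records")
    sample_wells = run.sample_wells()["well"]
    rec = rec[rec["well"].isin(set(sample_wells))]

    keep: list[int] = []
    offset = 0
    for p in run.protocol.phases:
        keep += [offset + 1 + o for o in p.selected_offsets()]
        offset += p.n_cycles
    sel = rec[rec["cycle_index"].isin(keep)]
    wide = sel.pivot_table(index="well", columns="phase", values=channel, aggfunc="mean")
    wide = wide.reindex(index=sample_wells, columns=list(run.protocol.phase_names))
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise PlateValidationError(f"missing selected cycles for phases {bad}")
    wide.columns.name = None
    return wide


def qc_flags(run: PlateRun, rates: pd.DataFrame) -> pd.DataFrame:
    """Flag wells whose post-rot/AA OCR is below -2 SD of the blank values
    (silent clamping would bias non-mitochondrial estimates, so flags are
    reported instead)."""
    blanks = run.records[run.records["well"].isin(set(run.blank_wells()["well"]))]
    blank_sd = float(blanks["ocr"].std(ddof=1)) if len(blanks) > 1 else 0.0
    flagged = rates.index[rates["post_raa"] < -2 * blank_sd]
    return pd.DataFrame({"well": flagged, "flag": "post_raa_below_blank_noise"})


def preprocess(run: PlateRun, channel: str = "ocr", robust_blanks: bool = False) -> pd.DataFrame:
    """blank_correct -> normalize_per_cell -> phase_rates, in one call."""
    return phase_rates(normalize_per_cell(blank_correct(run, robust=robust_blanks)), channel)
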