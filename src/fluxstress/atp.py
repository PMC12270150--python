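"""ATP production rates from stress-test outputs.

Mitochondrial ATP production = ATP-linked respiration (coupled OCR) times
2 O per O2 times the P/O ratio (ATP per O; default 2.75, the vendor
convention for oxidative phosphorylation).  Glycolytic ATP production is
1:1 with glycolytic PER (one H+ extruded per lactate, one ATP per lactate),
fed by default from ATP-demand-limited glycolysis; ``source="basal"``
switches to basal glycolysis.

Mitochondrial and glycolytic rates come from different stress tests and
may come from different experiment sets, so they are aggregated
independently; condition totals are sums of condition means, and
per-experiment totals are only formed where both tests share an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .plate import ConversionConstants

__all__ = ["AtpRates", "mito_atp", "glyco_atp", "atp_budget"]


@dataclass(frozen=True)
class AtpRates:
    """pmol ATP/min/1e4 cells; total = mito + glyco by construction."""

    mito: float
    glyco: float

    @property
    def total(self) -> float:
        return self.mito + self.glyco


def mito_atp(atp_linked, constants: ConversionConstants) -> float:
    """Coupled OCR (pmol O2/min) -> pmol ATP/min: 2 O per O2 times P/O."""
    return atp_linked * 2.0 * constants.po_ratio


def glyco_atp(atp_demand_limited):
    """Glycolytic PER -> pmol ATP/min (identity: 1 ATP per extruded H+).
    Negative inputs pass through; downstream QC flags them."""
    return atp_demand_limited


def atp_budget(mito_params: pd.DataFrame, glyco_params: pd.DataFrame,
               constants: ConversionConstants | None = None,
               glyco_source: str = "atp_demand_limited") -> pd.DataFrame:
    """Per-condition ATP budget from well-level parameter tables.

    ``mito_params`` must be CV_INHIBITED-arm rows (ATP-linked respiration
    requires oligomycin); ``glyco_params`` is a glyco-test table.  Each
    branch is reduced to per-(experiment, condition) means and then to
    condition means independently.  Returns one row per condition with
    mito/glyco/total ATP rates, SEMs and experiment counts; conditions
    present in neither input are omitted.
    """
    constants = constants or ConversionConstants()
    if glyco_source not in ("atp_demand_limited", "basal_glycolysis"):
        raise ValueError(f"unknown glyco ATP source {glyco_source!r}")

    m = mito_params.copy()
    if "atp_linked" not in m.columns or m["atp_linked"].isna().all():
        raise ValueError("mito input lacks ATP-linked respiration (CV_INHIBITED arm required)")
    m["mito_atp"] = mito_atp(m["atp_linked"], constants)
    g = glyco_params.copy()
    g["glyco_atp"] = glyco_atp(g[glyco_source])

    keys = ["substance", "dose"]

    def condense(tbl: pd.DataFrame, col: str) -> pd.DataFrame:
        per_exp = tbl.groupby(keys + ["experiment_id"])[col].mean().reset_index()
        agg = per_exp.groupby(keys)[col].agg(["mean", "sem", "count"])
        agg.columns = [f"{col}_{c}" for c in ("mean", "sem", "n")]
        return agg

    budget = condense(m, "mito_atp").join(condense(g, "glyco_atp"), how="outer")
    budget["total_atp_mean"] = budget["mito_atp_mean"] + budget["glyco_atp_mean"]
    return budget.reset_index()
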