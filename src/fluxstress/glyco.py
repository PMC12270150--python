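"""Glycolysis stress test: ECAR -> proton efflux rates and glycolytic parameters.

ECAR (mpH/min) is converted to a proton efflux rate (PER, pmol H+/min)
via the medium buffering factor, microchamber volume, and volume scaling:

    PER = ECAR * BF * V * Kvol

Total PER is then partitioned into mitochondrial (CO2/bicarbonate) and
glycolytic acidification using the CO2 contribution factor (CCF) and the
concurrent OCR trace: mito PER = CCF * (phase OCR - post-rot/AA OCR),
clamped at zero and zeroed from the rot/AA injection onward.

Parameters (PER per 1e4 cells):

    basal acidification    = glyco PER, pre-glucose
    basal glycolysis       = glyco PER post-glucose - glyco PER pre-glucose
    ATP-demand-limited gly = total PER post-rot/AA - total PER pre-glucose
    maximal glyco capacity = glyco PER post-monensin/FCCP - glyco PER pre-glucose
    glycolytic reserve     = maximal capacity - basal glycolysis
    2-DG residual          = glyco PER post-2-DG - glyco PER pre-glucose

The demand-limited parameter deliberately uses *total* PER on both sides
(the assay definition says PER, not glycolytic PER, for this parameter);
``demand_glyco_only=True`` switches to glycolytic PER.  The 2-DG residual
is a QC quantity — near zero when measured acidification was glucose
dependent — computed on glycolytic PER so that the vanished mitochondrial
CO2 term does not masquerade as residual glycolysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .plate import ConversionConstants, GLYCO_PHASES, PlateRun
from .preprocess import preprocess

__all__ = ["PerRates", "GlycoParams", "ecar_to_per", "partition_per",
           "glyco_params", "glyco_param_table"]

# phases at/after the rotenone+antimycin A injection: mitochondrial PER is zero
_POST_RAA = ("post_raa", "post_monensin_fccp", "post_2dg")


@dataclass(frozen=True)
class PerRates:
    """Per-phase (total, mitochondrial, glycolytic) PER for one well."""

    well: str
    total: dict
    mito: dict
    glyco: dict


@dataclass(frozen=True)
class GlycoParams:
    basal_acidification: float
    basal_glycolysis: float
    atp_demand_limited: float
    max_capacity: float
    reserve: float
    dg_residual: float


def ecar_to_per(ecar, constants: ConversionConstants) -> float:
    """mpH/min -> pmol H+/min (linear, strictly monotone)."""
    return ecar * constants.per_scale


def partition_per(ocr_rates, ecar_rates, constants: ConversionConstants,
                  well: str = "") -> PerRates:
    """Split one well's total PER into mitochondrial and glycolytic parts.

    ``ocr_rates`` / ``ecar_rates`` map glyco phase -> representative rate.
    Mito OCR is clamped at zero before applying the CCF (negative
    mitochondrial CO2 production is unphysical; blank noise can push a
    phase OCR below the post-rot/AA level).
    """
    for p in GLYCO_PHASES:
        if p not in ocr_rates or p not in ecar_rates:
            raise ValueError(f"missing GLYCO phase {p!r}")
    raa_ocr = float(ocr_rates["post_raa"])
    total, mito, glyco = {}, {}, {}
    for p in GLYCO_PHASES:
        total[p] = ecar_to_per(float(ecar_rates[p]), constants)
        if p in _POST_RAA:
            mito[p] = 0.0
        else:
            mito[p] = constants.ccf * max(float(ocr_rates[p]) - raa_ocr, 0.0)
        glyco[p] = total[p] - mito[p]
    return PerRates(well=well, total=total, mito=mito, glyco=glyco)


def glyco_params(per: PerRates, demand_glyco_only: bool = False) -> GlycoParams:
    """The glycolytic PER parameters for one well."""
    g, t = per.glyco, per.total
    demand = g if demand_glyco_only else t
    return GlycoParams(
        basal_acidification=g["pre_glucose"],
        basal_glycolysis=g["post_glucose"] - g["pre_glucose"],
        atp_demand_limited=demand["post_raa"] - demand["pre_glucose"],
        max_capacity=t["post_monensin_fccp"] - g["pre_glucose"],
        reserve=t["post_monensin_fccp"] - g["post_glucose"],
        dg_residual=g["post_2dg"] - g["pre_glucose"],
    )


def glyco_param_table(run: PlateRun, constants: ConversionConstants | None = None,
                      demand_glyco_only: bool = False,
                      robust_blanks: bool = False) -> pd.DataFrame:
    """Per-well glycolytic parameter table for one GLYCO run."""
    constants = constants or ConversionConstants()
    ocr = preprocess(run, "ocr", robust_blanks=robust_blanks)
    ecar = preprocess(run, "ecar", robust_blanks=robust_blanks)
    meta = run.sample_wells().set_index("well")
    rows = []
    for well in ocr.index:
        per = partition_per(ocr.loc[well], ecar.loc[well], constants, well=well)
        p = glyco_params(per, demand_glyco_only=demand_glyco_only)
        m = meta.loc[well]
        rows.append({
            "well": well, "experiment_id": m["experiment_id"],
            "substance": m["substance"], "dose": m["dose"],
            "basal_acidification": p.basal_acidification,
            "basal_glycolysis": p.basal_glycolysis,
            "atp_demand_limited": p.atp_demand_limited,
            "max_capacity": p.max_capacity,
            "reserve": p.reserve,
            "dg_residual": p.dg_residual,
        })
    return pd.DataFrame(rows)
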