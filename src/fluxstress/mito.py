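"""Mitochondrial stress-test parameters and the ±CV-inhibition comparison.

Six respiration parameters per well, from the four phase-representative
OCR values (all per 1e4 cells, blank-corrected):

    non-mito          = post_raa
    basal             = pre - post_raa
    MR                = post_fccp - post_raa
    SRC               = MR - basal            (see note below)
    ATP-linked        = pre - post_inj1       (CV_INHIBITED arm only)
    proton leak       = post_inj1 - post_raa  (CV_INHIBITED arm only)

SRC note: the literal textbook definition "FCCP OCR minus basal" retains
non-mitochondrial OCR; MR - basal (= post_fccp - pre) is the figure
arithmetic and standard practice, and is the default.  The literal variant
is available via ``src_literal=True``.

The confound statistic is the percent underestimation
100*(CV_free - CV_inhibited)/CV_free of MR or SRC, paired at the
experiment level (both arms share a plate within an experiment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .plate import Arm, MITO_PHASES, PlateRun
from .preprocess import preprocess

__all__ = [
    "MitoParams",
    "mito_params",
    "mito_param_table",
    "percent_underestimation",
    "paired_underestimation",
]


@dataclass(frozen=True)
class MitoParams:
    """The six respiration parameters for one well (normalized OCR units).
    ``atp_linked`` and ``proton_leak`` are None unless CV was inhibited."""

    basal: float
    mr: float
    src: float
    nonmito: float
    arm: Arm
    atp_linked: float | None = None
    proton_leak: float | None = None


def mito_params(rates, arm: Arm | str, src_literal: bool = False) -> MitoParams:
    """Compute the respiration parameters from one well's phase rates.

    ``rates`` is a mapping phase name -> representative OCR (dict or Series)
    covering the four MITO phases.
    """
    arm = Arm(arm)
    missing = [p for p in MITO_PHASES if p not in rates or pd.isna(rates[p])]
    if missing:
        raise ValueError(f"missing MITO phase rates: {missing}")
    pre, inj1, fccp, raa = (float(rates[p]) for p in MITO_PHASES)
    basal = pre - raa
    mr = fccp - raa
    src = (fccp - basal) if src_literal else (mr - basal)
    kwargs = {}
    if arm is Arm.CV_INHIBITED:
        kwargs = {"atp_linked": pre - inj1, "proton_leak": inj1 - raa}
    return MitoParams(basal=basal, mr=mr, src=src, nonmito=raa, arm=arm, **kwargs)


def mito_param_table(run: PlateRun, src_literal: bool = False,
                     robust_blanks: bool = False) -> pd.DataFrame:
    """Per-well parameter table for one run: preprocessing + ``mito_params``.

    Columns: well, experiment_id, substance, dose, arm, basal, atp_linked,
    proton_leak, mr, src, nonmito.
    """
    rates = preprocess(run, "ocr", robust_blanks=robust_blanks)
    meta = run.sample_wells().set_index("well")
    rows = []
    for well, r in rates.iterrows():
        m = meta.loc[well]
        p = mito_params(r, m["arm"], src_literal=src_literal)
        rows.append({
            "well": well, "experiment_id": m["experiment_id"],
            "substance": m["substance"], "dose": m["dose"], "arm": m["arm"],
            "basal": p.basal, "atp_linked": p.atp_linked, "proton_leak": p.proton_leak,
            "mr": p.mr, "src": p.src, "nonmito": p.nonmito,
        })
    return pd.DataFrame(rows)


def percent_underestimation(cv_free: float, cv_inhibited: float) -> float:
    """100*(cv_free - cv_inhibited)/cv_free; NaN (flagged missing) when the
    CV-free reference is zero."""
    if cv_free == 0 or pd.isna(cv_free):
        return float("nan")
    return 100.0 * (cv_free - cv_inhibited) / cv_free


def paired_underestimation(params: pd.DataFrame) -> pd.DataFrame:
    """Experiment-level paired ±CV-inhibition underestimation of MR and SRC.

    ``params`` is a well-level table (as from :func:`mito_param_table`,
    possibly outlier-filtered).  Per (experiment, condition): each arm's
    technical replicates are averaged, then the percent underestimation is
    computed for MR and SRC.  Conditions missing one arm are skipped with a
    warning.  Aggregation across experiments belongs to the stats layer.
    """
    out = []
    for (exp, subst, dose), g in params.groupby(["experiment_id", "substance", "dose"]):
        arm_means = g.groupby("arm")[["mr", "src"]].mean()
        if not {Arm.CV_FREE.value, Arm.CV_INHIBITED.value} <= set(arm_means.index):
            warnings.warn(
                f"({exp}, {subst} {dose}): one arm missing, skipping", stacklevel=2
            )
            continue
        free, inh = arm_means.loc[Arm.CV_FREE.value], arm_means.loc[Arm.CV_INHIBITED.value]
        for param in ("mr", "src"):
            out.append({
                "experiment_id": exp, "substance": subst, "dose": dose,
                "parameter": param.upper(),
                "value_cv_free": free[param], "value_cv_inhibited": inh[param],
                "percent_underestimation": percent_underestimation(free[param], inh[param]),
            })
    return pd.DataFrame(out)
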