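"""Seeded generator of synthetic plate runs.

The generator emulates the study design: 96-well runs with the mito
(3/3/3/2 cycles) and glyco (2/3/3/3/3 cycles) injection schedules, blank
wells, sextuplicate technical replicates per condition, 3-4 independent
experiments, and paired ±ATP-synthase(CV)-inhibition arms on each mito
plate.  Ground truth is held in :class:`ConditionTruth`; the key quantity
is the CV-inhibition underestimation fraction ``u`` applied to maximal
respiration in the CV_INHIBITED arm.

Generative model, per SAMPLE well
---------------------------------
Each experiment draws a multiplicative effect E ~ LogNormal(0, sigma_exp),
each well a multiplicative effect W ~ LogNormal(0, sigma_well) and a cell
count N ~ Normal(nominal, cv*nominal) (rounded, >= 1). The recorded value
of every measurement cycle is

    true_phase_rate * E * W * (N / 1e4)  +  Normal(0, sigma_cycle)

with sigma_cycle = max(floor, rel * |scaled rate|).  BLANK wells record
Normal(0, blank_sd).  True phase rates (per 1e4 cells):

MITO:   pre       = nonmito + basal_mito
        post_inj1 = nonmito + leak*basal_mito   (CV_INHIBITED; = pre otherwise)
        post_fccp = nonmito + MR*(1-u)          (CV_INHIBITED; u=0 otherwise)
        post_raa  = nonmito

GLYCO:  ECAR = (glyco PER target + CCF * mito OCR) / (BF*V*Kvol), with
        mito OCR = basal_mito before rot/AA and 0 after; glycolytic PER
        returns to its pre-glucose level after 2-DG.  Concurrent OCR is
        generated from the same condition truth.

Absolute control magnitudes (34.0, 81.0, 8.0 pmol O2/min/1e4 cells,
leak fraction 0.15) are fixture constants chosen so that every reported
ratio / fraction / fold is reproduced exactly in the noise-free limit;
only those scale-invariant quantities are anchored to the study.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plate import (
    Arm,
    ConversionConstants,
    PlateRun,
    ProtocolKind,
    default_protocol,
)

__all__ = [
    "ConditionTruth",
    "NoiseModel",
    "SimScenario",
    "scenario_mito_confound",
    "scenario_atp_budget",
    "simulate_run",
    "simulate_experiment_set",
]

_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class ConditionTruth:
    """Ground-truth rates for one condition, per 1e4 cells.

    Respiration truth: non-mitochondrial OCR, basal mitochondrial OCR, the
    proton-leak fraction of basal, true maximal respiration (MR), and the
    fraction ``underestimation_mr`` of MR suppressed when CV is inhibited.
    Glycolysis truth: pre-glucose glycolytic PER plus the three glycolytic
    parameter targets (basal glycolysis, ATP-demand-limited glycolysis,
    maximal glycolytic capacity), all pmol H+/min/1e4 cells.
    """

    substance: str  # NONE | NI | LPS
    dose: float
    dose_unit: str
    nonmito_ocr: float
    basal_mito_ocr: float
    leak_fraction: float
    max_resp_ocr: float
    underestimation_mr: float
    glyco_pre_per: float = 5.0
    glyco_basal_per: float = 24.0
    glyco_demand_per: float = 24.2
    glyco_max_per: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.underestimation_mr <= 1):
            raise ValueError("underestimation_mr must be in [0, 1]")
        if not (0 <= self.leak_fraction < 1):
            raise ValueError("leak_fraction must be in [0, 1)")
        if self.max_resp_ocr < self.basal_mito_ocr:
            raise ValueError("max_resp_ocr must be >= basal_mito_ocr")

    @property
    def label(self) -> tuple[str, float]:
        return (self.substance, self.dose)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-structure noise; defaults chosen to reproduce the magnitude
    of between-experiment SEMs reported for this assay (roughly 3-12% of the
    mean with n = 3-4 experiments and sextuplicates)."""

    sigma_experiment: float = 0.10  # lognormal scale, between experiments
    sigma_well: float = 0.06        # lognormal scale, between wells
    sigma_cycle_floor: float = 0.5  # additive SD floor, OCR units (PER units for ECAR)
    sigma_cycle_rel: float = 0.02   # additive SD, fraction of the well-level rate
    blank_sd: float = 0.5           # additive SD of blank wells
    cellcount_cv: float = 0.10      # CV of counted cells per well

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimScenario:
    name: str
    conditions: tuple[ConditionTruth, ...]
    n_experiments: int = 4
    replicates_per_condition_arm: int = 6
    n_blanks: int = 4
    nominal_cells_per_well: int = 24000
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 1
    # optional per-condition cell-count multiplier, e.g. {("NI", 72.0): 1.1},
    # to probe normalization robustness; off (1.0) by default
    cellcount_multiplier: tuple[tuple[tuple[str, float], float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.replicates_per_condition_arm < 2:
            raise ValueError("replicates_per_condition_arm must be >= 2")
        if self.n_blanks < 1:
            raise ValueError("n_blanks must be >= 1")

    def experiment_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_experiments)]

    def noise_free(self) -> "SimScenario":
        """Deterministic limit used by recovery tests: no noise, N = 1e4."""
        return replace(self, noise=NoiseModel.none(), nominal_cells_per_well=10_000)


NI_DOSES = (6.0, 12.0, 24.0, 48.0, 72.0)

# Control fixture constants (see module docstring): only ratios are anchored.
_CONTROL = dict(nonmito_ocr=8.0, basal_mito_ocr=34.0, leak_fraction=0.15,
                max_resp_ocr=81.0, underestimation_mr=0.56)
_ATP_LINKED_0 = 28.9           # = basal * (1 - leak)
_ATP_LINKED_SLOPE = -0.14      # pmol O2/min/1e4 cells per ppm Ni
_MR_DECREASE_72 = 0.33         # fractional MR loss at 72 ppm
_U_SLOPE = -0.005              # underestimation fraction per ppm Ni
_GLYCO_FOLD_72 = 3.3           # glycolytic parameter fold at 72 ppm (and LPS)


def _ni_truth(c: float) -> ConditionTruth:
    atp_linked = _ATP_LINKED_0 + _ATP_LINKED_SLOPE * c
    basal = atp_linked / (1 - _CONTROL["leak_fraction"])
    fold = 1 + (_GLYCO_FOLD_72 - 1) * c / 72.0
    return ConditionTruth(
        "NI", c, "ppm",
        nonmito_ocr=8.0,
        basal_mito_ocr=basal,
        leak_fraction=0.15,
        max_resp_ocr=81.0 * (1 - _MR_DECREASE_72 * c / 72.0),
        underestimation_mr=0.56 + _U_SLOPE * c,
        glyco_basal_per=24.0 * fold,
        glyco_demand_per=24.2 * fold,
        glyco_max_per=60.0 * fold,
    )


def _control_truth() -> ConditionTruth:
    return ConditionTruth("NONE", 0.0, "", **_CONTROL)


def _lps_truth(mito_fold: float = 1.0) -> ConditionTruth:
    # LPS: MR collapses to basal scale (58% decrease), underestimation vanishes.
    return ConditionTruth(
        "LPS", 1.0, "ug/mL",
        nonmito_ocr=8.0,
        basal_mito_ocr=24.2 if mito_fold == 1.0 else _ATP_LINKED_0 * mito_fold / 0.85,
        leak_fraction=0.15,
        max_resp_ocr=34.0,
        underestimation_mr=0.0,
        glyco_basal_per=24.0 * _GLYCO_FOLD_72,
        glyco_demand_per=24.2 * _GLYCO_FOLD_72,
        glyco_max_per=60.0 * _GLYCO_FOLD_72,
    )


def scenario_mito_confound(seed: int = 1, n_experiments: int = 4,
                           noise: NoiseModel | None = None) -> SimScenario:
    """The Ni dose-response + LPS confound scenario.

    Control truth: basal mito OCR 34.0, leak fraction 0.15, MR 81.0,
    non-mito OCR 8.0, u = 0.56 (hence SRC underestimation
    u*MR/(MR-basal) = 0.965 in the noise-free limit).  Ni dose c:
    MR(c) = 81*(1 - 0.33*c/72), ATP-linked OCR = 28.9 - 0.14*c,
    u(c) = 0.56 - 0.005*c.  LPS: MR 34.0, basal 24.2, u = 0.
    """
    conds = (_control_truth(), *map(_ni_truth, NI_DOSES), _lps_truth())
    return SimScenario("mito_confound", conds, n_experiments=n_experiments,
                       noise=noise or NoiseModel(), seed=seed)


def scenario_atp_budget(seed: int = 1, n_experiments: int = 3,
                        noise: NoiseModel | None = None) -> SimScenario:
    """Independent fixture for ATP-production-rate recovery.

    Control ATP-linked OCR 28.9 declining at 0.14 per ppm Ni; control
    ATP-demand-limited glycolytic PER 24.2 (glycolytic share of total ATP
    0.132 at P/O 2.75); glycolytic parameters scale up to 3.3-fold at
    72 ppm Ni and with LPS; LPS mitochondrial ATP fold 0.90.  Kept separate
    from the confound scenario: the source study used separate experiment
    groups for the two stress tests and cautions against cross-combining.
    """
    conds = (_control_truth(), *map(_ni_truth, NI_DOSES), _lps_truth(mito_fold=0.90))
    return SimScenario("atp_budget", conds, n_experiments=n_experiments,
                       noise=noise or NoiseModel(), seed=seed)


def _stream_key(label: str) -> int:
    """Stable 31-bit key for an RNG stream label."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little") % (2**31)


def _mito_phase_truth(ct: ConditionTruth, arm: Arm) -> dict[str, float]:
    pre = ct.nonmito_ocr + ct.basal_mito_ocr
    if arm is Arm.CV_INHIBITED:
        inj1 = ct.nonmito_ocr + ct.leak_fraction * ct.basal_mito_ocr
        fccp = ct.nonmito_ocr + ct.max_resp_ocr * (1 - ct.underestimation_mr)
    else:
        inj1 = pre
        fccp = ct.nonmito_ocr + ct.max_resp_ocr
    return {"pre": pre, "post_inj1": inj1, "post_fccp": fccp, "post_raa": ct.nonmito_ocr}


def _glyco_phase_truth(ct: ConditionTruth, ccf: float) -> tuple[dict, dict]:
    """(OCR truth, total-PER truth) per glyco phase."""
    bm = ct.basal_mito_ocr
    ocr = {
        "pre_glucose": ct.nonmito_ocr + bm,
        "post_glucose": ct.nonmito_ocr + bm,
        "post_raa": ct.nonmito_ocr,
        "post_monensin_fccp": ct.nonmito_ocr,
        "post_2dg": ct.nonmito_ocr,
    }
    g_pre = ct.glyco_pre_per
    glyco = {
        "pre_glucose": g_pre,
        "post_glucose": g_pre + ct.glyco_basal_per,
        # demand-limited glycolysis is defined on *total* PER, whose pre-glucose
        # baseline carries the mitochondrial CO2 term; solve for the post-rot/AA
        # glycolytic PER that makes the parameter recover exactly
        "post_raa": ct.glyco_demand_per + g_pre + ccf * bm,
        "post_monensin_fccp": g_pre + ct.glyco_max_per,
        "post_2dg": g_pre,
    }
    mito_per = {ph: ccf * (ocr[ph] - ct.nonmito_ocr) for ph in ocr}
    total = {ph: glyco[ph] + mito_per[ph] for ph in ocr}
    return ocr, total


def simulate_run(scenario: SimScenario, kind: ProtocolKind | str, experiment_id: str,
                 arm_split: bool = True,
                 constants: ConversionConstants | None = None) -> PlateRun:
    """Simulate one plate run (one experiment) and return a validated PlateRun.

    MITO runs with ``arm_split`` carry both ±CV-inhibition arms side by side
    (as in the study, where FCCP at 3 uM was injected in half of the wells);
    without it every well is CV_INHIBITED (the standard test).  GLYCO runs
    carry a single arm and both OCR and ECAR channels.
    """
    kind = ProtocolKind(kind)
    constants = constants or ConversionConstants()
    protocol = default_protocol(kind)
    noise = scenario.noise
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed % (2**31), _stream_key(f"{experiment_id}|{kind.value}")])
    )

    if kind is ProtocolKind.MITO:
        arms = [Arm.CV_INHIBITED, Arm.CV_FREE] if arm_split else [Arm.CV_INHIBITED]
    else:
        arms = [Arm.CV_FREE]

    layout: list[tuple[ConditionTruth | None, Arm | None]] = []
    for ct in scenario.conditions:
        for arm in arms:
            layout += [(ct, arm)] * scenario.replicates_per_condition_arm
    layout += [(None, None)] * scenario.n_blanks
    if len(layout) > 96:
        raise ValueError(f"layout needs {len(layout)} wells; a plate has 96")

    coords = [f"{_ROWS[i // 12]}{i % 12 + 1}" for i in range(len(layout))]
    plate_id = f"{kind.value}-{experiment_id}"
    ccmult = dict(scenario.cellcount_multiplier)

    E = rng.lognormal(0.0, noise.sigma_experiment) if noise.sigma_experiment > 0 else 1.0
    n_wells = len(layout)
    W = rng.lognormal(0.0, noise.sigma_well, n_wells) if noise.sigma_well > 0 else np.ones(n_wells)

    nominal = np.array([
        0.0 if ct is None else scenario.nominal_cells_per_well * ccmult.get(ct.label, 1.0)
        for ct, _ in layout
    ])
    if noise.cellcount_cv > 0:
        cells = np.rint(rng.normal(nominal, noise.cellcount_cv * nominal)).clip(min=1)
    else:
        cells = np.rint(nominal)
    cells[nominal == 0] = 0

    cp = protocol.cycle_phase()
    phases = cp.to_numpy()  # phase label per cycle, length n_cycles
    n_cycles = protocol.n_cycles

    # per-well true per-1e4 rates per cycle
    truth_ocr = np.zeros((n_wells, n_cycles))
    truth_per = np.full((n_wells, n_cycles), np.nan)
    for i, (ct, arm) in enumerate(layout):
        if ct is None:
            continue
        if kind is ProtocolKind.MITO:
            t = _mito_phase_truth(ct, arm)
            truth_ocr[i] = [t[ph] for ph in phases]
        else:
            ocr_t, per_t = _glyco_phase_truth(ct, constants.ccf)
            truth_ocr[i] = [ocr_t[ph] for ph in phases]
            truth_per[i] = [per_t[ph] for ph in phases]

    is_sample = np.array([ct is not None for ct, _ in layout])
    scale = np.where(is_sample, E * W * cells / 1e4, 0.0)[:, None]

    def measure(truth: np.ndarray) -> np.ndarray:
        scaled = truth * scale
        sd = np.where(
            is_sample[:, None],
            np.maximum(noise.sigma_cycle_floor, noise.sigma_cycle_rel * np.abs(scaled)),
            noise.blank_sd,
        )
        return scaled + rng.standard_normal(scaled.shape) * sd

    ocr_vals = measure(truth_ocr)
    if kind is ProtocolKind.GLYCO:
        ecar_vals = measure(np.nan_to_num(truth_per)) / constants.per_scale
    else:
        ecar_vals = np.full_like(ocr_vals, np.nan)

    wells = pd.DataFrame({
        "plate_id": plate_id,
        "well": coords,
        "role": ["SAMPLE" if s else "BLANK" for s in is_sample],
        "experiment_id": experiment_id,
        "substance": [ct.substance if ct else "NONE" for ct, _ in layout],
        "dose": [ct.dose if ct else np.nan for ct, _ in layout],
        "dose_unit": [ct.dose_unit if ct else "" for ct, _ in layout],
        "arm": [arm.value if arm else "" for _, arm in layout],
        "cell_count": cells.astype(int),
    })
    cyc_idx = np.arange(1, n_cycles + 1)
    records = pd.DataFrame({
        "plate_id": plate_id,
        "well": np.repeat(coords, n_cycles),
        "cycle_index": np.tile(cyc_idx, n_wells),
        "phase": np.tile(phases, n_wells),
        "time_min": np.tile(cyc_idx * protocol.cycle_interval, n_wells),
        "ocr": ocr_vals.ravel(),
        "ecar": ecar_vals.ravel(),
    })
    run = PlateRun(protocol, wells, records,
                   meta={"scenario": scenario.name, "seed": scenario.seed,
                         "experiment_id": experiment_id, "kind": kind.value})
    return run.validate()


def simulate_experiment_set(scenario: SimScenario, kind: ProtocolKind | str,
                            arm_split: bool = True,
                            constants: ConversionConstants | None = None) -> list[PlateRun]:
    """One run per independent experiment, deterministically seeded."""
    return [
        simulate_run(scenario, kind, eid, arm_split=arm_split, constants=constants)
        for eid in scenario.experiment_ids()
    ]
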