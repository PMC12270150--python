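"""End-to-end confound and ATP-budget analyses over sets of plate runs.

``run_confound_analysis`` reproduces the paired ±CV-inhibition analysis:
preprocessing, per-well respiration parameters, Tukey-fence outlier
removal, experiment-level percent underestimation of MR and SRC, Ni
dose-response slopes, per-condition summaries, and the inferential tests
(two-way arm x condition ANOVA with Tukey HSD, per-arm Dunnett contrasts
vs control, Levene check, Cohen's d for the control ±CV contrast).

``run_atp_analysis`` assembles mitochondrial (coupled OCR x 2 x P/O) and
glycolytic (demand-limited PER) ATP production rates, per-condition folds
vs the shared control, and the mito-ATP dose slope.

Arms are never mixed when computing ATP-linked parameters; MR and SRC
summaries default to the CV-free arm (the recommended procedure), with
CV-inhibited values reported alongside for the confound contrast.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .atp import atp_budget, mito_atp
from .glyco import glyco_param_table
from .mito import mito_param_table, paired_underestimation
from .plate import Arm, ConversionConstants, PlateRun
from .stats import (
    TestResult,
    aggregate,
    cohens_d,
    one_way_dunnett,
    slope_test,
    t_test,
    tukey_fences,
    tukey_pairwise,
    two_way_tukey,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_confound_analysis",
           "run_atp_analysis", "render_report", "condition_label",
           "replicate_confound_flags", "headline_metrics", "load_config"]

CONTROL = ("NONE", 0.0)
_MITO_PARAMS = ["basal", "atp_linked", "proton_leak", "mr", "src", "nonmito"]
_GLYCO_PARAMS = ["basal_acidification", "basal_glycolysis", "atp_demand_limited",
                 "max_capacity", "reserve", "dg_residual"]


@dataclass(frozen=True)
class AnalysisConfig:
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    fences_k: float = 1.5
    src_literal: bool = False
    demand_glyco_only: bool = False
    glyco_atp_source: str = "atp_demand_limited"
    robust_blanks: bool = False
    seed: int = 0  # seeds the randomized Dunnett integration

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML (or JSON) file.

    The file holds top-level config fields plus an optional ``constants``
    mapping for :class:`ConversionConstants`, e.g.::

        constants: {buffering_factor: 2.4, ccf: 0.61, po_ratio: 2.75}
        fences_k: 1.5
        glyco_atp_source: atp_demand_limited
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    constants = ConversionConstants(**data.pop("constants", {}))
    return AnalysisConfig(constants=constants, **data)


@dataclass
class AnalysisReport:
    kind: str
    group_summaries: pd.DataFrame | None = None
    combined_summary: pd.DataFrame | None = None
    underestimation: pd.DataFrame | None = None
    underestimation_per_experiment: pd.DataFrame | None = None
    dose_response: dict = field(default_factory=dict)
    parameter_changes: pd.DataFrame | None = None
    atp_budget: pd.DataFrame | None = None
    atp_folds: pd.DataFrame | None = None
    tests: list = field(default_factory=list)
    confound_flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def df(d):
            if d is None:
                return None
            clean = d.replace({np.nan: None})
            return clean.to_dict(orient="records")

        return {
            "kind": self.kind,
            "group_summaries": df(self.group_summaries),
            "combined_summary": df(self.combined_summary),
            "underestimation": df(self.underestimation),
            "underestimation_per_experiment": df(self.underestimation_per_experiment),
            "dose_response": {k: v.to_dict() for k, v in self.dose_response.items()},
            "parameter_changes": df(self.parameter_changes),
            "atp_budget": df(self.atp_budget),
            "atp_folds": df(self.atp_folds),
            "tests": [t.to_dict() for t in self.tests],
            "confound_flags": self.confound_flags,
            "provenance": self.provenance,
        }


def condition_label(substance: str, dose: float) -> str:
    return f"{substance}:{dose:g}"


def _provenance(config: AnalysisConfig, runs: list[PlateRun]) -> dict:
    try:
        version = metadata.version("fluxstress")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {
        "config_hash": config.digest(),
        "package_version": version,
        "runs": sorted({str(r.meta.get("experiment_id", "?")) for r in runs}),
        "seeds": sorted({int(r.meta["seed"]) for r in runs if "seed" in r.meta}),
    }


def _fence_to_nan(df: pd.DataFrame, cols: list[str], keys: list[str], k: float) -> pd.DataFrame:
    """Technical-level fences: flagged values become NaN (per parameter, so
    one aberrant parameter does not discard the well's other parameters)."""
    out = df.copy()
    for col in cols:
        def mask(s: pd.Series) -> pd.Series:
            v = s.to_numpy(dtype=float)
            ok = tukey_fences(v[~np.isnan(v)], k)
            full = np.ones(v.shape, dtype=bool)
            full[~np.isnan(v)] = ok
            return pd.Series(full, index=s.index)

        keep = out.groupby(keys, dropna=False)[col].transform(mask)
        out.loc[~keep.astype(bool), col] = np.nan
    return out


def _per_experiment_means(params: pd.DataFrame, cols: list[str],
                          keys: list[str]) -> pd.DataFrame:
    return params.groupby(keys + ["experiment_id"], dropna=False)[cols].mean().reset_index()


def _paired_change(per_exp: pd.DataFrame, col: str) -> pd.DataFrame:
    """Percent decrease vs the same experiment's control, then mean ± SEM."""
    ctrl = per_exp[(per_exp["substance"] == CONTROL[0]) & (per_exp["dose"] == CONTROL[1])]
    ctrl = ctrl.set_index("experiment_id")[col]
    work = per_exp.copy()
    work["pct_decrease"] = 100.0 * (1.0 - work[col] / work["experiment_id"].map(ctrl))
    agg = work.groupby(["substance", "dose"])["pct_decrease"].agg(["mean", "sem", "count"])
    agg.columns = ["pct_decrease_mean", "pct_decrease_sem", "n"]
    return agg.reset_index()


def run_confound_analysis(mito_runs: list[PlateRun],
                          config: AnalysisConfig | None = None) -> AnalysisReport:
    """Full paired ±CV-inhibition analysis over one run per experiment."""
    config = config or AnalysisConfig()
    params = pd.concat(
        [mito_param_table(r, src_literal=config.src_literal,
                          robust_blanks=config.robust_blanks) for r in mito_runs],
        ignore_index=True,
    )
    params = _fence_to_nan(params, _MITO_PARAMS,
                           ["experiment_id", "substance", "dose", "arm"], config.fences_k)

    # experiment-level paired underestimation of MR and SRC
    urec = paired_underestimation(params)
    u_summary = aggregate(urec, "percent_underestimation",
                          ["substance", "dose", "parameter"],
                          k_technical=None, k_experimental=config.fences_k)

    # Ni dose-response of the underestimation (per-experiment observations)
    ni = urec[urec["substance"].isin([CONTROL[0], "NI"])]
    dose_response = {}
    for param in ("MR", "SRC"):
        sub = ni[ni["parameter"] == param]
        dose_response[f"U_{param}"] = slope_test(
            sub["dose"], sub["percent_underestimation"],
            label=f"percent underestimation of {param} vs Ni ppm",
        )

    # per-condition/arm summaries of every parameter
    long = params.melt(id_vars=["experiment_id", "substance", "dose", "arm"],
                       value_vars=_MITO_PARAMS, var_name="parameter")
    summaries = aggregate(long.dropna(subset=["value"]), "value",
                          ["substance", "dose", "arm", "parameter"],
                          k_technical=None, k_experimental=None)

    # reporting convention: basal averages both arms; ATP-linked and leak come
    # from the CV-inhibited arm; MR, SRC, non-mito from the CV-free arm
    conv = {"basal": None, "atp_linked": Arm.CV_INHIBITED.value,
            "proton_leak": Arm.CV_INHIBITED.value, "mr": Arm.CV_FREE.value,
            "src": Arm.CV_FREE.value, "nonmito": Arm.CV_FREE.value}
    combined_rows = []
    for p, arm in conv.items():
        sub = long[long["parameter"] == p]
        if arm is not None:
            sub = sub[sub["arm"] == arm]
        else:
            sub = sub.groupby(["experiment_id", "substance", "dose", "parameter"],
                              as_index=False)["value"].mean()
        agg = aggregate(sub.dropna(subset=["value"]), "value",
                        ["substance", "dose", "parameter"],
                        k_technical=None, k_experimental=None)
        combined_rows.append(agg)
    combined = pd.concat(combined_rows, ignore_index=True)

    # paired percent changes vs control, per arm
    per_exp = _per_experiment_means(params, ["mr", "src"], ["substance", "dose", "arm"])
    changes = []
    for arm in (Arm.CV_FREE.value, Arm.CV_INHIBITED.value):
        for col in ("mr", "src"):
            ch = _paired_change(per_exp[per_exp["arm"] == arm], col)
            ch.insert(0, "parameter", col.upper())
            ch.insert(0, "arm", arm)
            changes.append(ch)
    changes = pd.concat(changes, ignore_index=True)

    # inferential tests on per-experiment means (need >= 2 experiments)
    rng = np.random.default_rng(config.seed)
    tests: list[TestResult] = []
    per_exp["condition"] = [condition_label(s, d) for s, d in
                            zip(per_exp["substance"], per_exp["dose"])]
    n_exp = params["experiment_id"].nunique()
    flags: dict = {}
    if n_exp >= 2:
        flags = _confound_flags(per_exp)
        tests = _confound_tests(per_exp, config, rng)

    report = AnalysisReport(
        kind="confound",
        group_summaries=summaries,
        combined_summary=combined,
        underestimation=u_summary,
        underestimation_per_experiment=urec,
        dose_response=dose_response,
        parameter_changes=changes,
        tests=tests,
        confound_flags=flags,
        provenance=_provenance(config, mito_runs),
    )
    return report


def _confound_tests(per_exp: pd.DataFrame, config: AnalysisConfig, rng) -> list[TestResult]:
    tests: list[TestResult] = []
    for col in ("mr", "src"):
        tests += two_way_tukey(per_exp.rename(columns={col: "value"}),
                               "value", "arm", "condition", label=col.upper())
        ni_only = per_exp[per_exp["substance"].isin([CONTROL[0], "NI"])]
        for arm in (Arm.CV_FREE.value, Arm.CV_INHIBITED.value):
            sub = ni_only[ni_only["arm"] == arm].rename(columns={col: "value"})
            tests += one_way_dunnett(sub, "value", "condition",
                                     condition_label(*CONTROL), rng=rng,
                                     label=f"{col.upper()} | {arm}")
    ctrl = per_exp[(per_exp["substance"] == CONTROL[0]) & (per_exp["dose"] == CONTROL[1])]
    eff = cohens_d(ctrl.loc[ctrl["arm"] == Arm.CV_FREE.value, "mr"],
                   ctrl.loc[ctrl["arm"] == Arm.CV_INHIBITED.value, "mr"])
    tests.append(TestResult("T_TEST", "control MR: CV_FREE vs CV_INHIBITED",
                            float("nan"), (len(ctrl) - 2,), float("nan"), effect=eff))
    return tests


def _confound_flags(per_exp: pd.DataFrame, alpha: float = 0.05,
                    high_dose: float = 72.0) -> dict:
    """The qualitative confound contrasts, from Tukey HSD over the
    arm x condition cell means (the two-way design of the source analysis):
    is the high-dose vs control change in MR / SRC significant in each arm?
    """
    flags: dict[str, bool | float] = {}
    cells = per_exp.groupby(["arm", "substance", "dose"])
    keys = sorted(cells.groups)
    for col in ("mr", "src"):
        groups = [cells.get_group(k)[col].dropna().to_numpy() for k in keys]
        _, pmat, _ = tukey_pairwise(groups)
        for arm in (Arm.CV_FREE.value, Arm.CV_INHIBITED.value):
            i = keys.index((arm, CONTROL[0], CONTROL[1]))
            j = keys.index((arm, "NI", high_dose))
            p = float(pmat[i, j])
            diff = float(np.mean(groups[j]) - np.mean(groups[i]))
            tag = f"{col}_{'free' if arm == Arm.CV_FREE.value else 'inhibited'}"
            flags[f"{tag}_significant"] = bool(p < alpha)
            flags[f"{tag}_p"] = p
            flags[f"{tag}_change"] = diff
    flags["mr_masked"] = bool(flags["mr_free_significant"] and not flags["mr_inhibited_significant"])
    flags["src_inverted"] = bool(
        flags["src_inhibited_significant"] and flags["src_inhibited_change"] > 0
        and not flags["src_free_significant"]
    )
    return flags


def replicate_confound_flags(n_reps: int, base_seed: int = 1,
                             n_experiments: int = 4,
                             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Replicate the qualitative confound contrasts over fresh simulations.

    For each replication the default dose-response scenario is re-simulated
    with seed ``base_seed + i`` and only the per-experiment cell means and
    Tukey contrasts are computed (the expensive full report is skipped).
    Returns one row of :func:`_confound_flags` output per replication.
    """
    from .simulate import scenario_mito_confound, simulate_experiment_set

    config = config or AnalysisConfig()
    rows = []
    for i in range(n_reps):
        sc = scenario_mito_confound(seed=base_seed + i, n_experiments=n_experiments)
        runs = simulate_experiment_set(sc, "MITO")
        params = pd.concat([mito_param_table(r) for r in runs], ignore_index=True)
        params = _fence_to_nan(params, ["mr", "src"],
                               ["experiment_id", "substance", "dose", "arm"],
                               config.fences_k)
        per_exp = _per_experiment_means(params, ["mr", "src"], ["substance", "dose", "arm"])
        rows.append({"replication": i, "seed": base_seed + i, **_confound_flags(per_exp)})
    return pd.DataFrame(rows)


def run_atp_analysis(mito_runs: list[PlateRun], glyco_runs: list[PlateRun],
                     config: AnalysisConfig | None = None) -> AnalysisReport:
    """Mitochondrial + glycolytic ATP production rates and folds vs control."""
    config = config or AnalysisConfig()
    mparams = pd.concat([mito_param_table(r, robust_blanks=config.robust_blanks)
                         for r in mito_runs], ignore_index=True)
    mparams = mparams[mparams["arm"] == Arm.CV_INHIBITED.value]
    if mparams.empty:
        raise ValueError("ATP analysis requires CV_INHIBITED mito wells")
    mparams = _fence_to_nan(mparams, ["atp_linked"],
                            ["experiment_id", "substance", "dose"], config.fences_k)
    gparams = pd.concat(
        [glyco_param_table(r, constants=config.constants,
                           demand_glyco_only=config.demand_glyco_only,
                           robust_blanks=config.robust_blanks) for r in glyco_runs],
        ignore_index=True,
    )
    gsource = "basal_glycolysis" if config.glyco_atp_source == "basal_glycolysis" \
        else "atp_demand_limited"
    gparams = _fence_to_nan(gparams, [gsource],
                            ["experiment_id", "substance", "dose"], config.fences_k)

    budget = atp_budget(mparams, gparams, constants=config.constants,
                        glyco_source=gsource)

    # per-experiment paired folds vs control for each branch
    mexp = _per_experiment_means(mparams, ["atp_linked"], ["substance", "dose"])
    mexp["mito_atp"] = mito_atp(mexp["atp_linked"], config.constants)
    gexp = _per_experiment_means(gparams, [gsource], ["substance", "dose"])
    gexp = gexp.rename(columns={gsource: "glyco_atp"})

    def paired_fold(per_exp: pd.DataFrame, col: str) -> pd.DataFrame:
        ctrl = per_exp[(per_exp["substance"] == CONTROL[0]) & (per_exp["dose"] == CONTROL[1])]
        ctrl = ctrl.set_index("experiment_id")[col]
        w = per_exp.copy()
        w["fold"] = w[col] / w["experiment_id"].map(ctrl)
        agg = w.groupby(["substance", "dose"])["fold"].agg(["mean", "sem", "count"])
        agg.columns = [f"{col}_fold", f"{col}_fold_sem", f"{col}_fold_n"]
        return agg

    folds = paired_fold(mexp, "mito_atp").join(paired_fold(gexp, "glyco_atp"), how="outer")
    # totals mix experiment sets, so the total fold uses condition means
    b = budget.set_index(["substance", "dose"])
    ctrl_total = b.loc[CONTROL, "total_atp_mean"]
    folds["total_atp_fold"] = b["total_atp_mean"] / ctrl_total
    folds = folds.reset_index()

    ni = mexp[mexp["substance"].isin([CONTROL[0], "NI"])]
    dose_response = {"mito_atp": slope_test(ni["dose"], ni["mito_atp"],
                                            label="mitochondrial ATP rate vs Ni ppm")}

    rng = np.random.default_rng(config.seed)
    tests: list[TestResult] = []
    if min(mexp["experiment_id"].nunique(), gexp["experiment_id"].nunique()) >= 2:
        gni = gexp[gexp["substance"].isin([CONTROL[0], "NI"])].copy()
        gni["condition"] = [condition_label(s, d) for s, d in zip(gni["substance"], gni["dose"])]
        tests += one_way_dunnett(gni.rename(columns={"glyco_atp": "value"}), "value",
                                 "condition", condition_label(*CONTROL), rng=rng,
                                 label="glyco ATP")
        for col, tbl in (("mito_atp", mexp), ("glyco_atp", gexp)):
            lps = tbl[tbl["substance"] == "LPS"][col]
            ctrl = tbl[(tbl["substance"] == CONTROL[0]) & (tbl["dose"] == CONTROL[1])][col]
            if len(lps) >= 2:
                tests.append(t_test(lps, ctrl, label=f"{col}: LPS vs control"))

    runs = list(mito_runs) + list(glyco_runs)
    return AnalysisReport(
        kind="atp_budget",
        atp_budget=budget,
        atp_folds=folds,
        dose_response=dose_response,
        tests=tests,
        provenance=_provenance(config, runs),
    )


def headline_metrics(seed: int, n_experiments_confound: int = 4,
                     n_experiments_atp: int = 3,
                     config: AnalysisConfig | None = None) -> dict:
    """Recompute the study's headline statistics from fresh simulations.

    Runs the default dose-response scenario through the confound analysis
    and the ATP scenario through the budget analysis, then extracts the
    reported quantities.  Returns ``{name: {"value": float, "n": int}}``
    where ``n`` is the number of experiment-level observations behind each
    number.
    """
    from .simulate import scenario_atp_budget, scenario_mito_confound, simulate_experiment_set

    config = config or AnalysisConfig(seed=seed)
    sc = scenario_mito_confound(seed=seed, n_experiments=n_experiments_confound)
    report = run_confound_analysis(simulate_experiment_set(sc, "MITO"), config)
    n = n_experiments_confound

    u = report.underestimation.set_index(["substance", "dose", "parameter"])["mean"]
    ch = report.parameter_changes.set_index(
        ["arm", "parameter", "substance", "dose"])["pct_decrease_mean"]
    free = Arm.CV_FREE.value
    n_slope = len(report.underestimation_per_experiment.query(
        "substance in ('NONE', 'NI') and parameter == 'MR'"))
    out = {
        "u_mr_control_pct": (u[("NONE", 0.0, "MR")], n),
        "u_src_control_pct": (u[("NONE", 0.0, "SRC")], n),
        "mr_decrease_ni72_pct": (ch[(free, "MR", "NI", 72.0)], n),
        "u_mr_ni72_pct": (u[("NI", 72.0, "MR")], n),
        "u_src_ni72_pct": (u[("NI", 72.0, "SRC")], n),
        "u_mr_slope_pct_per_ppm": (report.dose_response["U_MR"].slope["estimate"], n_slope),
        "mr_decrease_lps_pct": (ch[(free, "MR", "LPS", 1.0)], n),
        "src_decrease_lps_pct": (ch[(free, "SRC", "LPS", 1.0)], n),
    }

    sca = scenario_atp_budget(seed=seed, n_experiments=n_experiments_atp)
    atp = run_atp_analysis(simulate_experiment_set(sca, "MITO", arm_split=False),
                           simulate_experiment_set(sca, "GLYCO"), config)
    folds = atp.atp_folds.set_index(["substance", "dose"])
    out["glyco_atp_fold_ni72"] = (folds.loc[("NI", 72.0), "glyco_atp_fold"], n_experiments_atp)
    out["total_atp_fold_lps"] = (folds.loc[("LPS", 1.0), "total_atp_fold"], n_experiments_atp)
    out["mito_atp_slope_per_ppm"] = (
        atp.dose_response["mito_atp"].slope["estimate"],
        n_experiments_atp * 6,
    )
    return {k: {"value": float(v), "n": int(m)} for k, (v, m) in out.items()}


def _md_table(df: pd.DataFrame) -> str:
    d = df.copy()
    for c in d.columns:
        if d[c].dtype.kind == "f":
            d[c] = d[c].map(lambda x: "" if pd.isna(x) else f"{x:.4g}")
    header = "| " + " | ".join(map(str, d.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(d.columns)) + "|"
    rows = ["| " + " | ".join(map(str, r)) + " |" for r in d.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def render_report(report: AnalysisReport, path) -> None:
    """Write the report as machine JSON and human Markdown (deterministic)."""
    path = Path(path)
    if path.suffix:
        base = path.with_suffix("")
    elif path.is_dir() or str(path).endswith(("/", "\\")):
        path.mkdir(parents=True, exist_ok=True)
        base = path / "report"
    else:
        base = path
    payload = _sanitize(report.to_dict())
    (base.parent).mkdir(parents=True, exist_ok=True)
    base.with_suffix(".json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )

    lines = [f"# Analysis report ({report.kind})", ""]
    sections = [
        ("Percent underestimation (±CV inhibition)", report.underestimation),
        ("Parameter summaries (mean ± SEM over experiments)", report.group_summaries),
        ("Reporting-convention summary", report.combined_summary),
        ("Percent change vs control (paired per experiment)", report.parameter_changes),
        ("ATP production rates", report.atp_budget),
        ("ATP folds vs control", report.atp_folds),
    ]
    for title, df in sections:
        if df is None:
            if title.startswith("ATP") and report.kind == "confound":
                lines += [f"## {title}", "", "not computed", ""]
            continue
        lines += [f"## {title}", "", _md_table(df), ""]
    if report.dose_response:
        lines += ["## Dose-response slopes", ""]
        for k, t in sorted(report.dose_response.items()):
            s = t.slope or {}
            lines.append(
                f"- **{k}**: slope {s.get('estimate', float('nan')):.4g} ± "
                f"{s.get('se', float('nan')):.2g}, R² {s.get('r2', float('nan')):.3f}, "
                f"F({t.df[0]}, {t.df[1]}) = {t.statistic:.3g}, p = {t.p:.3g}"
            )
        lines.append("")
    if report.tests:
        lines += ["## Statistical tests", ""]
        for t in report.tests:
            extra = ""
            if t.effect is not None and not np.isnan(t.effect.d):
                extra = f", d = {t.effect.d:.2f} [{t.effect.ci_low:.2f}, {t.effect.ci_high:.2f}]"
            stat = "" if np.isnan(t.statistic) else f"stat = {t.statistic:.3g}, "
            ptxt = "" if np.isnan(t.p) else f"p = {t.p:.3g}"
            lines.append(f"- {t.test} {t.label}: {stat}{ptxt}{extra}")
        lines.append("")
    base.with_suffix(".md").write_text("\n".join(lines))


def _sanitize(obj):
    """Make a report payload strictly JSON: numpy scalars -> python,
    non-finite floats -> null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
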