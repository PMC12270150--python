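import dataclasses

import numpy as np
import pandas as pd
import pytest

from fluxstress.mito import mito_param_table
from fluxstress.simulate import (
    ConditionTruth,
    scenario_atp_budget,
    scenario_mito_confound,
    simulate_experiment_set,
    simulate_run,
)


def test_same_seed_gives_identical_runs():
    sc = scenario_mito_confound(seed=11)
    a = simulate_run(sc, "MITO", "E1")
    b = simulate_run(sc, "MITO", "E1")
    pd.testing.assert_frame_equal(a.records, b.records)
    pd.testing.assert_frame_equal(a.wells, b.wells)


def test_streams_differ_by_experiment_and_kind():
    sc = scenario_mito_confound(seed=11)
    a = simulate_run(sc, "MITO", "E1")
    b = simulate_run(sc, "MITO", "E2")
    assert not np.allclose(a.records["ocr"], b.records["ocr"])


def test_layout_matches_study_design():
    """7 conditions x 2 arms x sextuplicates + 4 blanks on a mito plate."""
    run = simulate_run(scenario_mito_confound(seed=1), "MITO", "E1")
    wells = run.wells
    assert len(wells) == 7 * 2 * 6 + 4
    assert (wells["role"] == "BLANK").sum() == 4
    counts = wells[wells["role"] == "SAMPLE"].groupby(["substance", "dose", "arm"]).size()
    assert (counts == 6).all()
    assert run.records.groupby("well").size().eq(11).all()


def test_noise_free_recovery_of_condition_truth(noisefree_mito_runs):
    """With zero noise and N = 1e4, the pipeline returns the generator's
    ground truth exactly: control CV-free MR 81, basal 34, non-mito 8."""
    params = mito_param_table(noisefree_mito_runs[0])
    ctrl = params[(params["substance"] == "NONE") & (params["arm"] == "CV_FREE")]
    np.testing.assert_allclose(ctrl["mr"], 81.0, rtol=1e-9)
    np.testing.assert_allclose(ctrl["basal"], 34.0, rtol=1e-9)
    np.testing.assert_allclose(ctrl["nonmito"], 8.0, atol=1e-9)


def test_noise_free_cv_inhibited_mr_shows_underestimation(noisefree_mito_runs):
    """The generative formula: measured MR under CV inhibition is
    MR*(1-u) = 81*0.44 = 35.64 for the control condition."""
    params = mito_param_table(noisefree_mito_runs[0])
    inh = params[(params["substance"] == "NONE") & (params["arm"] == "CV_INHIBITED")]
    np.testing.assert_allclose(inh["mr"], 81.0 * (1 - 0.56), rtol=1e-9)


def test_atp_scenario_defaults_mirror_study_sizes():
    sc = scenario_atp_budget()
    assert sc.n_experiments == 3
    assert scenario_mito_confound().n_experiments == 4
    doses = sorted(ct.dose for ct in sc.conditions if ct.substance == "NI")
    assert doses == [6.0, 12.0, 24.0, 48.0, 72.0]


def test_condition_truth_validation():
    with pytest.raises(ValueError):
        ConditionTruth("NONE", 0.0, "", nonmito_ocr=8, basal_mito_ocr=40,
                       leak_fraction=0.15, max_resp_ocr=30, underestimation_mr=0.5)
    with pytest.raises(ValueError):
        ConditionTruth("NONE", 0.0, "", nonmito_ocr=8, basal_mito_ocr=20,
                       leak_fraction=0.15, max_resp_ocr=30, underestimation_mr=1.5)


def test_between_experiment_sem_magnitude():
    """Default noise should put the relative SEM of recovered MR within a
    factor 3 of the study's printed relative SEM (~12.5% = 7/56).  A single
    4-experiment SEM has 3 df and all cells of one simulation share the same
    experiment draws, so the relative variance is pooled over all
    condition x arm cells of three independent simulations."""
    rels = []
    for seed in (1, 2, 3):
        runs = simulate_experiment_set(scenario_mito_confound(seed=seed), "MITO")
        params = pd.concat([mito_param_table(r) for r in runs])
        per_exp = params.groupby(
            ["substance", "dose", "arm", "experiment_id"])["mr"].mean().reset_index()
        g = per_exp.groupby(["substance", "dose", "arm"])["mr"]
        rels += list(g.var(ddof=1) / g.mean() ** 2)
    rel_sem = np.sqrt(np.mean(rels)) / 2  # SEM with n = 4 experiments
    assert 0.125 / 3 <= rel_sem <= 0.125 * 3


def test_post_raa_ocr_nonnegative_in_expectation(default_mito_runs):
    """Non-mitochondrial OCR stays positive on average after blank correction."""
    params = pd.concat([mito_param_table(r) for r in default_mito_runs])
    assert params["nonmito"].mean() > 0
    assert (params.groupby(["substance", "dose"])["nonmito"].mean() > 0).all()


def test_cellcount_multiplier_is_absorbed_by_normalization():
    """A condition-specific shift in attached-cell numbers must not move
    the per-1e4-cell parameters (the normalization-robustness probe)."""
    base = scenario_mito_confound(seed=9, n_experiments=1).noise_free()
    bumped = dataclasses.replace(base, cellcount_multiplier=((("NI", 72.0), 1.15),))
    p0 = mito_param_table(simulate_run(base, "MITO", "E1"))
    p1 = mito_param_table(simulate_run(bumped, "MITO", "E1"))
    hi0 = p0[(p0["substance"] == "NI") & (p0["dose"] == 72.0)]["mr"]
    hi1 = p1[(p1["substance"] == "NI") & (p1["dose"] == 72.0)]["mr"]
    np.testing.assert_allclose(hi0.to_numpy(), hi1.to_numpy(), rtol=1e-9)


def test_oversized_layout_rejected():
    sc = scenario_mito_confound(seed=1)
    big = dataclasses.replace(sc, replicates_per_condition_arm=8)
    with pytest.raises(ValueError, match="96"):
        simulate_run(big, "MITO", "E1")
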