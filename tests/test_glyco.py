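import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxstress.glyco import (
    PerRates,
    ecar_to_per,
    glyco_param_table,
    glyco_params,
    partition_per,
)
from fluxstress.plate import GLYCO_PHASES, ConversionConstants, PlateValidationError
from fluxstress.simulate import scenario_atp_budget, simulate_run

CC = ConversionConstants()


def test_ecar_to_per_unit_conversion():
    """10 mpH/min * 2.4 mmol/L/pH * 2.28 uL * 1.6 = 87.552 pmol H+/min
    (mmol/L in a uL chamber is a nmol scale; the mpH prefix brings it to pmol)."""
    assert ecar_to_per(10.0, CC) == pytest.approx(87.552)
    assert ecar_to_per(0.0, CC) == 0.0


@given(e=st.floats(min_value=-10, max_value=100))
def test_ecar_to_per_linear_and_monotone(e):
    assert ecar_to_per(2 * e, CC) == pytest.approx(2 * ecar_to_per(e, CC))
    double_bf = ConversionConstants(buffering_factor=4.8)
    assert ecar_to_per(e, double_bf) == pytest.approx(2 * ecar_to_per(e, CC))


def test_nonpositive_constants_rejected():
    with pytest.raises(PlateValidationError):
        ConversionConstants(buffering_factor=0.0)


def _phase_map(**kw):
    base = {p: 0.0 for p in GLYCO_PHASES}
    base.update(kw)
    return base


def test_partition_uses_ccf_on_mito_ocr():
    ocr = _phase_map(pre_glucose=40.0, post_glucose=40.0, post_raa=8.0,
                     post_monensin_fccp=8.0, post_2dg=8.0)
    ecar = {p: 50.0 / CC.per_scale for p in GLYCO_PHASES}
    per = partition_per(ocr, ecar, CC, well="A1")
    assert per.mito["pre_glucose"] == pytest.approx(0.61 * 32.0)  # 19.52
    assert per.glyco["pre_glucose"] == pytest.approx(50.0 - 19.52)
    for p in ("post_raa", "post_monensin_fccp", "post_2dg"):
        assert per.mito[p] == 0.0
        assert per.glyco[p] == pytest.approx(per.total[p])


def test_negative_mito_ocr_clamped_to_zero():
    ocr = _phase_map(pre_glucose=5.0, post_glucose=5.0, post_raa=8.0)
    ecar = {p: 1.0 for p in GLYCO_PHASES}
    per = partition_per(ocr, ecar, CC)
    assert per.mito["pre_glucose"] == 0.0
    assert per.glyco["pre_glucose"] <= per.total["pre_glucose"]


def test_missing_phase_is_an_error():
    ocr = {p: 1.0 for p in GLYCO_PHASES if p != "post_raa"}
    with pytest.raises(ValueError, match="post_raa"):
        partition_per(ocr, {p: 1.0 for p in GLYCO_PHASES}, CC)


def test_glyco_parameter_deltas():
    per = PerRates(
        well="A1",
        total={"pre_glucose": 25.74, "post_glucose": 49.74, "post_raa": 49.94,
               "post_monensin_fccp": 65.0, "post_2dg": 5.0},
        mito={"pre_glucose": 20.74, "post_glucose": 20.74, "post_raa": 0.0,
              "post_monensin_fccp": 0.0, "post_2dg": 0.0},
        glyco={"pre_glucose": 5.0, "post_glucose": 29.0, "post_raa": 49.94,
               "post_monensin_fccp": 65.0, "post_2dg": 5.0},
    )
    p = glyco_params(per)
    assert p.basal_acidification == pytest.approx(5.0)
    assert p.basal_glycolysis == pytest.approx(24.0)
    assert p.atp_demand_limited == pytest.approx(49.94 - 25.74)  # 24.2
    assert p.max_capacity == pytest.approx(60.0)
    assert p.reserve == pytest.approx(p.max_capacity - p.basal_glycolysis)
    assert p.dg_residual == pytest.approx(0.0)


def test_all_phases_equal_gives_zero_deltas():
    flat = {p: 7.0 for p in GLYCO_PHASES}
    per = PerRates("A1", total=flat, mito={p: 0.0 for p in GLYCO_PHASES}, glyco=flat)
    p = glyco_params(per)
    assert p.basal_glycolysis == p.atp_demand_limited == p.reserve == p.dg_residual == 0.0


def test_noise_free_run_recovers_glyco_targets():
    """The pipeline on a noise-free glyco plate returns the scenario's
    parameter targets to 1e-6 relative error, and the 2-DG residual
    confirms glucose dependence (== 0)."""
    sc = scenario_atp_budget(seed=2, n_experiments=1).noise_free()
    tbl = glyco_param_table(simulate_run(sc, "GLYCO", "E1"))
    ctrl = tbl[(tbl["substance"] == "NONE")]
    np.testing.assert_allclose(ctrl["basal_glycolysis"], 24.0, rtol=1e-6)
    np.testing.assert_allclose(ctrl["atp_demand_limited"], 24.2, rtol=1e-6)
    np.testing.assert_allclose(ctrl["max_capacity"], 60.0, rtol=1e-6)
    np.testing.assert_allclose(ctrl["dg_residual"], 0.0, atol=1e-6)
    ni72 = tbl[(tbl["substance"] == "NI") & (tbl["dose"] == 72.0)]
    np.testing.assert_allclose(ni72["atp_demand_limited"], 24.2 * 3.3, rtol=1e-6)


def test_demand_glyco_only_variant_drops_mito_baseline():
    """With active mitochondria pre-glucose, the total-PER definition of
    demand-limited glycolysis and the glyco-only variant differ by the
    mitochondrial CO2 term, which cancels in the generator's construction."""
    sc = scenario_atp_budget(seed=2, n_experiments=1).noise_free()
    run = simulate_run(sc, "GLYCO", "E1")
    total_def = glyco_param_table(run).set_index("well")["atp_demand_limited"]
    glyco_def = glyco_param_table(run, demand_glyco_only=True).set_index("well")["atp_demand_limited"]
    ctrl_wells = total_def.index[:3]
    # glyco-only subtracts a smaller baseline, so it is larger by ccf*basal mito OCR
    diff = (glyco_def - total_def)[ctrl_wells]
    np.testing.assert_allclose(diff, 0.61 * 34.0, rtol=1e-6)
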