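import numpy as np
import pandas as pd
import pytest

from conftest import build_run
from fluxstress.plate import PlateValidationError, ProtocolKind
from fluxstress.preprocess import blank_correct, normalize_per_cell, phase_rates


def flat(v, n=11):
    return [v] * n


def test_blank_mean_is_subtracted_per_cycle():
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(50.0)},
        {"well": "H11", "role": "BLANK", "values": flat(2.0)},
        {"well": "H12", "role": "BLANK", "values": flat(4.0)},
    ])
    out = blank_correct(run)
    a1 = out.records[out.records["well"] == "A1"]["ocr"]
    np.testing.assert_allclose(a1, 47.0)
    # blank records untouched
    h11 = out.records[out.records["well"] == "H11"]["ocr"]
    np.testing.assert_allclose(h11, 2.0)


def test_zero_blanks_leave_samples_unchanged():
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(50.0)},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    out = blank_correct(run)
    np.testing.assert_allclose(out.records[out.records["well"] == "A1"]["ocr"], 50.0)


def test_negative_blank_raises_sample_signed_subtraction():
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(50.0)},
        {"well": "H12", "role": "BLANK", "values": flat(-1.0)},
    ])
    out = blank_correct(run)
    np.testing.assert_allclose(out.records[out.records["well"] == "A1"]["ocr"], 51.0)


def test_blank_correction_is_linear():
    """Applying the correction twice equals subtracting the blank mean twice
    (blanks keep their values, so the reference does not move)."""
    rng = np.random.default_rng(0)
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": list(rng.normal(40, 3, 11))},
        {"well": "H11", "role": "BLANK", "values": list(rng.normal(1, 0.5, 11))},
        {"well": "H12", "role": "BLANK", "values": list(rng.normal(-1, 0.5, 11))},
    ])
    once = blank_correct(run)
    twice = blank_correct(once)
    blank_mean = run.records[run.records["well"].isin(["H11", "H12"])] \
        .groupby("cycle_index")["ocr"].mean()
    orig = run.records[run.records["well"] == "A1"].set_index("cycle_index")["ocr"]
    got = twice.records[twice.records["well"] == "A1"].set_index("cycle_index")["ocr"]
    np.testing.assert_allclose(got, orig - 2 * blank_mean, rtol=1e-12)


def test_no_blanks_is_an_error():
    run = build_run(ProtocolKind.MITO, [{"well": "A1", "values": flat(50.0)}])
    run.wells = run.wells[run.wells["role"] == "SAMPLE"]
    with pytest.raises(PlateValidationError):
        blank_correct(run)


@pytest.mark.parametrize("value,cells,expected", [(60.0, 20_000, 30.0),
                                                  (60.0, 10_000, 60.0),
                                                  (-2.0, 5_000, -4.0)])
def test_per_cell_normalization(value, cells, expected):
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(value), "cell_count": cells},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    out = normalize_per_cell(run)
    np.testing.assert_allclose(out.records[out.records["well"] == "A1"]["ocr"], expected)


def test_normalization_rejects_zero_cell_count():
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(1.0), "cell_count": 10_000},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    run.wells.loc[run.wells["well"] == "A1", "cell_count"] = 0
    with pytest.raises(PlateValidationError, match="A1"):
        normalize_per_cell(run)


def test_phase_rates_apply_selection_rules():
    """pre (LAST_2): mean of cycles 2-3; post_fccp (FIRST_1): first cycle;
    post_raa (ALL): both cycles."""
    values = [10, 12, 14,  20, 22, 24,  70, 60, 50,  8, 6]
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": [float(v) for v in values]},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    rates = phase_rates(run, "ocr")
    assert rates.loc["A1", "pre"] == 13.0
    assert rates.loc["A1", "post_inj1"] == 23.0
    assert rates.loc["A1", "post_fccp"] == 70.0
    assert rates.loc["A1", "post_raa"] == 7.0


def test_glyco_monensin_phase_uses_last_two_cycles():
    values = [1, 1,  2, 2, 2,  3, 3, 3,  40, 44, 46,  1, 1, 1]
    run = build_run(ProtocolKind.GLYCO, [
        {"well": "A1", "values": [float(x) for x in values],
         "ecar": [float(x) for x in values]},
        {"well": "H12", "role": "BLANK", "values": [0.0] * 14, "ecar": [0.0] * 14},
    ])
    rates = phase_rates(run, "ecar")
    assert rates.loc["A1", "post_monensin_fccp"] == 45.0


def test_phase_rates_invariant_to_record_order():
    rng = np.random.default_rng(4)
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": list(rng.normal(40, 5, 11))},
        {"well": "B1", "values": list(rng.normal(30, 5, 11))},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    shuffled = run.copy()
    shuffled.records = shuffled.records.sample(frac=1, random_state=7).reset_index(drop=True)
    pd.testing.assert_frame_equal(phase_rates(run, "ocr"), phase_rates(shuffled, "ocr"))


def test_missing_channel_is_an_error():
    run = build_run(ProtocolKind.MITO, [
        {"well": "A1", "values": flat(1.0)},
        {"well": "H12", "role": "BLANK", "values": flat(0.0)},
    ])
    with pytest.raises(PlateValidationError, match="ecar"):
        phase_rates(run, "ecar")
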