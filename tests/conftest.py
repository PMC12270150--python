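import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fluxstress.plate import PlateRun, ProtocolKind, default_protocol
from fluxstress.simulate import scenario_mito_confound, simulate_experiment_set

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")


def build_run(kind, wells_spec):
    """Hand-build a PlateRun from explicit per-cycle values.

    ``wells_spec``: list of dicts with keys well, values (list of one value
    per protocol cycle), and optional role/arm/cell_count/substance/dose.
    """
    protocol = default_protocol(kind)
    phases = protocol.cycle_phase()
    wrows, rrows = [], []
    for spec in wells_spec:
        role = spec.get("role", "SAMPLE")
        wrows.append({
            "plate_id": "P1", "well": spec["well"], "role": role,
            "experiment_id": spec.get("experiment_id", "E1"),
            "substance": spec.get("substance", "NONE"),
            "dose": spec.get("dose", 0.0),
            "dose_unit": spec.get("dose_unit", ""),
            "arm": spec.get("arm", "CV_FREE" if role == "SAMPLE" else ""),
            "cell_count": spec.get("cell_count", 10_000 if role == "SAMPLE" else 0),
        })
        values = spec["values"]
        ecar = spec.get("ecar")
        assert len(values) == protocol.n_cycles
        for i, v in enumerate(values, start=1):
            rrows.append({
                "plate_id": "P1", "well": spec["well"], "cycle_index": i,
                "phase": phases[i], "time_min": 6.0 * i,
                "ocr": v, "ecar": np.nan if ecar is None else ecar[i - 1],
            })
    return PlateRun(default_protocol(kind), pd.DataFrame(wrows), pd.DataFrame(rrows))


@pytest.fixture(scope="session")
def mito_protocol():
    return default_protocol(ProtocolKind.MITO)


@pytest.fixture(scope="session")
def glyco_protocol():
    return default_protocol(ProtocolKind.GLYCO)


@pytest.fixture(scope="session")
def default_mito_runs():
    """Four noisy paired-arm mito plates of the dose-response scenario."""
    return simulate_experiment_set(scenario_mito_confound(seed=1), "MITO")


@pytest.fixture(scope="session")
def noisefree_mito_runs():
    sc = scenario_mito_confound(seed=3, n_experiments=1).noise_free()
    return simulate_experiment_set(sc, "MITO")
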