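import numpy as np
import pandas as pd
import pytest

from panelnet.synthetic import default_scale_definitions, default_spec, simulate_scores


@pytest.fixture(scope="session")
def spec():
    """The canonical 9-node two-wave simulation spec."""
    return default_spec()


@pytest.fixture(scope="session")
def scale_defs(spec):
    return default_scale_definitions(spec)


@pytest.fixture(scope="session")
def big_scores():
    """Large continuous two-wave sample for consistency-type checks."""
    sp = default_spec(n=100_000, likert_levels="continuous", seed=7)
    return simulate_scores(sp)


@pytest.fixture(scope="session")
def medium_scores():
    """n=5000 continuous sample shared by several estimation tests."""
    sp = default_spec(n=5000, likert_levels="continuous", seed=11)
    return simulate_scores(sp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_panel_csv(tmp_path):
    """A tiny well-formed wide panel CSV with two 3-item scales."""
    from panelnet.panel_io import ScaleDefinition

    defs = [
        ScaleDefinition("warmth", "parenting", ("w1", "w2", "w3"),
                        reverse_keyed=("w3",), response_range=(1, 5)),
        ScaleDefinition("anxiety", "mental_health", ("a1", "a2", "a3"),
                        response_range=(1, 5)),
    ]
    rows = []
    rng = np.random.default_rng(0)
    for pid in (1, 2, 3):
        row = {"participant_id": pid, "gender": pid % 2, "age": 12 + pid,
               "maternal_education": 1, "income_band": 2}
        for suf in ("_t1", "_t2"):
            for item in ("w1", "w2", "w3", "a1", "a2", "a3"):
                row[f"{item}{suf}"] = int(rng.integers(1, 6))
        rows.append(row)
    path = tmp_path / "toy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path, defs
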