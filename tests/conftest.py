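import pandas as pd
import pytest

from afhs_cost import (
    SynthConfig,
    generate_config,
    load_config,
    load_default_registry,
    make_toy_worked_example,
    run_scenario,
)

CUBE_KEYS = ["country_id", "item_id", "item_kind", "year", "cost_category"]


@pytest.fixture(scope="session")
def registry():
    """(countries, interventions, characteristics) from the packaged tables."""
    return load_default_registry()


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """The 2-country, 2-intervention worked example: (config, expected cube)."""
    return make_toy_worked_example(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def synth5_dir(tmp_path_factory):
    """A 5-country synthetic configuration directory (seed 42)."""
    out = tmp_path_factory.mktemp("synth5")
    return generate_config(SynthConfig(seed=42, n_countries=5), out / "cfg")


@pytest.fixture(scope="session")
def synth5_config(synth5_dir):
    return load_config(synth5_dir)


@pytest.fixture(scope="session")
def synth5_incremental(synth5_config):
    return run_scenario(synth5_config, "incremental")


def trim_interventions(config_dir, keep, out_dir):
    """Restrict a configuration directory to a subset of interventions."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for f in config_dir.iterdir():
        (out_dir / f.name).write_bytes(f.read_bytes())
    for name, col in (("interventions.csv", "intervention_id"),
                      ("need_params.csv", "intervention_id"),
                      ("baselines.csv", "intervention_id"),
                      ("ingredients.csv", "intervention_id")):
        df = pd.read_csv(out_dir / name, dtype={col: str})
        df[df[col].isin(keep)].to_csv(out_dir / name, index=False)
    return out_dir


def assert_cubes_match(actual, expected, rel=1e-9):
    """Cell-wise comparison of two tidy cost cubes."""
    m = actual.merge(expected, on=CUBE_KEYS, how="outer",
                     suffixes=("_act", "_exp"), indicator=True)
    assert (m["_merge"] == "both").all(), "cubes have different cells"
    scale = m["amount_exp"].abs().clip(lower=1.0)
    assert ((m["amount_act"] - m["amount_exp"]).abs() <= rel * scale).all()
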