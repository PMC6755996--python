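import pytest

from grnx.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """Default noisy two-species universe (15 datasets, sensitivity 0.9,
    false-call rate 0.02, peak dropout 0.2), fixed seed."""
    return generate_scenario(ScenarioConfig(rng_seed=1))


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Noise-free limit: every regulated gene is called in every dataset,
    no spurious calls, no peak dropout, no background peaks."""
    return generate_scenario(
        ScenarioConfig(
            detection_sensitivity=1.0,
            false_call_rate=0.0,
            peak_dropout=0.0,
            noise_peaks_per_dataset=0,
            rng_seed=3,
        )
    )


@pytest.fixture(scope="session")
def default_bundle(default_scenario, tmp_path_factory):
    """Default scenario written out in its external file formats."""
    from grnx.synthetic_data import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(default_scenario, out)
    return out


def expression_calls(scenario, species):
    """Tidy per-dataset calls for one species of a scenario."""
    from grnx.expression_score import calls_from_tables

    cfg = scenario.expression_config
    return calls_from_tables(
        scenario.expression[species], cfg[cfg["species"] == species]
    )
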