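import pandas as pd
import pytest

from outlethei import hei_engine, synthetic_data


@pytest.fixture(scope="session")
def standards():
    return hei_engine.load_standards()


@pytest.fixture(scope="session")
def small_population():
    """Four-outlet synthetic population, modest size, fixed seed."""
    config = synthetic_data.demo_config(n_respondents=300, n_strata=8, seed=11)
    respondents, items = synthetic_data.generate(config)
    return config, respondents, items


@pytest.fixture()
def toy_respondents():
    """2 strata x 2 PSUs, three respondents per PSU."""
    rows = []
    k = 0
    for s in range(2):
        for p in range(2):
            for _ in range(3):
                rows.append(
                    dict(
                        respondent_id=f"r{k}",
                        cycle="a",
                        age_years=30.0,
                        day1_weight=1.0 + 0.5 * k,
                        stratum=f"s{s}",
                        psu=str(p),
                        recall_reliable=True,
                        consumes_human_milk=False,
                    )
                )
                k += 1
    return pd.DataFrame(rows)
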