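import numpy as np
import pandas as pd
import pytest

import oralforce as of


@pytest.fixture(scope="session")
def truth():
    return of.default_truth(seed=0)


@pytest.fixture(scope="session")
def survey_5k(truth):
    return of.gen_survey(truth, 5000, seed=11)


@pytest.fixture(scope="session")
def rates_5k(survey_5k):
    return of.estimate_need_rates(survey_5k)


@pytest.fixture(scope="session")
def population(truth):
    return of.gen_population(truth, (2017, 2050))


@pytest.fixture()
def toy_survey():
    """Four hand-built respondents: two visitors, two non-visitors."""
    return pd.DataFrame(
        {
            "sex": ["female", "female", "male", "male"],
            "age_years": [30, 40, 50, 60],
            "natural_teeth_category": ["all_natural"] * 4,
            "food_pain_problem": [False, True, False, False],
            "visited_12m": [True, False, True, False],
            "frequency_category": ["twice", None, "once", None],
            "last_visit_type": ["checkup_exam_cleaning", None, "emergency_treatment", None],
        }
    )
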