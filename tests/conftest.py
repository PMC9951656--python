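import pytest

import hedgelife as hl


@pytest.fixture(scope="session")
def study_counts():
    return hl.study_age_counts()


@pytest.fixture(scope="session")
def study_records():
    return hl.study_records()


@pytest.fixture(scope="session")
def male_table(study_counts):
    return hl.build_life_table(study_counts["male"])


@pytest.fixture(scope="session")
def female_table(study_counts):
    return hl.build_life_table(study_counts["female"])
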