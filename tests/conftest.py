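import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from mnminer import SurveyConfig, read_leaf_table
from mnminer.simulate import gen_survey, gen_tree_traits_rates


@pytest.fixture(scope="session")
def survey():
    """One paper-like synthetic survey, parsed through the reader."""
    leaf, soil, truth = gen_survey(SurveyConfig(seed=11))
    return leaf, soil, truth


@pytest.fixture(scope="session")
def survey_samples(survey, tmp_path_factory):
    leaf, _, _ = survey
    path = tmp_path_factory.mktemp("survey") / "leaf.csv"
    leaf.to_csv(path, index=False)
    return read_leaf_table(path)


@pytest.fixture(scope="session")
def small_tree_bundle():
    """20-tip Yule tree with a Brownian trait and trait-linked rates."""
    return gen_tree_traits_rates(n_tips=20, seed=7)


def leaf_csv(tmp_path, rows, header=None):
    header = header or (
        "site_id,region,species,genus,role,replicate,N,P,Mn"
    )
    path = tmp_path / "leaf.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
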