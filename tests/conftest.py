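import logging

import pytest

from metaror import OutcomeConfig, ReviewDataset, TrialRecord
from metaror.data_model import ROB_DOMAINS

# the k=1 DerSimonian-Laird warning is expected in small strata and would
# otherwise flood captured logs
logging.getLogger("metaror.meta").setLevel(logging.ERROR)


def rob(rating="low", **overrides):
    judgements = {domain: rating for domain in ROB_DOMAINS}
    judgements.update(overrides)
    return judgements


def trial(review_id, trial_id, language="chinese", population="chinese",
          events_treat=10, n_treat=100, events_ctrl=20, n_ctrl=100, rob_map=None):
    return TrialRecord(
        review_id=review_id,
        trial_id=trial_id,
        language=language,
        population=population,
        events_treat=events_treat,
        n_treat=n_treat,
        events_ctrl=events_ctrl,
        n_ctrl=n_ctrl,
        rob=rob_map or rob(),
    )


def config(review_id, outcome_name="mortality", outcome_role="primary",
           model="fixed", method="mantel_haenszel",
           continuity_correction="constant_half", invert_direction=False):
    return OutcomeConfig(
        review_id=review_id,
        outcome_name=outcome_name,
        outcome_role=outcome_role,
        model=model,
        method=method,
        continuity_correction=continuity_correction,
        invert_direction=invert_direction,
    )


@pytest.fixture
def small_dataset():
    """Two reviews, each with trials in both languages and mixed ROB."""
    trials = [
        trial("R1", "T1", language="chinese", events_treat=8, events_ctrl=20,
              rob_map=rob("high")),
        trial("R1", "T2", language="chinese", events_treat=12, events_ctrl=22,
              rob_map=rob("unclear")),
        trial("R1", "T3", language="other", population="non_chinese",
              events_treat=15, events_ctrl=18, rob_map=rob("low")),
        trial("R1", "T4", language="other", population="non_chinese",
              events_treat=17, events_ctrl=20, rob_map=rob("low")),
        trial("R2", "T1", language="chinese", events_treat=10, events_ctrl=25,
              rob_map=rob("high")),
        trial("R2", "T2", language="other", population="non_chinese",
              events_treat=14, events_ctrl=16, rob_map=rob("low")),
    ]
    configs = [
        config("R1"),
        config("R2", model="random", method="inverse_variance"),
    ]
    return ReviewDataset(trials, configs)
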