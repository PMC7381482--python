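"""Shared fixtures.

The expensive fixtures (trained hub cohorts, trained SRN cohort) are
session-scoped and shared between the module tests and the acceptance
suite; their seeds mirror the desk-scale experiment defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

from lesionlab import beverage as bev
from lesionlab import hub, patterns, srn
from lesionlab.seeds import derive_seed

MASTER_SEED = 0
DESK_NETWORKS = 5


def train_hub_cohort(profile_id: str, n: int = DESK_NETWORKS,
                     master_seed: int = MASTER_SEED):
    """Train one network per template-generated pattern-set variant."""
    profile = patterns.build_profile(profile_id)
    nets, sets = [], []
    for i in range(n):
        ps = patterns.generate_patterns(
            profile, derive_seed(master_seed, f"{profile_id}-variant", i))
        net = hub.init_network(
            seed=derive_seed(master_seed, f"{profile_id}-netinit", i))
        hub.train(net, ps,
                  seed=derive_seed(master_seed, f"{profile_id}-train", i))
        nets.append(net)
        sets.append(ps)
    return nets, sets


@pytest.fixture(scope="session")
def p1_cohort():
    return train_hub_cohort("P1-like")


@pytest.fixture(scope="session")
def p2_cohort():
    return train_hub_cohort("P2-like")


@pytest.fixture(scope="session")
def corpus_grammar():
    return bev.build_corpus()


@pytest.fixture(scope="session")
def srn_cohort(corpus_grammar):
    corpus, _ = corpus_grammar
    nets = [srn.train_srn(corpus=corpus,
                          seed=derive_seed(MASTER_SEED, "srn-init", i))
            for i in range(3)]
    return nets


@pytest.fixture()
def p2_profile():
    return patterns.build_profile("P2-like")


@pytest.fixture()
def small_pattern_set(p2_profile):
    return patterns.generate_patterns(p2_profile, 123)
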