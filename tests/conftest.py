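import numpy as np
import pytest

import metascore as ms

# Light boosting profile for desk-scale synthetic checks: identical model
# family and contract as the paper-scale defaults, sized for quick repeated
# fits. Background and real runs always share the profile, so empirical
# p-value calibration is unaffected by it.
LIGHT_XGB = {"n_estimators": 30, "max_depth": 3, "max_bin": 64, "n_jobs": 1}


@pytest.fixture(scope="session")
def light_params():
    return dict(LIGHT_XGB)


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separable cohort: 5 planted genes at 5 noise SDs."""
    return ms.generate_cohort(
        n_genes=50, n_informative=5, effect_size=5.0,
        class_sizes=(60, 60), noise_sd=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """No planted structure: labels independent of expression."""
    return ms.generate_cohort(
        n_genes=100, n_informative=0, effect_size=1.0,
        class_sizes=(40, 40), noise_sd=1.0, seed=5,
    )


@pytest.fixture(scope="session")
def scored_cohort(light_params):
    """A full small scoring run shared by selection/evaluation tests."""
    expr, labels, truth = ms.generate_cohort(
        n_genes=120, n_informative=6, effect_size=3.0,
        class_sizes=(50, 50), noise_sd=1.0, seed=23,
    )
    records = ms.train_eval_models(expr, labels, 8, seed=2,
                                   backend_params=light_params)
    score = ms.compute_ms(records)
    pool = ms.build_background(expr, labels, 3, 8, seed=3,
                               backend_params=light_params)
    ep = ms.empirical_pvalues(score, pool)
    table = ms.score_table(expr.index, score, ep)
    return expr, labels, truth, table, pool
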