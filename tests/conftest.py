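"""Shared fixtures: one default synthetic cohort, processed once per session."""

import pytest

from colonsurv import adherence, claims_engine, cohort_synth, default_config, weighting


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: n=2000 confounded cohort, fully processed."""
    cfg = default_config(n_patients=2000, seed=11)
    patients, claims, truth = cohort_synth.simulate_cohort(cfg)
    counts = claims_engine.build_counts(patients, claims)
    profiles = adherence.build_profiles(counts)
    return {
        "config": cfg,
        "patients": patients,
        "claims": claims,
        "truth": truth,
        "counts": counts,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def weighted_default_cohort(default_cohort):
    """Boosted-propensity ATE weighting of the default cohort."""
    cohort = weighting.weight_cohort(
        default_cohort["patients"], default_cohort["profiles"]
    )
    return {**default_cohort, "weighted": cohort}
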