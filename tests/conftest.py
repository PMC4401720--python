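import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from saemir import ThresholdConfig
from saemir import synthetic as syn

settings.register_profile(
    "deterministic", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def paper_cfg() -> ThresholdConfig:
    """The published thresholds (p<0.01/|FC|>1.5 select; p<0.05 persist)."""
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    design = syn.CohortDesign(n_mirna=150, n_up=10, n_down=6,
                              persist_fraction=0.5, effect_log2=2.0,
                              noise_sd_log2=0.5, seed=11)
    return syn.generate_cohort(design)


def make_meta(groups, genders=None, subjects=None) -> pd.DataFrame:
    """Build a metadata frame from parallel lists (helper for toy designs)."""
    n = len(groups)
    if genders is None:
        genders = ["F" if i % 2 == 0 else "M" for i in range(n)]
    if subjects is None:
        subjects = [f"subj{i:02d}" for i in range(n)]
        # pair quitters with baseline subjects in order of appearance
        base = [s for s, g in zip(subjects, groups) if g == "smoker_baseline"]
        qi = 0
        for i, g in enumerate(groups):
            if g == "quitter":
                subjects[i] = base[qi]
                qi += 1
    return pd.DataFrame({
        "sample_id": [f"s{i:02d}" for i in range(n)],
        "subject_id": subjects, "group": groups, "gender": genders})
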