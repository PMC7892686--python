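"""Shared fixtures: published candidate rows and reduced synthetic bundles."""

import pytest
from hypothesis import HealthCheck, settings

from pistilmet.screen import run_screen
from pistilmet.simulate import generate_study_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The 16 internally consistent published candidate rows for the m/z 549.3273
# precursor: ([M+H]+ formula, printed theoretical m/z, printed neutral RDBE).
# Two further printed rows are corrupted as typeset and excluded; the
# reconstruction of one of them (C32H47N4P2, RDBE 13) is kept separately
# because its recomputed m/z rounds 0.1 mDa away from the printed value.
PUBLISHED_CANDIDATE_ROWS = [
    ("C27H49O11", 549.3269, 4),
    ("C22H46N8O6P", 549.3272, 5),
    ("C21H50N4O10P", 549.3259, 0),
    ("C24H41N10O5", 549.3256, 10),
    ("C24H53N6P4", 549.3277, 4),
    ("C25H37N14O", 549.3269, 15),
    ("C24H51N6O2P2S", 549.3264, 4),
    ("C31H51O4P2", 549.3257, 8),
    ("C19H38N18P", 549.3259, 11),
    ("C17H43N16OP2", 549.3275, 6),
    ("C28H45N4O7", 549.3283, 9),
    ("C25H52N4O3P3", 549.3247, 4),
    ("C23H42N12O2P", 549.3286, 10),
    ("C30H50N2O3PS", 549.3274, 8),
    ("C20H49N6O9S", 549.3276, 0),
    ("C17H41N16O3S", 549.3263, 6),
]

RECONSTRUCTED_CANDIDATE_ROW = ("C32H47N4P2", 549.3271, 13)

# Published in-source fragment ladder of the m/z 549.3273 precursor
# (descending fragment m/z values below the largest fragment).
FRAGMENT_LADDER_MZS = [285.2429, 267.2320, 253.2166, 235.2075, 217.1949]

#: Documented reduced problem size used throughout the test suite: the full
#: default design (4000 + 1000 null features) exercises nothing additional
#: per feature, so tests run the same pipeline on fewer nulls.
REDUCED_NULLS = {"positive": 300, "negative": 100}

#: Documented bundle seed used for ground-truth recovery checks.
BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    return generate_study_bundle(BUNDLE_SEED, n_null_features=REDUCED_NULLS)


@pytest.fixture(scope="session")
def screen_report(bundle):
    return run_screen(bundle.tables)
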