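"""Exact patient-level reconstruction of printed cohort tables.

Each published stratum gives a denominator and nested outcome counts
(live_birth <= ongoing <= clinical <= biochemical <= n).  Reconstruction
is deterministic: the first ``live_birth`` patients in a stratum carry
all four outcomes, the next ``ongoing - live_birth`` carry the upper
three, and so on.  Covariates are filled with stratum-level constants so
that stratified analyses land each patient in the right stratum; they
carry no individual-level information (the source publications print
only aggregates), so covariate-adjusted models on reconstructed tables
are not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from nics.clinical_outcomes import GROUP_CONTROL, GROUP_NICS, OUTCOME_COLUMNS

_DEFAULT_COVARIATES = {
    "male_age": 33.0,
    "n_prior_miscarriages": 0,
    "indication": "female",
    "infertility_type": "secondary",
    "gn_dosage": 1900.0,
    "gn_days": 9.7,
}


@dataclass(frozen=True)
class StratumSpec:
    """Printed counts for one (group, stratum) cell."""

    group: str
    label: str
    n: int
    biochemical: int
    clinical: int
    ongoing: int
    live_birth: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = (self.n, self.biochemical, self.clinical, self.ongoing, self.live_birth)
        names = ("n", "biochemical", "clinical", "ongoing", "live_birth")
        if min(seq) < 0:
            raise ValueError(f"stratum {self.group}/{self.label}: negative count")
        for (an, a), (bn, b) in zip(zip(names, seq), list(zip(names, seq))[1:]):
            if b > a:
                raise ValueError(
                    f"stratum {self.group}/{self.label}: {bn}={b} exceeds {an}={a} "
                    "(outcome counts must nest)"
                )


@dataclass(frozen=True)
class CohortSpec:
    """A set of strata that partition each study arm."""

    name: str
    strata: tuple[StratumSpec, ...]
    stratifier: str | None = None  # None | "age" | "miscarriages"


def reconstruct_patient_table(spec: CohortSpec) -> pd.DataFrame:
    """Patient-level binary table whose marginals equal the printed counts."""
    rows = []
    for st in spec.strata:
        cov = dict(_DEFAULT_COVARIATES)
        cov.setdefault("female_age", 33.0)
        cov.update(st.covariates)
        # ranks: patients [0, live) have all outcomes, [live, ongoing) the
        # next three, etc.; thresholds are cumulative by construction
        for i in range(st.n):
            rows.append(
                {
                    "group": st.group,
                    "stratum": st.label,
                    **cov,
                    "biochemical": int(i < st.biochemical),
                    "clinical": int(i < st.clinical),
                    "ongoing": int(i < st.ongoing),
                    "live_birth": int(i < st.live_birth),
                }
            )
    columns = [
        "group",
        "stratum",
        "female_age",
        "male_age",
        "n_prior_miscarriages",
        "indication",
        "infertility_type",
        "gn_dosage",
        "gn_days",
        *OUTCOME_COLUMNS,
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def _stratum(group, label, n, b, c, o, l, **cov) -> StratumSpec:
    return StratumSpec(group, label, n, b, c, o, l, covariates=cov)


#: Whole-cohort outcome counts (90 screened vs 161 control patients).
TABLE2_COHORT = CohortSpec(
    name="overall",
    strata=(
        _stratum(GROUP_NICS, "all", 90, 75, 63, 53, 51, female_age=35.1),
        _stratum(GROUP_CONTROL, "all", 161, 118, 87, 72, 69, female_age=32.5),
    ),
)

#: Female-age-stratified outcome counts (< 35 vs >= 35 years).
TABLE3_COHORT = CohortSpec(
    name="age_stratified",
    stratifier="age",
    strata=(
        _stratum(GROUP_NICS, "<35", 28, 24, 21, 18, 17, female_age=30.0),
        _stratum(GROUP_CONTROL, "<35", 105, 81, 69, 58, 55, female_age=30.0),
        _stratum(GROUP_NICS, ">=35", 62, 51, 42, 35, 34, female_age=38.0),
        _stratum(GROUP_CONTROL, ">=35", 56, 37, 18, 14, 14, female_age=38.0),
    ),
)

#: Prior-miscarriage-count-stratified outcome counts (0 / 1 / >= 2).
TABLE4_COHORT = CohortSpec(
    name="miscarriage_stratified",
    stratifier="miscarriages",
    strata=(
        _stratum(GROUP_NICS, "0", 59, 52, 44, 37, 36, n_prior_miscarriages=0),
        _stratum(GROUP_CONTROL, "0", 130, 97, 75, 64, 61, n_prior_miscarriages=0),
        _stratum(GROUP_NICS, "1", 19, 16, 14, 12, 11, n_prior_miscarriages=1),
        _stratum(GROUP_CONTROL, "1", 23, 16, 11, 8, 8, n_prior_miscarriages=1),
        _stratum(GROUP_NICS, ">=2", 12, 7, 5, 4, 4, n_prior_miscarriages=2),
        _stratum(GROUP_CONTROL, ">=2", 8, 5, 1, 0, 0, n_prior_miscarriages=2),
    ),
)
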