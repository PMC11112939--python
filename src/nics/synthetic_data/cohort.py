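"""Simulated patient cohorts with logistic-model binary outcomes.

Covariates are drawn per study arm from configurable distributions
(defaults follow the trial's baseline table: e.g. female age 35.1 +/- 4.2
in the screened arm, 32.5 +/- 4.9 in the control arm).  The primary
outcome is drawn from a logistic model whose design matrix is built by
the same encoder the analysis module fits with, so generating effects are
recoverable by :func:`nics.clinical_outcomes.fit_logistic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from nics._util import as_rng
from nics.clinical_outcomes import GROUP_CONTROL, GROUP_NICS, build_design


@dataclass(frozen=True)
class ArmCovariates:
    """Mean/SD (continuous) and category probabilities for one study arm."""

    female_age: tuple[float, float] = (35.1, 4.2)
    male_age: tuple[float, float] = (34.6, 4.2)
    gn_dosage: tuple[float, float] = (2077.5, 674.9)
    gn_days: tuple[float, float] = (10.0, 1.8)
    #: P(0), P(1), P(>=2) prior early spontaneous miscarriages
    miscarriage_probs: tuple[float, float, float] = (0.656, 0.211, 0.133)
    #: P(male), P(female), P(both) indication
    indication_probs: tuple[float, float, float] = (0.133, 0.767, 0.100)
    p_secondary_infertility: float = 0.778


#: Baseline-table-like covariate distributions per arm.
DEFAULT_ARMS = {
    GROUP_NICS: ArmCovariates(),
    GROUP_CONTROL: ArmCovariates(
        female_age=(32.5, 4.9),
        male_age=(33.1, 4.9),
        gn_dosage=(1856.0, 617.8),
        gn_days=(9.5, 1.8),
        miscarriage_probs=(0.807, 0.143, 0.050),
        indication_probs=(0.379, 0.441, 0.180),
        p_secondary_infertility=0.509,
    ),
}


@dataclass(frozen=True)
class CohortModel:
    """Group sizes, covariate distributions, and the true outcome model."""

    n_nics: int = 90
    n_control: int = 161
    arms: dict = field(default_factory=lambda: dict(DEFAULT_ARMS))
    outcome: str = "live_birth"
    intercept: float = -0.2
    log_or_group: float = 0.0
    #: effects keyed by design-matrix column name (see build_design)
    betas: dict = field(
        default_factory=lambda: {
            "female_age": -0.06,
            "male_age": -0.01,
            "n_miscarriages_1": -0.15,
            "n_miscarriages_2plus": -0.35,
            "indication_female": 0.1,
            "indication_both": -0.1,
            "infertility_secondary": 0.05,
            "gn_dosage": -0.0002,
            "gn_days": 0.02,
        }
    )
    #: centering applied to numeric covariates before the linear predictor
    centers: dict = field(
        default_factory=lambda: {
            "female_age": 33.0,
            "male_age": 33.0,
            "gn_dosage": 1900.0,
            "gn_days": 9.7,
        }
    )
    #: probabilities of upstream outcomes given the downstream one failed
    p_ongoing_extra: float = 0.04
    p_clinical_extra: float = 0.10
    p_biochemical_extra: float = 0.18

    def __post_init__(self) -> None:
        if self.n_nics <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")


def _draw_arm(
    rng: np.random.Generator, group: str, n: int, cov: ArmCovariates
) -> pd.DataFrame:
    def normal(ms, lo, hi):
        return np.clip(rng.normal(ms[0], ms[1], n), lo, hi)

    def probs(p):
        p = np.asarray(p, dtype=float)
        return p / p.sum()

    return pd.DataFrame(
        {
            "group": group,
            "female_age": np.round(normal(cov.female_age, 22, 40), 1),
            "male_age": np.round(normal(cov.male_age, 20, 60), 1),
            "n_prior_miscarriages": rng.choice(
                [0, 1, 2], size=n, p=probs(cov.miscarriage_probs)
            ),
            "indication": rng.choice(
                ["male", "female", "both"], size=n, p=probs(cov.indication_probs)
            ),
            "infertility_type": np.where(
                rng.random(n) < cov.p_secondary_infertility, "secondary", "primary"
            ),
            "gn_dosage": np.round(normal(cov.gn_dosage, 300, 6000), 1),
            "gn_days": np.round(normal(cov.gn_days, 4, 20), 1),
        }
    )


def simulate_patient_cohort(
    model: CohortModel, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Simulate one cohort; reproducible given the seed."""
    rng = as_rng(rng)
    frames = [
        _draw_arm(rng, GROUP_NICS, model.n_nics, model.arms[GROUP_NICS]),
        _draw_arm(rng, GROUP_CONTROL, model.n_control, model.arms[GROUP_CONTROL]),
    ]
    df = pd.concat(frames, ignore_index=True)

    X, names = build_design(df, include_group=True)
    beta = np.zeros(len(names))
    centers_shift = 0.0
    for j, name in enumerate(names):
        if name == "intercept":
            beta[j] = model.intercept
        elif name == "group_nics":
            beta[j] = model.log_or_group
        else:
            beta[j] = model.betas.get(name, 0.0)
            center = model.centers.get(name, 0.0)
            centers_shift += beta[j] * center
    lp = X @ beta - centers_shift
    y = rng.random(len(df)) < expit(lp)

    ongoing = y | (rng.random(len(df)) < model.p_ongoing_extra)
    clinical = ongoing | (rng.random(len(df)) < model.p_clinical_extra)
    biochemical = clinical | (rng.random(len(df)) < model.p_biochemical_extra)
    df["biochemical"] = biochemical.astype(int)
    df["clinical"] = clinical.astype(int)
    df["ongoing"] = ongoing.astype(int)
    df["live_birth"] = y.astype(int)
    return df


def default_cohort_model(true_or: float = 1.0, **overrides) -> CohortModel:
    """Baseline-table-like cohort model with a chosen true group odds ratio."""
    return CohortModel(log_or_group=float(np.log(true_or)), **overrides)
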