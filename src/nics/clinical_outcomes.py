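"""Cohort outcome statistics: rates, 2x2 chi-square tests, and
covariate-adjusted logistic regression on patient-level tables.

Patient tables are pandas DataFrames with one row per patient and binary
outcome columns obeying the monotone nesting
``live_birth <= ongoing <= clinical <= biochemical``.

The logistic fit is a hand-rolled Newton/IRLS maximum-likelihood solver
with Wald confidence intervals; :mod:`statsmodels` is used only as an
independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from nics._util import pct

GROUP_NICS = "NICS"
GROUP_CONTROL = "control"

OUTCOME_COLUMNS = ["biochemical", "clinical", "ongoing", "live_birth"]

COVARIATE_COLUMNS = [
    "female_age",
    "male_age",
    "n_prior_miscarriages",
    "indication",
    "infertility_type",
    "gn_dosage",
    "gn_days",
]

PATIENT_COLUMNS = ["group", *COVARIATE_COLUMNS, *OUTCOME_COLUMNS]

INDICATIONS = ("male", "female", "both")
INFERTILITY_TYPES = ("primary", "secondary")


@dataclass(frozen=True)
class PatientRecord:
    group: str
    female_age: float
    male_age: float
    n_prior_miscarriages: int
    indication: str
    infertility_type: str
    gn_dosage: float
    gn_days: float
    biochemical: bool
    clinical: bool
    ongoing: bool
    live_birth: bool

    def __post_init__(self) -> None:
        if self.group not in (GROUP_NICS, GROUP_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")
        if not (self.biochemical >= self.clinical >= self.ongoing >= self.live_birth):
            raise ValueError("outcomes must nest: live <= ongoing <= clinical <= biochemical")


@dataclass(frozen=True)
class ContingencyResult:
    """One outcome's group comparison."""

    outcome: str
    nics_numerator: int
    nics_denominator: int
    control_numerator: int
    control_denominator: int
    nics_rate_pct: float | None
    control_rate_pct: float | None
    chi_square: float | None = None
    p_value: float | None = None
    fisher_p: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    flags: tuple[str, ...] = ()


def validate_patients(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    for col in OUTCOME_COLUMNS:
        vals = df[col]
        if not vals.isin([0, 1]).all():
            raise ValueError(f"outcome column {col!r} must be binary 0/1")
    b, c, o, l = (df[col].astype(int) for col in OUTCOME_COLUMNS)
    bad = ~((b >= c) & (c >= o) & (o >= l))
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ValueError(
            f"outcome nesting violated (live <= ongoing <= clinical <= biochemical) "
            f"at rows {rows}"
        )
    bad_groups = set(df["group"].unique()) - {GROUP_NICS, GROUP_CONTROL}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    return df


def load_patients(path: str | Path) -> pd.DataFrame:
    return validate_patients(pd.read_csv(path))


def write_patients(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c in PATIENT_COLUMNS or c == "stratum"]
    df[cols].to_csv(path, index=False)


def rate(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (100 * num / den)."""
    return pct(numerator, denominator, ndigits=1)


def chisq_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (rows: groups, cols: yes/no).

    Returns (statistic, p).  ``correction=True`` applies the Yates
    continuity correction.  Zero margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    _, p = stats.fisher_exact(np.asarray(table))
    return float(p)


# ---------------------------------------------------------------------------
# logistic regression (Newton / IRLS)
# ---------------------------------------------------------------------------


def build_design(
    df: pd.DataFrame,
    covariates: list[str] | None = None,
    include_group: bool = True,
    drop_constant: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with declared reference levels.

    Reference levels: control group, male-factor indication, primary
    infertility, zero prior miscarriages (miscarriage count is encoded as
    the categories 0 / 1 / >= 2).
    """
    if covariates is None:
        covariates = list(COVARIATE_COLUMNS)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]

    def add(name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if drop_constant and len(df) and np.ptp(values) == 0:
            return
        cols.append(values)
        names.append(name)

    if include_group:
        add("group_nics", (df["group"] == GROUP_NICS).to_numpy())
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        if df[cov].isna().any():
            rows = df.index[df[cov].isna()].tolist()[:10]
            raise ValueError(f"missing values in covariate {cov!r} at rows {rows}")
        if cov == "n_prior_miscarriages":
            m = df[cov].to_numpy()
            add("n_miscarriages_1", m == 1)
            add("n_miscarriages_2plus", m >= 2)
        elif cov == "indication":
            ind = df[cov].to_numpy()
            add("indication_female", ind == "female")
            add("indication_both", ind == "both")
        elif cov == "infertility_type":
            add("infertility_secondary", (df[cov] == "secondary").to_numpy())
        else:
            add(cov, df[cov].to_numpy())
    return np.column_stack(cols), names


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class LogisticFit:
    terms: dict = field(default_factory=dict)
    converged: bool = True
    separation: bool = False
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def __getitem__(self, name: str) -> LogisticTerm:
        return self.terms[name]


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    converged = False
    it = 0
    xtwx = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        xtwx = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ValueError("singular information matrix") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    return beta, xtwx, converged, it


def fit_logistic(
    df: pd.DataFrame,
    outcome: str = "live_birth",
    covariates: list[str] | None = None,
    include_group: bool = True,
    drop_constant: bool = False,
) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    Diverging coefficients (separation) are flagged, not silently returned
    as valid estimates.
    """
    if outcome not in df.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = df[outcome].to_numpy(dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary")
    X, names = build_design(
        df, covariates=covariates, include_group=include_group, drop_constant=drop_constant
    )
    beta, xtwx, converged, it = _irls(X, y)
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    separation = (not converged) or bool(np.max(np.abs(beta)) > 15)
    z = 1.959963984540054  # Phi^{-1}(0.975)
    terms = {}
    with np.errstate(over="ignore"):  # separation can push CIs to inf
        for j, name in enumerate(names):
            wald = beta[j] / se[j] if se[j] > 0 else np.inf
            terms[name] = LogisticTerm(
                name=name,
                coef=float(beta[j]),
                se=float(se[j]),
                odds_ratio=float(np.exp(beta[j])),
                ci_low=float(np.exp(beta[j] - z * se[j])),
                ci_high=float(np.exp(beta[j] + z * se[j])),
                p_value=float(2 * stats.norm.sf(abs(wald))),
            )
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return LogisticFit(
        terms=terms, converged=converged, separation=separation, n_iter=it, log_likelihood=ll
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def _outcome_result(
    df: pd.DataFrame, outcome: str, correction: bool = False
) -> ContingencyResult:
    nics = df[df["group"] == GROUP_NICS]
    ctrl = df[df["group"] == GROUP_CONTROL]
    nn, nd = int(nics[outcome].sum()), len(nics)
    cn, cd = int(ctrl[outcome].sum()), len(ctrl)
    flags: list[str] = []
    chi = p = fisher_p = None
    if nd and cd:
        table = [[nn, nd - nn], [cn, cd - cn]]
        fisher_p = fisher_2x2(table)
        try:
            chi, p = chisq_2x2(table, correction=correction)
        except ValueError:
            flags.append("zero_margin")
        expected = np.outer([nd, cd], [nn + cn, nd - nn + cd - cn]) / (nd + cd)
        if (expected < 5).any():
            flags.append("small_expected_cell")
    else:
        flags.append("empty_stratum")
    return ContingencyResult(
        outcome=outcome,
        nics_numerator=nn,
        nics_denominator=nd,
        control_numerator=cn,
        control_denominator=cd,
        nics_rate_pct=rate(nn, nd) if nd else None,
        control_rate_pct=rate(cn, cd) if cd else None,
        chi_square=chi,
        p_value=p,
        fisher_p=fisher_p,
        flags=tuple(flags),
    )


def compare_groups(
    df: pd.DataFrame, adjusted: bool = True, correction: bool = False
) -> dict[str, ContingencyResult]:
    """Per-outcome rates, chi-square tests, and adjusted group odds ratios.

    Adjusted ORs come from a logistic model with the seven declared
    covariates; when the reconstructed table's covariates are degenerate
    (aggregate-only source data) the adjusted fit is flagged and omitted
    rather than reported.
    """
    validate_patients(df)
    if not (df["group"] == GROUP_NICS).any() or not (df["group"] == GROUP_CONTROL).any():
        raise ValueError("both groups must be non-empty")
    report: dict[str, ContingencyResult] = {}
    for outcome in OUTCOME_COLUMNS:
        res = _outcome_result(df, outcome, correction=correction)
        if adjusted:
            try:
                fit = fit_logistic(df, outcome=outcome, drop_constant=True)
                term = fit["group_nics"]
                if fit.separation:
                    res = _replace(res, flags=res.flags + ("separation",))
                else:
                    res = _replace(
                        res,
                        odds_ratio=term.odds_ratio,
                        ci_low=term.ci_low,
                        ci_high=term.ci_high,
                    )
            except ValueError:
                res = _replace(res, flags=res.flags + ("adjusted_fit_unavailable",))
        report[outcome] = res
    return report


def _replace(res: ContingencyResult, **kw) -> ContingencyResult:
    from dataclasses import replace

    return replace(res, **kw)


def _stratum_labels(df: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "age":
        return pd.Series(
            np.where(df["female_age"] >= 35, ">=35", "<35"), index=df.index
        )
    if stratifier == "miscarriages":
        m = df["n_prior_miscarriages"]
        return pd.Series(
            np.where(m >= 2, ">=2", m.astype(int).astype(str)), index=df.index
        )
    raise ValueError(f"unknown stratifier {stratifier!r} (use 'age' or 'miscarriages')")


def stratified_outcomes(
    df: pd.DataFrame, stratifier: str, correction: bool = False
) -> dict[str, dict[str, ContingencyResult]]:
    """Per-stratum, per-outcome group comparisons.

    ``stratifier`` is ``"age"`` (< 35 vs >= 35 years) or ``"miscarriages"``
    (0 / 1 / >= 2 prior early spontaneous miscarriages).
    """
    validate_patients(df)
    labels = _stratum_labels(df, stratifier)
    order = ["<35", ">=35"] if stratifier == "age" else ["0", "1", ">=2"]
    out: dict[str, dict[str, ContingencyResult]] = {}
    for label in order:
        sub = df[labels == label]
        out[label] = {
            outcome: _outcome_result(sub, outcome, correction=correction)
            for outcome in OUTCOME_COLUMNS
        }
    return out


def report_to_frame(report: dict[str, ContingencyResult]) -> pd.DataFrame:
    rows = []
    for outcome, r in report.items():
        rows.append(
            {
                "outcome": outcome,
                "nics": f"{r.nics_numerator}/{r.nics_denominator}",
                "nics_rate_pct": r.nics_rate_pct,
                "control": f"{r.control_numerator}/{r.control_denominator}",
                "control_rate_pct": r.control_rate_pct,
                "chi_square": r.chi_square,
                "p_value": r.p_value,
                "fisher_p": r.fisher_p,
                "adjusted_or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
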