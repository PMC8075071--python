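"""Pre-post incidence-rate-ratio analysis with Poisson GEE.

Each patient contributes two rows — a fixed 365-day pre-intervention
period and a death-truncated post-intervention follow-up — with event
counts (total exacerbations, hospital days) and exposure time.  A
log-linear count model with a log-exposure offset, fitted by generalized
estimating equations with patient clusters and robust (sandwich)
standard errors, estimates the post/pre incidence rate ratio (IRR):

    log E[count] = log(exposure) + b0 + b1 * intervention + covariates

so exp(b1) is the IRR.  Four nested covariate sets mirror a standard
confounder-adjustment ladder: (1) intervention only, (2) + sex and age,
(3) + GOLD category, (4) + inhaled-corticosteroid use; models 3-4 drop
patients whose GOLD category is missing.

A dispersion check on a Poisson fit decides between the Poisson and
negative-binomial families, and a companion linear GEE estimates the
trend of repeated health-status (CCQ) scores over time.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.generalized_estimating_equations import GEE

from .cohort import ExacerbationEvent, PatientProfile

__all__ = [
    "PeriodRow",
    "GEEFit",
    "FitError",
    "OUTCOMES",
    "build_period_table",
    "period_table_frame",
    "select_family",
    "fit_irr",
    "ccq_trend",
]

#: analysis outcomes -> PeriodRow count column
OUTCOMES = {"exacerbations": "n_exacerbations", "hosp_days": "n_hosp_days"}

PRE_EXPOSURE_DAYS = 365

#: Pearson chi^2 / df above which the Poisson family is abandoned
OVERDISPERSION_THRESHOLD = 1.5

_Z975 = 1.959963984540054


class FitError(RuntimeError):
    """Model fitting failed; carries convergence diagnostics."""


class _BoundedExchangeable(Exchangeable):
    """Exchangeable working correlation clamped to the admissible range.

    With two observations per cluster the moment estimator can exceed 1
    in small samples, which makes the working covariance non-positive-
    definite and the fit diverge; clamping keeps it admissible while
    robust SEs stay valid under any working structure.
    """

    def update(self, params) -> None:
        super().update(params)
        self.dep_params = float(np.clip(self.dep_params, -0.95, 0.95))


@dataclass(frozen=True)
class PeriodRow:
    """One patient-period: the GEE analysis unit (two rows per patient)."""

    patient_id: int
    intervention: int  # 0 = pre, 1 = post
    exposure_days: float
    n_exacerbations: int
    n_hosp_days: int
    age: float
    sex: str
    gold: str | None
    ics_use: bool


@dataclass(frozen=True)
class GEEFit:
    """Intervention-effect estimate from one fitted count model."""

    outcome_name: str
    model_id: int
    coef: float  # log rate ratio for the intervention indicator
    robust_se: float
    irr: float
    ci_low: float
    ci_high: float
    n_patients: int
    family: str
    working_correlation: str

    def to_dict(self) -> dict:
        return asdict(self)


def build_period_table(
    profiles: Sequence[PatientProfile],
    pre_events: Mapping[int, Sequence[ExacerbationEvent]],
    post_events: Mapping[int, Sequence[ExacerbationEvent]],
) -> list[PeriodRow]:
    """Aggregate per-patient event lists into two analysis rows per patient.

    The pre period always spans 365 days; the post period spans the
    patient's (death-truncated) follow-up.
    """
    rows: list[PeriodRow] = []
    for p in profiles:
        for period, events_map in (("pre", pre_events), ("post", post_events)):
            if p.patient_id not in events_map:
                raise KeyError(
                    f"patient {p.patient_id} missing {period}-period events"
                )
            events = events_map[p.patient_id]
            rows.append(
                PeriodRow(
                    patient_id=p.patient_id,
                    intervention=0 if period == "pre" else 1,
                    exposure_days=float(
                        PRE_EXPOSURE_DAYS if period == "pre" else p.followup_post
                    ),
                    n_exacerbations=len(events),
                    n_hosp_days=int(sum(e.hosp_days for e in events)),
                    age=p.age,
                    sex=p.sex,
                    gold=None if p.gold == "missing" else p.gold,
                    ics_use=p.ics_use,
                )
            )
    return rows


def period_table_frame(table: Sequence[PeriodRow] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a period table to a DataFrame with normalized dtypes."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame([asdict(r) for r in table])
    if df.empty:
        raise ValueError("period table is empty")
    df["gold"] = df["gold"].replace({"missing": None, "": None})
    df["ics_use"] = df["ics_use"].astype(int)
    if (df["exposure_days"] <= 0).any():
        raise ValueError("exposure_days must be positive")
    counts = df.groupby("patient_id")["intervention"].agg(["count", "sum"])
    if not ((counts["count"] == 2) & (counts["sum"] == 1)).all():
        raise ValueError("each patient needs exactly one pre and one post row")
    return df


def select_family(
    table: Sequence[PeriodRow] | pd.DataFrame, outcome: str
) -> Literal["poisson", "negative_binomial"]:
    """Choose the count-model family by a Poisson overdispersion check.

    Fits the intervention-only Poisson model with log-exposure offset and
    computes the Pearson chi-square per residual degree of freedom; a
    value above 1.5 selects the negative-binomial family.
    """
    df = period_table_frame(table)
    col = OUTCOMES[outcome]
    y = df[col].to_numpy(dtype=float)
    if (y == 0).all():
        raise ValueError(
            f"outcome {outcome!r} is all zero; report descriptives only"
        )
    if df["patient_id"].nunique() < 2:
        raise ValueError("family selection needs at least 2 patients")
    X = sm.add_constant(df["intervention"].to_numpy(dtype=float))
    glm = sm.GLM(
        y, X, family=sm.families.Poisson(), offset=np.log(df["exposure_days"])
    ).fit()
    dispersion = glm.pearson_chi2 / glm.df_resid
    return "poisson" if dispersion <= OVERDISPERSION_THRESHOLD else "negative_binomial"


_MODEL_TERMS = {
    1: "intervention",
    2: "intervention + C(sex, Treatment('male')) + age",
    3: "intervention + C(sex, Treatment('male')) + age + C(gold)",
    4: "intervention + C(sex, Treatment('male')) + age + C(gold) + ics_use",
}


def fit_irr(
    table: Sequence[PeriodRow] | pd.DataFrame,
    outcome: str,
    model_id: int = 1,
    family: str = "poisson",
    working_correlation: str = "exchangeable",
) -> GEEFit:
    """Estimate the post/pre IRR for one outcome with a count GEE.

    Parameters
    ----------
    table
        Period rows (two per patient).
    outcome
        ``"exacerbations"`` or ``"hosp_days"``.
    model_id
        Covariate ladder step 1-4 (see module docstring).
    family
        ``"poisson"`` (default) or ``"negative_binomial"``; use
        :func:`select_family` to choose data-driven.
    working_correlation
        ``"exchangeable"`` (default, two repeated measures per patient)
        or ``"independence"`` (GEE point estimates then coincide with an
        ordinary Poisson GLM).

    Returns the intervention coefficient with robust (sandwich) SE and
    the Wald 95% CI on the IRR scale.
    """
    if model_id not in _MODEL_TERMS:
        raise ValueError(f"model_id must be 1-4, got {model_id}")
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {sorted(OUTCOMES)}")
    df = period_table_frame(table)
    if model_id >= 3:
        df = df[df["gold"].notna()].copy()
    n_clusters = df["patient_id"].nunique()
    if n_clusters < 2:
        raise FitError("need at least 2 patient clusters after exclusions")

    fam = {
        "poisson": sm.families.Poisson(),
        "negative_binomial": sm.families.NegativeBinomial(alpha=1.0),
    }[family]
    cov = {"exchangeable": _BoundedExchangeable(), "independence": Independence()}[
        working_correlation
    ]
    formula = f"{OUTCOMES[outcome]} ~ {_MODEL_TERMS[model_id]}"
    model = GEE.from_formula(
        formula,
        groups="patient_id",
        data=df,
        family=fam,
        cov_struct=cov,
        offset=np.log(df["exposure_days"]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=200)
    if not np.all(np.isfinite(result.params)):
        raise FitError(f"GEE did not converge: params={result.params}")

    coef = float(result.params["intervention"])
    if not np.isfinite(coef):
        raise FitError(f"non-finite intervention estimate (coef={coef})")
    se = float(result.bse["intervention"])
    if not np.isfinite(se):
        # a numerically zero sandwich variance (e.g. perfectly symmetric
        # pre/post data) shows up as sqrt of a tiny negative number
        idx = list(result.params.index).index("intervention")
        var = float(np.asarray(result.cov_robust)[idx, idx])
        if np.isfinite(var) and -1e-8 < var < 1e-12:
            warnings.warn(
                "robust variance numerically zero; CI degenerates to the point",
                RuntimeWarning,
                stacklevel=2,
            )
            se = 0.0
        else:
            raise FitError(
                f"non-finite robust SE (variance={var}); model may not have converged"
            )
    return GEEFit(
        outcome_name=outcome,
        model_id=model_id,
        coef=coef,
        robust_se=se,
        irr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z975 * se)),
        ci_high=float(np.exp(coef + _Z975 * se)),
        n_patients=int(n_clusters),
        family=family,
        working_correlation=working_correlation,
    )


def ccq_trend(ccq_long: pd.DataFrame) -> tuple[float, float]:
    """Linear time trend of repeated CCQ scores, clustered by patient.

    ``ccq_long`` needs columns ``patient_id``, ``day``, ``ccq``.  Fits a
    Gaussian GEE of CCQ on time with exchangeable working correlation and
    robust SEs; returns ``(slope_per_30_days, two_sided_p)``.
    """
    df = ccq_long.dropna(subset=["ccq"]).copy()
    if df["patient_id"].nunique() < 2 or len(df) < 4:
        raise ValueError("CCQ trend needs >=2 observations for >=2 patients")
    if np.ptp(df["ccq"].to_numpy(dtype=float)) == 0.0:
        warnings.warn(
            "all CCQ scores identical; slope is 0 with degenerate variance",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, float("nan")
    model = GEE.from_formula(
        "ccq ~ day",
        groups="patient_id",
        data=df,
        family=sm.families.Gaussian(),
        cov_struct=Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit()
    slope_30 = float(result.params["day"]) * 30.0
    p = float(result.pvalues["day"])
    return slope_30, p
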