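"""Random-intercept regression linking predictors to ocular shape outcomes.

Continuous predictors are standardized on the analysis sample; models are
linear mixed-effects regressions with a per-participant random intercept to
absorb inter-eye correlation. Estimation is REML by default (maximum
likelihood behind a flag) with Wald 95% confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TermResult",
    "ModelResult",
    "standardize",
    "fit_random_intercept",
    "run_shape_models",
    "run_feature_models",
]

logger = logging.getLogger(__name__)

SHAPE_OUTCOMES = ("Q_h", "Q_v")
FEATURE_COLUMNS = (
    "od_fovea_distance",
    "od_fovea_angle",
    "od_area",
    "od_orientation",
    "od_ovality",
    "crae",
    "crve",
    "tortuosity",
    "fd",
    "arterial_concavity",
    "venous_concavity",
    "fpi",
)


@dataclass
class TermResult:
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelResult:
    outcome: str
    terms: list[TermResult]
    n_eyes: int
    n_participants: int
    intercept_variance: float
    residual_variance: float
    singular: bool = False
    converged: bool = True
    label: str = ""

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_rows(self) -> list[dict]:
        return [
            {
                "model": self.label,
                "outcome": self.outcome,
                "term": t.term,
                "beta": t.beta,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p": t.p_value,
                "n_eyes": self.n_eyes,
                "n_participants": self.n_participants,
                "intercept_variance": self.intercept_variance,
                "residual_variance": self.residual_variance,
                "singular": self.singular,
            }
            for t in self.terms
        ]


def standardize(
    table: pd.DataFrame, columns: list[str], ddof: int = 1
) -> pd.DataFrame:
    """Return a copy with the named columns replaced by z-scores.

    Means and SDs are computed over the rows of ``table`` (the analysis
    sample). Binary indicators such as sex must not be passed here.
    """
    out = table.copy()
    for col in columns:
        x = pd.to_numeric(out[col], errors="raise")
        sd = x.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize column {col!r}: zero or undefined SD")
        out[col] = (x - x.mean()) / sd
    return out


def fit_random_intercept(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    group: str = "participant_id",
    reml: bool = True,
    label: str = "",
) -> ModelResult:
    """Fit outcome ~ fixed_terms + (1 | group) and return Wald summaries.

    A singular fit (random-intercept variance at the zero boundary) is
    flagged in the result, not raised. A rank-deficient fixed design is an
    error listing the aliased terms.
    """
    missing = [c for c in [outcome, group, *fixed_terms] if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = table[[outcome, group, *fixed_terms]].dropna()
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 participants")

    exog = sm.add_constant(data[list(fixed_terms)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        # identify aliased columns by checking rank with each column removed
        aliased = []
        mat = exog.to_numpy()
        for j, name in enumerate(exog.columns):
            if np.linalg.matrix_rank(np.delete(mat, j, axis=1)) == rank:
                aliased.append(name)
        raise ValueError(f"rank-deficient fixed design; aliased terms: {aliased}")

    endog = data[outcome].astype(float)
    model = sm.MixedLM(endog, exog, groups=data[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=reml, method="lbfgs")
            if not fit.converged:
                raise np.linalg.LinAlgError("lbfgs did not converge")
        except (np.linalg.LinAlgError, ValueError):
            # boundary (zero-variance) fits can break gradient methods
            fit = model.fit(reml=reml, method="powell")

        var_u = float(np.squeeze(fit.cov_re.to_numpy()))
        var_e = float(fit.scale)
        if 0 < var_u < 1e-3 * var_e:
            # gradient methods stall just off the zero-variance boundary;
            # a Powell polish reaches it, restoring exact OLS equivalence
            try:
                polished = model.fit(reml=reml, method="powell")
                if polished.llf >= fit.llf - 1e-10:
                    fit = polished
            except (np.linalg.LinAlgError, ValueError):
                pass

    var_u = float(np.squeeze(fit.cov_re.to_numpy()))
    var_e = float(fit.scale)
    singular = var_u <= 1e-8 * max(var_e, 1e-12)
    if singular:
        logger.info("singular fit for %s ~ %s: intercept variance ~ 0", outcome, fixed_terms)

    conf = fit.conf_int(alpha=0.05)
    terms = []
    for name in exog.columns:
        terms.append(
            TermResult(
                term=name,
                beta=float(fit.params[name]),
                ci_low=float(conf.loc[name, 0]),
                ci_high=float(conf.loc[name, 1]),
                p_value=float(fit.pvalues[name]),
            )
        )
    return ModelResult(
        outcome=outcome,
        terms=terms,
        n_eyes=len(data),
        n_participants=int(data[group].nunique()),
        intercept_variance=var_u,
        residual_variance=var_e,
        singular=singular,
        converged=bool(fit.converged),
        label=label,
    )


def run_shape_models(
    table: pd.DataFrame, group: str = "participant_id", reml: bool = True
) -> pd.DataFrame:
    """SER models for Q_h, Q_v and volume (age- and sex-adjusted).

    Fits Q_h|Q_v|volume ~ ser + age + sex, plus the height-adjusted volume
    variant. Continuous predictors are standardized on the analysis rows;
    sex stays a 0/1 indicator. Returns one tidy row per term per model.
    """
    required = ["ser", "age", "sex", "volume_mm3", *SHAPE_OUTCOMES]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    continuous = ["ser", "age"] + (["height"] if "height" in table.columns else [])
    ztab = standardize(table, continuous)

    rows: list[dict] = []
    for outcome in SHAPE_OUTCOMES:
        res = fit_random_intercept(
            ztab, outcome, ["ser", "age", "sex"], group=group, reml=reml,
            label=f"{outcome} ~ ser + age + sex",
        )
        rows.extend(res.to_rows())
    res = fit_random_intercept(
        ztab, "volume_mm3", ["ser", "age", "sex"], group=group, reml=reml,
        label="volume ~ ser + age + sex",
    )
    rows.extend(res.to_rows())
    if "height" in table.columns:
        res = fit_random_intercept(
            ztab, "volume_mm3", ["ser", "age", "sex", "height"], group=group, reml=reml,
            label="volume ~ ser + age + sex + height",
        )
        rows.extend(res.to_rows())
    return pd.DataFrame(rows)


def run_feature_models(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    group: str = "participant_id",
    reml: bool = True,
) -> pd.DataFrame:
    """Feature-asphericity models, unadjusted and SER/age/sex-adjusted.

    For each available feature and each of Q_h, Q_v, fits the feature-only
    model and the covariate-adjusted model. All-missing feature columns are
    skipped with a logged reason. Returns tidy rows with an ``adjusted``
    flag; no multiple-testing correction is applied.
    """
    rows: list[dict] = []
    for feature in features:
        if feature not in table.columns:
            logger.warning("feature %s absent from table; skipped", feature)
            continue
        sub = table.dropna(subset=[feature])
        if len(sub) == 0:
            logger.warning("feature %s is all-missing; skipped", feature)
            continue
        ztab = standardize(sub, [feature, "ser", "age"])
        for outcome in SHAPE_OUTCOMES:
            for adjusted, terms in ((False, [feature]), (True, [feature, "ser", "age", "sex"])):
                res = fit_random_intercept(
                    ztab, outcome, terms, group=group, reml=reml,
                    label=f"{outcome} ~ {feature}" + (" + ser + age + sex" if adjusted else ""),
                )
                for row in res.to_rows():
                    row["feature"] = feature
                    row["adjusted"] = adjusted
                    rows.append(row)
    return pd.DataFrame(rows)
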