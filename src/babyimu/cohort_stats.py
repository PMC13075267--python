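"""Longitudinal cohort analysis of orientation-variability metrics.

One row per child-visit: variability metrics at ages 3/6/9/12 months for two
cohorts (ILA: increased likelihood of autism — older sibling with ASD; LLA:
low likelihood), plus the Mullen Scales of Early Learning gross-motor (MSEL
GM) raw score and a walking flag.

Three analyses mirror the study design:

* per-metric linear mixed-effects model (REML, random intercept per child):
  fixed effects for cohort, linear age (months) and their interaction; the
  age main effect is the developmental slope.
* angle-contrast mixed model on the stacked pitch/roll/yaw circular SDs:
  angle level contrasts (roll-pitch, yaw-pitch), age, and angle-by-age slope
  contrasts.
* Spearman (or Pearson) correlations between generalized variance at one
  age and MSEL GM at the same or a later age, restricted to non-walking
  children.

p-values are Wald tests on the fixed effects; alpha = 0.05 with no
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "METRIC_COLUMNS",
    "AGES_MONTHS",
    "LmmResult",
    "validate_cohort_table",
    "fit_age_lmm",
    "fit_angle_contrast_lmm",
    "correlate_msel",
]

METRIC_COLUMNS = ("pitch_csd", "roll_csd", "yaw_csd", "gen_var")
AGES_MONTHS = (3, 6, 9, 12)
REQUIRED_COLUMNS = ("child_id", "cohort", "age_months", *METRIC_COLUMNS,
                    "msel_gm", "walking")


@dataclass
class LmmResult:
    """Fitted linear mixed-effects model summary.

    ``fixed_effects`` maps term name -> {estimate, se, p}; ``method``
    records the inference route (Wald z on REML estimates).
    """

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, p
    random_effect_var: float
    residual_var: float
    n_obs: int
    n_children: int
    converged: bool
    method: str = "REML + Wald"
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.fixed_effects.iterrows()},
            "random_effect_var": self.random_effect_var,
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "n_children": self.n_children,
            "converged": self.converged,
            "method": self.method,
            "notes": self.notes,
        }


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, study ages and one-row-per-child-visit."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad_ages = set(table["age_months"].unique()) - set(AGES_MONTHS)
    if bad_ages:
        raise ValueError(f"ages outside study visits {AGES_MONTHS}: {bad_ages}")
    if table.duplicated(subset=["child_id", "age_months"]).any():
        raise ValueError("duplicate child-visit rows")
    bad_cohort = set(table["cohort"].unique()) - {"ILA", "LLA"}
    if bad_cohort:
        raise ValueError(f"unknown cohort labels: {bad_cohort}")
    return table


def _fit_mixedlm(formula: str, data: pd.DataFrame) -> tuple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # boundary (zero) random-effect variance is legitimate under a null
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=data, groups=data["child_id"])
        fit = model.fit(reml=True)
        if not fit.converged:
            retry = model.fit(reml=True, method="powell", maxiter=500)
            if retry.converged:
                fit = retry
    return model, fit


def _usable(fit) -> bool:
    """A fit is usable when all fixed-effect SEs are finite and positive;
    a singular fit (degenerate covariance) is not."""
    bse = np.asarray(fit.bse_fe, dtype=float)
    return bool(np.all(np.isfinite(bse)) and np.all(bse > 0))


def _collect_result(fit, data: pd.DataFrame, notes: list[str]) -> LmmResult:
    fe_names = [n for n in fit.fe_params.index]
    rows = {}
    for name in fe_names:
        rows[name] = {
            "estimate": float(fit.fe_params[name]),
            "se": float(fit.bse_fe[name]),
            "p": float(fit.pvalues[name]),
        }
    fe = pd.DataFrame.from_dict(rows, orient="index")
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return LmmResult(
        fixed_effects=fe,
        random_effect_var=re_var,
        residual_var=float(fit.scale),
        n_obs=int(len(data)),
        n_children=int(data["child_id"].nunique()),
        converged=bool(fit.converged),
        notes=notes,
    )


def fit_age_lmm(table: pd.DataFrame, metric: str) -> LmmResult:
    """Age trend of one metric: ``metric ~ age * cohort`` with a random
    intercept per child.

    The ``age_months`` coefficient is the developmental slope (units of the
    metric per month, in the reference cohort under treatment coding; equal
    to the common slope when cohorts share one).  On a singular or
    non-converged fit the model is refit without the interaction and the
    fallback is noted.
    """
    validate_cohort_table(table)
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}; one of {METRIC_COLUMNS}")
    data = table.dropna(subset=[metric]).copy()
    children_with_repeats = (data.groupby("child_id").size() >= 2).sum()
    if data["child_id"].nunique() < 2 or children_with_repeats < 2:
        raise ValueError("need >= 2 children with >= 2 visits")
    notes: list[str] = []
    formula = f"{metric} ~ age_months * C(cohort, Treatment('ILA'))"
    _, fit = _fit_mixedlm(formula, data)
    if not _usable(fit):
        notes.append("interaction model singular; "
                     "refit without cohort-by-age interaction")
        formula = f"{metric} ~ age_months + C(cohort, Treatment('ILA'))"
        _, fit = _fit_mixedlm(formula, data)
    return _collect_result(fit, data, notes)


def fit_angle_contrast_lmm(table: pd.DataFrame) -> LmmResult:
    """Angle level and slope contrasts on stacked pitch/roll/yaw circular SDs.

    Long-format model ``csd ~ angle * age`` (treatment coding, pitch as
    reference) with a random intercept per child; reports roll-pitch and
    yaw-pitch level differences and the corresponding age-slope contrasts.
    """
    validate_cohort_table(table)
    long = table.melt(
        id_vars=["child_id", "age_months", "cohort"],
        value_vars=["pitch_csd", "roll_csd", "yaw_csd"],
        var_name="angle", value_name="csd").dropna(subset=["csd"])
    long["angle"] = long["angle"].str.replace("_csd", "", regex=False)
    notes: list[str] = []
    formula = "csd ~ C(angle, Treatment('pitch')) * age_months"
    _, fit = _fit_mixedlm(formula, long)
    if not _usable(fit):
        notes.append("interaction model singular; "
                     "refit without angle-by-age interaction")
        formula = "csd ~ C(angle, Treatment('pitch')) + age_months"
        _, fit = _fit_mixedlm(formula, long)
    return _collect_result(fit, long, notes)


def correlate_msel(table: pd.DataFrame, metric_age: int, msel_age: int,
                   method: str = "spearman",
                   metric: str = "gen_var") -> tuple[float, float, int]:
    """Correlation between a metric at ``metric_age`` and MSEL GM at
    ``msel_age`` (>= metric_age) across non-walking children.

    Returns ``(r, p, n)``.  Only concurrent-and-future pairings are allowed
    (the metric may predict later motor scores; the reverse pairing is not
    part of the design).  Ties receive average ranks.
    """
    validate_cohort_table(table)
    if msel_age < metric_age:
        raise ValueError("msel_age must be >= metric_age "
                         "(concurrent or future scores only)")
    nonwalk = table[~table["walking"].astype(bool)]
    m = nonwalk[nonwalk["age_months"] == metric_age][["child_id", metric]]
    s = nonwalk[nonwalk["age_months"] == msel_age][["child_id", "msel_gm"]]
    pairs = m.merge(s, on="child_id").dropna()
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 children with both measurements, got {n}")
    if method == "spearman":
        res = stats.spearmanr(pairs[metric], pairs["msel_gm"])
    elif method == "pearson":
        res = stats.pearsonr(pairs[metric], pairs["msel_gm"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), n
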