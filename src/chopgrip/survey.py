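"""Questionnaire analysis.

Covers the statistics reported alongside a grip-classification study:
DCDQ scoring (15 parent-rated items, three subscales), grip-class tallies
with the palm+others merge, Fleiss' kappa for inter-rater agreement,
normality screening (Lilliefors-corrected Kolmogorov-Smirnov with optional
log transform), multinomial logistic regression with four-finger prehension
as the reference category (odds ratios, Wald 95% CIs, optional sandwich
standard errors), Nagelkerke pseudo-R², and the cohort description table.

Missing data are handled by listwise deletion on the model variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DCDQ_N_ITEMS, DCDQ_SUBSCALES, GRIP_CLASSES, DcdqScore
from .errors import ChopgripError, FitError

ALPHA = 0.05

MERGED_CLASS = "palm_other"
#: outcome levels of the regression: reference first
OUTCOME_LEVELS = ("four_finger", "three_finger", MERGED_CLASS)
DEFAULT_PREDICTORS = ("age", "sex", "cohabitation", "training", "dcdq_total")


# ---------------------------------------------------------------------------
# DCDQ
# ---------------------------------------------------------------------------


def score_dcdq(items) -> DcdqScore:
    """Score the 15 DCDQ items into subscales and total.

    Items are rated 1-5; the standard split is items 1-6 control during
    movement, 7-10 fine motor/handwriting, 11-15 general coordination.  Any
    missing item makes its subscale — and the total — missing (NaN); no
    imputation is attempted.
    """
    items = list(items)
    if len(items) != DCDQ_N_ITEMS:
        raise ChopgripError(f"expected {DCDQ_N_ITEMS} DCDQ items, got {len(items)}")
    vals = np.array([np.nan if v is None else float(v) for v in items])
    ok = ~np.isnan(vals)
    if ((vals[ok] < 1) | (vals[ok] > 5) | (vals[ok] % 1 != 0)).any():
        raise ChopgripError("DCDQ items must be integers in 1..5")
    subs = {}
    for name, idx in DCDQ_SUBSCALES.items():
        sub = vals[[i - 1 for i in idx]]
        subs[name] = float(sub.sum()) if not np.isnan(sub).any() else np.nan
    total = sum(subs.values())  # NaN propagates
    return DcdqScore(**subs, total=float(total))


def dcdq_totals(df: pd.DataFrame) -> pd.Series:
    """Vectorized DCDQ totals for a survey table (NaN where any item missing)."""
    items = df[[f"dcdq_{i}" for i in range(1, 16)]]
    return items.sum(axis=1, min_count=15)


# ---------------------------------------------------------------------------
# Grip tallies
# ---------------------------------------------------------------------------


def tally_grip_classes(records: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Counts and percentages per grip class, plus the palm+others merge.

    Accepts a survey table (uses its ``grip_class`` column) or a Series of
    labels.  Always reports all four classes, zero-filled, and a
    ``palm_other`` row treating palm prehension and others as one group.
    """
    labels = records["grip_class"] if isinstance(records, pd.DataFrame) else records
    labels = pd.Series(labels).dropna()
    counts = labels.value_counts().reindex(GRIP_CLASSES, fill_value=0)
    counts[MERGED_CLASS] = counts["palm"] + counts["other"]
    n = len(labels)
    pct = 100 * counts / n if n else counts * 0.0
    return pd.DataFrame({"count": counts.astype(int), "percent": pct.round(1)})


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------


def fleiss_kappa(rating_matrix) -> float:
    """Fleiss' kappa for n subjects rated by r raters.

    ``rating_matrix`` is (n_subjects, n_raters) of categorical labels; every
    subject must be rated by every rater.  Delegates to the standard
    category-proportion formula (statsmodels) after aggregating ratings into
    subject x category counts.
    """
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _fk

    m = np.asarray(rating_matrix, dtype=object)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ChopgripError("rating matrix must be n_subjects x (>=2) raters")
    if pd.isna(m.astype(object)).any():
        raise ChopgripError("every subject needs a rating from every rater")
    table, _ = aggregate_raters(m)
    return float(_fk(table, method="fleiss"))


# ---------------------------------------------------------------------------
# Normality screening
# ---------------------------------------------------------------------------


def ks_normality(values, alpha: float = ALPHA, transform_if_rejected: bool = True) -> dict:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Uses the Lilliefors correction (mean and sd are estimated from the
    sample).  When normality is rejected at ``alpha`` and
    ``transform_if_rejected`` is set, log-transformed values are returned
    alongside; this requires strictly positive data.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ChopgripError("normality test needs at least 5 observations")
    stat, p = lilliefors(x, dist="norm")
    rejected = p < alpha
    out = {"statistic": float(stat), "p": float(p), "normal": not rejected}
    if rejected and transform_if_rejected:
        if (x <= 0).any():
            raise ChopgripError("log transform requires strictly positive values")
        out["log_values"] = np.log(x)
    return out


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------


def _merge_outcome(grip: pd.Series, include_others: bool = True) -> pd.Series:
    out = grip.copy()
    out[out == "palm"] = MERGED_CLASS
    if include_others:
        out[out == "other"] = MERGED_CLASS
    else:
        out[out == "other"] = np.nan
    return out


def _model_frame(
    records: pd.DataFrame, predictors=DEFAULT_PREDICTORS, include_others: bool = True
) -> pd.DataFrame:
    """Listwise-complete model frame with dummy coding.

    Coding: sex boy = 1, girl = 0; cohabitation yes = 1; training yes = 1;
    age in years; dcdq_total the raw 15-item sum.
    """
    cols = {}
    for p in predictors:
        if p == "age":
            cols[p] = records["age"].astype(float)
        elif p == "sex":
            s = records["sex"]
            cols[p] = (
                s.map({"boy": 1.0, "girl": 0.0}) if s.dtype == object else s.astype(float)
            )
        elif p in ("cohabitation", "training"):
            cols[p] = records[p].astype(float)
        elif p == "dcdq_total":
            cols[p] = (
                records["dcdq_total"].astype(float)
                if "dcdq_total" in records
                else dcdq_totals(records)
            )
        else:
            raise ChopgripError(f"unknown predictor {p!r}")
    frame = pd.DataFrame(cols)
    frame["_outcome"] = _merge_outcome(records["grip_class"], include_others)
    return frame.dropna()


def fit_multinomial_logit(
    records: pd.DataFrame,
    reference: str = "four_finger",
    predictors=DEFAULT_PREDICTORS,
    robust: bool = False,
    include_others: bool = True,
) -> "MultinomialFit":
    """Multinomial logit of grip class on child and household predictors.

    The outcome has three levels — the reference (four-finger prehension),
    three-finger prehension, and palm prehension merged with others.  Rows
    with any missing model variable are dropped (listwise deletion).
    ``robust=True`` reports sandwich (HC1) standard errors; the point
    estimates are the ordinary maximum-likelihood ones either way.

    Returns a :class:`MultinomialFit` whose ``table`` has one row per
    (contrast, predictor): log-odds, OR = exp(coef), Wald 95% CI and p.
    """
    import statsmodels.api as sm

    if reference != OUTCOME_LEVELS[0]:
        raise ChopgripError("four_finger is the only supported reference category")
    frame = _model_frame(records, predictors, include_others)
    levels = [lvl for lvl in OUTCOME_LEVELS if lvl in set(frame["_outcome"])]
    if len(levels) < 2 or levels[0] != reference:
        raise FitError("outcome needs the reference plus at least one contrast")
    endog = frame["_outcome"].map({lvl: i for i, lvl in enumerate(levels)}).to_numpy()
    exog = sm.add_constant(frame[list(predictors)], has_constant="add")

    model = sm.MNLogit(endog, exog)
    fit_kwargs = {"method": "newton", "maxiter": 200, "tol": 1e-8, "disp": False}
    if robust:
        fit_kwargs["cov_type"] = "HC1"
    try:
        res = model.fit(**fit_kwargs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - separation guard
        raise FitError(f"multinomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or not np.isfinite(
        np.asarray(res.params)
    ).all():
        raise FitError(_diagnose_separation(frame, predictors))

    z = 1.959963984540054
    rows = []
    names = list(exog.columns)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvalues = np.asarray(res.pvalues)
    for j, contrast in enumerate(levels[1:]):
        coefs, ses, pvals = params[:, j], bse[:, j], pvalues[:, j]
        for i, name in enumerate(names):
            b, se, p = float(coefs[i]), float(ses[i]), float(pvals[i])
            rows.append(
                {
                    "contrast": contrast,
                    "predictor": name,
                    "coef": b,
                    "se": se,
                    "or": np.exp(b),
                    "ci_low": np.exp(b - z * se),
                    "ci_high": np.exp(b + z * se),
                    "p": p,
                }
            )
    return MultinomialFit(
        table=pd.DataFrame(rows),
        llf=float(res.llf),
        n=len(frame),
        result=res,
        levels=tuple(levels),
        predictors=tuple(predictors),
        frame=frame,
    )


def _diagnose_separation(frame: pd.DataFrame, predictors) -> str:
    """Name predictors that perfectly separate an outcome level."""
    culprits = []
    for p in predictors:
        for lvl, grp in frame.groupby("_outcome"):
            if grp[p].nunique() == 1 and frame[p].nunique() > 1:
                culprits.append(p)
                break
    hint = f" (suspect predictors: {sorted(set(culprits))})" if culprits else ""
    return f"multinomial fit did not converge; possible perfect separation{hint}"


class MultinomialFit:
    """Fitted multinomial logit with its tidy coefficient table."""

    def __init__(self, table, llf, n, result, levels, predictors, frame):
        self.table = table
        self.llf = llf
        self.n = n
        self.result = result
        self.levels = levels
        self.predictors = predictors
        self.frame = frame

    def odds_ratio(self, predictor: str, contrast: str) -> float:
        row = self.table[
            (self.table.predictor == predictor) & (self.table.contrast == contrast)
        ]
        if row.empty:
            raise KeyError((predictor, contrast))
        return float(row["or"].iloc[0])

    def null_llf(self) -> float:
        """Log-likelihood of the intercept-only model on the same rows."""
        import statsmodels.api as sm

        endog = (
            self.frame["_outcome"]
            .map({lvl: i for i, lvl in enumerate(self.levels)})
            .to_numpy()
        )
        exog0 = np.ones((self.n, 1))
        res0 = sm.MNLogit(endog, exog0).fit(method="newton", disp=False, tol=1e-10)
        return float(res0.llf)


def nagelkerke_r2(llf: float, null_llf: float, n: int) -> float:
    """Nagelkerke pseudo-R² from model and null log-likelihoods.

    Cox-Snell R² = 1 - exp(2 (ll0 - ll1) / n), rescaled by its maximum
    1 - exp(2 ll0 / n) so a saturated fit approaches 1.
    """
    if llf < null_llf - 1e-8:
        raise FitError("fitted log-likelihood below the null; fits are swapped")
    cox_snell = 1.0 - np.exp(2.0 * (null_llf - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * null_llf / n)
    return float(cox_snell / max_cs)


def model_nagelkerke(fit: MultinomialFit) -> float:
    """Nagelkerke pseudo-R² of a fitted multinomial model."""
    return nagelkerke_r2(fit.llf, fit.null_llf(), fit.n)


# ---------------------------------------------------------------------------
# Cohort description
# ---------------------------------------------------------------------------


def _mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    if len(x) == 0:
        return "-"
    if len(x) == 1:
        return f"{x.iloc[0]:.2f} ± -"
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def describe_cohort(records: pd.DataFrame) -> dict:
    """Cohort summary: DCDQ means ± sd overall and by age/sex, maternal items.

    Returns a dict with a DCDQ table (subscales and total, columns for the
    whole sample and the age/sex strata), maternal age mean ± sd, and
    counts/percentages of the maternal teaching/knowledge/use flags.
    """
    if len(records) == 0:
        raise ChopgripError("describe_cohort needs at least one record")
    df = records.copy()
    df["dcdq_total"] = (
        df["dcdq_total"] if "dcdq_total" in df else dcdq_totals(df)
    )
    for name, idx in DCDQ_SUBSCALES.items():
        cols = [f"dcdq_{i}" for i in idx]
        if set(cols) <= set(df.columns):
            df[name] = df[cols].sum(axis=1, min_count=len(cols))

    strata = {
        f"total (n = {len(df)})": df,
        "age 6": df[df["age"] == 6],
        "age 7": df[df["age"] == 7],
        "boy": df[df["sex"] == "boy"],
        "girl": df[df["sex"] == "girl"],
    }
    rows = list(DCDQ_SUBSCALES) + ["dcdq_total"]
    dcdq_table = pd.DataFrame(
        {name: [_mean_sd(sub[r]) if r in sub else "-" for r in rows] for name, sub in strata.items()},
        index=rows,
    )

    out = {"n": len(df), "dcdq": dcdq_table}
    if "maternal_age" in df:
        ma = df["maternal_age"].dropna()
        out["maternal_age_mean"] = float(ma.mean()) if len(ma) else np.nan
        out["maternal_age_sd"] = float(ma.std(ddof=1)) if len(ma) > 1 else np.nan
    for col in ("maternal_taught", "maternal_knows", "maternal_can_use"):
        if col in df:
            v = df[col].dropna()
            out[f"{col}_count"] = int(v.sum())
            out[f"{col}_percent"] = round(100 * v.sum() / len(df), 1)
    out["dcdq_total_mean"] = float(df["dcdq_total"].mean())
    out["grip_tally"] = tally_grip_classes(df) if "grip_class" in df else None
    return out
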