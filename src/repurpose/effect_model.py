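"""Paired linear mixed-effects treatment-effect estimation and classification.

The model for each drug's cohort is

    biomarkerVal ~ b0 + b1*drugExposure + b2*Age + b3*Gender
                   + b4*Ethnicity + b5*Comorbidity + (1 | Individual)

fit by REML on the two-row-per-person table; the treatment effect is the
drugExposure coefficient b1 (mg/dL for LDL-C, mmHg for SBP) with a Wald
normal 95% CI and two-tailed p.  A paired t-test on within-person
differences serves as an independent oracle: without covariates the mixed
model's b1 equals the mean paired difference exactly on balanced tables.
Classification follows the screen convention: *therapeutic* means b1 < 0
with p < 0.05; Bonferroni significance uses 0.05 divided by the number of
drugs tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

logger = logging.getLogger(__name__)

#: reporting floor for extreme p-values
P_FLOOR = 2.2e-16

COVARIATES = ("Age", "Gender", "Ethnicity", "Comorbidity")


@dataclass
class TreatmentEffect:
    drug: str
    beta1: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_persons: int
    betas: dict = field(default_factory=dict)
    sigma_u: float = np.nan
    sigma_e: float = np.nan
    converged: bool = True


@dataclass
class ScreenSummary:
    disease: str
    biomarker: str
    effects: list[TreatmentEffect]
    n_tested: int
    bonferroni_threshold: float
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# disease={self.disease}\tbiomarker={self.biomarker}\n")
            fh.write(f"# n_tested={self.n_tested}\t"
                     f"bonferroni_threshold={self.bonferroni_threshold:.6g}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _check_table(table: pd.DataFrame) -> None:
    counts = table.groupby("person_id")["period"].count()
    if not (counts == 2).all():
        bad = counts[counts != 2].index.tolist()[:5]
        raise ValueError(f"model table must have two rows per person; bad: {bad}")
    required = {"person_id", "period", "biomarkerVal", "drugExposure", *COVARIATES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"model table missing columns {sorted(missing)}")


def _drop_collinear(exog: pd.DataFrame) -> pd.DataFrame:
    """Drop constant or linearly dependent covariate columns (keep the
    intercept and drugExposure)."""
    keep = ["const", "drugExposure"]
    for col in exog.columns:
        if col in keep:
            continue
        trial = exog[keep + [col]].to_numpy(float)
        if exog[col].nunique() <= 1 or np.linalg.matrix_rank(trial) < trial.shape[1]:
            logger.info("dropping collinear/constant covariate %r", col)
        else:
            keep.append(col)
    return exog[keep]


def fit_sccs_lmm(
    table: pd.DataFrame,
    drug: str = "drug",
    covariates: tuple[str, ...] = COVARIATES,
    reml: bool = True,
) -> TreatmentEffect:
    """REML fit of the paired random-intercept model; b1 inference is Wald-z.

    On non-convergence the paired-difference oracle supplies the estimate
    and the result is flagged ``converged=False``.
    """
    _check_table(table)
    n_persons = table["person_id"].nunique()
    endog = table["biomarkerVal"].to_numpy(float)
    exog = sm.add_constant(table[["drugExposure", *covariates]].astype(float),
                           has_constant="add")
    exog = _drop_collinear(exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog, exog, groups=table["person_id"])
            res = model.fit(reml=reml)
        if not getattr(res, "converged", True):
            raise RuntimeError("optimizer reported non-convergence")
        beta1 = float(res.params["drugExposure"])
        se = float(res.bse["drugExposure"])
        z975 = stats.norm.ppf(0.975)
        zstat = beta1 / se if se > 0 else np.inf * np.sign(beta1)
        p = max(float(2 * stats.norm.sf(abs(zstat))), P_FLOOR)
        return TreatmentEffect(
            drug=drug,
            beta1=beta1,
            se=se,
            ci_low=beta1 - z975 * se,
            ci_high=beta1 + z975 * se,
            p=p,
            n_persons=n_persons,
            betas={k: float(v) for k, v in res.params.items()},
            sigma_u=float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0))),
            sigma_e=float(np.sqrt(res.scale)),
            converged=True,
        )
    except Exception as exc:  # singular fits, boundary variance, etc.
        logger.warning("%s: mixed model did not converge cleanly (%s); "
                       "falling back to paired-difference estimate", drug, exc)
        est, (lo, hi), p = paired_difference_oracle(table)
        se = (hi - lo) / (2 * stats.t.ppf(0.975, df=max(n_persons - 1, 1)))
        return TreatmentEffect(drug, est, se, lo, hi, max(p, P_FLOOR),
                               n_persons, converged=False)


def paired_difference_oracle(
    table: pd.DataFrame,
) -> tuple[float, tuple[float, float], float]:
    """Mean within-person (treatment - baseline) difference with a paired
    t-test CI and p-value.  Independent of the mixed-model path."""
    wide = table.pivot(index="person_id", columns="period", values="biomarkerVal")
    diffs = (wide["treatment"] - wide["baseline"]).to_numpy(float)
    n = len(diffs)
    if n < 2:
        raise ValueError("paired oracle needs at least 2 persons")
    est = float(diffs.mean())
    sd = diffs.std(ddof=1)
    if sd == 0:
        p = 1.0 if est == 0 else P_FLOOR
        return est, (est, est), p
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    tstat = est / se
    p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
    return est, (est - tcrit * se, est + tcrit * se), max(p, P_FLOOR)


def classify_effects(
    effects: list[TreatmentEffect],
    n_tested: int | None = None,
    alpha: float = 0.05,
    approved_drugs: set[str] | None = None,
    disease: str = "disease",
    biomarker: str = "biomarker",
) -> ScreenSummary:
    """Flag therapeutic (b1 < 0, p < alpha) and Bonferroni-significant drugs.

    The Bonferroni threshold is alpha divided by the number of drugs tested
    (defaults to the number of supplied results).
    """
    if n_tested is None:
        n_tested = len(effects)
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    approved_drugs = approved_drugs or set()
    threshold = alpha / n_tested
    rows = []
    for e in sorted(effects, key=lambda e: e.drug):
        therapeutic = (e.beta1 < 0) and (e.p < alpha)
        rows.append(
            {
                "drug": e.drug,
                "n": e.n_persons,
                "estimate": e.beta1,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "converged": e.converged,
                "therapeutic": therapeutic,
                "bonferroni_significant": therapeutic and (e.p < threshold),
                "approved_for_disease": e.drug in approved_drugs,
            }
        )
    return ScreenSummary(disease, biomarker, list(effects), n_tested,
                         threshold, pd.DataFrame(rows))


SUPPRESSED = "<20"


def demographics_report(
    demo: pd.DataFrame,
    category_flags: pd.DataFrame | None = None,
    suppression_n: int = 20,
) -> dict[str, pd.DataFrame]:
    """Cohort demographic tables with small-cell suppression.

    ``demo`` has one row per person with columns gender, ethnicity,
    age_baseline, age_treatment, comorbidity_baseline, comorbidity_treatment.
    ``category_flags`` (optional) has per-person 0/1 columns
    ``<category>_baseline`` / ``<category>_treatment`` for each comorbidity
    category; baseline vs treatment prevalence is compared by McNemar's test
    (continuity-corrected).  Continuous variables are compared by a paired
    Wilcoxon signed-rank test; all-tied pairs report 'NA'.  Any subgroup
    count below ``suppression_n`` is rendered as the suppression marker.
    """
    n = len(demo)

    def supp(count: int) -> str:
        return SUPPRESSED if count < suppression_n else str(count)

    counts = pd.DataFrame(
        [
            ("n", str(n)),
            ("female", supp(int((demo["gender"].str.lower().isin(["f", "female"])).sum()))),
            ("non_white", supp(int((~demo["ethnicity"].str.lower().isin(["white"])).sum()))),
        ],
        columns=["subgroup", "count"],
    )

    cont_rows = []
    for label, bcol, tcol in (
        ("age", "age_baseline", "age_treatment"),
        ("elixhauser_index", "comorbidity_baseline", "comorbidity_treatment"),
    ):
        b, t = demo[bcol].to_numpy(float), demo[tcol].to_numpy(float)
        diffs = t - b
        if np.all(diffs == 0):
            p: float | str = "NA"
        else:
            p = float(stats.wilcoxon(b, t, zero_method="wilcox").pvalue)
        cont_rows.append(
            (label,
             f"{np.median(b):.1f} ({np.percentile(b, 25):.1f}-{np.percentile(b, 75):.1f})",
             f"{np.median(t):.1f} ({np.percentile(t, 25):.1f}-{np.percentile(t, 75):.1f})",
             p)
        )
    continuous = pd.DataFrame(
        cont_rows, columns=["variable", "baseline_median_iqr",
                            "treatment_median_iqr", "wilcoxon_p"]
    )

    out = {"counts": counts, "continuous": continuous}
    if category_flags is not None:
        cats = sorted(
            {c.rsplit("_", 1)[0] for c in category_flags.columns
             if c.endswith("_baseline")}
        )
        rows = []
        for cat in cats:
            b = category_flags[f"{cat}_baseline"].astype(bool)
            t = category_flags[f"{cat}_treatment"].astype(bool)
            nb, nt = int(b.sum()), int(t.sum())
            tab = np.array(
                [[int((b & t).sum()), int((b & ~t).sum())],
                 [int((~b & t).sum()), int((~b & ~t).sum())]]
            )
            if tab[0, 1] + tab[1, 0] == 0:
                p = "NA"
            else:
                p = float(mcnemar(tab, exact=False, correction=True).pvalue)
            rows.append((cat, supp(nb), supp(nt), p))
        out["comorbidities"] = pd.DataFrame(
            rows, columns=["category", "n_baseline", "n_treatment", "mcnemar_p"]
        )
    return out
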