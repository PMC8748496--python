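"""Self-controlled case-series cohort construction from minimal EHR tables.

For one candidate ingredient the observation window per person is anchored on
the *index date* (first outpatient exposure): a baseline period of up to 365
days ending on the index date (inclusive), and a treatment period from the
index date to the last exposure date, capped at 365 days, with the first 30
days discarded as a pharmacologic induction period.  A fixed exclusion
cascade (adult age, biomarker present in both periods, no co-exposure to
drugs approved for the target disease, a two-visits-in-two-years information
leakage guard, optional systemic-route restriction) yields the final cohort,
with per-step attrition accounting.  Per-period median biomarkers, a
1.5×IQR outlier screen, and an Elixhauser comorbidity index feed the paired
model table consumed by the mixed-effects fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import InputError, SchemaError

logger = logging.getLogger(__name__)

DAY = pd.Timedelta(days=1)

#: compact ICD-prefix → Elixhauser-category mapping (subset of the standard
#: 31 categories; extend via elixhauser_map.tsv for real data)
DEFAULT_ELIXHAUSER_MAP = pd.DataFrame(
    [
        ("428", "chf"), ("I50", "chf"),
        ("427.3", "arrhythmia"), ("I48", "arrhythmia"),
        ("401", "hypertension"), ("I10", "hypertension"),
        ("250", "diabetes"), ("E11", "diabetes"),
        ("496", "copd"), ("J44", "copd"),
        ("585", "renal_failure"), ("N18", "renal_failure"),
        ("571", "liver_disease"), ("K74", "liver_disease"),
        ("244", "hypothyroidism"), ("E03", "hypothyroidism"),
        ("280", "anemia"), ("D50", "anemia"),
        ("296", "depression"), ("F32", "depression"),
    ],
    columns=["prefix", "category"],
)

EHR_SCHEMAS = {
    "persons": ["person_id", "birth_date", "gender", "ethnicity"],
    "drug_exposures": ["person_id", "ingredient", "start_date", "end_date",
                       "setting", "route"],
    "measurements": ["person_id", "concept", "date", "value", "setting"],
    "conditions": ["person_id", "code", "date"],
}


@dataclass
class EHRTables:
    """Minimal OMOP-inspired longitudinal record (four tables, ISO dates)."""

    persons: pd.DataFrame
    drug_exposures: pd.DataFrame
    measurements: pd.DataFrame
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        for name in EHR_SCHEMAS:
            df = getattr(self, name).copy()
            missing = [c for c in EHR_SCHEMAS[name] if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s) {missing}")
            df["person_id"] = df["person_id"].astype(str)
            for col in df.columns:
                if col.endswith("date") and not pd.api.types.is_datetime64_any_dtype(df[col]):
                    fmt = "ISO8601" if df[col].dtype == object else None
                    df[col] = pd.to_datetime(df[col], format=fmt)
            setattr(self, name, df)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in EHR_SCHEMAS:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False,
                                       date_format="%Y-%m-%d")


def load_ehr(indir: str | Path) -> EHRTables:
    indir = Path(indir)
    return EHRTables(
        **{
            name: pd.read_csv(indir / f"{name}.csv", dtype={"person_id": str})
            for name in EHR_SCHEMAS
        }
    )


@dataclass
class ObservationWindow:
    """Baseline [index-365d, index] (closed) and treatment (index, end]."""

    person_id: str
    index_date: pd.Timestamp
    treatment_end: pd.Timestamp
    induction_days: int = 30
    max_len_days: int = 365

    @property
    def baseline_start(self) -> pd.Timestamp:
        return self.index_date - self.max_len_days * DAY

    @property
    def effective_treatment_start(self) -> pd.Timestamp:
        """First day (exclusive bound) of post-induction treatment time."""
        return self.index_date + self.induction_days * DAY

    def in_baseline(self, dates) -> np.ndarray:
        d = np.asarray(dates)
        return (d >= self.baseline_start.to_datetime64()) & (
            d <= self.index_date.to_datetime64()
        )

    def in_effective_treatment(self, dates) -> np.ndarray:
        d = np.asarray(dates)
        return (d > self.effective_treatment_start.to_datetime64()) & (
            d <= self.treatment_end.to_datetime64()
        )


def build_window(
    exposures: pd.DataFrame,
    induction_days: int = 30,
    max_len_days: int = 365,
    default_supply_days: int = 90,
) -> tuple[ObservationWindow | None, str]:
    """Build one person's observation window from their exposure records.

    Missing end dates are imputed as start + ``default_supply_days``.
    Returns (window, "ok") or (None, reason) when ineligible: the treatment
    period must span at least ``induction_days`` before the 365-day cap.
    """
    outp = exposures[exposures["setting"] == "outpatient"]
    if len(outp) == 0:
        return None, "no_outpatient_exposure"
    person_id = str(exposures["person_id"].iloc[0])
    index_date = outp["start_date"].min()
    ends = exposures["end_date"].fillna(
        exposures["start_date"] + default_supply_days * DAY
    )
    if (ends < exposures["start_date"]).any():
        raise InputError(f"{person_id}: end_date before start_date")
    last_exposure = ends.max()
    if last_exposure - index_date < induction_days * DAY:
        return None, "treatment_shorter_than_induction"
    treatment_end = min(last_exposure, index_date + max_len_days * DAY)
    return (
        ObservationWindow(person_id, index_date, treatment_end,
                          induction_days, max_len_days),
        "ok",
    )


def build_windows(
    ehr: EHRTables,
    ingredient: str,
    induction_days: int = 30,
    max_len_days: int = 365,
    default_supply_days: int = 90,
) -> tuple[dict[str, ObservationWindow], dict[str, str]]:
    """Windows for every person exposed to ``ingredient``; plus reasons for
    the ineligible ones."""
    exp = ehr.drug_exposures[ehr.drug_exposures["ingredient"] == ingredient].copy()
    windows: dict[str, ObservationWindow] = {}
    ineligible: dict[str, str] = {}
    if len(exp) == 0:
        return windows, ineligible
    if (exp["end_date"].notna() & (exp["end_date"] < exp["start_date"])).any():
        raise InputError("end_date before start_date")
    exp["end_filled"] = exp["end_date"].fillna(
        exp["start_date"] + default_supply_days * DAY
    )
    outp = exp[exp["setting"] == "outpatient"]
    index_dates = outp.groupby("person_id")["start_date"].min()
    last_exposure = exp.groupby("person_id")["end_filled"].max()
    for pid in exp["person_id"].unique():
        pid = str(pid)
        if pid not in index_dates.index:
            ineligible[pid] = "no_outpatient_exposure"
            continue
        index_date = index_dates[pid]
        if last_exposure[pid] - index_date < induction_days * DAY:
            ineligible[pid] = "treatment_shorter_than_induction"
            continue
        windows[pid] = ObservationWindow(
            pid, index_date,
            min(last_exposure[pid], index_date + max_len_days * DAY),
            induction_days, max_len_days,
        )
    return windows, ineligible


@dataclass
class AttritionReport:
    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, count: int) -> None:
        if self.steps and count > self.steps[-1][1]:
            raise AssertionError("attrition counts must be nonincreasing")
        self.steps.append((name, count))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "persons_remaining"])


@dataclass
class CohortSelection:
    retained: dict[str, ObservationWindow]
    attrition: AttritionReport
    removals: dict[str, str]  # person_id -> reason of the step that removed them
    untestable: bool


def apply_exclusions(
    ehr: EHRTables,
    windows: dict[str, ObservationWindow],
    approved_drugs: set[str],
    tested_drug: str,
    concept: str,
    min_age: int = 18,
    max_age_exclusive: int = 90,
    min_cohort: int = 20,
    route_filter: bool = False,
    leakage_span_days: int = 730,
) -> CohortSelection:
    """Run the exclusion cascade in fixed order, recording attrition.

    Steps: (1) age at index in [min_age, max_age_exclusive); (2) at least one
    outpatient biomarker measurement in baseline AND in the post-induction
    treatment period; (3) no exposure to an approved drug for the disease —
    other than the tested drug itself — overlapping the observation window;
    (4) at least two distinct outpatient measurement dates within a two-year
    span inside the window; (5) optional systemic-route-only restriction.
    A final cohort below ``min_cohort`` flags the drug untestable.
    """
    report = AttritionReport()
    removals: dict[str, str] = {}
    current = dict(windows)
    report.add("eligible_window", len(current))

    births = dict(zip(ehr.persons["person_id"], ehr.persons["birth_date"]))

    def drop(pred, reason: str, step: str) -> None:
        nonlocal current
        keep = {}
        for pid, win in current.items():
            if pred(pid, win):
                keep[pid] = win
            else:
                removals[pid] = reason
        current = keep
        report.add(step, len(current))

    # (1) adult age at index
    def age_ok(pid, win):
        age = (win.index_date - births[pid]).days / 365.25
        return min_age <= age < max_age_exclusive

    drop(age_ok, "age_out_of_range", "age_in_range")

    # (2) biomarker present in both periods (outpatient only)
    meas = ehr.measurements
    meas = meas[(meas["concept"] == concept) & (meas["setting"] == "outpatient")]
    by_person = {
        pid: grp["date"].to_numpy() for pid, grp in meas.groupby("person_id", sort=False)
    }

    def both_periods(pid, win):
        dates = by_person.get(pid)
        if dates is None:
            return False
        return bool(win.in_baseline(dates).any() and win.in_effective_treatment(dates).any())

    drop(both_periods, "missing_period_measurement", "biomarker_both_periods")

    # (3) approved-drug co-exposure overlapping the observation window
    blocked = {d for d in approved_drugs if d != tested_drug}
    exp = ehr.drug_exposures[ehr.drug_exposures["ingredient"].isin(blocked)].copy()
    exp["end_filled"] = exp["end_date"].fillna(exp["start_date"] + 90 * DAY)
    exp_by_person = {
        pid: (grp["start_date"].to_numpy(), grp["end_filled"].to_numpy())
        for pid, grp in exp.groupby("person_id", sort=False)
    }

    def no_approved(pid, win):
        spans = exp_by_person.get(pid)
        if spans is None:
            return True
        starts, ends = spans
        overlap = (starts <= win.treatment_end.to_datetime64()) & (
            ends >= win.baseline_start.to_datetime64()
        )
        return not bool(overlap.any())

    drop(no_approved, "approved_drug_coexposure", "no_approved_drug")

    # (4) information-leakage guard: >=2 distinct outpatient measurement
    #     dates within leakage_span_days inside the window
    span_td = np.timedelta64(leakage_span_days, "D")

    def two_visits(pid, win):
        dates = by_person.get(pid)
        if dates is None:
            return False
        inside = np.unique(
            dates[
                (dates >= win.baseline_start.to_datetime64())
                & (dates <= win.treatment_end.to_datetime64())
            ]
        )
        if len(inside) < 2:
            return False
        return bool((np.diff(inside) <= span_td).any())

    drop(two_visits, "single_visit_window", "two_visits_two_years")

    # (5) optional systemic-route restriction on the tested drug
    if route_filter:
        tested = ehr.drug_exposures[ehr.drug_exposures["ingredient"] == tested_drug]
        nonsys = set(tested.loc[tested["route"] != "systemic", "person_id"])

        def systemic_only(pid, win):
            return pid not in nonsys

        drop(systemic_only, "non_systemic_route", "systemic_route_only")

    untestable = len(current) < min_cohort
    if untestable:
        logger.warning(
            "%s: final cohort n=%d < %d — drug untestable",
            tested_drug, len(current), min_cohort,
        )
    return CohortSelection(current, report, removals, untestable)


def period_medians(
    measurements: pd.DataFrame,
    windows: dict[str, ObservationWindow],
    concept: str,
) -> pd.DataFrame:
    """Per-person outpatient median biomarker for baseline and treatment.

    Baseline includes the index date; treatment uses only dates strictly
    after index + induction and at most the treatment end.
    """
    meas = measurements[
        (measurements["concept"] == concept)
        & (measurements["setting"] == "outpatient")
    ]
    by_person = {
        pid: (grp["date"].to_numpy(), grp["value"].to_numpy(float))
        for pid, grp in meas.groupby("person_id", sort=False)
    }
    rows = []
    for pid, win in windows.items():
        assert pid in by_person, f"{pid}: no measurements despite passing exclusions"
        dates, values = by_person[pid]
        b = values[win.in_baseline(dates)]
        t = values[win.in_effective_treatment(dates)]
        assert len(b) and len(t), f"{pid}: empty period despite passing exclusions"
        rows.append((pid, float(np.median(b)), float(np.median(t))))
    return pd.DataFrame(rows, columns=["person_id", "baseline", "treatment"])


def remove_outliers(medians: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop persons whose baseline or treatment median falls outside the
    Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR), computed per period across
    the cohort.  Quartiles use linear interpolation.  Cohorts smaller than 4
    are returned unchanged with a warning.
    """
    if len(medians) < 4:
        logger.warning("cohort of %d too small for outlier screen; skipping",
                       len(medians))
        return medians, []
    keep = np.ones(len(medians), dtype=bool)
    for col in ("baseline", "treatment"):
        vals = medians[col].to_numpy(float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        keep &= (vals >= lo) & (vals <= hi)
    dropped = medians.loc[~keep, "person_id"].tolist()
    if dropped:
        logger.info("outlier screen removed %d person(s)", len(dropped))
    return medians[keep].reset_index(drop=True), dropped


def load_elixhauser_map(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        return DEFAULT_ELIXHAUSER_MAP.copy()
    df = pd.read_csv(path, sep="\t")
    if not {"prefix", "category"}.issubset(df.columns):
        raise SchemaError("elixhauser map needs columns (prefix, category)")
    return df


def elixhauser_index(
    conditions: pd.DataFrame,
    obs_start: pd.Timestamp,
    as_of_date: pd.Timestamp,
    code_map: pd.DataFrame,
    weights: pd.Series | None = None,
) -> tuple[float, frozenset[str]]:
    """Comorbidity categories present between ``obs_start`` and ``as_of_date``.

    A category counts when any condition code starts with one of its ICD
    prefixes.  The index is the category count, or a weighted sum when a
    weight table (e.g., van Walraven) is supplied.
    """
    if len(code_map) == 0:
        raise InputError("empty Elixhauser code map")
    dates = conditions["date"].to_numpy()
    inside = (dates >= obs_start.to_datetime64()) & (dates <= as_of_date.to_datetime64())
    codes = [str(c) for c in conditions["code"].to_numpy()[inside]]
    pairs = _map_pairs(code_map)
    return _elixhauser_from_codes(codes, pairs, weights)


def _map_pairs(code_map: pd.DataFrame) -> list[tuple[str, str]]:
    return [
        (str(p), str(c))
        for p, c in zip(code_map["prefix"].to_numpy(), code_map["category"].to_numpy())
    ]


def _elixhauser_from_codes(
    codes: list[str],
    pairs: list[tuple[str, str]],
    weights: pd.Series | None = None,
) -> tuple[float, frozenset[str]]:
    cats: set[str] = set()
    if codes:
        for prefix, category in pairs:
            if category not in cats and any(c.startswith(prefix) for c in codes):
                cats.add(category)
    if weights is None:
        value = float(len(cats))
    else:
        value = float(sum(weights.get(c, 0.0) for c in cats))
    return value, frozenset(cats)


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def assemble_model_table(
    selection: CohortSelection,
    medians: pd.DataFrame,
    ehr: EHRTables,
    code_map: pd.DataFrame | None = None,
    elixhauser_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the paired two-row-per-person model table.

    Columns: person_id, period, biomarkerVal, drugExposure, Age, Gender,
    Ethnicity, Comorbidity.  Age is the age at the end of each period and,
    like the Elixhauser index (computed from observation start to the end of
    the respective period), is z-normalized across all rows.  Gender is 1
    for female, Ethnicity 1 for non-white.
    """
    if code_map is None:
        code_map = DEFAULT_ELIXHAUSER_MAP
    pairs = _map_pairs(code_map)
    persons = {
        rec.person_id: rec for rec in ehr.persons.itertuples(index=False)
    }
    cond_by_person = {
        pid: (grp["date"].to_numpy(), [str(c) for c in grp["code"]])
        for pid, grp in ehr.conditions.groupby("person_id", sort=False)
    }
    med = medians.set_index("person_id")
    rows = []
    for pid, win in selection.retained.items():
        rec = persons.get(pid)
        if rec is None:
            logger.warning("%s: missing demographics — dropped", pid)
            continue
        gender = 1 if str(rec.gender).lower() in ("f", "female", "1") else 0
        ethnicity = 0 if str(rec.ethnicity).lower() in ("white", "0") else 1
        cdates, ccodes = cond_by_person.get(pid, (np.array([], dtype="M8[ns]"), []))
        start64 = win.baseline_start.to_datetime64()
        for period, end in (("baseline", win.index_date),
                            ("treatment", win.treatment_end)):
            age = (end - rec.birth_date).days / 365.25
            inside = (cdates >= start64) & (cdates <= end.to_datetime64())
            comorb, _ = _elixhauser_from_codes(
                [c for c, ok in zip(ccodes, inside) if ok], pairs,
                elixhauser_weights,
            )
            rows.append(
                (pid, period, med.loc[pid, period], int(period == "treatment"),
                 age, gender, ethnicity, comorb)
            )
    table = pd.DataFrame(
        rows,
        columns=["person_id", "period", "biomarkerVal", "drugExposure",
                 "Age", "Gender", "Ethnicity", "Comorbidity"],
    )
    if len(table):
        table["Age"] = _znorm(table["Age"].to_numpy(float))
        table["Comorbidity"] = _znorm(table["Comorbidity"].to_numpy(float))
    return table


@dataclass
class CohortBuild:
    """Everything the validation stage needs for one drug."""

    drug: str
    model_table: pd.DataFrame
    attrition: AttritionReport
    removals: dict[str, str]
    untestable: bool
    n_persons: int


def build_cohort(
    ehr: EHRTables,
    ingredient: str,
    concept: str,
    approved_drugs: set[str],
    code_map: pd.DataFrame | None = None,
    induction_days: int = 30,
    max_len_days: int = 365,
    min_cohort: int = 20,
    route_filter: bool = False,
    outlier_screen: bool = True,
    apply_approved_filter: bool = True,
    default_supply_days: int = 90,
) -> CohortBuild:
    """Full cohort pipeline for one candidate drug.

    ``apply_approved_filter=False`` disables exclusion of approved-drug
    co-exposed persons (used to demonstrate confounding by indication).
    """
    windows, _ = build_windows(ehr, ingredient, induction_days, max_len_days,
                               default_supply_days)
    selection = apply_exclusions(
        ehr, windows,
        approved_drugs if apply_approved_filter else set(),
        ingredient, concept,
        min_cohort=min_cohort, route_filter=route_filter,
    )
    if len(selection.retained) == 0:
        return CohortBuild(ingredient, pd.DataFrame(), selection.attrition,
                           selection.removals, True, 0)
    medians = period_medians(ehr.measurements, selection.retained, concept)
    if outlier_screen:
        medians, dropped = remove_outliers(medians)
        for pid in dropped:
            selection.retained.pop(pid)
            selection.removals[pid] = "median_outlier"
        selection.attrition.add("median_outlier_screen", len(medians))
    untestable = len(medians) < min_cohort
    table = assemble_model_table(selection, medians, ehr, code_map)
    return CohortBuild(ingredient, table, selection.attrition,
                       selection.removals, untestable,
                       table["person_id"].nunique() if len(table) else 0)


def read_approved_drugs(path: str | Path, disease: str | None = None) -> set[str]:
    """Read the approved-drug reference table (disease, ingredient)."""
    df = pd.read_csv(path, sep="\t")
    if not {"disease", "ingredient"}.issubset(df.columns):
        raise SchemaError("approved drugs table needs columns (disease, ingredient)")
    if disease is not None:
        df = df[df["disease"] == disease]
    return set(df["ingredient"])
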