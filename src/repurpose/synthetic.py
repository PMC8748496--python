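"""Synthetic inputs for every pipeline stage, with a ground-truth manifest.

Three generators emulate the statistical structure of the real resources the
pipeline is designed for, at desk scale:

* ``gen_deg_table`` — an imputed DEG table (gene, Z, p) with a planted set
  of causal genes whose |Z| is shifted away from the null;
* ``gen_perturbation_library`` — a drug perturbation library containing a
  few planted reversers (noisy negated copies of the disease signature at a
  chosen fidelity) among independent-noise decoys;
* ``gen_ehr`` — longitudinal outpatient biomarker trajectories around a
  first-exposure index date, with per-person random intercepts, covariate
  effects, an injected post-induction treatment effect per drug, and
  planted exclusion violations (under-age persons, missing-period
  measurements, approved-drug co-exposure, non-systemic routes).

Every generator is deterministic under the config seed, and every planted
feature is recorded in a :class:`TruthManifest` so tests can check the
pipeline against exact expectations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import DAY, DEFAULT_ELIXHAUSER_MAP, EHRTables
from .matching import DrugSignature
from .signatures import DiseaseSignature, InputError

logger = logging.getLogger(__name__)

VIOLATION_REASONS = (
    "age_out_of_range",
    "missing_period_measurement",
    "approved_drug_coexposure",
    "non_systemic_route",
)

#: ingredient name used for the planted FDA-approved comparator drug
APPROVED_ANCHOR = "anchor-approved"


@dataclass
class SimulationConfig:
    """All tunables of the synthetic study, with field-realistic defaults.

    Biomarker defaults emulate outpatient LDL-C (mg/dL): population mean
    130, per-person random-intercept sd 10, within-person residual sd 5,
    about six outpatient measurements per year.
    """

    seed: int
    # DEG table
    n_genes: int = 5000
    n_signature_causal: int = 300
    causal_z_mean: float = 6.0
    # perturbation library
    n_drugs: int = 500
    n_reversers: int = 5
    reverser_fidelity: float = 0.9
    library_overlap: float = 1.0
    n_extra_genes: int = 878
    # EHR / biomarker model
    n_persons: int = 300
    visit_rate_per_year: float = 6.0
    concept: str = "LDL-C"
    baseline_mean: float = 130.0
    person_sd: float = 10.0
    residual_sd: float = 5.0
    age_effect: float = 3.0          # per decade of age
    gender_effect: float = -3.0      # female vs male
    ethnicity_effect: float = 2.0    # non-white vs white
    comorbidity_effect: float = 2.0  # per Elixhauser category
    frac_inpatient_extra: float = 0.15
    frac_missing_end: float = 0.1
    exposure_min_days: int = 90
    exposure_max_days: int = 360
    induction_days: int = 30
    # confounding-by-indication stressor
    coexposure_effect: float = -30.0
    coexposure_baseline_shift: float = 10.0
    # medication non-adherence (attenuation of delta), off by default
    nonadherence_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        for name in ("person_sd", "residual_sd"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        for name in ("library_overlap", "frac_missing_end",
                     "frac_inpatient_extra", "nonadherence_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise InputError(f"{name} must be in [0, 1]")
        if not 0 < self.reverser_fidelity <= 1:
            raise InputError("reverser_fidelity must be in (0, 1]")
        if self.n_persons < 1:
            raise InputError("n_persons must be >= 1")
        if self.n_drugs < self.n_reversers:
            raise InputError("n_drugs must be >= n_reversers")
        if self.n_genes < 2 * self.n_signature_causal:
            raise InputError("n_genes must be at least 2 * n_signature_causal")


@dataclass
class TruthManifest:
    """Ground truth for everything the generators planted."""

    deltas: dict[str, float] = field(default_factory=dict)
    n_per_drug: dict[str, int] = field(default_factory=dict)
    violations: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    reversers: list[str] = field(default_factory=list)
    causal_genes: list[str] = field(default_factory=list)
    person_intercepts: dict[str, float] = field(default_factory=dict)

    def violation_set(self, drug: str) -> set[tuple[str, str]]:
        return {(v["person_id"], v["reason"]) for v in self.violations.get(drug, [])}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ------------------------------------------------------------------ DEG stage

def gen_deg_table(
    config: SimulationConfig, disease: str = "synthetic-disease"
) -> tuple[pd.DataFrame, dict]:
    """DEG table with ``n_signature_causal`` genes at shifted |Z|.

    Causal genes draw Z ~ ±N(causal_z_mean, 1) (random sign); null genes
    Z ~ N(0, 1).  p is the two-tailed normal tail of Z.
    """
    rng = np.random.default_rng(config.seed)
    n, nc = config.n_genes, config.n_signature_causal
    genes = np.array([f"G{i:05d}" for i in range(n)])
    causal_idx = rng.choice(n, size=nc, replace=False)
    z = rng.normal(0.0, 1.0, n)
    signs = rng.choice([-1.0, 1.0], size=nc)
    z[causal_idx] = signs * rng.normal(config.causal_z_mean, 1.0, nc)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({"gene": genes, "zscore": z, "pvalue": p})
    truth = {
        "disease": disease,
        "causal_genes": sorted(genes[causal_idx].tolist()),
    }
    return df, truth


# -------------------------------------------------------------- library stage

def gen_perturbation_library(
    signature: DiseaseSignature, config: SimulationConfig
) -> tuple[list[DrugSignature], dict]:
    """Library of planted reversers plus independent-noise decoys.

    A reverser's profile over the signature genes is the negated signature
    score plus Gaussian noise scaled so its expected correlation with the
    signature equals ``-reverser_fidelity``; all other genes, and every
    decoy, are standard-normal noise.  ``library_overlap`` controls the
    fraction of signature genes present in the library's gene universe.
    """
    if len(signature) == 0:
        raise InputError("empty disease signature")
    rng = np.random.default_rng(config.seed + 1)
    scores = signature.scores
    n_keep = max(2, int(round(config.library_overlap * len(scores))))
    kept = rng.choice(scores.index.to_numpy(), size=n_keep, replace=False)
    kept = pd.Index(sorted(kept))
    extra = pd.Index([f"LG{i:05d}" for i in range(config.n_extra_genes)])
    universe = kept.append(extra)

    s = float(scores.loc[kept].std(ddof=0))
    f = config.reverser_fidelity
    noise_sd = 0.0 if f >= 1.0 else s * np.sqrt(1.0 / f**2 - 1.0)

    library: list[DrugSignature] = []
    reversers = [f"reverser-{i + 1:02d}" for i in range(config.n_reversers)]
    for name in reversers:
        vals = pd.Series(rng.normal(0.0, 1.0, len(universe)), index=universe)
        vals.loc[kept] = -scores.loc[kept].to_numpy() + rng.normal(
            0.0, noise_sd, len(kept)
        )
        library.append(DrugSignature(name, vals, source="planted-reverser"))
    n_decoys = config.n_drugs - config.n_reversers
    for i in range(n_decoys):
        vals = pd.Series(rng.normal(0.0, 1.0, len(universe)), index=universe)
        library.append(DrugSignature(f"decoy-{i + 1:04d}", vals, source="decoy"))
    truth = {"reversers": reversers, "n_decoys": n_decoys,
             "universe_size": len(universe)}
    return library, truth


def library_to_frame(library: list[DrugSignature]) -> pd.DataFrame:
    """Long-format (drug, gene, value) frame for on-disk storage."""
    parts = [
        pd.DataFrame({"drug": d.drug, "gene": d.values.index,
                      "value": d.values.to_numpy()})
        for d in library
    ]
    return pd.concat(parts, ignore_index=True)


# ------------------------------------------------------------------ EHR stage

_ELIX_CATEGORIES = DEFAULT_ELIXHAUSER_MAP["category"].unique()
_ELIX_PREFIX = (
    DEFAULT_ELIXHAUSER_MAP.drop_duplicates("category").set_index("category")["prefix"]
)

_EPOCH = pd.Timestamp("2010-01-01")


def gen_ehr(
    config: SimulationConfig,
    drugs: dict[str, float],
    n_per_drug: dict[str, int] | None = None,
    violations: dict[str, dict[str, int]] | None = None,
) -> tuple[EHRTables, TruthManifest]:
    """Four EHR tables for a set of candidate drugs with injected effects.

    ``drugs`` maps ingredient name → true treatment effect delta (applied to
    outpatient biomarker values measured after the induction period while
    exposed).  ``violations`` plants additional persons per drug who violate
    one exclusion each (see :data:`VIOLATION_REASONS`); clean persons are
    constructed to pass the whole cascade, so on this data the cascade's
    removals equal the manifest exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_per_drug = n_per_drug or {}
    violations = violations or {}
    manifest = TruthManifest(deltas={d: float(v) for d, v in drugs.items()})

    persons_rows, exposure_rows, meas_rows, cond_rows = [], [], [], []

    for drug in sorted(drugs):
        delta = drugs[drug]
        n_clean = n_per_drug.get(drug, config.n_persons)
        plan: list[str | None] = [None] * n_clean
        drug_viol = violations.get(drug, {})
        for reason, count in sorted(drug_viol.items()):
            if reason not in VIOLATION_REASONS:
                raise InputError(f"unknown violation reason {reason!r}")
            plan.extend([reason] * count)
        manifest.n_per_drug[drug] = n_clean
        manifest.violations[drug] = []

        for i, reason in enumerate(plan):
            pid = f"{drug}-{i:04d}"
            _gen_person(
                config, rng, pid, drug, delta, reason,
                persons_rows, exposure_rows, meas_rows, cond_rows, manifest,
            )
            if reason is not None:
                manifest.violations[drug].append(
                    {"person_id": pid, "reason": reason}
                )

    ehr = EHRTables(
        persons=pd.DataFrame(
            persons_rows, columns=["person_id", "birth_date", "gender", "ethnicity"]
        ),
        drug_exposures=pd.DataFrame(
            exposure_rows,
            columns=["person_id", "ingredient", "start_date", "end_date",
                     "setting", "route"],
        ),
        measurements=pd.DataFrame(
            meas_rows, columns=["person_id", "concept", "date", "value", "setting"]
        ),
        conditions=pd.DataFrame(cond_rows, columns=["person_id", "code", "date"]),
    )
    return ehr, manifest


def _gen_person(
    config: SimulationConfig,
    rng: np.random.Generator,
    pid: str,
    drug: str,
    delta: float,
    reason: str | None,
    persons_rows: list,
    exposure_rows: list,
    meas_rows: list,
    cond_rows: list,
    manifest: TruthManifest,
) -> None:
    index = _EPOCH + int(rng.integers(0, 1500)) * DAY
    if reason == "age_out_of_range":
        age = float(rng.uniform(10, 17))
    else:
        age = float(rng.uniform(25, 80))
    birth = index - pd.Timedelta(days=round(age * 365.25))
    female = bool(rng.random() < 0.5)
    nonwhite = bool(rng.random() < 0.3)
    persons_rows.append(
        (pid, birth.date().isoformat(), "female" if female else "male",
         "other" if nonwhite else "white")
    )

    # exposure to the candidate drug
    duration = int(rng.integers(config.exposure_min_days,
                                config.exposure_max_days + 1))
    missing_end = rng.random() < config.frac_missing_end
    if missing_end:
        duration = 90  # true course matches the pipeline's imputation default
    end = index + duration * DAY
    route = "non-systemic" if reason == "non_systemic_route" else "systemic"
    exposure_rows.append(
        (pid, drug, index.date().isoformat(),
         None if missing_end else end.date().isoformat(), "outpatient", route)
    )
    t_end_off = min(duration, 365)

    # confounding co-exposure to the approved comparator
    coexposed = reason == "approved_drug_coexposure"
    coexp_off = None
    if coexposed:
        coexp_off = int(rng.integers(5, min(40, t_end_off - config.induction_days)))
        coexp_start = index + coexp_off * DAY
        exposure_rows.append(
            (pid, APPROVED_ANCHOR, coexp_start.date().isoformat(),
             (index + t_end_off * DAY).date().isoformat(), "outpatient",
             "systemic")
        )

    # comorbidities: a handful of baseline categories, occasionally one new
    # category appearing during treatment
    k_b = int(min(rng.poisson(1.5), len(_ELIX_CATEGORIES)))
    cats = list(rng.choice(_ELIX_CATEGORIES, size=k_b, replace=False))
    for cat in cats:
        off = int(rng.integers(-360, 0))
        cond_rows.append(
            (pid, f"{_ELIX_PREFIX[cat]}.{int(rng.integers(0, 10))}",
             (index + off * DAY).date().isoformat())
        )
    k_t = k_b
    if rng.random() < 0.15 and k_b < len(_ELIX_CATEGORIES):
        new_cat = rng.choice([c for c in _ELIX_CATEGORIES if c not in cats])
        off = int(rng.integers(config.induction_days + 1, max(t_end_off, 32)))
        cond_rows.append(
            (pid, f"{_ELIX_PREFIX[new_cat]}.{int(rng.integers(0, 10))}",
             (index + off * DAY).date().isoformat())
        )
        k_t += 1

    # person-level value model
    intercept = float(rng.normal(0.0, config.person_sd))
    if coexposed:
        intercept += config.coexposure_baseline_shift
    manifest.person_intercepts[pid] = intercept
    adherence = 1.0
    if config.nonadherence_fraction and rng.random() < config.nonadherence_fraction:
        adherence = float(rng.uniform(0.2, 0.8))

    # age enters at the end of the period a measurement falls in, matching
    # the covariate definition the paired model uses
    age_treatment = age + t_end_off / 365.25

    def level(k_cats: int, age_years: float) -> float:
        return (
            config.baseline_mean
            + intercept
            + config.age_effect * (age_years - 55.0) / 10.0
            + config.gender_effect * female
            + config.ethnicity_effect * nonwhite
            + config.comorbidity_effect * k_cats
        )

    def emit(offsets: np.ndarray, k_cats: int, with_delta: bool,
             setting: str = "outpatient") -> None:
        age_years = age_treatment if with_delta else age
        for off in offsets:
            val = level(k_cats, age_years) + rng.normal(0.0, config.residual_sd)
            if with_delta:
                val += delta * adherence
            if coexp_off is not None and off >= coexp_off:
                val += config.coexposure_effect
            meas_rows.append(
                (pid, config.concept, (index + int(off) * DAY).date().isoformat(),
                 round(float(val), 2), setting)
            )

    rate = config.visit_rate_per_year
    # baseline period [index-365, index]
    if reason != "missing_period_measurement":
        n_b = max(1, int(rng.poisson(rate)))
        emit(rng.integers(-365, 1, n_b), k_b, with_delta=False)
    # induction period (index, index+30]: no treatment effect yet
    n_i = int(rng.poisson(rate * config.induction_days / 365.0))
    if n_i:
        emit(rng.integers(1, config.induction_days + 1, n_i), k_t, with_delta=False)
    # effective treatment period (index+30, t_end]
    span = t_end_off - config.induction_days
    n_t = max(1, int(rng.poisson(rate * span / 365.0)))
    emit(
        rng.integers(config.induction_days + 1, t_end_off + 1, n_t),
        k_t, with_delta=True,
    )
    # a few inpatient measurements (pipeline must ignore them)
    if rng.random() < config.frac_inpatient_extra:
        emit(rng.integers(-365, t_end_off + 1, 1), k_t, with_delta=False,
             setting="inpatient")


# ------------------------------------------------------------- full scenarios

DEFAULT_SCENARIO_DRUGS = {
    # deltas follow the magnitudes seen for strong approved lipid-lowering
    # drugs (~ -30 mg/dL) vs weak off-label signals (~ -5 mg/dL)
    "cand-strong": -30.0,
    "cand-weak": -5.0,
    "cand-null": 0.0,
    "cand-small": -10.0,
}

DEFAULT_SCENARIO_VIOLATIONS = {
    "cand-null": {
        "age_out_of_range": 3,
        "missing_period_measurement": 4,
        "approved_drug_coexposure": 5,
    },
}


def gen_scenario(
    outdir: str | Path,
    seed: int,
    config: SimulationConfig | None = None,
    drugs: dict[str, float] | None = None,
    n_per_drug: dict[str, int] | None = None,
    violations: dict[str, dict[str, int]] | None = None,
    disease: str = "synthetic-disease",
) -> Path:
    """Write a complete, self-consistent input bundle to ``outdir``.

    The bundle contains a DEG table, a perturbation library whose planted
    reversers map (via the ingredient table) onto the candidate ingredients
    present in the EHR, the four EHR tables, reference tables, the truth
    manifest, and a ready-to-run YAML configuration.
    """
    from .signatures import select_topk

    outdir = Path(outdir)
    (outdir / "ehr").mkdir(parents=True, exist_ok=True)
    (outdir / "reference").mkdir(exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed, n_persons=60, n_drugs=120)
    drugs = dict(DEFAULT_SCENARIO_DRUGS if drugs is None else drugs)
    if n_per_drug is None:
        n_per_drug = {"cand-small": 19} if "cand-small" in drugs else {}
    if violations is None:
        violations = {
            k: dict(v) for k, v in DEFAULT_SCENARIO_VIOLATIONS.items() if k in drugs
        }

    deg, deg_truth = gen_deg_table(config, disease)
    deg.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)

    signature = select_topk(deg, k=50, disease=disease)
    library, lib_truth = gen_perturbation_library(signature, config)
    library_to_frame(library).to_csv(outdir / "library.tsv", sep="\t", index=False)

    ehr, manifest = gen_ehr(config, drugs, n_per_drug, violations)
    ehr.write(outdir / "ehr")
    manifest.reversers = lib_truth["reversers"]
    manifest.causal_genes = deg_truth["causal_genes"]
    manifest.to_yaml(outdir / "manifest.yaml")

    # reference tables: reversers map onto the EHR candidate ingredients
    candidates = sorted(drugs)
    map_rows = []
    for i, rev in enumerate(manifest.reversers):
        if i < len(candidates):
            map_rows.append((rev, candidates[i], 1))
    map_rows.append(("decoy-0001", "otc-ingredient", 0))
    pd.DataFrame(map_rows, columns=["drug", "ingredient", "prescription"]).to_csv(
        outdir / "reference" / "ingredient_map.tsv", sep="\t", index=False
    )
    approved = [(disease, APPROVED_ANCHOR)]
    if "cand-strong" in drugs:
        approved.append((disease, "cand-strong"))
    pd.DataFrame(approved, columns=["disease", "ingredient"]).to_csv(
        outdir / "reference" / "approved_drugs.tsv", sep="\t", index=False
    )
    DEFAULT_ELIXHAUSER_MAP.to_csv(
        outdir / "reference" / "elixhauser_map.tsv", sep="\t", index=False
    )

    run_config = {
        "disease": disease,
        "biomarker": config.concept,
        "seed": seed,
        "deg_table": "deg_table.tsv",
        "library": "library.tsv",
        "ehr_dir": "ehr",
        "ingredient_map": "reference/ingredient_map.tsv",
        "approved_drugs": "reference/approved_drugs.tsv",
        "elixhauser_map": "reference/elixhauser_map.tsv",
        "K": 50,
        "q": 0.05,
        "alpha_screen": 0.05,
        "alpha_validate": 0.05,
        "min_cohort": 20,
        "induction_days": 30,
        "max_window_days": 365,
        "output_dir": "results",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=False)
    logger.info("scenario bundle written to %s", outdir)
    return outdir
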