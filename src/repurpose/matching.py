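"""Reversal screening of a drug perturbation library against a disease signature.

Each drug carries a gene → differential-expression profile (a LINCS- or
DrugMatrix-style signature).  A drug *reverses* a disease signature when the
(optionally weighted) Pearson correlation between the two profiles over their
shared genes is negative and significant: the drug pushes disease-upregulated
genes down and vice versa.  The screen scores every drug, keeps the
significant reversers, merges candidate lists produced from different
signature constructions, and maps library names to prescribable ingredients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import DiseaseSignature, InputError, SchemaError

logger = logging.getLogger(__name__)

#: reported instead of 0 when |r| = 1, so -log10(p) stays finite
P_EPS = float(np.finfo(float).eps)


@dataclass
class DrugSignature:
    """One drug's gene-expression perturbation profile."""

    drug: str
    values: pd.Series  # index: gene symbol (upper-cased), values: signed DE
    source: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.Series):
            self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            raise InputError(f"{self.drug}: duplicate gene keys")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise InputError(f"{self.drug}: non-finite perturbation values")


@dataclass
class MatchResult:
    drug: str
    r: float
    p: float
    n_overlap: int
    signature_method: str = ""
    degenerate: bool = False
    insufficient_overlap: bool = False


@dataclass
class CandidateList:
    disease: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: drug, r, p, n_overlap, methods (comma-joined provenance)


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> float:
    """Weighted Pearson correlation; weights default to 1 (plain Pearson)."""
    if w is None:
        w = np.ones_like(x)
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx == 0 or vy == 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def pearson_match(
    disease: DiseaseSignature,
    drug: DrugSignature,
    weights: pd.Series | None = None,
) -> MatchResult:
    """Correlate a disease signature with one drug profile over shared genes.

    p comes from the two-tailed t transform with ``n_overlap - 2`` degrees of
    freedom.  With only 2 shared genes r is reported without p; with fewer
    the result is undefined.  |r| = 1 gets a machine-epsilon p floor and a
    degeneracy flag.
    """
    dscores = disease.scores
    shared = dscores.index.intersection(drug.values.index)
    n = len(shared)
    method = disease.method
    if n < 2:
        return MatchResult(drug.drug, np.nan, np.nan, n, method,
                           insufficient_overlap=True)
    x = dscores.loc[shared].to_numpy(float)
    y = drug.values.loc[shared].to_numpy(float)
    w = None
    if weights is not None:
        w = weights.reindex(shared).to_numpy(float)
        if np.isnan(w).any() or (w < 0).any():
            raise InputError("weights must be non-negative and cover shared genes")
    r = weighted_pearson(x, y, w)
    if np.isnan(r):
        return MatchResult(drug.drug, np.nan, np.nan, n, method, degenerate=True)
    if n == 2:
        return MatchResult(drug.drug, r, np.nan, n, method,
                           insufficient_overlap=True)
    if abs(r) >= 1.0 - 1e-12:
        return MatchResult(drug.drug, float(np.sign(r)), P_EPS, n, method,
                           degenerate=True)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return MatchResult(drug.drug, r, max(p, P_EPS), n, method)


@dataclass
class ScreenResult:
    retained: list[MatchResult]
    all_results: list[MatchResult]
    insufficient: list[MatchResult]


def screen_library(
    disease: DiseaseSignature,
    library: list[DrugSignature],
    alpha: float = 0.05,
    weights: pd.Series | None = None,
) -> ScreenResult:
    """Score every drug; retain significant reversers (r < 0 and p < alpha).

    Retained results are sorted by ascending r (strongest reversal first).
    Drugs with insufficient gene overlap are reported separately.
    """
    if not library:
        raise InputError("empty perturbation library")
    results, insufficient = [], []
    for drug in library:
        res = pearson_match(disease, drug, weights=weights)
        if res.insufficient_overlap or np.isnan(res.r):
            insufficient.append(res)
        else:
            results.append(res)
    retained = sorted(
        (r for r in results if r.r < 0 and r.p < alpha), key=lambda m: m.r
    )
    logger.info(
        "screened %d drugs: %d reversers at alpha=%g, %d with insufficient overlap",
        len(library), len(retained), alpha, len(insufficient),
    )
    return ScreenResult(retained, results, insufficient)


def _to_frame(results: list[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug": [m.drug for m in results],
            "r": [m.r for m in results],
            "p": [m.p for m in results],
            "n_overlap": [m.n_overlap for m in results],
            "methods": [m.signature_method for m in results],
        }
    )


def combine_candidates(
    list_topk: list[MatchResult] | CandidateList,
    list_fdr: list[MatchResult] | CandidateList,
    disease: str = "disease",
) -> CandidateList:
    """Union the top-K and FDR candidate lists into one list per disease.

    A drug found by both keeps its most negative r (and that record's p);
    the ``methods`` column records which signature construction(s) found it.
    """
    frames = []
    for lst in (list_topk, list_fdr):
        if isinstance(lst, CandidateList):
            if lst.disease != disease:
                raise InputError(
                    f"disease label mismatch: {lst.disease!r} vs {disease!r}"
                )
            frames.append(lst.table)
        else:
            frames.append(_to_frame(lst))
    both = pd.concat(frames, ignore_index=True)
    if len(both) == 0:
        return CandidateList(disease, _to_frame([]))
    both = both.sort_values("r", kind="stable")
    methods = both.groupby("drug", sort=False)["methods"].agg(
        lambda s: ",".join(sorted(set(s)))
    )
    best = both.drop_duplicates("drug", keep="first").set_index("drug")
    best["methods"] = methods
    table = best.reset_index().sort_values("r", kind="stable").reset_index(drop=True)
    return CandidateList(disease, table)


def filter_candidates(
    cands: CandidateList,
    ingredient_map: pd.DataFrame,
    prescription_only: bool = True,
) -> CandidateList:
    """Map library drug names to ingredients; drop unmapped and OTC entries.

    ``ingredient_map`` needs columns (drug, ingredient, prescription); salts
    mapping to one ingredient collapse to a single candidate keeping the
    best (most negative) r.
    """
    required = {"drug", "ingredient", "prescription"}
    if not required.issubset(ingredient_map.columns):
        raise SchemaError(
            f"ingredient map needs columns {sorted(required)}, got {list(ingredient_map.columns)}"
        )
    table = cands.table
    if len(table) == 0:
        return CandidateList(cands.disease, table.copy())
    merged = table.merge(ingredient_map, on="drug", how="left")
    unmapped = merged["ingredient"].isna()
    if unmapped.any():
        logger.info(
            "dropping %d candidate(s) with no ingredient mapping: %s",
            int(unmapped.sum()), merged.loc[unmapped, "drug"].tolist(),
        )
        merged = merged[~unmapped]
    if prescription_only:
        rx = merged["prescription"].astype(bool)
        if (~rx).any():
            logger.info(
                "dropping %d non-prescription ingredient(s): %s",
                int((~rx).sum()), sorted(set(merged.loc[~rx, "ingredient"])),
            )
        merged = merged[rx]
    merged = merged.sort_values("r", kind="stable")
    methods = merged.groupby("ingredient", sort=False)["methods"].agg(
        lambda s: ",".join(sorted(set(",".join(s).split(","))))
    )
    out = merged.drop_duplicates("ingredient", keep="first").set_index("ingredient")
    out["methods"] = methods
    out = (
        out.reset_index()[["ingredient", "drug", "r", "p", "n_overlap", "methods"]]
        .sort_values("r", kind="stable")
        .reset_index(drop=True)
    )
    return CandidateList(cands.disease, out)


# ---------------------------------------------------------------- library IO

def read_library(path: str | Path, source: str = "") -> list[DrugSignature]:
    """Read a perturbation library from disk.

    Two dialects are auto-detected from the header: a long TSV with columns
    (drug, gene, value), or a wide CSV matrix with genes as rows and drugs as
    columns (first column holds gene symbols).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    head = pd.read_csv(path, sep=sep, nrows=0)
    cols = [c.lower() for c in head.columns]
    if {"drug", "gene", "value"}.issubset(cols):
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.lower() for c in df.columns]
        return [
            DrugSignature(str(drug), grp.set_index("gene")["value"].astype(float),
                          source=source)
            for drug, grp in df.groupby("drug", sort=True)
        ]
    wide = pd.read_csv(path, sep=sep, index_col=0)
    return [
        DrugSignature(str(drug), wide[drug].dropna().astype(float), source=source)
        for drug in wide.columns
    ]


def write_candidates(cands: CandidateList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# disease={cands.disease}\n")
        cands.table.to_csv(fh, sep="\t", index=False)
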