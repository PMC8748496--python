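"""Disease gene-expression signatures from imputed DEG tables.

A DEG table holds one row per gene with an imputed association Z-score and
two-tailed p-value (the output schema of transcriptome-wide imputation tools
such as S-PrediXcan).  Two selection rules turn a table into a disease
signature:

* **top-K** — the K most upregulated (largest Z) and K most downregulated
  (smallest Z) genes, giving up to 2K genes;
* **FDR** — all genes passing a Benjamini–Hochberg q-value cutoff, with
  direction taken from the sign of Z.

The signature is the gene → signed-Z mapping that downstream reversal
screening correlates against drug perturbation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {"gene": "gene", "zscore": "zscore", "pvalue": "pvalue"}


class SchemaError(ValueError):
    """A required column is missing or a reference table is malformed."""


class InputError(ValueError):
    """Input data violate a precondition (empty table, bad threshold...)."""


@dataclass
class DiseaseSignature:
    """An ordered set of signed gene scores representing a disease state.

    ``table`` has columns ``gene``, ``score`` (signed Z copy) and
    ``direction`` (``up`` iff score > 0), sorted by descending score.
    """

    disease: str
    method: str  # "topK" or "fdr"
    params: dict = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.table):
            validate_signature_table(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def scores(self) -> pd.Series:
        """Gene → signed score mapping (index: uppercase gene symbol)."""
        return pd.Series(
            self.table["score"].to_numpy(), index=self.table["gene"].str.upper()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiseaseSignature):
            return NotImplemented
        return (
            self.disease == other.disease
            and self.method == other.method
            and self.params == other.params
            and len(self.table) == len(other.table)
            and (
                len(self.table) == 0
                or (
                    (self.table["gene"].to_numpy() == other.table["gene"].to_numpy()).all()
                    and np.allclose(self.table["score"], other.table["score"])
                    and (
                        self.table["direction"].to_numpy()
                        == other.table["direction"].to_numpy()
                    ).all()
                )
            )
        )


def validate_signature_table(table: pd.DataFrame) -> None:
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise InputError(f"duplicate genes in signature: {dupes}")
    up = table["score"] > 0
    if not (table.loc[up, "direction"] == "up").all() or not (
        table.loc[~up, "direction"] == "down"
    ).all():
        raise InputError("direction inconsistent with score sign")
    if not table["score"].is_monotonic_decreasing:
        raise InputError("signature entries must be sorted by descending score")


def read_deg_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a DEG table (TSV/CSV) into the standard (gene, zscore, pvalue) frame.

    Duplicate gene symbols are collapsed keeping the record with the smallest
    p-value; the number of collapsed rows is logged.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(raw.columns)}")
    df = pd.DataFrame(
        {
            "gene": raw[cols["gene"]].astype(str).str.strip(),
            "zscore": _numeric(raw[cols["zscore"]], path, cols["zscore"]),
            "pvalue": _numeric(raw[cols["pvalue"]], path, cols["pvalue"]),
        }
    )
    return validate_deg_table(df)


def validate_deg_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants and collapse duplicate genes (min p wins)."""
    if (df["gene"] == "").any():
        raise InputError("empty gene symbol")
    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    if bad_p.any():
        raise InputError(
            f"pvalue outside (0, 1] for genes {df.loc[bad_p, 'gene'].tolist()[:5]}"
        )
    if not np.isfinite(df["zscore"]).all():
        raise InputError("non-finite zscore")
    n_dup = int(df["gene"].duplicated().sum())
    if n_dup:
        df = (
            df.sort_values("pvalue", kind="stable")
            .drop_duplicates("gene", keep="first")
            .sort_index()
        )
        logger.info("collapsed %d duplicate gene record(s), keeping min p-value", n_dup)
    return df.reset_index(drop=True)


def _numeric(s: pd.Series, path: Path, name: str) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise InputError(f"{path}: non-numeric {name} at row {row}: {s[row]!r}")
    if out.isna().any():
        row = int(out.isna().idxmax())
        raise InputError(f"{path}: missing {name} at row {row}")
    return out


def _drop_zero_z(degs: pd.DataFrame) -> pd.DataFrame:
    zero = degs["zscore"] == 0
    if zero.any():
        logger.warning("excluding %d gene(s) with Z = 0 (no direction)", int(zero.sum()))
    return degs[~zero]


def _finalize(disease: str, method: str, params: dict, sel: pd.DataFrame) -> DiseaseSignature:
    table = pd.DataFrame(
        {
            "gene": sel["gene"].to_numpy(),
            "score": sel["zscore"].to_numpy(float),
            "direction": np.where(sel["zscore"] > 0, "up", "down"),
        }
    )
    # deterministic order: descending score, ties by ascending p then symbol
    order = np.lexsort(
        (table["gene"].to_numpy(), sel["pvalue"].to_numpy(), -table["score"].to_numpy())
    )
    table = table.iloc[order].reset_index(drop=True)
    return DiseaseSignature(disease=disease, method=method, params=params, table=table)


def select_topk(
    degs: pd.DataFrame,
    k: int = 50,
    disease: str = "disease",
    restrict_to: list[str] | None = None,
) -> DiseaseSignature:
    """Top-K rule: the K largest-Z genes (up) and K smallest-Z genes (down).

    Ties in Z break by ascending p-value then gene symbol.  If fewer than K
    genes of a sign exist, only those are taken (with a warning).
    ``restrict_to`` optionally intersects the table with a causal-gene list
    before selection.
    """
    if k < 1:
        raise InputError(f"K must be >= 1, got {k}")
    if len(degs) == 0:
        raise InputError("empty DEG table")
    if restrict_to is not None:
        allowed = {g.upper() for g in restrict_to}
        degs = degs[degs["gene"].str.upper().isin(allowed)]
        if len(degs) == 0:
            raise InputError("restriction list removed every gene")
    degs = _drop_zero_z(degs)
    pos = degs[degs["zscore"] > 0]
    neg = degs[degs["zscore"] < 0]
    if len(pos) < k or len(neg) < k:
        logger.warning(
            "top-K with K=%d: only %d upregulated / %d downregulated genes available",
            k, len(pos), len(neg),
        )
    up = pos.iloc[np.lexsort((pos["gene"], pos["pvalue"], -pos["zscore"]))].head(k)
    down = neg.iloc[np.lexsort((neg["gene"], neg["pvalue"], neg["zscore"]))].head(k)
    return _finalize(disease, "topK", {"K": k}, pd.concat([up, down]))


def select_fdr(degs: pd.DataFrame, q: float = 0.05, disease: str = "disease") -> DiseaseSignature:
    """FDR rule: genes whose Benjamini–Hochberg q-value is below ``q``.

    q-values are computed over every gene in the table; direction comes from
    the sign of Z (Z = 0 genes excluded).
    """
    if not 0 < q < 1:
        raise InputError(f"q must be in (0, 1), got {q}")
    if len(degs) == 0:
        raise InputError("empty DEG table")
    qvals = bh_qvalues(degs["pvalue"].to_numpy(float))
    sel = degs[qvals < q]
    sel = _drop_zero_z(sel)
    return _finalize(disease, "fdr", {"q": q}, sel)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (in input order)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def write_signature(sig: DiseaseSignature, path: str | Path) -> None:
    """Write a signature as TSV with '#' metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# disease={sig.disease}\n")
        fh.write(f"# method={sig.method}\n")
        for key, val in sorted(sig.params.items()):
            fh.write(f"# param:{key}={val}\n")
        sig.table.to_csv(fh, sep="\t", index=False)


def read_signature(path: str | Path) -> DiseaseSignature:
    path = Path(path)
    meta: dict[str, str] = {}
    params: dict = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
        if key.startswith("param:"):
            name = key[len("param:"):]
            try:
                num = float(val)
                params[name] = int(num) if num == int(num) else num
            except ValueError:
                params[name] = val
        else:
            meta[key] = val
    else:
        body_start = len(lines)
    from io import StringIO

    body = "".join(lines[body_start:])
    if not body.strip():
        raise InputError(f"{path}: no header row")
    table = pd.read_csv(StringIO(body), sep="\t")
    expected = {"gene", "score", "direction"}
    if set(table.columns) != expected:
        raise SchemaError(f"{path}: expected columns {sorted(expected)}, got {list(table.columns)}")
    if len(table) == 0:
        logger.warning("%s: empty signature", path)
    sig = DiseaseSignature(
        disease=meta.get("disease", "disease"),
        method=meta.get("method", "topK"),
        params=params,
        table=table,
    )
    return sig
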