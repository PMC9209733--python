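"""Reading and writing GWAS summary statistics and MR result tables.

The canonical dialect is tab-separated with a header row. Source files with
arbitrary column headers are mapped onto the canonical fields through a
``column_map`` (source header -> canonical field name). LD matrices are
accepted either as a labelled square matrix or as long-format triplets.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AssociationRecord,
    ConfigurationError,
    LDMatrix,
    MetaResult,
    MREstimate,
    StudyMeta,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: canonical association fields; the first five are mandatory in any column_map
CANONICAL_FIELDS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "eaf",
    "pvalue",
    "n",
    "n_cases",
    "n_controls",
)
REQUIRED_FIELDS = CANONICAL_FIELDS[:5]

RESULTS_HEADER = [
    "exposure",
    "outcome",
    "method",
    "nsnp",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pvalue",
    "q",
    "i2",
]


def _normalise_column_map(column_map: Optional[Mapping[str, str]], columns: Sequence[str]) -> dict:
    """Return a {canonical_field: source_column} dict, validated against the header."""
    if column_map is None:
        column_map = {c: c for c in columns if c in CANONICAL_FIELDS}
    # accept either orientation: {source: canonical} or {canonical: source}
    canonical_to_source = {}
    for key, value in column_map.items():
        if value in CANONICAL_FIELDS and key not in CANONICAL_FIELDS:
            canonical_to_source[value] = key
        elif key in CANONICAL_FIELDS:
            canonical_to_source[key] = value
        else:
            raise ConfigurationError(
                f"column_map entry {key!r}:{value!r} names no canonical field"
            )
    for fld in REQUIRED_FIELDS:
        if fld not in canonical_to_source:
            raise ConfigurationError(f"column_map does not cover required field {fld!r}")
    for fld, col in canonical_to_source.items():
        if col not in columns:
            raise ConfigurationError(f"mapped column {col!r} (field {fld!r}) absent from file header")
    return canonical_to_source


def read_associations(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    trait_meta: Optional[StudyMeta] = None,
    strict: bool = True,
) -> List[AssociationRecord]:
    """Read one association record per row from a headered delimited file.

    Parameters
    ----------
    path
        Tab-separated (or whitespace-tolerant) file with a header row.
    column_map
        Mapping between source headers and canonical fields (either
        orientation); must cover rsid, alleles, beta and se. When omitted,
        headers are assumed canonical already.
    trait_meta
        Trait label, type and cohort sizes stamped onto every record;
        per-row n/n_cases/n_controls columns take precedence when mapped.
    strict
        In strict mode any invalid row raises ``ValidationError`` naming the
        row and field; in lenient mode the row is skipped with a log entry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns.size == 1 and df.columns[0].count(",") >= 2:
        df = pd.read_csv(path)  # tolerate comma-separated input
    c2s = _normalise_column_map(column_map, list(df.columns))
    meta = trait_meta or StudyMeta(label="", trait="")

    records: List[AssociationRecord] = []
    for idx, row in df.iterrows():
        kwargs = dict(
            trait=meta.trait,
            trait_type=meta.trait_type,
            n=meta.n,
            n_cases=meta.n_cases,
            n_controls=meta.n_controls,
        )
        try:
            for fld, col in c2s.items():
                value = row[col]
                if fld in ("rsid", "effect_allele", "other_allele"):
                    kwargs[fld] = str(value).strip()
                elif fld in ("n", "n_cases", "n_controls"):
                    kwargs[fld] = int(value)
                else:
                    value = float(value)
                    if fld in ("eaf", "pvalue") and math.isnan(value):
                        value = None
                    kwargs[fld] = value
            records.append(AssociationRecord(**kwargs))
        except (ValidationError, ValueError, TypeError) as exc:
            if strict:
                raise ValidationError(f"{path.name} row {idx + 1}: {exc}") from exc
            logger.warning("skipping %s row %d: %s", path.name, idx + 1, exc)
    return records


def _fmt(value, decimals: Optional[int] = None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if decimals is not None:
        return f"{value:.{decimals}f}"
    return f"{value:.6g}"


def write_results_table(
    results: Iterable[Union[MREstimate, MetaResult]],
    path: Union[str, Path],
    or_decimals: int = 2,
) -> Path:
    """Write estimates and/or meta results as a fixed-header TSV.

    Odds-scale columns are rendered at ``or_decimals`` decimal places (the
    convention of published MR tables); log-scale columns keep six
    significant digits.
    """
    path = Path(path)
    lines = ["\t".join(RESULTS_HEADER)]
    for res in results:
        if isinstance(res, MetaResult):
            method, nsnp = f"meta_{res.model}", res.k
            q, i2 = _fmt(res.q), _fmt(res.i2)
        else:
            method, nsnp = res.method, res.n_snps
            q = i2 = "NA"
        lines.append(
            "\t".join(
                [
                    res.exposure or "NA",
                    res.outcome or "NA",
                    method,
                    str(nsnp),
                    _fmt(res.beta),
                    _fmt(res.se),
                    _fmt(res.odds_ratio, or_decimals),
                    _fmt(res.or_ci_low if res.odds_ratio is not None else res.ci_low,
                         or_decimals if res.odds_ratio is not None else None),
                    _fmt(res.or_ci_high if res.odds_ratio is not None else res.ci_high,
                         or_decimals if res.odds_ratio is not None else None),
                    _fmt(res.pvalue),
                    q,
                    i2,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_associations(records: Sequence[AssociationRecord], path: Union[str, Path]) -> Path:
    """Write records in the canonical headered TSV dialect."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_ld_matrix(path: Union[str, Path]) -> LDMatrix:
    """Read an LD r-squared matrix from TSV.

    Two layouts are accepted: a square matrix whose first column and header
    carry rsid labels, or long-format triplets with columns
    (rsid_a, rsid_b, r2); unstated off-diagonal pairs in long format
    default to r2 = 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and "r2" in cols:
        a_col, b_col = df.columns[0], df.columns[1]
        r2_col = df.columns[cols.index("r2")]
        rsids = sorted(set(df[a_col]).union(df[b_col]))
        index = {r: i for i, r in enumerate(rsids)}
        mat = np.eye(len(rsids))
        for _, row in df.iterrows():
            i, j = index[row[a_col]], index[row[b_col]]
            mat[i, j] = mat[j, i] = float(row[r2_col])
        return LDMatrix(rsids, mat)
    df = df.set_index(df.columns[0])
    return LDMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(ld.r2, index=list(ld.rsids), columns=list(ld.rsids))
    df.index.name = "rsid"
    df.to_csv(path, sep="\t", float_format="%.6g")
    return path
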