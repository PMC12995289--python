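"""Tab-separated exchange formats for counts, designs, truth, DE and regulation tables.

All tables are UTF-8 TSV with a mandatory header row, ``.`` decimal and
missing values encoded as empty fields.  Readers validate schemas and report
the offending column or line on failure, so tables exported from other DE
tools can be fed into the classifier with early, explicit errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CountMatrix, DIET_LEVELS, TEMPERATURE_LEVELS

DE_COLUMNS = ["gene_id", "contrast", "log2fc", "se", "wald", "pvalue", "padj"]
DESIGN_COLUMNS = ["sample_id", "diet", "temperature"]
TRUTH_COLUMNS = ["gene_id", "archetype", "beta0", "beta_diet", "beta_temp", "beta_int", "dispersion"]
REGULATION_COLUMNS = [
    "gene_id", "dir_A", "dir_B", "dir_AB", "dir_INT", "mode", "category",
    "expected_l2fc", "synergy_score", "synergy_class",
]


class SchemaError(ValueError):
    """A table does not conform to its declared TSV schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: malformed numeric value {df[col][bad.idxmax()]!r} "
                f"in column '{col}' at line {line}"
            )
        df[col] = converted
    return df


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_counts(counts_path, design_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    _require_columns(df, ["gene_id"], counts_path)
    design = read_design(design_path)
    df = df.set_index("gene_id")
    df.index.name = None
    sample_cols = list(design["sample_id"])
    missing = [s for s in sample_cols if s not in df.columns]
    if missing:
        raise SchemaError(f"{counts_path}: missing sample column(s): {', '.join(missing)}")
    df = df[sample_cols]
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise SchemaError(f"{counts_path}: counts must be integers")
        df = df.round().astype(np.int64)
    return CountMatrix(counts=df, design=design)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DESIGN_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["diet"]) - set(DIET_LEVELS)
    if bad:
        raise SchemaError(f"{path}: invalid diet level(s) {sorted(bad)} in column 'diet'")
    bad = set(df["temperature"]) - set(TEMPERATURE_LEVELS)
    if bad:
        raise SchemaError(f"{path}: invalid temperature level(s) {sorted(bad)} in column 'temperature'")
    if "size_factor" in df.columns:
        df = _coerce_numeric(df, ["size_factor"], path)
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the "null" archetype label is data, not a missing value
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "archetype": str},
        keep_default_na=False, na_values=[""],
    )
    _require_columns(df, TRUTH_COLUMNS, path)
    return _coerce_numeric(df, ["beta0", "beta_diet", "beta_temp", "beta_int", "dispersion"], path)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False, na_rep="")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DE_COLUMNS, path)
    df = _coerce_numeric(df, ["log2fc", "se", "wald", "pvalue", "padj"], path)
    bad = ~df["contrast"].isin(["A", "B", "AB", "INT"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: invalid contrast {df['contrast'][bad.idxmax()]!r} at line {line}"
        )
    return df


def write_regulation(reg: pd.DataFrame, path) -> None:
    reg.to_csv(path, sep="\t", index=False, na_rep="")


def read_regulation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, REGULATION_COLUMNS, path)
    return _coerce_numeric(df, ["expected_l2fc", "synergy_score"], path)
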