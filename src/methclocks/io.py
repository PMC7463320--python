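"""Readers and writers for beta matrices, coefficient sets and sample sheets.

All formats are plain delimited text.  Beta matrices follow the public 450K
matrix convention of probes in rows and samples in columns (a flag
transposes).  Coefficient files are two-column (probe id, weight) tables
with optional ``#key=value`` header lines; the bundled MRscore set ships in
this format.  Missing values are written with a configurable token
(default "NA") and held internally as NaN.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BetaMatrix, CoefficientSet, SampleSheet, SHEET_COLUMNS

log = logging.getLogger(__name__)

ORIENTATIONS = ("probes-in-rows", "samples-in-rows")

#: header keys understood by the coefficient-file parser; ``transform.*``
#: keys carry the constants of a nonlinear output transformation.
_COEF_HEADER_KEYS = ("name", "intercept", "transform")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path: str | Path,
    orientation: str = "probes-in-rows",
    missing_token: str = "NA",
    detection_p_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a delimited beta-value matrix.

    The first column holds row identifiers and the first line column
    identifiers.  Values outside [0, 1] and duplicate identifiers are hard
    errors; the offending cell or label is named in the message.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    values = _read_labelled_matrix(path, missing_token)
    dp = None
    if detection_p_path is not None:
        dp = _read_labelled_matrix(detection_p_path, missing_token)
    if orientation == "samples-in-rows":
        values = values.T
        dp = dp.T if dp is not None else None
    return BetaMatrix(values, dp)


def _read_labelled_matrix(path: str | Path, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        dtype=str,
        na_values=[missing_token],
        keep_default_na=False,
    )
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # astype, unlike to_numeric, parses with correct rounding and so
            # round-trips repr output bit-for-bit
            out[col] = df[col].astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r} of {path}: {exc}") from exc
    return out


def write_beta_matrix(
    m: BetaMatrix,
    path: str | Path,
    orientation: str = "probes-in-rows",
    missing_token: str = "NA",
    detection_p_path: str | Path | None = None,
) -> None:
    """Write a beta matrix (and optionally its detection p-values).

    Floats are written with shortest round-trip representation, so
    ``read_beta_matrix(write_beta_matrix(m))`` reproduces values exactly.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    values = m.values if orientation == "probes-in-rows" else m.values.T
    values.to_csv(path, sep=_sep_for(path), na_rep=missing_token)
    if detection_p_path is not None:
        if m.detection_p is None:
            raise ValueError("matrix has no detection p-values to write")
        dp = m.detection_p if orientation == "probes-in-rows" else m.detection_p.T
        dp.to_csv(detection_p_path, sep=_sep_for(detection_p_path), na_rep=missing_token)


# ---------------------------------------------------------------------------
# coefficient sets
# ---------------------------------------------------------------------------

def parse_coefficients(lines, source: str = "<coefficients>") -> CoefficientSet:
    """Parse coefficient-file lines into a :class:`CoefficientSet`."""
    name = "clock"
    intercept = 0.0
    transform = "identity"
    transform_params: dict[str, float] = {}
    terms: dict[str, float] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise ValueError(f"{source}:{lineno}: malformed header line {line!r}")
            key, _, value = line[1:].partition("=")
            key = key.strip()
            value = value.strip()
            if key == "name":
                name = value
            elif key == "intercept":
                intercept = float(value)
            elif key == "transform":
                transform = value
            elif key.startswith("transform."):
                transform_params[key[len("transform."):]] = float(value)
            else:
                raise ValueError(
                    f"{source}:{lineno}: unknown header key {key!r} "
                    f"(known: {list(_COEF_HEADER_KEYS)} and 'transform.<param>')"
                )
            continue
        fields = line.replace(",", "\t").split("\t")
        fields = [f for f in (fld.strip() for fld in fields) if f]
        if len(fields) != 2:
            raise ValueError(f"{source}:{lineno}: expected two columns, got {fields!r}")
        probe, weight_str = fields
        if probe in terms:
            raise ValueError(f"{source}:{lineno}: duplicate probe id {probe!r}")
        try:
            weight = float(weight_str)
        except ValueError as exc:
            raise ValueError(
                f"{source}:{lineno}: non-numeric weight {weight_str!r} for {probe!r}"
            ) from exc
        terms[probe] = weight
    return CoefficientSet(
        name=name,
        terms=terms,
        intercept=intercept,
        transform=transform,
        transform_params=transform_params,
    )


def read_coefficients(path: str | Path) -> CoefficientSet:
    """Read a clock coefficient file (two columns plus ``#key=value`` headers)."""
    with open(path) as fh:
        return parse_coefficients(fh, source=str(path))


def write_coefficients(c: CoefficientSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={c.name}\n")
        fh.write(f"#intercept={c.intercept!r}\n")
        fh.write(f"#transform={c.transform}\n")
        for key, value in c.transform_params.items():
            fh.write(f"#transform.{key}={value!r}\n")
        for probe, weight in c.terms.items():
            fh.write(f"{probe}\t{weight!r}\n")


def load_bundled_coefficients(name: str = "mrscore") -> CoefficientSet:
    """Load a coefficient set shipped with the package (currently "mrscore")."""
    ref = resources.files("methclocks").joinpath(f"data/{name}.tsv")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"no bundled coefficient set named {name!r}") from exc
    return parse_coefficients(text.splitlines(), source=f"bundled:{name}")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path, missing_token: str = "NA") -> SampleSheet:
    """Read and validate a sample sheet TSV/CSV with the fixed column names."""
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype=str,
        na_values=[missing_token],
        keep_default_na=False,
    )
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    for col in ("tissue_role", "group", "stage", "sex"):
        df[col] = df[col].fillna("unknown" if col in ("stage", "sex") else "none")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, missing_token: str = "NA") -> None:
    sheet.data.to_csv(path, sep=_sep_for(path), index=False, na_rep=missing_token)


# ---------------------------------------------------------------------------
# probe category maps and run configuration
# ---------------------------------------------------------------------------

def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe id, category) file into a dict."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, names=["probe", "category"], dtype=str)
    dup = df["probe"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe id in category map: {df['probe'][dup].iloc[0]!r}")
    return dict(zip(df["probe"], df["category"]))


def write_category_map(cats: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for probe, cat in cats.items():
            fh.write(f"{probe}\t{cat}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep=_sep_for(path), index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
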