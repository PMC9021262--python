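"""CSV schemas and readers/writers for the pipeline's tabular interfaces.

All files are UTF-8 CSV with snake_case headers, "." decimal separator and
empty strings for missing values. See SCHEMAS.md at the repository root for
the column-by-column documentation.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .simulate import SyntheticDataset

__all__ = [
    "CHILDREN_REQUIRED",
    "MACRO_REQUIRED",
    "META_REQUIRED",
    "PROJECTION_REQUIRED",
    "read_children",
    "read_macro",
    "read_meta",
    "read_projection_input",
    "write_dataset",
    "read_dataset",
]

CHILDREN_REQUIRED = (
    "country",
    "region",
    "round_id",
    "interview_year",
    "interview_month",
    "age_months",
    "design_weight",
)

MACRO_REQUIRED = ("country", "year")

META_REQUIRED = ("country", "region", "pop_u5")

PROJECTION_REQUIRED = ("country", "g2020", "g_decade_mean", "prev2019", "pop_u5")


def _require(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing required columns: {missing}")


def read_children(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CHILDREN_REQUIRED, "children table")
    if not df["interview_month"].between(1, 12).all():
        raise ValidationError("interview_month outside 1-12")
    if not df["age_months"].between(0, 59).all():
        raise ValidationError("age_months outside 0-59")
    if (df["design_weight"] <= 0).any():
        raise ValidationError("non-positive design weights")
    return df


def read_macro(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, MACRO_REQUIRED, "macro table")
    has_levels = {"gni_pc", "gdp_pc"} & set(df.columns)
    has_growth = {"gni_growth", "gdp_growth"} & set(df.columns)
    if not has_levels and not has_growth:
        raise ValidationError(
            "macro table needs level columns (gni_pc/gdp_pc) or growth columns"
        )
    return df


def read_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, META_REQUIRED, "countries table")
    if (df["pop_u5"] <= 0).any():
        raise ValidationError("pop_u5 must be positive")
    return df


def read_projection_input(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PROJECTION_REQUIRED, "projection input")
    return df


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write children.csv, macro.csv, countries.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "children": outdir / "children.csv",
        "macro": outdir / "macro.csv",
        "countries": outdir / "countries.csv",
        "truth": outdir / "truth.json",
    }
    ds.children.to_csv(paths["children"], index=False)
    ds.macro.to_csv(paths["macro"], index=False)
    ds.meta.to_csv(paths["countries"], index=False)
    paths["truth"].write_text(json.dumps(ds.truth, indent=2, sort_keys=True))
    return paths


def read_dataset(outdir: str | Path) -> SyntheticDataset:
    """Round-trip companion to :func:`write_dataset`."""
    outdir = Path(outdir)
    truth_path = outdir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticDataset(
        children=read_children(outdir / "children.csv"),
        macro=read_macro(outdir / "macro.csv"),
        meta=read_meta(outdir / "countries.csv"),
        truth=truth,
    )
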