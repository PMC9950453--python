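"""Delimited-text readers and writers for peak tables and sample metadata.

Both comma- and tab-delimited files are accepted (auto-detected from the
header line); all writers emit tab-delimited text.  The peak-table layout is
compounds as rows by default: a header row of sample IDs and a first column
of ``mass@retention-time`` compound labels.
"""

from __future__ import annotations

import enum
from pathlib import Path

import pandas as pd

from .datatypes import (
    BodySite,
    CompoundID,
    PeakTable,
    SampleMetadata,
    Sex,
    Stage,
)

__all__ = [
    "Orientation",
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "write_metadata",
]


class Orientation(str, enum.Enum):
    COMPOUNDS_AS_ROWS = "compounds_as_rows"
    SAMPLES_AS_ROWS = "samples_as_rows"


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_peak_table(
    path: str | Path,
    orientation: Orientation | str = Orientation.COMPOUNDS_AS_ROWS,
) -> PeakTable:
    """Read a raw peak table from delimited text.

    Rejects negative or unparsable cells (naming the offending cell) and
    duplicate compound or sample IDs; input ordering is preserved.
    """
    path = Path(path)
    orientation = Orientation(orientation)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    if orientation is Orientation.SAMPLES_AS_ROWS:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate compound ID {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise ValueError(
                f"unparsable abundance at compound {row!r}, sample {col!r} in {path}"
            )
        values[col] = parsed
    neg = values.lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = neg.index[neg[col]][0]
        raise ValueError(
            f"negative abundance at compound {row!r}, sample {col!r} in {path}"
        )
    compounds = [CompoundID(str(label)) for label in values.index]
    return PeakTable(compounds, [str(s) for s in values.columns],
                     values.to_numpy(), Stage.RAW)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a peak table as tab-delimited text, compounds as rows."""
    table.to_frame().to_csv(Path(path), sep="\t", index_label="compound")


_REQUIRED_META_COLS = (
    "sample_id",
    "individual_id",
    "sex",
    "age_years",
    "body_site",
    "replicate",
)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata from delimited text.

    Required columns: sample_id, individual_id, sex, age_years, body_site,
    replicate.  An optional ``age_class`` column is validated against the
    age rule; when missing it is derived.  Enum tokens are case-insensitive.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = [c for c in _REQUIRED_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    records = []
    for _, row in df.iterrows():
        try:
            sex = Sex(row["sex"].strip().upper())
        except ValueError:
            raise ValueError(
                f"sample {row['sample_id']!r}: unknown sex token {row['sex']!r}"
            ) from None
        try:
            site = BodySite(row["body_site"].strip().lower())
        except ValueError:
            raise ValueError(
                f"sample {row['sample_id']!r}: unknown body_site token "
                f"{row['body_site']!r}"
            ) from None
        kwargs = {}
        if "age_class" in df.columns and isinstance(row.get("age_class"), str):
            from .datatypes import AgeClass

            kwargs["age_class"] = AgeClass(row["age_class"].strip().lower())
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                individual_id=str(row["individual_id"]),
                sex=sex,
                age_years=int(row["age_years"]),
                body_site=site,
                replicate=int(row["replicate"]),
                **kwargs,
            )
        )
    return records


def write_metadata(metadata: list[SampleMetadata], path: str | Path) -> None:
    from .datatypes import metadata_frame

    metadata_frame(metadata).drop(columns=["age_sex_class"]).to_csv(
        Path(path), sep="\t", index=False
    )
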