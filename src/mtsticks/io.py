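"""CSV input/output for section-count tables.

Schema: UTF-8 CSV with header ``animal_id,genotype,section_position_um,count``;
counts are non-negative integers, positions decimal µm.  Parse errors name
the offending row (1-based, excluding the header).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stick_model import SECTION_COLUMNS

__all__ = ["read_section_counts", "write_section_counts"]


class SectionCountsParseError(ValueError):
    """A section-count CSV violated the schema."""


def read_section_counts(path: str | Path) -> pd.DataFrame:
    """Read a section-count table, validating the schema row by row.

    Row order is preserved; counts come back as integers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SectionCountsParseError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(SECTION_COLUMNS)}"
        )
    counts = []
    positions = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw_count = getattr(row, "count")
        try:
            count = int(raw_count)
        except (TypeError, ValueError):
            raise SectionCountsParseError(
                f"{path}: row {i}: count {raw_count!r} is not an integer"
            ) from None
        if str(count) != str(raw_count).strip():
            raise SectionCountsParseError(
                f"{path}: row {i}: count {raw_count!r} is not an integer"
            )
        if count < 0:
            raise SectionCountsParseError(
                f"{path}: row {i}: count {count} is negative"
            )
        try:
            pos = float(row.section_position_um)
        except (TypeError, ValueError):
            raise SectionCountsParseError(
                f"{path}: row {i}: section_position_um "
                f"{row.section_position_um!r} is not a number"
            ) from None
        counts.append(count)
        positions.append(pos)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"].astype(str),
            "genotype": df["genotype"].astype(str),
            "section_position_um": positions,
            "count": counts,
        },
        columns=SECTION_COLUMNS,
    )
    return out


def write_section_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a section-count table in the canonical column order."""
    counts.loc[:, SECTION_COLUMNS].to_csv(path, index=False)
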