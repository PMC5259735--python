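"""Long-format trait datasets and delimited-text I/O.

A :class:`Dataset` holds one measured value per plant per day per trait in
long format (columns ``plant_id, line_id, day, trait, value``), together
with the pedigree of the four lines.  Validation rejects duplicate
(plant, day, trait) records, non-finite values, negative days and line ids
absent from the pedigree, reporting offending row numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grouping import LineDefinition, default_lines

__all__ = ["Dataset", "load_dataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("plant_id", "line_id", "day", "trait", "value")


@dataclass
class Dataset:
    """Validated long-format trait table plus the line pedigree."""

    records: pd.DataFrame
    lines: Mapping[str, LineDefinition] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lines:
            self.lines = {l.line_id: l for l in default_lines()}
        elif not isinstance(self.lines, Mapping):
            self.lines = {l.line_id: l for l in self.lines}
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["plant_id"] = df["plant_id"].astype(str)
        df["line_id"] = df["line_id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["day"] = pd.to_numeric(df["day"], errors="coerce")
        df["value"] = pd.to_numeric(df["value"], errors="coerce")

        bad = df.index[~np.isfinite(df["value"]) | ~np.isfinite(df["day"])]
        if len(bad):
            raise ValueError(
                f"non-finite day/value in rows {list(bad[:10])}"
                + ("..." if len(bad) > 10 else ""))
        neg = df.index[df["day"] < 0]
        if len(neg):
            raise ValueError(f"negative day in rows {list(neg[:10])}")
        dup = df.duplicated(subset=["plant_id", "day", "trait"], keep=False)
        if dup.any():
            rows = list(df.index[dup][:10])
            raise ValueError(
                f"duplicate (plant_id, day, trait) records in rows {rows}"
                + ("..." if dup.sum() > 10 else ""))
        unknown = sorted(set(df["line_id"]) - set(self.lines))
        if unknown:
            raise ValueError(f"line_id(s) {unknown} not declared in the "
                             "pedigree")
        self.records = df.reset_index(drop=True)

    @property
    def traits(self) -> tuple:
        return tuple(sorted(self.records["trait"].unique()))

    def subset(self, trait: str) -> pd.DataFrame:
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise ValueError(f"no records for trait {trait!r}")
        return sub.reset_index(drop=True)

    def to_csv(self, path) -> None:
        """Write the canonical comma-separated, '.'-decimal format."""
        self.records.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


def load_dataset(path, lines: Iterable[LineDefinition] | None = None
                 ) -> Dataset:
    """Read and validate a delimited long-format trait table.

    The file must be comma-separated UTF-8 text with a header row carrying
    the canonical column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    return Dataset(df, lines={l.line_id: l for l in lines} if lines else {})
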