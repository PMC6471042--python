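"""Genomic interval sets (0-based, half-open; strand-free)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .genome import GenomeLayout

__all__ = ["IntervalSet"]

_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass
class IntervalSet:
    """A list of (chrom, start, end, optional name) intervals.

    Backed by a pandas DataFrame with columns chrom/start/end/name. When a
    layout is supplied, intervals are checked to lie within their chromosome.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "name" not in df.columns:
            df = df.assign(name=None)
        df = df.loc[:, _COLUMNS].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise CoordinateError(f"interval with start >= end: {row.chrom}:{row.start}-{row.end}")
        if (df["start"] < 0).any():
            raise CoordinateError("interval with negative start")
        self.frame = df

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        layout: Optional[GenomeLayout] = None,
    ) -> "IntervalSet":
        rows = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 else None
            rows.append((str(chrom), start, end, name))
        obj = cls(pd.DataFrame(rows, columns=_COLUMNS))
        if layout is not None:
            obj.check_layout(layout)
        return obj

    def check_layout(self, layout: GenomeLayout) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            length = layout.length_of(str(chrom))
            if int(sub["end"].max()) > length:
                raise CoordinateError(
                    f"interval ends at {int(sub['end'].max())} beyond {chrom!r} length {length}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[tuple[str, int, int, object]]:
        for row in self.frame.itertuples(index=False):
            yield (row.chrom, int(row.start), int(row.end), row.name)

    def restrict_to(self, layout: GenomeLayout) -> "IntervalSet":
        """Drop intervals on chromosomes absent from ``layout``."""
        keep = self.frame["chrom"].isin(layout.names)
        return IntervalSet(self.frame[keep].reset_index(drop=True))
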