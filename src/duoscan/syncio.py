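"""Reading and writing PoPoolation2 "sync" Pool-Seq count files.

A sync file is tab-separated with three leading columns (chromosome/arm,
1-based position, reference base) followed by one column per sequenced
sample holding colon-separated counts ``A:T:C:G:N:del``.  No installed
library parses this format, so the (trivial) parser lives here.

Coverage convention: coverage = A+T+C+G; ``N`` and deletion counts are
excluded, matching common sync-handling practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MarkerCatalog

logger = logging.getLogger(__name__)

#: column order of the six count fields in a sync entry
SYNC_FIELDS = ("A", "T", "C", "G", "N", "del")
NUC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3}


class SyncFormatError(ValueError):
    """Raised on malformed sync input, with the offending line number."""


@dataclass
class CountTable:
    """Per-sample, per-marker nucleotide counts aligned to a catalogue.

    ``counts`` has shape ``(n_markers, n_samples, 6)`` in ``A,T,C,G,N,del``
    order; ``missing`` flags markers absent from a sample's input.
    """

    catalog: MarkerCatalog
    counts: np.ndarray
    samples: list[str]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n, s = len(self.catalog), len(self.samples)
        if self.counts.shape != (n, s, 6):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {s}, 6)"
            )
        if self.missing is None:
            self.missing = np.zeros((n, s), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        """Read depth per marker and sample: A+T+C+G (N/del excluded)."""
        return self.counts[:, :, :4].sum(axis=2)


def read_sync(path, catalog: MarkerCatalog, samples: list[str] | None = None) -> CountTable:
    """Read a sync file, returning counts at catalogue markers in catalogue order.

    Markers absent from the file are flagged missing.  Lines on
    chromosomes/arms not present in the catalogue are skipped with a
    warning; malformed count columns raise :class:`SyncFormatError` naming
    the line.
    """
    frame = catalog.frame
    row_of = {
        (a, p): i
        for i, (a, p) in enumerate(zip(frame["arm"], frame["position"]))
    }
    known_arms = set(catalog.arms)

    n_samples: int | None = None
    rows: list[int] = []
    payload: list[list[int]] = []
    skipped_arms: set[str] = set()

    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SyncFormatError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns"
                )
            arm, pos_str = parts[0], parts[1]
            if arm not in known_arms:
                skipped_arms.add(arm)
                continue
            if n_samples is None:
                n_samples = len(parts) - 3
            elif len(parts) - 3 != n_samples:
                raise SyncFormatError(
                    f"{path}:{lineno}: inconsistent sample column count"
                )
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise SyncFormatError(f"{path}:{lineno}: bad position {pos_str!r}") from exc
            row = row_of.get((arm, pos))
            if row is None:
                continue  # site not in the marker catalogue
            entry: list[int] = []
            for col in parts[3:]:
                fields = col.split(":")
                if len(fields) != 6:
                    raise SyncFormatError(
                        f"{path}:{lineno}: count column {col!r} has "
                        f"{len(fields)} fields, expected 6"
                    )
                try:
                    entry.extend(int(x) for x in fields)
                except ValueError as exc:
                    raise SyncFormatError(
                        f"{path}:{lineno}: non-integer count in {col!r}"
                    ) from exc
            rows.append(row)
            payload.append(entry)

    if skipped_arms:
        logger.warning(
            "%s: skipped lines on chromosomes not in catalogue: %s",
            path,
            sorted(skipped_arms),
        )
    if n_samples is None:
        raise SyncFormatError(f"{path}: no parseable sample columns found")

    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    elif len(samples) != n_samples:
        raise ValueError(
            f"{len(samples)} sample names given but file has {n_samples} columns"
        )

    counts = np.zeros((len(catalog), n_samples, 6), dtype=np.int64)
    missing = np.ones((len(catalog), n_samples), dtype=bool)
    if rows:
        idx = np.asarray(rows)
        counts[idx] = np.asarray(payload, dtype=np.int64).reshape(len(rows), n_samples, 6)
        missing[idx] = False
    return CountTable(catalog, counts, list(samples), missing)


def write_sync(table: CountTable, path) -> None:
    """Write a CountTable as a sync file (one line per non-missing marker).

    The reference-base column holds the catalogue's focal allele; it is
    ignored on reading, so ``read_sync(write_sync(x))`` restores counts
    exactly.  Markers missing in *every* sample are omitted from the file.
    """
    frame = table.catalog.frame
    all_missing = table.missing.all(axis=1)
    with open(path, "wt") as handle:
        for i in range(len(frame)):
            if all_missing[i]:
                continue
            cols = [
                str(frame["arm"].iloc[i]),
                str(frame["position"].iloc[i]),
                str(frame["focal_allele"].iloc[i]),
            ]
            for j in range(table.n_samples):
                cols.append(":".join(str(c) for c in table.counts[i, j]))
            handle.write("\t".join(cols) + "\n")


def sync_to_frame(table: CountTable) -> pd.DataFrame:
    """Tidy per-marker, per-sample counts (mainly for inspection/tests)."""
    frames = []
    for j, name in enumerate(table.samples):
        df = table.catalog.frame[["arm", "position"]].copy()
        for k, fieldname in enumerate(SYNC_FIELDS):
            df[fieldname] = table.counts[:, j, k]
        df["sample"] = name
        df["missing"] = table.missing[:, j]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
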