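"""Recombination maps and per-chromosome genetic coordinates.

A :class:`RecombinationMap` lists intervals (arm, start, end, rate in
cM/Mb).  For simulation, the arms of each chromosome are concatenated
(same convention as windowing) and turned into a piecewise-linear
cumulative genetic map (Morgans as a function of the concatenated
physical coordinate), which supports crossover placement by inverse-CDF
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAP_COLUMNS = ["arm", "start", "end", "rate_cm_per_mb"]

MORGAN_PER_CM = 0.01
BP_PER_MB = 1e6


class MapError(ValueError):
    pass


@dataclass
class RecombinationMap:
    """Interval rates: ``start`` inclusive, ``end`` exclusive, 1-based bp."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.frame.columns]
        if missing:
            raise MapError(f"map lacks columns {missing}")
        f = self.frame[MAP_COLUMNS].reset_index(drop=True).copy()
        f["start"] = f["start"].astype(np.int64)
        f["end"] = f["end"].astype(np.int64)
        if (f["rate_cm_per_mb"] < 0).any():
            raise MapError("negative recombination rates")
        for arm, grp in f.groupby("arm", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if np.any(e <= s):
                raise MapError(f"empty or inverted interval on arm {arm}")
            if np.any(s[1:] < e[:-1]):
                raise MapError(f"overlapping/unsorted intervals on arm {arm}")
        self.frame = f

    @classmethod
    def uniform(cls, arm_rates: dict[str, float], arm_lengths: dict[str, int]) -> "RecombinationMap":
        """One constant-rate interval per arm covering [1, length]."""
        rows = [
            {"arm": a, "start": 1, "end": arm_lengths[a] + 1, "rate_cm_per_mb": r}
            for a, r in arm_rates.items()
        ]
        return cls(pd.DataFrame(rows))

    def arm_length(self, arm: str) -> int:
        grp = self.frame[self.frame["arm"] == arm]
        if grp.empty:
            raise MapError(f"arm {arm} not covered by the map")
        return int(grp["end"].max() - 1)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"arm": str}))


@dataclass
class GeneticMap:
    """Cumulative genetic map of one chromosome (arms concatenated).

    ``phys`` (bp, float) and ``gen`` (Morgans) are matched breakpoints of a
    piecewise-linear, non-decreasing map.  ``arm_offsets`` maps each arm to
    the physical offset applied when concatenating.
    """

    phys: np.ndarray
    gen: np.ndarray
    arm_offsets: dict[str, int]

    @property
    def total_morgans(self) -> float:
        return float(self.gen[-1])

    @property
    def length_bp(self) -> float:
        return float(self.phys[-1])

    def to_morgans(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.phys, self.gen)

    def to_phys(self, g: np.ndarray) -> np.ndarray:
        # flat (zero-rate) stretches invert to their left edge, which is a
        # measure-zero event for crossover placement
        return np.interp(g, self.gen, self.phys)


def build_genetic_map(rmap: RecombinationMap, arms: list[str]) -> GeneticMap:
    """Concatenate ``arms`` (in order) into one chromosome-level genetic map."""
    phys = [0.0]
    gen = [0.0]
    offsets: dict[str, int] = {}
    offset = 0
    for arm in arms:
        grp = rmap.frame[rmap.frame["arm"] == arm]
        if grp.empty:
            raise MapError(f"arm {arm} not covered by the recombination map")
        offsets[arm] = offset
        if int(grp["start"].min()) != 1:
            raise MapError(f"map for arm {arm} must start at position 1")
        prev_end = 1
        for _, row in grp.iterrows():
            if row["start"] != prev_end:
                raise MapError(f"gap in map coverage on arm {arm} at {prev_end}")
            span_bp = row["end"] - row["start"]
            d_morgan = row["rate_cm_per_mb"] * MORGAN_PER_CM * span_bp / BP_PER_MB
            phys.append(float(offset + row["end"] - 1))
            gen.append(gen[-1] + d_morgan)
            prev_end = int(row["end"])
        offset += int(grp["end"].max() - 1)
    return GeneticMap(np.asarray(phys), np.asarray(gen), offsets)
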