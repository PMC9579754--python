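"""Non-overlapping w-SNP windows and windowed allele-frequency change (AFC).

Markers are grouped into windows of exactly ``w`` consecutive SNPs per
chromosome, with the arms of a chromosome concatenated in arm order (2L
then 2R, 3L then 3R) before windowing — the scheme that reproduces the
published window totals — so windows may span the centromere.  The
trailing partial window of each chromosome is dropped by default.

The windowed AFC of a replicate is the unweighted mean marker frequency in
the window minus the starting frequency ``p0``; positive AFC means the
focal founder's allele rose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MarkerCatalog
from .frequencies import AlleleFrequencyTable

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ["chromosome", "window", "start", "stop", "n_markers", "center", "partial"]


@dataclass
class WindowIndex:
    """Windows of ``w`` consecutive markers, chromosome arms concatenated.

    ``frame`` rows hold: chromosome, window ordinal (0-based within the
    chromosome), ``start``/``stop`` marker-row bounds into the catalogue
    (half-open), marker count, the window centre on the concatenated-arm
    coordinate, and a ``partial`` flag (only present when partial windows
    are kept, for diagnostics).
    """

    catalog: MarkerCatalog
    frame: pd.DataFrame
    w: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chromosome"]))

    def counts_by_chromosome(self) -> pd.Series:
        return self.frame.groupby("chromosome", sort=False).size()

    def member_rows(self, i: int) -> np.ndarray:
        row = self.frame.iloc[i]
        return np.arange(row["start"], row["stop"])

    def mean_center_spacing(self, chromosome: str) -> float:
        """Mean distance between adjacent window centres on a chromosome."""
        centers = self.frame.loc[
            self.frame["chromosome"] == chromosome, "center"
        ].to_numpy()
        if len(centers) < 2:
            raise ValueError(f"chromosome {chromosome} has fewer than 2 windows")
        return float(np.diff(centers).mean())


def assign_windows(
    catalog: MarkerCatalog,
    w: int,
    exclude_chromosomes: tuple[str, ...] = ("4",),
    keep_partial: bool = False,
) -> WindowIndex:
    """Partition catalogue markers into ``w``-SNP windows per chromosome.

    Each chromosome contributes ``floor(n_markers / w)`` complete windows;
    the trailing remainder is dropped unless ``keep_partial`` flags it for
    diagnostics.  Chromosome 4 is excluded by default (too few markers to
    window in the fly catalogue).
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    offsets = catalog.arm_offsets()
    frame = catalog.frame
    gpos = frame["position"].to_numpy() + frame["arm"].map(offsets).to_numpy()

    records = []
    for chrom, grp in frame.groupby("chromosome", sort=False):
        if chrom in exclude_chromosomes:
            continue
        lo, hi = grp.index[0], grp.index[-1] + 1
        n = hi - lo
        n_full = n // w
        for i in range(n_full):
            start, stop = lo + i * w, lo + (i + 1) * w
            records.append(
                (chrom, i, start, stop, w, (gpos[start] + gpos[stop - 1]) / 2.0, False)
            )
        if keep_partial and n % w:
            start, stop = lo + n_full * w, hi
            records.append(
                (
                    chrom,
                    n_full,
                    start,
                    stop,
                    stop - start,
                    (gpos[start] + gpos[stop - 1]) / 2.0,
                    True,
                )
            )
    if not records:
        logger.warning("window size w=%d exceeds every chromosome's marker count", w)
    out = pd.DataFrame(records, columns=WINDOW_COLUMNS)
    return WindowIndex(catalog, out, w)


def window_means(values: np.ndarray, index: WindowIndex) -> np.ndarray:
    """Per-window unweighted means of a per-marker matrix ``(n_markers, k)``.

    NaN markers are skipped; a window that is all-NaN in a column yields
    NaN there.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(index.catalog):
        values = values.T
    out = np.empty((len(index), values.shape[1]))
    starts = index.frame["start"].to_numpy()
    stops = index.frame["stop"].to_numpy()
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for i in range(len(index)):
            block = values[starts[i] : stops[i]]
            out[i] = np.nanmean(block, axis=0) if len(block) else np.nan
    return out


@dataclass
class WindowTable:
    """Windowed frequencies and AFCs for all samples of an experiment.

    ``freq`` and ``afc`` are ``(n_windows, n_samples)``; windows where any
    sample had no measurable marker are flagged in ``window_missing`` and
    excluded from downstream testing.
    """

    index: WindowIndex
    samples: pd.DataFrame
    freq: np.ndarray
    afc: np.ndarray
    p0: float

    @property
    def window_missing(self) -> np.ndarray:
        return np.isnan(self.freq).any(axis=1)

    def columns_for(self, temperature: int) -> np.ndarray:
        meta = self.samples
        sel = meta.index[meta["temperature"] == temperature]
        if len(sel) == 0:
            raise ValueError(f"no samples at temperature {temperature}")
        order = np.argsort(meta.loc[sel, "replicate"].to_numpy(), kind="stable")
        return sel.to_numpy()[order]

    def replicate_afc(self, temperature: int) -> np.ndarray:
        """Per-replicate window AFCs ``(n_windows, n_replicates)``."""
        return self.afc[:, self.columns_for(temperature)]

    def replicate_freq(self, temperature: int) -> np.ndarray:
        return self.freq[:, self.columns_for(temperature)]

    def mean_afc(self, temperature: int) -> np.ndarray:
        return self.replicate_afc(temperature).mean(axis=1)

    def se_afc(self, temperature: int) -> np.ndarray:
        reps = self.replicate_afc(temperature)
        return reps.std(axis=1, ddof=1) / np.sqrt(reps.shape[1])

    def ci_afc(self, temperature: int) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence interval: mean +/- 1.96 standard errors."""
        m, se = self.mean_afc(temperature), self.se_afc(temperature)
        return m - 1.96 * se, m + 1.96 * se

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-temperature export (replicate AFCs, mean, s.e., CI)."""
        rows = []
        for temp in sorted(set(self.samples["temperature"])):
            reps = self.replicate_afc(temp)
            mean, se = self.mean_afc(temp), self.se_afc(temp)
            lo, hi = self.ci_afc(temp)
            df = self.index.frame[["chromosome", "window", "center"]].copy()
            for r in range(reps.shape[1]):
                df[f"afc_rep{r + 1}"] = reps[:, r]
            df["mean_afc"] = mean
            df["se"] = se
            df["ci_low"] = lo
            df["ci_high"] = hi
            df["temperature"] = temp
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def window_afc(
    freqs: AlleleFrequencyTable,
    index: WindowIndex,
    p0: float = 0.3,
) -> WindowTable:
    """Windowed mean frequencies and AFCs for every sample.

    Marker-level missingness inside a window is tolerated (mean over
    available markers); a window in which some sample has *no* available
    marker is flagged missing as a whole.
    """
    freq = window_means(freqs.freq, index)
    afc = freq - p0
    n_bad = int(np.isnan(freq).any(axis=1).sum())
    if n_bad:
        logger.info("%d windows flagged missing (no measurable marker in a sample)", n_bad)
    return WindowTable(index, freqs.samples.copy(), freq, afc, p0)
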