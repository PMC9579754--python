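"""Spatial autocorrelation of windowed frequencies along chromosomes.

The sample autocorrelation of the window-frequency series quantifies how
far linkage carries allele-frequency information along a chromosome in a
two-founder cross; the lag at which it first drops below the 5%
significance bound ``1.96/sqrt(n)`` (n windows) is a rough proxy for the
decorrelation distance, converted to base pairs with the mean spacing of
window centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from .windows import WindowTable

logger = logging.getLogger(__name__)


@dataclass
class AcfProfile:
    """Autocorrelation by lag for one window series."""

    lags: np.ndarray
    acf: np.ndarray
    n: int
    bound: float
    first_below: int | None
    distance_bp: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "acf": self.acf,
                "bound": self.bound,
                "below_bound": self.acf < self.bound,
            }
        )


def acf_profile(
    series,
    max_lag: int | None = None,
    center_spacing: float | None = None,
) -> AcfProfile:
    """Sample autocorrelation (mean-centred, lag-0 normalized) of a series.

    Records the smallest lag ``k >= 1`` with ``acf(k) < 1.96/sqrt(n)``;
    ``center_spacing`` (bp between adjacent window centres) converts that
    lag to a physical distance.  Constant series raise (undefined
    correlation).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant series: autocorrelation undefined")
    n = len(x)
    if max_lag is None:
        max_lag = min(n - 1, int(np.ceil(10 * np.log10(n))))
    max_lag = min(max_lag, n - 1)
    vals = _sm_acf(x, nlags=max_lag, adjusted=False, fft=False)
    lags = np.arange(max_lag + 1)
    bound = 1.96 / np.sqrt(n)
    below = np.flatnonzero(vals[1:] < bound)
    first = int(below[0]) + 1 if len(below) else None
    distance = (
        first * center_spacing if (first is not None and center_spacing) else None
    )
    return AcfProfile(lags, vals, n, bound, first, distance)


def acf_profiles(
    wtable: WindowTable,
    temperatures: tuple[int, ...] = (18, 29),
    max_lag: int | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-chromosome, per-replicate ACF of window frequencies (tidy frame).

    With ``pooled=True`` the replicate-mean frequency series is used
    instead of individual replicates.
    """
    idx = wtable.index.frame
    rows = []
    for temp in temperatures:
        freq = wtable.replicate_freq(temp)
        series_set = (
            {"pooled": freq.mean(axis=1)}
            if pooled
            else {f"rep{r + 1}": freq[:, r] for r in range(freq.shape[1])}
        )
        for chrom in dict.fromkeys(idx["chromosome"]):
            mask = (idx["chromosome"] == chrom).to_numpy()
            if mask.sum() < 3:
                logger.info("chromosome %s: fewer than 3 windows, skipped", chrom)
                continue
            spacing = wtable.index.mean_center_spacing(chrom)
            for name, series in series_set.items():
                s = series[mask]
                s = s[~np.isnan(s)]
                if len(s) < 3 or np.ptp(s) == 0:
                    logger.info(
                        "chromosome %s %s: series too short or constant, skipped",
                        chrom, name,
                    )
                    continue
                prof = acf_profile(s, max_lag=max_lag, center_spacing=spacing)
                df = prof.to_frame()
                df.insert(0, "chromosome", chrom)
                df.insert(1, "replicate", name)
                df.insert(2, "temperature", temp)
                df["first_below"] = prof.first_below
                df["distance_bp"] = prof.distance_bp
                rows.append(df)
    return pd.concat(rows, ignore_index=True)
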