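"""Neutrality testing, temperature-contrast model and six-class labels.

Each window is tested per temperature against a simulated drift null
(empirical, direction-conditional p-values pooled per chromosome), the
two temperatures are contrasted with a per-window linear model (AFC ~
temperature, equivalent to a pooled-variance two-sample t-test), and
every window receives exactly one of six labels:

========================  ==============================================
label                     meaning
========================  ==============================================
drift_only                no significant change at either temperature
change_18C_only           significant only at 18 degrees C
change_29C_only           significant only at 29 degrees C
no_temperature_effect     significant at both, no significant contrast
different_magnitude       both + significant contrast, same direction
different_direction       both + significant contrast, opposite alleles
========================  ==============================================

Direction is taken from the signs of the observed replicate-mean AFCs at
the two temperatures (not from the sign pair of the model coefficients,
which would mislabel same-direction-but-smaller responses); see the
methods note for the rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .windows import WindowTable

logger = logging.getLogger(__name__)

CLASS_DRIFT = "drift_only"
CLASS_18_ONLY = "change_18C_only"
CLASS_29_ONLY = "change_29C_only"
CLASS_NO_TEMP = "no_temperature_effect"
CLASS_MAGNITUDE = "different_magnitude"
CLASS_DIRECTION = "different_direction"

CLASS_LABELS = [
    CLASS_DRIFT,
    CLASS_18_ONLY,
    CLASS_29_ONLY,
    CLASS_NO_TEMP,
    CLASS_MAGNITUDE,
    CLASS_DIRECTION,
]


@dataclass
class NullDistribution:
    """Simulated neutral window-mean AFCs, pooled per chromosome.

    ``frame`` keeps run/window provenance (chromosome, run, window, afc);
    :meth:`values` returns the pooled, sorted AFC values of a chromosome.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"chromosome", "run", "window", "afc"}
        if not needed <= set(self.frame.columns):
            raise ValueError(f"null frame needs columns {sorted(needed)}")
        self._sorted: dict[str, np.ndarray] = {}

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chromosome"]))

    def values(self, chromosome: str) -> np.ndarray:
        if chromosome not in self._sorted:
            v = self.frame.loc[
                self.frame["chromosome"] == chromosome, "afc"
            ].to_numpy(float)
            if len(v) == 0:
                raise ValueError(f"empty null distribution for chromosome {chromosome}")
            self._sorted[chromosome] = np.sort(v)
        return self._sorted[chromosome]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NullDistribution":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def empirical_pvalue(observed, null_values) -> np.ndarray | float:
    """Direction-conditional empirical p-value against a simulated null.

    For a positive observation, the fraction of null values strictly
    greater; for a negative one, the fraction strictly smaller; an exact
    zero maps to p = 1 (no evidence of change).  No pseudocount is added,
    so p = 0 is a legal outcome.
    """
    null_sorted = np.sort(np.asarray(null_values, dtype=float))
    n = len(null_sorted)
    if n == 0:
        raise ValueError("empty null distribution")
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    p = np.ones_like(obs)
    pos = obs > 0
    neg = obs < 0
    p[pos] = (n - np.searchsorted(null_sorted, obs[pos], side="right")) / n
    p[neg] = np.searchsorted(null_sorted, obs[neg], side="left") / n
    return p if np.ndim(observed) else float(p[0])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LMResult:
    """Per-window linear-model estimates: AFC ~ temperature (18 reference).

    ``alpha_intercept`` is the 18-degree mean AFC; ``alpha_temperature``
    the 29-minus-18 contrast; ``p`` the two-sided p-value of the contrast
    (pooled-variance two-sample t, df = 2(R-1)).
    """

    alpha_intercept: np.ndarray
    alpha_temperature: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray


def fit_window_lm(afc18: np.ndarray, afc29: np.ndarray) -> LMResult:
    """Fit AFC ~ temperature per window (vectorized over windows).

    Accepts ``(n_windows, R)`` arrays (or single-window triplets).  With a
    categorical two-level factor the OLS contrast p-value equals the
    pooled-variance two-sample t-test, which is computed directly.  Zero
    pooled variance yields p = 1 when the contrast is 0 and p = 0
    otherwise.
    """
    a18 = np.atleast_2d(np.asarray(afc18, dtype=float))
    a29 = np.atleast_2d(np.asarray(afc29, dtype=float))
    if a18.shape != a29.shape:
        raise ValueError("replicate AFC arrays must have matching shapes")
    r = a18.shape[1]
    if r < 2:
        raise ValueError("need at least two replicates per temperature")
    m18 = a18.mean(axis=1)
    m29 = a29.mean(axis=1)
    contrast = m29 - m18
    df = 2 * (r - 1)
    sp2 = (a18.var(axis=1, ddof=1) + a29.var(axis=1, ddof=1)) / 2.0
    se = np.sqrt(sp2 * 2.0 / r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # identical replicates at both temperatures: zero pooled variance
    zero_var = (np.ptp(a18, axis=1) == 0) & (np.ptp(a29, axis=1) == 0)
    p[zero_var & (contrast == 0)] = 1.0
    p[zero_var & (contrast != 0)] = 0.0
    t[zero_var & (contrast == 0)] = 0.0
    return LMResult(m18, m29 - m18, t, df, p)


def classify_windows(
    padj18: np.ndarray,
    padj29: np.ndarray,
    padj_lm: np.ndarray,
    afc18: np.ndarray,
    afc29: np.ndarray,
    fdr: float,
) -> np.ndarray:
    """Assign each window exactly one of the six selection-response labels.

    ``padj_lm`` may be NaN for windows outside the linear-model BH pool
    (not significant at either temperature); those windows never reach an
    LM-dependent branch.  Direction comes from the observed mean AFC signs.
    """
    sig18 = np.asarray(padj18) <= fdr
    sig29 = np.asarray(padj29) <= fdr
    plm = np.asarray(padj_lm, dtype=float)
    sig_lm = np.where(np.isnan(plm), False, plm <= fdr)
    same_sign = np.sign(afc18) == np.sign(afc29)
    labels = np.select(
        [
            ~sig18 & ~sig29,
            sig18 & ~sig29,
            ~sig18 & sig29,
            sig18 & sig29 & ~sig_lm,
            sig18 & sig29 & sig_lm & same_sign,
            sig18 & sig29 & sig_lm & ~same_sign,
        ],
        CLASS_LABELS,
        default="__unassigned__",
    )
    if (labels == "__unassigned__").any():  # branches are exhaustive
        raise AssertionError("classification branches failed to cover a window")
    return labels.astype(object)


@dataclass
class ScanResult:
    """Per-window test results and class labels for one FDR threshold."""

    frame: pd.DataFrame
    fdr: float

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def labels(self) -> pd.Series:
        return self.frame["label"]


def scan_windows(
    wtable: WindowTable,
    null: NullDistribution,
    fdr: float = 0.10,
    temperatures: tuple[int, int] = (18, 29),
) -> ScanResult:
    """Full per-window scan: empirical p, BH per chromosome, LM, classes.

    Windows missing in any sample are excluded (count logged).  The LM
    adjusted p-values are BH-corrected per chromosome over the non-neutral
    windows only (significant at either temperature), as the classifier
    requires.
    """
    t_lo, t_hi = temperatures
    valid = ~wtable.window_missing
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("excluding %d windows missing in some sample", n_dropped)
    base = wtable.index.frame.loc[valid, ["chromosome", "window", "center"]].copy()
    chroms = base["chromosome"].to_numpy()

    reps_lo = wtable.replicate_afc(t_lo)[valid]
    reps_hi = wtable.replicate_afc(t_hi)[valid]
    afc_lo = reps_lo.mean(axis=1)
    afc_hi = reps_hi.mean(axis=1)

    p_lo = np.empty(len(base))
    p_hi = np.empty(len(base))
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        nv = null.values(chrom)
        p_lo[mask] = empirical_pvalue(afc_lo[mask], nv)
        p_hi[mask] = empirical_pvalue(afc_hi[mask], nv)

    padj_lo = np.empty_like(p_lo)
    padj_hi = np.empty_like(p_hi)
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        padj_lo[mask] = bh_adjust(p_lo[mask])
        padj_hi[mask] = bh_adjust(p_hi[mask])

    lm = fit_window_lm(reps_lo, reps_hi)
    sig_any = (padj_lo <= fdr) | (padj_hi <= fdr)
    padj_lm = np.full(len(base), np.nan)
    for chrom in dict.fromkeys(chroms):
        mask = (chroms == chrom) & sig_any
        if mask.any():
            padj_lm[mask] = bh_adjust(lm.p[mask])

    labels = classify_windows(padj_lo, padj_hi, padj_lm, afc_lo, afc_hi, fdr)

    frame = base.reset_index(drop=True)
    frame[f"afc{t_lo}"] = afc_lo
    frame[f"afc{t_hi}"] = afc_hi
    frame[f"p{t_lo}"] = p_lo
    frame[f"p{t_hi}"] = p_hi
    frame[f"padj{t_lo}"] = padj_lo
    frame[f"padj{t_hi}"] = padj_hi
    frame["alpha_intercept"] = lm.alpha_intercept
    frame["alpha_temperature"] = lm.alpha_temperature
    frame["p_lm"] = lm.p
    frame["padj_lm"] = padj_lm
    frame["label"] = labels
    return ScanResult(frame, fdr)


@dataclass
class ClassSummary:
    """Class fractions per chromosome and genome-wide."""

    fractions: pd.DataFrame
    more_extreme_at_29: float
    n_windows: int


def class_summary(
    scan: ScanResult,
    weighted: bool = False,
    temperatures: tuple[int, int] = (18, 29),
) -> ClassSummary:
    """Per-chromosome class fractions, a genome-wide (GW) row, and the
    share of different-magnitude windows whose |AFC| is larger at the
    higher temperature.

    The GW row is the unweighted mean of per-chromosome fractions
    ("averaged genome-wide"); ``weighted=True`` instead pools windows.
    """
    f = scan.frame
    t_lo, t_hi = temperatures
    per_chrom = (
        f.groupby("chromosome", sort=False)["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=CLASS_LABELS, fill_value=0.0)
    )
    if weighted:
        gw = f["label"].value_counts(normalize=True).reindex(CLASS_LABELS, fill_value=0.0)
    else:
        gw = per_chrom.mean(axis=0)
    fractions = pd.concat([per_chrom, gw.rename("GW").to_frame().T])

    mag = f[f["label"] == CLASS_MAGNITUDE]
    share = (
        float((mag[f"afc{t_hi}"].abs() > mag[f"afc{t_lo}"].abs()).mean())
        if len(mag)
        else float("nan")
    )
    return ClassSummary(fractions, share, len(f))


def fdr_sweep(
    wtable: WindowTable,
    null: NullDistribution,
    fdrs: tuple[float, ...] = (0.05, 0.10, 0.15),
) -> dict[float, ScanResult]:
    """Re-run classification at several FDR thresholds (default 5/10/15%)."""
    return {q: scan_windows(wtable, null, fdr=q) for q in fdrs}
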