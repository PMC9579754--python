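"""Focal-allele frequencies from Pool-Seq counts.

The focal-allele frequency at a marker is focal/(focal+other) using only
the two parental alleles; reads supporting any third allele are ignored
(biallelic contract) but tallied per sample.  A marker with zero
informative coverage is *missing* (NaN), never silently 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MarkerCatalog
from .syncio import NUC_INDEX, CountTable

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTable:
    """Per-sample focal-allele frequencies at catalogue markers.

    ``freq`` is ``(n_markers, n_samples)`` with NaN marking missing
    measurements; ``depth`` is the informative coverage (focal+other reads)
    used for each frequency.  ``samples`` carries one row per column with
    ``sample``, ``temperature`` and ``replicate``.
    """

    catalog: MarkerCatalog
    freq: np.ndarray
    depth: np.ndarray
    samples: pd.DataFrame
    ignored_reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n, s = len(self.catalog), len(self.samples)
        if self.freq.shape != (n, s) or self.depth.shape != (n, s):
            raise ValueError("freq/depth shape does not match catalogue/samples")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < 0 or np.nanmax(self.freq, initial=0.0) > 1:
                raise ValueError("frequencies outside [0, 1]")
        for col in ("sample", "temperature", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.freq)

    def columns_for(self, temperature: int) -> np.ndarray:
        """Column indices of a temperature's replicates, ordered by replicate."""
        meta = self.samples
        sel = meta.index[meta["temperature"] == temperature]
        if len(sel) == 0:
            raise ValueError(f"no samples at temperature {temperature}")
        order = np.argsort(meta.loc[sel, "replicate"].to_numpy(), kind="stable")
        return sel.to_numpy()[order]


def focal_allele_frequency(
    counts: CountTable,
    temperature: int,
    replicates: list[int] | None = None,
) -> AlleleFrequencyTable:
    """Frequencies of the focal founder allele from a count table.

    Third-allele reads are ignored; their per-sample totals are logged and
    kept on the result as ``ignored_reads``.
    """
    cat = counts.catalog.frame
    focal_idx = cat["focal_allele"].map(NUC_INDEX).to_numpy()
    other_idx = cat["other_allele"].map(NUC_INDEX).to_numpy()

    focal = np.take_along_axis(counts.counts, focal_idx[:, None, None], axis=2)[:, :, 0]
    other = np.take_along_axis(counts.counts, other_idx[:, None, None], axis=2)[:, :, 0]
    depth = focal + other
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, focal / np.maximum(depth, 1), np.nan)
    freq[counts.missing] = np.nan
    depth = np.where(counts.missing, 0, depth)

    ignored = (counts.coverage - depth) * ~counts.missing
    ignored_per_sample = ignored.sum(axis=0)
    if ignored_per_sample.any():
        logger.info(
            "third-allele reads ignored per sample: %s",
            dict(zip(counts.samples, ignored_per_sample.tolist())),
        )

    if replicates is None:
        replicates = list(range(1, counts.n_samples + 1))
    meta = pd.DataFrame(
        {
            "sample": counts.samples,
            "temperature": temperature,
            "replicate": replicates,
        }
    )
    return AlleleFrequencyTable(counts.catalog, freq, depth, meta, ignored_per_sample)


def concat_samples(*tables: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Column-concatenate tables that share one catalogue."""
    first = tables[0]
    for t in tables[1:]:
        if not t.catalog.frame[["arm", "position"]].equals(
            first.catalog.frame[["arm", "position"]]
        ):
            raise ValueError("tables do not share a catalogue")
    return AlleleFrequencyTable(
        first.catalog,
        np.hstack([t.freq for t in tables]),
        np.hstack([t.depth for t in tables]),
        pd.concat([t.samples for t in tables], ignore_index=True),
    )


def intersect_samples(*tables: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Keep only markers measured (non-missing) in every sample of every table.

    This is the "SNPs measured at both temperatures" filter: pass one table
    per temperature (or any split); the result is a single combined table on
    the subset catalogue.  Raises if the intersection is empty.
    """
    combined = tables[0] if len(tables) == 1 else concat_samples(*tables)
    keep = ~combined.missing.any(axis=1)
    if not keep.any():
        raise ValueError("no marker is measured in every sample")
    sub = combined.catalog.subset(keep)
    retained = sub.counts_by_arm()
    logger.info(
        "retained %d/%d markers measured in all %d samples; per arm: %s",
        keep.sum(),
        len(combined.catalog),
        combined.n_samples,
        retained.to_dict(),
    )
    return AlleleFrequencyTable(
        sub,
        combined.freq[keep],
        combined.depth[keep],
        combined.samples,
        combined.ignored_reads,
    )


def downsample_coverage(
    table: AlleleFrequencyTable,
    target_mean: float,
    seed: int,
    samples: list[str] | None = None,
) -> AlleleFrequencyTable:
    """Re-sample coverage to a Poisson(target_mean) depth per marker.

    For each marker and selected sample a new coverage ``c* ~
    Poisson(target_mean)`` is drawn and the focal count re-sampled as
    ``Binomial(c*, old frequency)``, mimicking Pool-Seq sampling noise at
    the reduced depth.  ``c* = 0`` makes the marker missing.  Per-sample
    random streams are derived from ``seed`` via
    ``SeedSequence(seed).spawn`` in column order, so results are
    reproducible and independent of which samples are selected.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    cols = (
        range(table.n_samples)
        if samples is None
        else [list(table.samples["sample"]).index(s) for s in samples]
    )
    streams = np.random.SeedSequence(seed).spawn(table.n_samples)
    freq = table.freq.copy()
    depth = table.depth.copy()
    for j in cols:
        rng = np.random.default_rng(streams[j])
        old = table.freq[:, j]
        valid = ~np.isnan(old)
        c_star = rng.poisson(target_mean, size=valid.sum())
        drawn = rng.binomial(c_star, old[valid])
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(c_star > 0, drawn / np.maximum(c_star, 1), np.nan)
        freq[valid, j] = new
        depth[valid, j] = c_star
        depth[np.isnan(freq[:, j]), j] = 0
    return AlleleFrequencyTable(table.catalog, freq, depth, table.samples.copy(), table.ignored_reads)
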