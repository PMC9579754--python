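"""End-to-end orchestration: files in, classified windows out.

``run_pipeline`` drives the full scan from a catalogue, two sync files
(one per temperature, three replicate columns each) and a recombination
map: frequency extraction, cross-temperature marker intersection,
coverage down-sampling of the high-coverage regime, windowing, the
neutral simulation null, the selection scan, class summaries and
autocorrelation profiles — writing tab-separated outputs plus a manifest
that suffices to reproduce the run.

``scan_experiment`` applies the same stages to an in-memory synthetic
experiment (no file round-trip), which is how the recovery checks run.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocorr import acf_profiles
from .catalog import MarkerCatalog
from .frequencies import (
    AlleleFrequencyTable,
    downsample_coverage,
    focal_allele_frequency,
    intersect_samples,
)
from .recomb import RecombinationMap
from .scan import ClassSummary, NullDistribution, ScanResult, class_summary, scan_windows
from .simulate import SimConfig, simulate_null
from .syncio import read_sync
from .synthetic import SyntheticExperiment
from .windows import WindowIndex, WindowTable, assign_windows, window_afc

logger = logging.getLogger(__name__)

TEMPERATURES = (18, 29)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (YAML-loadable)."""

    catalog: str
    sync_18: str
    sync_29: str
    recomb_map: str
    output_dir: str
    w: int = 250
    fdr: float = 0.10
    n_runs: int = 100
    downsample_to: float = 12.0
    p0: float = 0.3
    census: int = 1500
    generations: int = 20
    replicates: int = 3
    seed: int = 0
    x_chromosome: str = "X"
    exclude_chromosomes: tuple[str, ...] = ("4",)
    null: str | None = None  # persisted null TSV: reuse instead of resimulating

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        for name in ("catalog", "sync_18", "sync_29", "recomb_map"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if "exclude_chromosomes" in raw:
            raw["exclude_chromosomes"] = tuple(str(c) for c in raw["exclude_chromosomes"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything one run produces (also returned by ``scan_experiment``)."""

    scan: ScanResult
    summary: ClassSummary
    wtable: WindowTable
    windows: WindowIndex
    null: NullDistribution
    freqs: AlleleFrequencyTable
    acf: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _downsample_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(4,)).generate_state(1)[0])


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context logger with per-stage timing, aborting with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
        return False


def _scan_stages(
    freqs18: AlleleFrequencyTable,
    freqs29: AlleleFrequencyTable,
    rmap: RecombinationMap,
    *,
    w: int,
    fdr: float,
    n_runs: int,
    downsample_to: float,
    p0: float,
    census: int,
    generations: int,
    replicates: int,
    seed: int,
    x_chromosome: str = "X",
    exclude_chromosomes: tuple[str, ...] = (),
    with_acf: bool = False,
    null: NullDistribution | None = None,
) -> PipelineResult:
    with _Stage("intersect"):
        combined = intersect_samples(freqs18, freqs29)
    with _Stage("downsample"):
        hi_samples = list(
            combined.samples.loc[combined.samples["temperature"] == 29, "sample"]
        )
        combined = downsample_coverage(
            combined, downsample_to, _downsample_seed(seed), samples=hi_samples
        )
        # re-intersect: markers drawn to zero coverage became missing
        combined = intersect_samples(combined)
    with _Stage("window"):
        windex = assign_windows(combined.catalog, w, exclude_chromosomes)
        wtable = window_afc(combined, windex, p0)
    if null is None:
        with _Stage("simulate-null"):
            sim = SimConfig(
                census=census,
                p_geno=p0,
                generations=generations,
                replicates=replicates,
                seed=seed,
            )
            null = simulate_null(
                combined.catalog, rmap, sim, windex, n_runs, seed=seed,
                p0=p0, x_chromosome=x_chromosome,
            )
    else:
        per_chrom = windex.counts_by_chromosome()
        for chrom in windex.chromosomes:
            if len(null.values(chrom)) % per_chrom[chrom]:
                raise ValueError(
                    "precomputed null does not match the window index "
                    f"(chromosome {chrom})"
                )
    with _Stage("scan"):
        scan = scan_windows(wtable, null, fdr=fdr)
        summary = class_summary(scan)
    acf = None
    if with_acf:
        with _Stage("acf"):
            acf = acf_profiles(wtable)
    return PipelineResult(scan, summary, wtable, windex, null, combined, acf)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages from files and write every export plus a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _Stage("read"):
        catalog = MarkerCatalog.from_tsv(config.catalog)
        rmap = RecombinationMap.from_tsv(config.recomb_map)
        freqs = {}
        for temp, path in ((18, config.sync_18), (29, config.sync_29)):
            counts = read_sync(path, catalog)
            logger.info("%s: %d samples, %d markers", path, counts.n_samples, len(catalog))
            freqs[temp] = focal_allele_frequency(counts, temp)
        null = NullDistribution.from_tsv(config.null) if config.null else None
    result = _scan_stages(
        freqs[18],
        freqs[29],
        rmap,
        w=config.w,
        fdr=config.fdr,
        n_runs=config.n_runs,
        downsample_to=config.downsample_to,
        p0=config.p0,
        census=config.census,
        generations=config.generations,
        replicates=config.replicates,
        seed=config.seed,
        x_chromosome=config.x_chromosome,
        exclude_chromosomes=config.exclude_chromosomes,
        with_acf=True,
        null=null,
    )
    with _Stage("write"):
        result.wtable.to_tsv(out / "windows.tsv")
        result.null.to_tsv(out / "null.tsv")
        result.scan.to_tsv(out / "scan.tsv")
        result.summary.fractions.to_csv(out / "class_fractions.tsv", sep="\t")
        result.acf.to_csv(out / "acf.tsv", sep="\t", index=False)
        manifest = {
            "package": "duoscan",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "w": config.w,
                "fdr": config.fdr,
                "n_runs": config.n_runs,
                "downsample_to": config.downsample_to,
                "p0": config.p0,
                "census": config.census,
                "generations": config.generations,
                "replicates": config.replicates,
            },
            "inputs": {
                name: {"path": str(getattr(config, name)), "md5": _md5(getattr(config, name))}
                for name in ("catalog", "sync_18", "sync_29", "recomb_map")
            },
        }
        with open(out / "manifest.yaml", "wt") as handle:
            yaml.safe_dump(manifest, handle, sort_keys=False)
        result.manifest = manifest
    return result


def scan_experiment(
    exp: SyntheticExperiment,
    n_runs: int = 100,
    fdr: float = 0.10,
    w: int | None = None,
    downsample_to: float = 12.0,
    with_acf: bool = False,
    null: NullDistribution | None = None,
) -> PipelineResult:
    """Run the scan stages on an in-memory synthetic experiment.

    Uses the experiment's own seed for the null simulations and the
    down-sampling streams, so a given experiment always scans identically.
    A precomputed ``null`` may be supplied when several experiments share
    one genome layout and seed (e.g. per-class recovery checks): marker
    placement and Pool-Seq coverage draws depend only on the seed, so the
    retained windows — and therefore the neutral null — are identical.
    """
    freqs18 = focal_allele_frequency(exp.counts[18], 18)
    freqs29 = focal_allele_frequency(exp.counts[29], 29)
    return _scan_stages(
        freqs18,
        freqs29,
        exp.rmap,
        w=w if w is not None else exp.config.w,
        fdr=fdr,
        n_runs=n_runs,
        downsample_to=downsample_to,
        p0=exp.config.p_geno,
        census=exp.config.census,
        generations=exp.config.generations,
        replicates=exp.config.replicates,
        seed=exp.config.seed,
        with_acf=with_acf,
        null=null,
    )
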