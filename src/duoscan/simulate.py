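"""Two-founder Wright-Fisher forward simulator with recombination.

The simulator mimics the experimental design directly: a census of ``N``
diploid flies founded by two fully homozygous genotypes (a fraction
``p_geno`` carrying the focal genotype), discrete generations of random
mating with optional fitness differences, crossover placed along the
female genetic map (achiasmatic males never recombine), and an explicitly
sexed X chromosome (two copies in females, one in males; sons inherit the
maternal X).  Genomes are founder-ancestry mosaics, so marker allele
frequencies are read directly off segment ancestry.

Randomness: every replicate run draws from a ``numpy`` Generator seeded by
``SeedSequence(master_seed, spawn_key=...)``; the spawn keys are
``(1, temperature_index, replicate)`` for experiment replicates and
``(2, run, replicate)`` for neutral null runs, making every trajectory
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .catalog import MarkerCatalog
from .recomb import GeneticMap, MapError, RecombinationMap, build_genetic_map
from .windows import WindowIndex, window_means

logger = logging.getLogger(__name__)

SEX_FEMALE = 0
SEX_MALE = 1

_INITIAL_BP_CAPACITY = 32
_MAX_BP_CAPACITY = 4096


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SelectionTarget:
    """A selected site: genotype fitnesses 1, 1+hs, 1+s (focal dose 0/1/2).

    ``position`` is on the chromosome's concatenated-arm coordinate.
    Hemizygous X males have fitness 1 or 1+s.  Fitness is multiplicative
    across targets.
    """

    chromosome: str
    position: float
    s18: float
    s29: float
    h: float = 0.5

    def coefficient(self, temperature: int) -> float:
        if temperature == 18:
            return self.s18
        if temperature == 29:
            return self.s29
        raise ValueError(f"unknown temperature {temperature}")


@dataclass(frozen=True)
class SimConfig:
    """Experiment-scale parameters of one simulated population."""

    census: int = 1500
    p_geno: float = 0.3
    generations: int = 20
    replicates: int = 3
    seed: int = 0
    targets: tuple[SelectionTarget, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_geno <= 1.0:
            raise ValueError("p_geno must be in [0, 1]")
        if self.census < 2:
            raise ValueError("census must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class ChromosomeCopy:
    """A single transmitted chromosome as an ancestry mosaic."""

    anc0: int
    breakpoints: np.ndarray

    def ancestry_at(self, x: float) -> int:
        return self.anc0 ^ (int(np.searchsorted(self.breakpoints, x)) & 1)

    @property
    def n_switches(self) -> int:
        return len(self.breakpoints)


@dataclass
class LinkageGroup:
    """A chromosome as the simulator sees it: map plus marker coordinates."""

    chromosome: str
    arms: list[str]
    gmap: GeneticMap
    marker_rows: np.ndarray
    marker_pos: np.ndarray  # concatenated-arm coordinates, ascending
    is_x: bool


def build_linkage_groups(
    catalog: MarkerCatalog,
    rmap: RecombinationMap,
    x_chromosome: str = "X",
) -> list[LinkageGroup]:
    groups = []
    frame = catalog.frame
    for chrom in catalog.chromosomes:
        sub = frame[frame["chromosome"] == chrom]
        arms = list(dict.fromkeys(sub["arm"]))
        gmap = build_genetic_map(rmap, arms)
        pos = sub["position"].to_numpy() + sub["arm"].map(gmap.arm_offsets).to_numpy()
        pos = pos.astype(float)
        if pos.max() > gmap.length_bp or pos.min() < 1:
            raise MapError(
                f"markers on chromosome {chrom} fall outside the map support"
            )
        groups.append(
            LinkageGroup(
                chrom, arms, gmap, sub.index.to_numpy(), pos, chrom == x_chromosome
            )
        )
    return groups


class _GroupState:
    """Mosaic arrays of one linkage group for the whole population."""

    __slots__ = ("anc0", "nbp", "bp", "anc0_buf", "nbp_buf", "bp_buf")

    def __init__(self, n_slots: int, capacity: int = _INITIAL_BP_CAPACITY):
        self.anc0 = np.zeros(n_slots, dtype=np.uint8)
        self.nbp = np.zeros(n_slots, dtype=np.int64)
        self.bp = np.zeros((n_slots, capacity), dtype=np.float64)
        self.anc0_buf = np.zeros(n_slots, dtype=np.uint8)
        self.nbp_buf = np.zeros(n_slots, dtype=np.int64)
        self.bp_buf = np.zeros((n_slots, capacity), dtype=np.float64)

    def grow(self) -> None:
        cap = self.bp.shape[1] * 2
        if cap > _MAX_BP_CAPACITY:
            raise SimulationError("mosaic breakpoint capacity exhausted")
        for name in ("bp", "bp_buf"):
            old = getattr(self, name)
            new = np.zeros((old.shape[0], cap), dtype=np.float64)
            new[:, : old.shape[1]] = old
            setattr(self, name, new)

    def swap(self) -> None:
        self.anc0, self.anc0_buf = self.anc0_buf, self.anc0
        self.nbp, self.nbp_buf = self.nbp_buf, self.nbp
        self.bp, self.bp_buf = self.bp_buf, self.bp


@dataclass
class Population:
    """Mosaic genomes plus sexes for one replicate population."""

    groups: list[LinkageGroup]
    config: SimConfig
    sex: np.ndarray = field(init=False)
    generation: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        n = self.config.census
        n_focal = int(round(n * self.config.p_geno))
        if n_focal in (0, n) and 0.0 < self.config.p_geno < 1.0:
            logger.warning(
                "founder fraction %.3g rounds to a mono-founder population of %d",
                self.config.p_geno,
                n,
            )
        # alternate sexes within each founder class so both classes carry
        # both sexes (females first)
        sex = np.empty(n, dtype=np.uint8)
        sex[:n_focal] = np.arange(n_focal) % 2
        sex[n_focal:] = np.arange(n - n_focal) % 2
        self.sex = sex
        self._state = [_GroupState(2 * n) for _ in self.groups]
        for st in self._state:
            st.anc0[: 2 * n_focal] = 1
        self.n_focal = n_focal

    # ---- bookkeeping ------------------------------------------------------

    def valid_copy_mask(self, group: LinkageGroup) -> np.ndarray:
        mask = np.ones(2 * self.config.census, dtype=np.bool_)
        if group.is_x:
            mask[1::2] = self.sex == SEX_FEMALE
        return mask

    def copies(self, individual: int, group_index: int) -> list[ChromosomeCopy]:
        st = self._state[group_index]
        group = self.groups[group_index]
        out = []
        slots = [2 * individual, 2 * individual + 1]
        if group.is_x and self.sex[individual] == SEX_MALE:
            slots = slots[:1]
        for s in slots:
            out.append(
                ChromosomeCopy(int(st.anc0[s]), st.bp[s, : st.nbp[s]].copy())
            )
        return out

    def marker_frequencies(self) -> np.ndarray:
        """Focal-allele frequency at every catalogue marker (copy-counted:
        2 per female and 1 per male on the X)."""
        n_markers = sum(len(g.marker_rows) for g in self.groups)
        total = max(g.marker_rows.max() for g in self.groups) + 1
        freqs = np.full(max(n_markers, total), np.nan)
        for group, st in zip(self.groups, self._state):
            use = self.valid_copy_mask(group)
            counts = np.zeros(len(group.marker_pos), dtype=np.int64)
            _kernels.focal_count_at_markers(
                st.anc0, st.nbp, st.bp, use, group.marker_pos, counts
            )
            freqs[group.marker_rows] = counts / use.sum()
        return freqs

    # ---- fitness ----------------------------------------------------------

    def _fitness(self, temperature: int | None) -> np.ndarray | None:
        targets = self.config.targets
        if not targets or temperature is None:
            return None
        n = self.config.census
        w = np.ones(n)
        by_chrom: dict[str, list[SelectionTarget]] = {}
        for t in targets:
            by_chrom.setdefault(t.chromosome, []).append(t)
        for gi, group in enumerate(self.groups):
            tlist = by_chrom.get(group.chromosome)
            if not tlist:
                continue
            pos = np.array([t.position for t in tlist], dtype=float)
            st = self._state[gi]
            anc = np.zeros((2 * n, len(tlist)), dtype=np.uint8)
            _kernels.ancestry_at_positions(st.anc0, st.nbp, st.bp, pos, anc)
            valid = self.valid_copy_mask(group)
            dose = (anc * valid[:, None]).reshape(n, 2, len(tlist)).sum(axis=1)
            hemi = group.is_x & (self.sex == SEX_MALE)
            for k, t in enumerate(tlist):
                s = t.coefficient(temperature)
                if s == 0.0:
                    continue
                table = np.array([1.0, 1.0 + t.h * s, 1.0 + s])
                wt = table[dose[:, k]]
                if group.is_x:
                    hemi_table = np.array([1.0, 1.0 + s])
                    wt = np.where(hemi, hemi_table[np.minimum(dose[:, k], 1)], wt)
                w *= wt
        return w

    # ---- reproduction -----------------------------------------------------

    def next_generation(
        self, rng: np.random.Generator, temperature: int | None = None
    ) -> None:
        """Advance one generation in place (fitness-weighted parent sampling)."""
        n = self.config.census
        females = np.flatnonzero(self.sex == SEX_FEMALE)
        males = np.flatnonzero(self.sex == SEX_MALE)
        if len(females) == 0 or len(males) == 0:
            raise SimulationError(
                f"a sex went extinct at generation {self.generation}"
            )
        w = self._fitness(temperature)

        child_sex = rng.integers(0, 2, size=n).astype(np.uint8)
        if w is None:
            mothers = females[rng.integers(0, len(females), size=n)]
            fathers = males[rng.integers(0, len(males), size=n)]
        else:
            pf = w[females] / w[females].sum()
            pm = w[males] / w[males].sum()
            mothers = rng.choice(females, size=n, p=pf)
            fathers = rng.choice(males, size=n, p=pm)

        for group, st in zip(self.groups, self._state):
            mo_start = rng.integers(0, 2, size=n).astype(np.int64)
            fa_copy = rng.integers(0, 2, size=n).astype(np.int64)
            length = group.gmap.total_morgans
            xo_counts = rng.poisson(length, size=n).astype(np.int64)
            u = rng.random(xo_counts.sum()) * length
            xo_flat = group.gmap.to_phys(u)
            while True:
                if group.is_x:
                    status = _kernels.make_offspring_x(
                        st.anc0, st.nbp, st.bp, mothers, fathers, mo_start,
                        xo_counts, xo_flat.copy(), child_sex,
                        st.anc0_buf, st.nbp_buf, st.bp_buf,
                    )
                else:
                    status = _kernels.make_offspring_autosome(
                        st.anc0, st.nbp, st.bp, mothers, fathers, mo_start,
                        fa_copy, xo_counts, xo_flat.copy(),
                        st.anc0_buf, st.nbp_buf, st.bp_buf,
                    )
                if status == 0:
                    break
                st.grow()
            st.swap()
        self.sex = child_sex
        self.generation += 1


def init_population(
    catalog: MarkerCatalog,
    rmap: RecombinationMap,
    config: SimConfig,
    x_chromosome: str = "X",
) -> Population:
    """Found a population: round(N*p_geno) focal homozygotes, rest other."""
    groups = build_linkage_groups(catalog, rmap, x_chromosome)
    return Population(groups, config)


def make_gamete(
    copies: list[ChromosomeCopy],
    gmap: GeneticMap,
    rng: np.random.Generator,
    male: bool = False,
) -> ChromosomeCopy:
    """Form one gamete from a parent's chromosome copies.

    Females place ``Poisson(genetic length)`` crossovers by inverse-CDF on
    the cumulative genetic map; males transmit one whole copy (no
    recombination, as in Drosophila).  A hemizygous (single-copy) parent
    transmits that copy unchanged.
    """
    if len(copies) == 1:
        return ChromosomeCopy(copies[0].anc0, copies[0].breakpoints.copy())
    a, b = copies
    if male:
        pick = a if rng.integers(0, 2) == 0 else b
        return ChromosomeCopy(pick.anc0, pick.breakpoints.copy())
    length = gmap.total_morgans
    n_xo = int(rng.poisson(length))
    xo = np.sort(gmap.to_phys(rng.random(n_xo) * length))
    start = int(rng.integers(0, 2))
    out = np.empty(len(a.breakpoints) + len(b.breakpoints) + n_xo + 2)
    anc0, n_out = _kernels._merge_gamete(
        np.uint8(a.anc0), len(a.breakpoints), a.breakpoints.astype(float),
        np.uint8(b.anc0), len(b.breakpoints), b.breakpoints.astype(float),
        xo, n_xo, start, out,
    )
    return ChromosomeCopy(int(anc0), out[:n_out].copy())


def simulate_replicate(
    catalog: MarkerCatalog,
    rmap: RecombinationMap,
    config: SimConfig,
    rng: np.random.Generator,
    temperature: int | None = None,
    x_chromosome: str = "X",
) -> np.ndarray:
    """Run one replicate to generation ``t``; return final marker frequencies."""
    pop = init_population(catalog, rmap, config, x_chromosome)
    for _ in range(config.generations):
        pop.next_generation(rng, temperature)
    return pop.marker_frequencies()


def experiment_rng(seed: int, temperature_index: int, replicate: int) -> np.random.Generator:
    """Stream for an observed-experiment replicate (documented spawn keys)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, temperature_index, replicate))
    )


def null_rng(seed: int, run: int, replicate: int) -> np.random.Generator:
    """Stream for neutral-null run ``run``, replicate ``replicate``."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(2, run, replicate))
    )


def simulate_null(
    catalog: MarkerCatalog,
    rmap: RecombinationMap,
    config: SimConfig,
    windex: WindowIndex,
    n_runs: int,
    seed: int | None = None,
    p0: float = 0.3,
    x_chromosome: str = "X",
):
    """Neutral window-AFC null distribution, pooled per chromosome.

    For each of ``n_runs`` runs, ``config.replicates`` neutral replicates
    are simulated, window-mean frequencies computed and the replicate-mean
    AFC recorded per window; values are pooled per chromosome across runs
    and windows.
    """
    from .scan import NullDistribution  # local import to avoid a cycle

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config.targets:
        raise ValueError("null simulations must be neutral (no selection targets)")
    if seed is None:
        seed = config.seed
    chroms = windex.frame["chromosome"].to_numpy()
    windows = windex.frame["window"].to_numpy()
    records = []
    for run in range(n_runs):
        reps = np.column_stack(
            [
                simulate_replicate(
                    catalog, rmap, config, null_rng(seed, run, rep),
                    temperature=None, x_chromosome=x_chromosome,
                )
                for rep in range(config.replicates)
            ]
        )
        wmean = window_means(reps, windex)
        afc = wmean.mean(axis=1) - p0
        for c, wdx, v in zip(chroms, windows, afc):
            records.append((c, run, int(wdx), float(v)))
        if (run + 1) % 25 == 0:
            logger.info("neutral simulations: %d/%d runs", run + 1, n_runs)
    import pandas as pd

    frame = pd.DataFrame(records, columns=["chromosome", "run", "window", "afc"])
    return NullDistribution(frame)


def deterministic_trajectory(p0: float, s: float, t: int, h: float = 0.5) -> np.ndarray:
    """Infinite-population allele-frequency trajectory under one selected
    locus with genotype fitnesses 1, 1+hs, 1+s (an oracle for tests and
    for choosing planted effect sizes)."""
    p = np.empty(t + 1)
    p[0] = p0
    for g in range(t):
        q = 1.0 - p[g]
        wbar = 1.0 + s * (p[g] ** 2 + 2 * h * p[g] * q)
        p[g + 1] = p[g] * (p[g] * (1 + s) + q * (1 + h * s)) / wbar
    return p
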