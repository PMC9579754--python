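"""Marker-SNP catalogue for a two-founder experimental-evolution design.

A *marker SNP* is a site at which the two founder strains carry different,
(nearly) fixed alleles, so that the population frequency of the focal
founder's allele directly tracks founder ancestry.  The catalogue is the
ordered list of such sites together with the allele carried by each founder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "T", "C", "G")

#: Default Drosophila melanogaster arm -> chromosome assignment.
DEFAULT_ARM_TO_CHROMOSOME = {
    "2L": "2",
    "2R": "2",
    "3L": "3",
    "3R": "3",
    "4": "4",
    "X": "X",
}

#: Default arm ordering (defines catalogue sort order and arm concatenation).
DEFAULT_ARM_ORDER = ("2L", "2R", "3L", "3R", "4", "X")

CATALOG_COLUMNS = ["chromosome", "arm", "position", "focal_allele", "other_allele"]


class CatalogError(ValueError):
    """Raised when catalogue contents violate the catalogue invariants."""


@dataclass
class MarkerCatalog:
    """Ordered fixed-difference marker SNPs between two founder strains.

    Parameters
    ----------
    frame
        One row per marker with columns ``chromosome``, ``arm``,
        ``position`` (1-based), ``focal_allele`` and ``other_allele``.
    arm_order
        Ordering of arms; arms of the same chromosome must be adjacent so
        they can be concatenated for windowing.  Defaults to the Drosophila
        convention ``2L, 2R, 3L, 3R, 4, X``.
    """

    frame: pd.DataFrame
    arm_order: tuple[str, ...] = field(default=DEFAULT_ARM_ORDER)

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
        if missing:
            raise CatalogError(f"catalogue frame lacks columns: {missing}")
        self.frame = frame[CATALOG_COLUMNS].copy()
        self.frame["position"] = self.frame["position"].astype(np.int64)
        self._validate()

    def _validate(self) -> None:
        f = self.frame
        arms = f["arm"].to_numpy()
        unknown = set(arms) - set(self.arm_order)
        if unknown:
            raise CatalogError(f"arms absent from arm_order: {sorted(unknown)}")
        rank = f["arm"].map({a: i for i, a in enumerate(self.arm_order)}).to_numpy()
        if np.any(np.diff(rank) < 0):
            raise CatalogError("markers are not sorted by arm order")
        pos = f["position"].to_numpy()
        same_arm = np.diff(rank) == 0
        if np.any(same_arm & (np.diff(pos) <= 0)):
            raise CatalogError(
                "positions must be strictly increasing within an arm "
                "(duplicates or unsorted input)"
            )
        if np.any(pos < 1):
            raise CatalogError("positions are 1-based and must be >= 1")
        bad = f["focal_allele"] == f["other_allele"]
        if bad.any():
            raise CatalogError(
                f"focal and other allele identical at {int(bad.sum())} markers"
            )
        for col in ("focal_allele", "other_allele"):
            if not f[col].isin(NUCLEOTIDES).all():
                raise CatalogError(f"{col} contains non-ACGT symbols")

    # -- basic introspection ------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in catalogue order."""
        return list(dict.fromkeys(self.frame["chromosome"]))

    @property
    def arms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["arm"]))

    def counts_by_arm(self) -> pd.Series:
        return self.frame.groupby("arm", sort=False).size()

    def counts_by_chromosome(self) -> pd.Series:
        return self.frame.groupby("chromosome", sort=False).size()

    def summary(self) -> pd.DataFrame:
        """Per-chromosome marker counts plus a genome-wide total row."""
        counts = self.counts_by_chromosome()
        out = counts.rename("n_markers").to_frame()
        out.loc["total"] = counts.sum()
        return out

    def subset(self, mask: np.ndarray) -> "MarkerCatalog":
        """Row-subset preserving order (e.g. after sample intersection)."""
        return MarkerCatalog(self.frame.loc[np.asarray(mask)], self.arm_order)

    def arm_offsets(self) -> dict[str, int]:
        """Cumulative offsets used to concatenate arms of one chromosome.

        The offset of an arm is the summed extent (max marker position) of
        the preceding arms of the same chromosome, so that
        ``offset + position`` is a monotone coordinate along the chromosome.
        """
        offsets: dict[str, int] = {}
        running: dict[str, int] = {}
        for arm, grp in self.frame.groupby("arm", sort=False):
            chrom = grp["chromosome"].iloc[0]
            offsets[arm] = running.get(chrom, 0)
            running[chrom] = offsets[arm] + int(grp["position"].max())
        return offsets

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, arm_order: tuple[str, ...] | None = None) -> "MarkerCatalog":
        frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "arm": str})
        if arm_order is None:
            arm_order = tuple(dict.fromkeys(frame["arm"]))
            if set(frame["arm"]) <= set(DEFAULT_ARM_ORDER):
                arm_order = DEFAULT_ARM_ORDER
        return cls(frame, arm_order)


def build_marker_catalog(
    parental_calls_a: pd.DataFrame,
    parental_calls_b: pd.DataFrame,
    focal: str = "a",
    max_alt_freq: float = 0.05,
    min_alt_freq: float = 0.95,
    arm_to_chromosome: dict[str, str] | None = None,
    arm_order: tuple[str, ...] | None = None,
) -> MarkerCatalog:
    """Derive the marker catalogue from two parental genotype call sets.

    A site becomes a marker when one parent is homozygous reference (``0/0``)
    and the other homozygous alternate (``1/1``) and each parent's
    alternate-allele frequency estimate confirms the call: below
    ``max_alt_freq`` for ``0/0``, above ``min_alt_freq`` for ``1/1``.  The
    focal founder's allele is whichever allele that founder carries.

    Parameters
    ----------
    parental_calls_a, parental_calls_b
        Per-site calls with columns ``arm``, ``position``, ``ref``, ``alt``,
        ``genotype`` (``0/0``, ``1/1`` or anything else), ``alt_freq``.
        Both inputs must describe the same sites.
    focal
        Which parent (``"a"`` or ``"b"``) is the focal founder whose allele
        frequency the scan tracks.
    """
    if focal not in ("a", "b"):
        raise ValueError("focal must be 'a' or 'b'")
    arm_to_chromosome = dict(arm_to_chromosome or DEFAULT_ARM_TO_CHROMOSOME)

    cols = ["arm", "position", "ref", "alt", "genotype", "alt_freq"]
    for name, calls in (("a", parental_calls_a), ("b", parental_calls_b)):
        lacking = [c for c in cols if c not in calls.columns]
        if lacking:
            raise ValueError(f"parental calls '{name}' lack columns {lacking}")

    merged = parental_calls_a[cols].merge(
        parental_calls_b[cols],
        on=["arm", "position"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    clash = merged["ref_a"] != merged["ref_b"]
    if clash.any():
        site = merged.loc[clash, ["arm", "position"]].iloc[0]
        raise CatalogError(
            "inconsistent reference alleles between parents at "
            f"{site['arm']}:{site['position']} "
            f"({int(clash.sum())} such sites)"
        )

    def confirmed(geno: pd.Series, freq: pd.Series) -> pd.Series:
        return ((geno == "0/0") & (freq < max_alt_freq)) | (
            (geno == "1/1") & (freq > min_alt_freq)
        )

    ok_a = confirmed(merged["genotype_a"], merged["alt_freq_a"])
    ok_b = confirmed(merged["genotype_b"], merged["alt_freq_b"])
    differs = merged["genotype_a"] != merged["genotype_b"]
    keep = ok_a & ok_b & differs
    kept = merged.loc[keep].copy()

    focal_geno = kept["genotype_a"] if focal == "a" else kept["genotype_b"]
    # alt allele must share the ref of both parents (checked above)
    focal_allele = np.where(focal_geno == "1/1", kept["alt_a"], kept["ref_a"])
    other_allele = np.where(focal_geno == "1/1", kept["ref_a"], kept["alt_a"])

    frame = pd.DataFrame(
        {
            "chromosome": kept["arm"].map(arm_to_chromosome),
            "arm": kept["arm"],
            "position": kept["position"].astype(np.int64),
            "focal_allele": focal_allele,
            "other_allele": other_allele,
        }
    )
    if frame["chromosome"].isna().any():
        bad = sorted(set(kept.loc[frame["chromosome"].isna(), "arm"]))
        raise CatalogError(f"arms without chromosome assignment: {bad}")

    if arm_order is None:
        if set(frame["arm"]) <= set(DEFAULT_ARM_ORDER):
            arm_order = DEFAULT_ARM_ORDER
        else:
            arm_order = tuple(dict.fromkeys(frame["arm"]))
    rank = frame["arm"].map({a: i for i, a in enumerate(arm_order)})
    frame = frame.iloc[np.lexsort((frame["position"], rank))]
    logger.info("marker catalogue: retained %d of %d sites", len(frame), len(merged))
    return MarkerCatalog(frame, tuple(arm_order))
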