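"""Core data containers shared across the pipeline.

The whole toolkit operates on a dense diploid dosage matrix
(:class:`GenotypeMatrix`), a sample-to-population assignment
(:class:`PopulationMap`), and half-open genomic interval sets
(:class:`RegionSet`).  Coordinates are 0-based half-open everywhere except
at VCF read/write boundaries, where the 1-based convention of the format
applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing diploid genotype.
MISSING: int = -1

_SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: chromosome, 1-based position, and its two alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")


class GenotypeMatrix:
    """Samples x biallelic sites with diploid alt-allele dosages.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (``pos`` 1-based),
        sorted by chromosome appearance order and strictly increasing
        position within each chromosome.
    samples
        Ordered sample identifiers; must be unique.
    dosage
        ``(n_samples, n_sites)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    """

    def __init__(self, sites: pd.DataFrame, samples: Sequence[str], dosage: np.ndarray):
        sites = sites.reset_index(drop=True)
        missing_cols = set(_SITE_COLUMNS) - set(sites.columns)
        if missing_cols:
            raise ValueError(f"sites table missing columns: {sorted(missing_cols)}")
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample IDs")
        dosage = np.asarray(dosage)
        if dosage.shape != (len(samples), len(sites)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(samples)} samples x {len(sites)} sites"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")
        for _, sub in sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError("site positions must strictly increase within a chromosome")
        self.sites = sites
        self.samples = samples
        self.dosage = dosage.astype(np.int8, copy=False)

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_list(self) -> list[VariantSite]:
        return [VariantSite(*row) for row in self.sites[list(_SITE_COLUMNS)].itertuples(index=False)]

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index (order preserved)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.sites.iloc[idx], self.samples, self.dosage[:, idx])

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(self.sites, list(names), self.dosage[idx, :])

    # -- allele frequencies --------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over a sample subset."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx, :]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        n_called = 2 * called.sum(axis=0)
        return alt.astype(float), n_called.astype(float)

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site alt-allele frequency; NaN where no genotype is called."""
        alt, n = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites[list(_SITE_COLUMNS)].equals(other.sites[list(_SITE_COLUMNS)])
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


@dataclass
class PopulationMap:
    """Sample -> population assignment, with optional role labels.

    ``roles`` may mark pair membership or analysis roles (e.g.
    ``{"outgroup": "outgroup"}`` mapping a population label to a role).
    """

    assignment: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, p in self.assignment.items():
            if not p:
                raise ValueError(f"empty population label for sample {s!r}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        out = [s for s, p in self.assignment.items() if p == population]
        if not out:
            raise KeyError(f"unknown or empty population {population!r}")
        return out

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unassigned = [s for s in gm.samples if s not in self.assignment]
        if unassigned:
            raise ValueError(f"samples missing from popmap: {unassigned}")


class RegionSet:
    """A sorted set of 0-based half-open genomic intervals.

    Optional ``annotation`` carries per-interval metadata (source statistic,
    score) aligned with the interval order.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]],
        annotation: pd.DataFrame | None = None,
    ):
        ivals = list(intervals)
        for chrom, start, end in ivals:
            if start < 0 or end < 0:
                raise ValueError(f"negative coordinate in {chrom}:{start}-{end}")
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        order = sorted(range(len(ivals)), key=lambda i: (ivals[i][0], ivals[i][1], ivals[i][2]))
        self.intervals: list[tuple[str, int, int]] = [ivals[i] for i in order]
        if annotation is not None:
            annotation = annotation.iloc[order].reset_index(drop=True)
        self.annotation = annotation

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)

    def __contains__(self, interval: tuple[str, int, int]) -> bool:
        return interval in set(self.intervals)

    def as_set(self) -> set[tuple[str, int, int]]:
        return set(self.intervals)

    def intersection(self, other: "RegionSet") -> "RegionSet":
        """Intervals present identically in both sets (grid-window identity)."""
        common = self.as_set() & other.as_set()
        return RegionSet(sorted(common))

    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def size_multiset(self) -> tuple[int, ...]:
        return tuple(sorted(e - s for _, s, e in self.intervals))

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_span()} bp)"


def popmap_from_pairs(pairs: Iterable[tuple[str, str]]) -> PopulationMap:
    return PopulationMap(assignment=dict(pairs))
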