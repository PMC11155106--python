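"""Windowed nucleotide diversity (pi), absolute (Dxy) and relative (Fst)
divergence in non-overlapping windows (default 5 kb).

Per site with alt-allele count ``c`` out of ``n`` called alleles in a
population, within-population diversity is the unbiased heterozygosity
``pi_site = 2*(c/n)*(1-c/n)*n/(n-1)`` and between-population divergence is
``dxy_site = p1*(1-p2) + p2*(1-p1)``.  Window values divide the per-site
sums by an effective length (monomorphic sites contribute zero), and Fst is
the Hudson-type ratio of window sums ``1 - mean(pi1, pi2)/dxy`` —
computed on sums, not averaged per-site ratios, which keeps it stable in
low-diversity windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class WindowSpec:
    """Non-overlapping window grid: ``step`` equals ``size``.

    ``effective_length_mode`` is ``"window_length"`` (default; suits VCFs
    carrying variant sites only) or ``"genotyped_sites"`` (divide by the
    number of analyzed variant sites instead).
    """

    size: int = 5_000
    min_snps: int = 1
    effective_length_mode: str = "window_length"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        if self.effective_length_mode not in ("window_length", "genotyped_sites"):
            raise ValueError(f"unknown effective_length_mode {self.effective_length_mode!r}")

    @property
    def step(self) -> int:
        return self.size


def window_iter(
    genome: Sequence[tuple[str, int]], spec: WindowSpec
) -> Iterator[tuple[str, int, int, bool]]:
    """Yield half-open windows tiling each chromosome; the terminal partial
    window (if any) is flagged by the fourth element."""
    for chrom, length in genome:
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 0
        while start < length:
            end = min(start + spec.size, length)
            yield chrom, start, end, (end - start) < spec.size
            start += spec.size


def window_grid(genome: Sequence[tuple[str, int]], spec: WindowSpec) -> pd.DataFrame:
    rows = [(c, s, e, partial) for c, s, e, partial in window_iter(genome, spec)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def _per_site_pi(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity; zero where < 2 called alleles."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n, 1)
        pi = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0)
    return np.where(n >= 2, pi, 0.0)


def windowed_stats(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop1: str,
    pop2: str,
    spec: WindowSpec | None = None,
    genome: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-window pi (each population), Dxy and Hudson-type Fst.

    Parameters
    ----------
    genome
        Chromosome lengths defining the window grid; defaults to the span
        of observed sites (last window end rounded up to window size).

    Returns
    -------
    DataFrame with columns ``chrom, start, end, n_snps, pi_1, pi_2, dxy,
    fst``; windows failing ``min_snps`` or with zero Dxy denominator carry
    NaN in the affected columns.
    """
    spec = spec or WindowSpec()
    idx1 = gm.sample_indices(popmap.samples_in(pop1))
    idx2 = gm.sample_indices(popmap.samples_in(pop2))
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each population needs >= 2 samples for within-population pi")

    alt1, n1 = gm.allele_counts(idx1)
    alt2, n2 = gm.allele_counts(idx2)
    # Sites where either population is entirely missing are skipped.
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / np.maximum(n1, 1)
        p2 = alt2 / np.maximum(n2, 1)
    pi1_site = np.where(usable, _per_site_pi(alt1, n1), 0.0)
    pi2_site = np.where(usable, _per_site_pi(alt2, n2), 0.0)
    dxy_site = np.where(usable, p1 * (1 - p2) + p2 * (1 - p1), 0.0)

    if genome is None:
        lengths: dict[str, int] = {}
        for chrom, sub in gm.sites.groupby("chrom", sort=False):
            max_pos = int(sub["pos"].max())
            lengths[chrom] = int(np.ceil(max_pos / spec.size)) * spec.size
        genome = list(lengths.items())

    grid = window_grid(genome, spec)
    chroms = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    rows = []
    for chrom, start, end, _ in grid[["chrom", "start", "end", "partial"]].itertuples(index=False):
        in_win = np.flatnonzero((chroms == chrom) & (pos0 >= start) & (pos0 < end))
        use = in_win[usable[in_win]]
        n_snps = len(use)
        if spec.effective_length_mode == "window_length":
            eff_len = end - start
        else:
            eff_len = max(n_snps, 1)
        sum_pi1 = pi1_site[use].sum()
        sum_pi2 = pi2_site[use].sum()
        sum_dxy = dxy_site[use].sum()
        if n_snps < spec.min_snps:
            rows.append((chrom, start, end, n_snps, np.nan, np.nan, np.nan, np.nan))
            continue
        pi_1 = sum_pi1 / eff_len
        pi_2 = sum_pi2 / eff_len
        dxy = sum_dxy / eff_len
        fst = 1.0 - 0.5 * (sum_pi1 + sum_pi2) / sum_dxy if sum_dxy > 0 else np.nan
        rows.append((chrom, start, end, n_snps, pi_1, pi_2, dxy, fst))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "pi_1", "pi_2", "dxy", "fst"]
    )


def write_window_stats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_window_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
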