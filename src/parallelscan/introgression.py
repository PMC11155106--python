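"""Gene-flow statistics: Patterson's D with block-jackknife significance,
the split-half f4-ratio admixture proportion, windowed fd, introgression
window calling, and empirical nulls from shuffled regions.

Site patterns are frequency-based.  With derived-allele frequencies
``p1, p2, p3, pO`` in populations P1, P2, P3 and the outgroup O (derived =
the allele at minority frequency in the outgroup),

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

Under incomplete lineage sorting alone D is 0; gene flow between P3 and P2
(P1) drives it positive (negative).  Significance uses a delete-one block
jackknife over contiguous equal-span genome blocks; |Z| >= 3 is the
conventional critical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, PopulationMap, RegionSet
from .divergence_scan import HDRSet, chi_square_2x2
from .window_stats import WindowSpec, window_grid


@dataclass(frozen=True)
class TrioConfig:
    """P1, P2, P3 and outgroup population labels for a four-taxon test."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"trio populations must be distinct, got {labels}")

    def swapped(self) -> "TrioConfig":
        return TrioConfig(self.p2, self.p1, self.p3, self.outgroup)


@dataclass
class DStatResult:
    d: float
    z: float
    p_value: float
    sum_abba: float
    sum_baba: float
    n_blocks: int
    n_sites_used: int
    f4_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "D": self.d,
            "Z": self.z,
            "p_value": self.p_value,
            "sum_abba": self.sum_abba,
            "sum_baba": self.sum_baba,
            "n_blocks": self.n_blocks,
            "n_sites_used": self.n_sites_used,
            "f4_ratio": self.f4_ratio,
        }


def _derived_freqs(
    gm: GenotypeMatrix, popmap: PopulationMap, trio: TrioConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived-allele frequencies (p1, p2, p3, pO) and a usable-site
    mask.

    The derived allele is the one at frequency < 0.5 in the outgroup; sites
    with outgroup frequency exactly 0.5, outgroup entirely missing, or any
    trio population entirely missing are excluded.
    """
    freqs = {}
    called_ok = np.ones(gm.n_sites, dtype=bool)
    for pop in (trio.p1, trio.p2, trio.p3, trio.outgroup):
        idx = gm.sample_indices(popmap.samples_in(pop))
        alt, n = gm.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        called_ok &= n > 0
    po_alt = freqs[trio.outgroup]
    usable = called_ok & ~np.isnan(po_alt) & (po_alt != 0.5)
    # Polarize: derived allele has outgroup frequency < 0.5.
    flip = po_alt > 0.5
    out = []
    for pop in (trio.p1, trio.p2, trio.p3, trio.outgroup):
        p = freqs[pop].copy()
        p[flip] = 1.0 - p[flip]
        out.append(p)
    return out[0], out[1], out[2], out[3], usable


def site_pattern_weights(
    gm: GenotypeMatrix, popmap: PopulationMap, trio: TrioConfig
) -> pd.DataFrame:
    """Per-site ABBA/BABA weights (zero at unusable sites), with coordinates."""
    p1, p2, p3, po, usable = _derived_freqs(gm, popmap, trio)
    abba = np.where(usable, (1 - p1) * p2 * p3 * (1 - po), 0.0)
    baba = np.where(usable, p1 * (1 - p2) * p3 * (1 - po), 0.0)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "abba": np.nan_to_num(abba),
            "baba": np.nan_to_num(baba),
            "usable": usable,
        }
    )


def _genome_blocks(
    weights: pd.DataFrame, genome: list[tuple[str, int]] | None, n_blocks: int
) -> np.ndarray:
    """Assign each site to one of ``n_blocks`` contiguous equal-span blocks
    over the concatenated genome; blocks without informative sites are
    merged into their left neighbour."""
    if genome is None:
        genome = [
            (chrom, int(sub["pos"].max()))
            for chrom, sub in weights.groupby("chrom", sort=False)
        ]
    offsets = {}
    total = 0
    for chrom, length in genome:
        offsets[chrom] = total
        total += length
    coord = weights["chrom"].map(offsets).to_numpy() + weights["pos"].to_numpy() - 1
    edges = np.linspace(0, total, n_blocks + 1)
    block = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_blocks - 1)
    # merge empty blocks (no informative weight) leftwards
    informative = (weights["abba"] + weights["baba"]).to_numpy() > 0
    occupied = sorted({int(b) for b in block[informative]})
    if not occupied:
        raise ValueError("no informative sites for the D statistic")
    remap = {}
    for b in range(n_blocks):
        prior = [o for o in occupied if o <= b]
        remap[b] = prior[-1] if prior else occupied[0]
    renumber = {o: i for i, o in enumerate(occupied)}
    return np.array([renumber[remap[int(b)]] for b in block])


def _jackknife_d(abba: np.ndarray, baba: np.ndarray, block: np.ndarray) -> tuple[float, float, int]:
    """Genome-wide D, its delete-one block-jackknife SE, and block count."""
    s_abba, s_baba = abba.sum(), baba.sum()
    denom = s_abba + s_baba
    if denom <= 0:
        raise ValueError("no informative sites: ABBA + BABA sums to zero")
    d = (s_abba - s_baba) / denom
    n_blocks = int(block.max()) + 1
    ab_b = np.bincount(block, weights=abba, minlength=n_blocks)
    ba_b = np.bincount(block, weights=baba, minlength=n_blocks)
    d_minus = np.empty(n_blocks)
    for j in range(n_blocks):
        num = (s_abba - ab_b[j]) - (s_baba - ba_b[j])
        den = (s_abba - ab_b[j]) + (s_baba - ba_b[j])
        d_minus[j] = num / den if den > 0 else 0.0
    se = np.sqrt((n_blocks - 1) / n_blocks * ((d_minus - d_minus.mean()) ** 2).sum())
    return d, se, n_blocks


def abba_baba(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    trio: TrioConfig,
    n_blocks: int = 20,
    genome: list[tuple[str, int]] | None = None,
) -> DStatResult:
    """Genome-wide Patterson's D with block-jackknife Z and two-sided p."""
    if n_blocks < 5:
        raise ValueError("need >= 5 jackknife blocks")
    w = site_pattern_weights(gm, popmap, trio)
    block = _genome_blocks(w, genome, n_blocks)
    abba, baba = w["abba"].to_numpy(), w["baba"].to_numpy()
    d, se, nb = _jackknife_d(abba, baba, block)
    z = d / se if se > 0 else np.inf * np.sign(d) if d != 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if np.isfinite(z) else 0.0
    n_used = int(((abba + baba) > 0).sum())
    return DStatResult(
        d=float(d), z=float(z), p_value=p,
        sum_abba=float(abba.sum()), sum_baba=float(baba.sum()),
        n_blocks=nb, n_sites_used=n_used,
    )


def _f4_sum(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    idx_c: np.ndarray,
    idx_o: np.ndarray,
) -> float:
    """S(A,B,C,O) = sum over usable sites of (pB - pA) * pC * (1 - pO),
    polarized by the outgroup minority allele."""
    freqs = []
    ok = np.ones(gm.n_sites, dtype=bool)
    for idx in (idx_a, idx_b, idx_c, idx_o):
        alt, n = gm.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(n > 0, alt / np.maximum(n, 1), np.nan))
        ok &= n > 0
    pa, pb, pc, po = freqs
    ok &= ~np.isnan(po) & (po != 0.5)
    flip = po > 0.5
    pa, pb, pc, po = (np.where(flip, 1 - p, p) for p in (pa, pb, pc, po))
    s = np.where(ok, (pb - pa) * pc * (1 - po), 0.0)
    return float(np.nan_to_num(s).sum())


def f4_ratio(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    trio: TrioConfig,
    seed: int,
    n_resample: int = 10,
) -> float:
    """Split-half f4-ratio estimate of the fraction of P2's ancestry derived
    from P3.

    P3's samples are split at random (seeded) into halves P3a/P3b and
    ``f = S(P1,P2,P3a,O) / S(P1,P3b,P3a,O)``; the split is resampled
    ``n_resample`` times and averaged for stability.  Only consistent for
    recent introgression: donor drift after the pulse attenuates the
    estimate.
    """
    p3_samples = popmap.samples_in(trio.p3)
    if len(p3_samples) < 2:
        raise ValueError("P3 must have >= 2 samples to split")
    idx1 = gm.sample_indices(popmap.samples_in(trio.p1))
    idx2 = gm.sample_indices(popmap.samples_in(trio.p2))
    idx3 = gm.sample_indices(p3_samples)
    idxo = gm.sample_indices(popmap.samples_in(trio.outgroup))
    rng = np.random.default_rng(seed)
    half = len(idx3) // 2
    estimates = []
    for _ in range(n_resample):
        perm = rng.permutation(len(idx3))
        p3a, p3b = idx3[perm[:half]], idx3[perm[half:]]
        num = _f4_sum(gm, popmap, idx1, idx2, p3a, idxo)
        den = _f4_sum(gm, popmap, idx1, p3b, p3a, idxo)
        if abs(den) < 1e-12:
            raise ValueError("f4-ratio denominator ~ 0: configuration not informative")
        estimates.append(num / den)
    return float(np.mean(estimates))


# ---------------------------------------------------------------------------
# fd windows
# ---------------------------------------------------------------------------

def fd_windows(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    trio: TrioConfig,
    spec: WindowSpec | None = None,
    genome: list[tuple[str, int]] | None = None,
    min_informative: int = 10,
) -> pd.DataFrame:
    """Per-window fd: ABBA-BABA excess normalized by its value under
    complete introgression from a dynamic donor.

    The denominator replaces both P2 and P3 by the donor proxy PD — per
    site, whichever of P2/P3 has the higher derived-allele frequency.
    Windows with window-level D <= 0 are clamped to fd = 0; windows with
    fewer than ``min_informative`` informative sites are NaN.  Reported fd
    is clamped into [0, 1].
    """
    spec = spec or WindowSpec()
    p1, p2, p3, po, usable = _derived_freqs(gm, popmap, trio)
    abba = np.where(usable, (1 - p1) * p2 * p3 * (1 - po), 0.0)
    baba = np.where(usable, p1 * (1 - p2) * p3 * (1 - po), 0.0)
    pd_ = np.maximum(p2, p3)
    abba_d = np.where(usable, (1 - p1) * pd_ * pd_ * (1 - po), 0.0)
    baba_d = np.where(usable, p1 * (1 - pd_) * pd_ * (1 - po), 0.0)
    abba, baba = np.nan_to_num(abba), np.nan_to_num(baba)
    abba_d, baba_d = np.nan_to_num(abba_d), np.nan_to_num(baba_d)
    informative = (abba + baba) > 0

    if genome is None:
        genome = [
            (chrom, int(np.ceil(int(sub["pos"].max()) / spec.size)) * spec.size)
            for chrom, sub in gm.sites.groupby("chrom", sort=False)
        ]
    grid = window_grid(genome, spec)
    chroms = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    rows = []
    for chrom, start, end in grid[["chrom", "start", "end"]].itertuples(index=False):
        in_win = np.flatnonzero((chroms == chrom) & (pos0 >= start) & (pos0 < end))
        n_inf = int(informative[in_win].sum())
        num = abba[in_win].sum() - baba[in_win].sum()
        den = abba_d[in_win].sum() - baba_d[in_win].sum()
        d_sign = np.sign(num)
        if n_inf < min_informative:
            fd = np.nan
        elif num <= 0:
            fd = 0.0
        elif den <= 0:
            fd = np.nan
        else:
            fd = min(num / den, 1.0)
        rows.append((chrom, int(start), int(end), n_inf, d_sign, fd))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_informative", "d_sign", "fd"])


@dataclass
class IntrogressionSet:
    regions: RegionSet
    target_proportion: float
    achieved_proportion: float
    fd_threshold: float

    def __len__(self) -> int:
        return len(self.regions)


def call_introgressed(fd_track: pd.DataFrame, target_prop: float) -> IntrogressionSet:
    """Top-fd windows summing to ``target_prop`` of defined windows (count
    fraction): the smallest prefix of fd-descending windows reaching the
    target.  Ties break by genomic order."""
    if not 0 <= target_prop <= 1:
        raise ValueError("target proportion must be in [0, 1]")
    defined = fd_track.dropna(subset=["fd"]).reset_index(drop=True)
    n_def = len(defined)
    if n_def == 0:
        raise ValueError("no defined fd windows")
    if target_prop == 0:
        return IntrogressionSet(RegionSet([]), 0.0, 0.0, np.inf)
    order = defined.sort_values(
        ["fd", "chrom", "start"], ascending=[False, True, True], kind="stable"
    )
    k = int(np.ceil(target_prop * n_def))
    chosen = order.iloc[:k]
    regions = RegionSet(
        [(r.chrom, int(r.start), int(r.end)) for r in chosen.itertuples(index=False)],
        annotation=pd.DataFrame({"fd": chosen["fd"].to_numpy()}),
    )
    return IntrogressionSet(
        regions=regions,
        target_proportion=target_prop,
        achieved_proportion=k / n_def,
        fd_threshold=float(chosen["fd"].min()),
    )


# ---------------------------------------------------------------------------
# empirical null from shuffled regions
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    observed: float
    replicates: np.ndarray = field(repr=False)
    p_value: float = np.nan

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def random_region_null(
    observed: RegionSet,
    genome: list[tuple[str, int]],
    stat_windows: pd.DataFrame,
    stat_values: np.ndarray,
    n: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null for the mean of a window statistic over a region set.

    Each replicate re-places the observed intervals uniformly at random on
    their source chromosomes (window-grid aligned, non-overlapping within a
    replicate), preserving the interval-size multiset; the replicate
    summary is the mean statistic over windows covered by the placed
    intervals.  One-sided empirical p for "observed >= null":
    ``(1 + #{replicate >= observed}) / (n + 1)``.
    """
    values = np.asarray(stat_values, dtype=float)
    if len(values) != len(stat_windows):
        raise ValueError("stat track and window grid lengths differ")
    lengths = dict(genome)
    win_size = int(stat_windows["end"].iat[0] - stat_windows["start"].iat[0])
    lookup = {
        (stat_windows["chrom"].iat[i], int(stat_windows["start"].iat[i])): values[i]
        for i in range(len(stat_windows))
    }

    def region_mean(regions: list[tuple[str, int, int]]) -> float:
        vals = []
        for chrom, start, end in regions:
            for s in range(start, end, win_size):
                v = lookup.get((chrom, s), np.nan)
                if not np.isnan(v):
                    vals.append(v)
        return float(np.mean(vals)) if vals else np.nan

    obs_list = list(observed)
    for chrom, start, end in obs_list:
        if chrom not in lengths:
            raise ValueError(f"region chromosome {chrom!r} not in genome")
        if end - start > lengths[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} longer than its chromosome")
    obs_mean = region_mean(obs_list)
    rng = np.random.default_rng(seed)
    reps = np.empty(n)
    for r in range(n):
        placed: list[tuple[str, int, int]] = []
        occupied: dict[str, set[int]] = {}
        for chrom, start, end in obs_list:
            size = end - start
            n_slots = (lengths[chrom] - size) // win_size + 1
            used = occupied.setdefault(chrom, set())
            for _ in range(10_000):
                slot = int(rng.integers(0, n_slots))
                s = slot * win_size
                span = set(range(s, s + size, win_size))
                if not span & used:
                    used |= span
                    placed.append((chrom, s, s + size))
                    break
            else:
                raise RuntimeError("could not place region without overlap")
        reps[r] = region_mean(placed)
    p = (1 + int((reps >= obs_mean).sum())) / (n + 1)
    return NullDistribution(observed=obs_mean, replicates=reps, p_value=p)


def overlap_report(
    introgressed: IntrogressionSet, hdrs: HDRSet, shared: HDRSet | None = None
) -> dict:
    """Fractions of HDRs (and shared HDRs) intersecting introgression
    windows, plus a 2x2 chi-square comparing shared vs remaining HDRs on
    overlap status."""
    intro = introgressed.regions.as_set()
    hdr_set = hdrs.regions.as_set()
    out: dict = {
        "n_hdrs": len(hdr_set),
        "n_hdrs_overlapping": len(hdr_set & intro),
        "frac_hdrs_overlapping": len(hdr_set & intro) / len(hdr_set) if hdr_set else 0.0,
    }
    if shared is not None:
        shared_set = shared.regions.as_set()
        if not shared_set <= hdr_set:
            raise ValueError("shared HDRs must be a subset of the HDR set")
        remaining = hdr_set - shared_set
        a = len(shared_set & intro)
        b = len(shared_set) - a
        c = len(remaining & intro)
        d = len(remaining) - c
        out.update(
            n_shared=len(shared_set),
            n_shared_overlapping=a,
            frac_shared_overlapping=a / len(shared_set) if shared_set else 0.0,
            frac_remaining_overlapping=c / len(remaining) if remaining else 0.0,
        )
        table = np.array([[a, b], [c, d]], dtype=float)
        if table.sum() > 0 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p = chi_square_2x2(table)
            out.update(chi2=chi2, p_value=p)
    return out
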