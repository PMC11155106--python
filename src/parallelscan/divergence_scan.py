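"""Z-standardization of window statistics, HDR calling and sharing.

A window's statistic (Fst or Dxy) is standardized across all defined
windows of one species pair: ``Z = (value - mean) / sd`` (sample sd).
Windows with Z >= 2 are highly diverged regions (HDRs).  "Shared" HDRs are
grid windows called in both species pairs; sharing enrichment is tested
with a plain 2x2 chi-square (no continuity correction), and group
comparisons (HDR vs non-HDR values) use Welch's t-test.  No
multiple-testing correction is applied to these scan-level tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import RegionSet


def zscore(values: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize to mean 0 / sample sd 1 over defined (non-NaN) entries;
    NaNs are preserved."""
    x = np.asarray(values, dtype=float)
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined windows to standardize")
    mean = x[defined].mean()
    sd = x[defined].std(ddof=1)
    if sd == 0:
        raise ValueError("constant input: standard deviation is zero")
    z = np.full_like(x, np.nan)
    z[defined] = (x[defined] - mean) / sd
    return z


@dataclass
class HDRSet:
    """HDR windows for one species pair and one statistic."""

    regions: RegionSet
    statistic: str = ""
    pair: str = ""

    def __len__(self) -> int:
        return len(self.regions)


def call_hdrs(
    windows: pd.DataFrame,
    z: np.ndarray,
    threshold: float = 2.0,
    statistic: str = "",
    pair: str = "",
) -> HDRSet:
    """Windows with Z >= threshold (inclusive), in genomic order.

    ``windows`` must carry ``chrom, start, end`` aligned with ``z``.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != len(windows):
        raise ValueError("z track and window grid lengths differ")
    with np.errstate(invalid="ignore"):
        keep = np.flatnonzero(~np.isnan(z) & (z >= threshold))
    intervals = [
        (windows["chrom"].iat[i], int(windows["start"].iat[i]), int(windows["end"].iat[i]))
        for i in keep
    ]
    ann = pd.DataFrame({"z": z[keep]})
    return HDRSet(regions=RegionSet(intervals, annotation=ann), statistic=statistic, pair=pair)


def call_top_quantile(
    windows: pd.DataFrame, values: np.ndarray, top_frac: float = 0.10,
    statistic: str = "", pair: str = "",
) -> HDRSet:
    """Alternative HDR mode: the top ``top_frac`` of defined windows by raw value."""
    x = np.asarray(values, dtype=float)
    defined = np.flatnonzero(~np.isnan(x))
    k = int(np.ceil(top_frac * len(defined)))
    order = defined[np.argsort(-x[defined], kind="stable")][:k]
    order = np.sort(order)
    intervals = [
        (windows["chrom"].iat[i], int(windows["start"].iat[i]), int(windows["end"].iat[i]))
        for i in order
    ]
    return HDRSet(regions=RegionSet(intervals), statistic=statistic, pair=pair)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Plain Pearson chi-square (1 df, no Yates correction) on a 2x2 table.

    Warns when any expected count is below 5 (Fisher's exact test would be
    more appropriate there).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5 in 2x2 table; consider Fisher's exact test")
    return float(chi2), float(p)


@dataclass
class SharedHDRReport:
    n_hdr_a: int
    n_hdr_b: int
    n_shared: int
    prop_shared_a: float
    prop_shared_b: float
    table: np.ndarray = field(repr=False)
    chi2: float = np.nan
    p_value: float = np.nan

    def to_dict(self) -> dict:
        return {
            "n_hdr_a": self.n_hdr_a,
            "n_hdr_b": self.n_hdr_b,
            "n_shared": self.n_shared,
            "prop_shared_a": self.prop_shared_a,
            "prop_shared_b": self.prop_shared_b,
            "chi2": self.chi2,
            "p_value": self.p_value,
        }


def shared_hdrs(hdr_a: HDRSet, hdr_b: HDRSet, grid: pd.DataFrame) -> SharedHDRReport:
    """Count grid windows that are HDRs in both pairs and test whether HDR
    windows of pair A are shared (HDR in pair B) more or less often than
    non-HDR windows are.

    The 2x2 table is {HDR_A, non-HDR_A} x {HDR_B, non-HDR_B} over all grid
    windows.
    """
    grid_set = {
        (grid["chrom"].iat[i], int(grid["start"].iat[i]), int(grid["end"].iat[i]))
        for i in range(len(grid))
    }
    set_a, set_b = hdr_a.regions.as_set(), hdr_b.regions.as_set()
    if not set_a <= grid_set or not set_b <= grid_set:
        raise ValueError("HDR sets are not subsets of the window grid")
    shared = set_a & set_b
    n_grid = len(grid_set)
    table = np.array(
        [
            [len(shared), len(set_a) - len(shared)],
            [len(set_b) - len(shared), n_grid - len(set_a) - len(set_b) + len(shared)],
        ],
        dtype=float,
    )
    chi2 = p = np.nan
    if table.sum() > 0 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p = chi_square_2x2(table)
    return SharedHDRReport(
        n_hdr_a=len(set_a),
        n_hdr_b=len(set_b),
        n_shared=len(shared),
        prop_shared_a=len(shared) / len(set_a) if set_a else 0.0,
        prop_shared_b=len(shared) / len(set_b) if set_b else 0.0,
        table=table,
        chi2=chi2,
        p_value=p,
    )


def selection_overlap(
    hdrs: HDRSet, windows: pd.DataFrame, scores: np.ndarray, top_frac: float = 0.05
) -> tuple[RegionSet, dict]:
    """HDR windows whose selection score (e.g. XP-CLR/XP-EHH) ranks in the
    top ``top_frac`` of defined scores — candidate positive-selection HDRs."""
    x = np.asarray(scores, dtype=float)
    if len(x) != len(windows):
        raise ValueError("score track and window grid lengths differ")
    defined = np.flatnonzero(~np.isnan(x))
    if len(defined) == 0:
        raise ValueError("all scores are NA")
    k = int(np.ceil(top_frac * len(defined)))
    top_idx = defined[np.argsort(-x[defined], kind="stable")][:k]
    top_set = {
        (windows["chrom"].iat[i], int(windows["start"].iat[i]), int(windows["end"].iat[i]))
        for i in top_idx
    }
    selected = sorted(hdrs.regions.as_set() & top_set)
    report = {
        "n_hdrs": len(hdrs.regions),
        "n_top_windows": len(top_set),
        "n_selected": len(selected),
        "frac_hdrs_selected": len(selected) / len(hdrs.regions) if len(hdrs.regions) else 0.0,
    }
    return RegionSet(selected), report


def compare_groups(values_in, values_out) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between two groups of window values."""
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 defined values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
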