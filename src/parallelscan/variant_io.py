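"""Reading/writing VCF, popmap, BED, score tables and FASTA; site filters.

Only biallelic SNPs enter the :class:`~parallelscan.core.GenotypeMatrix`;
multiallelic records and indels are dropped on read (with a logged count).
Genotype phase is discarded — every statistic downstream is computed on
alt-allele dosage.  Depth/quality filtering belongs upstream of this
toolkit: the matrix is the entry point, and only minor-allele-frequency and
missingness filters are applied here (vcftools ``--maf`` / ``--max-missing``
semantics, inclusive thresholds).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, PopulationMap, RegionSet

logger = logging.getLogger(__name__)

#: Unordered heterozygote base pair -> IUPAC ambiguity code.
IUPAC_HET = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

_NUCS = set("ACGT")


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _NUCS
        and alts[0].upper() in _NUCS
    )


def read_vcf(path: str | Path, keep_samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix, keeping only biallelic SNP records.

    Parameters
    ----------
    path
        VCF 4.x file with GT fields.
    keep_samples
        Optional subset (and order) of samples to retain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample IDs in VCF header")
    if keep_samples is not None:
        missing = [s for s in keep_samples if s not in samples]
        if missing:
            raise KeyError(f"samples not in VCF: {missing}")

    rows: list[tuple[str, int, str, str]] = []
    dosage_cols: list[np.ndarray] = []
    n_dropped = 0
    saw_gt = False
    for var in vcf:
        if not _is_biallelic_snp(var.REF, var.ALT):
            n_dropped += 1
            continue
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        if gts is None:
            raise ValueError(f"{path}: record without GT field at {var.CHROM}:{var.POS}")
        saw_gt = True
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            else:
                col[i] = a + b
        rows.append((var.CHROM, var.POS, var.REF.upper(), var.ALT[0].upper()))
        dosage_cols.append(col)
    if rows and not saw_gt:
        raise ValueError(f"{path}: no GT genotypes found")
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records from %s", n_dropped, path)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites, samples, dosage)
    if keep_samples is not None:
        gm = gm.take_samples(list(keep_samples))
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path, contigs: Sequence[tuple[str, int]] | None = None) -> None:
    """Write a minimal deterministic VCF (GT only, unphased)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if contigs is None:
        seen: dict[str, int] = {}
        for chrom, pos in zip(gm.sites["chrom"], gm.sites["pos"]):
            seen[chrom] = max(seen.get(chrom, 0), int(pos))
        contigs = list(seen.items())
    for chrom, length in contigs:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    gt_repr = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    sites = gm.sites
    for j in range(gm.n_sites):
        fields = [
            str(sites["chrom"].iat[j]),
            str(int(sites["pos"].iat[j])),
            ".",
            sites["ref"].iat[j],
            sites["alt"].iat[j],
            ".",
            "PASS",
            ".",
            "GT",
        ]
        fields.extend(gt_repr[int(gm.dosage[i, j])] for i in range(gm.n_samples))
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def filter_sites(gm: GenotypeMatrix, min_maf: float = 0.02, max_missing: float = 0.5) -> GenotypeMatrix:
    """Keep sites with MAF >= ``min_maf`` and missing fraction <= ``max_missing``.

    MAF is computed over non-missing genotypes only; thresholds are
    inclusive, matching vcftools ``--maf`` / ``--max-missing``
    (``max_missing`` here is the tolerated *missing* fraction).  Idempotent.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if gm.n_sites == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    alt, n_called = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    maf = np.fmin(p, 1 - p)
    miss_frac = (gm.dosage == MISSING).mean(axis=0)
    keep = (miss_frac <= max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    n_out = int((~keep).sum())
    if n_out:
        logger.info("filter_sites: removed %d of %d sites", n_out, gm.n_sites)
    return gm.take_sites(keep)


def export_iupac_fasta(
    gm: GenotypeMatrix,
    region: RegionSet | None = None,
    drop_invariant: bool = True,
) -> dict[str, str]:
    """One sequence per sample over variant sites, heterozygotes as IUPAC codes.

    Homozygotes are written as their base, heterozygotes as the ambiguity
    code for the unordered {ref, alt} pair, missing genotypes as ``N``.
    Columns with no variation among called characters are removed (the
    matrix may contain sites monomorphic within the exported sample set).
    """
    if gm.n_sites == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    if region is not None:
        keep = np.zeros(gm.n_sites, dtype=bool)
        chroms = gm.sites["chrom"].to_numpy()
        pos0 = gm.sites["pos"].to_numpy() - 1  # 0-based site coordinate
        for chrom, start, end in region:
            keep |= (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        gm = gm.take_sites(keep)
        if gm.n_sites == 0:
            raise ValueError("no sites fall in the requested region")

    cols = np.empty((gm.n_samples, gm.n_sites), dtype="U1")
    for j in range(gm.n_sites):
        ref = gm.sites["ref"].iat[j]
        alt = gm.sites["alt"].iat[j]
        het = IUPAC_HET.get(frozenset((ref, alt)))
        if het is None:
            raise ValueError(f"non-nucleotide alleles {ref}/{alt}")
        code = {0: ref, 1: het, 2: alt, MISSING: "N"}
        for i in range(gm.n_samples):
            cols[i, j] = code[int(gm.dosage[i, j])]

    if drop_invariant:
        keep_cols = []
        for j in range(gm.n_sites):
            called = {c for c in cols[:, j] if c != "N"}
            if len(called) > 1:
                keep_cols.append(j)
        cols = cols[:, keep_cols]
    return {s: "".join(cols[i, :]) for i, s in enumerate(gm.samples)}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# -- popmap ------------------------------------------------------------------

def read_popmap(path: str | Path) -> PopulationMap:
    """Parse ``sample<TAB>population`` (whitespace tolerated)."""
    assignment: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population', got {line!r}")
        assignment[parts[0]] = parts[1]
    return PopulationMap(assignment=assignment)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignment.items():
            fh.write(f"{s}\t{p}\n")


# -- BED ---------------------------------------------------------------------

def read_bed(path: str | Path) -> RegionSet:
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet(intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write intervals 0-based half-open (BED convention)."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# -- per-window score tables -------------------------------------------------

def read_score_track(path: str | Path) -> pd.DataFrame:
    """Parse ``chrom  start  end  score`` (e.g. XP-CLR/XP-EHH window scores)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected chrom start end score")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def write_score_track(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=True, na_rep="NA")
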