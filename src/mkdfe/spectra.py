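"""Site-frequency spectra: data model, construction, projection, I/O.

The central container is :class:`Spectrum`, an SFS indexed by derived-allele
count (1-based).  An unfolded SFS over ``2n`` chromosomes has ``2n - 1``
entries; a folded SFS merges mirror classes ``k`` and ``2n - k`` and has
``n`` entries.  Counts may be fractional: hypergeometric projection of SNPs
onto a common subsample size produces expected (real-valued) class counts.

A :class:`PolyDivDataset` bundles, for one focal/outgroup species pair, the
non-synonymous and synonymous SFS together with fixed-difference counts and
site numbers -- everything the Poisson likelihood consumes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A site-frequency spectrum.

    Parameters
    ----------
    counts
        SNP counts per derived-allele class, 1-based: entry ``j`` holds the
        (possibly fractional) number of SNPs with ``j + 1`` derived copies.
    n_chrom
        Number of sampled chromosomes (``2n``; even).
    folded
        If True, classes ``k`` and ``2n - k`` are merged and ``counts`` has
        ``n`` entries; otherwise ``2n - 1``.
    """

    counts: np.ndarray
    n_chrom: int
    folded: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.n_chrom < 2 or self.n_chrom % 2:
            raise ValueError(f"n_chrom must be a positive even integer, got {self.n_chrom}")
        expected = self.n_chrom // 2 if self.folded else self.n_chrom - 1
        if counts.ndim != 1 or len(counts) != expected:
            raise ValueError(
                f"SFS length {len(counts)} inconsistent with n_chrom={self.n_chrom}, "
                f"folded={self.folded} (expected {expected})"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("SFS counts must be finite and non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    def total(self) -> float:
        """Total number of SNPs in the spectrum."""
        return float(self.counts.sum())


@dataclass(frozen=True)
class PolyDivDataset:
    """Polymorphism and divergence summary for one species pair.

    ``D_N``/``D_S`` are counts of fixed non-synonymous/synonymous differences
    to the outgroup; ``L_N``/``L_S`` the corresponding site numbers for the
    polymorphism data, ``Ldiv_N``/``Ldiv_S`` for the divergence data (these
    may differ when within- and between-species alignments cover different
    site sets; by default they are equal).
    """

    label: str
    sfs_nonsyn: Spectrum
    sfs_syn: Spectrum
    D_N: float
    D_S: float
    L_N: float
    L_S: float
    Ldiv_N: float = 0.0
    Ldiv_S: float = 0.0

    def __post_init__(self) -> None:
        if self.sfs_nonsyn.n_chrom != self.sfs_syn.n_chrom:
            raise ValueError("non-synonymous and synonymous SFS must share n_chrom")
        if self.sfs_nonsyn.folded != self.sfs_syn.folded:
            raise ValueError("non-synonymous and synonymous SFS must share folded flag")
        if self.L_N <= 0 or self.L_S <= 0:
            raise ValueError("site numbers L_N, L_S must be positive")
        if self.D_N < 0 or self.D_S < 0:
            raise ValueError("divergence counts must be non-negative")
        if self.Ldiv_N <= 0:
            object.__setattr__(self, "Ldiv_N", self.L_N)
        if self.Ldiv_S <= 0:
            object.__setattr__(self, "Ldiv_S", self.L_S)

    @property
    def n_chrom(self) -> int:
        return self.sfs_syn.n_chrom

    @property
    def folded(self) -> bool:
        return self.sfs_syn.folded

    @property
    def dn(self) -> float:
        """Per-site non-synonymous divergence d_N."""
        return self.D_N / self.Ldiv_N

    @property
    def ds(self) -> float:
        """Per-site synonymous divergence d_S."""
        return self.D_S / self.Ldiv_S


@dataclass(frozen=True)
class SNPRecord:
    """One raw SNP: focal-species allele counts plus the outgroup state.

    ``outgroup_state`` is a nucleotide, or the sentinel strings
    ``"polymorphic"`` / ``"missing"``.
    """

    focal_alleles: dict[str, int]
    outgroup_state: str
    site_class: str  # "synonymous" | "non-synonymous"

    @property
    def genotyped_chrom(self) -> int:
        return sum(self.focal_alleles.values())


# ---------------------------------------------------------------------------
# SFS construction
# ---------------------------------------------------------------------------

def orient_and_filter(
    snps: Iterable[SNPRecord],
) -> list[tuple[int, int, str]]:
    """Orient SNPs by the outgroup state and drop unusable ones.

    Keeps only bi-allelic SNPs whose outgroup state is a nucleotide matching
    one of the two focal alleles; the derived allele is the one *not* seen in
    the outgroup.  Returns ``(derived_count, genotyped_chrom, site_class)``
    tuples.  Discards are silent but tallied to the module logger by reason.
    """
    kept: list[tuple[int, int, str]] = []
    reasons: Counter[str] = Counter()
    for snp in snps:
        alleles = {a: c for a, c in snp.focal_alleles.items() if c > 0}
        if len(alleles) != 2:
            reasons["not_biallelic"] += 1
            continue
        out = snp.outgroup_state
        if out in ("missing", "polymorphic"):
            reasons[f"outgroup_{out}"] += 1
            continue
        if out not in alleles:
            reasons["outgroup_not_focal_allele"] += 1
            continue
        (derived,) = [a for a in alleles if a != out]
        kept.append((alleles[derived], snp.genotyped_chrom, snp.site_class))
        reasons["kept"] += 1
    logger.info("orient_and_filter: %s", dict(reasons))
    return kept


def project_sfs(
    snps: Sequence[tuple[int, int]],
    target_chrom: int,
) -> Spectrum:
    """Hypergeometric projection of observed SNPs onto a common sample size.

    Each SNP with ``i`` derived copies among ``2n`` genotyped chromosomes
    contributes to class ``j`` of the target spectrum (size ``2m``) the
    probability that a without-replacement subsample of ``2m`` chromosomes
    contains exactly ``j`` derived copies.  Weight landing on classes 0 and
    ``2m`` (monomorphic after subsampling) is dropped, not renormalized.
    SNPs genotyped in fewer than ``target_chrom`` chromosomes are discarded.
    """
    if target_chrom < 2:
        raise ValueError("target_chrom must be >= 2")
    counts = np.zeros(target_chrom - 1)
    n_discarded = 0
    j = np.arange(target_chrom + 1)
    for i, n_chrom in snps:
        if n_chrom < target_chrom:
            n_discarded += 1
            continue
        if not 1 <= i <= n_chrom - 1:
            raise ValueError(f"derived count {i} outside (0, {n_chrom})")
        # P(j derived in subsample of 2m | i derived among 2n)
        weights = hypergeom.pmf(j, n_chrom, i, target_chrom)
        counts += weights[1:-1]
    if n_discarded:
        logger.info(
            "project_sfs: discarded %d SNPs genotyped in < %d chromosomes",
            n_discarded, target_chrom,
        )
    return Spectrum(counts=counts, n_chrom=target_chrom, folded=False)


def default_target_size(total_individuals: int) -> int:
    """Diploid subsample size n used for projection, given total sample size.

    4 for 4-5 individuals, 5 for 6, 6 for 7-8, 7 above 8.
    """
    if total_individuals < 4:
        raise ValueError("at least 4 individuals are required")
    if total_individuals <= 5:
        return 4
    if total_individuals == 6:
        return 5
    if total_individuals <= 8:
        return 6
    return 7


def fold(sfs: Spectrum) -> Spectrum:
    """Fold an unfolded SFS: merge mirror classes k and 2n-k."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n_chrom // 2
    counts = np.empty(n)
    u = sfs.counts
    for k in range(1, n):
        counts[k - 1] = u[k - 1] + u[sfs.n_chrom - k - 1]
    counts[n - 1] = u[n - 1]
    return Spectrum(counts=counts, n_chrom=sfs.n_chrom, folded=True)


def pi_from_sfs(sfs: Spectrum, n_sites: float) -> float:
    """Per-site nucleotide diversity (unbiased pairwise heterozygosity).

    pi = (1/L) * sum_i counts[i] * 2 i (2n - i) / (2n (2n - 1)).  Folded
    spectra give the same value because i(2n - i) is mirror-symmetric.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    two_n = sfs.n_chrom
    i = np.arange(1, sfs.n_classes + 1)
    per_snp = 2.0 * i * (two_n - i) / (two_n * (two_n - 1))
    return float(np.dot(sfs.counts, per_snp)) / n_sites


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "#sfs_format v1"


def write_dataset(datasets: Sequence[PolyDivDataset], path) -> None:
    """Write datasets in the tab-separated flat format (one line per pair)."""
    if not datasets:
        raise ValueError("no datasets to write")
    folded = datasets[0].folded
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX} {'folded' if folded else 'unfolded'}\n")
        for ds in datasets:
            if ds.folded != folded:
                raise ValueError("all datasets in one file must share folded flag")
            fields = [ds.label, str(ds.n_chrom), _fmt(ds.L_N)]
            fields += [_fmt(v) for v in ds.sfs_nonsyn.counts]
            fields.append(_fmt(ds.L_S))
            fields += [_fmt(v) for v in ds.sfs_syn.counts]
            fields += [_fmt(ds.Ldiv_N), _fmt(ds.D_N), _fmt(ds.Ldiv_S), _fmt(ds.D_S)]
            fh.write("\t".join(fields) + "\n")


def _fmt(x: float) -> str:
    return repr(float(x))


def read_dataset(path) -> list[PolyDivDataset]:
    """Read datasets from the flat format; see :func:`write_dataset`."""
    datasets: list[PolyDivDataset] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise ValueError(f"line 1: bad header {header!r}")
        mode = header[len(_HEADER_PREFIX):].strip()
        if mode not in ("unfolded", "folded"):
            raise ValueError(f"line 1: orientation must be 'unfolded' or 'folded', got {mode!r}")
        folded = mode == "folded"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                datasets.append(_parse_record(fields, folded))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return datasets


def _parse_record(fields: list[str], folded: bool) -> PolyDivDataset:
    label = fields[0]
    n_chrom = int(fields[1])
    k = n_chrom // 2 if folded else n_chrom - 1
    expected_len = 2 + 1 + k + 1 + k + 4
    if len(fields) != expected_len:
        raise ValueError(
            f"expected {expected_len} fields for 2n={n_chrom} "
            f"({'folded' if folded else 'unfolded'}), got {len(fields)}"
        )
    pos = 2
    L_N = float(fields[pos]); pos += 1
    pn = np.array([float(v) for v in fields[pos:pos + k]]); pos += k
    L_S = float(fields[pos]); pos += 1
    ps = np.array([float(v) for v in fields[pos:pos + k]]); pos += k
    Ldiv_N, D_N, Ldiv_S, D_S = (float(v) for v in fields[pos:pos + 4])
    if np.any(pn < 0) or np.any(ps < 0):
        raise ValueError("negative SFS counts")
    return PolyDivDataset(
        label=label,
        sfs_nonsyn=Spectrum(pn, n_chrom, folded),
        sfs_syn=Spectrum(ps, n_chrom, folded),
        D_N=D_N, D_S=D_S, L_N=L_N, L_S=L_S, Ldiv_N=Ldiv_N, Ldiv_S=Ldiv_S,
    )


def fold_dataset(ds: PolyDivDataset) -> PolyDivDataset:
    """Fold both spectra of a dataset (divergence data unchanged)."""
    return replace(ds, sfs_nonsyn=fold(ds.sfs_nonsyn), sfs_syn=fold(ds.sfs_syn))
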