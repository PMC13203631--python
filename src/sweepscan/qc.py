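"""Site-level quality control: missingness, minor allele frequency and
Hardy–Weinberg equilibrium filters.

Filters are applied in the order missingness → MAF → HWE on the merged
two-population matrix, and a removed site is attributed to the first
filter that rejects it.  Boundary behavior follows a strict reading of
the thresholds: a site with missing rate exactly equal to the maximum, or
MAF exactly equal to the minimum, is retained.

Testing HWE on a merged sample of two diverged populations conflates the
Wahlund effect with genotyping error; a per-population mode
(``per_population=True``) tests each population separately and removes a
site if it fails in either.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix, PopulationMap, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    max_missing_rate: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    sites_before: int
    sites_after: int
    removed_missing: int
    removed_maf: int
    removed_hwe: int
    #: per-site flag: "pass", "missing", "maf" or "hwe"
    site_flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"sites before QC: {self.sites_before}\n"
            f"removed by missingness filter: {self.removed_missing}\n"
            f"removed by MAF filter: {self.removed_maf}\n"
            f"removed by HWE filter: {self.removed_hwe}\n"
            f"sites after QC: {self.sites_after}\n"
        )


def site_missing_rate(gm: GenotypeMatrix, site_index: int) -> float:
    """Fraction of samples with a missing call at one site."""
    col = gm.dosage[:, site_index]
    return float(np.count_nonzero(col == MISSING)) / gm.n_samples


def minor_allele_frequency(gm: GenotypeMatrix, site_index: int) -> float:
    """Folded allele frequency over non-missing genotypes; NaN if all calls
    are missing."""
    col = gm.dosage[:, site_index]
    ok = col != MISSING
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    f = float(col[ok].sum()) / (2 * n)
    return min(f, 1 - f)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test.

    Conditions on the observed allele counts: with ``n`` diploid
    individuals and ``n_a`` copies of the rarer allele fixed, the
    heterozygote count ``k`` (same parity as ``n_a``) has probability
    proportional to ``n! / (n_AA! k! n_aa!) * 2**k``.  The p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValidationError("need at least one genotype")
    n_a = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor-allele copies
    probs, ks = _hwe_het_distribution(n, n_a)
    p_obs = probs[ks == n_het][0]
    # tolerance guards against log-space rounding splitting exact ties
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given ``n``
    individuals and ``n_a`` minor-allele copies.  Returns (probabilities,
    heterozygote counts), parity-matched to ``n_a``."""
    ks = np.arange(n_a % 2, n_a + 1, 2)
    ks = ks[(n_a - ks) // 2 + ks <= n]  # n_minor_hom + het cannot exceed n
    n_minor_hom = (n_a - ks) // 2
    n_major_hom = n - ks - n_minor_hom
    valid = n_major_hom >= 0
    ks, n_minor_hom, n_major_hom = ks[valid], n_minor_hom[valid], n_major_hom[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(n_major_hom + 1)
        - gammaln(ks + 1)
        - gammaln(n_minor_hom + 1)
        + ks * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return p, ks


def genotype_counts(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """(n_sites, 3) counts of hom-ref / het / hom-alt over non-missing calls."""
    d = gm.dosage if sample_idx is None else gm.dosage[sample_idx, :]
    return np.stack([(d == g).sum(axis=0) for g in (0, 1, 2)], axis=1)


def hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    """Vectorized exact HWE p-values for an (n_sites, 3) count array.
    Duplicate count triples are computed once."""
    counts = np.asarray(counts)
    uniq, inverse = np.unique(counts, axis=0, return_inverse=True)
    pvals = np.array([hwe_exact_test(*row) for row in uniq])
    return pvals[inverse]


def apply_qc(
    gm: GenotypeMatrix,
    popmap: PopulationMap | None,
    thresholds: QCThresholds = QCThresholds(),
    per_population: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter sites by missingness, MAF and HWE, in that order.

    Missingness and MAF are always computed on the merged matrix.  HWE is
    tested on the merged matrix by default, or per population when
    ``per_population`` is set (requires ``popmap``).
    """
    d = gm.dosage
    n_sites = gm.n_sites
    miss_rate = (d == MISSING).sum(axis=0) / gm.n_samples
    n_nonmiss = ((d != MISSING).sum(axis=0)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(d == MISSING, 0, d).sum(axis=0) / (2 * n_nonmiss)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    fail_missing = miss_rate > thresholds.max_missing_rate
    fail_maf = ~fail_missing & ((maf < thresholds.min_maf) | np.isnan(maf))

    candidate = ~fail_missing & ~fail_maf
    fail_hwe = np.zeros(n_sites, dtype=bool)
    if candidate.any():
        if per_population:
            if popmap is None:
                raise ValidationError("per-population HWE requires a population map")
            for lab in popmap.labels:
                idx = popmap.indices(gm.samples, lab)
                counts = genotype_counts(gm.take_sites(np.where(candidate)[0]), idx)
                p = hwe_pvalues(counts)
                fail_hwe[np.where(candidate)[0][p < thresholds.hwe_alpha]] = True
        else:
            counts = genotype_counts(gm.take_sites(np.where(candidate)[0]))
            p = hwe_pvalues(counts)
            fail_hwe[np.where(candidate)[0][p < thresholds.hwe_alpha]] = True

    keep = ~(fail_missing | fail_maf | fail_hwe)
    flags = np.full(n_sites, "pass", dtype=object)
    flags[fail_hwe] = "hwe"
    flags[fail_maf] = "maf"
    flags[fail_missing] = "missing"

    filtered = gm.take_sites(np.where(keep)[0])
    report = QCReport(
        sites_before=n_sites,
        sites_after=int(keep.sum()),
        removed_missing=int(fail_missing.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        site_flags=list(flags),
    )
    if report.sites_after == 0:
        warnings.warn("no sites survive QC; returning an empty matrix")
    return filtered, report
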