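"""Sliding-window selection-signature scan.

Per SNP site the scan computes the two-population differentiation
statistic

    F_ST = (pA − pB)^2 / (pA (1 − pA) + pB (1 − pB))

from the per-population alternate-allele frequencies, and within each
population the pairwise nucleotide diversity

    π = 1 / (n (n − 1)) * Σ_{i<j} d_ij,    d_ij = |g_i − g_j| / 2,

where ``g`` are diploid dosages, so ``d_ij`` ∈ {0, 0.5, 1}.  Sites are
aggregated over 50-kb windows advanced in 25-kb steps: window F_ST is the
unweighted mean of the defined per-site values, window π is the summed
per-site π divided by the window span in bp, and the two populations'
diversities are compared as ``log2(π_A / π_B)``.  Windows in the upper
tail of the genome-wide F_ST distribution that are simultaneously in an
extreme tail of the log2 ratio are candidate sweep regions: a high ratio
(diversity lost in B) marks selection in population B, a low ratio marks
selection in population A.

Note the per-site F_ST expression above is not bounded by 1 for
intermediate frequencies (e.g. pA = 0.9, pB = 0.1 gives 3.56); values are
clipped at 1.0 and the clip count is reported.  Hudson's estimator and
the Weir–Cockerham (ratio-of-averages) estimator are available as
alternatives.  The π normalization 1/(n(n−1)) is half the conventional
mean over C(n, 2) pairs; the log2 ratio is invariant to any constant
factor shared by both populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap, ValidationError

UNDEFINED = float("nan")

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_STEP = 25_000
DEFAULT_MIN_SNPS = 3


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    snp_count: int = 0

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError(f"window [{self.start}, {self.end}) is empty")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanThresholds:
    fst_top_fraction: float = 0.05
    ratio_tail_fraction: float = 0.025

    def __post_init__(self) -> None:
        for name in ("fst_top_fraction", "ratio_tail_fraction"):
            v = getattr(self, name)
            if not (0 < v < 0.5):
                raise ValidationError(f"{name} must be in (0, 0.5), got {v}")


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    direction: str  # "SELECTED_IN_A" | "SELECTED_IN_B"
    n_windows: int
    gene_ids: tuple[str, ...] = ()


@dataclass
class ScanResult:
    """Per-window statistics table plus bookkeeping counters.

    ``table`` columns: chrom, start, end, n_snps, fst, pi_A, pi_B,
    log2_ratio.  Undefined values are NaN; an infinite log2 ratio marks a
    window where exactly one population has zero diversity.
    """

    table: pd.DataFrame
    pop_a: str
    pop_b: str
    fst_clip_count: int = 0
    counters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def fst_site(p_a: float, p_b: float) -> float:
    """Two-population per-site F_ST; NaN when both populations are fixed
    for the same allele, 1.0 for a fixed difference, clipped at 1."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise ValidationError(f"allele frequencies must be in [0,1], got {p_a}, {p_b}")
    denom = p_a * (1 - p_a) + p_b * (1 - p_b)
    if denom == 0:
        return 1.0 if p_a != p_b else UNDEFINED
    return min(1.0, (p_a - p_b) ** 2 / denom)


def _fst_sites_eq(p_a: np.ndarray, p_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized per-site F_ST (direct-ratio form, clipped at 1).
    Returns (values with NaN where undefined, clip count)."""
    denom = p_a * (1 - p_a) + p_b * (1 - p_b)
    num = (p_a - p_b) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = num / denom
    raw = np.where(denom == 0, np.where(num > 0, 1.0, np.nan), raw)
    clip_count = int(np.nansum(raw > 1.0))
    return np.minimum(raw, 1.0), clip_count


def _fst_components_hudson(p_a, p_b, n_a, n_b):
    """Hudson estimator components: numerator and denominator per site."""
    num = (p_a - p_b) ** 2 - p_a * (1 - p_a) / np.maximum(n_a - 1, 1) \
        - p_b * (1 - p_b) / np.maximum(n_b - 1, 1)
    den = p_a * (1 - p_b) + p_b * (1 - p_a)
    return num, den


def _fst_components_wc(p_a, p_b, n_a, n_b, het_a, het_b):
    """Weir–Cockerham variance components (a, a+b+c) per site for two
    populations, from frequencies and observed heterozygosities."""
    r = 2.0
    n_bar = (n_a + n_b) / r
    nc = (n_a + n_b - (n_a**2 + n_b**2) / (n_a + n_b)) / (r - 1)
    p_bar = (n_a * p_a + n_b * p_b) / (n_a + n_b)
    s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n_a * het_a + n_b * het_b) / (n_a + n_b)
    pq = p_bar * (1 - p_bar)
    a = n_bar / nc * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, a + b + c


def pi_pairwise_site(dosages) -> float:
    """Per-site nucleotide diversity over one population's non-missing
    dosages: ``1/(n(n−1)) Σ_{i<j} |g_i − g_j| / 2``.  NaN when fewer than
    two genotypes are available."""
    d = np.asarray([x for x in dosages if x != MISSING])
    n = len(d)
    if n < 2:
        return UNDEFINED
    n0 = int(np.sum(d == 0))
    n1 = int(np.sum(d == 1))
    n2 = int(np.sum(d == 2))
    pair_sum = 0.5 * (n0 * n1 + n1 * n2) + 1.0 * (n0 * n2)
    return pair_sum / (n * (n - 1))


def _pi_sites(dosage: np.ndarray) -> np.ndarray:
    """Vectorized per-site π for a (n_samples, n_sites) population slice.
    Sites with < 2 called genotypes get 0 (they contribute nothing to a
    window sum)."""
    n0 = (dosage == 0).sum(axis=0).astype(np.float64)
    n1 = (dosage == 1).sum(axis=0).astype(np.float64)
    n2 = (dosage == 2).sum(axis=0).astype(np.float64)
    n = n0 + n1 + n2
    pair_sum = 0.5 * (n0 * n1 + n1 * n2) + n0 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = pair_sum / (n * (n - 1))
    return np.where(n >= 2, pi, 0.0)


def log2_pi_ratio(pi_a: float, pi_b: float) -> float:
    """log2(π_A / π_B); ±inf when exactly one diversity is zero (complete
    local loss of diversity — the strongest possible sweep signal), NaN
    when both are zero."""
    if pi_a < 0 or pi_b < 0:
        raise ValidationError("pi values must be non-negative")
    if pi_a > 0 and pi_b > 0:
        return math.log2(pi_a / pi_b)
    if pi_a > 0:
        return float("inf")
    if pi_b > 0:
        return float("-inf")
    return UNDEFINED


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    chrom_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> list[Window]:
    """Sliding windows starting at 0, step, 2·step, … per chromosome; a
    window is emitted iff its start is inside the chromosome, and its end
    is truncated to the chromosome length."""
    if not (window_size >= step > 0):
        raise ValidationError("need window_size >= step > 0")
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + window_size, length)))
            start += step
    return windows


def _window_site_slices(sites: pd.DataFrame, windows: list[Window]) -> list[np.ndarray]:
    """Index arrays of in-window sites (0-based site coordinates = pos − 1).
    Sites are coordinate-sorted, so each chromosome is a contiguous run
    and each window resolves to two binary searches."""
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    by_chrom: dict[str, tuple[int, np.ndarray]] = {}
    start = 0
    while start < len(chroms):
        end = start
        while end < len(chroms) and chroms[end] == chroms[start]:
            end += 1
        by_chrom[chroms[start]] = (start, pos0[start:end])
        start = end
    empty = np.array([], dtype=np.intp)
    out = []
    for w in windows:
        if w.chrom not in by_chrom:
            out.append(empty)
            continue
        offset, p = by_chrom[w.chrom]
        lo = int(np.searchsorted(p, w.start, side="left"))
        hi = int(np.searchsorted(p, w.end, side="left"))
        out.append(np.arange(offset + lo, offset + hi, dtype=np.intp))
    return out


def window_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    min_snps: int = DEFAULT_MIN_SNPS,
    estimator: str = "direct",
) -> tuple[np.ndarray, int]:
    """Per-window F_ST.  ``estimator``:

    - ``"direct"`` (default): unweighted mean of the per-site direct
      formula, clipped at 1;
    - ``"hudson"``: ratio of summed Hudson numerator/denominator
      components over the window;
    - ``"wc"``: ratio of summed Weir–Cockerham variance components.

    Windows with fewer than ``min_snps`` defined sites are NaN.
    Returns (values, per-site clip count — 0 for the ratio estimators).
    """
    lab_a, lab_b = popmap.labels
    ia = popmap.indices(gm.samples, lab_a)
    ib = popmap.indices(gm.samples, lab_b)
    p_a, n_a, het_a = _pop_freqs(gm.dosage[ia, :])
    p_b, n_b, het_b = _pop_freqs(gm.dosage[ib, :])
    slices = _window_site_slices(gm.sites, windows)
    values = np.full(len(windows), np.nan)
    clip_total = 0
    if estimator == "direct":
        site_fst, clip_total = _fst_sites_eq(p_a, p_b)
        for wi, idx in enumerate(slices):
            vals = site_fst[idx]
            vals = vals[~np.isnan(vals)]
            if len(vals) >= min_snps:
                values[wi] = vals.mean()
    elif estimator in ("hudson", "wc"):
        callable_ = (n_a >= (2 if estimator == "hudson" else 1)) & (n_b >= 2)
        if estimator == "hudson":
            num, den = _fst_components_hudson(p_a, p_b, n_a, n_b)
        else:
            num, den = _fst_components_wc(p_a, p_b, n_a, n_b, het_a, het_b)
        defined = callable_ & (n_a > 0) & (n_b > 0)
        for wi, idx in enumerate(slices):
            idx = idx[defined[idx]]
            if len(idx) >= min_snps and den[idx].sum() != 0:
                values[wi] = num[idx].sum() / den[idx].sum()
    else:
        raise ValidationError(f"unknown F_ST estimator {estimator!r}")
    return values, clip_total


def _pop_freqs(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt frequency, called-sample count, observed het fraction)
    for one population slice; frequency is NaN where nothing is called."""
    obs = dosage != MISSING
    n = obs.sum(axis=0).astype(np.float64)
    alt = np.where(obs, dosage, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        het = (dosage == 1).sum(axis=0) / n
    return p, n, het


def window_pi(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray,
    windows: list[Window],
) -> np.ndarray:
    """Per-window diversity of one population, per bp: summed per-site π
    over in-window sites divided by the window span.  Sites with fewer
    than two called genotypes contribute 0."""
    site_pi = _pi_sites(gm.dosage[sample_idx, :])
    slices = _window_site_slices(gm.sites, windows)
    out = np.zeros(len(windows))
    for wi, idx in enumerate(slices):
        w = windows[wi]
        out[wi] = site_pi[idx].sum() / w.span
    return out


# ---------------------------------------------------------------------------
# Full scan, thresholds, candidates
# ---------------------------------------------------------------------------

def scan_windows(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
    estimator: str = "direct",
) -> ScanResult:
    """Windowed F_ST / π / log2-ratio table for a QC'd two-population
    matrix.  Population A is the lexicographically first label."""
    popmap.validate_against(gm, scan_mode=True)
    lab_a, lab_b = popmap.labels
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(sub["pos"].max()) for c, sub in gm.sites.groupby("chrom", sort=True)
        }
    windows = make_windows(chrom_lengths, window_size, step)
    slices = _window_site_slices(gm.sites, windows)
    n_snps = np.array([len(idx) for idx in slices])
    fst, clip_count = window_fst(gm, popmap, windows, min_snps, estimator)
    ia = popmap.indices(gm.samples, lab_a)
    ib = popmap.indices(gm.samples, lab_b)
    pi_a = window_pi(gm, ia, windows)
    pi_b = window_pi(gm, ib, windows)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (pi_a > 0) & (pi_b > 0),
            np.log2(np.where(pi_b > 0, pi_a, 1) / np.where(pi_b > 0, pi_b, 1)),
            np.where(
                (pi_a > 0) & (pi_b == 0),
                np.inf,
                np.where((pi_a == 0) & (pi_b > 0), -np.inf, np.nan),
            ),
        )
    # windows with no SNPs have pi 0/0: keep them NaN across the board
    empty = n_snps == 0
    ratio[empty] = np.nan
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": n_snps,
            "fst": fst,
            "pi_A": pi_a,
            "pi_B": pi_b,
            "log2_ratio": ratio,
        }
    )
    counters = {
        "n_windows": len(windows),
        "n_windows_fst_defined": int(np.isfinite(fst).sum()),
        "n_windows_ratio_defined": int((~np.isnan(ratio)).sum()),
        "n_windows_ratio_infinite": int(np.isinf(ratio).sum()),
        "fst_clip_count": clip_count,
    }
    return ScanResult(
        table=table, pop_a=lab_a, pop_b=lab_b, fst_clip_count=clip_count, counters=counters
    )


def percentile_cutoffs(values: np.ndarray, fraction: float, tail: str) -> float:
    """Empirical quantile threshold (linear interpolation between order
    statistics) for the upper (``tail="top"``) or lower (``tail="bottom"``)
    ``fraction`` of the finite values.  Selection downstream is strict, so
    ties at the threshold are excluded."""
    finite = np.asarray(values, dtype=float)
    finite = finite[np.isfinite(finite)]
    if len(finite) < 20:
        raise ValidationError(f"need >= 20 defined values, got {len(finite)}")
    if tail == "top":
        return float(np.quantile(finite, 1 - fraction))
    if tail == "bottom":
        return float(np.quantile(finite, fraction))
    raise ValidationError(f"tail must be 'top' or 'bottom', got {tail!r}")


def candidate_windows(
    result: ScanResult, thresholds: ScanThresholds = ScanThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Intersect the F_ST upper tail with each log2-ratio tail.

    Returns ``(selected_in_B, selected_in_A, info)`` where the first
    holds windows in the top F_ST fraction whose ratio is in the upper
    tail (diversity lost in B), and the second those whose ratio is in
    the lower tail (diversity lost in A).  Infinite ratios always belong
    to their tail; NaN windows are excluded from the respective ranking.
    """
    t = result.table
    fst = t["fst"].to_numpy(dtype=float)
    ratio = t["log2_ratio"].to_numpy(dtype=float)
    fst_thr = percentile_cutoffs(fst, thresholds.fst_top_fraction, "top")
    hi_thr = percentile_cutoffs(ratio, thresholds.ratio_tail_fraction, "top")
    lo_thr = percentile_cutoffs(ratio, thresholds.ratio_tail_fraction, "bottom")
    top_fst = np.isfinite(fst) & (fst > fst_thr)
    hi_ratio = (~np.isnan(ratio)) & (ratio > hi_thr)
    lo_ratio = (~np.isnan(ratio)) & (ratio < lo_thr)
    info = {
        "fst_threshold": fst_thr,
        "ratio_upper_threshold": hi_thr,
        "ratio_lower_threshold": lo_thr,
        "n_top_fst": int(top_fst.sum()),
        "n_upper_ratio": int(hi_ratio.sum()),
        "n_lower_ratio": int(lo_ratio.sum()),
    }
    sel_b = t[top_fst & hi_ratio].reset_index(drop=True)
    sel_a = t[top_fst & lo_ratio].reset_index(drop=True)
    return sel_b, sel_a, info


def merge_regions(selected: pd.DataFrame, direction: str) -> list[CandidateRegion]:
    """Merge overlapping or book-ended selected windows (one direction)
    into maximal candidate regions."""
    if len(selected) == 0:
        return []
    rows = selected.sort_values(["chrom", "start"]).itertuples(index=False)
    regions: list[CandidateRegion] = []
    cur_chrom, cur_start, cur_end, cur_n = None, 0, 0, 0
    for row in rows:
        if row.chrom == cur_chrom and row.start <= cur_end:
            cur_end = max(cur_end, row.end)
            cur_n += 1
        else:
            if cur_chrom is not None:
                regions.append(CandidateRegion(cur_chrom, cur_start, cur_end, direction, cur_n))
            cur_chrom, cur_start, cur_end, cur_n = row.chrom, row.start, row.end, 1
    regions.append(CandidateRegion(cur_chrom, cur_start, cur_end, direction, cur_n))
    return regions
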