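"""Population structure: PCA on a variance-standardized relationship
matrix, neighbor-joining from an allele-sharing distance matrix, and
NMF-based ancestry inference with held-out cross-entropy model selection.

The ancestry model factorizes the scaled dosage matrix ``X`` (entries
``g/2``) as ``X ≈ Q F`` with row-stochastic ancestry proportions ``Q``
(n × K) and cluster allele frequencies ``F`` (K × L) in [0, 1].  It is
fitted by alternating least squares with projection (Q rows onto the
probability simplex, F clipped to the unit interval); missing and
held-out entries are handled EM-style by re-imputing them with the
current reconstruction each sweep.  Model choice across K uses the
cross-entropy of the held-out entries, so extra clusters that only fit
noise are penalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, ValidationError


@dataclass
class RelationshipMatrix:
    values: np.ndarray  # (n, n)
    samples: list[str]
    n_sites_used: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("relationship matrix must be square")
        if not np.isfinite(v).all():
            raise ValidationError("relationship matrix has non-finite entries")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValidationError("relationship matrix not symmetric to 1e-10")


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n, k), eigenvector * sqrt(eigenvalue)
    variance_fraction: np.ndarray  # (k,)
    samples: list[str]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if np.abs(np.diag(v)).max() > 0:
            raise ValidationError("distance matrix diagonal must be zero")
        if np.abs(v - v.T).max() > 1e-12 or (v < 0).any():
            raise ValidationError("distance matrix must be symmetric and non-negative")


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (n, K) row-stochastic
    F: np.ndarray  # (K, L) in [0, 1]
    masked_cross_entropy: float
    K: int
    seed: int
    converged: bool
    loss_trace: list[float]


# ---------------------------------------------------------------------------
# Relationship matrix and PCA
# ---------------------------------------------------------------------------

def relationship_matrix(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Variance-standardized genomic relationship matrix.

    Per polymorphic site ``j`` with alt-allele frequency ``p_j`` (over
    non-missing calls), genotypes are standardized to
    ``z = (g − 2 p_j) / sqrt(2 p_j (1 − p_j))``; missing entries
    contribute 0 after standardization (mean imputation).  Returns
    ``Z Zᵀ / m`` over the ``m`` sites used.
    """
    if gm.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    d = gm.dosage.astype(np.float64)
    obs = gm.dosage != MISSING
    d[~obs] = 0.0
    n_obs = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2 * n_obs)
    poly = (p > 0) & (p < 1) & (n_obs > 0)
    if not poly.any():
        raise ValidationError("all sites monomorphic; relationship matrix undefined")
    p = p[poly]
    z = (d[:, poly] - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    z[~obs[:, poly]] = 0.0
    m = int(poly.sum())
    r = z @ z.T / m
    r = (r + r.T) / 2
    return RelationshipMatrix(values=r, samples=list(gm.samples), n_sites_used=m)


def pca(rel: RelationshipMatrix, k: int = 10) -> PCAResult:
    """Top-``k`` eigendecomposition of the relationship matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (non-negative part of the) eigenvalue; each eigenvector's
    largest-magnitude entry is made positive for reproducibility.
    """
    n = rel.values.shape[0]
    if k >= n:
        raise ValidationError(f"k must be < n_samples ({n})")
    evals, evecs = np.linalg.eigh(rel.values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = np.maximum(evals, 0).sum()
    top_vals, top_vecs = evals[:k], evecs[:, :k]
    for j in range(k):
        i_max = np.argmax(np.abs(top_vecs[:, j]))
        if top_vecs[i_max, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    coords = top_vecs * np.sqrt(np.maximum(top_vals, 0))[None, :]
    vf = np.maximum(top_vals, 0) / total if total > 0 else np.zeros(k)
    return PCAResult(coordinates=coords, variance_fraction=vf, samples=list(rel.samples))


# ---------------------------------------------------------------------------
# Allele-sharing distances and neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(gm: GenotypeMatrix, chunk: int = 2048) -> DistanceMatrix:
    """Pairwise allele-sharing p-distance on dosages.

    ``d(i, j)`` is the mean of ``|g_i − g_j| / 2`` over sites where both
    samples are called.  Computed from genotype-class indicator products
    so that large matrices stay in BLAS.
    """
    if gm.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    d = gm.dosage
    n = gm.n_samples
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for lo in range(0, gm.n_sites, chunk):
        block = d[:, lo : lo + chunk]
        obs = (block != MISSING).astype(np.float64)
        g = np.where(block == MISSING, 0, block).astype(np.float64)
        g2 = g * g
        # sum over jointly-observed sites of (g_i - g_j)^2
        s2 = (g2 @ obs.T) + (obs @ g2.T) - 2 * (g @ g.T)
        # |a-b| = (a-b)^2 - 2*[{a,b}={0,2}] for dosages
        a0 = ((block == 0)).astype(np.float64)
        a2 = ((block == 2)).astype(np.float64)
        opp = a0 @ a2.T
        num += s2 - 2 * (opp + opp.T)
        cnt += obs @ obs.T
    np.fill_diagonal(num, 0.0)
    if (cnt + np.eye(n) == 0).any():
        i, j = np.argwhere((cnt + np.eye(n)) == 0)[0]
        raise ValidationError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no called sites"
        )
    vals = num / np.maximum(cnt, 1) / 2.0
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(values=vals, samples=list(gm.samples))


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou–Nei) serialized as an unrooted newick
    string with a trifurcating root.

    At each step the pair minimizing ``Q(i,j) = (N−2) d(i,j) − r_i − r_j``
    is joined; branch lengths use the standard three-point formulas.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the path length between the joined pair.
    """
    d = dm.values.copy().astype(np.float64)
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    n = d.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    nodes = [_escape_newick(s) for s in dm.samples]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k_loc, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        nodes.append(f"({nodes[i]}:{li:.17g},{nodes[j]}:{lj:.17g})")
        active = [a for a in active if a not in (i, j)] + [d.shape[0] - 1]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    return f"({nodes[i]}:{li:.17g},{nodes[j]}:{lj:.17g},{nodes[k]}:{lk:.17g});"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _escape_newick(name: str) -> str:
    if any(c in name for c in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# NMF ancestry
# ---------------------------------------------------------------------------

def _project_rows_to_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True index
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(q - theta[:, None], 0.0)


def admixture_nmf(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    mask_fraction: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
    mask_seed: int | None = None,
) -> AdmixtureResult:
    """Fit the K-cluster ancestry model and score it by held-out
    cross-entropy.

    A random ``mask_fraction`` of the non-missing entries is held out
    before fitting; ``masked_cross_entropy`` is the mean binomial
    cross-entropy of those entries under the fitted reconstruction
    (clipped to [1e-6, 1 − 1e-6]).  ``mask_seed`` decouples the hold-out
    pattern from the initialization so that different models can be
    scored on the same held-out entries (paired comparison); it defaults
    to ``seed``.
    """
    n, L = gm.n_samples, gm.n_sites
    if not (1 <= K <= n):
        raise ValidationError(f"K must be in [1, {n}], got {K}")
    if not (0 < mask_fraction <= 0.5):
        raise ValidationError("mask_fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    rng_mask = np.random.default_rng(seed if mask_seed is None else mask_seed)
    x_obs = gm.dosage != MISSING
    x = np.where(x_obs, gm.dosage, 0).astype(np.float64) / 2.0

    held = x_obs & (rng_mask.random((n, L)) < mask_fraction)
    fit_mask = x_obs & ~held
    col_mean = np.where(
        fit_mask.sum(axis=0) > 0,
        (x * fit_mask).sum(axis=0) / np.maximum(fit_mask.sum(axis=0), 1),
        0.5,
    )
    x_work = np.where(fit_mask, x, col_mean[None, :])

    q = _project_rows_to_simplex(rng.random((n, K)))
    f = rng.random((K, L))
    eye = np.eye(K)
    loss_trace: list[float] = []
    converged = False
    prev_loss = np.inf
    for _ in range(max_iter):
        # F-step: ridge-stabilized least squares, clipped to [0, 1]
        f = np.linalg.solve(q.T @ q + 1e-9 * eye, q.T @ x_work)
        np.clip(f, 0.0, 1.0, out=f)
        # Q-step: least squares rows projected to the simplex
        q_new = np.linalg.solve(f @ f.T + 1e-9 * eye, f @ x_work.T).T
        q = _project_rows_to_simplex(q_new)
        recon = q @ f
        loss = float(np.sum((x - recon) ** 2, where=fit_mask))
        if loss > prev_loss:  # projection overshoot: stop at the best point
            converged = True
            break
        loss_trace.append(loss)
        x_work = np.where(fit_mask, x, recon)
        if np.isfinite(prev_loss) and prev_loss - loss <= tol * max(prev_loss, 1e-30):
            converged = True
            prev_loss = loss
            break
        prev_loss = loss

    recon = np.clip(q @ f, 1e-6, 1 - 1e-6)
    if held.sum() > 0:
        xh = x[held]
        rh = recon[held]
        ce = float(-np.mean(xh * np.log(rh) + (1 - xh) * np.log(1 - rh)))
    else:
        ce = float("nan")
    return AdmixtureResult(
        Q=q, F=f, masked_cross_entropy=ce, K=K, seed=seed,
        converged=converged, loss_trace=loss_trace,
    )


def select_K(
    gm: GenotypeMatrix,
    K_range: range | list[int] = range(2, 11),
    seeds_per_K: int = 3,
    seed: int = 0,
    mask_fraction: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[int, dict[int, float]]:
    """Fit each candidate K ``seeds_per_K`` times (distinct
    initializations) and keep the minimum held-out cross-entropy; the
    best K minimizes that criterion.  All K share the same hold-out
    pattern so the comparison across K is paired."""
    ks = sorted(K_range)
    n = gm.n_samples
    if not ks or ks[0] < 2 or ks[-1] > n:
        raise ValidationError(f"K range must lie within [2, {n}]")
    if seeds_per_K < 1:
        raise ValidationError("seeds_per_K must be >= 1")
    mask_seed = (seed * 2_654_435_761 + 97) % (2**31 - 1)
    table: dict[int, float] = {}
    for k in ks:
        ces = []
        for rep in range(seeds_per_K):
            sub_seed = (seed * 1_000_003 + rep * 10_007 + k) % (2**31 - 1)
            res = admixture_nmf(
                gm, k, seed=sub_seed, mask_fraction=mask_fraction,
                max_iter=max_iter, tol=tol, mask_seed=mask_seed,
            )
            ces.append(res.masked_cross_entropy)
        table[k] = float(min(ces))
    best = min(table, key=lambda k: (table[k], k))
    return best, table
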