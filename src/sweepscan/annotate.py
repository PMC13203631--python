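"""Gene annotation of candidate regions and gene-set enrichment.

A gene is assigned to a candidate region when their half-open intervals
share at least one base pair; strand is ignored.  Enrichment of a gene
set among the candidate genes is scored with the upper-tail
hypergeometric test against a user-supplied universe, with
Benjamini–Hochberg control of the false discovery rate across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneRecord, ValidationError
from .scan import CandidateRegion


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    set_size: int  # |set ∩ universe|
    overlap: int  # |set ∩ candidates|
    p_value: float
    fdr: float


def overlap_genes(
    regions: list[CandidateRegion], genes: list[GeneRecord]
) -> tuple[list[CandidateRegion], dict[str, list[str]]]:
    """Fill each region's ``gene_ids`` with the overlapping genes and
    return the deduplicated per-direction gene lists.

    Both inputs use half-open coordinates, so a gene ending where a
    region starts does not overlap it.
    """
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in genes_by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end))

    annotated: list[CandidateRegion] = []
    per_direction: dict[str, list[str]] = {}
    missing_chroms = set()
    for region in regions:
        chrom_genes = genes_by_chrom.get(region.chrom)
        if chrom_genes is None:
            missing_chroms.add(region.chrom)
            hits: list[str] = []
        else:
            starts = np.array([g.start for g in chrom_genes])
            ends = np.array([g.end for g in chrom_genes])
            mask = (starts < region.end) & (ends > region.start)
            hits = [chrom_genes[i].gene_id for i in np.where(mask)[0]]
        annotated.append(replace(region, gene_ids=tuple(hits)))
        bucket = per_direction.setdefault(region.direction, [])
        for gid in hits:
            if gid not in bucket:
                bucket.append(gid)
    if missing_chroms:
        warnings.warn(
            f"chromosomes in candidate regions absent from annotation: {sorted(missing_chroms)}"
        )
    return annotated, per_direction


def hypergeometric_enrichment(
    candidate_genes: list[str],
    gene_sets: dict[str, set[str] | list[str]],
    universe: list[str] | set[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of each gene set among the
    candidates, BH-adjusted across all tested sets, sorted by p-value.

    ``P(X >= k)`` with population size ``|universe|``, ``|set ∩ universe|``
    successes and ``|candidates ∩ universe|`` draws.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    candidates = set(candidate_genes) & universe
    if set(candidate_genes) - universe:
        warnings.warn(
            f"{len(set(candidate_genes) - universe)} candidate genes outside the "
            "universe were dropped"
        )
    m_univ = len(universe)
    n_draw = len(candidates)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        k = len(members & candidates)
        # P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, m_univ, len(members), n_draw))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(EnrichmentRow(set_id, len(members), k, p, fdr=1.0))
    if rows:
        fdr = bh_adjust([r.p_value for r in rows])
        rows = [replace(r, fdr=q) for r, q in zip(rows, fdr)]
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, returned in the
    input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def read_gene_sets(path: str) -> dict[str, set[str]]:
    """Two-column TSV (set_id, gene_id) → mapping of set to members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{ln}: expected 2 columns")
            sets.setdefault(parts[0], set()).add(parts[1])
    return sets
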