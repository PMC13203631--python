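"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every genomic interval is **0-based half-open** ``[start, end)``.
The 1-based conventions of VCF (positions) and GFF3 (inclusive intervals)
are converted at the I/O boundary and nowhere else.  BED input is already
half-open and passes through unchanged.

Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with
:data:`MISSING` (-1) for no-calls.  Half-calls such as ``0/.`` are treated
as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "site_id", "ref", "alt"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate an internal invariant."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP site. ``pos`` is 1-based, as printed in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"site position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval in internal 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass
class GenotypeMatrix:
    """Samples-by-sites diploid dosage matrix plus site metadata.

    Parameters
    ----------
    samples
        Ordered sample names, unique.
    sites
        DataFrame with columns ``chrom, pos, site_id, ref, alt``; ``pos`` is
        1-based.  Rows must be sorted by ``(chrom, pos)`` with no duplicate
        ``(chrom, pos)`` pair.
    dosage
        ``(n_samples, n_sites)`` integer array; entries in ``{0, 1, 2}`` or
        :data:`MISSING`.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample names")
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("dosage entries must be in {0, 1, 2, MISSING}")
        if len(self.sites):
            key = list(zip(self.sites["chrom"], self.sites["pos"]))
            if sorted(key) != key:
                raise ValidationError("sites not sorted by (chrom, pos)")
            if len(set(key)) != len(key):
                raise ValidationError("duplicate (chrom, pos) site")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, index: int) -> VariantSite:
        row = self.sites.iloc[index]
        return VariantSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"], row["site_id"])

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            samples=list(names),
            sites=self.sites.copy(),
            dosage=self.dosage[idx, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class PopulationMap:
    """Assignment of samples to population labels.

    In two-population scan mode exactly two labels are allowed; they are
    reported in lexicographic order so that "population A" and
    "population B" are deterministic for a given input file.
    """

    assignment: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def samples_of(self, label: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == label]

    def indices(self, samples: list[str], label: str) -> np.ndarray:
        """Row indices of *samples* assigned to *label*."""
        return np.array(
            [i for i, s in enumerate(samples) if self.assignment.get(s) == label], dtype=int
        )

    def validate_against(self, gm: GenotypeMatrix, scan_mode: bool = True) -> None:
        missing = [s for s in gm.samples if s not in self.assignment]
        if missing:
            raise ValidationError(f"samples without population assignment: {missing[:5]}...")
        if scan_mode and len(self.labels) != 2:
            raise ValidationError(
                f"scan mode requires exactly two populations, got {self.labels}"
            )
        for lab in self.labels:
            if not any(self.assignment.get(s) == lab for s in gm.samples):
                raise ValidationError(f"population {lab!r} has no samples in the matrix")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF v4.x file with GT fields into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (``strict=False``, the
    default) or rejected with :class:`FormatError` (``strict=True``).
    Phasing separators are ignored; any genotype containing a no-call
    allele becomes :data:`MISSING`.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample names in {path}")

    rows = []
    dosages = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if strict:
                raise FormatError(
                    f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} (strict mode)"
                )
            continue
        # allele-level array: any no-call allele (half-calls included) → MISSING
        alleles = rec.genotype.array()[:, :2]
        d = alleles.sum(axis=1).astype(np.int8)
        d[(alleles < 0).any(axis=1)] = MISSING
        dosages.append(d)
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0]))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = (
        np.array(dosages, dtype=np.int8).T
        if dosages
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal GT-only VCF v4.2 that round-trips through :func:`read_vcf`.

    Output is byte-stable for a fixed input: genotypes are emitted unphased
    as ``0/0``, ``0/1``, ``1/1`` or ``./.`` and no per-run metadata (dates,
    hostnames) is written.
    """
    if contig_lengths is None:
        contig_lengths = {}
        for chrom, sub in gm.sites.groupby("chrom", sort=False):
            contig_lengths[chrom] = int(sub["pos"].max()) + 1
    gt_lookup = np.array(["0/0", "0/1", "1/1"] + [""] * 252 + ["./."], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=sweepscan\n')
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        dosage = gm.dosage
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            gts = gt_lookup[dosage[:, j]]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['site_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path: str, scan_mode: bool = True) -> PopulationMap:
    """Read a two-column whitespace-delimited sample→population file."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in assignment and assignment[sample] != pop:
                raise ValidationError(
                    f"{path}:{ln}: sample {sample!r} assigned to both "
                    f"{assignment[sample]!r} and {pop!r}"
                )
            assignment[sample] = pop
    pm = PopulationMap(assignment=assignment)
    if scan_mode and len(pm.labels) > 2:
        raise ValidationError(
            f"scan mode allows at most two populations, found {pm.labels}"
        )
    return pm


def write_population_map(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in pm.assignment.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str, fmt: str = "BED") -> list[GeneRecord]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive, only ``gene``-type records).

    Returns records normalized to internal half-open coordinates and sorted
    by ``(chrom, start)``.
    """
    fmt = fmt.upper()
    records: list[GeneRecord] = []
    if fmt == "BED":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"feature_{ln}"
                strand = parts[5] if len(parts) > 5 else "."
                records.append(GeneRecord(chrom, start, end, name, strand))
    elif fmt == "GFF3":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
                if parts[2] != "gene":
                    continue
                chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
                gene_id = _gff3_id(parts[8]) or f"gene_{ln}"
                records.append(GeneRecord(chrom, start - 1, end, gene_id, strand))
        if not records:
            warnings.warn(f"no gene-type records found in {path}")
    else:
        raise ValueError(f"unknown annotation format {fmt!r}; use BED or GFF3")
    records.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return records


def _gff3_id(attributes: str) -> str | None:
    for kv in attributes.split(";"):
        kv = kv.strip()
        if kv.startswith("ID="):
            return kv[3:]
        if kv.startswith("Name="):
            return kv[5:]
    return None


def write_bed(intervals, path: str) -> None:
    """Write ``(chrom, start, end, name)`` tuples as BED4."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
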