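"""Two-population genotype simulator with known ground truth.

The generator emulates a medium-density SNP-chip study of two diverged
populations: sites are scattered over a small set of chicken-scale
chromosomes, per-population allele frequencies are drawn from the
Balding–Nichols model around a shared ancestral frequency, genotypes are
binomial draws under Hardy–Weinberg equilibrium (with an optional fraction
of heterozygote-deficient sites), and selective sweeps are injected as
deterministic pulls of one population's frequency toward fixation inside
declared intervals.  Everything the downstream scan should recover —
per-population frequencies, sweep intervals, the identity of
HWE-violating sites — is recorded in a :class:`SimulationTruth`.

Chip ascertainment is approximated by a floor on the ancestral minor
allele frequency, which reproduces the depleted rare-variant spectrum of
genotyping arrays without modeling an ascertainment panel.  Linkage is
not simulated: the windowed statistics downstream depend only on
allele-frequency structure and independent genotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, SITE_COLUMNS, GenotypeMatrix, PopulationMap, ValidationError

#: Five chicken-like macrochromosomes totaling ~300 Mb.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 100_000_000,
    "chr2": 80_000_000,
    "chr3": 60_000_000,
    "chr4": 40_000_000,
    "chr5": 20_000_000,
}


@dataclass(frozen=True)
class SweepSpec:
    """A selective sweep: pull ``swept_population``'s allele frequencies
    toward the nearest fixation boundary inside ``[start, end)`` by
    ``intensity`` (1.0 = complete sweep, local monomorphism)."""

    chrom: str
    start: int
    end: int
    swept_population: str
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"sweep interval [{self.start}, {self.end}) invalid")
        if not (0 < self.intensity <= 1):
            raise ValidationError(f"sweep intensity must be in (0, 1], got {self.intensity}")


@dataclass
class SimulationConfig:
    n_per_pop: int = 144
    n_sites: int = 60_000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    divergence_fst: float = 0.05
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.02
    hwe_violation_fraction: float = 0.0
    hwe_het_deficit: float = 0.6  # F_IS-like deflation of heterozygote probability
    maf_floor: float = 0.05
    pop_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_pop < 2:
            raise ValidationError("n_per_pop must be >= 2")
        if not (0 < self.divergence_fst < 1):
            raise ValidationError("divergence_fst must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0 <= self.hwe_violation_fraction < 1):
            raise ValidationError("hwe_violation_fraction must be in [0, 1)")
        if not (0 < self.maf_floor < 0.5):
            raise ValidationError("maf_floor must be in (0, 0.5)")
        for sw in self.sweep_specs:
            if sw.chrom not in self.chrom_lengths:
                raise ValidationError(f"sweep chromosome {sw.chrom!r} not in chrom_lengths")
            if sw.end > self.chrom_lengths[sw.chrom]:
                raise ValidationError(
                    f"sweep [{sw.start}, {sw.end}) exceeds {sw.chrom} length "
                    f"{self.chrom_lengths[sw.chrom]}"
                )
            if sw.swept_population not in self.pop_labels:
                raise ValidationError(
                    f"swept population {sw.swept_population!r} not in {self.pop_labels}"
                )


@dataclass
class SimulationTruth:
    """Ground-truth record of a simulation run."""

    sites: pd.DataFrame  # chrom, pos (1-based)
    ancestral_freq: np.ndarray  # (n_sites,)
    pop_freq: dict[str, np.ndarray]  # label -> (n_sites,) post-sweep frequency
    sweep_specs: list[SweepSpec]
    hwe_violating_sites: np.ndarray  # indices into sites


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Draw a two-population genotype dataset, fully reproducible from
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    lab_a, lab_b = config.pop_labels

    # -- site placement: uniform over the genome, then coordinate-sorted
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=lengths / lengths.sum())
    pos = np.empty(n_sites, dtype=np.int64)
    for ci, length in enumerate(lengths):
        mask = chrom_idx == ci
        pos[mask] = rng.integers(1, int(length) + 1, size=mask.sum())
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    # de-duplicate coordinates by nudging collisions forward
    for ci in range(len(chroms)):
        mask = chrom_idx == ci
        if mask.any():
            p = pos[mask]
            for k in range(1, len(p)):
                if p[k] <= p[k - 1]:
                    p[k] = p[k - 1] + 1
            pos[mask] = p
    site_chroms = np.array(chroms, dtype=object)[chrom_idx]

    # -- ancestral and per-population frequencies (Balding–Nichols)
    p_anc = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=n_sites)
    fst = config.divergence_fst
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    freq = {lab_a: rng.beta(a, b), lab_b: rng.beta(a, b)}

    # -- sweeps: pull the swept population toward the nearest boundary
    for sw in config.sweep_specs:
        in_sweep = (
            (site_chroms == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
        )
        f = freq[sw.swept_population]
        target = np.round(f[in_sweep])
        f[in_sweep] = f[in_sweep] + sw.intensity * (target - f[in_sweep])

    # -- HWE-violating sites: heterozygote deficit in both populations
    n_viol = int(round(config.hwe_violation_fraction * n_sites))
    viol_idx = (
        rng.choice(n_sites, size=n_viol, replace=False) if n_viol else np.array([], dtype=int)
    )
    viol_mask = np.zeros(n_sites, dtype=bool)
    viol_mask[viol_idx] = True

    # -- genotypes
    n = config.n_per_pop
    dosage_blocks = []
    for lab in (lab_a, lab_b):
        f = freq[lab]
        g = _draw_genotypes(rng, f, n, viol_mask, config.hwe_het_deficit)
        dosage_blocks.append(g)
    dosage = np.vstack(dosage_blocks).astype(np.int8)

    # -- missingness
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING

    samples = [f"{lab_a}_{i:04d}" for i in range(n)] + [f"{lab_b}_{i:04d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": site_chroms,
            "pos": pos,
            "site_id": [f"snp{j:06d}" for j in range(n_sites)],
            "ref": "A",
            "alt": "G",
        }
    )[SITE_COLUMNS]
    gm = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)
    pm = PopulationMap(
        assignment={s: (lab_a if i < n else lab_b) for i, s in enumerate(samples)}
    )
    truth = SimulationTruth(
        sites=sites[["chrom", "pos"]].copy(),
        ancestral_freq=p_anc,
        pop_freq=freq,
        sweep_specs=list(config.sweep_specs),
        hwe_violating_sites=np.sort(viol_idx),
    )
    return gm, pm, truth


def _draw_genotypes(
    rng: np.random.Generator,
    freq: np.ndarray,
    n_ind: int,
    viol_mask: np.ndarray,
    het_deficit: float,
) -> np.ndarray:
    """Genotypes for one population: HWE binomial draws, except at flagged
    sites where the heterozygote class is deflated by ``het_deficit``
    (an inbreeding-coefficient-like factor) with the excess moved to the
    homozygote classes in proportion to allele frequency."""
    n_sites = len(freq)
    g = rng.binomial(2, freq[None, :].repeat(n_ind, axis=0)).astype(np.int8)
    if viol_mask.any():
        f = freq[viol_mask]
        p_het = 2 * f * (1 - f) * (1 - het_deficit)
        p_hom_alt = f**2 + f * (1 - f) * het_deficit
        p_hom_ref = 1 - p_het - p_hom_alt
        u = rng.random((n_ind, viol_mask.sum()))
        gv = np.full(u.shape, 1, dtype=np.int8)
        gv[u < p_hom_ref[None, :]] = 0
        gv[u >= (p_hom_ref + p_het)[None, :]] = 2
        g[:, viol_mask] = gv
    return g


def write_truth(truth: SimulationTruth, bed_path: str, freq_path: str) -> None:
    """Write sweep intervals as BED4 (name = swept population label) and
    per-site frequencies as TSV."""
    with open(bed_path, "w") as fh:
        for sw in truth.sweep_specs:
            fh.write(f"{sw.chrom}\t{sw.start}\t{sw.end}\t{sw.swept_population}\n")
    df = truth.sites.copy()
    df["ancestral_freq"] = truth.ancestral_freq
    for lab in sorted(truth.pop_freq):
        df[f"freq_{lab}"] = truth.pop_freq[lab]
    df["hwe_violating"] = 0
    df.loc[df.index[truth.hwe_violating_sites], "hwe_violating"] = 1
    df.to_csv(freq_path, sep="\t", index=False, float_format="%.8g")


def read_truth_bed(path: str) -> list[SweepSpec]:
    specs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, pop = line.split("\t")[:4]
            specs.append(SweepSpec(chrom, int(start), int(end), pop.strip()))
    return specs
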