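"""Coalescent simulation of base-population haplotypes and trait architecture.

The base population of a breeding scheme is represented by a panel of phased
haplotypes sampled from a neutral coalescent with recombination at constant
effective population size.  Markers and QTL are ascertained uniformly at
random among the segregating sites, and additive QTL effects are drawn from
a gamma distribution with random sign, giving the leptokurtic effect-size
distribution typical of quantitative traits in livestock.

The genetic map is uniform at 1 cM per Mb, so a 1e8 bp chromosome spans
100 cM (one Morgan per 1e8 bp at the default recombination rate of 1e-8
per bp per generation).
"""
from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from ._util import ParameterError, derive_int_seed, derive_rng

#: genetic-map constant: centimorgans per base pair (1 cM / Mb)
CM_PER_BP = 1e-6

#: default recombination rate, consistent with the 1 cM/Mb map
DEFAULT_RECOMBINATION_RATE = 1e-8


@dataclass(frozen=True)
class Chromosome:
    """Physical and genetic extent of one autosome."""

    chrom_id: int
    length_bp: float

    @property
    def length_cm(self) -> float:
        return self.length_bp * CM_PER_BP


@dataclass
class HaplotypePanel:
    """Phased base-generation haplotypes at segregating biallelic sites.

    ``alleles[c]`` is an ``(n_haplotypes, n_sites_c)`` int8 matrix of 0/1
    allele codes for chromosome ``c``; ``positions_bp[c]`` holds the
    strictly increasing site coordinates.  Sites are indexed globally in
    chromosome-major order.
    """

    chromosomes: list[Chromosome]
    positions_bp: list[np.ndarray]
    alleles: list[np.ndarray]

    @property
    def n_haplotypes(self) -> int:
        return int(self.alleles[0].shape[0]) if self.alleles else 0

    @property
    def site_counts(self) -> np.ndarray:
        return np.array([a.shape[1] for a in self.alleles], dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.site_counts.sum())

    def positions_cm(self, chrom_index: int) -> np.ndarray:
        return self.positions_bp[chrom_index] * CM_PER_BP

    def chrom_of_site(self) -> np.ndarray:
        """Chromosome index for every global site index."""
        return np.repeat(np.arange(len(self.chromosomes)), self.site_counts)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the 1 allele at every site (global order)."""
        n = self.n_haplotypes
        return np.concatenate([a.sum(axis=0) / n for a in self.alleles])

    def extract(self, global_sites: np.ndarray) -> np.ndarray:
        """Haplotype matrix ``(n_haplotypes, len(global_sites))`` at the
        given global site indices, columns in the requested order."""
        order = np.asarray(global_sites, dtype=np.int64)
        if order.size == 0:
            return np.empty((self.n_haplotypes, 0), dtype=np.int8)
        offsets = np.concatenate([[0], np.cumsum(self.site_counts)])
        if order.min() < 0 or order.max() >= offsets[-1]:
            raise ParameterError("site index out of range")
        chrom = np.searchsorted(offsets, order, side="right") - 1
        out = np.empty((self.n_haplotypes, order.size), dtype=np.int8)
        for c in range(len(self.chromosomes)):
            mask = chrom == c
            if mask.any():
                out[:, mask] = self.alleles[c][:, order[mask] - offsets[c]]
        return out

    def validate(self) -> None:
        n = self.n_haplotypes
        for c, (pos, al) in enumerate(zip(self.positions_bp, self.alleles)):
            if al.shape[0] != n:
                raise ParameterError("inconsistent haplotype counts across chromosomes")
            if pos.shape[0] != al.shape[1]:
                raise ParameterError("positions and allele matrix disagree")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ParameterError(f"sites not strictly ordered on chromosome {c}")
            counts = al.sum(axis=0)
            if np.any((counts <= 0) | (counts >= n)):
                raise ParameterError(f"non-segregating site on chromosome {c}")

    def save(self, path) -> None:
        """Write to a compressed .npz container."""
        payload = {"lengths_bp": np.array([c.length_bp for c in self.chromosomes])}
        for c in range(len(self.chromosomes)):
            payload[f"pos_{c}"] = self.positions_bp[c]
            payload[f"hap_{c}"] = self.alleles[c]
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "HaplotypePanel":
        with np.load(path) as z:
            lengths = z["lengths_bp"]
            chroms = [Chromosome(i, float(l)) for i, l in enumerate(lengths)]
            pos = [z[f"pos_{c}"] for c in range(len(chroms))]
            hap = [z[f"hap_{c}"].astype(np.int8) for c in range(len(chroms))]
        return cls(chroms, pos, hap)


def simulate_base_haplotypes(
    n_haplotypes: int,
    n_chromosomes: int,
    chrom_length_bp: float,
    ne: float,
    mutation_rate: float,
    recombination_rate: float = DEFAULT_RECOMBINATION_RATE,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate base haplotypes under a neutral coalescent with recombination.

    Each chromosome is an independent msprime ancestry simulation at constant
    diploid effective size ``ne`` with an infinite-sites binary mutation
    model, so every returned site is biallelic and segregating in the sample.
    Deterministic given ``seed``.
    """
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise ParameterError("n_haplotypes must be even and >= 4")
    if n_chromosomes < 1 or chrom_length_bp <= 0 or ne <= 0:
        raise ParameterError("chromosome number/length and Ne must be positive")
    if mutation_rate < 0 or recombination_rate <= 0:
        raise ParameterError("mutation rate must be >= 0, recombination rate > 0")

    chroms, positions, alleles = [], [], []
    for c in range(n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_haplotypes // 2,
            population_size=ne,
            sequence_length=chrom_length_bp,
            recombination_rate=recombination_rate,
            random_seed=derive_int_seed(seed, "ancestry", c),
            discrete_genome=False,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            random_seed=derive_int_seed(seed, "mutation", c),
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        pos = mts.tables.sites.position.copy()
        geno = mts.genotype_matrix().T.astype(np.int8)
        chroms.append(Chromosome(c, float(chrom_length_bp)))
        positions.append(pos)
        alleles.append(np.ascontiguousarray(geno))
    panel = HaplotypePanel(chroms, positions, alleles)
    panel.validate()
    return panel


def expected_segregating_sites(n_haplotypes: int, ne: float, mutation_rate: float,
                               length_bp: float) -> float:
    """Watterson expectation 4*Ne*mu*L*sum_{i<n} 1/i for a sample of
    ``n_haplotypes`` sequences (closed-form check on the simulator)."""
    harmonic = np.sum(1.0 / np.arange(1, n_haplotypes))
    return 4.0 * ne * mutation_rate * length_bp * harmonic


@dataclass(frozen=True)
class LocusSelection:
    """Disjoint marker and QTL subsets of a panel's global site indices."""

    marker_site_indices: np.ndarray
    qtl_site_indices: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.marker_site_indices)
        q = np.asarray(self.qtl_site_indices)
        if np.intersect1d(m, q).size:
            raise ParameterError("marker and QTL index sets must be disjoint")


def select_loci(panel: HaplotypePanel, n_markers: int, n_qtl: int,
                seed: int = 0) -> LocusSelection:
    """Uniform random disjoint draw of marker and QTL sites, without
    replacement, from all segregating sites of the panel."""
    if n_markers < 0 or n_qtl < 0:
        raise ParameterError("locus counts must be non-negative")
    total = panel.n_sites
    if n_markers + n_qtl > total:
        raise ParameterError(
            f"requested {n_markers + n_qtl} loci but panel has {total} sites")
    rng = derive_rng(seed, "select_loci")
    draw = rng.choice(total, size=n_markers + n_qtl, replace=False)
    markers = np.sort(draw[:n_markers]).astype(np.int64)
    qtl = np.sort(draw[n_markers:]).astype(np.int64)
    return LocusSelection(markers, qtl)


@dataclass(frozen=True)
class QtlEffects:
    """Signed additive effects per QTL locus (trait units per allele copy)."""

    beta: np.ndarray

    @property
    def n_qtl(self) -> int:
        return int(self.beta.shape[0])


def sample_qtl_effects(n_qtl: int, shape: float = 0.4, scale: float = 1.66,
                       seed: int = 0) -> QtlEffects:
    """Gamma-distributed effect magnitudes with independent random signs.

    Magnitudes are Gamma(shape, scale); each effect is positive or negative
    with probability one half. Deterministic given ``seed``: magnitudes are
    drawn first, then the sign vector.
    """
    if n_qtl < 0:
        raise ParameterError("n_qtl must be non-negative")
    if shape <= 0 or scale <= 0:
        raise ParameterError("gamma shape and scale must be positive")
    rng = derive_rng(seed, "qtl_effects")
    mag = rng.gamma(shape, scale, size=n_qtl)
    sign = rng.integers(0, 2, size=n_qtl) * 2 - 1
    return QtlEffects(beta=mag * sign)


def panel_to_vcf(panel: HaplotypePanel, path, sample_prefix: str = "H") -> None:
    """Export the panel as an uncompressed VCF with phased genotypes.

    Consecutive haplotype pairs (2i, 2i+1) are written as one diploid
    sample. Continuous coalescent coordinates are rounded up to integer bp;
    collisions are resolved by bumping to the next free position so records
    stay strictly ordered.
    """
    n_samp = panel.n_haplotypes // 2
    names = [f"{sample_prefix}{i:04d}" for i in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gsrelate\n")
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID=chr{c.chrom_id + 1},length={int(c.length_bp)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for c, (pos, al) in enumerate(zip(panel.positions_bp, panel.alleles)):
            ipos = np.ceil(pos).astype(np.int64)
            for k in range(1, len(ipos)):
                if ipos[k] <= ipos[k - 1]:
                    ipos[k] = ipos[k - 1] + 1
            for j in range(al.shape[1]):
                gt = "\t".join(
                    f"{al[2 * s, j]}|{al[2 * s + 1, j]}" for s in range(n_samp))
                fh.write(f"chr{c + 1}\t{ipos[j]}\tchr{c+1}_{j}\tA\tT\t.\tPASS\t.\tGT\t{gt}\n")


def pairwise_r2(haps: np.ndarray) -> np.ndarray:
    """Squared allele-count correlation (LD r^2) between haplotype columns."""
    h = haps.astype(np.float64)
    h -= h.mean(axis=0)
    sd = h.std(axis=0)
    sd[sd == 0] = np.nan
    corr = (h.T @ h) / h.shape[0] / np.outer(sd, sd)
    return corr**2
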