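"""Text-format interchange: pedigree, phenotypes, genotypes, EBV reports.

Pedigrees travel as 3-column whitespace text (id, sire, dam; 0 = unknown),
phenotypes as CSV (id, trait, generation, sex), genotypes as PLINK
.ped/.map text or VCF, relationship matrices as id-labelled CSV.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import DataError
from .breeding import MALE, Population


def write_pedigree(pop_or_frame, path) -> None:
    df = pop_or_frame.pedigree_frame() if isinstance(pop_or_frame, Population) \
        else pd.DataFrame(pop_or_frame)
    df[["id", "sire", "dam"]].to_csv(path, sep=" ", header=False, index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError("pedigree file needs >= 3 whitespace-separated columns")
    df = df.iloc[:, :3]
    df.columns = ["id", "sire", "dam"]
    return df.astype(np.int64)


def write_phenotypes(pop: Population, path, which: str = "recorded") -> None:
    """CSV of (id, trait, generation, sex); ``which='recorded'`` keeps only
    animals with a phenotype."""
    df = pop.pedigree_frame()
    df["trait"] = pop.phenotype
    if which == "recorded":
        df = df[np.isfinite(pop.phenotype)]
    df[["id", "trait", "generation", "sex"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df or "trait" not in df:
        raise DataError("phenotype CSV needs 'id' and 'trait' columns")
    return df


def write_plink(pop: Population, ped_path, map_path, ids=None) -> None:
    """PLINK .ped/.map text export of marker genotypes.

    Alleles are coded 1/2 (1 = reference 0-allele); the .ped family id is
    the generation, and phenotype column carries the simulated trait value
    (-9 when absent). The .map genetic distance column is in Morgans.
    """
    loci = pop.loci
    cols = loci.marker_cols
    ids = pop.id if ids is None else np.asarray(ids)
    rows = pop.rows_of(ids)
    with open(map_path, "w") as fh:
        for j in cols:
            fh.write(f"{loci.chrom_id[j] + 1} m{j} "
                     f"{loci.pos_cm[j] / 100.0:.6f} {int(loci.pos_bp[j])}\n")
    with open(ped_path, "w") as fh:
        for i, r in zip(ids, rows):
            g = int(pop.generation[r])
            if g not in pop.haplotypes:
                raise DataError(f"genotypes of generation {g} unavailable")
            hap = pop.haplotypes[g][r - pop._gen_start[g]]
            phen = pop.phenotype[r]
            phen_s = f"{phen:.6g}" if np.isfinite(phen) else "-9"
            sex = 1 if pop.sex[r] == MALE else 2
            alleles = (hap[:, cols] + 1).T.reshape(-1)  # a1 b1 a2 b2 ...
            fh.write(f"{g} {i} {pop.sire[r]} {pop.dam[r]} {sex} {phen_s} "
                     + " ".join(map(str, alleles)) + "\n")


def read_plink(ped_path, map_path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read PLINK text genotypes back as (dosage matrix, sample frame,
    marker frame); dosage counts '2' alleles."""
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "bp"])
    samples, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 + 2 * len(mp):
                raise DataError("truncated .ped line")
            samples.append(parts[:6])
            al = np.array(parts[6:], dtype=np.int8).reshape(-1, 2)
            rows.append((al - 1).sum(axis=1))
    fam = pd.DataFrame(samples, columns=["fid", "id", "sire", "dam", "sex", "phen"])
    return np.array(rows, dtype=np.int8), fam, mp


def write_population_vcf(pop: Population, path, ids=None) -> None:
    """Phased VCF of the marker genotypes of the given animals."""
    loci = pop.loci
    cols = loci.marker_cols
    ids = pop.id if ids is None else np.asarray(ids)
    rows = pop.rows_of(ids)
    haps = []
    for r in rows:
        g = int(pop.generation[r])
        if g not in pop.haplotypes:
            raise DataError(f"genotypes of generation {g} unavailable")
        haps.append(pop.haplotypes[g][r - pop._gen_start[g]][:, cols])
    haps = np.array(haps)  # (n, 2, m)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=gsrelate\n")
        for c in np.unique(loci.chrom_id):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(f"A{int(a)}" for a in ids) + "\n")
        last_pos = {}
        for jj, j in enumerate(cols):
            c = int(loci.chrom_id[j])
            p = int(np.ceil(loci.pos_bp[j]))
            if p <= last_pos.get(c, 0):
                p = last_pos[c] + 1
            last_pos[c] = p
            gt = "\t".join(f"{haps[i, 0, jj]}|{haps[i, 1, jj]}"
                           for i in range(len(ids)))
            fh.write(f"chr{c + 1}\t{p}\tm{j}\tA\tT\t.\tPASS\t.\tGT\t{gt}\n")


def read_vcf_genotypes(path) -> tuple[np.ndarray, list, pd.DataFrame]:
    """Read a VCF into an (animals x sites) 0/1/2 dosage matrix plus sample
    names and a site frame."""
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    v = VCF(str(path))
    samples = list(v.samples)
    rows, meta = [], []
    for rec in v:
        dos = np.array([g[0] + g[1] for g in rec.genotypes], dtype=np.int8)
        rows.append(dos)
        meta.append((rec.CHROM, rec.POS, rec.ID))
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "id"])
    return np.array(rows, dtype=np.int8).T, samples, sites


def write_ebv_report(fit, path, r_pev=None) -> None:
    """EBV CSV (id, ebv, pev, r_pev) from a MixedModelFit."""
    df = pd.DataFrame({"id": fit.ids, "ebv": fit.g_hat, "pev": fit.pev()})
    if r_pev is not None:
        df["r_pev"] = r_pev
    df.to_csv(path, index=False)
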