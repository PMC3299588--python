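"""Forward-in-time breeding population with Mendelian transmission.

A base population is founded by allocating coalescent haplotypes (restricted
to the ascertained marker and QTL loci) to founder animals.  Discrete
generations are then produced by random mating of a fixed number of sires,
each to a fixed number of dams with a fixed litter size.  Gametes recombine
as a Poisson crossover process along the genetic map (1% recombination per
cM) with a random start strand per chromosome, i.e. no interference.

True breeding values are the sum of QTL allele effects; phenotypes add a
normal environmental deviate whose variance is fixed from the base
generation's genetic variance at the chosen heritability.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import DataError, DesignError, ParameterError, StateError, derive_rng
from .haplotypes import CM_PER_BP, HaplotypePanel, LocusSelection, QtlEffects

MALE, FEMALE = 0, 1


@dataclass
class LocusMap:
    """Genomic coordinates of the loci carried by a population.

    Loci are stored in chromosome-major order, strictly increasing within a
    chromosome. ``is_qtl`` distinguishes QTL from markers.
    """

    chrom_id: np.ndarray          # int per locus
    pos_bp: np.ndarray
    is_qtl: np.ndarray            # bool per locus
    chrom_length_cm: np.ndarray   # per chromosome (indexed by chrom id)

    @property
    def pos_cm(self) -> np.ndarray:
        return self.pos_bp * CM_PER_BP

    @property
    def n_loci(self) -> int:
        return int(self.chrom_id.shape[0])

    @property
    def marker_cols(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_cols(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """Contiguous (chrom_id, slice) blocks in storage order."""
        out = []
        ids = self.chrom_id
        start = 0
        for c in np.unique(ids):
            n = int((ids == c).sum())
            out.append((int(c), slice(start, start + n)))
            start += n
        return out


class Population:
    """Pedigree, phased genotypes, breeding values and phenotypes.

    Animal ids are consecutive integers starting at 1 in birth order; 0
    denotes an unknown parent.  Phased genotypes are held per generation as
    ``(n_animals, 2, n_loci)`` int8 arrays and may be dropped once no longer
    needed (they are the dominant memory cost).
    """

    def __init__(self, loci: LocusMap):
        self.loci = loci
        self.id = np.empty(0, dtype=np.int64)
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.generation = np.empty(0, dtype=np.int16)
        self.tbv = np.empty(0, dtype=np.float64)
        self.phenotype = np.empty(0, dtype=np.float64)
        self.haplotypes: dict[int, np.ndarray] = {}
        self.base_freq: np.ndarray | None = None
        self.sigma_e2: float | None = None
        self.h2: float | None = None
        self._gen_start: dict[int, int] = {}

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.id.shape[0]

    @property
    def max_generation(self) -> int:
        return int(self.generation.max()) if self.n_animals else -1

    def rows_of(self, ids) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 1 or ids.max() > self.n_animals):
            raise ParameterError("unknown animal id")
        return ids - 1

    def gen_rows(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.generation == g)

    def ids_of_generation(self, g: int, sex: int | None = None) -> np.ndarray:
        rows = self.gen_rows(g)
        if sex is not None:
            rows = rows[self.sex[rows] == sex]
        return self.id[rows]

    def _append(self, sire, dam, sex, generation) -> np.ndarray:
        n_new = len(sex)
        first = self.n_animals + 1
        new_ids = np.arange(first, first + n_new, dtype=np.int64)
        self.id = np.concatenate([self.id, new_ids])
        self.sire = np.concatenate([self.sire, np.asarray(sire, dtype=np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, dtype=np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.full(n_new, generation, dtype=np.int16)])
        self.tbv = np.concatenate([self.tbv, np.full(n_new, np.nan)])
        self.phenotype = np.concatenate([self.phenotype, np.full(n_new, np.nan)])
        self._gen_start[int(generation)] = first - 1
        return new_ids

    def drop_haplotypes(self, g: int) -> None:
        self.haplotypes.pop(g, None)

    def genotypes(self, ids, loci_cols: np.ndarray | None = None) -> np.ndarray:
        """0/1/2 dosage matrix for the given animals (rows in id order).

        Requires the phased genotypes of every involved generation to still
        be in memory.
        """
        rows = self.rows_of(ids)
        cols = np.arange(self.loci.n_loci) if loci_cols is None else loci_cols
        out = np.empty((rows.size, cols.size), dtype=np.int8)
        gens = self.generation[rows]
        for g in np.unique(gens):
            if int(g) not in self.haplotypes:
                raise StateError(f"genotypes of generation {g} have been dropped")
            sel = gens == g
            local = rows[sel] - self._gen_start[int(g)]
            hap = self.haplotypes[int(g)]
            out[sel] = hap[local][:, 0, cols] + hap[local][:, 1, cols]
        return out

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.id, "sire": self.sire, "dam": self.dam,
            "sex": np.where(self.sex == MALE, "M", "F"),
            "generation": self.generation,
        })


def found_base_population(panel: HaplotypePanel, selection: LocusSelection,
                          n_males: int, n_females: int, seed: int = 0) -> Population:
    """Allocate base haplotypes to founder animals, two per animal,
    drawn without replacement from the panel."""
    if n_males < 1 or n_females < 1:
        raise ParameterError("founder counts must be positive")
    need = 2 * (n_males + n_females)
    if need > panel.n_haplotypes:
        raise ParameterError(
            f"{need} haplotypes needed for {n_males + n_females} founders, "
            f"panel has {panel.n_haplotypes}")

    sel = np.sort(np.concatenate([selection.marker_site_indices,
                                  selection.qtl_site_indices]))
    is_qtl = np.isin(sel, selection.qtl_site_indices)
    chrom_all = panel.chrom_of_site()
    pos_all = np.concatenate(panel.positions_bp) if panel.n_sites else np.empty(0)
    loci = LocusMap(
        chrom_id=chrom_all[sel].astype(np.int32),
        pos_bp=pos_all[sel],
        is_qtl=is_qtl,
        chrom_length_cm=np.array([c.length_cm for c in panel.chromosomes]),
    )
    pop = Population(loci)

    rng = derive_rng(seed, "founders")
    perm = rng.permutation(panel.n_haplotypes)[:need]
    haps = panel.extract(sel)[perm]
    n_ind = n_males + n_females
    hap_arr = haps.reshape(n_ind, 2, loci.n_loci)

    sexes = np.concatenate([np.full(n_males, MALE, dtype=np.int8),
                            np.full(n_females, FEMALE, dtype=np.int8)])
    pop._append(np.zeros(n_ind), np.zeros(n_ind), sexes, 0)
    pop.haplotypes[0] = hap_arr
    pop.base_freq = hap_arr.sum(axis=(0, 1)) / (2.0 * n_ind)
    return pop


def _gametes(parent_haps: np.ndarray, parent_local_rows: np.ndarray,
             loci: LocusMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per entry of ``parent_local_rows``.

    Crossovers per chromosome are Poisson with mean = map length in Morgans,
    positions uniform on the map, start strand random per chromosome.
    """
    n = parent_local_rows.size
    out = np.empty((n, loci.n_loci), dtype=np.int8)
    pos_cm = loci.pos_cm
    rows = np.asarray(parent_local_rows, dtype=np.intp)
    for c, sl in loci.chrom_slices():
        length_cm = float(loci.chrom_length_cm[c])
        pos = pos_cm[sl]
        m = pos.size
        k = rng.poisson(length_cm / 100.0, size=n)
        start = rng.integers(0, 2, size=n, dtype=np.uint8)
        strand = np.repeat(start[:, None], m, axis=1)
        act = np.flatnonzero(k > 0)
        total = int(k.sum())
        if total > 0:
            # strand at a locus = start XOR parity of crossovers to its left;
            # crossovers are binned at their locus insertion index and the
            # parity rolled out with a cumulative XOR
            x = rng.uniform(0.0, length_cm, size=total)
            gam = np.repeat(np.arange(act.size), k[act])
            cut = np.searchsorted(pos, x)
            flips = np.zeros((act.size, m + 1), dtype=np.uint8)
            np.add.at(flips, (gam, cut), 1)
            flips &= 1
            strand[act] ^= np.bitwise_xor.accumulate(flips[:, :m], axis=1)
        h0 = parent_haps[rows, 0, sl]
        h1 = parent_haps[rows, 1, sl]
        out[:, sl] = np.where(strand == 0, h0, h1)
    return out


def advance_generation(pop: Population, n_sires: int, dams_per_sire: int,
                       offspring_per_dam: int, seed: int = 0) -> Population:
    """Create the next generation by random mating.

    ``n_sires`` males are drawn without replacement from the current
    generation, each mated to ``dams_per_sire`` distinct females (each
    female used at most once), each mating producing ``offspring_per_dam``
    offspring. Sexes are assigned half male / half female at random.
    """
    g = pop.max_generation
    if g < 0:
        raise StateError("population has no animals")
    if g not in pop.haplotypes:
        raise StateError(f"genotypes of generation {g} are no longer available")
    males = pop.ids_of_generation(g, MALE)
    females = pop.ids_of_generation(g, FEMALE)
    n_dams = n_sires * dams_per_sire
    if len(males) < n_sires or len(females) < n_dams:
        raise StateError(
            f"generation {g} has {len(males)} males / {len(females)} females; "
            f"need {n_sires} sires and {n_dams} dams")
    n_off = n_dams * offspring_per_dam
    if n_off % 2:
        raise ParameterError("offspring count must be even for a half/half sex ratio")

    rng = derive_rng(seed, "mating", g)
    sires = rng.choice(males, size=n_sires, replace=False)
    dams = rng.choice(females, size=n_dams, replace=False)

    sire_of_dam = np.repeat(sires, dams_per_sire)
    sire_of_off = np.repeat(sire_of_dam, offspring_per_dam)
    dam_of_off = np.repeat(dams, offspring_per_dam)

    gen_start = pop._gen_start[g]
    pat = _gametes(pop.haplotypes[g], pop.rows_of(sire_of_off) - gen_start,
                   pop.loci, rng)
    mat = _gametes(pop.haplotypes[g], pop.rows_of(dam_of_off) - gen_start,
                   pop.loci, rng)

    sexes = np.concatenate([np.full(n_off // 2, MALE, dtype=np.int8),
                            np.full(n_off - n_off // 2, FEMALE, dtype=np.int8)])
    rng.shuffle(sexes)

    pop._append(sire_of_off, dam_of_off, sexes, g + 1)
    pop.haplotypes[g + 1] = np.stack([pat, mat], axis=1)
    return pop


def compute_tbv(pop: Population, effects: QtlEffects,
                generations=None) -> Population:
    """True breeding value TBV_k = sum_j beta_j * Q_kj over QTL dosages.

    Computed for every generation whose genotypes are still in memory, or
    only for ``generations`` when given.
    """
    qtl = pop.loci.qtl_cols
    if effects.n_qtl != qtl.size:
        raise DataError(
            f"effects for {effects.n_qtl} QTL but population carries {qtl.size}")
    gens = pop.haplotypes.keys() if generations is None else generations
    for g in gens:
        if g not in pop.haplotypes:
            raise StateError(f"genotypes of generation {g} unavailable")
        hap = pop.haplotypes[g]
        rows = pop.gen_rows(g)
        dosage = hap[:, 0, :][:, qtl].astype(np.float64) + hap[:, 1, :][:, qtl]
        pop.tbv[rows] = dosage @ effects.beta
    return pop


def assign_phenotypes(pop: Population, h2: float, seed: int = 0) -> Population:
    """Phenotype = TBV + e with e ~ N(0, sigma_e^2).

    sigma_e^2 = var(TBV_base) * (1 - h2) / h2 is fixed from the base
    generation on the first call and reused thereafter, so drift in later
    generations does not change the environmental variance.  Only animals
    with a computed TBV and no phenotype yet are assigned.
    """
    if not (0 < h2 <= 1):
        raise ParameterError("h2 must be in (0, 1]")
    if pop.sigma_e2 is None:
        base = pop.gen_rows(0)
        if base.size == 0 or not np.isfinite(pop.tbv[base]).all():
            raise StateError("base-generation TBV must be computed first")
        var_tbv = float(np.var(pop.tbv[base]))
        pop.sigma_e2 = var_tbv * (1.0 - h2) / h2
        pop.h2 = float(h2)
    elif pop.h2 is not None and not np.isclose(pop.h2, h2):
        raise ParameterError("h2 differs from the value used to fix sigma_e2")
    todo = np.flatnonzero(np.isfinite(pop.tbv) & ~np.isfinite(pop.phenotype))
    rng = derive_rng(seed, "phenotypes")
    noise = rng.normal(0.0, np.sqrt(pop.sigma_e2), size=todo.size)
    pop.phenotype[todo] = pop.tbv[todo] + noise
    return pop


@dataclass(frozen=True)
class ReferenceDesign:
    """Reference (training) and test id sets for one relatedness scenario."""

    label: str                    # "close" | "distant" | "unrelated"
    reference_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.reference_ids, self.test_ids).size:
            raise DesignError("reference and test sets must be disjoint")


def _families(pop: Population, g: int):
    """Offspring of generation g grouped by sire, litters grouped by dam."""
    rows = pop.gen_rows(g)
    fams: dict[int, dict[int, list[int]]] = {}
    for r in rows:
        fams.setdefault(int(pop.sire[r]), {}).setdefault(int(pop.dam[r]), []).append(int(pop.id[r]))
    return fams


def build_reference_design(pop: Population, label: str, n_reference: int,
                           n_test: int, half_sibs_in_reference: int = 20,
                           seed: int = 0) -> ReferenceDesign:
    """Construct one of the three relatedness scenarios.

    close
        Reference and test both from the last generation; every test animal
        has exactly ``half_sibs_in_reference`` paternal half sibs (and no
        full sibs) in the reference.
    distant
        Both from the last generation, drawn from disjoint sire families so
        no test animal shares a parent with any reference animal; deeper
        links (cousins and beyond) remain.
    unrelated
        Reference drawn from generation-1 females, test from the last
        generation, giving near-zero pedigree relationships.
    """
    if n_reference < 1 or n_test < 1:
        raise ParameterError("reference and test sizes must be positive")
    g = pop.max_generation
    rng = derive_rng(seed, "design", label)

    if label == "unrelated":
        if g < 2:
            raise DesignError("unrelated design needs at least 2 generations")
        pool = pop.ids_of_generation(1, FEMALE)
        if pool.size < n_reference:
            raise DesignError(
                f"generation 1 has {pool.size} females; need {n_reference}")
        ref = np.sort(rng.choice(pool, size=n_reference, replace=False))
        test_pool = pop.ids_of_generation(g)
        if test_pool.size < n_test:
            raise DesignError("last generation too small for the test set")
        test = np.sort(rng.choice(test_pool, size=n_test, replace=False))
        return ReferenceDesign(label, ref, test)

    if g < 2:
        raise DesignError(f"{label} design needs at least 2 generations")
    fams = _families(pop, g)
    fam_list = sorted(fams.keys())
    rng.shuffle(fam_list)
    fam_sizes = {s: sum(len(v) for v in fams[s].values()) for s in fam_list}
    fam_size = min(fam_sizes.values())
    F = len(fam_list)

    if label == "distant":
        t_f = int(np.ceil(n_test / fam_size))
        r_f = int(np.ceil(n_reference / fam_size))
        if t_f + r_f > F:
            raise DesignError(
                f"need {t_f}+{r_f} disjoint sire families, only {F} available")
        test_pool = np.array([a for s in fam_list[:t_f]
                              for lit in fams[s].values() for a in lit])
        ref_pool = np.array([a for s in fam_list[t_f:t_f + r_f]
                             for lit in fams[s].values() for a in lit])
        test = np.sort(rng.choice(test_pool, size=n_test, replace=False))
        ref = np.sort(rng.choice(ref_pool, size=n_reference, replace=False))
        return ReferenceDesign(label, ref, test)

    if label != "close":
        raise ParameterError(f"unknown design label {label!r}")

    h = half_sibs_in_reference
    if h < 1 or h >= fam_size:
        raise DesignError(
            f"half-sib count {h} infeasible for family size {fam_size}")
    # per-family accounting: h reference animals from whole litters, test
    # animals one per untouched litter (so they share only the sire with the
    # family's reference members)
    caps, ref_choices, test_pools = {}, {}, {}
    for s in fam_list:
        litters = [sorted(v) for _, v in sorted(fams[s].items())]
        rng.shuffle(litters)
        take, ref_ids, used = h, [], 0
        for lit in litters:
            if take <= 0:
                break
            cnt = min(len(lit), take)
            ref_ids.extend(lit[:cnt])
            take -= cnt
            used += 1
        if take > 0:
            raise DesignError("family too small for requested half-sib count")
        ref_choices[s] = ref_ids
        test_pools[s] = [lit[0] for lit in litters[used:]]
        caps[s] = len(test_pools[s])

    s_max = min(F, n_reference // h,
                (sum(fam_sizes.values()) - n_reference) // max(fam_size - h, 1))
    total_cap = 0
    s_min = None
    for i, s in enumerate(fam_list):
        total_cap += caps[s]
        if total_cap >= n_test:
            s_min = i + 1
            break
    if s_min is None or s_min > s_max:
        raise DesignError("cannot host the requested test set with exact "
                          "half-sib counts at this reference size")
    hosting = fam_list[:s_max]
    fill_fams = fam_list[s_max:]

    reference = [a for s in hosting for a in ref_choices[s]]
    fill_needed = n_reference - len(reference)
    fill_pool = [a for s in fill_fams for lit in fams[s].values() for a in lit]
    if fill_needed > len(fill_pool):
        raise DesignError("not enough animals outside hosting families to "
                          "fill the reference")
    if fill_needed:
        reference.extend(rng.choice(np.array(fill_pool), size=fill_needed,
                                    replace=False).tolist())

    test: list[int] = []
    i = 0
    pools = {s: list(test_pools[s]) for s in hosting}
    while len(test) < n_test:
        s = hosting[i % len(hosting)]
        if pools[s]:
            test.append(pools[s].pop(0))
        i += 1
        if i > 10 * len(hosting) * max(1, n_test):
            raise DesignError("test distribution failed")  # pragma: no cover
    return ReferenceDesign(label, np.sort(np.array(reference)),
                           np.sort(np.array(test)))
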