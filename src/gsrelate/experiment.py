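"""End-to-end replicated experiments: simulate, fit, evaluate.

One replicate runs the whole chain — coalescent base haplotypes, locus
ascertainment and QTL effects, forward breeding for the configured number
of generations, the three reference/test relatedness designs, and for each
(design, method) pair the relationship matrix, REML variance components,
the MME solve and both accuracy measures.

Methods:

==========  =========================================================
gBLUP       VanRaden GRM from markers, base-generation frequencies
BLUP-S      pedigree NRM from a shallow (single-generation) pedigree
BLUP-D      pedigree NRM from the full deep pedigree
==========  =========================================================

Two scale presets are provided: ``paper`` (60k markers / 10k QTL, 10
replicates) and ``desk`` (15k markers / 2.5k QTL, 3 replicates), sharing
every population parameter.  Only marker/QTL density and replicate count
differ; empirical accuracies drift slightly downward at desk scale.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import DesignError, ParameterError, derive_int_seed
from .accuracy import empirical_accuracy, pev_accuracy
from .breeding import (Population, ReferenceDesign, advance_generation,
                       assign_phenotypes, build_reference_design, compute_tbv,
                       found_base_population)
from .haplotypes import (QtlEffects, sample_qtl_effects, select_loci,
                         simulate_base_haplotypes)
from .mixed_models import (MixedModelSpec, VarianceComponents,
                           estimate_variance_components, solve_mme)
from .relatedness import (RelationshipMatrix, compute_grm, compute_nrm,
                          nrm_submatrix, relationship_summaries,
                          truncate_pedigree)

METHODS = ("gBLUP", "BLUP-S", "BLUP-D")
DESIGNS = ("close", "distant", "unrelated")


@dataclass
class ExperimentConfig:
    # genome
    n_chromosomes: int = 30
    chrom_length_bp: float = 1e8
    ne: float = 100.0
    mutation_rate: float = 2.5e-8
    recombination_rate: float = 1e-8
    # loci & trait architecture
    n_markers: int = 60_000
    n_qtl: int = 10_000
    qtl_shape: float = 0.4
    qtl_scale: float = 1.66
    # population structure
    base_males: int = 80
    base_females: int = 2000
    n_sires: int = 80
    dams_per_sire: int = 25
    offspring_per_dam: int = 2
    n_generations: int = 10
    # reference/test designs
    designs: tuple = DESIGNS
    n_reference: int = 1750
    n_test: int = 250
    half_sibs_in_reference: int = 20
    # trait
    h2: float = 0.3
    # estimation
    methods: tuple = METHODS
    variance_mode: str = "reml"     # "reml" | "true"
    grm_ridge: float = 1e-6
    # experiment
    n_replicates: int = 10
    master_seed: int = 1
    scale_preset: str = "paper"

    def __post_init__(self):
        for name in ("n_chromosomes", "n_markers", "n_qtl", "base_males",
                     "base_females", "n_sires", "dams_per_sire",
                     "offspring_per_dam", "n_generations", "n_reference",
                     "n_test", "n_replicates"):
            if getattr(self, name) < 0 or (name not in ("n_markers", "n_qtl")
                                           and getattr(self, name) == 0):
                raise ParameterError(f"{name} must be positive")
        self.designs = tuple(self.designs)
        self.methods = tuple(self.methods)

    @classmethod
    def preset(cls, name: str = "paper", **overrides) -> "ExperimentConfig":
        if name == "paper":
            base = {}
        elif name == "desk":
            base = {"n_markers": 15_000, "n_qtl": 2_500, "n_replicates": 3}
        else:
            raise ParameterError(f"unknown preset {name!r}")
        base["scale_preset"] = name
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):   # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        preset = flat.pop("preset", None)
        if preset:
            return cls.preset(preset, **flat)
        return cls(**flat)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["designs"] = list(self.designs)
        d["methods"] = list(self.methods)
        return d


@dataclass
class FitResult:
    """One (design, method) fit within one replicate."""

    design: str
    method: str
    r_cor: float
    mean_r_pev: float
    variances: VarianceComponents | None
    sigma_g2: float
    sigma_e2: float
    per_animal: pd.DataFrame   # index: test id; ebv, tbv, r_pev + summaries


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    fits: dict = field(default_factory=dict)   # (design, method) -> FitResult

    def accuracy(self, design: str, method: str) -> float:
        return self.fits[(design, method)].r_cor


def simulate_population(config: ExperimentConfig, seed: int
                        ) -> tuple[Population, QtlEffects]:
    """Run the genetic simulation for one replicate.

    Memory contract: only the genotypes needed downstream are retained —
    generation 1 (unrelated-design reference pool) and the final
    generation; earlier generations are dropped once their gametes have
    been transmitted.
    """
    n_founders = config.base_males + config.base_females
    panel = simulate_base_haplotypes(
        n_haplotypes=2 * n_founders,
        n_chromosomes=config.n_chromosomes,
        chrom_length_bp=config.chrom_length_bp,
        ne=config.ne,
        mutation_rate=config.mutation_rate,
        recombination_rate=config.recombination_rate,
        seed=derive_int_seed(seed, "panel"),
    )
    selection = select_loci(panel, config.n_markers, config.n_qtl,
                            seed=derive_int_seed(seed, "loci"))
    effects = sample_qtl_effects(config.n_qtl, config.qtl_shape,
                                 config.qtl_scale,
                                 seed=derive_int_seed(seed, "effects"))
    pop = found_base_population(panel, selection, config.base_males,
                                config.base_females,
                                seed=derive_int_seed(seed, "founders"))
    del panel

    compute_tbv(pop, effects)
    assign_phenotypes(pop, config.h2, seed=derive_int_seed(seed, "pheno", 0))

    keep = {config.n_generations}
    if "unrelated" in config.designs:
        keep.add(1)
    for g in range(1, config.n_generations + 1):
        advance_generation(pop, config.n_sires, config.dams_per_sire,
                           config.offspring_per_dam,
                           seed=derive_int_seed(seed, "mating", g))
        compute_tbv(pop, effects, generations=[g])
        assign_phenotypes(pop, config.h2, seed=derive_int_seed(seed, "pheno", g))
        if g - 1 not in keep:
            pop.drop_haplotypes(g - 1)
    return pop, effects


def _build_K(pop: Population, config: ExperimentConfig, method: str,
             design: ReferenceDesign) -> RelationshipMatrix:
    ids = np.concatenate([design.reference_ids, design.test_ids])
    if method == "gBLUP":
        geno = pop.genotypes(ids, pop.loci.marker_cols)
        return compute_grm(geno, pop.base_freq[pop.loci.marker_cols], ids=ids)
    ped = pop.pedigree_frame()
    if method == "BLUP-S":
        shallow = truncate_pedigree(ped, 1)
        par = np.unique(np.concatenate(
            [shallow.loc[shallow["id"].isin(ids), "sire"],
             shallow.loc[shallow["id"].isin(ids), "dam"]]))
        par = par[par > 0]
        sub_ids = np.unique(np.concatenate([ids, par]))
        sub = shallow[shallow["id"].isin(sub_ids)].copy()
        # parents of the retained parents are outside the shallow pedigree
        sub.loc[~sub["sire"].isin(sub["id"]), "sire"] = 0
        sub.loc[~sub["dam"].isin(sub["id"]), "dam"] = 0
        return compute_nrm(sub[["id", "sire", "dam"]]).submatrix(ids)
    if method == "BLUP-D":
        return nrm_submatrix(ped[["id", "sire", "dam"]], ids)
    raise ParameterError(f"unknown method {method!r}")


def fit_design(pop: Population, config: ExperimentConfig, method: str,
               design: ReferenceDesign, K: RelationshipMatrix | None = None
               ) -> FitResult:
    """REML + MME for one method on one design; evaluates the test set."""
    ref, test = design.reference_ids, design.test_ids
    if K is None:
        K = _build_K(pop, config, method, design)
    y = pop.phenotype[pop.rows_of(ref)]
    if not np.isfinite(y).all():
        raise DesignError("reference animals lack phenotypes")
    X = np.ones((y.size, 1))
    K_obs = K.submatrix(ref)

    if config.variance_mode == "true":
        base = pop.gen_rows(0)
        sigma_g2 = float(np.var(pop.tbv[base]))
        sigma_e2 = float(pop.sigma_e2)
        vc = None
    else:
        vc = estimate_variance_components(y, X, K_obs)
        sigma_g2, sigma_e2 = vc.sigma_g2, vc.sigma_e2

    spec = MixedModelSpec(y=y, X=X, z_indices=np.arange(ref.size),
                          K=K, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                          ridge=config.grm_ridge)
    fit = solve_mme(spec)

    ebv = fit.ebv_of(test)
    tbv = pop.tbv[pop.rows_of(test)]
    r_cor = empirical_accuracy(ebv, tbv)
    r_pev = pev_accuracy(fit.c_diag_of(test), K.diagonal(test),
                         sigma_g2, sigma_e2)
    summ = relationship_summaries(K, test, ref)
    per_animal = summ.assign(ebv=ebv, tbv=tbv, r_pev=r_pev)
    return FitResult(design=design.label, method=method, r_cor=float(r_cor),
                     mean_r_pev=float(np.mean(r_pev)), variances=vc,
                     sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                     per_animal=per_animal)


def run_replicate(config: ExperimentConfig, replicate_seed: int,
                  jobs: list[tuple[str, str]] | None = None,
                  replicate_index: int = 0) -> ReplicateResult:
    """Execute one full replicate.

    ``jobs`` restricts the (design, method) pairs fitted (default: the full
    cross of the configured designs and methods).  Deterministic given
    ``replicate_seed``.
    """
    if jobs is None:
        jobs = [(d, m) for d in config.designs for m in config.methods]
    bad = [j for j in jobs if j[0] not in DESIGNS or j[1] not in METHODS]
    if bad:
        raise ParameterError(f"unknown (design, method) jobs: {bad}")

    pop, _effects = simulate_population(config, replicate_seed)

    labels = sorted({d for d, _ in jobs}, key=DESIGNS.index)
    designs = {
        lab: build_reference_design(
            pop, lab, config.n_reference, config.n_test,
            config.half_sibs_in_reference,
            seed=derive_int_seed(replicate_seed, "design", lab))
        for lab in labels
    }

    result = ReplicateResult(replicate=replicate_index, seed=replicate_seed)
    for lab in labels:
        design = designs[lab]
        cache: dict[str, RelationshipMatrix] = {}
        for d, m in jobs:
            if d != lab:
                continue
            if m not in cache:
                cache[m] = _build_K(pop, config, m, design)
            result.fits[(d, m)] = fit_design(pop, config, m, design, cache[m])
        cache.clear()
    return result


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    replicates: list

    def accuracy_table(self) -> pd.DataFrame:
        """Mean empirical accuracy with its standard error (SD/sqrt(n))
        per method x design over replicates."""
        rows = []
        for rep in self.replicates:
            for (d, m), fit in rep.fits.items():
                rows.append({"replicate": rep.replicate, "design": d,
                             "method": m, "r_cor": fit.r_cor,
                             "mean_r_pev": fit.mean_r_pev})
        df = pd.DataFrame(rows)
        g = df.groupby(["method", "design"])
        out = g["r_cor"].agg(["mean", "count"])
        out["se"] = g["r_cor"].std(ddof=1) / np.sqrt(out["count"])
        out["mean_r_pev"] = g["mean_r_pev"].mean()
        return out.reset_index()

    def per_animal_table(self) -> pd.DataFrame:
        frames = []
        for rep in self.replicates:
            for (d, m), fit in rep.fits.items():
                f = fit.per_animal.reset_index()
                f.insert(0, "method", m)
                f.insert(0, "design", d)
                f.insert(0, "replicate", rep.replicate)
                frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.accuracy_table().to_csv(out / "accuracy_table.csv", index=False)
        self.per_animal_table().to_csv(out / "per_animal.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "replicate_seeds": [r.seed for r in self.replicates],
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def run_experiment(config: ExperimentConfig,
                   n_replicates: int | None = None,
                   jobs: list[tuple[str, str]] | None = None,
                   out_dir=None) -> ExperimentResult:
    """Run ``n_replicates`` independent replicates with seeds derived from
    the config's master seed, and aggregate accuracies."""
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    if n_rep < 1:
        raise ParameterError("need at least one replicate")
    reps = []
    for i in range(n_rep):
        seed = derive_int_seed(config.master_seed, "replicate", i)
        reps.append(run_replicate(config, seed, jobs=jobs, replicate_index=i))
    result = ExperimentResult(config=config, replicates=reps)
    if out_dir is not None:
        result.save(out_dir)
    return result
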