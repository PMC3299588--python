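"""Empirical, PEV-based and deterministic accuracies of breeding values.

Empirical accuracy is the Pearson correlation between estimated and true
breeding values in a validation group (r_cor).  Per-animal accuracy is
derived from the prediction error variance of the mixed-model equations,

    r_i = sqrt(1 - sigma_e^2 C_ii / (sigma_a^2 K_ii)),

where C_ii is the diagonal of the inverse coefficient matrix and K_ii the
animal's own relationship (genomic or pedigree) diagonal.

Two deterministic predictions of the accuracy achievable for an individual
with no phenotype of its own are provided: Goddard's formula, driven by the
effective number of independent chromosome segments Me, and the simpler
Daetwyler formula r = sqrt(N h^2 / (N h^2 + Me)).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import ParameterError

ME_VARIANTS = ("2NeL", "4NeL", "2NeL_over_ln4NeL")


def empirical_accuracy(ebv, truth, group_labels=None):
    """Pearson correlation between EBV and truth, per group.

    If either vector is constant within a group the correlation is reported
    as 0.0 — the convention for shallow-pedigree BLUP, where unrelated test
    animals all receive an EBV of exactly zero.  Returns a float when no
    groups are given, else a dict keyed by group label; groups of size < 2
    yield NaN.
    """
    ebv = np.asarray(ebv, float)
    truth = np.asarray(truth, float)
    if ebv.shape != truth.shape:
        raise ParameterError("ebv and truth must have equal length")

    def _corr(a, b):
        if a.size < 2:
            return np.nan
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    if group_labels is None:
        return _corr(ebv, truth)
    group_labels = np.asarray(group_labels)
    return {g: _corr(ebv[group_labels == g], truth[group_labels == g])
            for g in np.unique(group_labels)}


def pev_accuracy(c_diag, K_diag, sigma_a2: float, sigma_e2: float,
                 tol: float = 1e-4) -> np.ndarray:
    """Per-animal accuracy from the prediction error variance,
    r_i = sqrt(1 - PEV_i / (sigma_a^2 K_ii)) with PEV_i = sigma_e^2 c_ii.

    For an animal carrying no information PEV equals sigma_a^2 K_ii exactly,
    so the radicand sits at 0; the ridge stabilizing K^-1 in the MME can push
    it slightly negative.  Radicands within ``tol`` of zero are clipped with
    a warning; anything lower raises.
    """
    c_diag = np.asarray(c_diag, float)
    K_diag = np.asarray(K_diag, float)
    if np.any(K_diag <= 0):
        raise ParameterError("K diagonal must be positive")
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ParameterError("variances must be positive")
    radicand = 1.0 - sigma_e2 * c_diag / (sigma_a2 * K_diag)
    if np.any(radicand < -tol):
        raise FloatingPointError(
            f"PEV exceeds the genetic variance (min radicand "
            f"{radicand.min():.3g}); check the variance components")
    if np.any(radicand < 0):
        warnings.warn("clipping tiny negative reliability radicands at 0")
    return np.sqrt(np.clip(radicand, 0.0, 1.0))


def effective_segments(ne: float, genome_length_morgans: float,
                       me_variant: str = "2NeL") -> float:
    """Effective number of independently segregating chromosome segments."""
    if ne <= 0 or genome_length_morgans <= 0:
        raise ParameterError("Ne and L must be positive")
    L = genome_length_morgans
    if me_variant == "2NeL":
        return 2.0 * ne * L
    if me_variant == "4NeL":
        return 4.0 * ne * L
    if me_variant == "2NeL_over_ln4NeL":
        return 2.0 * ne * L / np.log(4.0 * ne * L)
    raise ParameterError(f"unknown Me variant {me_variant!r}; "
                         f"choose one of {ME_VARIANTS}")


@dataclass(frozen=True)
class DeterministicPrediction:
    """Goddard-formula accuracy with all intermediates.

    k = 1/ln(2 Ne) rescales heterozygosity across segment sizes;
    lambda = Me k / h^2 is the shrinkage of a single segment effect with the
    total variance standardized; a = 1 + 2 lambda / N.
    """

    n_reference: int
    ne: float
    h2: float
    genome_length_morgans: float
    me_variant: str
    k: float
    me: float
    lambda_: float
    a: float
    rho_plus: float
    rho_minus: float
    r: float


def goddard_accuracy(n_reference: int, ne: float, h2: float,
                     genome_length_morgans: float,
                     me_variant: str = "2NeL") -> DeterministicPrediction:
    """Deterministic accuracy for an unphenotyped individual:

        r = sqrt(1 - lambda/(2 N sqrt(a)) * ln((1+a+2 sqrt(a))/(1+a-2 sqrt(a))))

    with k = 1/ln(2 Ne), Me per variant, lambda = Me k / h^2 and
    a = 1 + 2 lambda / N (natural logarithms throughout).
    """
    if n_reference <= 0 or ne <= 0 or genome_length_morgans <= 0:
        raise ParameterError("N, Ne and L must be positive")
    if not (0 < h2 <= 1):
        raise ParameterError("h2 must be in (0, 1]")
    N = float(n_reference)
    k = 1.0 / np.log(2.0 * ne)
    me = effective_segments(ne, genome_length_morgans, me_variant)
    lam = me * k / h2
    a = 1.0 + 2.0 * lam / N
    sqa = np.sqrt(a)
    rho_plus = 1.0 + a + 2.0 * sqa
    rho_minus = 1.0 + a - 2.0 * sqa
    if rho_minus <= 0:
        raise FloatingPointError("log argument non-positive")
    r2 = 1.0 - lam / (2.0 * N * sqa) * np.log(rho_plus / rho_minus)
    if r2 < 0:
        raise FloatingPointError("negative squared accuracy; inputs out of "
                                 "the formula's domain")
    return DeterministicPrediction(
        n_reference=int(n_reference), ne=float(ne), h2=float(h2),
        genome_length_morgans=float(genome_length_morgans),
        me_variant=me_variant, k=float(k), me=float(me), lambda_=float(lam),
        a=float(a), rho_plus=float(rho_plus), rho_minus=float(rho_minus),
        r=float(np.sqrt(r2)))


def daetwyler_accuracy(n_reference: int, h2: float, me: float) -> float:
    """Deterministic accuracy r = sqrt(N h^2 / (N h^2 + Me))."""
    if n_reference <= 0 or me <= 0:
        raise ParameterError("N and Me must be positive")
    if not (0 < h2 <= 1):
        raise ParameterError("h2 must be in (0, 1]")
    nh2 = n_reference * h2
    return float(np.sqrt(nh2 / (nh2 + me)))
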