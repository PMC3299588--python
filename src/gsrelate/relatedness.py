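"""Genomic and pedigree relationship matrices, summaries and SNP QC.

The genomic relationship matrix follows VanRaden's first method,

    G = W W' / (2 * sum_i p_i (1 - p_i)),   W = M - 2P,

where M holds 0/1/2 genotypes and column i of P is the allele frequency
p_i.  With base-generation frequencies E[G] equals the pedigree numerator
relationship matrix (NRM), while realized values vary around it — the
variation that lets gBLUP exploit Mendelian sampling and distant
relationships.

The NRM is built by the tabular method; for deep generation-structured
pedigrees a layered recurrence computes the needed sub-blocks without ever
holding the full matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import DataError, ParameterError


@dataclass
class RelationshipMatrix:
    """Symmetric additive-relationship matrix over an ordered id set."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "genomic" | "pedigree"

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.values.shape != (self.ids.size, self.ids.size):
            raise ParameterError("matrix shape does not match id count")

    def index_of(self, ids) -> np.ndarray:
        lookup = {int(a): i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[int(a)] for a in np.asarray(ids).ravel()])
        except KeyError as e:  # pragma: no cover - defensive
            raise ParameterError(f"id {e} not in relationship matrix") from e

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(np.asarray(ids), self.values[np.ix_(idx, idx)],
                                  self.kind)

    def block(self, row_ids, col_ids) -> np.ndarray:
        return self.values[np.ix_(self.index_of(row_ids), self.index_of(col_ids))]

    def diagonal(self, ids=None) -> np.ndarray:
        if ids is None:
            return np.diag(self.values)
        return self.values[self.index_of(ids), self.index_of(ids)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(np.int64), df.to_numpy(np.float64), kind)

    def save(self, path) -> None:
        np.savez_compressed(path, ids=self.ids, values=self.values,
                            kind=np.array(self.kind))

    @classmethod
    def load(cls, path) -> "RelationshipMatrix":
        with np.load(path) as z:
            return cls(z["ids"], z["values"], str(z["kind"]))


def compute_grm(genotypes: np.ndarray, allele_freqs: np.ndarray | None = None,
                ids=None) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    ``allele_freqs`` defaults to observed column frequencies; pass
    base-generation frequencies in simulations so that E[G] matches the
    pedigree expectation.  Monomorphic markers (p(1-p)=0) are excluded from
    both numerator and denominator with a warning.
    """
    M = np.asarray(genotypes)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ParameterError("genotypes must be an (n>=2) x m matrix")
    n, m = M.shape
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    if p.shape != (m,):
        raise ParameterError("allele frequency vector length mismatch")
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from the GRM")
    W = M[:, poly].astype(np.float32) - (2.0 * p[poly]).astype(np.float32)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom <= 0:
        raise ParameterError("no polymorphic markers: GRM undefined")
    G = (W @ W.T).astype(np.float64) / denom
    G = (G + G.T) / 2.0
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    return RelationshipMatrix(ids, G, "genomic")


# ---------------------------------------------------------------------------
# pedigree handling
# ---------------------------------------------------------------------------

def _as_pedigree_frame(pedigree) -> pd.DataFrame:
    if isinstance(pedigree, pd.DataFrame):
        df = pedigree.copy()
    else:
        df = pd.DataFrame(pedigree, columns=["id", "sire", "dam"])
    for col in ("id", "sire", "dam"):
        if col not in df:
            raise DataError(f"pedigree lacks column {col!r}")
        df[col] = df[col].astype(np.int64)
    if (df["id"] <= 0).any():
        raise DataError("animal ids must be positive (0 is reserved for unknown)")
    if df["id"].duplicated().any():
        raise DataError("duplicate animal id in pedigree")
    return df


def _topo_levels(df: pd.DataFrame) -> np.ndarray:
    """Topological depth per animal (founders = 0); raises on cycles."""
    ids = df["id"].to_numpy()
    pos = {int(a): i for i, a in enumerate(ids)}
    sire = df["sire"].to_numpy()
    dam = df["dam"].to_numpy()
    level = np.full(ids.size, -1, dtype=np.int64)

    def depth(i, stack):
        if level[i] >= 0:
            return level[i]
        if i in stack:
            raise DataError("cyclic pedigree")
        stack.add(i)
        d = 0
        for par in (sire[i], dam[i]):
            if par != 0:
                if int(par) not in pos:
                    raise DataError(f"parent {par} not in pedigree")
                d = max(d, depth(pos[int(par)], stack) + 1)
        stack.discard(i)
        level[i] = d
        return d

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, ids.size * 2 + 100))
    try:
        for i in range(ids.size):
            depth(i, set())
    finally:
        sys.setrecursionlimit(old)
    return level


def compute_nrm(pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire_i, dam_i); a_ij = 0.5 * (a(j, sire_i) +
    a(j, dam_i)) for j processed before i; an unknown parent contributes 0.
    The pedigree is topologically sorted internally, so row order does not
    matter.  O(n^2) memory — intended for pedigrees up to a few thousand
    animals; use :func:`nrm_submatrix` for deep generation pedigrees.
    """
    df = _as_pedigree_frame(pedigree)
    levels = _topo_levels(df)
    order = np.argsort(levels, kind="stable")
    ids = df["id"].to_numpy()[order]
    pos = {int(a): i for i, a in enumerate(ids)}
    sire = np.array([pos.get(int(s), -1) for s in df["sire"].to_numpy()[order]])
    dam = np.array([pos.get(int(d), -1) for d in df["dam"].to_numpy()[order]])

    n = ids.size
    A = np.zeros((n + 1, n + 1))  # index n = unknown (all-zero row/col)
    sire[sire < 0] = n
    dam[dam < 0] = n
    for i in range(n):
        s, d = sire[i], dam[i]
        row = 0.5 * (A[s, :n] + A[d, :n])
        A[i, :n] = row
        A[:n, i] = row
        A[i, i] = 1.0 + 0.5 * A[s, d]
        A[n, :] = 0.0
        A[:, n] = 0.0
    # restore original row order
    back = np.argsort(order, kind="stable")
    return RelationshipMatrix(df["id"].to_numpy(), A[:n, :n][np.ix_(back, back)],
                              "pedigree")


def nrm_submatrix(pedigree, ids) -> RelationshipMatrix:
    """Exact NRM block for ``ids`` from a deep pedigree.

    Works level by level through the topologically sorted pedigree keeping
    only animals that are still needed (future parents or requested ids),
    so memory scales with the largest active layer rather than the full
    pedigree.  Matches :func:`compute_nrm` exactly.
    """
    df = _as_pedigree_frame(pedigree)
    levels = _topo_levels(df)
    ids = np.asarray(ids, dtype=np.int64)
    want = set(int(a) for a in ids)
    missing = want - set(int(a) for a in df["id"])
    if missing:
        raise ParameterError(f"ids not in pedigree: {sorted(missing)[:5]} ...")

    id_arr = df["id"].to_numpy()
    sire_arr = df["sire"].to_numpy()
    dam_arr = df["dam"].to_numpy()
    lvl_of = {int(a): int(l) for a, l in zip(id_arr, levels)}

    # last level at which each animal is needed
    last = {int(a): (np.inf if int(a) in want else -1) for a in id_arr}
    for a, s, d in zip(id_arr, sire_arr, dam_arr):
        for par in (int(s), int(d)):
            if par != 0:
                last[par] = max(last[par], lvl_of[int(a)])

    parents = {int(a): (int(s), int(d)) for a, s, d in zip(id_arr, sire_arr, dam_arr)}
    max_level = int(levels.max())
    active: list[int] = []
    A = np.zeros((0, 0))
    idx: dict[int, int] = {}

    for lev in range(max_level + 1):
        members = [int(a) for a, l in zip(id_arr, levels)
                   if l == lev and last[int(a)] >= lev]
        if not members:
            continue
        k = len(active)
        Ap = np.zeros((k + 1, k + 1))
        Ap[:k, :k] = A
        s_idx = np.array([idx.get(parents[a][0], k) for a in members])
        d_idx = np.array([idx.get(parents[a][1], k) for a in members])
        # animals with known parents not in `active` would be an error:
        for a in members:
            for par in parents[a]:
                if par != 0 and par not in idx:
                    raise DataError("parent dropped before use (pedigree not "
                                    "generation-structured)")  # pragma: no cover
        cross = 0.5 * (Ap[:k, s_idx] + Ap[:k, d_idx])          # k x m
        mm = 0.25 * (Ap[np.ix_(s_idx, s_idx)] + Ap[np.ix_(s_idx, d_idx)]
                     + Ap[np.ix_(d_idx, s_idx)] + Ap[np.ix_(d_idx, d_idx)])
        np.fill_diagonal(mm, 1.0 + 0.5 * Ap[s_idx, d_idx])
        m = len(members)
        newA = np.empty((k + m, k + m))
        newA[:k, :k] = A
        newA[:k, k:] = cross
        newA[k:, :k] = cross.T
        newA[k:, k:] = mm
        new_active = active + members
        keep = [i for i, a in enumerate(new_active) if last[a] > lev or a in want]
        A = newA[np.ix_(keep, keep)]
        active = [new_active[i] for i in keep]
        idx = {a: i for i, a in enumerate(active)}

    sel = np.array([idx[int(a)] for a in ids])
    return RelationshipMatrix(ids, A[np.ix_(sel, sel)], "pedigree")


def truncate_pedigree(pedigree, depth_generations: int) -> pd.DataFrame:
    """Set parents unknown beyond ``depth_generations`` above the youngest
    generation; all individuals are retained.

    With depth 1 only the youngest generation keeps its parent links — the
    shallow pedigree used by single-generation BLUP.
    """
    if depth_generations < 1:
        raise ParameterError("depth must be >= 1")
    df = _as_pedigree_frame(pedigree)
    if "generation" in df:
        gen = df["generation"].to_numpy(np.int64)
    else:
        gen = _topo_levels(df)
    gmax = gen.max()
    cut = gen < gmax - depth_generations + 1
    out = df.copy()
    out.loc[cut, ["sire", "dam"]] = 0
    return out


def relationship_summaries(rel: RelationshipMatrix, test_ids, reference_ids,
                           top: tuple[int, ...] = (10, 100)) -> pd.DataFrame:
    """Per-test-animal relationship summaries over the test x reference block:
    mean, maximum, and means of the top-k relationships (k = 10 and 100 by
    default; if the reference is smaller than k all of it is used)."""
    test_ids = np.asarray(test_ids)
    reference_ids = np.asarray(reference_ids)
    if test_ids.size == 0 or reference_ids.size == 0:
        raise ParameterError("empty test or reference set")
    block = rel.block(test_ids, reference_ids)
    # exclude self-pairs if sets overlap
    overlap = np.intersect1d(test_ids, reference_ids)
    if overlap.size:
        block = block.astype(float).copy()
        for a in overlap:
            block[np.flatnonzero(test_ids == a)[0],
                  np.flatnonzero(reference_ids == a)[0]] = np.nan
    sorted_desc = -np.sort(-block, axis=1)  # NaNs sort to the end
    out = {"mean": np.nanmean(block, axis=1), "max": np.nanmax(block, axis=1)}
    for k in top:
        kk = min(k, reference_ids.size)
        out[f"mean_top_{k}"] = np.nanmean(sorted_desc[:, :kk], axis=1)
    return pd.DataFrame(out, index=pd.Index(test_ids, name="id"))


# ---------------------------------------------------------------------------
# SNP quality control
# ---------------------------------------------------------------------------

@dataclass
class SnpQcReport:
    """Per-SNP filter flags and the retained index list."""

    flags: dict[str, np.ndarray]
    retained: np.ndarray
    n_input: int

    @property
    def counts_removed(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.flags.items()}

    @property
    def n_retained(self) -> int:
        return int(self.retained.size)


def qc_filter_snps(genotypes: np.ndarray,
                   chrom: np.ndarray | None = None,
                   pos: np.ndarray | None = None,
                   call_rate: np.ndarray | None = None,
                   gc_score: np.ndarray | None = None,
                   has_location: np.ndarray | None = None,
                   min_call_rate: float = 0.95,
                   min_gc_score: float = 0.6,
                   min_maf: float = 0.01,
                   het_sd_limit: float = 3.0,
                   hwe_p_cutoff: float = 1e-15,
                   ld_r2_cutoff: float = 0.99) -> SnpQcReport:
    """Standard SNP-chip quality filters.

    Genotypes are an ``n x m`` matrix of 0/1/2 dosages with missing values
    coded as negative or NaN.  Filters: call rate < 0.95, GC score < 0.6,
    MAF < 0.01, heterozygosity more than 3 SD above the batch mean, HWE
    chi-square (1 df) p < 1e-15, missing genome location, and r^2 > 0.99
    with an already-retained SNP (the earlier SNP by position is kept).
    A filter whose metadata is unavailable is skipped with a warning.
    """
    Gm = np.asarray(genotypes, dtype=float)
    n, m = Gm.shape
    miss = ~np.isfinite(Gm) | (Gm < 0)
    Gm = np.where(miss, np.nan, Gm)
    flags: dict[str, np.ndarray] = {}

    obs = n - miss.sum(axis=0)
    cr = (obs / n) if call_rate is None else np.asarray(call_rate, float)
    flags["call_rate"] = cr < min_call_rate

    if gc_score is not None:
        flags["gc_score"] = np.asarray(gc_score, float) < min_gc_score
    else:
        warnings.warn("no GC scores supplied; GC filter skipped")

    with np.errstate(invalid="ignore"):
        p = np.nanmean(Gm, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    flags["maf"] = maf < min_maf

    het = np.nanmean(Gm == 1, axis=0)
    mu, sd = float(np.mean(het)), float(np.std(het))
    flags["heterozygosity"] = het > mu + het_sd_limit * sd if sd > 0 else np.zeros(m, bool)

    n_aa = np.nansum(Gm == 0, axis=0)
    n_ab = np.nansum(Gm == 1, axis=0)
    n_bb = np.nansum(Gm == 2, axis=0)
    tot = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (n_ab + 2 * n_bb) / (2 * tot)
        exp = np.stack([tot * (1 - q) ** 2, 2 * tot * q * (1 - q), tot * q**2])
        obs3 = np.stack([n_aa, n_ab, n_bb])
        chi2 = np.where(exp > 0, (obs3 - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum(axis=0)
    hwe_p = stats.chi2.sf(chi2, df=1)
    flags["hwe"] = hwe_p < hwe_p_cutoff

    if has_location is not None:
        flags["location"] = ~np.asarray(has_location, bool)
    elif chrom is not None:
        flags["location"] = ~np.isfinite(np.asarray(chrom, float))
    else:
        warnings.warn("no location metadata supplied; location filter skipped")

    pre = np.zeros(m, dtype=bool)
    for f in flags.values():
        pre |= f

    # LD pruning among SNPs that survived everything else, within chromosome,
    # keeping the first SNP by position of each high-LD pair
    ld = np.zeros(m, dtype=bool)
    chrom_arr = np.zeros(m) if chrom is None else np.asarray(chrom)
    pos_arr = np.arange(m) if pos is None else np.asarray(pos)
    Gz = np.where(np.isnan(Gm), np.nanmean(Gm, axis=0), Gm)
    for c in np.unique(chrom_arr):
        cand = np.flatnonzero((chrom_arr == c) & ~pre)
        cand = cand[np.argsort(pos_arr[cand], kind="stable")]
        if cand.size < 2:
            continue
        X = Gz[:, cand]
        X = X - X.mean(axis=0)
        sd_x = X.std(axis=0)
        sd_x[sd_x == 0] = np.nan
        r = (X.T @ X) / n / np.outer(sd_x, sd_x)
        r2 = np.nan_to_num(r**2)
        kept: list[int] = []
        for j in range(cand.size):
            if kept and np.any(r2[j, kept] > ld_r2_cutoff):
                ld[cand[j]] = True
            else:
                kept.append(j)
    flags["ld"] = ld

    removed = pre | ld
    return SnpQcReport(flags=flags, retained=np.flatnonzero(~removed), n_input=m)
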