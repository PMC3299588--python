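"""GRM, NRM (tabular vs independent recursion), summaries and SNP QC."""
import numpy as np
import pandas as pd
import pytest

from gsrelate import DataError, ParameterError
from gsrelate.relatedness import (RelationshipMatrix, compute_grm, compute_nrm,
                                  nrm_submatrix, qc_filter_snps,
                                  relationship_summaries, truncate_pedigree)


def kinship_oracle(ped: pd.DataFrame) -> np.ndarray:
    """Independent NRM oracle: recursive coancestry (path counting),
    a_ij = 2 f_ij, a_ii = 1 + f_sd.  Assumes parents listed before
    offspring; no memoized tabular rows are used."""
    ids = ped["id"].tolist()
    pos = {a: i for i, a in enumerate(ids)}
    sire = ped["sire"].tolist()
    dam = ped["dam"].tolist()
    cache = {}

    def f(i, j):
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            s, d = sire[i], dam[i]
            val = 0.5
            if s and d:
                val += 0.5 * f(pos[s], pos[d])
        else:
            # j is the younger (later-listed) animal
            s, d = sire[j], dam[j]
            val = 0.0
            if s:
                val += 0.5 * f(i, pos[s])
            if d:
                val += 0.5 * f(i, pos[d])
        cache[(i, j)] = val
        return val

    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2 * f(i, j) if i != j else 2 * f(i, i)
    return A


def random_generation_pedigree(rng, n_founders=4, n_gens=3, per_gen=5):
    rows = [(i + 1, 0, 0) for i in range(n_founders)]
    next_id = n_founders + 1
    prev = list(range(1, n_founders + 1))
    for _ in range(n_gens):
        cur = []
        for _ in range(per_gen):
            s, d = rng.choice(prev, 2, replace=len(prev) < 2)
            rows.append((next_id, int(s), int(d)))
            cur.append(next_id)
            next_id += 1
        prev = cur
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


class TestGrm:
    def test_identical_genotypes_share_all_entries(self):
        g = np.array([[0, 1, 2, 1], [0, 1, 2, 1]])
        grm = compute_grm(g, allele_freqs=np.array([0.3, 0.5, 0.7, 0.5]))
        assert grm.values[0, 1] == pytest.approx(grm.values[0, 0])
        assert grm.values[0, 0] == pytest.approx(grm.values[1, 1])

    def test_all_heterozygous_at_half_frequency_gives_zero_diag(self):
        g = np.array([[1, 1, 1, 1], [0, 2, 0, 2]])
        grm = compute_grm(g, allele_freqs=np.full(4, 0.5))
        # W row of the heterozygote is all zeros
        assert grm.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_diagonal_near_one_with_base_frequencies(self, small_pop):
        cols = small_pop.loci.marker_cols
        ids = small_pop.ids_of_generation(0)
        grm = compute_grm(small_pop.genotypes(ids, cols),
                          small_pop.base_freq[cols], ids=ids)
        assert np.diag(grm.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_markers_warn_and_are_excluded(self):
        g = np.array([[0, 0, 2], [0, 2, 0], [0, 1, 1]])
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(g)
        g2 = g[:, 1:]
        grm2 = compute_grm(g2)
        np.testing.assert_allclose(grm.values, grm2.values)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            compute_grm(np.array([[0, 1, 2]]))  # single animal

    def test_grm_tracks_pedigree_classes_but_varies_around_them(self, small_pop):
        """Realized genomic relationships average to the pedigree
        expectation within a relationship class (here paternal half sibs,
        0.25) yet vary around it — the extra information genomic BLUP
        exploits and pedigree BLUP cannot.  Generation 1 is used so parents
        are unrelated founders and the class value is exactly 0.25."""
        rows = small_pop.gen_rows(1)
        ids = small_pop.id[rows]
        cols = small_pop.loci.marker_cols
        grm = compute_grm(small_pop.genotypes(ids, cols),
                          small_pop.base_freq[cols], ids=ids)
        sire = small_pop.sire[rows]
        dam = small_pop.dam[rows]
        same_sire = sire[:, None] == sire[None, :]
        same_dam = dam[:, None] == dam[None, :]
        hs = np.triu(same_sire & ~same_dam, k=1)
        vals = grm.values[hs]
        assert vals.size > 100
        assert np.mean(vals) == pytest.approx(0.25, abs=0.04)
        assert np.std(vals) > 0.02


class TestNrm:
    def test_parent_offspring_and_half_sibs(self):
        ped = pd.DataFrame({"id": [1, 2, 3, 4, 5],
                            "sire": [0, 0, 0, 1, 1],
                            "dam": [0, 0, 0, 2, 3]})
        A = compute_nrm(ped)
        assert A.block([1], [4])[0, 0] == pytest.approx(0.5)
        assert A.block([4], [5])[0, 0] == pytest.approx(0.25)  # paternal HS
        assert A.values[0, 0] == pytest.approx(1.0)

    def test_full_sibs_and_inbred_offspring(self):
        ped = pd.DataFrame({"id": [1, 2, 3, 4, 5],
                            "sire": [0, 0, 1, 1, 3],
                            "dam": [0, 0, 2, 2, 4]})
        A = compute_nrm(ped)
        assert A.block([3], [4])[0, 0] == pytest.approx(0.5)   # full sibs
        # offspring of full sibs: F = 0.25
        assert A.block([5], [5])[0, 0] == pytest.approx(1.25)

    @pytest.mark.parametrize("seed", range(8))
    def test_tabular_equals_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_generation_pedigree(rng)
        A = compute_nrm(ped)
        np.testing.assert_allclose(A.values, kinship_oracle(ped), atol=1e-12)

    def test_row_order_does_not_matter(self):
        ped = pd.DataFrame({"id": [4, 1, 2, 3], "sire": [1, 0, 0, 1],
                            "dam": [2, 0, 0, 2]})
        A = compute_nrm(ped)
        assert A.block([3], [4])[0, 0] == pytest.approx(0.5)

    def test_cycle_detection(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [2, 1], "dam": [0, 0]})
        with pytest.raises(DataError):
            compute_nrm(ped)

    @pytest.mark.parametrize("seed", range(4))
    def test_layered_submatrix_equals_tabular(self, seed):
        rng = np.random.default_rng(100 + seed)
        ped = random_generation_pedigree(rng, n_founders=6, n_gens=4, per_gen=8)
        ids = rng.choice(ped["id"].to_numpy(), 10, replace=False)
        sub = nrm_submatrix(ped, ids)
        full = compute_nrm(ped).submatrix(ids)
        np.testing.assert_allclose(sub.values, full.values, atol=1e-12)

    def test_layered_submatrix_on_simulated_population(self, small_pop):
        ped = small_pop.pedigree_frame()[["id", "sire", "dam"]]
        last = small_pop.ids_of_generation(small_pop.max_generation)[:30]
        early = small_pop.ids_of_generation(1)[:10]
        ids = np.concatenate([early, last])
        sub = nrm_submatrix(ped, ids)
        full = compute_nrm(ped).submatrix(ids)
        np.testing.assert_allclose(sub.values, full.values, atol=1e-10)


class TestTruncatePedigree:
    def make_three_gen(self):
        return pd.DataFrame({
            "id": [1, 2, 3, 4, 5, 6],
            "sire": [0, 0, 1, 1, 3, 3],
            "dam": [0, 0, 2, 2, 4, 4],
            "generation": [0, 0, 1, 1, 2, 2]})

    def test_depth_one_keeps_only_youngest_links(self):
        out = truncate_pedigree(self.make_three_gen(), 1)
        assert (out.loc[out["generation"] < 2, ["sire", "dam"]] == 0).all().all()
        assert (out.loc[out["generation"] == 2, "sire"] == 3).all()

    def test_depth_beyond_pedigree_is_identity(self):
        ped = self.make_three_gen()
        out = truncate_pedigree(ped, 10)
        pd.testing.assert_frame_equal(out, ped)

    def test_truncation_zeroes_grandparent_relationship(self):
        """Depth-1 NRM: grandparent links vanish, parent-based full sibs
        keep 0.5."""
        ped = self.make_three_gen()
        A = compute_nrm(truncate_pedigree(ped, 1)[["id", "sire", "dam"]])
        assert A.block([1], [5])[0, 0] == 0.0          # grandparent
        assert A.block([5], [6])[0, 0] == pytest.approx(0.5)  # full sibs


class TestRelationshipSummaries:
    def test_single_reference_animal(self):
        rel = RelationshipMatrix(np.array([1, 2]), np.array([[1.0, 0.3],
                                                             [0.3, 1.0]]),
                                 "pedigree")
        s = relationship_summaries(rel, [1], [2])
        np.testing.assert_allclose(s.loc[1].to_numpy(), 0.3)

    def test_constant_matrix(self):
        n = 30
        ids = np.arange(1, n + 1)
        rel = RelationshipMatrix(ids, np.full((n, n), 0.2), "genomic")
        s = relationship_summaries(rel, ids[:5], ids[5:])
        for col in s:
            np.testing.assert_allclose(s[col], 0.2)

    def test_order_statistics_property(self):
        rng = np.random.default_rng(3)
        n = 150
        M = rng.normal(size=(n, n))
        M = (M + M.T) / 2
        ids = np.arange(1, n + 1)
        rel = RelationshipMatrix(ids, M, "genomic")
        s = relationship_summaries(rel, ids[:20], ids[20:])
        assert (s["max"] >= s["mean_top_10"] - 1e-12).all()
        assert (s["mean_top_10"] >= s["mean_top_100"] - 1e-12).all()
        assert (s["mean_top_100"] >= s["mean"] - 1e-12).all()
        # brute-force check of one row
        row = np.sort(M[0, 20:])[::-1]
        assert s["mean_top_10"].iloc[0] == pytest.approx(row[:10].mean())

    def test_empty_sets_raise(self):
        rel = RelationshipMatrix(np.array([1]), np.eye(1), "genomic")
        with pytest.raises(ParameterError):
            relationship_summaries(rel, [], [1])


class TestSnpQc:
    def make_geno(self, rng, n=200, m=40, maf_low=0.05):
        p = rng.uniform(maf_low, 0.5, m)
        return rng.binomial(2, p, size=(n, m)).astype(float)

    def test_low_maf_removed(self):
        rng = np.random.default_rng(1)
        G = self.make_geno(rng)
        G[:, 0] = 0.0
        G[0, 0] = 1.0  # MAF = 1/400 < 0.01
        rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                             pos=np.arange(G.shape[1]))
        assert rep.flags["maf"][0]
        assert 0 not in rep.retained

    def test_all_pass(self):
        rng = np.random.default_rng(2)
        G = self.make_geno(rng, maf_low=0.2)
        rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                             pos=np.arange(G.shape[1]),
                             gc_score=np.ones(G.shape[1]))
        assert rep.n_retained == G.shape[1]
        assert all(v == 0 for v in rep.counts_removed.values())

    def test_duplicate_column_pruned_once(self):
        rng = np.random.default_rng(3)
        G = self.make_geno(rng, maf_low=0.2)
        G[:, 5] = G[:, 4]  # r^2 = 1 pair
        rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                             pos=np.arange(G.shape[1]))
        assert rep.flags["ld"][5] and not rep.flags["ld"][4]

    def test_call_rate_and_location_filters(self):
        rng = np.random.default_rng(4)
        G = self.make_geno(rng, maf_low=0.2)
        G[: G.shape[0] // 2, 3] = np.nan       # call rate 0.5
        has_loc = np.ones(G.shape[1], bool)
        has_loc[7] = False
        rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                             pos=np.arange(G.shape[1]), has_location=has_loc)
        assert rep.flags["call_rate"][3]
        assert rep.flags["location"][7]

    def test_hwe_filter_catches_gross_departure(self):
        rng = np.random.default_rng(5)
        G = self.make_geno(rng, n=2000, maf_low=0.2)
        G[:, 2] = 1.0  # everyone heterozygous: extreme HWE departure
        rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                             pos=np.arange(G.shape[1]))
        assert rep.flags["hwe"][2] or rep.flags["heterozygosity"][2]

    def test_retained_is_complement_of_flag_union(self):
        """Structural invariant: retained indices = input minus the union of
        all per-filter flags, and counts are reproducible from the flags."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=20, derandomize=True, deadline=None)
        @given(st.integers(0, 2**31 - 1))
        def check(seed):
            rng = np.random.default_rng(seed)
            G = self.make_geno(rng, n=60, m=25, maf_low=0.0)
            rep = qc_filter_snps(G, chrom=np.zeros(25), pos=np.arange(25))
            union = np.zeros(25, bool)
            for name, f in rep.flags.items():
                union |= f
                assert rep.counts_removed[name] == int(f.sum())
            np.testing.assert_array_equal(rep.retained, np.flatnonzero(~union))

        check()

    def test_missing_metadata_skips_filter_with_warning(self):
        rng = np.random.default_rng(6)
        G = self.make_geno(rng, maf_low=0.2)
        with pytest.warns(UserWarning, match="GC"):
            rep = qc_filter_snps(G, chrom=np.zeros(G.shape[1]),
                                 pos=np.arange(G.shape[1]))
        assert "gc_score" not in rep.flags
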