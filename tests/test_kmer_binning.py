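import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from twinmag.kmer_binning import (
    UNASSIGNED,
    BinningConfig,
    BinSignature,
    bin_pc1,
    canonical_kmers,
    clr,
    kmer_profile,
    recruit,
    run_binning,
    seed_bins,
)
from twinmag.synthetic_data import (
    ContigRecord,
    GenomeSpec,
    TwinDesign,
    fragment_genomes,
    generate_genomes,
    simulate_coverage,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_force_profile(seq: str, k: int = 5) -> dict:
    """Sliding-window canonical k-mer counter, independent of the
    vectorized implementation."""
    counts: dict = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(b not in "ACGT" for b in kmer):
            continue
        canon = min(kmer, revcomp(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    return counts


dna = st.text(alphabet="ACGT", min_size=5, max_size=80)


class TestKmerProfile:
    def test_canonical_space_size(self):
        assert len(canonical_kmers(5)) == 512

    def test_homopolymer(self):
        row = kmer_profile([ContigRecord("c", "AAAAAAA")], k=5).iloc[0]
        assert row["AAAAA"] == 3
        assert row.sum() == 3

    @given(seq=dna)
    def test_strand_symmetry(self, seq):
        prof = kmer_profile(
            [ContigRecord("f", seq), ContigRecord("r", revcomp(seq))], k=5
        )
        assert (prof.iloc[0] == prof.iloc[1]).all()

    def test_matches_brute_force_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        row = kmer_profile([ContigRecord("c", seq)], k=5).iloc[0]
        expected = brute_force_profile(seq)
        for kmer, n in expected.items():
            assert row[kmer] == n
        assert row.sum() == sum(expected.values())

    def test_n_windows_skipped(self):
        seq = "ACGTACGTNACGTACGT"
        row = kmer_profile([ContigRecord("c", seq)], k=5).iloc[0]
        expected = brute_force_profile(seq)
        assert row.sum() == sum(expected.values())
        assert row.sum() == (len(seq) - 4) - 5  # 5 windows touch the N

    def test_short_contig_raises_with_name(self):
        with pytest.raises(ValueError, match="shorty"):
            kmer_profile([ContigRecord("shorty", "ACG")], k=5)


class TestCLR:
    def test_constant_row_is_zero(self):
        counts = pd.DataFrame([[5.0] * 8], index=["c"])
        assert np.allclose(clr(counts, pseudocount=1e-9).iloc[0], 0.0)

    def test_direct_formula(self):
        counts = pd.DataFrame([[1.0, 3.0]], index=["c"])
        out = clr(counts, pseudocount=1.0).iloc[0].to_numpy()
        logs = np.log([2.0, 4.0])
        assert np.allclose(out, logs - logs.mean())

    @given(
        row=st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=20)
    )
    def test_rows_sum_to_zero(self, row):
        counts = pd.DataFrame([row], index=["c"], dtype=float)
        assert abs(clr(counts).iloc[0].sum()) < 1e-9

    def test_scale_invariance_in_small_pc_limit(self):
        row = np.array([[4.0, 9.0, 25.0]])
        a = clr(pd.DataFrame(row), pseudocount=1e-12)
        b = clr(pd.DataFrame(row * 10), pseudocount=1e-12)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            clr(pd.DataFrame([[1.0]]), pseudocount=0.0)


class TestSeedBins:
    def test_three_separated_genomes_three_pure_bins(self, small_mixture):
        contigs = small_mixture["contigs"]
        large = [c for c in contigs if c.length >= 2500]
        prof = kmer_profile(large)
        assignment = seed_bins(clr(prof), min_cluster_size=5)
        truth = {c.contig_id: c.truth_genome for c in large}
        binned = {c: b for c, b in assignment.assignment.items() if b != UNASSIGNED}
        assert len(set(binned.values())) == 3
        for bid in set(binned.values()):
            members = [c for c, b in binned.items() if b == bid]
            labels = pd.Series([truth[c] for c in members])
            assert labels.value_counts(normalize=True).iloc[0] >= 0.99

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no binnable contigs"):
            seed_bins(pd.DataFrame(np.empty((0, 512))))

    def test_single_genome_single_bin(self):
        spec = GenomeSpec("solo", length=200_000, gc_target=0.45)
        contigs = fragment_genomes(generate_genomes([spec], seed=8), seed=8)
        large = [c for c in contigs if c.length >= 2500]
        assignment = seed_bins(clr(kmer_profile(large)), min_cluster_size=5)
        bins = {b for b in assignment.assignment.values() if b != UNASSIGNED}
        assert bins == {"bin_1"}


class TestBinPC1:
    def test_centered_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((4, 3))
        cov = pd.DataFrame(X.T, columns=[f"c{i}" for i in range(4)])
        kmer = pd.DataFrame(rng.standard_normal((4, 6)), index=cov.columns)
        sig = bin_pc1("b", list(cov.columns), cov, kmer, center=True)
        C = np.cov(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        lead = V[:, np.argmax(w)]
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        assert np.allclose(np.abs(sig.pc1_coverage @ lead), 1.0, atol=1e-10)
        assert abs(sig.evf_coverage - w.max() / w.sum()) < 1e-10

    def test_equal_rows_degenerate_flagged(self):
        cov = pd.DataFrame(np.ones((5, 4)), columns=["a", "b", "c", "d"])
        kmer = pd.DataFrame(np.ones((4, 6)), index=["a", "b", "c", "d"])
        sig = bin_pc1("b", ["a", "b", "c", "d"], cov, kmer, center=True)
        assert sig.degenerate
        assert np.isnan(sig.evf_coverage)

    def test_rank_one_data_evf_near_one(self, rng):
        base = rng.standard_normal(7)
        scales = rng.uniform(1, 3, size=5)
        X = np.outer(scales, base) + 1e-6 * rng.standard_normal((5, 7))
        cov = pd.DataFrame(X.T, columns=[f"c{i}" for i in range(5)])
        kmer = pd.DataFrame(rng.standard_normal((5, 6)), index=cov.columns)
        sig = bin_pc1("b", list(cov.columns), cov, kmer)
        assert sig.evf_coverage > 0.999

    def test_unit_norm_and_sign_convention(self, rng):
        X = rng.standard_normal((6, 4))
        cov = pd.DataFrame(X.T, columns=[f"c{i}" for i in range(6)])
        kmer = pd.DataFrame(rng.standard_normal((6, 8)), index=cov.columns)
        sig = bin_pc1("b", list(cov.columns), cov, kmer)
        for v in (sig.pc1_coverage, sig.pc1_kmer):
            assert abs(np.linalg.norm(v) - 1.0) < 1e-9
            assert v[np.argmax(np.abs(v))] > 0


def _signature(bin_id, cov_vec, kmer_vec):
    cov_vec = np.asarray(cov_vec, dtype=float)
    kmer_vec = np.asarray(kmer_vec, dtype=float)
    return BinSignature(
        bin_id=bin_id,
        pc1_coverage=cov_vec / np.linalg.norm(cov_vec),
        pc1_kmer=kmer_vec / np.linalg.norm(kmer_vec),
        evf_coverage=1.0,
        evf_kmer=1.0,
    )


class TestRecruit:
    def test_perfect_candidate_scores_one(self):
        cov_vec = np.array([1.0, 2.0, 3.0, 4.0])
        kmer_vec = np.array([0.5, -0.5, 1.5, -1.5, 0.0])
        sigs = {"bin_1": _signature("bin_1", cov_vec, kmer_vec)}
        coverage = pd.DataFrame({"cand": cov_vec})
        kmer = pd.DataFrame([kmer_vec], index=["cand"])
        out = recruit(sigs, ["cand"], coverage, kmer)
        bid, score = out["cand"]
        assert bid == "bin_1"
        assert score == pytest.approx(1.0)

    def test_per_iteration_cap_500(self, rng):
        cov_vec = rng.standard_normal(6)
        kmer_vec = rng.standard_normal(8)
        sigs = {"bin_1": _signature("bin_1", cov_vec, kmer_vec)}
        ids = [f"c{i:04d}" for i in range(600)]
        coverage = pd.DataFrame(
            np.tile(cov_vec[:, None], (1, 600)), columns=ids
        )
        kmer = pd.DataFrame(np.tile(kmer_vec, (600, 1)), index=ids)
        out = recruit(sigs, ids, coverage, kmer, top_n=500)
        assert len(out) == 500

    def test_orthogonal_candidate_unassigned(self):
        sigs = {"bin_1": _signature("bin_1", [1, -1, 1, -1], [1, 0, -1, 0])}
        coverage = pd.DataFrame({"cand": [1.0, 1.0, -1.0, -1.0]})
        kmer = pd.DataFrame([[0.0, 1.0, 0.0, -1.0]], index=["cand"])
        out = recruit(sigs, ["cand"], coverage, kmer, r_min=0.5)
        assert "cand" not in out

    def test_empty_candidates_noop(self):
        sigs = {"bin_1": _signature("bin_1", [1, 2, 3], [1, 2, 3])}
        assert recruit(sigs, [], pd.DataFrame(), pd.DataFrame()) == {}


class TestRunBinning:
    def test_max_iter_zero_returns_seed_bins(self, small_mixture):
        res = run_binning(
            small_mixture["contigs"],
            small_mixture["coverage"],
            BinningConfig(min_cluster_size=5, max_iter=0),
        )
        assert not res.converged
        assert res.iteration_count == 0

    def test_deterministic_rerun(self, small_mixture):
        cfg = BinningConfig(min_cluster_size=5)
        a = run_binning(small_mixture["contigs"], small_mixture["coverage"], cfg)
        b = run_binning(small_mixture["contigs"], small_mixture["coverage"], cfg)
        assert a.assignment == b.assignment

    def test_flagged_contigs_never_assigned(self, small_mixture):
        contigs = [
            ContigRecord(c.contig_id, c.sequence, c.truth_genome, c.truth_genome == "g0")
            for c in small_mixture["contigs"]
        ]
        res = run_binning(
            contigs, small_mixture["coverage"], BinningConfig(min_cluster_size=5)
        )
        flagged = {c.contig_id for c in contigs if c.exclusion_flag}
        assert flagged.isdisjoint(res.assignment)

    def test_all_flagged_raises(self, small_mixture):
        contigs = [
            ContigRecord(c.contig_id, c.sequence, c.truth_genome, True)
            for c in small_mixture["contigs"]
        ]
        with pytest.raises(ValueError, match="no binnable contigs"):
            run_binning(contigs, small_mixture["coverage"], BinningConfig())

    def test_recovery_monotone_in_compositional_separation(self):
        """ARI over large contigs should not decrease as the GC spread
        between the three source genomes widens."""
        aris = []
        for gcs in ([0.44, 0.50, 0.56], [0.36, 0.50, 0.64], [0.30, 0.50, 0.70]):
            specs = [
                GenomeSpec(f"g{i}", length=150_000, gc_target=gc)
                for i, gc in enumerate(gcs)
            ]
            contigs = fragment_genomes(generate_genomes(specs, seed=6), seed=6)
            design = TwinDesign(n_mz_pairs=5, n_dz_pairs=5, ace=(0.5, 0.2, 0.3), seed=6)
            coverage, _, _ = simulate_coverage(contigs, design, depth=50.0)
            res = run_binning(contigs, coverage, BinningConfig(min_cluster_size=5))
            large = [c for c in contigs if c.length >= 2500]
            ari = adjusted_rand_score(
                [c.truth_genome for c in large],
                [res.assignment[c.contig_id] for c in large],
            )
            aris.append(ari)
        assert aris == sorted(aris)
        assert aris[-1] >= 0.95
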