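"""PWM log-odds, scanning, standardisation and cluster aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnkit import (MotifLibrary, ValidationError, cluster_scores,
                    pwm_log_odds, reference_standardise, reverse_complement,
                    scan_max_score, transcript_cluster_scores)
from ifnkit.motifs import scan_library, score_promoters

BASES = "ACGT"


def brute_force_scan(seq, lo):
    """Quadratic-time oracle: enumerate every window on both strands."""
    w = lo.shape[1]
    best = -np.inf
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - w + 1):
            score = sum(
                lo[BASES.index(b), j] if b in BASES else 0.0
                for j, b in enumerate(s[i:i + w]))
            best = max(best, score)
    return best


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class TestLogOdds:
    def test_uniform_column_scores_zero(self):
        lo = pwm_log_odds(np.array([[1.0], [1.0], [1.0], [1.0]]),
                          pseudocount=0.123)
        assert np.allclose(lo, 0.0)

    def test_pure_column_closed_form(self):
        lo = pwm_log_odds(np.array([[4.0], [0.0], [0.0], [0.0]]),
                          pseudocount=0.0)
        assert lo[0, 0] == pytest.approx(2.0)  # log2((4/4)/0.25)

    def test_hand_oracle_column(self):
        # counts (3,1,0,0), pseudocount 0.25: colsum 5; probabilities
        # (3.25, 1.25, 0.25, 0.25)/5 = (0.65, 0.25, 0.05, 0.05)
        lo = pwm_log_odds(np.array([[3.0], [1.0], [0.0], [0.0]]),
                          pseudocount=0.25)
        expected = np.log2(np.array([0.65, 0.25, 0.05, 0.05]) / 0.25)
        assert np.allclose(lo[:, 0], expected)

    def test_zero_column_without_pseudocount_is_an_error(self):
        with pytest.raises(ValidationError):
            pwm_log_odds(np.zeros((4, 2)), pseudocount=0.0)


class TestScan:
    def test_no_hit_on_either_strand(self):
        lo = np.array([[2.0], [0.0], [0.0], [0.0]])  # width-1, favours A
        score, _, _ = scan_max_score("CCCC", lo)  # revcomp GGGG: still no A
        assert score == 0.0

    def test_all_zero_matrix_scores_zero(self):
        assert scan_max_score("ACGTACGT", np.zeros((4, 3)))[0] == 0.0

    def test_short_sequence_is_an_error(self):
        with pytest.raises(ValidationError):
            scan_max_score("AC", np.zeros((4, 3)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 60)
            counts = rng.integers(0, 10, size=(4, 6)).astype(float) + 0.5
            lo = pwm_log_odds(counts)
            assert scan_max_score(seq, lo)[0] == \
                pytest.approx(brute_force_scan(seq, lo))

    def test_n_bases_contribute_zero(self):
        lo = pwm_log_odds(np.full((4, 3), 1.0))
        assert scan_max_score("NNNNN", lo)[0] == 0.0

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_strand_symmetry(self, seq):
        lo = pwm_log_odds(np.arange(12, dtype=float).reshape(4, 3) + 1)
        assert scan_max_score(seq, lo)[0] == \
            pytest.approx(scan_max_score(reverse_complement(seq), lo)[0])

    def test_planting_consensus_never_decreases_score(self, rng):
        counts = np.array([[9, 1, 1], [1, 9, 1], [1, 1, 9], [1, 1, 1]],
                          dtype=float)
        lo = pwm_log_odds(counts)
        consensus = "".join(BASES[i] for i in np.argmax(counts, axis=0))
        for _ in range(10):
            seq = random_seq(rng, 30)
            before = scan_max_score(seq, lo)[0]
            pos = int(rng.integers(0, len(seq) - 3 + 1))
            planted = seq[:pos] + consensus + seq[pos + 3:]
            assert scan_max_score(planted, lo)[0] >= before - 1e-12


class TestStandardise:
    def test_reference_arithmetic(self):
        raw = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = reference_standardise(raw, ["a", "b", "c"])
        assert z.loc["c", "m"] == pytest.approx(1.0)
        assert z.loc["b", "m"] == pytest.approx(0.0)

    def test_reference_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.normal(size=(30, 4)),
                           index=[f"p{i}" for i in range(30)],
                           columns=list("wxyz"))
        ref = [f"p{i}" for i in range(0, 30, 2)]
        z = reference_standardise(raw, ref)
        assert np.allclose(z.loc[ref].mean(), 0.0, atol=1e-9)
        assert np.allclose(z.loc[ref].std(ddof=1), 1.0, atol=1e-9)

    def test_zero_variance_names_the_pwm(self):
        raw = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]},
                           index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="flat"):
            reference_standardise(raw, ["a", "b", "c"])

    def test_missing_reference_id_is_an_error(self):
        raw = pd.DataFrame({"m": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            reference_standardise(raw, ["a", "zzz"])


class TestClusterScores:
    def test_singleton_cluster_is_identity(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame({"m": rng.normal(size=20)},
                           index=[f"p{i}" for i in range(20)])
        ref = list(raw.index)
        z = reference_standardise(raw, ref)
        cz = cluster_scores(z, {"c": ["m"]}, ref)
        assert np.allclose(cz["c"], z["m"])

    def test_two_member_cluster_hand_oracle(self):
        # 3 promoters, 2 PWMs; computed by hand:
        # raw z per column: a,b,c -> (-1, 0, 1) for both PWMs,
        # sums (-2, 0, 2), mean 0, sd 2 -> final (-1, 0, 1).
        raw = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [10.0, 20.0, 30.0]},
                           index=["a", "b", "c"])
        ref = ["a", "b", "c"]
        z = reference_standardise(raw, ref)
        cz = cluster_scores(z, {"c": ["m1", "m2"]}, ref)
        assert np.allclose(cz["c"], [-1.0, 0.0, 1.0])

    def test_reference_contract_after_aggregation(self, small_sim):
        from ifnkit.pipeline import reference_promoter_ids
        ref = reference_promoter_ids(small_sim.promoters, small_sim.transcripts)
        table = score_promoters(small_sim.promoter_sequences,
                                small_sim.library, ref)
        assert np.allclose(table.cluster_z.loc[ref].mean(), 0.0, atol=1e-9)
        assert np.allclose(table.cluster_z.loc[ref].std(ddof=1), 1.0,
                           atol=1e-9)

    def test_empty_cluster_is_an_error(self):
        raw = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = reference_standardise(raw, ["a", "b", "c"])
        with pytest.raises(ValidationError):
            cluster_scores(z, {"c": []}, ["a", "b", "c"])


class TestTranscriptScores:
    def test_max_over_promoters(self):
        cz = pd.DataFrame({"c": [-0.5, 2.3, 1.0]}, index=["p1", "p2", "p3"])
        tx = transcript_cluster_scores(cz, {"t1": ["p1", "p2"], "t2": ["p3"]})
        assert tx.loc["t1", "c"] == pytest.approx(2.3)
        assert tx.loc["t2", "c"] == pytest.approx(1.0)

    def test_matches_enumerated_toy(self, rng):
        cz = pd.DataFrame(rng.normal(size=(6, 2)), columns=["c1", "c2"],
                          index=[f"p{i}" for i in range(6)])
        mapping = {"t1": ["p0", "p3", "p5"], "t2": ["p1"], "t3": ["p2", "p4"]}
        tx = transcript_cluster_scores(cz, mapping)
        for tid, pids in mapping.items():
            for c in ("c1", "c2"):
                assert tx.loc[tid, c] == pytest.approx(
                    max(cz.loc[p, c] for p in pids))

    def test_transcript_without_promoter_is_an_error(self):
        cz = pd.DataFrame({"c": [1.0]}, index=["p1"])
        with pytest.raises(ValidationError):
            transcript_cluster_scores(cz, {"t1": []})


def test_full_scoring_matches_independent_reimplementation(small_sim):
    """Dual-route check on a small promoter subset: the pipeline's scores
    versus a direct quadratic-time recomputation."""
    from ifnkit.pipeline import reference_promoter_ids

    ref = reference_promoter_ids(small_sim.promoters, small_sim.transcripts)
    seqs = dict(list(small_sim.promoter_sequences.items())[:10])
    lib = small_sim.library
    sub_ref = [r for r in ref if r in seqs]
    if len(sub_ref) < 2:
        sub_ref = list(seqs)[:5]
    table = score_promoters(seqs, lib, sub_ref)

    # independent path: brute-force scan + plain numpy standardisation
    raw = {}
    for pid, counts in lib.pwms.items():
        lo = pwm_log_odds(counts)
        raw[pid] = np.array([brute_force_scan(s, lo) for s in seqs.values()])
    ids = list(seqs)
    ref_idx = [ids.index(r) for r in sub_ref]
    z = {}
    for pid, vals in raw.items():
        mu = vals[ref_idx].mean()
        sd = vals[ref_idx].std(ddof=1)
        z[pid] = (vals - mu) / sd
    for cid, members in lib.clusters.items():
        s = np.sum([z[m] for m in members], axis=0)
        mu, sd = s[ref_idx].mean(), s[ref_idx].std(ddof=1)
        expected = (s - mu) / sd
        assert np.allclose(table.cluster_z[cid].to_numpy(), expected)
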