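import numpy as np
import pytest

from introcap._seq import decode, mutate_substitutions
from introcap.efficacy import assign_nearest_reference, locus_align, probe_hits
from oracles import nw_score, sliding_window_hits


@pytest.fixture(scope="module")
def target_and_probes():
    """20 kb target plus 100 probes copied from it at varying divergence."""
    rng = np.random.default_rng(77)
    target = rng.integers(0, 4, size=20_000, dtype=np.uint8)
    probes = {}
    for i in range(100):
        s = int(rng.integers(0, 20_000 - 120))
        seq = target[s : s + 120].copy()
        d = float(rng.choice([0.0, 0.02, 0.05]))
        probes[f"p{i:03d}"] = mutate_substitutions(seq, d, rng)
    return target, probes


class TestProbeHits:
    def test_probes_against_their_source(self, target_and_probes):
        target, _ = target_and_probes
        rng = np.random.default_rng(5)
        exact = {
            f"e{i}": target[s : s + 120]
            for i, s in enumerate(rng.integers(0, 19_880, size=20))
        }
        summary, _ = probe_hits(exact, target)
        assert summary.n_probes_with_hit == summary.n_probes == 20
        assert summary.mean_best_identity == pytest.approx(100.0)

    def test_strict_identity_excludes_single_mismatch(self):
        rng = np.random.default_rng(6)
        target = rng.integers(0, 4, size=5_000, dtype=np.uint8)
        probe = target[1000:1120].copy()
        probe[60] = (probe[60] + 1) % 4
        summary, _ = probe_hits({"p": probe}, target, min_identity=1.0)
        assert summary.n_probes_with_hit == 0

    def test_reverse_strand_hits_found(self):
        rng = np.random.default_rng(7)
        target = rng.integers(0, 4, size=5_000, dtype=np.uint8)
        probe = (3 - target[2000:2120][::-1]).astype(np.uint8)
        summary, table = probe_hits({"p": probe}, target)
        assert summary.n_probes_with_hit == 1
        assert (table["strand"] == "-").any()
        assert 2000 in set(table["target_start"])

    def test_matches_sliding_window_oracle(self, target_and_probes):
        """Hit set identical to an exhaustive all-offsets scan
        (20 kb target, 100 probes)."""
        target, probes = target_and_probes
        _, table = probe_hits(probes, target, min_identity=0.80, min_cov=0.80)
        got = {
            (pid, strand, int(s))
            for pid, strand, s in zip(
                table["probe_id"], table["strand"], table["target_start"]
            )
        }
        expect = set()
        for pid, seq in probes.items():
            for strand, s in sliding_window_hits(seq, target, 0.80, 0.80):
                expect.add((pid, strand, s))
        assert got == expect

    def test_duplication_converts_single_to_multi_hit(self):
        rng = np.random.default_rng(8)
        target = rng.integers(0, 4, size=4_000, dtype=np.uint8)
        probes = {f"p{i}": target[s : s + 120] for i, s in enumerate((100, 500, 900))}
        base, _ = probe_hits(probes, target)
        dup = np.concatenate([target, target[:1200]])  # duplicate probe region
        dupped, _ = probe_hits(probes, dup)
        assert dupped.n_probes_with_hit == base.n_probes_with_hit
        assert dupped.n_single_hit_probes < base.n_single_hit_probes
        assert dupped.n_hits > base.n_hits

    def test_hit_counts_decay_with_divergence(self, target_and_probes):
        # capture-efficacy pattern: probes find fewer and worse hits as the
        # target diverges from their source
        target, _ = target_and_probes
        rng = np.random.default_rng(9)
        probes = {
            f"x{i}": target[s : s + 120]
            for i, s in enumerate(rng.integers(0, 19_880, size=60))
        }
        with_hit, identity = [], []
        for i, d in enumerate([0.0, 0.015, 0.06, 0.12]):
            diverged = mutate_substitutions(target, d, np.random.default_rng(40 + i))
            summary, _ = probe_hits(probes, diverged)
            with_hit.append(summary.n_probes_with_hit)
            identity.append(summary.mean_best_identity)
        assert with_hit == sorted(with_hit, reverse=True)
        assert identity == sorted(identity, reverse=True)

    def test_oversized_word_rejected(self):
        with pytest.raises(ValueError):
            probe_hits({"p": np.zeros(10, dtype=np.uint8)}, np.zeros(100, dtype=np.uint8), word_size=11)


class TestLocusAlign:
    def test_identical_sequences(self):
        aln = locus_align("ACGTACGT", "ACGTACGT")
        assert aln.score == 8
        assert aln.indels == []
        assert aln.percent_identity == 100.0

    def test_three_base_insertion_detected_at_offset(self):
        aln = locus_align("AAACCC", "AAATTTCCC")
        assert len(aln.indels) == 1
        ev = aln.indels[0]
        assert (ev.ref_pos, ev.length, ev.kind, ev.sequence) == (3, 3, "insertion", "TTT")

    def test_seven_base_insertion_detected_at_offset(self):
        ref = "ACGTACGTACGTACGTACGT"
        query = ref[:10] + "TTTTTTT" + ref[10:]
        aln = locus_align(ref, query)
        assert [(e.ref_pos, e.length, e.kind) for e in aln.indels] == [(10, 7, "insertion")]

    def test_deletion_reported_in_reference_frame(self):
        aln = locus_align("AAATTTCCC", "AAACCC")
        assert [(e.ref_pos, e.length, e.kind) for e in aln.indels] == [(3, 3, "deletion")]

    def test_empty_sequence_is_all_gaps(self):
        aln = locus_align("", "ACG")
        assert aln.score == 3 * -2
        assert aln.aligned_ref == "---"

    def test_gap_removal_recovers_inputs(self, rng):
        for _ in range(10):
            a = decode(rng.integers(0, 4, size=40, dtype=np.uint8))
            b = decode(rng.integers(0, 4, size=35, dtype=np.uint8))
            aln = locus_align(a, b)
            assert aln.aligned_ref.replace("-", "") == a
            assert aln.aligned_query.replace("-", "") == b

    def test_scores_match_independent_dp_oracle(self, rng):
        # 50 random 60-mer pairs vs a plain-Python DP
        for _ in range(50):
            a = decode(rng.integers(0, 4, size=60, dtype=np.uint8))
            b = decode(rng.integers(0, 4, size=60, dtype=np.uint8))
            assert locus_align(a, b).score == nw_score(a, b)


class TestAssignNearestReference:
    def test_exact_match_wins(self):
        rng = np.random.default_rng(10)
        c1 = rng.integers(0, 4, size=300, dtype=np.uint8)
        c2 = rng.integers(0, 4, size=300, dtype=np.uint8)
        table, verdict = assign_nearest_reference(c1, {"one": c1, "two": c2})
        assert verdict == "one"
        assert table.loc[table["candidate"] == "one", "percent_identity"].iloc[0] == 100.0

    def test_equidistant_query_is_ambiguous(self):
        _, verdict = assign_nearest_reference("ACGT", {"a": "ACGG", "b": "ACGC"})
        assert verdict == "AMBIGUOUS"

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError):
            assign_nearest_reference("ACGT", {"a": "ACGT"})

    def test_near_mutant_assigned_to_its_source(self):
        # queries at 1% divergence from candidate 2 pick candidate 2
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            c1 = rng.integers(0, 4, size=400, dtype=np.uint8)
            c2 = rng.integers(0, 4, size=400, dtype=np.uint8)
            query = mutate_substitutions(c2, 0.01, rng)
            _, verdict = assign_nearest_reference(query, {"c1": c1, "c2": c2})
            wins += verdict == "c2"
        assert wins >= 19
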