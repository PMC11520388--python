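import json
import math
import random

import numpy as np
import pytest

from conftest import brute_force_ric
from vdjbias.ric import (
    CONSENSUS_HEPTAMER,
    CONSENSUS_NONAMER,
    PositionGrouping,
    RICError,
    RSSSequence,
    classify_rss,
    default_grouping,
    model_from_dict,
    model_to_dict,
    read_rss_fasta,
    ric_score,
    train_ric,
    write_rss_fasta,
)

NT = "ACGT"


def _random_seq(rng, length):
    return "".join(rng.choice(NT) for _ in range(length))


def _rss(seq, gene="g"):
    spacer = len(seq) - 16
    side = "V3" if spacer == 23 else "J5"
    return RSSSequence(gene=gene, side=side, spacer_len=spacer, seq=seq)


class TestGrouping:
    @pytest.mark.parametrize(
        "kind,n_groups,length",
        [("RIC23", 18, 39), ("RIC12", 13, 28)],
    )
    def test_partition_exactly_covers_positions(self, kind, n_groups, length):
        g = default_grouping(kind)
        assert len(g.groups) == n_groups
        flat = [p for grp in g.groups for p in grp]
        assert len(flat) == len(set(flat)) == length
        assert set(flat) == set(range(1, length + 1))

    def test_non_partition_rejected(self):
        with pytest.raises(RICError):
            PositionGrouping("RIC12", ((1, 2), (2, 3)))


class TestRSSSequence:
    def test_length_must_match_spacer(self):
        with pytest.raises(RICError, match="length"):
            RSSSequence("g", "V3", 23, "ACGT")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(RICError, match="non-ACGT"):
            RSSSequence("g", "J5", 12, "N" * 28)

    def test_heptamer_nonamer_slices(self):
        seq = CONSENSUS_HEPTAMER + "A" * 23 + CONSENSUS_NONAMER
        s = RSSSequence("g", "V3", 23, seq)
        assert s.heptamer == CONSENSUS_HEPTAMER
        assert s.nonamer == CONSENSUS_NONAMER


class TestTraining:
    def test_identical_sequences_give_certainty(self):
        rng = random.Random(0)
        seq = _random_seq(rng, 39)
        model = train_ric([_rss(seq)] * 10, pseudocount=0.0)
        assert ric_score(model, _rss(seq)).value == pytest.approx(0.0, abs=1e-12)

    def test_empirical_frequency_single_position(self):
        rng = random.Random(1)
        base = _random_seq(rng, 39)
        a = "A" + base[1:]
        c = "C" + base[1:]
        model = train_ric([_rss(a), _rss(c)], pseudocount=0.0)
        g1 = model.grouping.groups.index((1,))
        assert model.tables[g1]["A"] == pytest.approx(0.5)
        assert model.tables[g1]["C"] == pytest.approx(0.5)

    def test_laplace_pseudocount_arity_one(self):
        # one sequence, pseudocount 1: P(observed) = 2/5, P(other) = 1/5
        seq = _rss("A" * 39)
        model = train_ric([seq], pseudocount=1.0)
        g1 = model.grouping.groups.index((1,))
        assert model.tables[g1]["A"] == pytest.approx(2 / 5)
        assert model.group_probability(g1, "G") == pytest.approx(1 / 5)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(RICError):
            train_ric([_rss("A" * 39), _rss("A" * 28)])

    def test_empty_training_rejected(self):
        with pytest.raises(RICError, match="empty"):
            train_ric([])


class TestScoring:
    def test_brute_force_oracle_small_model(self):
        rng = random.Random(2)
        seqs = [_random_seq(rng, 39) for _ in range(3)]
        model = train_ric([_rss(s) for s in seqs], pseudocount=0.5)
        query = _random_seq(rng, 39)
        expected = brute_force_ric(seqs, model.grouping.groups, 0.5, query)
        assert ric_score(model, _rss(query)).value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("length", [28, 39])
    def test_oracle_equivalence_randomized(self, length):
        # 200 random (training set <= 20, query) pairs per RSS kind
        rng = random.Random(1234 + length)
        for _ in range(200):
            n = rng.randint(1, 20)
            pc = rng.choice([0.0, 0.1, 0.5, 1.0, 2.0])
            seqs = [_random_seq(rng, length) for _ in range(n)]
            query = rng.choice(seqs) if rng.random() < 0.3 else _random_seq(rng, length)
            model = train_ric([_rss(s) for s in seqs], pseudocount=pc)
            got = ric_score(model, _rss(query))
            want = brute_force_ric(seqs, model.grouping.groups, pc, query)
            if math.isinf(want):
                assert not got.finite
            else:
                assert got.value == pytest.approx(want, abs=1e-12)

    def test_scores_negative_and_finite_with_pseudocount(self):
        rng = random.Random(3)
        model = train_ric([_rss(_random_seq(rng, 28)) for _ in range(5)], pseudocount=1.0)
        s = ric_score(model, _rss(_random_seq(rng, 28)))
        assert s.finite and s.value < 0

    def test_group_order_permutation_invariance(self):
        rng = random.Random(4)
        seqs = [_random_seq(rng, 28) for _ in range(6)]
        query = _random_seq(rng, 28)
        g = default_grouping("RIC12")
        shuffled = list(g.groups)
        rng.shuffle(shuffled)
        m1 = train_ric([_rss(s) for s in seqs], grouping=g, pseudocount=1.0)
        m2 = train_ric(
            [_rss(s) for s in seqs],
            grouping=PositionGrouping("RIC12", tuple(shuffled)),
            pseudocount=1.0,
        )
        assert ric_score(m1, query).value == pytest.approx(
            ric_score(m2, query).value, abs=1e-12
        )

    def test_unseen_sequence_score_increases_with_pseudocount(self):
        train_seq = _rss("A" * 39)
        query = "C" * 39
        scores = []
        for pc in (0.01, 0.1, 0.5, 1.0, 5.0):
            model = train_ric([train_seq], pseudocount=pc)
            scores.append(ric_score(model, query).value)
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_zero_probability_flagged_distinctly(self):
        model = train_ric([_rss("A" * 39)], pseudocount=0.0)
        got = ric_score(model, "C" * 39)
        assert not got.finite and got.value == -math.inf

    def test_length_mismatch_rejected(self):
        model = train_ric([_rss("A" * 39)])
        with pytest.raises(RICError, match="length"):
            ric_score(model, "A" * 28)

    def test_consensus_dominates_mutated_variants(self):
        # model trained on consensus-with-noise: the exact consensus scores
        # at least as well as the average mutated variant
        rng = np.random.default_rng(5)
        consensus = CONSENSUS_HEPTAMER + "".join(
            rng.choice(list(NT), size=23)
        ) + CONSENSUS_NONAMER

        def mutate(seq, rate):
            out = list(seq)
            for i in range(len(out)):
                if rng.random() < rate:
                    out[i] = rng.choice([b for b in NT if b != out[i]])
            return "".join(out)

        training = [_rss(mutate(consensus, 0.1)) for _ in range(50)]
        model = train_ric(training, pseudocount=1.0)
        consensus_score = ric_score(model, consensus).value
        variant_scores = [
            ric_score(model, mutate(consensus, 0.1)).value for _ in range(1000)
        ]
        assert consensus_score >= np.mean(variant_scores)


class TestClassification:
    @pytest.mark.parametrize(
        "score,label",
        [(-50.42, "very_low"), (-43.05, "normal"), (-45.0, "normal"), (-45.0001, "very_low")],
    )
    def test_threshold_is_strict(self, score, label):
        assert classify_rss(score) == label

    def test_non_finite_rejected(self):
        with pytest.raises(RICError):
            classify_rss(float("-inf"))


class TestInterchange:
    def test_fasta_round_trip(self, tmp_path):
        rng = random.Random(6)
        seqs = [
            RSSSequence("TRBV1", "V3", 23, _random_seq(rng, 39)),
            RSSSequence("TRBJ1-1", "J5", 12, _random_seq(rng, 28)),
        ]
        path = tmp_path / "rss.fasta"
        write_rss_fasta(seqs, path)
        back = read_rss_fasta(path)
        assert back == seqs

    def test_model_json_round_trip_preserves_scores(self, tmp_path):
        rng = random.Random(7)
        seqs = [_rss(_random_seq(rng, 28)) for _ in range(8)]
        model = train_ric(seqs, pseudocount=1.0)
        back = model_from_dict(json.loads(json.dumps(model_to_dict(model))))
        q = _random_seq(rng, 28)
        assert ric_score(back, q).value == pytest.approx(
            ric_score(model, q).value, abs=1e-15
        )
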