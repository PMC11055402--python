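"""Tokenizer trainers and inference, checked against brute-force oracles."""

import itertools
import json
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqtok import corpus as cm
from seqtok import tokenizers as tk


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_pair_counts(sequences):
    """Adjacent character-pair counts with multiplicity (training oracle)."""
    counts = Counter()
    for s in sequences:
        for a, b in zip(s, s[1:]):
            counts[(a, b)] += 1
    return counts


def enumerate_segmentations(s):
    """All 2^(L-1) ways to split s into contiguous pieces."""
    if not s:
        yield []
        return
    L = len(s)
    for mask in range(1 << (L - 1)):
        parts, start = [], 0
        for i in range(1, L):
            if mask & (1 << (i - 1)):
                parts.append(s[start:i])
                start = i
        parts.append(s[start:])
        yield parts


def best_enumerated_logscore(s, log_probs):
    best = -math.inf
    for parts in enumerate_segmentations(s):
        if all(p in log_probs for p in parts):
            best = max(best, sum(log_probs[p] for p in parts))
    return best


def unigram_model(probs):
    """A unigram TokenizerModel over DNA with the given token probabilities.

    Alphabet characters absent from ``probs`` receive a negligible floor so
    the vocabulary stays closed; probabilities are renormalized.
    """
    full = dict(probs)
    for c in "ACGT":
        full.setdefault(c, 1e-15)
    z = sum(full.values())
    log_probs = {t: math.log(p / z) for t, p in full.items()}
    tokens = list(tk.SPECIAL_TOKENS) + sorted(full)
    vocab = tk.Vocabulary(tokens=tokens, target_size=len(tokens),
                          log_probs=log_probs)
    return tk.TokenizerModel(method="unigram", alphabet=cm.DNA, vocabulary=vocab)


# ---------------------------------------------------------------------------
# BPE
# ---------------------------------------------------------------------------


class TestTrainBPE:
    def test_first_merge_is_most_frequent_pair(self):
        # AC=5, CA=2, CG=1 by brute-force counting
        seqs = ["ACAC", "ACAC", "ACG"]
        counts = brute_pair_counts(seqs)
        assert counts[("A", "C")] == 5
        model = tk.train_bpe(cm.from_sequences(seqs, cm.DNA), 7)
        assert (model.merges[0].left, model.merges[0].right) == ("A", "C")
        assert model.merges[0].result == "AC"

    def test_homopolymer_merges_overlapping_pair(self):
        # "AAAA" has pair (A,A) three times; first merge is AA
        model = tk.train_bpe(cm.from_sequences(["AAAA"], cm.DNA), 7)
        assert model.merges[0].result == "AA"
        assert tk.tokenize(model, "AAAA").tokens == ["AA", "AA"]

    def test_base_vocab_size_yields_character_tokenization(self):
        model = tk.train_bpe(cm.from_sequences(["ACGT"], cm.DNA), 6)
        assert model.merges == []
        assert tk.tokenize(model, "ACGT").tokens == ["A", "C", "G", "T"]

    def test_vocab_size_below_base_is_an_error(self):
        with pytest.raises(tk.TokenizerError):
            tk.train_bpe(cm.from_sequences(["ACGT"], cm.DNA), 5)

    def test_stops_when_no_pair_repeats(self):
        model = tk.train_bpe(cm.from_sequences(["ACGT"], cm.DNA), 100)
        # every adjacent pair occurs once only; nothing is adoptable
        assert model.merges == []

    def test_monotone_token_counts_under_nested_merges(self, dna_corpus):
        model = tk.train_bpe(dna_corpus, 14)
        seqs = dna_corpus.sequences()
        prev = None
        for size in range(6, 15):
            sub = tk.truncate_merges(model, size)
            counts = [len(tk.tokenize(sub, s).tokens) for s in seqs]
            if prev is not None:
                assert all(c <= p for c, p in zip(counts, prev))
            prev = counts


# ---------------------------------------------------------------------------
# WordPiece
# ---------------------------------------------------------------------------


class TestTrainWordPiece:
    def test_score_formula(self):
        assert tk.pair_score(tk.PairStat("A", "C", f12=5, f1=5, f2=5)) == 0.2
        assert tk.pair_score(tk.PairStat("C", "G", f12=1, f1=5, f2=1)) == 0.2
        assert tk.pair_score(tk.PairStat("X", "Y", f12=0, f1=3, f2=3)) == 0.0
        with pytest.raises(tk.TokenizerError):
            tk.pair_score(tk.PairStat("X", "Y", f12=0, f1=0, f2=3))

    def test_first_merge_maximizes_score(self):
        # chars A=5, C=5, G=1; score(A,C)=5/25, score(C,A)=2/25; (C,G)
        # occurs once and is not adoptable, so (A,C) wins outright
        model = tk.train_wordpiece(cm.from_sequences(["ACAC", "ACAC", "ACG"], cm.DNA), 7)
        assert model.merges[0].result == "AC"

    def test_tie_breaks_by_larger_f12(self):
        # score(AC) = 4/(4*4) = 0.25 with f12=4; score(GT) = 2/(2*4) = 0.25
        # with f12=2 (T appears twice more as singletons) -> AC adopted
        seqs = ["ACACACAC", "GT", "GT", "T", "T"]
        model = tk.train_wordpiece(cm.from_sequences(seqs, cm.DNA), 7)
        assert model.merges[0].result == "AC"

    def test_tie_breaks_lexicographically_last(self):
        # AC and GT both: f12=2, parts each freq 2 -> equal score and f12
        model = tk.train_wordpiece(cm.from_sequences(["ACAC", "GTGT"], cm.DNA), 7)
        assert model.merges[0].result == "AC"

    def test_base_vocab_size_yields_zero_merges(self):
        model = tk.train_wordpiece(cm.from_sequences(["ACAC"], cm.DNA), 6)
        assert model.merges == []

    def test_wordpiece_vs_brute_force_on_small_corpora(self):
        # adopted first pair must maximize f12/(f1*f2) among pairs with
        # f12 >= 2, for several tiny corpora
        rng = np.random.default_rng(5)
        for _ in range(10):
            seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(4, 9)))
                    for _ in range(rng.integers(2, 6))]
            counts = brute_pair_counts(seqs)
            chars = Counter("".join(seqs))
            cands = {p: c / (chars[p[0]] * chars[p[1]])
                     for p, c in counts.items() if c >= 2}
            model = tk.train_wordpiece(cm.from_sequences(seqs, cm.DNA), 7)
            if not cands:
                assert model.merges == []
                continue
            best_score = max(cands.values())
            got = (model.merges[0].left, model.merges[0].right)
            assert math.isclose(cands[got], best_score)


# ---------------------------------------------------------------------------
# Unigram
# ---------------------------------------------------------------------------


class TestTrainUnigram:
    def test_small_corpus_probabilities_beat_character_split(self):
        # final vocabulary {A,C,G,T,AC}+specials on corpus ["AC"]
        c = cm.from_sequences(["AC"], cm.DNA)
        model = tk.train_unigram(c, 7)
        lp = model.vocabulary.log_probs
        assert "AC" in lp and lp["AC"] > -math.inf
        # loss equals the best of the enumerated segmentations
        loss = tk.unigram_loss(model, c)
        assert math.isclose(loss, -best_enumerated_logscore("AC", lp), rel_tol=1e-9)

    def test_base_size_reduces_to_character_frequencies(self):
        c = cm.from_sequences(["ACGT", "AAAA"], cm.DNA)
        model = tk.train_unigram(c, 6)
        lp = model.vocabulary.log_probs
        assert set(lp) == set("ACGT")
        # closed form: p(c) = count(c) / total characters
        counts = Counter("ACGTAAAA")
        for ch, n in counts.items():
            assert math.isclose(lp[ch], math.log(n / 8), abs_tol=1e-9)
        expected_loss = -sum(math.log(counts[ch] / 8) for ch in "ACGTAAAA")
        assert math.isclose(tk.unigram_loss(model, c), expected_loss, rel_tol=1e-9)

    def test_shared_kmer_survives_pruning(self):
        # every sequence carries "GTC"; removing it costs more than any
        # other 3-mer (verified against brute-force loss recomputation)
        rng = np.random.default_rng(3)
        seqs = []
        for _ in range(12):
            bg = "".join(rng.choice(list("ACGT"), size=10))
            seqs.append(bg[:5] + "GTC" + bg[5:])
        c = cm.from_sequences(seqs, cm.DNA)
        model = tk.train_unigram(c, 10)
        assert "GTC" in model.vocabulary
        lp = model.vocabulary.log_probs
        # brute-force: corpus loss without GTC is no smaller
        without = {t: p for t, p in lp.items() if t != "GTC"}
        loss_with = sum(-best_enumerated_logscore(s[:12], lp) for s in seqs)
        loss_without = sum(-best_enumerated_logscore(s[:12], without) for s in seqs)
        assert loss_without >= loss_with

    def test_probabilities_sum_to_one(self, dna_corpus):
        model = tk.train_unigram(dna_corpus, 10)
        total = sum(math.exp(p) for p in model.vocabulary.log_probs.values())
        assert abs(total - 1.0) < 1e-9

    def test_loss_examples(self):
        model = unigram_model({"A": 0.5, "C": 0.3, "AC": 0.2})
        c = cm.from_sequences(["AC"], cm.DNA)
        assert math.isclose(tk.unigram_loss(model, c), -math.log(0.2), rel_tol=1e-6)
        certain = unigram_model({"A": 1.0})
        assert tk.unigram_loss(certain, cm.from_sequences(["A"], cm.DNA)) < 1e-9

    def test_loss_additivity_under_corpus_doubling(self):
        model = unigram_model({"A": 0.4, "C": 0.3, "AC": 0.3})
        c1 = cm.from_sequences(["ACAC", "CA"], cm.DNA)
        c2 = cm.from_sequences(["ACAC", "CA", "ACAC", "CA"], cm.DNA)
        assert math.isclose(tk.unigram_loss(model, c2),
                            2 * tk.unigram_loss(model, c1), rel_tol=1e-12)


class TestViterbi:
    def test_prefers_whole_token_when_more_probable(self):
        model = unigram_model({"A": 0.5, "C": 0.3, "AC": 0.2})
        # g([AC]) = 0.2 > g([A,C]) = 0.15
        assert tk.tokenize(model, "AC").tokens == ["AC"]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        pieces = ["A", "C", "G", "T", "AC", "CA", "ACG", "GT", "TT", "CGT"]
        for trial in range(20):
            w = rng.dirichlet(np.ones(len(pieces)))
            probs = dict(zip(pieces, w))
            model = unigram_model(probs)
            lp = model.vocabulary.log_probs
            for L in (1, 4, 7, 10, 12):
                s = "".join(rng.choice(list("ACGT"), size=L))
                seg = tk.tokenize(model, s)
                assert math.isclose(
                    seg.log_score, best_enumerated_logscore(s, lp), rel_tol=1e-9
                ), (s, seg.tokens)


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------


class TestKmer:
    @pytest.mark.parametrize("k,n_kmers", [(1, 0), (2, 16), (3, 64)])
    def test_dictionary_sizes(self, k, n_kmers):
        model = tk.build_kmer(cm.DNA, k)
        base = 2 + 4  # specials + characters
        assert len(model.vocabulary) == base + n_kmers

    def test_k1_tokenizes_to_characters(self):
        model = tk.build_kmer(cm.DNA, 1)
        assert len(tk.tokenize(model, "AAGTCAAGGATC").tokens) == 12

    def test_k2_halves_even_sequences(self):
        model = tk.build_kmer(cm.DNA, 2)
        assert tk.tokenize(model, "AAGTCA").tokens == ["AA", "GT", "CA"]

    def test_tail_falls_back_to_characters(self):
        model = tk.build_kmer(cm.DNA, 3)
        assert tk.tokenize(model, "AAGTC").tokens == ["AAG", "T", "C"]

    def test_cap(self):
        with pytest.raises(tk.TokenizerError):
            tk.build_kmer(cm.PROTEIN, 9, cap=10**6)


# ---------------------------------------------------------------------------
# Inference, detokenize, serialization
# ---------------------------------------------------------------------------


def fig1_style_model():
    """Greedy tokenizer with the dictionary {AAG, TC, GA} plus characters."""
    tokens = list(tk.SPECIAL_TOKENS) + ["A", "C", "G", "T", "AAG", "GA", "TC"]
    vocab = tk.Vocabulary(tokens=tokens, target_size=len(tokens))
    return tk.TokenizerModel(method="wordpiece", alphabet=cm.DNA, vocabulary=vocab)


class TestTokenize:
    def test_custom_dictionary_gives_five_tokens(self):
        seg = tk.tokenize(fig1_style_model(), "AAGTCAAGGATC")
        assert seg.tokens == ["AAG", "TC", "AAG", "GA", "TC"]

    def test_unknown_marker_becomes_unk(self):
        seg = tk.tokenize(fig1_style_model(), "AAG?TC")
        assert seg.tokens == ["AAG", tk.UNK_TOKEN, "TC"]

    def test_uncleaned_input_rejected(self):
        with pytest.raises(tk.TokenizerError):
            tk.tokenize(fig1_style_model(), "AAGX")

    def test_token_count_bounded_by_length(self, dna_corpus):
        bpe = tk.train_bpe(dna_corpus, 12)
        for s in dna_corpus.sequences():
            assert len(tk.tokenize(bpe, s).tokens) <= len(s)


class TestDetokenize:
    def test_fig1_roundtrip(self):
        seg = tk.Segmentation(tokens=["AAG", "TC", "AAG", "GA", "TC"])
        assert tk.detokenize(seg) == "AAGTCAAGGATC"

    def test_empty(self):
        assert tk.detokenize(tk.Segmentation(tokens=[])) == ""

    def test_unk_raises_unless_best_effort(self):
        seg = tk.Segmentation(tokens=["AAG", tk.UNK_TOKEN])
        with pytest.raises(tk.LossyDecodeError):
            tk.detokenize(seg)
        assert tk.detokenize(seg, best_effort=True) == "AAG?"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_property_all_methods(self, s):
        corpus = cm.from_sequences(["AAGTCAAGGATC", "AAGAAGTC", s], cm.DNA)
        models = [
            tk.train_bpe(corpus, 10),
            tk.train_wordpiece(corpus, 10),
            tk.train_unigram(corpus, 8),
            tk.build_kmer(cm.DNA, 1),
            tk.build_kmer(cm.DNA, 2),
            tk.build_kmer(cm.DNA, 3),
        ]
        for m in models:
            assert tk.detokenize(tk.tokenize(m, s)) == s


class TestSerialization:
    @pytest.mark.parametrize("method", ["bpe", "wordpiece", "unigram", "kmer"])
    def test_save_load_resave_byte_identical(self, tmp_path, dna_corpus, method):
        if method == "kmer":
            model = tk.build_kmer(cm.DNA, 2)
        else:
            model = tk.train(dna_corpus, method, vocab_size=10)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        model.save(p1)
        tk.TokenizerModel.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("method", ["bpe", "wordpiece", "unigram"])
    def test_trainer_determinism(self, tmp_path, dna_corpus, method):
        a = tk.train(dna_corpus, method, vocab_size=10)
        b = tk.train(dna_corpus, method, vocab_size=10)
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        a.save(pa)
        b.save(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_vocab_text_export(self, tmp_path, dna_corpus):
        model = tk.train_unigram(dna_corpus, 8)
        p = tmp_path / "vocab.tsv"
        model.save_vocab_text(p)
        lines = p.read_text().splitlines()
        assert len(lines) == len(model.vocabulary)
        assert lines[0].split("\t")[0] == tk.PAD_TOKEN


class TestVocabularyClosure:
    @pytest.mark.parametrize("method", ["bpe", "wordpiece", "unigram"])
    def test_all_alphabet_characters_present(self, dna_corpus, method):
        model = tk.train(dna_corpus, method, vocab_size=10)
        for c in "ACGT":
            assert c in model.vocabulary
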