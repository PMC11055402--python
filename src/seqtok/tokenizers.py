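"""Subword tokenizers for boundary-free biological sequences.

Five tokenizers are provided:

* **BPE** — iteratively merges the most frequent adjacent token pair.
* **WordPiece** — same loop, but the adopted pair maximizes
  ``f12 / (f1 * f2)``, the pair frequency over the product of the parts'
  frequencies.
* **Unigram** — a probabilistic model ``p(t)`` per token; sequences are
  segmented by the maximum-product (Viterbi) split and the vocabulary is
  trained by EM plus iterative pruning of a large seed vocabulary under the
  corpus negative log-likelihood.
* **k-mer baselines** — fixed dictionaries of all length-``k`` strings;
  ``k=1`` is the trivial single-character ("words") tokenizer and ``k=2``
  the all-pairs ("pairs") tokenizer.

Because biological sequences have no word boundaries, every sequence is one
uninterrupted token stream: merges and matches may span the entire sequence.
All trainers are deterministic — identical corpus and parameters yield a
byte-identical serialized model.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Alphabet, Corpus, DNA, PROTEIN, UNKNOWN_CHAR

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
SPECIAL_TOKENS = (PAD_TOKEN, UNK_TOKEN)

#: Dictionary sizes used throughout evaluation sweeps.
DICTIONARY_SIZE_PRESETS = (100, 200, 400, 800, 1600, 3200)

#: Longest substring considered when seeding a Unigram vocabulary.
UNIGRAM_MAX_PIECE_LEN = 8

#: Refuse to enumerate k-mer vocabularies above this size.
KMER_VOCAB_CAP = 1 << 20


class TokenizerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class Vocabulary:
    """An ordered token inventory with reserved PAD and UNK ids.

    ``tokens[0]`` is always PAD and ``tokens[1]`` UNK; every single alphabet
    character is present so no cleaned in-alphabet sequence is
    untokenizable.  For Unigram models ``log_probs`` maps each non-special
    token to ``log p(t)``; the probabilities sum to one.
    """

    tokens: list[str]
    target_size: int
    log_probs: dict[str, float] | None = None
    token_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tokens[:2] != list(SPECIAL_TOKENS):
            raise ValueError("vocabulary must start with PAD, UNK")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if self.log_probs is not None:
            total = sum(math.exp(lp) for lp in self.log_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"unigram probabilities sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)


@dataclass(frozen=True)
class MergeRule:
    """One adopted pair merge; ``rank`` is the 0-based adoption order."""

    left: str
    right: str
    rank: int

    @property
    def result(self) -> str:
        return self.left + self.right


@dataclass(frozen=True)
class PairStat:
    """Frequencies of an adjacent token pair under the current segmentation."""

    left: str
    right: str
    f12: int
    f1: int
    f2: int

    @property
    def score(self) -> float:
        return pair_score(self)


def pair_score(stat: PairStat) -> float:
    """WordPiece adoption score ``f12 / (f1 * f2)``.

    A pair that never occurs scores 0 and is never a merge candidate;
    zero part-frequencies are an error (a pair cannot occur without its
    parts).
    """
    if stat.f1 <= 0 or stat.f2 <= 0:
        raise TokenizerError("pair_score requires f1 >= 1 and f2 >= 1")
    if stat.f12 == 0:
        return 0.0
    return stat.f12 / (stat.f1 * stat.f2)


@dataclass
class Segmentation:
    """One sequence split into vocabulary tokens.

    ``log_score`` is set only for Unigram models, where it equals
    ``sum_j log p(t_j)`` of the Viterbi-optimal split.
    """

    tokens: list[str]
    log_score: float | None = None

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TokenizerModel:
    """A trained tokenizer: method tag, vocabulary and method-specific state."""

    method: str  # "bpe" | "wordpiece" | "unigram" | "kmer"
    alphabet: Alphabet
    vocabulary: Vocabulary
    merges: list[MergeRule] = field(default_factory=list)
    k: int | None = None
    trainer_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("bpe", "wordpiece", "unigram", "kmer"):
            raise ValueError(f"unknown tokenizer method {self.method!r}")
        if self.method == "kmer" and self.k is None:
            raise ValueError("kmer models require k")
        if self.method in ("unigram", "kmer") and self.merges:
            raise ValueError(f"{self.method} models carry no merge rules")
        if self.method == "unigram" and self.vocabulary.log_probs is None:
            raise ValueError("unigram models require token log-probabilities")
        for c in self.alphabet.characters:
            if c not in self.vocabulary:
                raise ValueError(f"vocabulary is missing alphabet character {c!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {
            "format": "seqtok-model-v1",
            "method": self.method,
            "alphabet": {"kind": self.alphabet.kind,
                         "characters": "".join(self.alphabet.characters)},
            "special_tokens": list(SPECIAL_TOKENS),
            "tokens": list(self.vocabulary.tokens),
            "target_size": self.vocabulary.target_size,
            "trainer_params": dict(sorted(self.trainer_params.items())),
        }
        if self.vocabulary.log_probs is not None:
            doc["log_probs"] = {t: self.vocabulary.log_probs[t]
                                for t in self.vocabulary.tokens
                                if t in self.vocabulary.log_probs}
        if self.method in ("bpe", "wordpiece"):
            doc["merges"] = [[m.left, m.right] for m in self.merges]
        if self.method == "kmer":
            doc["k"] = self.k
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "TokenizerModel":
        alph = doc["alphabet"]
        alphabet = Alphabet(alph["kind"], tuple(alph["characters"]))
        vocab = Vocabulary(
            tokens=list(doc["tokens"]),
            target_size=doc["target_size"],
            log_probs=dict(doc["log_probs"]) if "log_probs" in doc else None,
        )
        merges = [MergeRule(l, r, i) for i, (l, r) in enumerate(doc.get("merges", []))]
        return cls(
            method=doc["method"],
            alphabet=alphabet,
            vocabulary=vocab,
            merges=merges,
            k=doc.get("k"),
            trainer_params=doc.get("trainer_params", {}),
        )

    def save(self, path: str | Path) -> None:
        """Write the model as a single JSON document (stable key order)."""
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenizerModel":
        with open(path, "rt") as fh:
            return cls.from_dict(json.load(fh))

    def save_vocab_text(self, path: str | Path) -> None:
        """Plain-text vocabulary export: token, then rank or log-probability."""
        lp = self.vocabulary.log_probs
        with open(path, "wt") as fh:
            for i, t in enumerate(self.vocabulary.tokens):
                aux = f"{lp[t]:.10g}" if lp is not None and t in lp else str(i)
                fh.write(f"{t}\t{aux}\n")


# ---------------------------------------------------------------------------
# Shared trainer machinery
# ---------------------------------------------------------------------------


def _base_tokens(alphabet: Alphabet) -> list[str]:
    return list(SPECIAL_TOKENS) + sorted(alphabet.characters)


def _training_words(corpus: Corpus) -> list[list[str]]:
    """Each sequence is one uninterrupted token stream of characters.

    Unknown-marker characters split a sequence into independent streams:
    they never participate in merges or probability estimates.
    """
    words: list[list[str]] = []
    for rec in corpus.records:
        for segment in rec.sequence.split(UNKNOWN_CHAR):
            if segment:
                words.append(list(segment))
    return words


def _require_alphabet(corpus: Corpus) -> Alphabet:
    if corpus.alphabet is not None:
        return corpus.alphabet
    from .corpus import detect_alphabet

    return detect_alphabet(corpus)


def _check_vocab_size(vocab_size: int, alphabet: Alphabet) -> None:
    base = len(alphabet.characters) + len(SPECIAL_TOKENS)
    if vocab_size < base:
        raise TokenizerError(
            f"vocab_size {vocab_size} is below the base vocabulary size {base}"
        )


def _count_pairs(words: list[list[str]]) -> tuple[Counter, Counter, dict]:
    """Adjacent-pair counts (with multiplicity), token counts, pair→word index."""
    pair_counts: Counter = Counter()
    token_counts: Counter = Counter()
    index: dict[tuple[str, str], set[int]] = defaultdict(set)
    for wi, word in enumerate(words):
        token_counts.update(word)
        for a, b in zip(word, word[1:]):
            pair_counts[(a, b)] += 1
            index[(a, b)].add(wi)
    return pair_counts, token_counts, index


def _apply_merge_to_word(word: list[str], left: str, right: str) -> list[str]:
    """Left-to-right greedy replacement of the adjacent pair."""
    out: list[str] = []
    i = 0
    n = len(word)
    while i < n:
        if i + 1 < n and word[i] == left and word[i + 1] == right:
            out.append(left + right)
            i += 2
        else:
            out.append(word[i])
            i += 1
    return out


def _train_merge_based(
    corpus: Corpus, vocab_size: int, method: str
) -> TokenizerModel:
    alphabet = _require_alphabet(corpus)
    _check_vocab_size(vocab_size, alphabet)
    words = _training_words(corpus)
    pair_counts, token_counts, index = _count_pairs(words)

    tokens = _base_tokens(alphabet)
    merges: list[MergeRule] = []

    def bpe_key(pair: tuple[str, str]):
        # most frequent first; ties: lexicographically smaller result
        return (-pair_counts[pair], pair[0] + pair[1])

    def wp_key(pair: tuple[str, str]):
        f12 = pair_counts[pair]
        score = f12 / (token_counts[pair[0]] * token_counts[pair[1]])
        # highest score, then larger f12, then lexicographically smaller result
        return (-score, -f12, pair[0] + pair[1])

    key = bpe_key if method == "bpe" else wp_key

    while len(tokens) < vocab_size:
        candidates = [p for p, c in pair_counts.items() if c >= 2]
        if not candidates:
            break
        left, right = min(candidates, key=key)
        new_token = left + right
        merges.append(MergeRule(left, right, len(merges)))
        tokens.append(new_token)
        # Re-segment only the words containing the pair, recounting their
        # pair and token contributions.
        affected = sorted(index.pop((left, right), ()))
        for wi in affected:
            word = words[wi]
            token_counts.subtract(word)
            for a, b in zip(word, word[1:]):
                pair_counts[(a, b)] -= 1
                if pair_counts[(a, b)] <= 0:
                    del pair_counts[(a, b)]
                s = index.get((a, b))
                if s is not None:
                    s.discard(wi)
            new_word = _apply_merge_to_word(word, left, right)
            words[wi] = new_word
            token_counts.update(new_word)
            for a, b in zip(new_word, new_word[1:]):
                pair_counts[(a, b)] += 1
                index[(a, b)].add(wi)

    vocab = Vocabulary(tokens=tokens, target_size=vocab_size)
    return TokenizerModel(
        method=method,
        alphabet=alphabet,
        vocabulary=vocab,
        merges=merges,
        trainer_params={"vocab_size": vocab_size},
    )


def train_bpe(corpus: Corpus, vocab_size: int) -> TokenizerModel:
    """Train a byte-pair-encoding tokenizer.

    Starting from the alphabet characters, the most frequent adjacent token
    pair across the whole corpus is repeatedly adopted as a merge rule and
    the corpus re-segmented, until the vocabulary reaches ``vocab_size`` or
    no pair occurs at least twice.  Ties are broken toward the
    lexicographically smaller merged token for determinism.
    """
    return _train_merge_based(corpus, vocab_size, "bpe")


def train_wordpiece(corpus: Corpus, vocab_size: int) -> TokenizerModel:
    """Train a WordPiece tokenizer.

    Identical loop to :func:`train_bpe`, but the adopted pair maximizes
    ``f12 / (f1 * f2)`` computed from current-segmentation frequencies;
    ties are broken by larger ``f12``, then lexicographically.
    """
    return _train_merge_based(corpus, vocab_size, "wordpiece")


def truncate_merges(model: TokenizerModel, vocab_size: int) -> TokenizerModel:
    """Restrict a merge-based model to its first merges (nested vocabulary).

    A BPE/WordPiece model trained to a large vocabulary contains every
    smaller model of the same family as a prefix of its merge list; this
    returns that smaller model without retraining.
    """
    if model.method not in ("bpe", "wordpiece"):
        raise TokenizerError("truncate_merges applies to merge-based models only")
    base = len(SPECIAL_TOKENS) + len(model.alphabet.characters)
    _check_vocab_size(vocab_size, model.alphabet)
    n_merges = min(vocab_size - base, len(model.merges))
    merges = model.merges[:n_merges]
    tokens = model.vocabulary.tokens[: base + n_merges]
    return TokenizerModel(
        method=model.method,
        alphabet=model.alphabet,
        vocabulary=Vocabulary(tokens=list(tokens), target_size=vocab_size),
        merges=list(merges),
        trainer_params={**model.trainer_params, "vocab_size": vocab_size},
    )


# ---------------------------------------------------------------------------
# Unigram
# ---------------------------------------------------------------------------


def _seed_vocabulary(
    words: list[list[str]], alphabet: Alphabet, n_seed: int
) -> Counter:
    """Most frequent substrings up to :data:`UNIGRAM_MAX_PIECE_LEN`."""
    counts: Counter = Counter()
    for word in words:
        s = "".join(word)
        L = len(s)
        for i in range(L):
            for j in range(i + 1, min(i + UNIGRAM_MAX_PIECE_LEN, L) + 1):
                counts[s[i:j]] += 1
    # always keep the single characters
    chars = sorted(alphabet.characters)
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
    )
    kept: dict[str, int] = {c: counts.get(c, 1) for c in chars}
    for tok, cnt in ranked:
        if len(kept) >= n_seed:
            break
        kept.setdefault(tok, cnt)
    return Counter(kept)


def _viterbi(
    s: str, log_probs: dict[str, float], max_len: int = UNIGRAM_MAX_PIECE_LEN
) -> tuple[list[str], float]:
    """Maximum-probability segmentation of ``s``.

    Ties are broken toward fewer tokens, then toward the lexicographically
    smaller final token.  Assumes every character of ``s`` is in the
    vocabulary (guaranteed for cleaned in-alphabet text).
    """
    L = len(s)
    NEG = -math.inf
    best: list[float] = [NEG] * (L + 1)
    best_n: list[int] = [0] * (L + 1)
    back: list[tuple[int, str] | None] = [None] * (L + 1)
    best[0] = 0.0
    for i in range(1, L + 1):
        for j in range(max(0, i - max_len), i):
            if best[j] == NEG:
                continue
            piece = s[j:i]
            lp = log_probs.get(piece)
            if lp is None:
                continue
            cand = best[j] + lp
            cand_n = best_n[j] + 1
            if cand > best[i] or (
                cand == best[i]
                and (
                    cand_n < best_n[i]
                    or (cand_n == best_n[i] and back[i] is not None
                        and piece < back[i][1])
                )
            ):
                best[i] = cand
                best_n[i] = cand_n
                back[i] = (j, piece)
    if best[L] == NEG:
        raise TokenizerError(f"no valid segmentation for {s!r}")
    tokens: list[str] = []
    i = L
    while i > 0:
        j, piece = back[i]  # type: ignore[misc]
        tokens.append(piece)
        i = j
    tokens.reverse()
    return tokens, best[L]


def _forward_backward(
    s: str, log_probs: dict[str, float], expected: dict[str, float],
    max_len: int = UNIGRAM_MAX_PIECE_LEN,
) -> float:
    """Accumulate expected token counts for one word; returns log Z."""
    L = len(s)
    NEG = -math.inf
    # edges[j] = list of (i, piece, lp) with j < i
    edges: list[list[tuple[int, str, float]]] = [[] for _ in range(L)]
    for j in range(L):
        for i in range(j + 1, min(j + max_len, L) + 1):
            piece = s[j:i]
            lp = log_probs.get(piece)
            if lp is not None:
                edges[j].append((i, piece, lp))
    alpha = [NEG] * (L + 1)
    alpha[0] = 0.0
    for j in range(L):
        aj = alpha[j]
        if aj == NEG:
            continue
        for i, piece, lp in edges[j]:
            v = aj + lp
            ai = alpha[i]
            alpha[i] = v if ai == NEG else (
                max(ai, v) + math.log1p(math.exp(-abs(ai - v)))
            )
    logZ = alpha[L]
    if logZ == NEG:
        raise TokenizerError(f"no valid segmentation for {s!r}")
    beta = [NEG] * (L + 1)
    beta[L] = 0.0
    for j in range(L - 1, -1, -1):
        acc = NEG
        for i, piece, lp in edges[j]:
            if beta[i] == NEG:
                continue
            v = lp + beta[i]
            acc = v if acc == NEG else (
                max(acc, v) + math.log1p(math.exp(-abs(acc - v)))
            )
            if alpha[j] != NEG:
                expected[piece] = expected.get(piece, 0.0) + math.exp(
                    alpha[j] + v - logZ
                )
        beta[j] = acc
    return logZ


def _normalize(counts: dict[str, float]) -> dict[str, float]:
    total = sum(counts.values())
    log_total = math.log(total)
    logs = {t: math.log(c) - log_total for t, c in counts.items() if c > 0}
    # tokens with zero expected count keep a floor to stay segmentable
    floor = math.log(1e-12)
    for t in counts:
        if t not in logs:
            logs[t] = floor
    return _renormalize_logs(logs)


def _renormalize_logs(log_probs: dict[str, float]) -> dict[str, float]:
    m = max(log_probs.values())
    z = m + math.log(sum(math.exp(lp - m) for lp in log_probs.values()))
    return {t: lp - z for t, lp in log_probs.items()}


def train_unigram(
    corpus: Corpus,
    vocab_size: int,
    seed_multiplier: int = 10,
    shrink_fraction: float = 0.25,
    em_rounds: int = 2,
) -> TokenizerModel:
    """Train a Unigram language-model tokenizer.

    The seed vocabulary holds the ``seed_multiplier * vocab_size`` most
    frequent substrings (length <= 8) of the corpus, always including the
    single characters.  Training alternates (a) ``em_rounds`` of EM
    re-estimating ``p(t)`` from expected token counts under the full
    segmentation lattice, and (b) pruning the ``shrink_fraction`` of
    removable tokens whose removal least increases the corpus loss
    ``-sum_i log h(x_i)``, where ``h`` is the Viterbi-maximal segmentation
    probability.  Single-character tokens are never pruned and the loop
    stops when the vocabulary reaches ``vocab_size``.

    The per-token loss increase is scored by re-segmenting the token's own
    text with the remaining vocabulary, weighted by its Viterbi usage count
    — the standard fast approximation to leave-one-out loss.
    """
    alphabet = _require_alphabet(corpus)
    _check_vocab_size(vocab_size, alphabet)
    if not 0.0 < shrink_fraction < 1.0:
        raise TokenizerError("shrink_fraction must be in (0, 1)")
    words = ["".join(w) for w in _training_words(corpus)]
    n_target = vocab_size - len(SPECIAL_TOKENS)
    n_seed = max(n_target, seed_multiplier * n_target)
    seed_counts = _seed_vocabulary([list(w) for w in words], alphabet, n_seed)
    log_probs = _normalize({t: float(c) for t, c in seed_counts.items()})
    chars = set(alphabet.characters)

    while True:
        for _ in range(em_rounds):
            expected: dict[str, float] = {}
            for w in words:
                _forward_backward(w, log_probs, expected)
            for t in log_probs:
                expected.setdefault(t, 0.0)
            log_probs = _normalize(expected)
        if len(log_probs) <= n_target:
            break
        # Viterbi usage counts
        usage: Counter = Counter()
        for w in words:
            toks, _ = _viterbi(w, log_probs)
            usage.update(toks)
        removable = sorted(t for t in log_probs if t not in chars)
        deltas: list[tuple[float, str]] = []
        for t in removable:
            if usage[t] == 0:
                deltas.append((0.0, t))
                continue
            without = dict(log_probs)
            del without[t]
            try:
                _, alt = _viterbi(t, without)
            except TokenizerError:
                deltas.append((math.inf, t))
                continue
            deltas.append((usage[t] * (log_probs[t] - alt), t))
        deltas.sort()
        n_drop = max(1, int(shrink_fraction * len(removable)))
        n_drop = min(n_drop, len(log_probs) - n_target)
        for _, t in deltas[:n_drop]:
            del log_probs[t]
        log_probs = _renormalize_logs(log_probs)

    tokens = _base_tokens(alphabet) + sorted(
        t for t in log_probs if t not in chars
    )
    vocab = Vocabulary(
        tokens=tokens,
        target_size=vocab_size,
        log_probs=dict(log_probs),
    )
    return TokenizerModel(
        method="unigram",
        alphabet=alphabet,
        vocabulary=vocab,
        trainer_params={
            "vocab_size": vocab_size,
            "seed_multiplier": seed_multiplier,
            "shrink_fraction": shrink_fraction,
            "em_rounds": em_rounds,
        },
    )


# ---------------------------------------------------------------------------
# Fixed k-mer baselines
# ---------------------------------------------------------------------------


def build_kmer(alphabet: Alphabet, k: int, cap: int = KMER_VOCAB_CAP) -> TokenizerModel:
    """Fixed dictionary of all ``|alphabet|**k`` k-mers.

    ``k=1`` is the trivial single-character ("words") tokenizer; ``k=2`` the
    all-pairs tokenizer.  For ``k > 1`` the single characters are also kept
    so that a trailing fragment shorter than ``k`` remains tokenizable.
    """
    if k < 1:
        raise TokenizerError("k must be >= 1")
    n_kmers = len(alphabet.characters) ** k
    if n_kmers > cap:
        raise TokenizerError(
            f"{len(alphabet.characters)}^{k} = {n_kmers} k-mers exceeds cap {cap}"
        )
    tokens = _base_tokens(alphabet)
    if k > 1:
        from itertools import product

        tokens += ["".join(p) for p in product(sorted(alphabet.characters), repeat=k)]
    return TokenizerModel(
        method="kmer",
        alphabet=alphabet,
        vocabulary=Vocabulary(tokens=tokens, target_size=len(tokens)),
        k=k,
        trainer_params={"k": k},
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def _bpe_segment(segment: str, ranks: dict[tuple[str, str], int]) -> list[str]:
    """Replay merges in rank order (implemented as lowest-rank-first)."""
    word = list(segment)
    while len(word) > 1:
        best_rank = None
        best_pair = None
        for a, b in zip(word, word[1:]):
            r = ranks.get((a, b))
            if r is not None and (best_rank is None or r < best_rank):
                best_rank = r
                best_pair = (a, b)
        if best_pair is None:
            break
        word = _apply_merge_to_word(word, best_pair[0], best_pair[1])
    return word


def _wordpiece_segment(segment: str, vocab: Vocabulary) -> list[str]:
    """Greedy longest-prefix match; single characters guarantee progress."""
    out: list[str] = []
    i = 0
    L = len(segment)
    max_tok = max((len(t) for t in vocab.tokens), default=1)
    while i < L:
        for j in range(min(L, i + max_tok), i, -1):
            if segment[i:j] in vocab:
                out.append(segment[i:j])
                i = j
                break
        else:  # pragma: no cover - unreachable for closed vocabularies
            raise TokenizerError(f"cannot match prefix at position {i}")
    return out


def _kmer_segment(segment: str, k: int) -> list[str]:
    out = [segment[i : i + k] for i in range(0, len(segment) - len(segment) % k, k)]
    out.extend(segment[len(segment) - len(segment) % k :])
    return out


def tokenize(model: TokenizerModel, sequence: str) -> Segmentation:
    """Segment a cleaned sequence with a trained model.

    Unknown-marker characters always become UNK tokens and never
    participate in merges or matches.  The concatenation of the returned
    tokens (with UNK standing for the marker) reproduces the input exactly.
    """
    allowed = set(model.alphabet.characters)
    for c in sequence:
        if c not in allowed and c != UNKNOWN_CHAR:
            raise TokenizerError(
                f"character {c!r} is not cleaned {model.alphabet.kind} input"
            )
    if model.method == "bpe":
        ranks = {(m.left, m.right): m.rank for m in model.merges}
    tokens: list[str] = []
    log_score = 0.0 if model.method == "unigram" else None
    i = 0
    L = len(sequence)
    while i < L:
        if sequence[i] == UNKNOWN_CHAR:
            tokens.append(UNK_TOKEN)
            i += 1
            continue
        j = i
        while j < L and sequence[j] != UNKNOWN_CHAR:
            j += 1
        segment = sequence[i:j]
        if model.method == "bpe":
            tokens.extend(_bpe_segment(segment, ranks))
        elif model.method == "wordpiece":
            tokens.extend(_wordpiece_segment(segment, model.vocabulary))
        elif model.method == "unigram":
            toks, lp = _viterbi(segment, model.vocabulary.log_probs)
            tokens.extend(toks)
            log_score += lp
        else:
            tokens.extend(_kmer_segment(segment, model.k))
        i = j
    return Segmentation(tokens=tokens, log_score=log_score)


class LossyDecodeError(ValueError):
    pass


def detokenize(segmentation: Segmentation, best_effort: bool = False) -> str:
    """Concatenate tokens back into the sequence.

    UNK tokens make decoding lossy: by default this raises
    :class:`LossyDecodeError`; with ``best_effort=True`` each UNK is
    rendered as the unknown-marker character.
    """
    out = []
    for t in segmentation.tokens:
        if t == UNK_TOKEN:
            if not best_effort:
                raise LossyDecodeError("segmentation contains UNK tokens")
            out.append(UNKNOWN_CHAR)
        elif t == PAD_TOKEN:
            continue
        else:
            out.append(t)
    return "".join(out)


def unigram_loss(model: TokenizerModel, corpus: Corpus) -> float:
    """Corpus loss ``-sum_i log h(x_i)`` under a Unigram model.

    ``h(x_i)`` is the Viterbi-maximal segmentation probability of sequence
    ``i``; each corpus sequence counts once.
    """
    if model.method != "unigram":
        raise TokenizerError("unigram_loss requires a unigram model")
    total = 0.0
    for rec in corpus.records:
        seg = tokenize(model, rec.sequence)
        total -= seg.log_score
    return total


def train(
    corpus: Corpus, method: str, vocab_size: int | None = None, k: int | None = None,
    **kwargs,
) -> TokenizerModel:
    """Dispatch to the trainer for ``method`` (convenience front door)."""
    if method == "bpe":
        return train_bpe(corpus, vocab_size, **kwargs)
    if method == "wordpiece":
        return train_wordpiece(corpus, vocab_size, **kwargs)
    if method == "unigram":
        return train_unigram(corpus, vocab_size, **kwargs)
    if method == "kmer":
        return build_kmer(_require_alphabet(corpus), k or 1, **kwargs)
    raise TokenizerError(f"unknown method {method!r}")
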