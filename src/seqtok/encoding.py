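"""Fixed-length integer encoding and corpus-level compression statistics.

For transformer-style consumers every sequence must map to a vector of the
same length: token-id lists are truncated at ``max_len`` and right-padded
with the PAD id.  Compression is reported as the fold reduction in token
count relative to the character count — the quantity that trades off
against task performance when comparing tokenizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus
from .tokenizers import Segmentation, TokenizerModel, tokenize


@dataclass(frozen=True)
class EncodingConfig:
    """Fixed-length encoding parameters (typical ``max_len``: 100, 512, 1024)."""

    max_len: int
    pad_id: int = 0
    unk_id: int = 1

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass
class EncodedSequence:
    """A token-id vector of fixed length with padding/truncation bookkeeping."""

    ids: np.ndarray
    true_len: int
    truncated: bool

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)


@dataclass
class TokenizationStats:
    """Corpus-level token counts and fold reduction.

    ``mean_fold_reduction`` is the per-sequence mean of
    characters / tokens; ``total_fold_reduction`` (total characters over
    total tokens) is exposed alongside it.
    """

    mean_tokens_per_seq: float
    mean_fold_reduction: float
    total_tokens: int
    total_chars: int = 0

    @property
    def total_fold_reduction(self) -> float:
        return self.total_chars / self.total_tokens if self.total_tokens else 0.0


def encode_segmentation(
    seg: Segmentation, model: TokenizerModel, config: EncodingConfig
) -> EncodedSequence:
    ids = [model.vocabulary.id_of(t) for t in seg.tokens]
    true_len = len(ids)
    truncated = true_len > config.max_len
    ids = ids[: config.max_len]
    ids += [config.pad_id] * (config.max_len - len(ids))
    return EncodedSequence(ids=np.array(ids, dtype=np.int64),
                           true_len=true_len, truncated=truncated)


def encode_fixed(
    model: TokenizerModel, sequence: str, config: EncodingConfig
) -> EncodedSequence:
    """Tokenize, map to ids, truncate to ``max_len`` and right-pad."""
    return encode_segmentation(tokenize(model, sequence), model, config)


def corpus_stats(model: TokenizerModel, corpus: Corpus) -> TokenizationStats:
    """Tokenize every sequence (no truncation) and aggregate counts."""
    if corpus.N == 0:
        raise ValueError("corpus_stats requires a non-empty corpus")
    n_tokens = []
    n_chars = []
    for rec in corpus.records:
        seg = tokenize(model, rec.sequence)
        n_tokens.append(len(seg.tokens))
        n_chars.append(len(rec.sequence))
    n_tokens = np.array(n_tokens, dtype=float)
    n_chars = np.array(n_chars, dtype=float)
    return TokenizationStats(
        mean_tokens_per_seq=float(n_tokens.mean()),
        mean_fold_reduction=float((n_chars / n_tokens).mean()),
        total_tokens=int(n_tokens.sum()),
        total_chars=int(n_chars.sum()),
    )


def write_encoded(
    model: TokenizerModel, corpus: Corpus, config: EncodingConfig, path: str | Path
) -> None:
    """Write an encoded dataset as TSV: id, true_len, space-separated ids."""
    with open(path, "wt") as fh:
        for rec in corpus.records:
            enc = encode_fixed(model, rec.sequence, config)
            fh.write(f"{rec.id}\t{enc.true_len}\t"
                     + " ".join(map(str, enc.ids.tolist())) + "\n")


def read_encoded(path: str | Path) -> list[tuple[str, EncodedSequence]]:
    out = []
    with open(path, "rt") as fh:
        for line in fh:
            rec_id, true_len, ids = line.rstrip("\n").split("\t")
            vec = np.array([int(x) for x in ids.split()], dtype=np.int64)
            out.append(
                (rec_id,
                 EncodedSequence(ids=vec, true_len=int(true_len),
                                 truncated=int(true_len) > len(vec)))
            )
    return out
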