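"""Synthetic corpora and alignment pairs with planted structure.

Three generators cover the task families the toolkit evaluates:

* classification corpora with class-specific planted motifs and shared
  repetitive elements on an i.i.d. background — the structure that makes
  data-driven tokenizers discover multi-character tokens;
* regression corpora where the target is a linear function of the planted
  motif's occurrence count plus Gaussian noise;
* pairwise nucleotide alignments produced by simulating substitutions
  (Jukes–Cantor) and insertion/deletion events along a known history, so
  the true alignment is available by construction.  The indel simulation
  samples its parameters uniformly from configured ranges: root length
  150–300 nt, substitution distance 0.05–0.15 per site, indel rates
  0–0.05 events per substitution, and a Zipf length-distribution exponent
  A in 1.01–2.0 (truncated at a length cap).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .corpus import Alphabet, Corpus, DNA, PROTEIN, SeqRecord
from .metrics import PairwiseAlignment, validate_alignment


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Classification / regression corpora
# ---------------------------------------------------------------------------


@dataclass
class ClassTaskSpec:
    """Parameters of a planted-motif classification corpus.

    ``sequences_per_class`` gives the (train, validation, test) counts per
    class.  Each class receives ``motifs_per_class`` random motifs with
    lengths in ``motif_length_range`` planted at positions drawn from
    ``motif_position`` (``("uniform",)`` or ``("normal", mean, sd)``);
    ``repeat_elements`` shared repetitive elements are planted across all
    classes with probability ``repeat_prob`` each, emulating genomic
    repeats.
    """

    n_classes: int = 2
    sequences_per_class: tuple[int, int, int] = (180, 20, 20)
    length_range: tuple[int, int] = (80, 120)
    alphabet: Alphabet = PROTEIN
    motifs_per_class: int = 2
    motif_length_range: tuple[int, int] = (8, 12)
    motif_position: tuple = ("uniform",)
    background: Sequence[float] | None = None  # uniform when None
    repeat_elements: int = 4
    repeat_length: int = 15
    repeat_prob: float = 0.5
    #: explicit per-class motif lists; overrides random motif generation
    class_motifs: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or min(self.sequences_per_class) < 0:
            raise SynthError("counts must be positive")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if len(bg) != len(self.alphabet.characters):
                raise SynthError("background length must match alphabet size")
            if abs(bg.sum() - 1.0) > 1e-9:
                raise SynthError("background frequencies must sum to 1")
        if self.motif_length_range[1] > self.length_range[0]:
            raise SynthError("motif may not be longer than the shortest sequence")


@dataclass
class LabeledDataset:
    """Train/validation/test splits of (record, label) pairs."""

    train: list[tuple[SeqRecord, float]]
    validation: list[tuple[SeqRecord, float]]
    test: list[tuple[SeqRecord, float]]
    task: Literal["classification", "regression"]
    alphabet: Alphabet = PROTEIN
    #: generator ground truth (e.g. planted motifs per class), for checking
    metadata: dict = field(default_factory=dict)

    def split(self, name: str) -> list[tuple[SeqRecord, float]]:
        return getattr(self, name)

    def corpus(self, name: str) -> Corpus:
        return Corpus(records=[r for r, _ in self.split(name)],
                      alphabet=self.alphabet)

    def labels(self, name: str) -> np.ndarray:
        return np.array([y for _, y in self.split(name)])


def _random_string(rng: np.random.Generator, chars: str, n: int,
                   p: np.ndarray | None = None) -> str:
    return "".join(rng.choice(list(chars), size=n, p=p))


def _draw_position(rng: np.random.Generator, spec: ClassTaskSpec,
                   seq_len: int, motif_len: int) -> int:
    hi = seq_len - motif_len
    if spec.motif_position[0] == "uniform":
        return int(rng.integers(0, hi + 1))
    if spec.motif_position[0] == "normal":
        _, mean, sd = spec.motif_position
        return int(np.clip(round(rng.normal(mean, sd)), 0, hi))
    raise SynthError(f"unknown position law {spec.motif_position[0]!r}")


def _plant(seq: list[str], motif: str, pos: int) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def _free_position(
    rng: np.random.Generator, occupied: list[tuple[int, int]],
    seq_len: int, width: int, want: int | None = None, tries: int = 30,
) -> int | None:
    """A start position whose interval avoids already-planted intervals.

    Prefers ``want`` when given and free; otherwise rejection-samples, then
    scans deterministically.  Returns None when the sequence has no room,
    in which case the caller may overwrite (a disrupted element, as happens
    to real repeats).
    """

    def clashes(p: int) -> bool:
        return any(p < e and s < p + width for s, e in occupied)

    if want is not None and not clashes(want):
        return want
    hi = seq_len - width
    for _ in range(tries):
        p = int(rng.integers(0, hi + 1))
        if not clashes(p):
            return p
    for p in range(hi + 1):
        if not clashes(p):
            return p
    return None


def _gen_motifs(rng: np.random.Generator, spec: ClassTaskSpec) -> list[list[str]]:
    if spec.class_motifs is not None:
        if len(spec.class_motifs) != spec.n_classes:
            raise SynthError("class_motifs must give one motif list per class")
        return [list(m) for m in spec.class_motifs]
    chars = "".join(spec.alphabet.characters)
    seen: set[str] = set()
    per_class: list[list[str]] = []
    for _ in range(spec.n_classes):
        motifs = []
        for _ in range(spec.motifs_per_class):
            while True:
                n = int(rng.integers(spec.motif_length_range[0],
                                     spec.motif_length_range[1] + 1))
                m = _random_string(rng, chars, n)
                if m not in seen:
                    seen.add(m)
                    motifs.append(m)
                    break
        per_class.append(motifs)
    return per_class


def gen_classification_corpus(spec: ClassTaskSpec) -> LabeledDataset:
    """Generate a planted-motif classification corpus.

    Every sequence of class ``c`` carries each of that class's motifs
    (planted by overwriting the background, so lengths are preserved);
    shared repeat elements appear in all classes.  The planted motifs and
    their positions are recorded in the dataset metadata.
    """
    rng = np.random.default_rng(spec.seed)
    chars = "".join(spec.alphabet.characters)
    bg = None if spec.background is None else np.asarray(spec.background)
    motifs = _gen_motifs(rng, spec)
    if any(len(m) > spec.length_range[0] for ms in motifs for m in ms):
        raise SynthError("motif may not be longer than the shortest sequence")
    repeats = [_random_string(rng, chars, spec.repeat_length)
               for _ in range(spec.repeat_elements)]

    splits: dict[str, list[tuple[SeqRecord, float]]] = {
        "train": [], "validation": [], "test": []
    }
    positions: dict[int, list[int]] = {c: [] for c in range(spec.n_classes)}
    counter = 0
    for cls in range(spec.n_classes):
        for split_name, n in zip(("train", "validation", "test"),
                                 spec.sequences_per_class):
            for _ in range(n):
                L = int(rng.integers(spec.length_range[0],
                                     spec.length_range[1] + 1))
                seq = list(_random_string(rng, chars, L, bg))
                occupied: list[tuple[int, int]] = []
                # motifs first so every class sequence carries each one intact
                for m in motifs[cls]:
                    want = _draw_position(rng, spec, L, len(m))
                    pos = _free_position(rng, occupied, L, len(m), want=want)
                    if pos is None:
                        pos = want
                    _plant(seq, m, pos)
                    occupied.append((pos, pos + len(m)))
                    positions[cls].append(pos)
                for rep in repeats:
                    if rng.random() < spec.repeat_prob:
                        pos = _free_position(rng, occupied, L, len(rep))
                        if pos is None:
                            continue
                        _plant(seq, rep, pos)
                        occupied.append((pos, pos + len(rep)))
                rec = SeqRecord(f"c{cls}_s{counter}", "".join(seq))
                counter += 1
                splits[split_name].append((rec, float(cls)))
    return LabeledDataset(
        train=splits["train"], validation=splits["validation"],
        test=splits["test"], task="classification", alphabet=spec.alphabet,
        metadata={"motifs": motifs, "repeats": repeats,
                  "motif_positions": positions},
    )


def gen_regression_corpus(
    spec: ClassTaskSpec, effect_size: float, noise_sd: float,
    max_occurrences: int = 4,
) -> LabeledDataset:
    """Generate a regression corpus.

    The target of each sequence is ``effect_size * m + N(0, noise_sd)``
    where ``m`` is the number of planted occurrences of the task motif
    (uniform on 0..``max_occurrences``, planted at disjoint slots so the
    count is exact).
    """
    if noise_sd < 0:
        raise SynthError("noise_sd must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    chars = "".join(spec.alphabet.characters)
    bg = None if spec.background is None else np.asarray(spec.background)
    motif = _gen_motifs(rng, spec)[0][0]
    mlen = len(motif)

    splits: dict[str, list[tuple[SeqRecord, float]]] = {
        "train": [], "validation": [], "test": []
    }
    counter = 0
    for split_name, n_split in zip(("train", "validation", "test"),
                                   spec.sequences_per_class):
        n_total = n_split * spec.n_classes
        for _ in range(n_total):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            n_slots = L // mlen
            m = int(rng.integers(0, min(max_occurrences, n_slots) + 1))
            while True:  # resample a background with no chance occurrences
                seq = list(_random_string(rng, chars, L, bg))
                if motif not in "".join(seq):
                    break
            slots = rng.choice(n_slots, size=m, replace=False)
            for slot in slots:
                _plant(seq, motif, int(slot) * mlen)
            y = effect_size * m + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rec = SeqRecord(f"r_s{counter}", "".join(seq))
            counter += 1
            splits[split_name].append((rec, float(y)))
    return LabeledDataset(
        train=splits["train"], validation=splits["validation"],
        test=splits["test"], task="regression", alphabet=spec.alphabet,
        metadata={"motif": motif, "effect_size": effect_size,
                  "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Indel-simulated pairwise alignments
# ---------------------------------------------------------------------------


@dataclass
class IndelSimParams:
    """Parameter ranges for the pairwise indel simulation.

    For each simulated pair, one value per parameter is drawn uniformly
    from its range: root length, substitution distance (expected
    substitutions per site), insertion and deletion rates (events per
    substitution), and the Zipf exponent A of the indel length law for
    insertions and deletions separately.  Indel lengths follow a power law
    ``P(len = k) ∝ k^(-A)`` truncated at ``max_indel_len``.
    """

    root_length: tuple[int, int] = (150, 300)
    distance: tuple[float, float] = (0.05, 0.15)
    insertion_rate: tuple[float, float] = (0.0, 0.05)
    deletion_rate: tuple[float, float] = (0.0, 0.05)
    A_insertion: tuple[float, float] = (1.01, 2.0)
    A_deletion: tuple[float, float] = (1.01, 2.0)
    max_indel_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("root_length", "distance", "insertion_rate",
                     "deletion_rate", "A_insertion", "A_deletion"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SynthError(f"{name} range is not ordered")
        if self.insertion_rate[0] < 0 or self.deletion_rate[0] < 0:
            raise SynthError("rates must be nonnegative")


def _truncated_zipf(rng: np.random.Generator, A: float, cap: int) -> int:
    ks = np.arange(1, cap + 1, dtype=float)
    p = ks ** (-A)
    p /= p.sum()
    return int(rng.choice(cap, p=p)) + 1


def _jc_substitute(rng: np.random.Generator, root: str, distance: float) -> str:
    """Jukes–Cantor: each site differs with prob (3/4)(1 - exp(-4d/3))."""
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))
    bases = "ACGT"
    out = []
    for c in root:
        if rng.random() < p_diff:
            out.append(rng.choice([b for b in bases if b != c]))
        else:
            out.append(c)
    return "".join(out)


def gen_pairwise_alignment(
    params: IndelSimParams, rng: np.random.Generator | None = None
) -> tuple[str, str, PairwiseAlignment]:
    """Simulate one homologous pair with its true alignment.

    The root is uniform DNA of sampled length; the second sequence derives
    from it by Jukes–Cantor substitutions at the sampled distance, then
    Poisson numbers of deletion and insertion events (mean = rate *
    distance * root length) with truncated-Zipf lengths and uniform
    positions.  The emitted alignment records the event history and always
    satisfies :func:`~seqtok.metrics.validate_alignment`.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = int(rng.integers(params.root_length[0], params.root_length[1] + 1))
    d = float(rng.uniform(*params.distance))
    r_ins = float(rng.uniform(*params.insertion_rate))
    r_del = float(rng.uniform(*params.deletion_rate))
    A_ins = float(rng.uniform(*params.A_insertion))
    A_del = float(rng.uniform(*params.A_deletion))

    root = _random_string(rng, "ACGT", L)
    child = _jc_substitute(rng, root, d)
    # columns: (root char or None, child char or None)
    columns: list[tuple[str | None, str | None]] = list(zip(root, child))

    n_del = rng.poisson(r_del * d * L)
    for _ in range(n_del):
        length = _truncated_zipf(rng, A_del, params.max_indel_len)
        start = int(rng.integers(0, L))
        for i in range(start, min(start + length, L)):
            r, c = columns[i]
            columns[i] = (r, None)

    n_ins = rng.poisson(r_ins * d * L)
    for _ in range(n_ins):
        length = _truncated_zipf(rng, A_ins, params.max_indel_len)
        at = int(rng.integers(0, len(columns) + 1))
        inserted = _random_string(rng, "ACGT", length)
        columns[at:at] = [(None, c) for c in inserted]

    row1 = "".join(r if r is not None else "-" for r, _ in columns)
    row2 = "".join(c if c is not None else "-" for _, c in columns)
    src2 = row2.replace("-", "")
    aln = PairwiseAlignment(row1=row1, row2=row2, src1=root, src2=src2)
    assert validate_alignment(aln).valid
    return root, src2, aln


def gen_alignment_dataset(
    params: IndelSimParams, n: int
) -> list[tuple[str, str, PairwiseAlignment]]:
    """Simulate ``n`` pairs from one seeded stream."""
    rng = np.random.default_rng(params.seed)
    return [gen_pairwise_alignment(params, rng) for _ in range(n)]
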