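"""Attribution-based motif localization.

Consumes per-token attribution scores (e.g. integrated gradients from a
trained sequence model, or the exact gradient-times-input scores of the
bundled linear learner) and post-processes them into position histograms
and windowed motif annotations per class:

1. select tokens whose absolute attribution exceeds a threshold (0.2 by
   default);
2. histogram the character positions those tokens cover across the
   sequences of a class;
3. slide a 15-character window and emit an annotation wherever a specific
   token is selected in at least 8 of 100 sequences (pro-rated for other
   cohort sizes), with a sign: *enriched* (positive attribution supports
   membership) or *depleted* (negative attribution argues against it).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodingConfig
from .harness import ExperimentResult, _bag_features
from .synthgen import LabeledDataset
from .tokenizers import Segmentation, TokenizerModel, tokenize

ATTRIBUTION_THRESHOLD = 0.2
WINDOW_SIZE = 15
MIN_SUPPORT = 8
COHORT = 100


class InterpretationError(ValueError):
    pass


@dataclass
class AttributionTrack:
    """Per-token attribution scores for one sequence.

    ``spans`` are 0-based half-open character coordinates tiling the
    sequence in token order.
    """

    seq_id: str
    label: float
    tokens: list[str]
    scores: list[float]
    spans: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.scores) == len(self.spans)):
            raise InterpretationError("tokens, scores and spans must align")
        pos = 0
        for (s, e), t in zip(self.spans, self.tokens):
            if s != pos or e <= s:
                raise InterpretationError("spans must tile the sequence")
            pos = e


@dataclass(frozen=True)
class MotifAnnotation:
    """A token enriched or depleted at a location within a class."""

    token: str
    start: int
    support: int
    class_label: float
    sign: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if self.sign not in ("enriched", "depleted"):
            raise InterpretationError(f"bad sign {self.sign!r}")


def track_from_segmentation(
    seq_id: str, label: float, seg: Segmentation, scores: Sequence[float]
) -> AttributionTrack:
    spans = []
    pos = 0
    for t in seg.tokens:
        # UNK tokens cover exactly one marker character
        width = 1 if t == "<unk>" else len(t)
        spans.append((pos, pos + width))
        pos += width
    return AttributionTrack(seq_id=seq_id, label=label, tokens=list(seg.tokens),
                            scores=[float(s) for s in scores], spans=spans)


def linear_attribution_tracks(
    result: ExperimentResult, dataset: LabeledDataset, split: str = "test",
    target_class: int | None = None,
) -> list[AttributionTrack]:
    """Exact gradient-times-input attributions for the bag-linear learner.

    For a linear model the attribution of a token occurrence toward class
    ``c`` is that class's coefficient for the token (one-vs-rest margin for
    binary models).  Scores are normalized per sequence to a maximum
    absolute value of 1 so the selection threshold is scale-free.
    """
    if "coef" not in result.learner_state:
        raise InterpretationError("result carries no linear coefficients")
    coef = np.asarray(result.learner_state["coef"])
    classes = result.learner_state.get("classes")
    model = result.tokenizer
    tracks = []
    for rec, label in dataset.split(split):
        cls = int(label) if target_class is None else target_class
        if coef.ndim == 1:
            w = coef
        elif classes is not None and len(classes) == 2:
            # sklearn stores one row: the margin of classes[1]
            w = coef[0] if cls == int(classes[1]) else -coef[0]
        else:
            row = int(np.where(classes == cls)[0][0]) if classes is not None else cls
            w = coef[row]
        seg = tokenize(model, rec.sequence)
        raw = [float(w[model.vocabulary.id_of(t)]) for t in seg.tokens]
        m = max((abs(s) for s in raw), default=0.0)
        scores = [s / m if m > 0 else 0.0 for s in raw]
        tracks.append(track_from_segmentation(rec.id, label, seg, scores))
    return tracks


def high_attribution_positions(
    track: AttributionTrack, threshold: float = ATTRIBUTION_THRESHOLD
) -> list[int]:
    """Indices of tokens with ``|score| > threshold`` (sign preserved in track)."""
    if threshold < 0:
        raise InterpretationError("threshold must be nonnegative")
    return [i for i, s in enumerate(track.scores) if abs(s) > threshold]


def position_histogram(
    tracks: Sequence[AttributionTrack], threshold: float = ATTRIBUTION_THRESHOLD
) -> np.ndarray:
    """Per-position counts of sequences with a selected token covering it."""
    if not tracks:
        raise InterpretationError("no tracks given")
    if len({t.label for t in tracks}) > 1:
        raise InterpretationError("tracks must share a class")
    max_len = max(t.spans[-1][1] for t in tracks if t.spans)
    counts = np.zeros(max_len, dtype=int)
    for track in tracks:
        covered: set[int] = set()
        for i in high_attribution_positions(track, threshold):
            s, e = track.spans[i]
            covered.update(range(s, e))
        for p in covered:
            counts[p] += 1
    return counts


def motif_window_labels(
    tracks: Sequence[AttributionTrack],
    window: int = WINDOW_SIZE,
    min_support: int = MIN_SUPPORT,
    cohort: int = COHORT,
    threshold: float = ATTRIBUTION_THRESHOLD,
) -> list[MotifAnnotation]:
    """Windowed motif annotations for one class.

    A window of ``window`` characters slides along the sequences (stride
    1); for every (window position, token, sign) where the selected token
    starts inside the window in at least ``ceil(min_support *
    len(tracks) / cohort)`` distinct sequences, the window qualifies.
    Runs of overlapping qualifying windows for the same token and sign are
    merged into one annotation anchored at the modal occurrence start.
    """
    if window < 1:
        raise InterpretationError("window must be >= 1")
    if not tracks:
        raise InterpretationError("no tracks given")
    labels = {t.label for t in tracks}
    if len(labels) > 1:
        raise InterpretationError("tracks must share a class")
    class_label = labels.pop()
    support_needed = max(1, math.ceil(min_support * len(tracks) / cohort))

    # (token, sign) -> list of (start, seq_id)
    occurrences: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    for track in tracks:
        for i in high_attribution_positions(track, threshold):
            sign = "enriched" if track.scores[i] > 0 else "depleted"
            occurrences[(track.tokens[i], sign)].append(
                (track.spans[i][0], track.seq_id)
            )

    annotations: list[MotifAnnotation] = []
    for (token, sign) in sorted(occurrences):
        occs = occurrences[(token, sign)]
        max_start = max(s for s, _ in occs)
        qualifying: list[int] = []
        for w in range(0, max_start + 1):
            seqs = {sid for s, sid in occs if w <= s < w + window}
            if len(seqs) >= support_needed:
                qualifying.append(w)
        # merge runs of consecutive qualifying window positions
        run: list[int] = []
        for w in qualifying + [None]:  # type: ignore[list-item]
            if run and (w is None or w > run[-1] + 1):
                lo, hi = run[0], run[-1] + window
                in_run = [(s, sid) for s, sid in occs if lo <= s < hi]
                starts = Counter(s for s, _ in in_run)
                modal_start = min(
                    starts, key=lambda s: (-starts[s], s)
                )
                support = len({sid for _, sid in in_run})
                annotations.append(MotifAnnotation(
                    token=token, start=modal_start, support=support,
                    class_label=class_label, sign=sign,
                ))
                run = []
            if w is not None:
                run.append(w)
    return annotations


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_tracks(tracks: Sequence[AttributionTrack], path: str | Path) -> None:
    """TSV export: sequence id, class, token, start, end, score."""
    with open(path, "wt") as fh:
        for t in tracks:
            for tok, (s, e), sc in zip(t.tokens, t.spans, t.scores):
                fh.write(f"{t.seq_id}\t{t.label:g}\t{tok}\t{s}\t{e}\t{sc:.6g}\n")


def read_tracks(path: str | Path) -> list[AttributionTrack]:
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path, "rt") as fh:
        for line in fh:
            sid, label, tok, s, e, sc = line.rstrip("\n").split("\t")
            if sid not in rows:
                rows[sid] = {"label": float(label), "tokens": [],
                             "scores": [], "spans": []}
                order.append(sid)
            rows[sid]["tokens"].append(tok)
            rows[sid]["scores"].append(float(sc))
            rows[sid]["spans"].append((int(s), int(e)))
    return [
        AttributionTrack(seq_id=sid, label=rows[sid]["label"],
                         tokens=rows[sid]["tokens"], scores=rows[sid]["scores"],
                         spans=rows[sid]["spans"])
        for sid in order
    ]


def write_annotations(
    annotations: Sequence[MotifAnnotation], set_label: str, path: str | Path
) -> None:
    """BED-like TSV: set label, start, end, token, support, sign."""
    with open(path, "wt") as fh:
        for a in annotations:
            fh.write(f"{set_label}\t{a.start}\t{a.start + len(a.token)}\t"
                     f"{a.token}\t{a.support}\t{a.sign}\n")
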