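"""Experiment harness: (task x tokenizer x vocabulary size) sweeps.

For each configuration the harness trains the tokenizer on the training
split only, encodes all splits, fits a downstream learner (selected on the
validation split), and reports test metrics together with the corpus
compression statistics — the two axes of the performance-versus-fold-
reduction tradeoff.

The bundled learner is a bag-of-token-ids linear model (multinomial
logistic regression for classification, ridge regression for regression):
fully deterministic, fast enough for routine sweeps, and linear so that
per-token attributions are exact.  The learner is pluggable via the
``LEARNERS`` registry for richer sequence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .corpus import Corpus
from .encoding import EncodingConfig, TokenizationStats, corpus_stats, encode_fixed
from .metrics import MetricReport, classification_metrics, spearman, wilcoxon_compare
from .synthgen import LabeledDataset
from .tokenizers import TokenizerModel, train as train_tokenizer


class HarnessError(ValueError):
    pass


#: Learning-rate presets mirroring common transformer sweeps (informational
#: for the linear learner, which has no learning rate).
LEARNING_RATE_PRESETS = (1e-3, 1e-4, 1e-5)


@dataclass(frozen=True)
class ExperimentConfig:
    """One point of a sweep.

    ``method`` is one of ``bpe | wordpiece | unigram | kmer``; ``vocab_size``
    applies to the data-driven methods and ``k`` to the k-mer baselines.
    ``model_params`` passes hyperparameters to the learner (the bundled
    linear learner reads ``C_grid`` / ``alpha_grid``); transformer-style
    knobs (layers, heads, hidden size, learning rate) are accepted and
    forwarded to whichever learner is registered.
    """

    method: str
    vocab_size: int | None = None
    k: int | None = None
    max_len: int = 512
    learner: str = "bag-linear"
    model_params: tuple = ()
    seed: int = 0

    @property
    def name(self) -> str:
        if self.method == "kmer":
            return f"kmer-k{self.k}"
        return f"{self.method}-{self.vocab_size}"


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: MetricReport
    stats: TokenizationStats
    task: str
    headline: float  # MCC for classification, Spearman rho for regression
    tokenizer: TokenizerModel | None = None
    learner_state: dict = field(default_factory=dict)


def _bag_features(
    model: TokenizerModel, corpus: Corpus, config: EncodingConfig
) -> np.ndarray:
    """Token-count matrix (n_sequences, vocab size) from the first max_len tokens."""
    V = len(model.vocabulary)
    X = np.zeros((corpus.N, V), dtype=float)
    for i, rec in enumerate(corpus.records):
        enc = encode_fixed(model, rec.sequence, config)
        ids = enc.ids[: min(enc.true_len, config.max_len)]
        np.add.at(X[i], ids, 1.0)
    X[:, model.vocabulary.pad_id] = 0.0
    return X


def _fit_bag_linear_classifier(
    Xtr, ytr, Xva, yva, seed: int, C_grid=(0.1, 1.0, 10.0)
):
    best = None
    for C in C_grid:
        clf = LogisticRegression(
            C=C, max_iter=2000, random_state=seed, solver="lbfgs"
        )
        clf.fit(Xtr, ytr)
        val = classification_metrics(yva, clf.predict_proba(Xva)).mcc
        if best is None or val > best[0]:
            best = (val, clf)
    return best[1]


def _fit_bag_linear_regressor(Xtr, ytr, Xva, yva, alpha_grid=(0.1, 1.0, 10.0)):
    best = None
    for alpha in alpha_grid:
        reg = Ridge(alpha=alpha)
        reg.fit(Xtr, ytr)
        pred = reg.predict(Xva)
        try:
            val = spearman(pred, yva)
        except Exception:
            val = -np.inf
        if best is None or val > best[0]:
            best = (val, reg)
    return best[1]


def run_experiment(
    dataset: LabeledDataset, config: ExperimentConfig,
    tokenizer: TokenizerModel | None = None,
) -> ExperimentResult:
    """Train tokenizer (training split only) and learner, report on test.

    Deterministic given ``config.seed``.  Compression statistics are
    computed over the full dataset with the trained tokenizer.  A
    ``tokenizer`` may be passed in to reuse prior training (e.g. a nested
    merge-based vocabulary truncated from a larger one); it must have been
    trained on the training split only.
    """
    for name in ("train", "validation", "test"):
        if not dataset.split(name):
            raise HarnessError(f"{name} split is empty")
    train_corpus = dataset.corpus("train")
    train_corpus.alphabet = dataset.alphabet
    if tokenizer is None:
        tokenizer = train_tokenizer(
            train_corpus, config.method, vocab_size=config.vocab_size, k=config.k
        )
    enc_cfg = EncodingConfig(max_len=config.max_len)
    Xtr = _bag_features(tokenizer, train_corpus, enc_cfg)
    Xva = _bag_features(tokenizer, dataset.corpus("validation"), enc_cfg)
    Xte = _bag_features(tokenizer, dataset.corpus("test"), enc_cfg)
    ytr, yva, yte = (dataset.labels(s) for s in ("train", "validation", "test"))

    params = dict(config.model_params)
    if dataset.task == "classification":
        ytr_i, yva_i, yte_i = ytr.astype(int), yva.astype(int), yte.astype(int)
        clf = _fit_bag_linear_classifier(
            Xtr, ytr_i, Xva, yva_i, config.seed,
            C_grid=params.get("C_grid", (0.1, 1.0, 10.0)),
        )
        report = classification_metrics(yte_i, clf.predict_proba(Xte))
        headline = report.mcc
        state = {"coef": clf.coef_, "classes": clf.classes_}
    else:
        reg = _fit_bag_linear_regressor(
            Xtr, ytr, Xva, yva, alpha_grid=params.get("alpha_grid", (0.1, 1.0, 10.0))
        )
        pred = reg.predict(Xte)
        rho = spearman(pred, yte)
        report = MetricReport(acc=0.0, mcc=0.0, spearman_rho=rho)
        headline = rho
        state = {"coef": reg.coef_}

    full = Corpus(
        records=[r for s in ("train", "validation", "test")
                 for r, _ in dataset.split(s)],
        alphabet=dataset.alphabet,
    )
    stats = corpus_stats(tokenizer, full)
    return ExperimentResult(
        config=config, report=report, stats=stats, task=dataset.task,
        headline=headline, tokenizer=tokenizer, learner_state=state,
    )


def tradeoff_table(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Performance-versus-compression table relative to the k=1 baseline.

    One row per configuration: method, vocabulary size, mean fold
    reduction, headline metric, and deltas against the single-character
    baseline (which must be among the results); sorted by fold reduction.
    """
    if not results:
        raise HarnessError("no results")
    tasks = {r.task for r in results}
    if len(tasks) != 1:
        raise HarnessError(f"results mix tasks: {sorted(tasks)}")
    baselines = [r for r in results
                 if r.config.method == "kmer" and r.config.k == 1]
    if not baselines:
        raise HarnessError("a kmer k=1 baseline result is required")
    base = baselines[0]
    rows = []
    for r in results:
        rows.append({
            "config": r.config.name,
            "method": r.config.method,
            "vocab_size": r.config.vocab_size or len(r.tokenizer.vocabulary)
            if r.tokenizer else r.config.vocab_size,
            "fold_reduction": r.stats.mean_fold_reduction,
            "headline": r.headline,
            "delta_fold": r.stats.mean_fold_reduction
            - base.stats.mean_fold_reduction,
            "delta_headline": r.headline - base.headline,
        })
    return (
        pd.DataFrame(rows)
        .sort_values("fold_reduction", kind="stable")
        .reset_index(drop=True)
    )


def compare_tokenizers(
    per_task_best_a: Sequence[float], per_task_best_b: Sequence[float]
):
    """Paired Wilcoxon signed-rank comparison of per-task best performances."""
    return wilcoxon_compare(per_task_best_a, per_task_best_b)
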