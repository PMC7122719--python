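"""Corpus preprocessing, inverse document frequency, and word embeddings.

The scoring pipeline treats questionnaire items as tiny documents embedded
in a semantic vector space learned from a large text corpus.  This module
provides the three ingredients: a deterministic text normalizer, IDF weights
computed over a document collection, and skip-gram/negative-sampling word
embeddings (trainable at desk scale, or read from the standard word2vec
plain-text format).
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "EmbeddingTable",
    "IdfTable",
    "TrainingConfig",
    "preprocess_text",
    "compute_idf",
    "train_embeddings",
    "read_embeddings",
    "write_embeddings",
]

_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)

# Minimal deterministic suffix stripper, off by default.  A replacement for
# heavyweight lexical normalizers: lowercase + punctuation strip is the
# documented default; stemming is opt-in for sensitivity analyses.
_SUFFIXES = ("ing", "edly", "ed", "es", "s")


@dataclass(frozen=True)
class Document:
    """One input record of the corpus (one article, abstract or paragraph)."""

    id: str
    text: str


def preprocess_text(raw: str, stem: bool = False) -> list[str]:
    """Normalize free text to lowercase unigram tokens.

    All punctuation characters (and underscore) are replaced by whitespace,
    the text is case-folded, and tokens are produced by whitespace splitting.
    The default normalizer is idempotent: re-tokenizing its own joined output
    returns the same sequence.

    Parameters
    ----------
    raw : str
        Input text; may be empty.
    stem : bool
        If True, additionally strip a small fixed set of English suffixes
        from tokens longer than 4 characters.  Not idempotent in general;
        use consistently on corpus and questions.
    """
    tokens = _PUNCT_RE.sub(" ", raw).lower().split()
    if stem:
        tokens = [_strip_suffix(t) for t in tokens]
    return tokens


def _strip_suffix(token: str) -> str:
    for suf in _SUFFIXES:
        if len(token) > len(suf) + 3 and token.endswith(suf):
            return token[: -len(suf)]
    return token


@dataclass
class IdfTable:
    """Token -> inverse-document-frequency weight over ``n_documents`` docs."""

    n_documents: int
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_documents <= 0:
            raise ValueError("n_documents must be positive")
        for tok, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"non-finite or negative IDF for {tok!r}: {w}")

    def get(self, token: str, default: float | None = None) -> float | None:
        return self.weights.get(token, default)

    def __contains__(self, token: str) -> bool:
        return token in self.weights

    def __len__(self) -> int:
        return len(self.weights)


def compute_idf(
    docs: Iterable[Document],
    smooth: bool = False,
    stem: bool = False,
) -> IdfTable:
    """Compute IDF weights from a document collection.

    The default variant is the classic ``idf(w) = ln(N / df(w))`` where
    ``df`` counts documents containing the token at least once; a token
    present in every document gets weight 0.  With ``smooth=True`` the
    variant ``ln((1 + N)/(1 + df)) + 1`` is used instead (strictly positive,
    robust when new documents are scored against an old table).

    Documents that are empty after preprocessing are dropped (a count is
    logged) and do not enter ``N``.
    """
    df: Counter[str] = Counter()
    n_docs = 0
    n_dropped = 0
    for doc in docs:
        tokens = preprocess_text(doc.text, stem=stem)
        if not tokens:
            n_dropped += 1
            continue
        n_docs += 1
        df.update(set(tokens))
    if n_dropped:
        logger.info("compute_idf: dropped %d empty documents", n_dropped)
    if n_docs == 0:
        raise ValueError("compute_idf: no non-empty documents in corpus")
    if smooth:
        weights = {t: math.log((1 + n_docs) / (1 + d)) + 1.0 for t, d in df.items()}
    else:
        weights = {t: math.log(n_docs / d) for t, d in df.items()}
    return IdfTable(n_documents=n_docs, weights=weights)


@dataclass
class EmbeddingTable:
    """Token -> dense real vector, all of one dimension ``dimension``."""

    dimension: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        clean: dict[str, np.ndarray] = {}
        for tok, vec in self.entries.items():
            arr = np.asarray(vec, dtype=np.float64)
            if arr.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {tok!r} has shape {arr.shape}, expected ({self.dimension},)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite components in vector for {tok!r}")
            clean[tok] = arr
        self.entries = clean

    def get(self, token: str) -> np.ndarray | None:
        return self.entries.get(token)

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def tokens(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class TrainingConfig:
    """Skip-gram training settings.

    Defaults: 500-dimensional vectors, context window 10, 10 negative
    samples, minimum total token frequency 100, 5 epochs.
    """

    dimension: int = 500
    window: int = 10
    negative_samples: int = 10
    min_count: int = 100
    epochs: int = 5
    seed: int = 0
    learning_rate: float = 0.025

    def __post_init__(self) -> None:
        for name in ("dimension", "window", "negative_samples", "min_count", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def train_embeddings(docs: Iterable[Document], cfg: TrainingConfig) -> EmbeddingTable:
    """Train skip-gram word embeddings with negative sampling.

    A single-threaded numpy implementation of the skip-gram objective with
    negative sampling: for every (center, context) pair within a
    symmetric window of random radius 1..window, the center vector is pushed
    toward the context's output vector and away from ``negative_samples``
    noise tokens drawn from the unigram distribution raised to 3/4.  Runs
    are bit-reproducible given ``cfg.seed``.

    Only tokens with total corpus frequency >= ``cfg.min_count`` enter the
    vocabulary; an empty vocabulary raises ``ValueError``.
    """
    sentences = [preprocess_text(d.text) for d in docs]
    counts: Counter[str] = Counter()
    for s in sentences:
        counts.update(s)
    vocab = sorted(t for t, c in counts.items() if c >= cfg.min_count)
    if not vocab:
        raise ValueError(
            f"train_embeddings: no token reaches min_count={cfg.min_count}"
        )
    index = {t: i for i, t in enumerate(vocab)}
    encoded = [
        np.array([index[t] for t in s if t in index], dtype=np.int64)
        for s in sentences
    ]
    encoded = [s for s in encoded if len(s) >= 2]

    rng = np.random.default_rng(cfg.seed)
    V, D = len(vocab), cfg.dimension
    w_in = (rng.random((V, D)) - 0.5) / D   # standard word2vec init scale
    w_out = np.zeros((V, D))

    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    n_pairs_total = sum(len(s) for s in encoded) * cfg.epochs
    lr0, lr_min = cfg.learning_rate, 1e-4
    seen = 0
    for _epoch in range(cfg.epochs):
        for sent in encoded:
            n = len(sent)
            radii = rng.integers(1, cfg.window + 1, size=n)
            negs = rng.choice(V, size=(n, cfg.negative_samples), p=noise)
            for pos in range(n):
                lr = max(lr_min, lr0 * (1.0 - seen / max(1, n_pairs_total)))
                seen += 1
                center = sent[pos]
                r = radii[pos]
                lo, hi = max(0, pos - r), min(n, pos + r + 1)
                context = [sent[j] for j in range(lo, hi) if j != pos]
                if not context:
                    continue
                targets = np.concatenate(
                    [np.asarray(context, dtype=np.int64), negs[pos]]
                )
                labels = np.zeros(len(targets))
                labels[: len(context)] = 1.0
                v = w_in[center]
                out = w_out[targets]
                score = 1.0 / (1.0 + np.exp(-np.clip(out @ v, -30, 30)))
                g = (labels - score) * lr
                w_in[center] = v + g @ out
                w_out[targets] += np.outer(g, v)

    return EmbeddingTable(
        dimension=D, entries={t: w_in[index[t]].copy() for t in vocab}
    )


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in word2vec plain-text format.

    Components are printed with 9 significant digits so that a write/read
    round trip reproduces every component to 1e-6 absolute for the value
    ranges embeddings take.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for tok, vec in table.entries.items():
            fh.write(tok + " " + " ".join(f"{x:.9g}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read word2vec plain-text format: ``<vocab> <dim>`` header then rows."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        try:
            n_vocab, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed header {header!r}") from exc
        if n_vocab < 0 or dim <= 0:
            raise ValueError(f"{path}: invalid header counts {header!r}")
        entries: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            tok = parts[0]
            if len(parts) - 1 != dim:
                raise ValueError(
                    f"{path}:{lineno}: row for {tok!r} has {len(parts) - 1} "
                    f"components, expected {dim}"
                )
            if tok in entries:
                raise ValueError(f"{path}:{lineno}: duplicate token {tok!r}")
            entries[tok] = np.array(parts[1:], dtype=np.float64)
    if len(entries) != n_vocab:
        raise ValueError(
            f"{path}: header announces {n_vocab} tokens, file has {len(entries)}"
        )
    return EmbeddingTable(dimension=dim, entries=entries)


def write_idf(table: IdfTable, path: str | Path) -> None:
    """Write an IDF table as ``#N <n_documents>`` then tab-separated rows."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#N {table.n_documents}\n")
        for tok, w in table.weights.items():
            fh.write(f"{tok}\t{w:.10g}\n")


def read_idf(path: str | Path) -> IdfTable:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) != 2 or first[0] != "#N":
            raise ValueError(f"{path}: expected '#N <count>' header")
        n_docs = int(first[1])
        weights: dict[str, float] = {}
        for line in fh:
            if not line.strip():
                continue
            tok, w = line.split("\t")
            weights[tok] = float(w)
    return IdfTable(n_documents=n_docs, weights=weights)
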