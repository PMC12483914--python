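"""Trigram subword embeddings for peptide windows.

Windows are decomposed into overlapping length-3 subwords (a 21-mer yields 19
trigrams; an X-flanked 23-mer yields 21, one per original residue) and the
trigrams are treated as the atomic tokens of a skip-gram model: each trigram
receives one trained vector, and training maximises the probability of a
trigram's neighbours within a context window ``c``, estimated by negative
sampling against a smoothed unigram noise distribution.  This mirrors the
subword treatment of fastText applied to residue 3-grams, with the trigram
itself as the subword unit.

Embeddings are trained on training-split windows only; unseen trigrams embed
to the zero vector (there is no finer decomposition to back off to, and zero
is neutral under the downstream linear projections).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .seqdata import PeptideWindow, WINDOW_LENGTH

logger = logging.getLogger(__name__)

MAGIC = "SULFVEC1"


@dataclass
class SubwordVocab:
    index: dict[str, int]
    n: int = 3

    def __len__(self):
        return len(self.index)


@dataclass
class SkipGramConfig:
    dim: int = 60
    context_window: int = 5
    epochs: int = 5
    negatives_per_target: int = 5
    learning_rate: float = 0.05
    seed: int = 0
    batch_size: int = 1024

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        if self.context_window < 1:
            raise ValueError("context window must be >= 1")


@dataclass
class EmbeddingMatrix:
    vocab: SubwordVocab
    vectors: np.ndarray                      # |vocab| x dim input vectors
    context_vectors: np.ndarray | None = None  # |vocab| x dim output vectors
    loss_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


# ---------------------------------------------------------------------------
# tokenisation
# ---------------------------------------------------------------------------

def to_subwords(sequence: str, n: int = 3) -> list[str]:
    """Overlapping subwords of width ``n`` (stride 1): len(seq) − n + 1 tokens."""
    if len(sequence) < n:
        raise ValueError(f"sequence of length {len(sequence)} shorter than n={n}")
    return [sequence[i:i + n] for i in range(len(sequence) - n + 1)]


def pad_for_alignment(window: PeptideWindow | str) -> str:
    """Flank a 21-residue window with one X on each side.

    Trigram ``i`` of the padded 23-mer is then centered on residue ``i`` of
    the original window, so the trigram stream has exactly 21 positions and
    aligns 1:1 with the per-residue evolutionary-profile stream.
    """
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    if len(seq) != WINDOW_LENGTH:
        raise ValueError(f"expected a {WINDOW_LENGTH}-residue window")
    return "X" + seq + "X"


# ---------------------------------------------------------------------------
# skip-gram with negative sampling
# ---------------------------------------------------------------------------

def build_vocab(corpus: list[list[str]], n: int = 3) -> SubwordVocab:
    index: dict[str, int] = {}
    for tokens in corpus:
        for tok in tokens:
            if len(tok) != n:
                raise ValueError(f"token '{tok}' does not have length {n}")
            if tok not in index:
                index[tok] = len(index)
    return SubwordVocab(index, n)


def _pairs(corpus_ids: list[np.ndarray], c: int) -> tuple[np.ndarray, np.ndarray]:
    targets, contexts = [], []
    for ids in corpus_ids:
        T = len(ids)
        for j in range(1, c + 1):
            if T <= j:
                continue
            targets.append(ids[:-j]); contexts.append(ids[j:])
            targets.append(ids[j:]);  contexts.append(ids[:-j])
    if not targets:
        raise ValueError("corpus produced no training pairs")
    return np.concatenate(targets), np.concatenate(contexts)


def train_embeddings(corpus: list[list[str]],
                     config: SkipGramConfig | None = None) -> EmbeddingMatrix:
    """Train trigram vectors by skip-gram with negative sampling.

    Deterministic for a fixed ``config.seed``: initialisation, pair shuffling
    and negative draws all derive from one generator.  The recorded
    ``loss_history`` holds the mean per-pair negative-sampling loss of each
    epoch.
    """
    if config is None:
        config = SkipGramConfig()
    if not corpus:
        raise ValueError("empty corpus")
    vocab = build_vocab(corpus, n=len(corpus[0][0]))
    rng = np.random.default_rng(config.seed)
    V, d = len(vocab), config.dim

    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    corpus_ids = [np.array([vocab.index[t] for t in toks], dtype=np.int64)
                  for toks in corpus]
    targets, contexts = _pairs(corpus_ids, config.context_window)

    counts = np.bincount(np.concatenate(corpus_ids), minlength=V).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()

    n_pairs = len(targets)
    k = config.negatives_per_target
    history: list[float] = []
    step, total_steps = 0, config.epochs * ((n_pairs + config.batch_size - 1)
                                            // config.batch_size)
    for _ in range(config.epochs):
        order = rng.permutation(n_pairs)
        epoch_loss, epoch_n = 0.0, 0
        for start in range(0, n_pairs, config.batch_size):
            idx = order[start:start + config.batch_size]
            t_ids, c_ids = targets[idx], contexts[idx]
            neg_ids = rng.choice(V, size=(len(idx), k), p=noise)
            lr = config.learning_rate * max(1e-4, 1.0 - step / total_steps)
            step += 1

            vt = w_in[t_ids]                       # (B, d)
            uc = w_out[c_ids]                      # (B, d)
            un = w_out[neg_ids]                    # (B, k, d)

            s_pos = np.einsum("bd,bd->b", vt, uc)
            s_neg = np.einsum("bd,bkd->bk", vt, un)
            g_pos = _sigmoid(s_pos) - 1.0          # d loss / d s_pos
            g_neg = _sigmoid(s_neg)                # d loss / d s_neg

            epoch_loss += (_softplus(-s_pos).sum() + _softplus(s_neg).sum())
            epoch_n += len(idx)

            grad_vt = g_pos[:, None] * uc + np.einsum("bk,bkd->bd", g_neg, un)
            np.add.at(w_in, t_ids, -lr * grad_vt)
            np.add.at(w_out, c_ids, -lr * g_pos[:, None] * vt)
            np.add.at(w_out, neg_ids.ravel(),
                      -lr * (g_neg[:, :, None] * vt[:, None, :]).reshape(-1, d))
        history.append(epoch_loss / epoch_n)

    if not np.all(np.isfinite(w_in)):
        raise FloatingPointError("embedding training diverged")
    return EmbeddingMatrix(vocab, w_in, w_out, history)


def evaluate_loss(model: EmbeddingMatrix, corpus: list[list[str]],
                  config: SkipGramConfig | None = None, seed: int = 12345) -> float:
    """Mean per-pair negative-sampling loss of a model on a corpus.

    Negative draws use an independent fixed seed so that the same model and
    corpus always yield the same number.
    """
    if config is None:
        config = SkipGramConfig()
    rng = np.random.default_rng(seed)
    ids = [np.array([model.vocab.index[t] for t in toks if t in model.vocab.index],
                    dtype=np.int64) for toks in corpus]
    targets, contexts = _pairs(ids, config.context_window)
    V = len(model.vocab)
    counts = np.bincount(np.concatenate(ids), minlength=V).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()
    neg = rng.choice(V, size=(len(targets), config.negatives_per_target), p=noise)
    w_out = model.context_vectors if model.context_vectors is not None else model.vectors
    vt = model.vectors[targets]
    s_pos = np.einsum("bd,bd->b", vt, w_out[contexts])
    s_neg = np.einsum("bd,bkd->bk", vt, w_out[neg])
    return float((_softplus(-s_pos).sum() + _softplus(s_neg).sum()) / len(targets))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# applying the model
# ---------------------------------------------------------------------------

def embed_window(window: PeptideWindow | str, model: EmbeddingMatrix) -> np.ndarray:
    """Embed a window as a 21 × dim matrix, one row per residue position.

    The window is X-flanked first, so trigram ``i`` (row ``i``) is centered on
    residue ``i``.  Out-of-vocabulary trigrams embed to all-zero rows.
    """
    padded = pad_for_alignment(window)
    tokens = to_subwords(padded, model.vocab.n)
    out = np.zeros((len(tokens), model.dim))
    oov = []
    for i, tok in enumerate(tokens):
        j = model.vocab.index.get(tok)
        if j is None:
            oov.append(tok)
        else:
            out[i] = model.vectors[j]
    if oov:
        logger.debug("out-of-vocabulary trigrams embedded as zeros: %s", oov)
    return out


def embed_corpus(windows: list[PeptideWindow], model: EmbeddingMatrix) -> np.ndarray:
    """Stack :func:`embed_window` over windows → (n, 21, dim)."""
    return np.stack([embed_window(w, model) for w in windows])


# ---------------------------------------------------------------------------
# persistence: JSON vocab + raw little-endian float32 matrix
# ---------------------------------------------------------------------------

def save_embeddings(model: EmbeddingMatrix, vocab_path, matrix_path) -> None:
    with open(vocab_path, "w", encoding="utf-8") as fh:
        json.dump({"n": model.vocab.n, "index": model.vocab.index}, fh)
    header = f"{MAGIC}\n{len(model.vocab)}\n{model.dim}\n".encode("ascii")
    with open(matrix_path, "wb") as fh:
        fh.write(header)
        fh.write(model.vectors.astype("<f4").tobytes())


def load_embeddings(vocab_path, matrix_path) -> EmbeddingMatrix:
    with open(vocab_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    vocab = SubwordVocab({k: int(v) for k, v in meta["index"].items()}, int(meta["n"]))
    with open(matrix_path, "rb") as fh:
        lines = [fh.readline().rstrip(b"\n") for _ in range(3)]
        if lines[0].decode("ascii", "replace") != MAGIC:
            raise ValueError("bad magic in embedding matrix file")
        rows, dim = int(lines[1]), int(lines[2])
        if rows != len(vocab):
            raise ValueError("vocab size mismatch between files")
        data = np.frombuffer(fh.read(), dtype="<f4")
    if data.size != rows * dim:
        raise ValueError("matrix payload size does not match header")
    return EmbeddingMatrix(vocab, data.reshape(rows, dim).astype(np.float64))
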