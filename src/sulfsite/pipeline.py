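"""End-to-end sulfenylation-site prediction pipeline.

Glues the pieces together in the leakage-safe order: trigram skip-gram
embeddings are trained on the *training* windows only; evolutionary features
come from supplied PSSM profiles (or seed-deterministic synthetic profiles);
the training set is class-balanced by interpolation oversampling on the
flattened feature vectors; and the fusion network is trained with early
stopping.  ``predict_scores`` makes the pipeline usable directly as a model
for :func:`sulfsite.evaluation.repeated_cv`.
"""

from __future__ import annotations

import logging

import numpy as np

from . import bioencode, embedding, resampling
from .fusionnet import FusionModel, TrainConfig
from .seqdata import PeptideWindow, WINDOW_LENGTH

logger = logging.getLogger(__name__)


class SulfenylationPipeline:
    """Dual-stream predictor over raw peptide windows.

    Parameters mirror the tuned configuration: trigram length 3, embedding
    dim 60, 3 attention heads; hidden size, training schedule and resampling
    method are exposed.
    """

    def __init__(self, *, dim: int = 60, ngram: int = 3, heads: int = 3,
                 hidden_size: int = 64, model_dim: int = 60,
                 resample_method: str = "svmsmote",
                 embed_epochs: int = 5, train_config: TrainConfig | None = None,
                 profiles: dict | None = None, squash: bool = True,
                 seed: int = 0, dtype=np.float32):
        self.dim = dim
        self.ngram = ngram
        self.heads = heads
        self.hidden_size = hidden_size
        self.model_dim = model_dim
        self.resample_method = resample_method
        self.embed_epochs = embed_epochs
        self.train_config = train_config
        self.profiles = profiles
        self.squash = squash
        self.seed = seed
        self.dtype = dtype  # float32 keeps the network's memory traffic low
        self.embedder: embedding.EmbeddingMatrix | None = None
        self.model: FusionModel | None = None

    # ------------------------------------------------------------ features
    def _semantic_features(self, windows: list[PeptideWindow]) -> np.ndarray:
        return embedding.embed_corpus(windows, self.embedder)

    def _evolutionary_features(self, windows: list[PeptideWindow]) -> np.ndarray:
        return bioencode.encode_windows_pssm(windows, self.profiles,
                                             squash=self.squash, seed=self.seed)

    # ------------------------------------------------------------ training
    def fit(self, windows: list[PeptideWindow], labels) -> "SulfenylationPipeline":
        labels = np.asarray(labels).astype(int)
        corpus = [embedding.to_subwords(embedding.pad_for_alignment(w), self.ngram)
                  for w in windows]
        self.embedder = embedding.train_embeddings(
            corpus, embedding.SkipGramConfig(dim=self.dim,
                                             epochs=self.embed_epochs,
                                             seed=self.seed))
        H_W = self._semantic_features(windows)        # (n, 21, dim)
        H_P = self._evolutionary_features(windows)    # (n, 21, 20)

        n = len(windows)
        flat = np.concatenate([H_P.reshape(n, -1), H_W.reshape(n, -1)], axis=1)
        if self.resample_method != "none":
            cfg = resampling.ResampleConfig(method=self.resample_method,
                                            seed=self.seed)
            flat, labels = resampling.resample(flat, labels, cfg)
        n2 = len(labels)
        d_p = WINDOW_LENGTH * 20
        H_P = flat[:, :d_p].reshape(n2, WINDOW_LENGTH, 20)
        H_W = flat[:, d_p:].reshape(n2, WINDOW_LENGTH, self.dim)

        self.model = FusionModel.init(d_evo=20, d_sem=self.dim,
                                      seq_len=WINDOW_LENGTH,
                                      hidden_size=self.hidden_size,
                                      model_dim=self.model_dim,
                                      head_count=self.heads, seed=self.seed,
                                      dtype=self.dtype)
        cfg = self.train_config or TrainConfig(seed=self.seed)
        self.history = self.model.train(H_P.astype(self.dtype),
                                        H_W.astype(self.dtype), labels, cfg)
        return self

    # ----------------------------------------------------------- inference
    def predict_scores(self, windows: list[PeptideWindow]) -> np.ndarray:
        if self.model is None or self.embedder is None:
            raise RuntimeError("pipeline is not fitted")
        H_W = self._semantic_features(windows).astype(self.dtype)
        H_P = self._evolutionary_features(windows).astype(self.dtype)
        return self.model.predict(H_P, H_W)
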