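"""Linear-chain conditional random field and cross-validation folds.

A from-scratch CRF over string-valued token features: state weights per
(feature, label), transition weights per label pair, and explicit
begin/end-of-sequence weights.  Training minimises the regularised negative
log-likelihood either by stochastic gradient descent with an L2 term
(``l2sgd``, the default) or by full-batch L-BFGS with an elastic penalty
(``lbfgs``; the L1 coefficient is applied there via a smooth approximation).

The ``possible_states`` / ``possible_transitions`` switches control whether
(feature, label) and (label, label) pairs never seen in training are given
weights (and may therefore fire at prediction time) or are masked out.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from phenorec.features import LabeledSequence, repair_bio

__all__ = ["CRFConfig", "ChainCRF", "FoldPlan", "train", "predict", "make_folds"]


@dataclass
class CRFConfig:
    algorithm: str = "l2sgd"
    c1: float = 0.9833
    c2: float = 1.0
    possible_states: bool = True
    possible_transitions: bool = True
    max_iterations: int = 100
    seed: int = 42
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("regularisation coefficients must be >= 0")
        if self.algorithm not in ("l2sgd", "lbfgs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


class ChainCRF:
    """Linear-chain CRF over string feature sets."""

    def __init__(self, config: CRFConfig | None = None) -> None:
        self.config = config or CRFConfig()
        self.feature_index: dict[str, int] = {}
        self.labels: list[str] = []
        self.W: np.ndarray | None = None       # (F, L) state weights
        self.T: np.ndarray | None = None       # (L, L) transitions
        self.S: np.ndarray | None = None       # (L,) start
        self.E: np.ndarray | None = None       # (L,) end
        self.state_mask: np.ndarray | None = None
        self.trans_mask: np.ndarray | None = None
        self.training_log: list[dict] = []

    # -- encoding ----------------------------------------------------------

    def _index_sequences(self, X: list[list[list[str]]]) -> list[list[np.ndarray]]:
        out = []
        for seq in X:
            out.append([
                np.array(
                    [self.feature_index[f] for f in feats if f in self.feature_index],
                    dtype=np.intp,
                )
                for feats in seq
            ])
        return out

    def _emissions(self, idx_seq: list[np.ndarray]) -> np.ndarray:
        em = np.zeros((len(idx_seq), len(self.labels)))
        for t, idx in enumerate(idx_seq):
            if idx.size:
                em[t] = self.W[idx].sum(axis=0)
        return em

    # -- inference ---------------------------------------------------------

    def _forward_backward(self, em: np.ndarray):
        n, L = em.shape
        T = np.where(self.trans_mask, self.T, -np.inf)
        alpha = np.zeros((n, L))
        alpha[0] = self.S + em[0]
        for t in range(1, n):
            alpha[t] = logsumexp(alpha[t - 1][:, None] + T, axis=0) + em[t]
        beta = np.zeros((n, L))
        beta[-1] = self.E
        for t in range(n - 2, -1, -1):
            beta[t] = logsumexp(T + (em[t + 1] + beta[t + 1])[None, :], axis=1)
        log_z = logsumexp(alpha[-1] + self.E)
        return alpha, beta, log_z

    def _sequence_grad(self, idx_seq, y_ids):
        """NLL and its gradient for one sequence (dict of dense arrays)."""
        em = self._emissions(idx_seq)
        alpha, beta, log_z = self._forward_backward(em)
        n, L = em.shape
        post = np.exp(alpha + beta - log_z)

        gW = {}
        for t, idx in enumerate(idx_seq):
            diff = post[t].copy()
            diff[y_ids[t]] -= 1.0
            for f in idx:
                if f in gW:
                    gW[f] = gW[f] + diff
                else:
                    gW[f] = diff.copy()

        gT = np.zeros((L, L))
        if n > 1:
            T = np.where(self.trans_mask, self.T, -np.inf)
            for t in range(n - 1):
                pair = alpha[t][:, None] + T + (em[t + 1] + beta[t + 1])[None, :] - log_z
                gT += np.exp(pair)
            for t in range(n - 1):
                gT[y_ids[t], y_ids[t + 1]] -= 1.0

        gS = post[0].copy()
        gS[y_ids[0]] -= 1.0
        gE = post[-1].copy()
        gE[y_ids[-1]] -= 1.0

        score = self.S[y_ids[0]] + em[0, y_ids[0]]
        for t in range(1, n):
            score += self.T[y_ids[t - 1], y_ids[t]] + em[t, y_ids[t]]
        score += self.E[y_ids[-1]]
        nll = log_z - score
        return nll, gW, gT, gS, gE

    def _viterbi(self, em: np.ndarray) -> list[int]:
        n, L = em.shape
        T = np.where(self.trans_mask, self.T, -np.inf)
        delta = self.S + em[0]
        back = np.zeros((n, L), dtype=np.intp)
        for t in range(1, n):
            scores = delta[:, None] + T
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + em[t]
        delta = delta + self.E
        path = [int(delta.argmax())]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]

    # -- training ----------------------------------------------------------

    def fit(self, X: list[list[list[str]]], y: list[list[str]]) -> "ChainCRF":
        if not X or sum(len(s) for s in X) == 0:
            raise ValueError("empty training data")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")

        labels = sorted({lab for seq in y for lab in seq})
        if not set(labels) <= {"B", "I", "O"}:
            raise ValueError(f"label alphabet must be within B/I/O, got {labels}")
        if len(labels) == 1:
            warnings.warn("degenerate training data: single label observed")
        self.labels = labels
        L = len(labels)
        lab_id = {lab: i for i, lab in enumerate(labels)}

        feats = sorted({f for seq in X for tok in seq for f in tok})
        self.feature_index = {f: i for i, f in enumerate(feats)}
        F = len(feats)

        self.W = np.zeros((F, L))
        self.T = np.zeros((L, L))
        self.S = np.zeros(L)
        self.E = np.zeros(L)

        if self.config.possible_states:
            self.state_mask = np.ones((F, L), dtype=bool)
        else:
            self.state_mask = np.zeros((F, L), dtype=bool)
            for seq, labs in zip(X, y):
                for tok, lab in zip(seq, labs):
                    for f in tok:
                        self.state_mask[self.feature_index[f], lab_id[lab]] = True
        if self.config.possible_transitions:
            self.trans_mask = np.ones((L, L), dtype=bool)
        else:
            self.trans_mask = np.zeros((L, L), dtype=bool)
            for labs in y:
                for a, b in zip(labs, labs[1:]):
                    self.trans_mask[lab_id[a], lab_id[b]] = True
            if not self.trans_mask.any():
                self.trans_mask[:] = True

        idx_X = self._index_sequences(X)
        idx_y = [[lab_id[lab] for lab in labs] for labs in y]

        if self.config.algorithm == "l2sgd":
            self._fit_l2sgd(idx_X, idx_y)
        else:
            self._fit_lbfgs(idx_X, idx_y)
        return self

    def _fit_l2sgd(self, idx_X, idx_y) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = len(idx_X)
        eta0 = cfg.learning_rate
        t = 0
        for epoch in range(cfg.max_iterations):
            order = rng.permutation(n)
            total = 0.0
            for s in order:
                eta = eta0 / (1.0 + t / max(n * 10, 1))
                nll, gW, gT, gS, gE = self._sequence_grad(idx_X[s], idx_y[s])
                total += nll
                decay = 1.0 - eta * cfg.c2 / n
                self.W *= decay
                self.T *= decay
                self.S *= decay
                self.E *= decay
                for f, g in gW.items():
                    self.W[f] -= eta * g
                self.T -= eta * gT
                self.S -= eta * gS
                self.E -= eta * gE
                t += 1
            self.W[~self.state_mask] = 0.0
            self.training_log.append({"epoch": epoch, "loss": float(total)})

    def _fit_lbfgs(self, idx_X, idx_y) -> None:
        from scipy.optimize import minimize

        cfg = self.config
        F, L = self.W.shape
        shapes = [(F, L), (L, L), (L,), (L,)]
        sizes = [F * L, L * L, L, L]
        eps = 1e-6

        def unpack(w):
            parts, off = [], 0
            for shape, size in zip(shapes, sizes):
                parts.append(w[off : off + size].reshape(shape))
                off += size
            return parts

        def objective(w):
            self.W, self.T, self.S, self.E = unpack(w.copy())
            nll_total = 0.0
            gW_total = np.zeros((F, L))
            gT_total = np.zeros((L, L))
            gS_total = np.zeros(L)
            gE_total = np.zeros(L)
            for idx_seq, y_ids in zip(idx_X, idx_y):
                nll, gW, gT, gS, gE = self._sequence_grad(idx_seq, y_ids)
                nll_total += nll
                for f, g in gW.items():
                    gW_total[f] += g
                gT_total += gT
                gS_total += gS
                gE_total += gE
            # elastic penalty: exact L2, smoothed L1
            l1 = np.sqrt(w * w + eps)
            obj = nll_total + 0.5 * cfg.c2 * float(w @ w) + cfg.c1 * float(l1.sum() )
            grad = np.concatenate([
                gW_total.ravel(), gT_total.ravel(), gS_total, gE_total,
            ]) + cfg.c2 * w + cfg.c1 * (w / l1)
            return obj, grad

        w0 = np.zeros(sum(sizes))
        res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.max_iterations})
        self.W, self.T, self.S, self.E = unpack(res.x)
        self.W[~self.state_mask] = 0.0
        self.training_log.append({"epoch": int(res.nit), "loss": float(res.fun)})

    # -- prediction --------------------------------------------------------

    def predict(self, X: list[list[list[str]]]) -> list[list[str]]:
        if self.W is None:
            raise RuntimeError("model is not trained")
        out = []
        for idx_seq in self._index_sequences(X):
            if not idx_seq:
                out.append([])
                continue
            em = self._emissions(idx_seq)
            out.append(repair_bio([self.labels[i] for i in self._viterbi(em)]))
        return out

    # -- persistence (JSON text format) ------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "labels": self.labels,
            "features": list(self.feature_index),
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "S": self.S.tolist(),
            "E": self.E.tolist(),
            "state_mask": self.state_mask.astype(int).tolist(),
            "trans_mask": self.trans_mask.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ChainCRF":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(CRFConfig(**payload["config"]))
        model.labels = payload["labels"]
        model.feature_index = {f: i for i, f in enumerate(payload["features"])}
        model.W = np.array(payload["W"])
        model.T = np.array(payload["T"])
        model.S = np.array(payload["S"])
        model.E = np.array(payload["E"])
        model.state_mask = np.array(payload["state_mask"], dtype=bool)
        model.trans_mask = np.array(payload["trans_mask"], dtype=bool)
        return model


# --------------------------------------------------------------------------
# Convenience wrappers over LabeledSequence
# --------------------------------------------------------------------------

def train(sequences: list[LabeledSequence], config: CRFConfig | None = None) -> ChainCRF:
    """Fit a CRF on featurized labeled sequences (non-empty ones)."""
    usable = [s for s in sequences if s.sentence.tokens]
    if not usable:
        raise ValueError("no non-empty training sequences")
    for s in usable:
        if len(s.features) != len(s.sentence.tokens):
            raise ValueError("sequences must be featurized before training")
    X = [s.features for s in usable]
    y = [s.labels for s in usable]
    return ChainCRF(config).fit(X, y)


def predict(model: ChainCRF, sequences: list[LabeledSequence]) -> list[list[str]]:
    """Label sequences with the trained model; output is BIO-repaired."""
    return model.predict([s.features for s in sequences])


# --------------------------------------------------------------------------
# Cross-validation folds
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]
    seed: int = 42

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train_doc_ids, test_doc_ids) for one fold."""
        test = set(self.fold_ids(fold))
        train = sorted(d for d in self.assignment if d not in test)
        return train, sorted(test)


def make_folds(doc_ids: list[str], k: int = 10, seed: int = 42) -> FoldPlan:
    """Deterministic document-level k-fold partition; sizes differ by ≤ 1."""
    if k > len(doc_ids):
        raise ValueError(f"k={k} exceeds number of documents ({len(doc_ids)})")
    rng = np.random.default_rng(seed)
    shuffled = [doc_ids[i] for i in rng.permutation(len(doc_ids))]
    assignment = {doc: i % k for i, doc in enumerate(shuffled)}
    return FoldPlan(k, assignment, seed)
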