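"""Greedy agglomerative Brown clustering.

Bottom-up class-based bigram clustering: maintain a working set of clusters,
repeatedly merge the pair whose merge loses the least average mutual
information (AMI) of the class bigram distribution, and read each word's
bit-string path off the resulting merge tree.  The working-set trick keeps at
most ``num_clusters + 1`` clusters active, adding words in frequency order,
which is the standard way to keep the greedy search tractable.

Scaled for the modest vocabularies of annotated abstract collections; the
vocabulary is capped and rare words share an ``<unk>`` path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BrownClusters", "train_brown_clusters", "load_brown_clusters"]

UNK = "<unk>"


@dataclass
class BrownClusters:
    """Word → binary merge-tree path (root-to-leaf bit string)."""

    paths: dict[str, str] = field(default_factory=dict)

    def path(self, word: str) -> str:
        w = word.lower()
        return self.paths.get(w, self.paths.get(UNK, ""))

    def to_text(self) -> str:
        return "".join(f"{p}\t{w}\n" for w, p in sorted(self.paths.items()))


def load_brown_clusters(path) -> BrownClusters:
    """Read ``path<TAB>word`` lines (the common liang-style cluster format)."""
    paths: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            bits, word = line.rstrip("\n").split("\t")[:2]
            paths[word.lower()] = bits
    return BrownClusters(paths)


def _ami_terms(counts: np.ndarray, pl: np.ndarray, pr, total: float) -> float:
    """Sum of p*log(p/(pl*pr)) over positive entries of one row/col slice."""
    counts = np.asarray(counts, dtype=float)
    mask = counts > 0
    if not mask.any():
        return 0.0
    p = counts[mask] / total
    pl_ = (np.broadcast_to(pl, counts.shape)[mask]) / total
    pr_ = (np.broadcast_to(pr, counts.shape)[mask]) / total
    return float(np.sum(p * np.log(p / (pl_ * pr_))))


class _MergeTree:
    def __init__(self) -> None:
        self.children: dict[int, tuple[int, int]] = {}
        self.next_id = 0

    def leaf(self) -> int:
        self.next_id += 1
        return self.next_id - 1

    def merge(self, a: int, b: int) -> int:
        node = self.next_id
        self.next_id += 1
        self.children[node] = (a, b)
        return node

    def paths(self, root: int) -> dict[int, str]:
        out: dict[int, str] = {}
        stack = [(root, "")]
        while stack:
            node, path = stack.pop()
            kids = self.children.get(node)
            if kids is None:
                out[node] = path or "0"
            else:
                stack.append((kids[0], path + "0"))
                stack.append((kids[1], path + "1"))
        return out


def _merge_delta(counts: np.ndarray, pl: np.ndarray, pr: np.ndarray,
                 total: float, a: int, b: int) -> float:
    """AMI change if clusters a and b were merged (≤ 0)."""
    n = counts.shape[0]
    others = np.ones(n, dtype=bool)
    others[[a, b]] = False

    s_inv = (
        _ami_terms(counts[a, :], pl[a], pr, total)
        + _ami_terms(counts[b, :], pl[b], pr, total)
        + _ami_terms(counts[others, a], pl[others], pr[a], total)
        + _ami_terms(counts[others, b], pl[others], pr[b], total)
    )

    plm = pl[a] + pl[b]
    prm = pr[a] + pr[b]
    row_m = counts[a, others] + counts[b, others]
    col_m = counts[others, a] + counts[others, b]
    self_m = counts[a, a] + counts[a, b] + counts[b, a] + counts[b, b]
    s_new = (
        _ami_terms(row_m, plm, pr[others], total)
        + _ami_terms(col_m, pl[others], prm, total)
        + _ami_terms(np.array([self_m]), plm, prm, total)
    )
    return s_new - s_inv


def train_brown_clusters(
    sentences: list[list[str]],
    num_clusters: int = 50,
    max_vocab: int = 300,
) -> BrownClusters:
    """Cluster lower-cased word sequences; returns per-word bit paths.

    ``sentences`` are token-text sequences; bigrams do not cross sentence
    boundaries.  Words outside the ``max_vocab`` most frequent share the
    ``<unk>`` type.
    """
    unigrams: Counter[str] = Counter()
    for sent in sentences:
        unigrams.update(w.lower() for w in sent)
    if not unigrams:
        return BrownClusters({UNK: "0"})

    vocab = [w for w, _ in unigrams.most_common(max_vocab)]
    if len(unigrams) > len(vocab):
        vocab.append(UNK)
    index = {w: i for i, w in enumerate(vocab)}

    def wid(word: str) -> int:
        return index.get(word.lower(), index.get(UNK, 0))

    bigrams: Counter[tuple[int, int]] = Counter()
    for sent in sentences:
        ids = [wid(w) for w in sent]
        bigrams.update(zip(ids, ids[1:]))

    order = sorted(range(len(vocab)), key=lambda i: -unigrams[vocab[i]] if vocab[i] != UNK else 0)
    tree = _MergeTree()
    word_node = {i: tree.leaf() for i in range(len(vocab))}

    window = min(num_clusters + 1, len(vocab))
    # members[k] = set of word ids in active cluster k; node[k] = tree node
    active: list[set[int]] = [{order[i]} for i in range(window)]
    nodes: list[int] = [word_node[order[i]] for i in range(window)]
    pending = order[window:]

    full = Counter(bigrams)
    total = float(sum(full.values())) or 1.0

    def cluster_counts() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = len(active)
        owner = {w: k for k, members in enumerate(active) for w in members}
        counts = np.zeros((m, m), dtype=float)
        for (x, y), c in full.items():
            kx, ky = owner.get(x), owner.get(y)
            if kx is not None and ky is not None:
                counts[kx, ky] += c
        return counts, counts.sum(axis=1), counts.sum(axis=0)

    def best_merge() -> tuple[int, int]:
        counts, pl, pr = cluster_counts()
        best, best_pair = -np.inf, (0, 1)
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                d = _merge_delta(counts, pl, pr, total, a, b)
                if d > best:
                    best, best_pair = d, (a, b)
        return best_pair

    def do_merge() -> None:
        a, b = best_merge()
        nodes[a] = tree.merge(nodes[a], nodes[b])
        active[a] |= active[b]
        del active[b], nodes[b]

    while pending or len(active) > 1:
        if pending and len(active) <= num_clusters:
            w = pending.pop(0)
            active.append({w})
            nodes.append(word_node[w])
            continue
        do_merge()

    paths_by_node = tree.paths(nodes[0])
    return BrownClusters({vocab[i]: paths_by_node[word_node[i]] for i in range(len(vocab))})
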