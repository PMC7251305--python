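"""First-order Markov transition matrices and network export.

A state sequence yields a k x k count matrix ``counts[i, j] = #{t: X_t = i,
X_{t+1} = j}`` and its row-normalized transition matrix.  Matrices are kept at
the full pre-pruning size k so that subjects sharing one state space remain
comparable; a row whose state was never a transition source is *undefined*
(NaN), never imputed as zero.

Dyadic (patient <-> therapist) dynamics are built from interleaved label
sequences: patient-to-therapist pairs are simultaneous (pat_t -> ther_t),
therapist-to-patient pairs are lag-1 (ther_t -> pat_{t+1}); an alternative
treats the full interleaved sequence as a single chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .states import StateSequence


class MarkovError(ValueError):
    pass


@dataclass
class TransitionMatrix:
    """Transition counts and conditional probabilities over states 1..k."""

    k: int
    counts: np.ndarray  # (k, k) non-negative ints
    subject_id: str = ""
    role: str = ""
    direction: str | None = None  # None | "P2T" | "T2P" | "interleaved"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.k, self.k):
            raise MarkovError(f"counts must be {self.k}x{self.k}")
        if np.any(self.counts < 0):
            raise MarkovError("negative transition count")
        self.counts = self.counts.astype(int)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def defined_rows(self) -> np.ndarray:
        """Boolean mask of rows whose state occurred as a transition source."""
        return self.row_totals > 0

    @property
    def probs(self) -> np.ndarray:
        """Row-stochastic probabilities; undefined rows are all-NaN."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals[:, None]
        p[totals == 0] = np.nan
        return p

    def to_csv(self, path, what: str = "probs") -> None:
        """Write a k x k table; undefined cells are left blank."""
        mat = self.probs if what == "probs" else self.counts.astype(float)
        labels = [str(i) for i in range(1, self.k + 1)]
        df = pd.DataFrame(mat, index=labels, columns=labels)
        df.to_csv(path, float_format="%.6g", na_rep="")


def count_transitions(seq: StateSequence | Sequence[int], k: int) -> np.ndarray:
    """Count one-step transitions of a 1-based label sequence."""
    labels = np.asarray(seq.labels if isinstance(seq, StateSequence) else seq, dtype=int)
    if len(labels) < 2:
        raise MarkovError("need at least 2 observations to count transitions")
    if labels.min() < 1 or labels.max() > k:
        raise MarkovError(f"labels outside 1..{k}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    return counts


def mtm(
    seq: StateSequence | Sequence[int],
    k: int,
    subject_id: str = "",
    role: str = "",
) -> TransitionMatrix:
    """Markov transition matrix of one label sequence."""
    if isinstance(seq, StateSequence):
        subject_id = subject_id or seq.subject_id
        role = role or seq.role
    return TransitionMatrix(
        k=k, counts=count_transitions(seq, k), subject_id=subject_id, role=role
    )


def mtm_from_pairs(
    pairs: Iterable[tuple[int, int]],
    k: int,
    subject_id: str = "",
    direction: str | None = None,
) -> TransitionMatrix:
    """Transition matrix from explicit (source, target) 1-based pairs."""
    pairs = list(pairs)
    if not pairs:
        raise MarkovError("no transition pairs")
    arr = np.asarray(pairs, dtype=int)
    if arr.min() < 1 or arr.max() > k:
        raise MarkovError(f"pair labels outside 1..{k}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (arr[:, 0] - 1, arr[:, 1] - 1), 1)
    return TransitionMatrix(k=k, counts=counts, subject_id=subject_id, direction=direction)


def state_frequencies(seq: StateSequence | Sequence[int], k: int) -> np.ndarray:
    """Relative occurrence frequency of each state; sums to 1."""
    labels = np.asarray(seq.labels if isinstance(seq, StateSequence) else seq, dtype=int)
    if len(labels) == 0:
        raise MarkovError("empty sequence")
    if labels.min() < 1 or labels.max() > k:
        raise MarkovError(f"labels outside 1..{k}")
    return np.bincount(labels - 1, minlength=k) / len(labels)


def _align(pat: StateSequence, ther: StateSequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect the two roles' surviving block indices."""
    common, pi, ti = np.intersect1d(
        pat.block_indices, ther.block_indices, return_indices=True
    )
    if common.size == 0:
        raise MarkovError("no aligned blocks between the two roles")
    return common, pat.labels[pi], ther.labels[ti]


def dyad_sequence(
    pat: StateSequence, ther: StateSequence, direction: str = "P2T"
) -> list[tuple[int, int]]:
    """Directed transition pairs across the dyad.

    ``P2T``: simultaneous pairs (pat_t -> ther_t).  ``T2P``: lag-1 pairs
    (ther_t -> pat_{t+1}) over consecutive aligned blocks.  Rows of the
    resulting matrix are indexed by the source role's states, columns by the
    target role's.
    """
    common, pl, tl = _align(pat, ther)
    if direction == "P2T":
        return list(zip(pl.tolist(), tl.tolist()))
    if direction == "T2P":
        consec = np.nonzero(np.diff(common) == 1)[0]
        if consec.size == 0:
            raise MarkovError("no consecutive aligned blocks for T2P pairs")
        return list(zip(tl[consec].tolist(), pl[consec + 1].tolist()))
    raise MarkovError(f"unknown direction {direction!r}")


def interleaved_pairs(pat: StateSequence, ther: StateSequence) -> list[tuple[int, int]]:
    """Treat pat_1, ther_1, pat_2, ther_2, ... as one chain; all its steps."""
    _, pl, tl = _align(pat, ther)
    merged = np.empty(2 * len(pl), dtype=int)
    merged[0::2] = pl
    merged[1::2] = tl
    return list(zip(merged[:-1].tolist(), merged[1:].tolist()))


def row_max_flags(T: TransitionMatrix) -> list[tuple[int, int]]:
    """(row, col) 1-based cells holding each defined row's maximum; ties all flagged."""
    flags = []
    p = T.probs
    for i in np.nonzero(T.defined_rows)[0]:
        row = p[i]
        m = np.nanmax(row)
        for j in np.nonzero(row >= m - 1e-12)[0]:
            flags.append((int(i) + 1, int(j) + 1))
    return flags


def export_network(
    T: TransitionMatrix, path, fmt: str = "graphml", min_weight: float = 0.0
) -> nx.DiGraph:
    """Write the transition network as a weighted directed edge list.

    Nodes are states; each edge carries the transition probability, the raw
    count and a ``row_max`` flag marking the most probable destination(s) of
    its source state.  Formats: ``graphml`` or ``dot``.
    """
    flags = set(row_max_flags(T))
    g = nx.DiGraph()
    p = T.probs
    for i in range(T.k):
        g.add_node(i + 1)
    for i in np.nonzero(T.defined_rows)[0]:
        for j in range(T.k):
            w = p[i, j]
            if w > 0 and w >= min_weight:
                g.add_edge(
                    i + 1,
                    j + 1,
                    probability=float(w),
                    count=int(T.counts[i, j]),
                    row_max=(i + 1, j + 1) in flags,
                )
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph mtm {\n")
            for n in g.nodes:
                fh.write(f'  "{n}";\n')
            for u, v, d in g.edges(data=True):
                style = ", penwidth=2" if d["row_max"] else ""
                fh.write(
                    f'  "{u}" -> "{v}" [label="{d["probability"]:.3f}", '
                    f'weight={d["count"]}{style}];\n'
                )
            fh.write("}\n")
    else:
        raise MarkovError(f"unknown network format {fmt!r}")
    return g


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left unit eigenvector)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()
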