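"""Word-block segmentation and dictionary coding.

A transcript is reduced to a speaker-attributed token stream, cut into
consecutive fixed-size word blocks (150 words by convention), and each block is
scored for the relative frequency of three emotion/abstraction dictionaries
per speaker: positive emotional tone (POS), negative emotional tone (NEG) and
abstraction (AB).  The resulting six-column series (three features per
speaker, one row per block) is the raw material for all downstream symbolic
dynamics.

Conventions
-----------
* Frequencies are counts divided by the *block size* (total words in the
  block), not by the speaker's own word count, so a silent speaker scores
  (0, 0, 0) in that block.
* A trailing partial block is dropped: every row of the series shares the
  same denominator.
* Dictionaries must be pairwise disjoint sets of lowercase words; matching is
  exact string equality after lowercasing, no stemming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Speaker = Literal["patient", "therapist"]

#: canonical column order of a block series table
FEATURE_COLUMNS = ["pat_pos", "pat_neg", "pat_abs", "ther_pos", "ther_neg", "ther_abs"]
ALL_COLUMNS = ["t"] + FEATURE_COLUMNS

DEFAULT_BLOCK_SIZE = 150


class CodingError(ValueError):
    """Raised on invalid tokens, dictionaries or block-series tables."""


def _check_wordset(name: str, words: frozenset[str]) -> None:
    if not words:
        raise CodingError(f"dictionary {name!r} is empty")
    for w in words:
        if w != w.lower():
            raise CodingError(f"dictionary {name!r} entry {w!r} is not lowercase")
        if any(c.isspace() for c in w):
            raise CodingError(f"dictionary {name!r} entry {w!r} contains whitespace")


@dataclass(frozen=True)
class DictionarySet:
    """Three disjoint word lists: positive tone, negative tone, abstraction."""

    pos_words: frozenset[str]
    neg_words: frozenset[str]
    abs_words: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_words", frozenset(self.pos_words))
        object.__setattr__(self, "neg_words", frozenset(self.neg_words))
        object.__setattr__(self, "abs_words", frozenset(self.abs_words))
        _check_wordset("pos", self.pos_words)
        _check_wordset("neg", self.neg_words)
        _check_wordset("abs", self.abs_words)
        if (
            self.pos_words & self.neg_words
            or self.pos_words & self.abs_words
            or self.neg_words & self.abs_words
        ):
            raise CodingError("dictionaries overlap; POS/NEG/AB must be pairwise disjoint")

    @classmethod
    def from_files(cls, pos_path, neg_path, abs_path) -> "DictionarySet":
        """Load three plain-text word lists (one word per line)."""

        def read(path):
            with open(path) as fh:
                return frozenset(w.strip().lower() for w in fh if w.strip())

        return cls(read(pos_path), read(neg_path), read(abs_path))


@dataclass(frozen=True)
class SpeakerToken:
    token: str
    speaker: Speaker
    position: int


@dataclass
class WordBlockSeries:
    """Temporally ordered word blocks with six bounded frequency features.

    ``frame`` has columns ``t, pat_pos, pat_neg, pat_abs, ther_pos, ther_neg,
    ther_abs``; each feature is a fraction in [0, 1] and, per speaker,
    pos + neg + abs <= 1.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ALL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise CodingError(f"block series missing column(s): {missing}")
        f = self.frame
        for col in FEATURE_COLUMNS:
            vals = pd.to_numeric(f[col], errors="coerce")
            bad = vals.isna()
            if bad.any():
                raise CodingError(
                    f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
                )
            out = (vals < 0) | (vals > 1)
            if out.any():
                raise CodingError(
                    f"feature {col!r} outside [0, 1] at row {int(out.idxmax())}"
                )
        for role, cols in (("patient", FEATURE_COLUMNS[:3]), ("therapist", FEATURE_COLUMNS[3:])):
            s = f[cols].sum(axis=1)
            over = s > 1 + 1e-9
            if over.any():
                raise CodingError(
                    f"{role} features sum above 1 at row {int(over.idxmax())}"
                )
        t = f["t"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise CodingError("block index column 't' must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    def features(self, role: Speaker) -> np.ndarray:
        """(n_blocks, 3) array of POS/NEG/AB frequencies for one speaker."""
        cols = FEATURE_COLUMNS[:3] if role == "patient" else FEATURE_COLUMNS[3:]
        return self.frame[cols].to_numpy(dtype=float)


def segment_blocks(
    tokens: Sequence[SpeakerToken], block_size: int = DEFAULT_BLOCK_SIZE
) -> list[list[SpeakerToken]]:
    """Cut a token stream into consecutive non-overlapping fixed-size blocks.

    The trailing remainder of fewer than ``block_size`` tokens is dropped so
    that every block shares the same denominator.
    """
    if not tokens:
        raise CodingError("no input: empty token stream")
    if block_size < 1:
        raise CodingError("block_size must be >= 1")
    positions = [tok.position for tok in tokens]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise CodingError("token positions must be strictly increasing")
    n_blocks = len(tokens) // block_size
    return [
        list(tokens[i * block_size : (i + 1) * block_size]) for i in range(n_blocks)
    ]


def code_blocks(
    blocks: Sequence[Sequence[SpeakerToken]], dicts: DictionarySet
) -> WordBlockSeries:
    """Score each block: per speaker, (# matching tokens) / block_size."""
    if not blocks:
        raise CodingError("no input: empty block list")
    block_size = len(blocks[0])
    rows = []
    lookup = {
        "pos": dicts.pos_words,
        "neg": dicts.neg_words,
        "abs": dicts.abs_words,
    }
    for t, block in enumerate(blocks):
        row: dict[str, float] = {"t": t}
        for role, prefix in (("patient", "pat"), ("therapist", "ther")):
            toks = [tok.token.lower() for tok in block if tok.speaker == role]
            for cat, words in lookup.items():
                row[f"{prefix}_{cat}"] = sum(tok in words for tok in toks) / block_size
        rows.append(row)
    return WordBlockSeries(pd.DataFrame(rows, columns=ALL_COLUMNS))


def load_block_series(path, delimiter: str = ",") -> WordBlockSeries:
    """Read a delimited block-series table (header-driven column matching)."""
    frame = pd.read_csv(path, sep=delimiter)
    missing = [c for c in ALL_COLUMNS if c not in frame.columns]
    if missing:
        raise CodingError(f"{path}: missing column(s) {missing}")
    return WordBlockSeries(frame[ALL_COLUMNS].copy())


def write_block_series(series: WordBlockSeries, path, delimiter: str = ",") -> None:
    """Write the series so that ``load_block_series`` round-trips exactly."""
    series.frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")
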