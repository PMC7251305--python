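"""Direct comparison of transition networks across subjects.

Two dyads' dynamics are compared by the Pearson correlation of their
linearized Markov transition matrices, separately on the patient and the
therapist side, and by the difference of the two:

    DeltaCorr(i, j) = CorrPat(i, j) - CorrTher(i, j)

A positive DeltaCorr means the two patients' dynamics resemble each other
more than their therapists' do.  Per outcome class (poor-poor, good-good,
poor-good) the records are summarized with mean, sample SD, range and a
normal-approximation 95% confidence interval (mean +/- 1.96 * sd / sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markov import TransitionMatrix


class CompareError(ValueError):
    pass


def _cells(A: TransitionMatrix, B: TransitionMatrix, cell_policy: str) -> tuple[np.ndarray, np.ndarray]:
    if A.k != B.k:
        raise CompareError("matrices live on different state spaces")
    pa, pb = A.probs, B.probs
    if cell_policy == "both_defined":
        rows = A.defined_rows & B.defined_rows
        return pa[rows].ravel(), pb[rows].ravel()
    if cell_policy == "union_zero":
        return np.nan_to_num(pa).ravel(), np.nan_to_num(pb).ravel()
    raise CompareError(f"unknown cell_policy {cell_policy!r}")


def mtm_correlation(
    A: TransitionMatrix, B: TransitionMatrix, cell_policy: str = "both_defined"
) -> float:
    """Pearson correlation of two linearized transition matrices.

    ``both_defined`` (default) correlates only the rows defined in both
    matrices, avoiding manufactured zeros for structurally undefined rows;
    ``union_zero`` treats undefined rows as zeros over all k^2 cells.
    """
    a, b = _cells(A, B, cell_policy)
    if a.size < 3:
        raise CompareError("fewer than 3 comparable cells")
    if np.std(a) == 0 or np.std(b) == 0:
        raise CompareError("zero variance in a linearized matrix; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class DeltaCorrRecord:
    pair: tuple[str, str]
    corr_pat: float
    corr_ther: float
    delta: float
    class_label: str  # "poor-poor" | "good-good" | "poor-good"


def delta_corr(
    pat_a: TransitionMatrix,
    pat_b: TransitionMatrix,
    ther_a: TransitionMatrix,
    ther_b: TransitionMatrix,
    class_label: str = "",
    pair: tuple[str, str] = ("", ""),
    cell_policy: str = "both_defined",
) -> DeltaCorrRecord:
    """Patient-side minus therapist-side matrix correlation for one pair."""
    cp = mtm_correlation(pat_a, pat_b, cell_policy)
    ct = mtm_correlation(ther_a, ther_b, cell_policy)
    return DeltaCorrRecord(
        pair=pair, corr_pat=cp, corr_ther=ct, delta=cp - ct, class_label=class_label
    )


def pair_records(
    subjects: Sequence[tuple[str, str, TransitionMatrix, TransitionMatrix]],
    cell_policy: str = "both_defined",
) -> list[DeltaCorrRecord]:
    """DeltaCorr records over all unordered subject pairs.

    ``subjects`` holds (subject_id, outcome_class, patient_mtm,
    therapist_mtm) tuples; the class label of a pair is ``poor-poor``,
    ``good-good`` or ``poor-good``.
    """
    records = []
    for (ida, outa, pa, ta), (idb, outb, pb, tb) in combinations(subjects, 2):
        label = "-".join(sorted((outa, outb), reverse=True))  # poor before good
        records.append(
            delta_corr(pa, pb, ta, tb, class_label=label, pair=(ida, idb), cell_policy=cell_policy)
        )
    return records


@dataclass(frozen=True)
class ClassSummary:
    class_label: str
    field: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    ci95: tuple[float, float]


def normal_ci(mean: float, sd: float, n: int, z: float = 1.96) -> tuple[float, float]:
    half = z * sd / np.sqrt(n)
    return (mean - half, mean + half)


def class_summary(
    records: Iterable[DeltaCorrRecord], class_label: str, field: str = "delta"
) -> ClassSummary:
    """Mean / sample SD / range / normal 95% CI of one field within a class."""
    values = np.array(
        [getattr(r, field) for r in records if r.class_label == class_label], dtype=float
    )
    if values.size < 2:
        raise CompareError(f"need >= 2 records in class {class_label!r}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ClassSummary(
        class_label=class_label,
        field=field,
        n=int(values.size),
        mean=mean,
        sd=sd,
        minimum=float(values.min()),
        maximum=float(values.max()),
        ci95=normal_ci(mean, sd, values.size),
    )


def correlation_panel(
    matrices: Sequence[TransitionMatrix],
    ids: Sequence[str] | None = None,
    cell_policy: str = "both_defined",
) -> tuple[pd.DataFrame, dict]:
    """All pairwise matrix correlations plus the upper-triangle mean and SD."""
    m = len(matrices)
    if m < 2:
        raise CompareError("need at least 2 matrices")
    if ids is None:
        ids = [t.subject_id or f"m{i}" for i, t in enumerate(matrices)]
    r = np.ones((m, m))
    vals = []
    for i, j in combinations(range(m), 2):
        rij = mtm_correlation(matrices[i], matrices[j], cell_policy)
        r[i, j] = r[j, i] = rij
        vals.append(rij)
    vals = np.array(vals)
    panel = pd.DataFrame(r, index=list(ids), columns=list(ids))
    return panel, {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n_pairs": len(vals)}


def records_frame(records: Iterable[DeltaCorrRecord]) -> pd.DataFrame:
    """Tabular form of DeltaCorr records (one row per unordered pair)."""
    return pd.DataFrame(
        [
            {
                "subject_a": r.pair[0],
                "subject_b": r.pair[1],
                "class": r.class_label,
                "corr_pat": r.corr_pat,
                "corr_ther": r.corr_ther,
                "delta": r.delta,
            }
            for r in records
        ]
    )
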