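"""Non-stationarity tests: occupancy drift between the start and end of a series.

The symbolic sequence is split into its first and last thirds (each
floor(n/3) observations; the middle is discarded) and, per state, the two
occupancy counts are compared in a 2x2 contingency table with an odds ratio
and a chi-square test (Yates-corrected by default; uncorrected and Fisher
exact variants available).  A drift screen runs the test over every active
state, reporting raw p-values flagged at alpha plus a Benjamini-Hochberg
adjusted column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import StateSequence


class DriftError(ValueError):
    pass


def split_thirds(seq: StateSequence | Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Leading and trailing floor(n/3) labels; the middle is discarded."""
    labels = np.asarray(seq.labels if isinstance(seq, StateSequence) else seq, dtype=int)
    n = len(labels)
    if n < 6:
        raise DriftError("sequence too short to split into thirds (need >= 6)")
    m = n // 3
    return labels[:m], labels[-m:]


@dataclass(frozen=True)
class OddsRatioResult:
    subject_id: str
    role: str
    state: int
    a: int  # state count in first segment
    n1: int
    b: int  # state count in last segment
    n2: int
    odds_ratio: float  # NaN when a zero cell makes it undefined
    or_ci95: tuple[float, float]
    chi2: float
    p_value: float
    correction: str  # "none" | "yates" | "fisher"


def state_drift_test(
    first: Sequence[int],
    last: Sequence[int],
    state: int,
    correction: str = "yates",
    haldane: bool = False,
    subject_id: str = "",
    role: str = "",
) -> OddsRatioResult:
    """Odds ratio and test for one state's occupancy in first vs last segment.

    OR = a (n2 - b) / (b (n1 - a)) on the table ((a, n1-a), (b, n2-b)); its
    95% CI uses the log-OR normal approximation.  With a zero cell the OR is
    reported as undefined (NaN) unless ``haldane=True`` adds 0.5 to every
    cell.  ``correction``: "yates" (default), "none", or "fisher" (exact).
    """
    first = np.asarray(first, dtype=int)
    last = np.asarray(last, dtype=int)
    n1, n2 = len(first), len(last)
    if n1 == 0 or n2 == 0:
        raise DriftError("empty segment")
    a = int((first == state).sum())
    b = int((last == state).sum())
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)

    cells = table + 0.5 if haldane and (table == 0).any() else table
    if (cells == 0).any():
        odds_ratio = float("nan")
        ci = (float("nan"), float("nan"))
    else:
        odds_ratio = float(cells[0, 0] * cells[1, 1] / (cells[0, 1] * cells[1, 0]))
        se = float(np.sqrt((1.0 / cells).sum()))
        log_or = np.log(odds_ratio)
        ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))

    if correction == "fisher":
        res = stats.fisher_exact(table.astype(int))
        chi2, p = float("nan"), float(res.pvalue)
    elif correction in ("yates", "none"):
        if a + b == 0 or (n1 - a) + (n2 - b) == 0:
            chi2, p = 0.0, 1.0  # degenerate margin: no evidence of drift
        else:
            res = stats.chi2_contingency(table, correction=(correction == "yates"))
            chi2, p = float(res.statistic), float(res.pvalue)
    else:
        raise DriftError(f"unknown correction {correction!r}")

    return OddsRatioResult(
        subject_id=subject_id,
        role=role,
        state=state,
        a=a,
        n1=n1,
        b=b,
        n2=n2,
        odds_ratio=odds_ratio,
        or_ci95=ci,
        chi2=chi2,
        p_value=p,
        correction=correction,
    )


def drift_screen(
    seq: StateSequence,
    states: Sequence[int] | None = None,
    correction: str = "yates",
    alpha: float = 0.05,
    haldane: bool = False,
) -> pd.DataFrame:
    """Drift test over every active state of one sequence.

    Returns one row per state with the contingency counts, OR + CI, chi2, raw
    p (flagged at ``alpha``, mirroring how such screens are usually reported)
    and a Benjamini-Hochberg adjusted p column.
    """
    first, last = split_thirds(seq)
    if states is None:
        states = sorted(np.unique(seq.labels).tolist())
    results = [
        state_drift_test(
            first,
            last,
            s,
            correction=correction,
            haldane=haldane,
            subject_id=seq.subject_id,
            role=seq.role,
        )
        for s in states
    ]
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "role": r.role,
                "state": r.state,
                "first_count": r.a,
                "first_n": r.n1,
                "last_count": r.b,
                "last_n": r.n2,
                "odds_ratio": r.odds_ratio,
                "or_ci_low": r.or_ci95[0],
                "or_ci_high": r.or_ci95[1],
                "chi2": r.chi2,
                "p_value": r.p_value,
                "correction": r.correction,
            }
            for r in results
        ]
    )
    frame["significant"] = frame["p_value"] < alpha
    frame["p_bh"] = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")[1]
    return frame
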