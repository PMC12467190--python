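"""Reader-study (Likert) statistics.

Six raters scored denoised images on nine questions using a 5-point Likert
scale (1 = lowest, 5 = highest, 3 = neutral).  Published reader studies
often report only summary rows (mean, SD, median, IQR) rather than raw
scores; because the scores are small integer multisets, the raw data can
be recovered *exactly* by exhaustive search: for n = 6 raters there are
only C(10, 4) = 210 multisets of {1..5}, and a summary is accepted when
every statistic, rounded half-up at its printed precision, matches.

Downstream statistics per question: one-sample two-sided t-test of the
mean against the neutral midpoint 3, Cohen's d = (mean - 3)/SD, the 95%
confidence half-width t_{0.975, n-1} * SD/sqrt(n), and step-down
Holm-Bonferroni adjustment of the raw p-values across all questions
jointly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LikertSummary",
    "QuestionResult",
    "TABLE_SUMMARIES",
    "reconstruct_scores",
    "summarize_scores",
    "one_sample_t",
    "cohens_d",
    "holm_adjust",
    "ci95",
    "analyze_table",
    "results_to_frame",
]

NEUTRAL = 3.0


class ReconstructionError(ValueError):
    """No or multiple score multisets match a printed summary."""


@dataclass(frozen=True)
class LikertSummary:
    """Printed per-question summary row."""

    question_id: str
    mean: float
    sd: float
    median: float
    iqr: float
    n: int = 6

    def __post_init__(self) -> None:
        if not (1.0 <= self.mean <= 5.0):
            raise ValueError(f"{self.question_id}: mean must be in [1, 5]")
        if self.sd < 0:
            raise ValueError(f"{self.question_id}: sd must be >= 0")
        if self.n < 2:
            raise ValueError(f"{self.question_id}: need n >= 2 raters")


@dataclass(frozen=True)
class QuestionResult:
    question_id: str
    scores: tuple[int, ...]
    t: float
    df: int
    p_raw: float
    p_holm: float
    d: float
    se: float
    ci_low: float
    ci_high: float
    ci_width: float  # half-width, as reported


#: The published nine-question summary rows (6 raters each).
TABLE_SUMMARIES: tuple[LikertSummary, ...] = (
    LikertSummary("Q1", 4.5, 0.55, 4.5, 1.0),
    LikertSummary("Q2", 4.5, 0.55, 4.5, 1.0),
    LikertSummary("Q3", 4.67, 0.52, 5.0, 0.75),
    LikertSummary("Q4", 4.5, 0.84, 5.0, 0.75),
    LikertSummary("Q5", 4.33, 0.52, 4.0, 0.75),
    LikertSummary("Q6", 4.33, 0.52, 4.0, 0.75),
    LikertSummary("Q7", 3.83, 0.41, 4.0, 0.0),
    LikertSummary("Q8", 3.83, 0.75, 4.0, 0.75),
    LikertSummary("Q9", 4.83, 0.41, 5.0, 0.0),
)


def _decimals(x: float) -> int:
    """Matching precision for a printed summary value.

    Fractional values match at their printed number of decimals.  Integral
    values (a median of 5, an IQR of 0) are treated as exact at 2 decimals:
    on the quarter/sixth grids these statistics live on, an integer entry
    can only arise from the exact value, and integer-precision matching
    would make most summaries ambiguous.
    """
    if float(x) == int(x):
        return 2
    return len(repr(float(x)).split(".")[1])


def _round_half_up(x: float, nd: int) -> float:
    return math.floor(x * 10**nd + 0.5) / 10**nd


def _iqr(values: np.ndarray) -> float:
    # linear interpolation of order statistics (the numpy default)
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def summarize_scores(question_id: str, scores: tuple[int, ...], nd: int = 2) -> LikertSummary:
    """Summary row for a score multiset, rounded half-up to nd decimals."""
    arr = np.asarray(scores, dtype=float)
    return LikertSummary(
        question_id,
        mean=_round_half_up(float(arr.mean()), nd),
        sd=_round_half_up(float(arr.std(ddof=1)), nd),
        median=_round_half_up(float(np.median(arr)), nd),
        iqr=_round_half_up(_iqr(arr), nd),
        n=len(scores),
    )


def reconstruct_scores(summary: LikertSummary) -> tuple[int, ...]:
    """Recover the unique integer score multiset behind a summary row.

    Exhaustively enumerates every multiset of ``n`` values from {1..5} and
    keeps those whose mean, sample SD, median and IQR all round (half-up,
    at each statistic's printed precision) to the summary values.  Raises
    :class:`ReconstructionError` if no or several multisets match.
    """
    if summary.n > 12:
        raise ValueError("exhaustive reconstruction is limited to n <= 12 raters")
    targets = {
        "mean": (summary.mean, _decimals(summary.mean)),
        "sd": (summary.sd, _decimals(summary.sd)),
        "median": (summary.median, _decimals(summary.median)),
        "iqr": (summary.iqr, _decimals(summary.iqr)),
    }
    matches = []
    for combo in itertools.combinations_with_replacement(range(1, 6), summary.n):
        arr = np.asarray(combo, dtype=float)
        stats_ = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "median": float(np.median(arr)),
            "iqr": _iqr(arr),
        }
        if all(_round_half_up(stats_[k], nd) == v for k, (v, nd) in targets.items()):
            matches.append(combo)
    if not matches:
        raise ReconstructionError(f"{summary.question_id}: no score multiset matches the summary")
    if len(matches) > 1:
        raise ReconstructionError(
            f"{summary.question_id}: ambiguous summary, candidates {matches}"
        )
    return matches[0]


def one_sample_t(scores, mu0: float = NEUTRAL) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of the mean against mu0: (t, df, p)."""
    arr = np.asarray(scores, dtype=float)
    if arr.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    res = stats.ttest_1samp(arr, popmean=mu0)
    return float(res.statistic), int(res.df), float(res.pvalue)


def cohens_d(scores, mu0: float = NEUTRAL) -> float:
    """Standardised effect size (mean - mu0) / SD (sample SD)."""
    arr = np.asarray(scores, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("Cohen's d undefined for zero standard deviation")
    return float((arr.mean() - mu0) / sd)


def holm_adjust(p_raw: list[float], variant: str = "standard") -> list[float]:
    """Holm-Bonferroni adjustment of k p-values, returned in input order.

    ``variant="standard"`` is the step-down procedure: sort ascending,
    multiply the i-th smallest by (k - i + 1), enforce monotonicity by a
    running maximum, cap at 1.

    ``variant="tie-averaged"`` multiplies each p by (k - rank + 1) with
    *average* ranks over ties and applies no monotonicity pass.  This is
    not a proper step-down procedure, but it is what several spreadsheet
    and point-and-click implementations emit for tied p-values, and it is
    the convention behind the published reader-study table this package
    reproduces.  Both variants agree whenever all p-values are distinct
    and the monotonicity pass is inactive — in particular for the smallest
    p-value.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) == 1:
        return [float(p[0])]
    if variant == "standard":
        _, adjusted, _, _ = multipletests(p, method="holm")
    elif variant == "tie-averaged":
        ranks = stats.rankdata(p, method="average")
        adjusted = np.minimum(p * (len(p) - ranks + 1), 1.0)
    else:
        raise ValueError(f"unknown Holm variant {variant!r}")
    return [float(x) for x in adjusted]


def ci95(scores) -> tuple[float, float, float, float]:
    """95% CI of the mean: (low, high, half_width, se).

    The reported "CI width" is the half-width t_{0.975, n-1} * se, with
    bounds mean -/+ half-width.
    """
    arr = np.asarray(scores, dtype=float)
    n = len(arr)
    if n < 2:
        raise ValueError("need at least 2 scores")
    se = float(arr.std(ddof=1) / math.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1) * se)
    mean = float(arr.mean())
    return mean - half, mean + half, half, se


def analyze_table(
    summaries: list[LikertSummary] | None = None,
    raw_scores: dict[str, tuple[int, ...]] | None = None,
    mu0: float = NEUTRAL,
    holm_variant: str = "standard",
) -> list[QuestionResult]:
    """Full reader-study pipeline over all questions.

    Scores are reconstructed from summaries unless given directly; the
    Holm adjustment runs jointly across every question's unrounded raw p
    (see :func:`holm_adjust` for the two tie conventions).
    """
    if (summaries is None) == (raw_scores is None):
        raise ValueError("provide exactly one of summaries or raw_scores")
    if summaries is not None:
        if not summaries:
            raise ValueError("need at least one question")
        scores = {s.question_id: reconstruct_scores(s) for s in summaries}
    else:
        if not raw_scores:
            raise ValueError("need at least one question")
        scores = dict(raw_scores)

    stats_per_q = {}
    for qid, sc in scores.items():
        try:
            t, df, p = one_sample_t(sc, mu0)
            d = cohens_d(sc, mu0)
            lo, hi, half, se = ci95(sc)
        except ValueError as exc:
            raise ValueError(f"{qid}: {exc}") from exc
        stats_per_q[qid] = (t, df, p, d, lo, hi, half, se)

    qids = list(scores)
    p_holm = holm_adjust([stats_per_q[q][2] for q in qids], variant=holm_variant)
    results = []
    for qid, ph in zip(qids, p_holm):
        t, df, p, d, lo, hi, half, se = stats_per_q[qid]
        results.append(
            QuestionResult(
                question_id=qid,
                scores=tuple(scores[qid]),
                t=t,
                df=df,
                p_raw=p,
                p_holm=ph,
                d=d,
                se=se,
                ci_low=lo,
                ci_high=hi,
                ci_width=half,
            )
        )
    return results


def results_to_frame(results: list[QuestionResult]) -> pd.DataFrame:
    """Summary table, one column per question, rows mirroring the published
    layout (mean/median/SD/IQR/SE/critical t/CI/t/p/Holm p/d)."""
    cols = {}
    for r in results:
        arr = np.asarray(r.scores, dtype=float)
        crit_t = stats.t.ppf(0.975, r.df)
        cols[r.question_id] = {
            "mean": arr.mean(),
            "median": float(np.median(arr)),
            "sd": arr.std(ddof=1),
            "iqr": _iqr(arr),
            "se": r.se,
            "critical_t": crit_t,
            "ci_width": r.ci_width,
            "ci_min": r.ci_low,
            "ci_max": r.ci_high,
            "t": r.t,
            "p_raw": r.p_raw,
            "p_holm": r.p_holm,
            "cohens_d": r.d,
        }
    return pd.DataFrame(cols)
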