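"""Interobserver agreement statistics for paired interface-height judgments.

Surgeons judge the fluid/gas interface height through the dilated pupil;
patients judge it from their own visual field on the in-app chart. Agreement
between the two index-matched series is assessed with the Bland-Altman
method (bias and 95% limits of agreement of the paired differences,
surgeon - patient) and the Wilcoxon matched-pairs signed-rank test.
Descriptive summaries use median (range); Likert usability responses are
tabulated as counts and proportions per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DomainError, InsufficientDataError

__all__ = [
    "PairedJudgments",
    "AgreementReport",
    "WilcoxonResult",
    "LikertSummary",
    "bland_altman",
    "wilcoxon_signed_rank",
    "summarize",
    "tabulate_likert",
    "bland_altman_plot",
]

#: largest number of nonzero differences for which the exact null is enumerated
EXACT_LIMIT = 25


@dataclass(frozen=True)
class PairedJudgments:
    """Index-matched surgeon and patient interface heights, in percent."""

    surgeon: tuple[float, ...]
    patient: tuple[float, ...]

    def __init__(self, surgeon: Sequence[float], patient: Sequence[float]):
        s = tuple(float(x) for x in surgeon)
        p = tuple(float(x) for x in patient)
        if len(s) != len(p):
            raise DomainError(
                f"surgeon and patient series must have equal length, "
                f"got {len(s)} and {len(p)}"
            )
        if len(s) < 2:
            raise InsufficientDataError(
                f"at least 2 pairs are required, got {len(s)}"
            )
        for name, vals in (("surgeon", s), ("patient", p)):
            bad = [v for v in vals if not (0.0 <= v <= 100.0)]
            if bad:
                raise DomainError(
                    f"{name} values must lie in [0, 100] percent, got {bad[0]!r}"
                )
        object.__setattr__(self, "surgeon", s)
        object.__setattr__(self, "patient", p)

    @property
    def n(self) -> int:
        return len(self.surgeon)

    def differences(self) -> np.ndarray:
        """Paired differences, surgeon - patient."""
        return np.asarray(self.surgeon) - np.asarray(self.patient)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias and limits of agreement, all in percent."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    multiplier: float = 1.96

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "multiplier": self.multiplier,
        }


def bland_altman(pairs: PairedJudgments, multiplier: float = 1.96) -> AgreementReport:
    """Bland-Altman agreement of paired judgments.

    bias = mean(surgeon - patient); sd_diff uses the n-1 denominator;
    limits of agreement are bias +/- multiplier * sd_diff (1.96 for the
    conventional 95% band).
    """
    d = pairs.differences()
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        n=pairs.n,
        multiplier=multiplier,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided Wilcoxon signed-rank outcome.

    ``statistic`` is W+, the sum of ranks of positive differences among the
    ``n_nonzero`` retained pairs. ``degenerate`` marks the all-zero case,
    for which p = 1 by convention.
    """

    p_value: float
    statistic: float
    n_nonzero: int
    method: str
    degenerate: bool = False


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    # Enumerate the null distribution of W+ over all 2^n sign assignments by
    # dynamic programming on doubled ranks (average ranks are half-integers).
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    # Normal approximation with continuity correction and tie correction.
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    dev = abs(w_plus - mean)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_signed_rank(
    pairs: PairedJudgments,
    method: Literal["auto", "exact", "approx"] = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on surgeon - patient.

    Zero differences are dropped (Wilcoxon's method); tied absolute
    differences receive average ranks. With "auto", the exact null
    distribution is enumerated for up to 25 nonzero differences and the
    normal approximation with continuity correction is used above. If every
    difference is zero the result is flagged degenerate with p = 1.
    """
    d = pairs.differences()
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(
            p_value=1.0, statistic=0.0, n_nonzero=0, method="degenerate",
            degenerate=True,
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "approx"
    if method == "exact":
        if n > EXACT_LIMIT:
            raise DomainError(
                f"exact enumeration supports at most {EXACT_LIMIT} nonzero "
                f"differences, got {n}"
            )
        p = _exact_two_sided_p(ranks, w_plus)
    elif method == "approx":
        p = _approx_two_sided_p(ranks, w_plus)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(p_value=p, statistic=w_plus, n_nonzero=n, method=method)


def summarize(values: Sequence[float]) -> dict:
    """Median / min / max summary of a nonempty numeric series."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("cannot summarize an empty series")
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


@dataclass(frozen=True)
class LikertSummary:
    """Counts and proportions of 5-point Likert responses."""

    counts: dict[int, int]
    proportions: dict[int, float]
    n: int


def tabulate_likert(responses: Sequence[int]) -> LikertSummary:
    """Tabulate 1-5 Likert responses; out-of-range values report their index."""
    counts = {level: 0 for level in range(1, 6)}
    for i, r in enumerate(responses):
        r_int = int(r)
        if r_int != r or not 1 <= r_int <= 5:
            raise DomainError(
                f"Likert response at index {i} must be an integer in 1..5, got {r!r}"
            )
        counts[r_int] += 1
    n = sum(counts.values())
    proportions = {
        level: (c / n if n else 0.0) for level, c in counts.items()
    }
    return LikertSummary(counts=counts, proportions=proportions, n=n)


def bland_altman_plot(pairs: PairedJudgments, path, multiplier: float = 1.96):
    """Difference-vs-mean scatter with bias and limits-of-agreement lines.

    Writes SVG or PNG according to the file extension and returns the
    :class:`AgreementReport` used for the overlay lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(pairs, multiplier=multiplier)
    means = (np.asarray(pairs.surgeon) + np.asarray(pairs.patient)) / 2.0
    diffs = pairs.differences()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(report.bias, color="black", lw=1.2, label=f"bias {report.bias:.2f}%")
    for loa in (report.loa_low, report.loa_high):
        ax.axhline(loa, color="black", lw=1.0, ls="--")
    ax.set_xlabel("Mean of surgeon and patient judgment (%)")
    ax.set_ylabel("Surgeon - patient difference (%)")
    ax.set_title("Bland-Altman agreement of interface-height judgments")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
    return report
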