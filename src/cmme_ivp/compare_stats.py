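"""Paired sedation-effect analytics.

Centrepiece: an exact Wilcoxon matched-pairs signed-rank test with the
matched-pairs rank-biserial correlation

    rc = (W+ - W-) / (W+ + W-),

the effect size printed alongside each paired comparison (|rc| cutoffs
0.1 / 0.4 / 0.6 for small / medium / large).  Differences are taken as
``first argument - second`` (baseline - post), so a uniform decrease
after treatment gives rc = +1.  Zero differences are dropped
(Wilcoxon's convention; Pratt's zero-rank method available by flag),
|differences| are midranked, and the two-sided p is exact — the doubled
smaller tail of the full sign-pattern null distribution, computed by
dynamic programming over doubled midranks — for up to 20 effective
pairs, falling back to the normal approximation with continuity and tie
corrections beyond that.

Supporting routines (Spearman, Shapiro-Wilk, Fisher's exact) delegate
to scipy's implementations of the identical classical procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cmm_io import PairedTable, ValidationError

__all__ = [
    "WilcoxonResult", "wilcoxon_signed_rank", "rank_biserial",
    "classify_effect", "spearman", "shapiro_wilk", "fisher_exact_2x2",
    "paired_report", "correlation_report", "RC_CUTOFFS", "EXACT_N_MAX",
]

RC_CUTOFFS = (0.1, 0.4, 0.6)
#: largest n_effective for which the exact null distribution is enumerated
EXACT_N_MAX = 20


@dataclass(frozen=True)
class WilcoxonResult:
    n_effective: int
    w_plus: float
    w_minus: float
    p_two_sided: float
    method: str                  # "exact" | "normal_approx" | "degenerate"
    rc: float
    effect_class: str
    zero_method: str = "wilcox"

    def __post_init__(self) -> None:
        # with Wilcoxon's zero handling the effective ranks are 1..n_eff
        if self.method != "degenerate" and self.zero_method == "wilcox":
            expect = self.n_effective * (self.n_effective + 1) / 2
            if abs(self.w_plus + self.w_minus - expect) > 1e-9:
                raise ValidationError("rank sums inconsistent with n_effective")


def rank_biserial(w_plus: float, w_minus: float) -> float:
    """Matched-pairs rank-biserial correlation (W+ - W-) / (W+ + W-)."""
    tot = w_plus + w_minus
    if tot <= 0:
        raise ValidationError("rank sums must be positive")
    return (w_plus - w_minus) / tot


def classify_effect(rc: float, cutoffs: tuple[float, float, float] = RC_CUTOFFS) -> str:
    """negligible < 0.1 <= small < 0.4 <= medium < 0.6 <= large, on |rc|."""
    a = abs(rc)
    if a > 1 + 1e-12:
        raise ValidationError("|rc| cannot exceed 1")
    lo, mid, hi = cutoffs
    if a < lo:
        return "negligible"
    if a < mid:
        return "small"
    if a < hi:
        return "medium"
    return "large"


def _exact_tail_counts(ranks2: np.ndarray) -> np.ndarray:
    """Null counts of 2*W+ over all sign patterns, by DP convolution.

    ``ranks2`` are doubled midranks (integers), so W+ lives on a half-
    integer lattice made integral by doubling.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(baseline, post, zero_method: str = "wilcox") -> WilcoxonResult:
    """Exact Wilcoxon matched-pairs signed-rank test on d = baseline - post.

    Parameters
    ----------
    baseline, post
        Equal-length paired samples.
    zero_method
        "wilcox" (default) drops zero differences; "pratt" ranks them
        with the rest and then drops their rank contribution.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(post, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("baseline and post must be equal-length 1-D, n >= 1")
    if zero_method not in ("wilcox", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    d = x - y
    if np.all(d == 0):
        return WilcoxonResult(n_effective=0, w_plus=0.0, w_minus=0.0,
                              p_two_sided=1.0, method="degenerate",
                              rc=0.0, effect_class="negligible",
                              zero_method=zero_method)
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
    else:  # pratt: rank zeros too, then discard them
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    n_eff = d.size
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    rc = rank_biserial(w_plus, w_minus)

    if n_eff <= EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_tail_counts(ranks2)
        n_patterns = 2.0 ** n_eff
        w2 = int(round(2 * min(w_plus, w_minus)))
        # distribution is symmetric; doubled lower tail of the smaller sum
        p = min(1.0, 2.0 * float(counts[:w2 + 1].sum()) / n_patterns)
        method = "exact"
    else:
        mu = n_eff * (n_eff + 1) / 4.0
        # tie correction over groups of tied |d|
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term
        w = min(w_plus, w_minus)
        z = (w - mu + 0.5) / np.sqrt(var)    # continuity-corrected lower tail
        p = min(1.0, 2.0 * float(stats.norm.cdf(z)))
        method = "normal_approx"
    return WilcoxonResult(n_effective=n_eff, w_plus=w_plus, w_minus=w_minus,
                          p_two_sided=p, method=method, rc=rc,
                          effect_class=classify_effect(rc),
                          zero_method=zero_method)


# ---------------------------------------------------------------------------
# supporting classical tests
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks; t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("spearman needs equal-length samples, n >= 3")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's algorithm via scipy).

    Used as a reported gate on distributional shape only; it never
    switches downstream methods silently.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValidationError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (hypergeometric sum)."""
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValidationError("cells must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# report emitters
# ---------------------------------------------------------------------------

def paired_report(paired: PairedTable, variables: list[str] | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable paired summary (the study's Table-1 analogue).

    Median and min-max range per condition, exact Wilcoxon p, rank-
    biserial rc with class, and a significance flag at ``alpha``.
    """
    if variables is None:
        variables = paired.variables()
    rows = []
    for var in variables:
        base, post = paired.pairs_for(var)
        res = wilcoxon_signed_rank(base, post)
        rows.append({
            "variable": var,
            "baseline_median": float(np.median(base)),
            "baseline_min": float(base.min()), "baseline_max": float(base.max()),
            "post_median": float(np.median(post)),
            "post_min": float(post.min()), "post_max": float(post.max()),
            "p_value": res.p_two_sided,
            "method": res.method,
            "rc": res.rc,
            "effect_class": res.effect_class,
            "significant": res.p_two_sided < alpha,
        })
    return pd.DataFrame(rows)


def correlation_report(conventional: pd.DataFrame, cmme: pd.DataFrame) -> pd.DataFrame:
    """Spearman r_s and p for every conventional x CMME variable pair.

    Both inputs are wide per-subject frames (rows aligned on the same
    index, e.g. goat x condition); the output is the study's Table-3
    analogue in long form.
    """
    joined = conventional.join(cmme, how="inner", lsuffix="_conv", rsuffix="_cmme")
    if len(joined) < 3:
        raise ValidationError("correlation needs >= 3 aligned subjects")
    rows = []
    for cv in conventional.columns:
        for mv in cmme.columns:
            xcol = cv if cv in joined.columns else f"{cv}_conv"
            ycol = mv if mv in joined.columns else f"{mv}_cmme"
            r, p = spearman(joined[xcol].to_numpy(), joined[ycol].to_numpy())
            rows.append({"conventional": cv, "cmme": mv, "r_s": r, "p_value": p})
    return pd.DataFrame(rows)
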