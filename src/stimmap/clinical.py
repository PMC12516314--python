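"""Clinical score processing: percentage change, response categories,
UPDRS rescaling, Wilcoxon signed-rank tests, cohort summaries.

Motor outcomes are always analysed as percentage change from baseline, so
cohorts rated on UPDRS III and MDS-UPDRS III can be pooled without mixing
the two scales' absolute point ranges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_change",
    "classify_response",
    "RESPONSE_CATEGORIES",
    "rescale_updrs",
    "wilcoxon_signed_rank",
    "cohort_summary",
]

RESPONSE_CATEGORIES = ("excellent", "good", "medium", "non-responder", "worsening")

# category boundaries in % improvement; printed clinical bins overlap at the
# edges, so the convention is fixed here: left-closed up to "good", which is
# closed at 70 because "excellent" is strictly > 70.
DEFAULT_BOUNDARIES = {"non_responder_max": 15.0, "medium_max": 50.0, "good_max": 70.0}


def percent_change(pre: float, post: float) -> float:
    """Percentage improvement 100*(pre - post)/pre; positive = improvement."""
    if pre <= 0:
        raise ValueError(f"baseline score must be > 0, got {pre}")
    return 100.0 * (pre - post) / pre


def classify_response(pct: float, boundaries: dict | None = None) -> str:
    """Map a percentage improvement to one of five response categories.

    worsening: pct < 0; non-responder: [0, 15); medium: [15, 50);
    good: [50, 70]; excellent: > 70.
    """
    if not np.isfinite(pct):
        raise ValueError(f"percentage change must be finite, got {pct}")
    b = {**DEFAULT_BOUNDARIES, **(boundaries or {})}
    if pct < 0:
        return "worsening"
    if pct < b["non_responder_max"]:
        return "non-responder"
    if pct < b["medium_max"]:
        return "medium"
    if pct <= b["good_max"]:
        return "good"
    return "excellent"


def rescale_updrs(mean_item_score: float, n_items: int = 33) -> float:
    """Rescale a per-item mean UPDRS III score to the MDS-UPDRS III range.

    Multiplying the normalized (per-item) score by the MDS scale's item
    count (33) makes baselines from the two scales comparable.
    """
    if mean_item_score < 0:
        raise ValueError(f"mean item score must be >= 0, got {mean_item_score}")
    return float(mean_item_score) * n_items


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float, tail: str) -> float:
    """Exact signed-rank tail probability by convolution over sign patterns.

    Conditional on the observed (mid-)ranks, the null distributes each sign
    independently; the generating polynomial of W+ is prod_i (1 + x^{r_i}).
    Mid-ranks from ties are half-integers, so everything is doubled to work
    on an integer lattice.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    poly /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_ge = float(poly[w2:].sum())
    p_le = float(poly[: w2 + 1].sum())
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(diffs, tail: str = "two-sided", exact_max_n: int = 25) -> float:
    """Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped (classic treatment); ties get mid-ranks.
    For n <= ``exact_max_n`` the null distribution is enumerated exactly,
    conditional on the observed ranks; above that a normal approximation
    with tie correction and continuity correction is used.

    ``tail``: "two-sided", "greater" (median > 0) or "less".
    """
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"tail must be 'two-sided', 'greater' or 'less', got {tail!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: the signed-rank test carries no information")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus, tail)
    res = stats.wilcoxon(d, alternative=tail, method="approx", correction=True)
    return float(res.pvalue)


REQUIRED_SUMMARY_COLUMNS = ("subject_id", "state", "score_pre", "score_post", "pct_improvement")


def cohort_summary(table: pd.DataFrame, state: str = "MED-OFF") -> dict:
    """Descriptive cohort summary for one medication state.

    Returns mean/SD/median percentage improvement (sample SD, n-1),
    baseline score mean/SD, response-category counts, and percentage LED /
    CDRS changes when those columns are present.
    """
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    sub = table[table["state"] == state]
    if sub.empty:
        raise ValueError(f"no rows with state {state!r}")
    pct = sub["pct_improvement"].to_numpy(dtype=float)
    categories = [classify_response(p) for p in pct]
    counts = {cat: int(sum(c == cat for c in categories)) for cat in RESPONSE_CATEGORIES}
    summary = {
        "state": state,
        "n": int(len(sub)),
        "pct_improvement_mean": float(np.mean(pct)),
        "pct_improvement_sd": float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0,
        "pct_improvement_median": float(np.median(pct)),
        "baseline_mean": float(sub["score_pre"].mean()),
        "baseline_sd": float(sub["score_pre"].std(ddof=1)) if len(sub) > 1 else 0.0,
        "response_counts": counts,
    }
    for label, pre_col, post_col in (
        ("led", "led_pre", "led_post"),
        ("cdrs", "cdrs_pre", "cdrs_post"),
    ):
        if pre_col in sub.columns and post_col in sub.columns and sub[pre_col].notna().all():
            change = 100.0 * (sub[pre_col] - sub[post_col]) / sub[pre_col]
            summary[f"{label}_pct_change_mean"] = float(change.mean())
            summary[f"{label}_pct_change_sd"] = float(change.std(ddof=1))
    return summary
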