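"""TF expression versus motif-peak accessibility correlation.

For every expressed TF and every peak containing its motif, Pearson r is
computed over the matched timepoints (days 0, 1, 2, 3, 5; expression is
replicate-mean, GFP+ branch at days 4/5, accessibility has no day 4).
Per TAD class, each TF's correlations are split by sign and each side is
compared with the same TF's correlations in housekeeping-TAD peaks by a
two-sided Wilcoxon rank-sum test; a TF is called activator-like when the
median positive-side r clears the threshold with a significant test, and
repressor-like for the mirror image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "matched_trajectories",
    "correlate",
    "call_regulators",
    "RegulatorCall",
]

MATCH_DAYS = [0, 1, 2, 3, 5]


def tf_day_expression(
    cm: CountMatrix, tfs: list[str], normalized: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Replicate-mean normalized expression per TF over the matched days."""
    from .expression import normalize

    norm = normalize(cm) if normalized is None else normalized
    cols = {}
    for day in MATCH_DAYS:
        gfp = "positive" if day >= 4 else None
        ids = cm.samples_where(day=day, gfp=gfp)
        if not ids:
            raise ValueError(f"expression missing day {day}" + (" GFP+" if gfp else ""))
        cols[f"d{day}"] = norm[ids].mean(axis=1)
    df = pd.DataFrame(cols)
    present = [t for t in tfs if t in df.index]
    return df.loc[present]


def matched_trajectories(
    tf_expr: pd.DataFrame,
    accessibility: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Join (tf, peak) pairs with their matched expression/accessibility
    vectors; constant-accessibility pairs are dropped (counted in the log).

    ``pairs`` needs columns tf, peak_id; accessibility is the normalized
    peak x day matrix with columns d0..d5 (no d4).
    """
    day_cols = [f"d{d}" for d in MATCH_DAYS]
    missing = [c for c in day_cols if c not in accessibility.columns]
    if missing or len(day_cols) < 4:
        raise ValueError(f"accessibility missing day columns {missing}")
    keep = []
    dropped = 0
    for _, row in pairs.iterrows():
        tf, pid = row["tf"], row["peak_id"]
        if tf not in tf_expr.index or pid not in accessibility.index:
            continue
        acc = accessibility.loc[pid, day_cols].to_numpy(float)
        if np.ptp(acc) == 0 or np.ptp(tf_expr.loc[tf, day_cols].to_numpy(float)) == 0:
            dropped += 1
            continue
        keep.append((tf, pid))
    if dropped:
        logger.info("dropped %d constant (tf, peak) trajectory pairs", dropped)
    return pd.DataFrame(keep, columns=["tf", "peak_id"])


def correlate(
    tf_expr: pd.DataFrame,
    accessibility: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r per matched (tf, peak) pair."""
    day_cols = [f"d{d}" for d in MATCH_DAYS]
    rows = []
    for _, row in pairs.iterrows():
        e = tf_expr.loc[row["tf"], day_cols].to_numpy(float)
        a = accessibility.loc[row["peak_id"], day_cols].to_numpy(float)
        r = stats.pearsonr(e, a).statistic
        rows.append((row["tf"], row["peak_id"], float(r)))
    return pd.DataFrame(rows, columns=["tf", "peak_id", "r"])


@dataclass
class RegulatorCall:
    tf: str
    median_pos_r: float
    median_neg_r: float
    p_pos: float
    p_neg: float
    call: str  # activator_like | repressor_like | none
    n_pos: int
    n_neg: int


def call_regulators(
    corr: pd.DataFrame,
    background: pd.DataFrame,
    thresholds: Thresholds | None = None,
    min_side: int = 5,
) -> list[RegulatorCall]:
    """Per-TF activator/repressor calls against a background distribution.

    ``corr`` and ``background`` are correlation tables (tf, peak_id, r);
    the background is typically the same TFs' correlations in housekeeping
    TADs.  Each sign side is tested (two-sided Wilcoxon rank-sum) against
    the background's same-sign side.
    """
    th = thresholds or Thresholds()
    out = []
    for tf, grp in corr.groupby("tf"):
        r = grp["r"].to_numpy()
        bg = background.loc[background["tf"] == tf, "r"].to_numpy()
        pos, neg = r[r > 0], r[r < 0]
        bg_pos, bg_neg = bg[bg > 0], bg[bg < 0]
        med_pos = float(np.median(pos)) if len(pos) else np.nan
        med_neg = float(np.median(neg)) if len(neg) else np.nan
        p_pos = _ranksum(pos, bg_pos)
        p_neg = _ranksum(neg, bg_neg)
        call = "none"
        if len(pos) >= min_side and med_pos > th.corr_call_threshold and p_pos < th.corr_call_p:
            call = "activator_like"
        if len(neg) >= min_side and med_neg < -th.corr_call_threshold and p_neg < th.corr_call_p:
            # a TF passing both gates would be ambiguous; keep the stronger side
            if call == "none" or len(neg) > len(pos):
                call = "repressor_like"
        if call == "none" and (len(pos) < min_side and len(neg) < min_side):
            logger.info("TF %s: too few correlations on both sides, call none", tf)
        out.append(
            RegulatorCall(
                tf=tf,
                median_pos_r=med_pos,
                median_neg_r=med_neg,
                p_pos=p_pos,
                p_neg=p_neg,
                call=call,
                n_pos=len(pos),
                n_neg=len(neg),
            )
        )
    return out


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        return 1.0
    return float(stats.ranksums(x, y).pvalue)


def permutation_background(
    tf_expr: pd.DataFrame,
    accessibility: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Second null: timepoint labels of expression shuffled per permutation.

    Returns a correlation table pooling all permutations (columns tf,
    peak_id, r), usable as an alternative background for calls.
    """
    rng = np.random.default_rng(seed)
    day_cols = [f"d{d}" for d in MATCH_DAYS]
    rows = []
    per_perm = min(50, max(1, len(pairs)))  # cap work per permutation
    for _ in range(n_perm):
        perm = rng.permutation(len(day_cols))
        sub = pairs.sample(n=min(per_perm, len(pairs)), random_state=int(rng.integers(2**31)))
        for _, row in sub.iterrows():
            e = tf_expr.loc[row["tf"], day_cols].to_numpy(float)[perm]
            a = accessibility.loc[row["peak_id"], day_cols].to_numpy(float)
            if np.ptp(e) == 0 or np.ptp(a) == 0:
                continue
            rows.append((row["tf"], row["peak_id"], float(stats.pearsonr(e, a).statistic)))
    return pd.DataFrame(rows, columns=["tf", "peak_id", "r"])
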