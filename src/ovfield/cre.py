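"""Candidate cis-regulatory element prioritization within a gene's TAD.

For a target gene, the change matrix holds, per peak in the gene's TAD (or
inter-TAD gap) region, the change between two days in the median occurrence
footprint score of each key TF motif, alongside the accessibility change
and signed TSS distance.  Candidates are ranked by the sum of positive
key-TF changes (absent motifs contribute 0), tie-broken by accessibility
change then proximity to the TSS.  A deletion interval minimally covers the
selected motif instances, padded and clipped to the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KEY_TFS",
    "change_matrix",
    "rank_candidates",
    "deletion_interval",
    "perturbation_compare",
]

KEY_TFS = ["Rax", "Pax6", "Lhx2", "Sox2", "Otx2", "Tcf3", "Tcf7", "Tcf7l2"]


def change_matrix(
    gene: str,
    scores: pd.DataFrame,
    region_table,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    accessibility: pd.DataFrame,
    day_a: int = 3,
    day_b: int = 5,
    key_tfs: list[str] | None = None,
) -> pd.DataFrame:
    """Peak x key-TF matrix of median occurrence-score changes B - A.

    Rows are restricted to peaks in the target gene's region; cells without
    an occurrence of the TF are NaN (flagged absent).  Side columns:
    d_atac (accessibility change) and tss_distance (peak midpoint to the
    target TSS, signed by gene strand).
    """
    key_tfs = key_tfs or KEY_TFS
    region = region_table.gene_region.get(gene)
    if region is None:
        raise ValueError(f"gene {gene!r} has no region assignment")
    pids = [
        int(p) for p, r in region_table.peak_region.items() if r == region
    ]
    if not pids:
        logger.warning("gene %s: no peaks in region %s", gene, region)
        return pd.DataFrame(columns=key_tfs + ["d_atac", "tss_distance"])
    ca, cb = f"score_d{day_a}", f"score_d{day_b}"
    mat = pd.DataFrame(np.nan, index=pd.Index(pids, name="peak_id"), columns=key_tfs)
    sub = scores[scores["peak_id"].isin(pids) & scores["tf"].isin(key_tfs)]
    for (pid, tf), grp in sub.groupby(["peak_id", "tf"]):
        mat.loc[pid, tf] = grp[cb].median() - grp[ca].median()
    g = genes.set_index("name").loc[gene]
    pk = peaks.set_index("peak_id").loc[pids]
    mid = (pk["start"] + pk["end"]) // 2
    sign = 1 if g["strand"] == "+" else -1
    mat["d_atac"] = (
        accessibility.loc[pids, f"d{day_b}"] - accessibility.loc[pids, f"d{day_a}"]
    )
    mat["tss_distance"] = sign * (mid - int(g["tss"]))
    return mat


def rank_candidates(mat: pd.DataFrame, key_tfs: list[str] | None = None) -> pd.DataFrame:
    """Rank peaks by the sum of positive key-TF score changes.

    Ties break by larger accessibility change, then smaller |TSS distance|.
    The ranking is invariant under any increasing rescaling applied
    uniformly to all score changes.
    """
    key_tfs = key_tfs or [c for c in mat.columns if c not in ("d_atac", "tss_distance")]
    if mat.empty:
        raise ValueError("empty change matrix")
    pos_sum = mat[key_tfs].clip(lower=0).fillna(0.0).sum(axis=1)
    out = pd.DataFrame(
        {
            "score": pos_sum,
            "d_atac": mat["d_atac"],
            "tss_distance": mat["tss_distance"],
        }
    )
    out = out.sort_values(
        by=["score", "d_atac", "tss_distance"],
        ascending=[False, False, True],
        key=lambda s: s.abs() if s.name == "tss_distance" else s,
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def deletion_interval(
    peak: pd.Series,
    occurrences: pd.DataFrame,
    pad: int = 10,
) -> tuple[str, int, int]:
    """Minimal interval covering the selected motif instances, padded and
    clipped to the peak; length = end - start."""
    if occurrences.empty:
        raise ValueError("no occurrences selected for deletion")
    starts = peak["start"] + occurrences["offset"].to_numpy()
    ends = starts + occurrences["width"].to_numpy()
    s = int(max(peak["start"], starts.min() - pad))
    e = int(min(peak["end"], ends.max() + pad))
    if s > starts.min() - pad or e < ends.max() + pad:
        logger.info("deletion interval clipped to peak bounds")
    return str(peak["chrom"]), s, e


@dataclass
class PerturbationComparison:
    gene: str
    mean_log2_wt: float
    mean_log2_ko: float
    pct_change_log2: float
    p: float


def perturbation_compare(
    gene: str, log2_wt: np.ndarray, log2_ko: np.ndarray
) -> PerturbationComparison:
    """Welch's two-sided t-test on replicate log2 expression, WT vs KO,
    with the percent change of mean log2 expression."""
    wt = np.asarray(log2_wt, float)
    ko = np.asarray(log2_ko, float)
    if len(wt) < 3 or len(ko) < 3:
        raise ValueError("need >= 3 replicates per arm")
    if np.ptp(wt) == 0 and np.ptp(ko) == 0 and wt.mean() == ko.mean():
        p = 1.0
    else:
        p = float(stats.ttest_ind(ko, wt, equal_var=False).pvalue)
    m_wt, m_ko = float(wt.mean()), float(ko.mean())
    pct = 100.0 * (m_ko - m_wt) / m_wt
    return PerturbationComparison(
        gene=gene, mean_log2_wt=m_wt, mean_log2_ko=m_ko, pct_change_log2=pct, p=p
    )
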