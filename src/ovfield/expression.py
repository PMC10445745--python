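"""Expression normalization, differential expression and gene-set gating.

Normalization uses median-of-ratios size factors.  Differential expression
is a transparent engine: Welch's t-test on log2(normalized + pseudocount)
with BH-FDR and unshrunk log2 fold changes.  Gene sets are gated exactly as
the analysis defines them: eye-field up/down genes must pass *every* sorted
contrast at FDR < de_fdr and |log2FC| > de_lfc (strict inequalities);
housekeeping genes are flat (|log2FC| < hk_lfc per successive day) and
expressed (mean normalized > hk_min_expr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .io import CountMatrix

__all__ = [
    "size_factors",
    "normalize",
    "differential_expression",
    "ef_contrasts",
    "call_ef_genes",
    "housekeeping_genes",
    "stage_overlap",
    "GeneSets",
]


@dataclass
class GeneSets:
    ef_up: set[str]
    ef_down: set[str]
    housekeeping: set[str]
    d2d3_up: set[str] | None = None

    def __post_init__(self) -> None:
        if self.ef_up & self.ef_down:
            raise ValueError("ef_up and ef_down overlap")
        if self.housekeeping & (self.ef_up | self.ef_down):
            raise ValueError("housekeeping overlaps EF sets")


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, geometric mean normalized to 1.

    For each gene expressed in every sample, the ratio of its count to its
    across-sample geometric mean is formed; a sample's factor is the median
    ratio over those genes.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "add a pseudocount or filter samples"
        )
    sub = counts[all_pos]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_gm
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return cm.counts / size_factors(cm)


def differential_expression(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    thresholds: Thresholds | None = None,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC (B vs A), Welch-t p-value and BH-FDR.

    log2FC uses group means of normalized counts with a pseudocount; the
    test runs on log2(normalized + pseudocount) per replicate.  Identical
    groups are NaN-guarded to p = 1.
    """
    th = thresholds or Thresholds()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    norm = normalize(cm) if normalized is None else normalized
    c = th.pseudocount
    a = norm[group_a].to_numpy(float)
    b = norm[group_b].to_numpy(float)
    lfc = np.log2(b.mean(axis=1) + c) - np.log2(a.mean(axis=1) + c)
    la, lb = np.log2(a + c), np.log2(b + c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "fdr": bh_fdr(p)}, index=norm.index
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def ef_contrasts(cm: CountMatrix, thresholds: Thresholds | None = None) -> dict[str, pd.DataFrame]:
    """The three sorted contrasts defining the eye-field transition.

    d3 vs d4 GFP+, d4 GFP- vs d4 GFP+, d5 GFP- vs d5 GFP+ (log2FC is
    GFP+/later over the reference in each pair).
    """
    norm = normalize(cm)
    pairs = {
        "d3_vs_d4pos": (cm.samples_where(day=3), cm.samples_where(day=4, gfp="positive")),
        "d4neg_vs_d4pos": (
            cm.samples_where(day=4, gfp="negative"),
            cm.samples_where(day=4, gfp="positive"),
        ),
        "d5neg_vs_d5pos": (
            cm.samples_where(day=5, gfp="negative"),
            cm.samples_where(day=5, gfp="positive"),
        ),
    }
    out = {}
    for name, (a, b) in pairs.items():
        if not a or not b:
            raise ValueError(f"missing samples for contrast {name}")
        out[name] = differential_expression(cm, a, b, thresholds, normalized=norm)
    return out


def call_ef_genes(
    contrasts: dict[str, pd.DataFrame], thresholds: Thresholds | None = None
) -> tuple[set[str], set[str]]:
    """EF-up / EF-down: pass every contrast at fdr < de_fdr, |log2FC| > de_lfc."""
    th = thresholds or Thresholds()
    required = {"d3_vs_d4pos", "d4neg_vs_d4pos", "d5neg_vs_d5pos"}
    if set(contrasts) != required:
        raise ValueError(f"need exactly contrasts {sorted(required)}")
    tables = list(contrasts.values())
    genes = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(genes):
            raise ValueError("contrast tables cover different gene universes")
    up = np.ones(len(genes), dtype=bool)
    down = np.ones(len(genes), dtype=bool)
    for t in tables:
        sig = t["fdr"].to_numpy() < th.de_fdr
        up &= sig & (t["log2fc"].to_numpy() > th.de_lfc)
        down &= sig & (t["log2fc"].to_numpy() < -th.de_lfc)
    return set(genes[up]), set(genes[down])


def housekeeping_genes(
    cm: CountMatrix, thresholds: Thresholds | None = None
) -> set[str]:
    """Stably expressed genes: flat across successive days and expressed.

    Successive-day comparisons run d0->d1->d2->d3->d4->d5 on replicate
    means, following the GFP+ branch at days 4 and 5.  Both rules are
    strict: every |log2FC| < hk_lfc and overall mean > hk_min_expr.
    """
    th = thresholds or Thresholds()
    norm = normalize(cm)
    c = th.pseudocount
    day_means = []
    for day in range(6):
        gfp = "positive" if day >= 4 else None
        cols = cm.samples_where(day=day, gfp=gfp)
        if not cols:
            cols = cm.samples_where(day=day)
        day_means.append(norm[cols].mean(axis=1))
    dm = pd.concat(day_means, axis=1)
    lfc = np.log2(dm.iloc[:, 1:].to_numpy() + c) - np.log2(dm.iloc[:, :-1].to_numpy() + c)
    flat = (np.abs(lfc) < th.hk_lfc).all(axis=1)
    expressed = dm.mean(axis=1).to_numpy() > th.hk_min_expr
    return set(norm.index[flat & expressed])


def stage_overlap(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(|A|, |B|, |A intersect B|)."""
    return len(set_a), len(set_b), len(set_a & set_b)
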