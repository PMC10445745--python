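"""Footprint profiles, depth/flanking metrics, occurrence scores and
differential binding from per-bp corrected accessibility tracks.

Window geometry follows the aggregate-footprint convention: the central
region is the +/-12 bp window around the motif centre (24 bp), flanking
accessibility is the mean signal over the 60 bp either side of it, and
footprint depth is the central mean minus the flanking accessibility (a
real footprint is a depletion, so depth < 0).  Aggregate profiles average
corrected signal over +/-100 bp windows around motif centres, reversing
minus-strand windows so footprint asymmetries align.

The per-occurrence score combines normalized motif match with local
depletion: ``score = w_m * norm_llr + w_d * (flank - centre)``; any monotone
combination preserves the downstream logic (changes, rankings,
correlations), which is all the score is used for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .config import Thresholds
from .io import FootprintTrack

logger = logging.getLogger(__name__)

__all__ = [
    "occurrence_centres",
    "aggregate",
    "metrics",
    "delta_metrics",
    "occurrence_scores",
    "classify_bound",
    "differential_binding",
    "footprint_expression_correlation",
]


def occurrence_centres(occurrences: pd.DataFrame, peaks: pd.DataFrame, motif_widths: dict[str, int]) -> pd.DataFrame:
    """Genomic centre of each occurrence: peak start + offset + width // 2."""
    pk = peaks.set_index("peak_id")
    occ = occurrences.copy()
    if "peak_id" not in occ.columns:
        occ["peak_id"] = occ["peak"].str.removeprefix("peak").astype(int)
    occ["width"] = occ["motif_id"].map(motif_widths)
    starts = pk.loc[occ["peak_id"], "start"].to_numpy()
    occ["chrom"] = pk.loc[occ["peak_id"], "chrom"].to_numpy()
    occ["centre"] = starts + occ["offset"].to_numpy() + occ["width"].to_numpy() // 2
    return occ


def _window(track: FootprintTrack, chrom: str, centre: int, halfwidth: int, strand: str) -> np.ndarray:
    v = track.values(chrom, centre - halfwidth, centre + halfwidth)
    return v[::-1] if strand == "-" else v


def aggregate(
    track: FootprintTrack,
    occ: pd.DataFrame,
    halfwidth: int = 100,
) -> tuple[np.ndarray, int]:
    """Positionwise mean corrected signal over centred occurrence windows.

    ``occ`` needs chrom/centre/strand columns (see occurrence_centres).
    Windows running off a chromosome read zeros from the track and are kept;
    occurrences with no track coverage at all are skipped and counted.
    Returns (profile of length 2*halfwidth, n_occurrences used).
    """
    profiles = []
    skipped = 0
    for _, o in occ.iterrows():
        v = _window(track, o["chrom"], int(o["centre"]), halfwidth, o["strand"])
        if not np.any(v):
            skipped += 1
            continue
        profiles.append(v)
    if skipped:
        logger.info("aggregate: skipped %d occurrences without track signal", skipped)
    if not profiles:
        raise ValueError("no occurrences with track coverage")
    return np.mean(profiles, axis=0), len(profiles)


@dataclass
class FootprintMetrics:
    flanking_accessibility: float
    footprint_depth: float  # central mean minus flanking (depletion < 0)


def metrics(
    profile: np.ndarray,
    thresholds: Thresholds | None = None,
) -> FootprintMetrics:
    """Depth and flanking accessibility of a centre-aligned signal window.

    The window centre is ``len(profile) // 2``; it must cover the central
    region plus both 60 bp flanks.
    """
    th = thresholds or Thresholds()
    c = len(profile) // 2
    ch = th.fp_central_halfwidth
    fw = th.fp_flank_width
    if c - ch - fw < 0 or c + ch + fw > len(profile):
        raise ValueError(
            f"window of {len(profile)} bp too short for centre +/-{ch} plus {fw} bp flanks"
        )
    centre = float(np.mean(profile[c - ch : c + ch]))
    flank = float(
        np.mean(np.r_[profile[c - ch - fw : c - ch], profile[c + ch : c + ch + fw]])
    )
    return FootprintMetrics(flanking_accessibility=flank, footprint_depth=centre - flank)


def delta_metrics(m_a: FootprintMetrics, m_b: FootprintMetrics) -> dict[str, float]:
    """Change B - A in each footprint metric."""
    return {
        "d_flanking": m_b.flanking_accessibility - m_a.flanking_accessibility,
        "d_depth": m_b.footprint_depth - m_a.footprint_depth,
    }


def occurrence_scores(
    tracks: dict[int, FootprintTrack],
    occ: pd.DataFrame,
    thresholds: Thresholds | None = None,
    w_match: float = 0.3,
    w_depletion: float = 0.7,
) -> pd.DataFrame:
    """Per-occurrence, per-day footprint scores.

    norm_llr scales each motif's llr scores to [0, 1] over its occurrence
    set; depletion is flanking accessibility minus central mean, computed
    from the day's track.  Returns occ plus ``score_d<day>`` columns.
    """
    th = thresholds or Thresholds()
    out = occ.copy().reset_index(drop=True)
    norm_llr = np.zeros(len(out))
    for _, idx in out.groupby("motif_id").groups.items():
        llr = out.loc[idx, "llr_score"].to_numpy(float)
        span = llr.max() - llr.min()
        norm_llr[idx] = 0.0 if span == 0 else (llr - llr.min()) / span
    out["norm_llr"] = norm_llr
    ch, fw = th.fp_central_halfwidth, th.fp_flank_width
    half = ch + fw
    for day, track in tracks.items():
        depl = np.zeros(len(out))
        for i, o in out.iterrows():
            v = _window(track, o["chrom"], int(o["centre"]), half, o["strand"])
            centre = v[fw : fw + 2 * ch].mean()
            flank = np.r_[v[:fw], v[fw + 2 * ch :]].mean()
            depl[i] = flank - centre
        out[f"score_d{day}"] = w_match * norm_llr + w_depletion * depl
    return out


def classify_bound(scores: pd.Series, seed: int = 0) -> pd.Series:
    """Bound/unbound via a 2-component 1-D Gaussian mixture on scores.

    Bound = posterior of the upper-mean component > 0.5.  Degenerate fits
    (identical scores, or a collapsed single mode) yield all-unbound.
    """
    x = scores.to_numpy(float).reshape(-1, 1)
    if len(x) < 20:
        raise ValueError("need >= 20 occurrences to classify bound state")
    if np.ptp(x) == 0:
        logger.warning("all scores identical; calling all unbound")
        return pd.Series(False, index=scores.index)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
    upper = int(np.argmax(gm.means_.ravel()))
    sds = np.sqrt(gm.covariances_.ravel())
    sep = abs(gm.means_.ravel()[0] - gm.means_.ravel()[1]) / max(sds.max(), 1e-12)
    if sep < 1.0:
        logger.warning("score mixture effectively unimodal; calling all unbound")
        return pd.Series(False, index=scores.index)
    post = gm.predict_proba(x)[:, upper]
    return pd.Series(post > 0.5, index=scores.index)


def differential_binding(
    scores: pd.DataFrame,
    day_a: int,
    day_b: int,
    min_occurrences: int = 10,
) -> pd.DataFrame:
    """Per-motif mean score change B - A, standardized across motifs.

    z-scores use the across-motif mean and SD of deltas, so they have mean
    0 / SD 1 by construction; p is the two-sided normal tail.  Motifs with
    fewer occurrences than ``min_occurrences`` are flagged low-confidence.
    """
    ca, cb = f"score_d{day_a}", f"score_d{day_b}"
    rows = []
    for motif_id, grp in scores.groupby("motif_id"):
        delta = float(grp[cb].mean() - grp[ca].mean())
        rows.append((motif_id, grp["tf"].iloc[0], delta, len(grp)))
    df = pd.DataFrame(rows, columns=["motif_id", "tf", "delta", "n_occurrences"])
    sd = df["delta"].std(ddof=0)
    df["z"] = 0.0 if sd == 0 else (df["delta"] - df["delta"].mean()) / sd
    df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    df["low_confidence"] = df["n_occurrences"] < min_occurrences
    return df.set_index("motif_id")


def footprint_expression_correlation(
    scores: pd.DataFrame,
    tf_expr: pd.DataFrame,
    days: list[int] = (0, 1, 2, 3, 5),
) -> pd.DataFrame:
    """Median per-motif Pearson r between occurrence-score and TF-expression
    trajectories over the matched days; constant trajectories are dropped.
    """
    day_cols = [f"score_d{d}" for d in days]
    expr_cols = [f"d{d}" for d in days]
    rows = []
    for motif_id, grp in scores.groupby("motif_id"):
        tf = grp["tf"].iloc[0]
        if tf not in tf_expr.index:
            continue
        e = tf_expr.loc[tf, expr_cols].to_numpy(float)
        if np.ptp(e) == 0:
            continue
        rs = []
        for _, o in grp.iterrows():
            s = o[day_cols].to_numpy(float)
            if np.ptp(s) == 0:
                continue
            rs.append(stats.pearsonr(e, s).statistic)
        if rs:
            rows.append((motif_id, tf, float(np.median(rs)), len(rs)))
    return pd.DataFrame(rows, columns=["motif_id", "tf", "median_r", "n"]).set_index("motif_id")
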