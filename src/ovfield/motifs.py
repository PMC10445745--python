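"""PWM scanning, motif presence, enrichment and the motif-importance model.

The scanner reports, per position, the best strand's log-likelihood-ratio
score and an exact p-value computed by dynamic programming over the
integer-rounded score distribution (1000-bin lattice) under the background
base composition.  Presence is collapsed per TF (a TF is present in a peak
if any of its motifs has a significant occurrence there).  Enrichment is a
hypergeometric upper tail against housekeeping-TAD background peaks, and
motif importance comes from an L2 logistic model predicting opening versus
closing peaks, with CV-chosen regularization and seed-averaged coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .config import Thresholds
from .io import CountMatrix, Motif, MotifSet

__all__ = [
    "pwm_from_pfm",
    "score_pvalue_table",
    "scan",
    "expressed_tfs",
    "presence_matrix",
    "enrichment",
    "fit_motif_logit",
]

_SCORE_RANGE = 1000  # integer lattice size for the exact score distribution
_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_from_pfm(
    pfm: np.ndarray, background: np.ndarray | None = None, pseudocount: float = 0.1
) -> np.ndarray:
    """log2((pfm + pc) / column_total / background) position weight matrix."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    col = pfm + pseudocount
    probs = col / col.sum(axis=0, keepdims=True)
    return np.log2(probs / bg[:, None])


def _int_scores(pwm: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Round the PWM onto a shared integer lattice of ~_SCORE_RANGE steps.

    Returns (integer matrix, scale, offset) with
    ``int_score ~= (score - per-column min, summed) * scale``.
    """
    col_min = pwm.min(axis=0)
    span = (pwm.max(axis=0) - col_min).sum()
    scale = _SCORE_RANGE / span if span > 0 else 1.0
    ints = np.round((pwm - col_min[None, :]) * scale).astype(np.int64)
    return ints, scale, col_min.sum()


def score_pvalue_table(
    pwm: np.ndarray, background: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Exact null distribution of the integer-rounded PWM score.

    Convolves per-column score pmfs under the background composition and
    returns (int_pwm, pvalue_by_int_score, scale, offset): ``pvalue[s]`` is
    P(rounded score >= s) for a random background word.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    ints, scale, offset = _int_scores(pwm)
    max_total = int(ints.max(axis=0).sum())
    pdf = np.zeros(max_total + 1)
    pdf[0] = 1.0
    for j in range(ints.shape[1]):
        nxt = np.zeros_like(pdf)
        for b in range(4):
            s = ints[b, j]
            nxt[s:] += bg[b] * pdf[: len(pdf) - s if s else None]
        pdf = nxt
    sf = np.cumsum(pdf[::-1])[::-1]  # sf[s] = P(S >= s)
    return ints, np.minimum(sf, 1.0), scale, offset


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASES.get(ch, -1) for ch in seq.upper()], dtype=np.int64)


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def scan(
    motifs: MotifSet | list[Motif],
    seqs: dict[str, str],
    background: np.ndarray | None = None,
    p_thresh: float | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Scan sequences with every motif; report best-strand hits at p <= thresh.

    Positions containing N are skipped.  A motif wider than a sequence
    yields no occurrences.  Returns columns peak (sequence name), motif_id,
    tf, offset, strand, llr_score, pvalue.
    """
    th = thresholds or Thresholds()
    p_thresh = th.motif_pvalue if p_thresh is None else p_thresh
    rows = []
    enc = {name: _encode(s) for name, s in seqs.items()}
    for motif in motifs:
        pwm = pwm_from_pfm(motif.pfm, background)
        ints, sf, scale, offset = score_pvalue_table(pwm, background)
        ints_rc = _revcomp_pwm(ints)
        pwm_rc = _revcomp_pwm(pwm)
        w = motif.width
        for name, x in enc.items():
            n = len(x) - w + 1
            if n <= 0:
                continue
            idx = np.arange(n)[:, None] + np.arange(w)[None, :]
            window = x[idx]
            valid = (window >= 0).all(axis=1)
            if not valid.any():
                continue
            win = window[valid]
            cols = np.arange(w)
            s_fwd = ints[win, cols].sum(axis=1)
            s_rev = ints_rc[win, cols].sum(axis=1)
            best = np.maximum(s_fwd, s_rev)
            pvals = sf[best]
            hits = pvals <= p_thresh
            if not hits.any():
                continue
            pos = np.arange(n)[valid][hits]
            fwd_best = s_fwd[hits] >= s_rev[hits]
            real_fwd = pwm[win[hits], cols].sum(axis=1)
            real_rev = pwm_rc[win[hits], cols].sum(axis=1)
            for k, off in enumerate(pos):
                strand = "+" if fwd_best[k] else "-"
                llr = real_fwd[k] if fwd_best[k] else real_rev[k]
                rows.append(
                    (name, motif.motif_id, motif.tf, int(off), strand, float(llr), float(pvals[hits][k]))
                )
    return pd.DataFrame(
        rows, columns=["peak", "motif_id", "tf", "offset", "strand", "llr_score", "pvalue"]
    )


def expressed_tfs(
    cm: CountMatrix,
    tfs: list[str],
    thresholds: Thresholds | None = None,
    normalized: pd.DataFrame | None = None,
) -> set[str]:
    """TFs whose replicate-mean normalized expression exceeds the cutoff at
    any timepoint (strict >).  TFs without an expression record are skipped.
    """
    from .expression import normalize

    th = thresholds or Thresholds()
    norm = normalize(cm) if normalized is None else normalized
    groups: dict[tuple, list[str]] = {}
    for s in cm.samples:
        groups.setdefault((s.day, s.gfp), []).append(s.sample_id)
    out = set()
    for tf in tfs:
        if tf not in norm.index:
            continue
        for cols in groups.values():
            if norm.loc[tf, cols].mean() > th.tf_expr_min:
                out.add(tf)
                break
    return out


def presence_matrix(
    occurrences: pd.DataFrame, peak_ids: list, tfs: list[str]
) -> pd.DataFrame:
    """Binary peak x TF matrix: 1 iff any motif of the TF hits the peak."""
    mat = pd.DataFrame(0, index=pd.Index(peak_ids, name="peak"), columns=tfs, dtype=np.int8)
    hits = occurrences[occurrences["tf"].isin(tfs)]
    for (peak, tf), _ in hits.groupby(["peak", "tf"]):
        if peak in mat.index:
            mat.loc[peak, tf] = 1
    return mat


def enrichment(
    presence: pd.DataFrame,
    signal_peaks: list,
    background_peaks: list,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each TF in the signal set.

    Signal peaks are removed from the background first.  The odds ratio uses
    Haldane's +0.5 correction whenever a cell of the 2x2 table is zero.
    """
    sig = [p for p in signal_peaks if p in presence.index]
    bg = [p for p in background_peaks if p in presence.index and p not in set(sig)]
    if not bg:
        raise ValueError("empty background peak set")
    rows = []
    m_total = len(sig) + len(bg)
    for tf in presence.columns:
        k_sig = int(presence.loc[sig, tf].sum())
        k_bg = int(presence.loc[bg, tf].sum())
        n_with = k_sig + k_bg
        p = float(stats.hypergeom.sf(k_sig - 1, m_total, n_with, len(sig)))
        a, b = k_sig, len(sig) - k_sig
        c, d = k_bg, len(bg) - k_bg
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((tf, a * d / (b * c), p, k_sig, len(sig), k_bg, len(bg)))
    return pd.DataFrame(
        rows,
        columns=["tf", "odds_ratio", "pvalue", "k_signal", "n_signal", "k_background", "n_background"],
    ).set_index("tf")


def fit_motif_logit(
    presence: pd.DataFrame,
    labels: pd.Series,
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> tuple[pd.Series, float, float]:
    """Seed-averaged L2 logistic coefficients predicting opening vs closing.

    labels: 1 = opening, 0 = closing, indexed like ``presence``.  The
    regularization strength is chosen on a 13-point log grid in
    [1e-3, 1e3] by mean held-out log-loss over stratified 5-fold CV with
    balanced class weights; final coefficients are the mean over
    ``logit_n_seeds`` refits on all peaks.  Positive coefficients predict
    opening.  Returns (coefficients, lambda, cv_logloss).
    """
    th = thresholds or Thresholds()
    y = labels.loc[presence.index].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    x = presence.to_numpy(float)
    lambdas = np.logspace(-3, 3, 13)
    skf = StratifiedKFold(n_splits=th.logit_cv_folds, shuffle=True, random_state=seed)
    losses = []
    for lam in lambdas:
        fold_losses = []
        for tr, te in skf.split(x, y):
            clf = LogisticRegression(C=1.0 / lam, class_weight="balanced", max_iter=2000)
            clf.fit(x[tr], y[tr])
            fold_losses.append(log_loss(y[te], clf.predict_proba(x[te])[:, 1], labels=[0, 1]))
        losses.append(np.mean(fold_losses))
    lam = float(lambdas[int(np.argmin(losses))])
    seeds = np.random.SeedSequence(seed).generate_state(th.logit_n_seeds) % (2**31)
    coefs = []
    for s in seeds:
        clf = LogisticRegression(
            C=1.0 / lam,
            class_weight="balanced",
            max_iter=2000,
            solver="saga",
            random_state=int(s),
        )
        clf.fit(x, y)
        coefs.append(clf.coef_[0])
    mean_coef = pd.Series(np.mean(coefs, axis=0), index=presence.columns, name="coefficient")
    return mean_coef, lam, float(np.min(losses))
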