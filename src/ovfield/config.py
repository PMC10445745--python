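"""Pipeline thresholds and sample metadata.

All fixed analysis thresholds live in :class:`Thresholds`.  Defaults are the
values used throughout the analysis (DE gates, housekeeping gates, motif scan
p-value, footprint window geometry, model hyper-parameters); every one can be
overridden from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["Thresholds", "SampleMeta", "load_config"]


@dataclass(frozen=True)
class Thresholds:
    """Fixed numeric thresholds used across the pipeline.

    Attributes
    ----------
    de_fdr : float
        BH-FDR gate for differential expression (strict ``<``).
    de_lfc : float
        Absolute log2-fold-change gate for DE calls (strict ``>``).
    hk_lfc : float
        Max |log2FC| between successive days for housekeeping genes.
    hk_min_expr : float
        Min mean normalized expression for housekeeping genes.
    tf_expr_min : float
        A TF counts as expressed if its replicate-mean normalized
        expression exceeds this at any timepoint (strict ``>``).
    atac_dynamic_lfc : float
        |log2FC| gate calling opening/closing peaks between two days.
    model_dynamic_lfc : float
        Looser |log2FC| gate selecting peaks for the motif-importance
        logistic model.
    motif_pvalue : float
        Per-position PWM match p-value threshold.
    subnucleosomal_max_fragment : int
        Maximum ATAC fragment size (bp) assumed for the input tracks.
    fp_central_halfwidth : int
        Half-width (bp) of the central footprint region around a motif
        centre; the central region spans ``2 * fp_central_halfwidth`` bp.
    fp_flank_width : int
        Width (bp) of each flanking region either side of the centre.
    fp_aggregate_halfwidth : int
        Half-width (bp) of aggregate-profile windows around motif centres.
    corr_call_threshold : float
        |median r| needed to call a TF activator-/repressor-like.
    corr_call_p : float
        Wilcoxon rank-sum p-value gate accompanying the correlation call.
    gmm_n_init : int
        Random initializations per k in trajectory clustering.
    logit_n_seeds : int
        Seeded refits averaged for the final logistic coefficients.
    logit_cv_folds : int
        Stratified CV folds used to pick the regularization strength.
    promoter_window : int
        TSS +/- window (bp) used for promoter annotation.
    pseudocount : float
        Normalized-count pseudocount keeping log2 fold changes finite.
    """

    de_fdr: float = 0.001
    de_lfc: float = 1.5
    hk_lfc: float = 0.1
    hk_min_expr: float = 30.0
    tf_expr_min: float = 50.0
    atac_dynamic_lfc: float = 1.5
    model_dynamic_lfc: float = 1.0
    motif_pvalue: float = 1e-4
    subnucleosomal_max_fragment: int = 100
    fp_central_halfwidth: int = 12
    fp_flank_width: int = 60
    fp_aggregate_halfwidth: int = 100
    corr_call_threshold: float = 0.5
    corr_call_p: float = 1e-10
    gmm_n_init: int = 20
    logit_n_seeds: int = 10
    logit_cv_folds: int = 5
    promoter_window: int = 1000
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "motif_pvalue", "corr_call_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        for name in (
            "subnucleosomal_max_fragment",
            "fp_central_halfwidth",
            "fp_flank_width",
            "fp_aggregate_halfwidth",
            "gmm_n_init",
            "logit_n_seeds",
            "logit_cv_folds",
            "promoter_window",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.de_lfc < self.model_dynamic_lfc:
            raise ValueError("de_lfc must be >= model_dynamic_lfc")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: day, replicate and GFP sort status.

    GFP-sorted samples only exist from day 4 on (expression) or day 5
    (accessibility); earlier samples are unsorted.
    """

    sample_id: str
    day: int
    replicate: int = 1
    gfp: str = "unsorted"

    _GFP = ("positive", "negative", "unsorted")

    def __post_init__(self) -> None:
        if not 0 <= self.day <= 5:
            raise ValueError(f"day must be 0-5, got {self.day}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.gfp not in self._GFP:
            raise ValueError(f"gfp must be one of {self._GFP}, got {self.gfp!r}")
        if self.gfp != "unsorted" and self.day < 4:
            raise ValueError("GFP-sorted samples only allowed at days >= 4")

    @classmethod
    def parse(cls, sample_id: str) -> "SampleMeta":
        """Parse ``d<day>[_gfp<pos|neg>]_r<rep>`` sample identifiers."""
        parts = sample_id.split("_")
        try:
            day = int(parts[0].lstrip("d"))
            rep = int(parts[-1].lstrip("r"))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse sample id {sample_id!r}") from exc
        gfp = "unsorted"
        if len(parts) == 3:
            token = parts[1]
            gfp = {"gfppos": "positive", "gfpneg": "negative"}.get(token)
            if gfp is None:
                raise ValueError(f"cannot parse GFP token {token!r} in {sample_id!r}")
        return cls(sample_id=sample_id, day=day, replicate=rep, gfp=gfp)


def load_config(path: str | Path | None = None) -> Thresholds:
    """Load :class:`Thresholds`, optionally overriding defaults from YAML."""
    if path is None:
        return Thresholds()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Thresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Thresholds(**raw)
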