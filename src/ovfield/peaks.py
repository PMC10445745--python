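"""Consensus peak universe, normalization, annotation, dynamics and TADs.

Everything here operates on 0-based half-open intervals.  Peak-to-region
membership uses the peak midpoint so every peak belongs to exactly one TAD
or inter-TAD gap; region-to-gene association uses a basal-plus-extension
rule (5 kb upstream / 1 kb downstream basal domain, extended to the nearest
neighbouring basal domain up to 1 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "merge_consensus",
    "normalize_accessibility",
    "annotate",
    "dynamic_peaks",
    "assign_tads",
    "region_gene_associations",
    "promoter_stats",
]


def merge_consensus(
    day_peaks: list[pd.DataFrame], blacklist: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Union-merge per-day peak sets (touching intervals merge, as in
    ``bedtools merge``); drop merged peaks overlapping any blacklist
    interval; assign sorted integer peak_ids."""
    allp = pd.concat(
        [d[["chrom", "start", "end"]] for d in day_peaks], ignore_index=True
    ).sort_values(["chrom", "start", "end"], kind="mergesort")
    merged = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlapping or touching
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    if blacklist is not None and len(blacklist):
        keep = np.ones(len(out), dtype=bool)
        for _, b in blacklist.iterrows():
            hit = (
                (out["chrom"] == b["chrom"])
                & (out["start"] < b["end"])
                & (out["end"] > b["start"])
            )
            keep &= ~hit
        out = out[keep].reset_index(drop=True)
    out.insert(0, "peak_id", np.arange(len(out), dtype=np.int64))
    return out


def normalize_accessibility(
    raw: pd.DataFrame,
    gc: np.ndarray,
    width: np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Library-size scaling, log2(x+1), then binned GC/width de-trending.

    Per-day totals are scaled to their common mean and values logged.  The
    covariate trend is estimated on the across-day mean log signal as the
    median per (gc-decile x width-decile) bin, and the same per-peak
    correction is subtracted from every day (so within-peak day-to-day
    differences are untouched), restoring each day's mean afterwards.
    Sparse 2-D bins fall back to the two marginal decile corrections.
    """
    gc = np.asarray(gc, float)
    width = np.asarray(width, float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc must be in [0, 1]")
    if (width < 1).any():
        raise ValueError("width must be >= 1")
    totals = raw.sum(axis=0)
    scaled = raw * (1e6 / totals)  # fixed per-day target, CPM-style
    logm = np.log2(scaled + 1.0)

    gc_bin = _decile_bins(gc, n_bins)
    w_bin = _decile_bins(width, n_bins)
    cell = gc_bin * n_bins + w_bin
    counts = np.bincount(cell, minlength=n_bins * n_bins)
    use_2d = (counts[cell] >= 5).all()
    if not use_2d:
        logger.warning("sparse gc x width bins; falling back to marginal correction")
    v = logm.mean(axis=1).to_numpy()  # time-mean signal carries the bias
    if use_2d:
        med = pd.Series(v).groupby(cell).transform("median").to_numpy()
    else:
        med_gc = pd.Series(v).groupby(gc_bin).transform("median").to_numpy()
        med_w = pd.Series(v).groupby(w_bin).transform("median").to_numpy()
        med = med_gc + med_w - np.median(v)
    out = logm.sub(med, axis=0)
    out = out + logm.mean(axis=0) - out.mean(axis=0)  # mean-preserving per day
    return out


def _decile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = stats.rankdata(x, method="average") - 1
    return np.minimum((ranks / len(x) * n_bins).astype(int), n_bins - 1)


def annotate(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: int = 1000,
) -> pd.Series:
    """Annotate each peak: promoter > exonic > intronic > intergenic.

    Promoter: peak overlaps TSS +/- promoter_window.  The synthetic gene
    models are single-exon bodies, so 'exonic' means overlap with the gene
    body's exon blocks (columns exon_start/exon_end if present, else the
    whole body) and 'intronic' any other overlap with the body.
    """
    ann = np.full(len(peaks), "intergenic", dtype=object)
    for i, (_, p) in enumerate(peaks.iterrows()):
        g = genes[genes["chrom"] == p["chrom"]]
        if not len(g):
            continue
        tss = g["tss"].to_numpy()
        if ((p["start"] < tss + promoter_window) & (p["end"] > tss - promoter_window)).any():
            ann[i] = "promoter"
            continue
        body = (p["start"] < g["end"].to_numpy()) & (p["end"] > g["start"].to_numpy())
        if body.any():
            hit = g[body]
            if {"exon_start", "exon_end"} <= set(g.columns):
                ex = (p["start"] < hit["exon_end"].to_numpy()) & (
                    p["end"] > hit["exon_start"].to_numpy()
                )
                ann[i] = "exonic" if ex.any() else "intronic"
            else:
                ann[i] = "exonic"
    return pd.Series(ann, index=peaks.index, name="annotation")


def dynamic_peaks(
    norm: pd.DataFrame,
    day_a: str = "d3",
    day_b: str = "d5",
    lfc_thresh: float | None = None,
    thresholds: Thresholds | None = None,
) -> pd.Series:
    """Classify peaks opening/closing/static between two days.

    Uses the normalized log2 matrix: opening if signal(dayB) - signal(dayA)
    exceeds the threshold (strict), closing if below its negative.
    """
    th = thresholds or Thresholds()
    t = th.atac_dynamic_lfc if lfc_thresh is None else lfc_thresh
    for d in (day_a, day_b):
        if d not in norm.columns:
            raise ValueError(f"day column {d!r} missing from normalized matrix")
    delta = norm[day_b] - norm[day_a]
    out = pd.Series("static", index=norm.index, name="dynamic_class")
    out[delta > t] = "opening"
    out[delta < -t] = "closing"
    return out


@dataclass
class RegionTable:
    """TADs plus synthesized inter-TAD gaps, with memberships and classes."""

    regions: pd.DataFrame  # region_id, chrom, start, end, kind
    peak_region: pd.Series  # peak_id -> region_id (midpoint rule)
    gene_region: pd.Series  # gene -> region_id (TSS rule)
    region_classes: dict[str, set[str]]  # region_id -> subset of {ef_up, ef_down, housekeeping}

    def regions_of_class(self, cls: str, pure: bool = False) -> set[str]:
        """Regions carrying a class label; ``pure`` excludes regions that
        also carry any other label (e.g. housekeeping TADs that contain an
        EF gene are not a clean background)."""
        if pure:
            return {r for r, cs in self.region_classes.items() if cs == {cls}}
        return {r for r, cs in self.region_classes.items() if cls in cs}

    def peaks_in_classes(self, cls: str, pure: bool = False) -> pd.Index:
        wanted = self.regions_of_class(cls, pure=pure)
        return self.peak_region.index[self.peak_region.isin(wanted)]


def assign_tads(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    tads: pd.DataFrame,
    gene_sets: dict[str, set[str]],
) -> RegionTable:
    """Assign peaks and genes to TADs and synthesized inter-TAD gaps.

    Gap regions exactly tile the space between genomically adjacent TADs.
    Membership is by peak midpoint / gene TSS (half-open).  A region's class
    set contains every label whose gene set it intersects; a region holding
    both up- and down-regulated genes keeps both labels (logged).
    """
    tads = tads.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, grp in tads.groupby("chrom"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping TADs on {chrom}")
    rows = []
    for chrom, grp in tads.groupby("chrom", sort=True):
        prev_end = None
        for _, t in grp.iterrows():
            if prev_end is not None and t["start"] > prev_end:
                rows.append((f"gap_{chrom}_{prev_end}", chrom, prev_end, t["start"], "gap"))
            rows.append((str(t["tad_id"]), chrom, t["start"], t["end"], "tad"))
            prev_end = t["end"]
    regions = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "kind"])

    def locate(chrom: str, pos: int) -> str | None:
        g = regions[regions["chrom"] == chrom]
        hit = g[(g["start"] <= pos) & (pos < g["end"])]
        return None if hit.empty else str(hit["region_id"].iloc[0])

    peak_region = pd.Series(
        {
            int(p["peak_id"]): locate(p["chrom"], int((p["start"] + p["end"]) // 2))
            for _, p in peaks.iterrows()
        },
        name="region_id",
    ).dropna()
    gene_region = pd.Series(
        {g["name"]: locate(g["chrom"], int(g["tss"])) for _, g in genes.iterrows()},
        name="region_id",
    ).dropna()

    region_classes: dict[str, set[str]] = {r: set() for r in regions["region_id"]}
    for label, gset in gene_sets.items():
        for gene in gset:
            r = gene_region.get(gene)
            if r is not None:
                region_classes[r].add(label)
    dual = [r for r, cs in region_classes.items() if {"ef_up", "ef_down"} <= cs]
    if dual:
        logger.info("%d regions contain both EF-up and EF-down genes (dual-labelled)", len(dual))
    return RegionTable(
        regions=regions,
        peak_region=peak_region,
        gene_region=gene_region,
        region_classes=region_classes,
    )


def region_gene_associations(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension peak-to-gene links.

    Each gene gets a strand-aware basal domain (basal_up upstream,
    basal_down downstream of the TSS) extended outwards to the nearest
    neighbouring basal domain boundary, capped at max_extension.  A peak
    links to every gene whose regulatory domain it overlaps.
    """
    doms = []
    for chrom, g in genes.groupby("chrom", sort=True):
        g = g.sort_values("tss")
        basal = []
        for _, r in g.iterrows():
            if r["strand"] == "+":
                basal.append((r["tss"] - basal_up, r["tss"] + basal_down))
            else:
                basal.append((r["tss"] - basal_down, r["tss"] + basal_up))
        names = list(g["name"])
        for i, (bs, be) in enumerate(basal):
            lo_cap, hi_cap = bs - max_extension, be + max_extension
            left = max((e for s, e in basal[:i]), default=-np.inf)
            right = min((s for s, e in basal[i + 1 :]), default=np.inf)
            ext_s = int(max(lo_cap, min(bs, left if left > -np.inf else lo_cap)))
            ext_e = int(min(hi_cap, max(be, right if right < np.inf else hi_cap)))
            doms.append((chrom, max(0, ext_s), ext_e, names[i]))
    dom_df = pd.DataFrame(doms, columns=["chrom", "start", "end", "gene"])

    links = []
    for _, p in peaks.iterrows():
        d = dom_df[dom_df["chrom"] == p["chrom"]]
        hit = d[(p["start"] < d["end"]) & (p["end"] > d["start"])]
        for gene in hit["gene"]:
            links.append((int(p["peak_id"]), gene))
    return pd.DataFrame(links, columns=["peak_id", "gene"])


def promoter_stats(
    signal_a: pd.DataFrame, signal_b: pd.DataFrame
) -> dict[str, float]:
    """Median level and trajectory variability of two peak groups.

    Compares time-mean signal (location) and across-day SD (variability)
    between the groups with two-sided Mann-Whitney U tests; exact p for
    groups of <= 8, normal approximation with tie correction otherwise.
    """
    if len(signal_a) < 2 or len(signal_b) < 2:
        raise ValueError("each group needs >= 2 peaks")
    mean_a, mean_b = signal_a.mean(axis=1), signal_b.mean(axis=1)
    sd_a, sd_b = signal_a.std(axis=1, ddof=1), signal_b.std(axis=1, ddof=1)

    def mwu(x, y):
        method = "exact" if max(len(x), len(y)) <= 8 else "asymptotic"
        return stats.mannwhitneyu(x, y, alternative="two-sided", method=method)

    loc = mwu(mean_a, mean_b)
    var = mwu(sd_a, sd_b)
    return {
        "median_a": float(mean_a.median()),
        "median_b": float(mean_b.median()),
        "p_location": float(loc.pvalue),
        "sd_median_a": float(sd_a.median()),
        "sd_median_b": float(sd_b.median()),
        "p_variability": float(var.pvalue),
    }
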