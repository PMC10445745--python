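"""End-to-end orchestration of the analysis stages on one input bundle.

This is the integration surface used by the CLI and the acceptance checks:
expression gating -> trajectory clustering -> peak normalization/dynamics ->
TAD assignment -> motif scan/enrichment/model -> expression-accessibility
correlation -> footprint scoring -> CRE ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, correlate, cre, expression, footprint, motifs, peaks
from .config import Thresholds
from .simulate import ALL_TFS, ATAC_DAYS, SimBundle

__all__ = ["PipelineResult", "run_pipeline", "rank_region_cres"]


@dataclass
class PipelineResult:
    gene_sets: expression.GeneSets
    cluster_result: clustering.ClusterResult | None
    norm_access: pd.DataFrame  # normalized peak x day matrix (index peak_id)
    dynamic: pd.Series  # peak_id -> opening/closing/static
    annotation: pd.Series  # peak_id -> promoter/exonic/intronic/intergenic
    region_table: peaks.RegionTable
    occurrences: pd.DataFrame
    presence: pd.DataFrame
    expressed: set[str]
    enrich_opening: pd.DataFrame
    logit_coefs: pd.Series
    logit_lambda: float
    tf_expr: pd.DataFrame
    correlations: pd.DataFrame  # EF-up TAD (tf, peak) correlations
    correlations_bg: pd.DataFrame  # housekeeping-TAD background
    regulator_calls: list
    scores: pd.DataFrame  # per-occurrence footprint scores per day
    diffbind: pd.DataFrame
    fp_expr_corr_efup: pd.DataFrame
    cre_rankings: dict[str, pd.DataFrame]


def rank_region_cres(
    bundle: SimBundle,
    target_genes: list[str],
    thresholds: Thresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """CRE candidate rankings for target genes, touching only their regions.

    Runs the scan/score/rank path restricted to peaks in each target gene's
    TAD or gap region; used when only the prioritization stage is needed
    (e.g. scoring rank stability across many simulated replicates).
    """
    th = thresholds or Thresholds()
    genome = bundle.genome
    pk = genome.peaks
    raw = bundle.peak_signal.set_index("peak_id")
    widths = (pk["end"] - pk["start"]).to_numpy()
    norm_access = peaks.normalize_accessibility(raw, pk["gc"].to_numpy(), widths)
    region_table = peaks.assign_tads(pk, genome.genes, genome.tads, gene_sets={})
    wanted_regions = {region_table.gene_region.get(g) for g in target_genes}
    pids = set(
        int(p) for p, r in region_table.peak_region.items() if r in wanted_regions
    )
    seqs = {f"peak{p}": genome.seqs[f"peak{p}"] for p in pids}
    occurrences = motifs.scan(bundle.motifs, seqs, thresholds=th)
    occurrences["peak_id"] = occurrences["peak"].str.removeprefix("peak").astype(int)
    motif_widths = {m.motif_id: m.width for m in bundle.motifs}
    occ = footprint.occurrence_centres(occurrences, pk, motif_widths)
    scores = footprint.occurrence_scores(bundle.tracks, occ, th)
    out = {}
    for gene in target_genes:
        mat = cre.change_matrix(
            gene, scores, region_table, pk, genome.genes, norm_access, 3, 5
        )
        if len(mat):
            out[gene] = cre.rank_candidates(mat)
    return out


def run_pipeline(
    bundle: SimBundle,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    with_clustering: bool = True,
) -> PipelineResult:
    th = thresholds or Thresholds()
    cm = bundle.counts
    genome = bundle.genome

    # --- expression gating ------------------------------------------------
    contrasts = expression.ef_contrasts(cm, th)
    ef_up, ef_down = expression.call_ef_genes(contrasts, th)
    hk = expression.housekeeping_genes(cm, th) - ef_up - ef_down
    gene_sets = expression.GeneSets(ef_up=ef_up, ef_down=ef_down, housekeeping=hk)

    # --- trajectory clustering -------------------------------------------
    cluster_result = None
    if with_clustering and len(ef_up | ef_down) > 12:
        norm = expression.normalize(cm)
        day_cols = {}
        for day in range(6):
            gfp = "positive" if day >= 4 else None
            ids = cm.samples_where(day=day, gfp=gfp)
            day_cols[day] = norm[ids].mean(axis=1)
        traj = np.log2(pd.DataFrame(day_cols) + th.pseudocount)
        traj = traj.loc[sorted(ef_up | ef_down)]
        kmax = min(10, max(3, len(traj) // 8))
        cluster_result = clustering.cluster_trajectories(
            traj, days=list(range(6)), k_range=range(2, kmax + 1), thresholds=th, seed=seed
        )

    # --- accessibility ----------------------------------------------------
    pk = genome.peaks
    raw = bundle.peak_signal.set_index("peak_id")
    widths = (pk["end"] - pk["start"]).to_numpy()
    norm_access = peaks.normalize_accessibility(raw, pk["gc"].to_numpy(), widths)
    dynamic = peaks.dynamic_peaks(norm_access, "d3", "d5", thresholds=th)
    annotation = peaks.annotate(pk, genome.genes, promoter_window=th.promoter_window)
    annotation.index = pk["peak_id"].to_numpy()

    region_table = peaks.assign_tads(
        pk,
        genome.genes,
        genome.tads,
        gene_sets={"ef_up": ef_up, "ef_down": ef_down, "housekeeping": hk},
    )

    # --- motifs -----------------------------------------------------------
    occurrences = motifs.scan(bundle.motifs, genome.seqs, thresholds=th)
    occurrences["peak_id"] = occurrences["peak"].str.removeprefix("peak").astype(int)
    expressed = motifs.expressed_tfs(cm, ALL_TFS, th)
    feature_tfs = sorted(expressed)
    presence = motifs.presence_matrix(
        occurrences.rename(columns={"peak": "name"}).assign(peak=lambda d: d["peak_id"]),
        list(pk["peak_id"]),
        feature_tfs,
    )

    opening_ids = list(dynamic.index[dynamic == "opening"])
    closing_ids = list(dynamic.index[dynamic == "closing"])
    hk_peak_ids = list(region_table.peaks_in_classes("housekeeping", pure=True))
    enrich_opening = motifs.enrichment(presence, opening_ids, hk_peak_ids)

    # motif-importance model on dynamic peaks (looser model gate)
    model_dyn = peaks.dynamic_peaks(norm_access, "d3", "d5", lfc_thresh=th.model_dynamic_lfc)
    model_ids = list(model_dyn.index[model_dyn != "static"])
    labels = (model_dyn.loc[model_ids] == "opening").astype(int)
    logit_coefs, logit_lambda, _ = motifs.fit_motif_logit(
        presence.loc[model_ids], labels, th, seed=seed
    )

    # --- expression-accessibility correlation -----------------------------
    tf_expr = correlate.tf_day_expression(cm, feature_tfs)
    efup_peaks = set(region_table.peaks_in_classes("ef_up"))
    hk_peaks_set = set(hk_peak_ids)
    pair_src = occurrences[occurrences["tf"].isin(feature_tfs)][
        ["tf", "peak_id"]
    ].drop_duplicates()
    pairs_up = pair_src[pair_src["peak_id"].isin(efup_peaks)]
    pairs_hk = pair_src[pair_src["peak_id"].isin(hk_peaks_set)]
    pairs_up = correlate.matched_trajectories(tf_expr, norm_access, pairs_up)
    pairs_hk = correlate.matched_trajectories(tf_expr, norm_access, pairs_hk)
    correlations = correlate.correlate(tf_expr, norm_access, pairs_up)
    correlations_bg = correlate.correlate(tf_expr, norm_access, pairs_hk)
    regulator_calls = correlate.call_regulators(correlations, correlations_bg, th)

    # --- footprinting -----------------------------------------------------
    motif_widths = {m.motif_id: m.width for m in bundle.motifs}
    occ = footprint.occurrence_centres(occurrences, pk, motif_widths)
    scores = footprint.occurrence_scores(bundle.tracks, occ, th)
    diffbind = footprint.differential_binding(scores, 3, 5)
    efup_scores = scores[scores["peak_id"].isin(efup_peaks)]
    fp_corr = footprint.footprint_expression_correlation(efup_scores, tf_expr, days=ATAC_DAYS)

    # --- CRE prioritization ----------------------------------------------
    cre_rankings = {}
    for gene in bundle.truth.cre_peaks:
        mat = cre.change_matrix(
            gene, scores, region_table, pk, genome.genes, norm_access, 3, 5
        )
        if len(mat):
            cre_rankings[gene] = cre.rank_candidates(mat)

    return PipelineResult(
        gene_sets=gene_sets,
        cluster_result=cluster_result,
        norm_access=norm_access,
        dynamic=dynamic,
        annotation=annotation,
        region_table=region_table,
        occurrences=occurrences,
        presence=presence,
        expressed=expressed,
        enrich_opening=enrich_opening,
        logit_coefs=logit_coefs,
        logit_lambda=logit_lambda,
        tf_expr=tf_expr,
        correlations=correlations,
        correlations_bg=correlations_bg,
        regulator_calls=regulator_calls,
        scores=scores,
        diffbind=diffbind,
        fp_expr_corr_efup=fp_corr,
        cre_rankings=cre_rankings,
    )
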