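"""Synthetic optic-vesicle time-course data with planted ground truth.

Builds a toy genome (TADs with inter-TAD gaps, genes, accessibility peaks,
peak sequences), then simulates the study design: RNA-seq counts for days
0-5 in triplicate with a GFP+/GFP- sort at days 4-5, and ATAC-seq peak
signal plus per-bp corrected tracks for days 0, 1, 2, 3 and 5 (day 4 is
deliberately absent).  Gene programmes (steep up after day 3, gradual down,
transient, stable), TF roles (activator / repressor / inert), peak dynamics
(opening / closing / static), motif embeddings and per-bp footprints are all
planted and recorded in a :class:`TruthTable` so recovery can be scored.

Noise models: negative-binomial counts (mean-dispersion parameterization),
log-normal multiplicative noise on peak signal, Poisson per-bp track noise.
All randomness flows from one ``numpy.random.default_rng`` (PCG64) seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SampleMeta
from .io import CountMatrix, FootprintTrack, Motif, MotifSet

__all__ = [
    "SimConfig",
    "TruthTable",
    "Genome",
    "SimBundle",
    "builtin_motifs",
    "generate_genome",
    "generate_expression",
    "generate_accessibility",
    "simulate",
]

EXPR_DAYS = [0, 1, 2, 3, 4, 5]
ATAC_DAYS = [0, 1, 2, 3, 5]  # day 4 excluded (kept out of the design)

# TF panel: roles are planted and recorded in the truth table.
ACTIVATOR_TFS = ["Rax", "Pax6", "Lhx2"]
REPRESSOR_TFS = ["Pou5f1", "Nanog", "Zfp42"]
INERT_TFS = ["Sox2", "Otx2", "Tcf3", "Tcf7", "Tcf7l2", "Six3"]
ALL_TFS = ACTIVATOR_TFS + REPRESSOR_TFS + INERT_TFS

# Fixed width-8 consensus words, pairwise well-separated (and from reverse
# complements) so that at the default scan threshold only exact planted
# copies are recovered.  Rax carries two motifs to exercise per-TF collapse.
_CONSENSUS = {
    "Rax.A": ("Rax", "TAATCCGA"),
    "Rax.B": ("Rax", "TAATGGCA"),
    "Pax6.A": ("Pax6", "TTCACGCT"),
    "Lhx2.A": ("Lhx2", "TGATTGCC"),
    "Pou5f1.A": ("Pou5f1", "ATGCAAAT"),
    "Nanog.A": ("Nanog", "CCATTGTT"),
    "Zfp42.A": ("Zfp42", "GCGCATCC"),
    "Sox2.A": ("Sox2", "CATTGTAC"),
    "Otx2.A": ("Otx2", "GGATTAGG"),
    "Tcf3.A": ("Tcf3", "CACCTGCA"),
    "Tcf7.A": ("Tcf7", "CTTTGATC"),
    "Tcf7l2.A": ("Tcf7l2", "CTTTGTTG"),
    "Six3.A": ("Six3", "GTATCATG"),
}

# The planted candidate CRE embeds (bound) motifs of these key TFs.
CRE_TFS = ["Rax", "Pax6", "Lhx2", "Sox2", "Otx2", "Tcf3"]


def builtin_motifs() -> MotifSet:
    """Strong PFMs (85/5/5/5 per column) for the synthetic TF panel."""
    motifs = []
    for motif_id, (tf, cons) in _CONSENSUS.items():
        pfm = np.full((4, len(cons)), 5.0)
        for j, base in enumerate(cons):
            pfm["ACGT".index(base), j] = 85.0
        motifs.append(Motif(motif_id=motif_id, tf=tf, pfm=pfm))
    return MotifSet(motifs)


@dataclass
class SimConfig:
    """Study conditions for the synthetic preset.

    Defaults define the *default* preset: 12 TADs on 4 chromosomes
    (4 EF-up, 4 EF-down, 4 housekeeping by planted gene content), 30 genes
    and 30 peaks per TAD, triplicate expression, and effect sizes chosen so
    planted contrasts clear the analysis gates by a wide margin (8-fold DE
    steps, 3 log2-units of peak opening, footprint depth 4 signal units on
    a per-bp baseline of ~24).
    """

    n_tads: int = 15
    genes_per_tad: int = 30
    peaks_per_tad: int = 48
    tads_per_chrom: int = 3
    tad_length: int = 64_000
    gap_length: int = 12_000
    chrom_margin: int = 5_000
    peak_width_range: tuple[int, int] = (500, 700)
    cre_peak_width: int = 1200  # wide enough for well-separated bound motifs
    n_reps: int = 3
    dispersion: float = 2e-4
    # expression means (normalized-count scale); deep counts and low
    # dispersion keep every contrast arm's log-scale CV small, which the
    # unmoderated 3-replicate Welch test needs to resolve the planted steps
    up_traj: tuple = (400.0, 400.0, 600.0, 1200.0, 24000.0, 30000.0)  # d4/5 = GFP+
    up_gfpneg: tuple = (1200.0, 1200.0)  # low but non-zero at d4/d5 GFP-
    down_traj: tuple = (20000.0, 19000.0, 18000.0, 16000.0, 800.0, 700.0)
    down_gfpneg: tuple = (20000.0, 18000.0)
    transient_traj: tuple = (1500.0, 4000.0, 9000.0, 16000.0, 800.0, 700.0)
    transient_gfpneg: tuple = (16000.0, 14000.0)
    stable_expr_range: tuple[float, float] = (500.0, 20000.0)
    tf_inert_expr: float = 2000.0
    # accessibility (arbitrary corrected-signal units per bp)
    atac_low: float = 3.0
    atac_high: float = 24.0
    atac_base: float = 10.0
    atac_lognoise_sd: float = 0.18  # natural-log sd of peak-level noise
    gc_bias_strength: float = 1.0  # log2 units across the gc range
    footprint_depth: float = 4.0
    flank_boost_frac: float = 0.2  # fraction of depth added to flanks
    # motif embedding probabilities (recorded in the truth table)
    p_act_in_opening: float = 0.75
    p_rep_in_opening: float = 0.55
    p_act_in_closing: float = 0.15
    p_rep_in_closing: float = 0.9
    p_any_in_static: float = 0.35
    p_inert_in_dynamic: float = 0.5
    frac_opening_in_efup: float = 0.8
    frac_closing_in_efdown: float = 0.8

    @classmethod
    def preset(cls, name: str) -> "SimConfig":
        if name == "default":
            return cls()
        if name == "small":
            return cls(n_tads=6, tads_per_chrom=3, genes_per_tad=14, peaks_per_tad=12)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class TruthTable:
    """Planted ground truth joined to predictions by downstream tests."""

    gene_programme: dict[str, str]  # up_after_d3 | gradual_down | transient | stable
    tf_role: dict[str, str]  # activator | repressor | inert
    peak_dynamic: dict[int, str]  # opening | closing | static
    planted_motifs: list[dict]  # peak_id, tf, motif_id, offset, strand, bound_days
    footprint_depth_truth: float
    cre_peaks: dict[str, int]  # target gene -> planted CRE peak_id
    embedding_rates: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["peak_dynamic"] = {str(k): v for k, v in d["peak_dynamic"].items()}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        d["peak_dynamic"] = {int(k): v for k, v in d["peak_dynamic"].items()}
        return cls(**d)

    def genes_with(self, programme: str) -> set[str]:
        return {g for g, p in self.gene_programme.items() if p == programme}


@dataclass
class Genome:
    """Toy genome layout: TAD/gap regions, genes with TSS, peaks, sequences."""

    tads: pd.DataFrame  # chrom, start, end, tad_id
    genes: pd.DataFrame  # chrom, start, end, name, strand, tss
    peaks: pd.DataFrame  # peak_id, chrom, start, end, gc
    seqs: dict[str, str]  # peak name -> sequence
    chrom_sizes: dict[str, int]


@dataclass
class SimBundle:
    """Everything one pipeline run consumes, plus the truth table."""

    config: SimConfig
    genome: Genome
    motifs: MotifSet
    counts: CountMatrix
    peak_signal: pd.DataFrame  # raw peak x day signal, columns d0..d5
    tracks: dict[int, FootprintTrack]  # day -> per-bp corrected track
    truth: TruthTable


# ---------------------------------------------------------------------------
# genome + truth


def _tad_types(n_tads: int) -> list[str]:
    # round-robin so every chromosome carries a mix
    kinds = ["ef_up", "ef_down", "housekeeping"]
    return [kinds[i % 3] for i in range(n_tads)]


def generate_genome(
    n_tads: int = 12,
    genes_per_tad: int = 30,
    peaks_per_tad: int = 30,
    seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[Genome, TruthTable]:
    """Lay out TADs/gaps/genes/peaks and plant all ground truth.

    The target gene for the first activator TF (Rax) is placed in an
    inter-TAD gap together with its planted CRE, mirroring genes that fall
    between TAD calls; the other activator targets sit inside EF-up TADs.
    """
    cfg = config or SimConfig()
    cfg = SimConfig(**{**asdict(cfg), "n_tads": n_tads,
                       "genes_per_tad": genes_per_tad, "peaks_per_tad": peaks_per_tad})
    if min(n_tads, genes_per_tad, peaks_per_tad) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)

    n_chroms = int(np.ceil(n_tads / cfg.tads_per_chrom))
    chrom_len = (
        2 * cfg.chrom_margin
        + cfg.tads_per_chrom * cfg.tad_length
        + (cfg.tads_per_chrom - 1) * cfg.gap_length
    )
    slot = cfg.tad_length // max(cfg.genes_per_tad, cfg.peaks_per_tad)
    if slot < cfg.peak_width_range[1] + 10:
        raise ValueError(
            "requested elements exceed chromosome capacity: "
            f"{max(genes_per_tad, peaks_per_tad)} elements need more than "
            f"{cfg.tad_length} bp per TAD"
        )

    tad_rows, gap_rows = [], []
    tid = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = cfg.chrom_margin
        for j in range(cfg.tads_per_chrom):
            if tid >= n_tads:
                break
            tad_rows.append((chrom, pos, pos + cfg.tad_length, f"tad{tid}"))
            pos += cfg.tad_length
            if j < cfg.tads_per_chrom - 1 and tid + 1 < n_tads:
                gap_rows.append((chrom, pos, pos + cfg.gap_length))
            pos += cfg.gap_length
            tid += 1
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "tad_id"])
    types = _tad_types(len(tads))

    gene_programme: dict[str, str] = {}
    tf_role = {tf: "activator" for tf in ACTIVATOR_TFS}
    tf_role.update({tf: "repressor" for tf in REPRESSOR_TFS})
    tf_role.update({tf: "inert" for tf in INERT_TFS})

    # --- genes -----------------------------------------------------------
    gene_rows = []  # chrom, tss, strand, name
    up_tads = [i for i, t in enumerate(types) if t == "ef_up"]
    down_tads = [i for i, t in enumerate(types) if t == "ef_down"]
    hk_tads = [i for i, t in enumerate(types) if t == "housekeeping"]

    # TF gene placement: Rax in the first inter-TAD gap; other activators in
    # EF-up TADs; repressors in EF-down TADs; inert TFs in housekeeping TADs.
    special: dict[str, tuple[str, int, int]] = {}  # gene -> (chrom, lo, hi)
    if gap_rows:
        g = gap_rows[0]
        special["Rax"] = (g[0], g[1] + 1000, g[2] - 1000)
    else:
        special["Rax"] = _tad_span(tads, up_tads[0])
    for tf, ti in zip(ACTIVATOR_TFS[1:], up_tads):
        special[tf] = _tad_span(tads, ti)
    for tf, ti in zip(REPRESSOR_TFS, down_tads * 2):
        special[tf] = _tad_span(tads, ti)
    for tf, ti in zip(INERT_TFS, (hk_tads * 3)):
        special[tf] = _tad_span(tads, ti)

    for name, (chrom, lo, hi) in special.items():
        tss = int(rng.integers(lo, hi))
        gene_rows.append((chrom, tss, rng.choice(["+", "-"]), name))
        role = tf_role[name]
        gene_programme[name] = {
            "activator": "up_after_d3",
            "repressor": "gradual_down",
            "inert": "stable",
        }[role]

    gi = 0
    for ti, ttype in enumerate(types):
        chrom, lo, hi = _tad_span(tads, ti)
        if ttype == "ef_up":
            n_up = max(4, cfg.genes_per_tad // 4 + 1)
            mix = ["up_after_d3"] * n_up + ["stable"] * (cfg.genes_per_tad - n_up)
        elif ttype == "ef_down":
            n_dn = max(4, cfg.genes_per_tad // 3)
            n_tr = max(2, cfg.genes_per_tad // 6)
            mix = ["gradual_down"] * n_dn + ["transient"] * n_tr
            mix += ["stable"] * (cfg.genes_per_tad - len(mix))
        else:
            mix = ["stable"] * cfg.genes_per_tad
        for prog in mix[: cfg.genes_per_tad]:
            name = f"g{gi:04d}"
            gi += 1
            tss = int(rng.integers(lo + 200, hi - 200))
            gene_rows.append((chrom, tss, rng.choice(["+", "-"]), name))
            gene_programme[name] = prog
    # a couple of stable genes inside the remaining gaps
    for g in gap_rows[1:3]:
        name = f"g{gi:04d}"
        gi += 1
        tss = int(rng.integers(g[1] + 500, g[2] - 500))
        gene_rows.append((g[0], tss, rng.choice(["+", "-"]), name))
        gene_programme[name] = "stable"

    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "name"])
    # model each gene body as 2 kb downstream of the TSS
    body = 2000
    genes["start"] = np.where(genes["strand"] == "+", genes["tss"], genes["tss"] - body)
    genes["end"] = genes["start"] + body
    genes["start"] = genes["start"].clip(lower=0)

    # --- peaks -----------------------------------------------------------
    # each activator-TF gene's region also hosts one dedicated wide CRE peak
    act_tad = dict(zip(ACTIVATOR_TFS[1:], up_tads))
    peak_rows = []  # chrom, start, end, dynamic
    cre_rows: dict[str, int] = {}  # tf -> row index in peak_rows
    elem_w = max(cfg.peak_width_range[1], cfg.cre_peak_width)
    for ti, ttype in enumerate(types):
        chrom, lo, hi = _tad_span(tads, ti)
        if ttype == "ef_up":
            n_open = int(round(cfg.frac_opening_in_efup * cfg.peaks_per_tad))
            classes = ["opening"] * n_open + ["static"] * (cfg.peaks_per_tad - n_open)
        elif ttype == "ef_down":
            n_close = int(round(cfg.frac_closing_in_efdown * cfg.peaks_per_tad))
            classes = ["closing"] * n_close + ["static"] * (cfg.peaks_per_tad - n_close)
        else:
            classes = ["static"] * cfg.peaks_per_tad
        starts = _spread_positions(rng, lo, hi, cfg.peaks_per_tad, elem_w)
        cre_tf = next((tf for tf, t_i in act_tad.items() if t_i == ti), None)
        for k, (s, cl) in enumerate(zip(starts, classes)):
            if cre_tf is not None and k == len(starts) - 1:
                cre_rows[cre_tf] = len(peak_rows)
                peak_rows.append((chrom, s, s + cfg.cre_peak_width, "opening"))
            else:
                w = int(rng.integers(*cfg.peak_width_range))
                peak_rows.append((chrom, s, s + w, cl))

    # peaks in the Rax gap: the planted CRE plus competitors
    if gap_rows:
        g = gap_rows[0]
        starts = _spread_positions(rng, g[1], g[2], 6, elem_w)
        for j, s in enumerate(starts):
            if j == 0:
                cre_rows["Rax"] = len(peak_rows)
                peak_rows.append((g[0], s, s + cfg.cre_peak_width, "opening"))
            else:
                w = int(rng.integers(*cfg.peak_width_range))
                peak_rows.append((g[0], s, s + w, "opening"))

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "dynamic"])
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index()
    order = peaks.pop("index")  # original row -> sorted position
    peaks.insert(0, "peak_id", np.arange(len(peaks)))
    row_to_id = {orig: pid for pid, orig in zip(peaks["peak_id"], order)}

    peak_dynamic = dict(zip(peaks["peak_id"], peaks["dynamic"]))

    # --- sequences + motif embedding ------------------------------------
    motifs = builtin_motifs()
    by_tf = motifs.by_tf()
    seqs: dict[str, str] = {}
    planted: list[dict] = []
    bases = np.array(list("ACGT"))
    # GC content varies per peak so normalization has a real covariate
    gc = rng.uniform(0.3, 0.7, size=len(peaks))

    cre_peaks = {tf: int(row_to_id[row]) for tf, row in cre_rows.items()}

    cre_ids = set(cre_peaks.values())
    for i, row in peaks.iterrows():
        pid = int(row["peak_id"])
        width = int(row["end"] - row["start"])
        p_gc = gc[i]
        probs = np.array(
            [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
        )
        seq = list(rng.choice(bases, size=width, p=probs))
        embeds: list[tuple[str, list[int]]] = []  # (tf, bound_days)
        if pid in cre_ids:
            embeds = [(tf, [5]) for tf in CRE_TFS]
        elif row["dynamic"] == "opening":
            for tf in ACTIVATOR_TFS:
                if rng.random() < cfg.p_act_in_opening:
                    embeds.append((tf, [5]))
            for tf in REPRESSOR_TFS:
                if rng.random() < cfg.p_rep_in_opening:
                    embeds.append((tf, []))
            for tf in INERT_TFS:
                if rng.random() < cfg.p_inert_in_dynamic:
                    embeds.append((tf, []))
        elif row["dynamic"] == "closing":
            for tf in REPRESSOR_TFS:
                if rng.random() < cfg.p_rep_in_closing:
                    embeds.append((tf, [0, 1]))
            for tf in ACTIVATOR_TFS:
                if rng.random() < cfg.p_act_in_closing:
                    embeds.append((tf, []))
            for tf in INERT_TFS:
                if rng.random() < cfg.p_inert_in_dynamic:
                    embeds.append((tf, []))
        else:
            embeds = [
                (tf, []) for tf in ALL_TFS if rng.random() < cfg.p_any_in_static
            ]
        # place embeddings away from peak edges; the margin keeps
        # centre +/- (12 + 60) bp flanks inside the peak.  Bound embeds are
        # separated by >= 150 bp so their planted footprints (24 bp central
        # depletion, 60 bp flank boosts) never overlap another occurrence's
        # measurement windows; overflow demotes to unbound (presence kept).
        margin = 110
        span = width - 2 * margin
        bound = [e for e in embeds if e[1]]
        unbound = [e for e in embeds if not e[1]]
        max_bound = max(1, span // 160)
        if len(bound) > max_bound:
            keep = set(rng.choice(len(bound), size=max_bound, replace=False))
            unbound = [(tf, []) for i, (tf, _) in enumerate(bound) if i not in keep] + unbound
            bound = [b for i, b in enumerate(bound) if i in keep]
        off_bound = _spread_positions(rng, margin, width - margin, len(bound), 150)
        max_unb = max(0, span // 15 - len(bound))
        if len(unbound) > max_unb:
            keep = rng.choice(len(unbound), size=max_unb, replace=False)
            unbound = [unbound[k] for k in sorted(keep)]
        off_unb = [
            o
            for o in _spread_positions(rng, margin, width - margin, len(unbound), 10)
            if all(abs(o - ob) >= 12 for ob in off_bound)
        ]
        placed = list(zip(bound, off_bound)) + list(zip(unbound, off_unb))
        for (tf, bound_days), off in placed:
            motif = by_tf[tf][int(rng.integers(len(by_tf[tf])))]
            strand = "+" if rng.random() < 0.5 else "-"
            word = motif.consensus if strand == "+" else _revcomp(motif.consensus)
            seq[off : off + motif.width] = list(word)
            planted.append(
                {
                    "peak_id": pid,
                    "tf": tf,
                    "motif_id": motif.motif_id,
                    "offset": int(off),
                    "strand": strand,
                    "bound_days": list(bound_days),
                }
            )
        seqs[f"peak{pid}"] = "".join(seq)

    peaks["gc"] = gc
    chrom_sizes = {f"chr{c + 1}": chrom_len for c in range(n_chroms)}
    genome = Genome(
        tads=tads,
        genes=genes[["chrom", "start", "end", "name", "strand", "tss"]],
        peaks=peaks[["peak_id", "chrom", "start", "end", "gc"]].copy(),
        seqs=seqs,
        chrom_sizes=chrom_sizes,
    )
    truth = TruthTable(
        gene_programme=gene_programme,
        tf_role=tf_role,
        peak_dynamic=peak_dynamic,
        planted_motifs=planted,
        footprint_depth_truth=cfg.footprint_depth,
        cre_peaks=cre_peaks,
        embedding_rates={
            "act_in_opening": cfg.p_act_in_opening,
            "rep_in_closing": cfg.p_rep_in_closing,
            "any_in_static": cfg.p_any_in_static,
        },
    )
    return genome, truth


def _tad_span(tads: pd.DataFrame, i: int) -> tuple[str, int, int]:
    r = tads.iloc[i]
    return str(r["chrom"]), int(r["start"]) + 300, int(r["end"]) - 300


def _spread_positions(rng, lo: int, hi: int, n: int, elem_width: int) -> list[int]:
    """n non-overlapping start positions in [lo, hi), one per equal slot."""
    if n == 0:
        return []
    span = hi - lo
    slot = span // n
    if slot <= elem_width:
        raise ValueError(f"cannot place {n} elements of width {elem_width} in {span} bp")
    out = []
    for k in range(n):
        jitter = int(rng.integers(0, max(1, slot - elem_width)))
        out.append(lo + k * slot + jitter)
    return out


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    truth: TruthTable,
    n_reps: int = 3,
    dispersion: float = 0.01,
    seed: int = 0,
    config: SimConfig | None = None,
) -> CountMatrix:
    """Negative-binomial counts around programme-specific mean trajectories.

    Samples: days 0-3 unsorted triplicates, days 4-5 split GFP+/GFP-.
    Up-regulated genes keep low but non-zero GFP- means so the sorted
    contrasts behave like an imperfect FACS gate.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (differential expression needs replicates)")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    samples: list[SampleMeta] = []
    for day in EXPR_DAYS:
        gfps = ["unsorted"] if day < 4 else ["positive", "negative"]
        for gfp in gfps:
            for rep in range(1, n_reps + 1):
                tag = {"unsorted": "", "positive": "_gfppos", "negative": "_gfpneg"}[gfp]
                samples.append(
                    SampleMeta(sample_id=f"d{day}{tag}_r{rep}", day=day, replicate=rep, gfp=gfp)
                )

    genes = sorted(truth.gene_programme)
    # persistent per-gene baseline for stable genes (derived from the same rng)
    stable_base = {}
    lo, hi = cfg.stable_expr_range
    for g in genes:
        if truth.gene_programme[g] == "stable":
            if g in truth.tf_role:
                stable_base[g] = cfg.tf_inert_expr
            else:
                stable_base[g] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def mean_for(gene: str, s: SampleMeta) -> float:
        prog = truth.gene_programme[gene]
        d = s.day
        if prog == "stable":
            return stable_base[gene]
        traj, neg = {
            "up_after_d3": (cfg.up_traj, cfg.up_gfpneg),
            "gradual_down": (cfg.down_traj, cfg.down_gfpneg),
            "transient": (cfg.transient_traj, cfg.transient_gfpneg),
        }[prog]
        if s.gfp == "negative":
            return neg[d - 4]
        return traj[d]

    # sample-specific library factors so size-factor estimation is exercised
    libs = np.exp(rng.normal(0.0, 0.25, size=len(samples)))
    mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
    n_nb = 1.0 / dispersion
    for j, s in enumerate(samples):
        mu = np.array([mean_for(g, s) for g in genes]) * libs[j]
        p = n_nb / (n_nb + mu)
        mat[:, j] = rng.negative_binomial(n_nb, p)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=[s.sample_id for s in samples])
    return CountMatrix(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# accessibility


def generate_accessibility(
    truth: TruthTable,
    genome: Genome,
    seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, dict[int, FootprintTrack]]:
    """Per-day raw peak signal and per-bp corrected tracks with footprints.

    Opening peaks step from ``atac_low`` to ``atac_high`` between days 3 and
    5 (>1.5 log2 units before noise); closing peaks do the reverse; static
    peaks stay at ``atac_base``.  Raw peak signal carries log-normal noise, a
    planted GC bias and a peak-width effect (both removed by normalization
    downstream).  Tracks put Poisson noise around the per-bp day level, with
    a central depletion plus flanking boost at each planted bound occurrence.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    peaks = genome.peaks
    motif_widths = {m.motif_id: m.width for m in builtin_motifs()}

    level = np.zeros((len(peaks), len(ATAC_DAYS)))
    for i, pid in enumerate(peaks["peak_id"]):
        cl = truth.peak_dynamic[int(pid)]
        for j, day in enumerate(ATAC_DAYS):
            if cl == "opening":
                level[i, j] = cfg.atac_high if day == 5 else cfg.atac_low
            elif cl == "closing":
                level[i, j] = cfg.atac_low if day == 5 else cfg.atac_high
            else:
                level[i, j] = cfg.atac_base

    widths = (peaks["end"] - peaks["start"]).to_numpy()
    gc = peaks["gc"].to_numpy()
    # raw peak signal: level x width x planted GC bias x noise x day libsize
    day_lib = np.exp(rng.normal(0.0, 0.2, size=len(ATAC_DAYS)))
    gc_bias = 2.0 ** (cfg.gc_bias_strength * (gc - 0.5))
    noise = np.exp(rng.normal(0.0, cfg.atac_lognoise_sd, size=level.shape))
    raw = level * widths[:, None] / 450.0 * gc_bias[:, None] * noise * day_lib[None, :]
    signal = pd.DataFrame(raw, columns=[f"d{d}" for d in ATAC_DAYS])
    signal.insert(0, "peak_id", peaks["peak_id"].to_numpy())

    # per-bp tracks: Poisson noise around the day level, with footprints
    occ_by_peak: dict[int, list[dict]] = {}
    for occ in truth.planted_motifs:
        occ_by_peak.setdefault(occ["peak_id"], []).append(occ)

    d_central = cfg.footprint_depth * (1.0 - cfg.flank_boost_frac)
    d_flank = cfg.footprint_depth * cfg.flank_boost_frac
    tracks: dict[int, FootprintTrack] = {}
    for j, day in enumerate(ATAC_DAYS):
        recs = []
        for i, row in peaks.iterrows():
            pid = int(row["peak_id"])
            width = int(row["end"] - row["start"])
            lam = np.full(width, level[i, j])
            for occ in occ_by_peak.get(pid, []):
                if day not in occ["bound_days"]:
                    continue
                centre = occ["offset"] + motif_widths[occ["motif_id"]] // 2
                c0, c1 = centre - 12, centre + 12
                lam[max(0, c0) : c1] = np.maximum(lam[max(0, c0) : c1] - d_central, 0.05)
                lam[max(0, c0 - 60) : max(0, c0)] += d_flank
                lam[c1 : c1 + 60] += d_flank
            vals = rng.poisson(lam).astype(float)
            start = int(row["start"])
            recs.append((row["chrom"], start, vals))
        frames = []
        for chrom, start, vals in recs:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": np.arange(start, start + len(vals)),
                        "end": np.arange(start + 1, start + len(vals) + 1),
                        "value": vals,
                    }
                )
            )
        tracks[day] = FootprintTrack(pd.concat(frames, ignore_index=True))
    return signal, tracks


# ---------------------------------------------------------------------------
# one-call bundle


def simulate(preset: str = "default", seed: int = 0, config: SimConfig | None = None) -> SimBundle:
    """Generate the full input bundle for a pipeline run."""
    cfg = config or SimConfig.preset(preset)
    ss = np.random.SeedSequence(seed)
    s_gen, s_expr, s_atac = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    genome, truth = generate_genome(
        cfg.n_tads, cfg.genes_per_tad, cfg.peaks_per_tad, seed=s_gen, config=cfg
    )
    counts = generate_expression(
        truth, n_reps=cfg.n_reps, dispersion=cfg.dispersion, seed=s_expr, config=cfg
    )
    signal, tracks = generate_accessibility(truth, genome, seed=s_atac, config=cfg)
    return SimBundle(
        config=cfg,
        genome=genome,
        motifs=builtin_motifs(),
        counts=counts,
        peak_signal=signal,
        tracks=tracks,
        truth=truth,
    )
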