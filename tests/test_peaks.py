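"""Consensus merge, normalization, annotation, dynamics, TADs, associations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovfield.peaks import (
    annotate,
    assign_tads,
    dynamic_peaks,
    merge_consensus,
    normalize_accessibility,
    promoter_stats,
    region_gene_associations,
)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestMerge:
    def test_touching_intervals_merge(self):
        out = merge_consensus([_bed([("chr1", 0, 10)]), _bed([("chr1", 10, 20)])])
        assert len(out) == 1
        assert (int(out["start"][0]), int(out["end"][0])) == (0, 20)

    def test_disjoint_stay_separate(self):
        out = merge_consensus([_bed([("chr1", 0, 5), ("chr1", 7, 9)])])
        assert len(out) == 2

    def test_identical_days_idempotent(self):
        day = _bed([("chr1", 0, 5), ("chr1", 100, 130)])
        out = merge_consensus([day, day, day])
        assert out[["chrom", "start", "end"]].equals(day)

    def test_blacklist_removed_by_any_overlap(self):
        out = merge_consensus(
            [_bed([("chr1", 0, 10), ("chr1", 50, 60)])],
            blacklist=_bed([("chr1", 9, 12)]),
        )
        assert list(out["start"]) == [50]

    def test_matches_bedtools_semantics(self, tmp_path):
        """Independent oracle: bedtools merge on the same intervals."""
        import subprocess

        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, 5000, size=40))
        rows = [("chr1", int(s), int(s + rng.integers(5, 120))) for s in starts]
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows))
        try:
            res = subprocess.run(
                ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True, check=True
            )
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("bedtools unavailable")
        expected = [tuple(l.split("\t")) for l in res.stdout.strip().splitlines()]
        got = merge_consensus([_bed(rows)])
        assert [
            (c, str(s), str(e)) for c, s, e in zip(got["chrom"], got["start"], got["end"])
        ] == expected


class TestNormalize:
    def test_equal_covariates_reduce_to_scaling_log(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 50, size=(40, 3)), columns=["d0", "d3", "d5"])
        gc = np.full(40, 0.5)
        width = np.full(40, 500)
        out = normalize_accessibility(raw, gc, width)
        totals = raw.sum(axis=0)
        expected = np.log2(raw * (1e6 / totals) + 1)
        # identical covariates: the binned correction is a constant per peak
        diff = out - expected
        np.testing.assert_allclose(diff.std(axis=0), 0, atol=1e-9)

    def test_gc_bias_removed(self, rng):
        gc = rng.uniform(0.2, 0.8, size=300)
        width = rng.integers(300, 700, size=300).astype(float)
        base = rng.uniform(5, 15, size=300)
        biased = base * 2 ** (2.0 * (gc - 0.5))
        raw = pd.DataFrame(
            {d: biased * np.exp(rng.normal(0, 0.05, 300)) for d in ["d0", "d3", "d5"]}
        )
        before = abs(np.corrcoef(np.log2(raw["d3"] + 1), gc)[0, 1])
        out = normalize_accessibility(raw, gc, width)
        after = abs(np.corrcoef(out["d3"], gc)[0, 1])
        assert after <= 0.2 * before

    def test_day_scaling_invariance(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 50, size=(60, 3)), columns=["d0", "d3", "d5"])
        gc = rng.uniform(0.3, 0.7, size=60)
        width = rng.integers(300, 700, size=60).astype(float)
        out1 = normalize_accessibility(raw, gc, width)
        raw2 = raw.copy()
        raw2["d5"] = raw2["d5"] * 2
        out2 = normalize_accessibility(raw2, gc, width)
        np.testing.assert_allclose(out1["d5"], out2["d5"], atol=1e-9)

    def test_invalid_covariates(self):
        raw = pd.DataFrame({"d0": [1.0, 2.0]})
        with pytest.raises(ValueError):
            normalize_accessibility(raw, np.array([0.5, 1.5]), np.array([10.0, 10.0]))
        with pytest.raises(ValueError):
            normalize_accessibility(raw, np.array([0.5, 0.5]), np.array([0.0, 10.0]))


class TestAnnotate:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1"],
            "start": [10_000],
            "end": [18_000],
            "name": ["g"],
            "strand": ["+"],
            "tss": [10_000],
            "exon_start": [10_000],
            "exon_end": [10_400],
        }
    )

    def _ann(self, start, end):
        pk = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})
        return annotate(pk, self.GENES).iloc[0]

    def test_tss_overlap_is_promoter(self):
        assert self._ann(9_800, 10_100) == "promoter"

    def test_intron_without_tss(self):
        assert self._ann(14_000, 14_300) == "intronic"

    def test_exon(self):
        assert self._ann(12_000, 12_200) == "intronic"
        assert self._ann(10_350, 10_600) != "intergenic"

    def test_promoter_precedence_over_exon(self):
        # overlaps both the first exon and the promoter window
        assert self._ann(10_200, 10_500) == "promoter"

    def test_intergenic(self):
        assert self._ann(50_000, 50_200) == "intergenic"


class TestDynamic:
    def test_classes_and_strict_threshold(self):
        norm = pd.DataFrame(
            {"d3": [1.0, 1.0, 1.0], "d5": [3.0, 2.5, 0.2]}, index=[0, 1, 2]
        )
        # deltas: +2.0 -> opening; +1.5 exactly -> static; -0.8 -> static
        cls = dynamic_peaks(norm, "d3", "d5")
        assert list(cls) == ["opening", "static", "static"]

    def test_opening_recall_on_synthetic(self, bundle_default, result_default):
        truth = pd.Series(bundle_default.truth.peak_dynamic)
        opening = truth[truth == "opening"].index
        assert (result_default.dynamic.loc[opening] == "opening").mean() >= 0.95

    def test_missing_day_rejected(self):
        with pytest.raises(ValueError):
            dynamic_peaks(pd.DataFrame({"d3": [1.0]}), "d3", "d5")


class TestTads:
    TADS = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [1000, 5000],
            "end": [3000, 8000],
            "tad_id": ["t0", "t1"],
        }
    )
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1500, 3500, 6000],
            "end": [1600, 3600, 6100],
            "name": ["up1", "gapgene", "hk1"],
            "strand": ["+", "+", "-"],
            "tss": [1500, 3500, 6000],
        }
    )
    PEAKS = pd.DataFrame(
        {
            "peak_id": [0, 1, 2],
            "chrom": ["chr1"] * 3,
            "start": [4999, 3200, 1100],
            "end": [5001, 3300, 1200],
        }
    )

    def _rt(self, gene_sets=None):
        gs = gene_sets or {
            "ef_up": {"up1"},
            "ef_down": {"gapgene"},
            "housekeeping": {"hk1"},
        }
        return assign_tads(self.PEAKS, self.GENES, self.TADS, gs)

    def test_gap_synthesized_and_gene_in_gap(self):
        rt = self._rt()
        gaps = rt.regions[rt.regions["kind"] == "gap"]
        assert len(gaps) == 1
        assert (int(gaps["start"].iloc[0]), int(gaps["end"].iloc[0])) == (3000, 5000)
        gap_id = gaps["region_id"].iloc[0]
        assert rt.gene_region["gapgene"] == gap_id
        assert rt.region_classes[gap_id] == {"ef_down"}

    def test_midpoint_on_boundary_belongs_to_tad(self):
        rt = self._rt()
        assert rt.peak_region[0] == "t1"  # midpoint 5000 is t1's half-open start

    def test_classes(self):
        rt = self._rt()
        assert rt.region_classes["t0"] == {"ef_up"}
        assert rt.region_classes["t1"] == {"housekeeping"}
        assert set(rt.peaks_in_classes("housekeeping", pure=True)) == {0}

    def test_tiling_invariant(self):
        rt = self._rt()
        for chrom, grp in rt.regions.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()

    def test_overlapping_tads_rejected(self):
        bad = self.TADS.copy()
        bad.loc[1, "start"] = 2500
        with pytest.raises(ValueError, match="overlapping"):
            assign_tads(self.PEAKS, self.GENES, bad, {})


class TestRegionGeneAssociations:
    def test_basal_extension_cap(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "name": ["solo"],
                "strand": ["+"],
                "tss": [3_000_000],
            }
        )
        peaks = pd.DataFrame(
            {
                "peak_id": [0, 1],
                "chrom": ["chr1", "chr1"],
                "start": [2_998_000, 5_200_000],  # 2 kb upstream / >1 Mb away
                "end": [2_998_200, 5_200_200],
            }
        )
        links = region_gene_associations(peaks, genes)
        assert set(links["peak_id"]) == {0}

    def test_peak_between_close_genes_links_both(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "name": ["a", "b"],
                "strand": ["+", "+"],
                "tss": [1_000_000, 1_010_000],
            }
        )
        peaks = pd.DataFrame(
            {"peak_id": [0], "chrom": ["chr1"], "start": [1_004_000], "end": [1_004_300]}
        )
        links = region_gene_associations(peaks, genes)
        assert set(links["gene"]) == {"a", "b"}


class TestPromoterStats:
    def test_exact_small_case(self):
        """U on {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1
        (verified against full enumeration of all 20 arrangements)."""
        a = pd.DataFrame({"d0": [1.0, 2.0, 3.0], "d1": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"d0": [4.0, 5.0, 6.0], "d1": [4.0, 5.0, 6.0]})
        out = promoter_stats(a, b)
        assert out["p_location"] == pytest.approx(0.1)
        # oracle: enumerate all C(6,3) splits of the pooled values
        pooled = [1, 2, 3, 4, 5, 6]
        obs_u = 0
        count_le = 0
        total = 0
        for grp in itertools.combinations(range(6), 3):
            x = [pooled[i] for i in grp]
            y = [pooled[i] for i in range(6) if i not in grp]
            u = sum(1 for xi in x for yi in y if xi > yi)
            total += 1
            if min(u, 9 - u) <= min(obs_u, 9 - obs_u):
                count_le += 1
        assert count_le / total == pytest.approx(out["p_location"])

    def test_identical_groups_nonsignificant(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, size=(30, 4)))
        out = promoter_stats(a, a.copy())
        assert out["p_location"] > 0.9

    def test_large_shift_significant(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, size=(200, 4)))
        b = pd.DataFrame(rng.normal(2, 1, size=(200, 4)))
        out = promoter_stats(a, b)
        assert out["p_location"] < 1e-10
        assert out["median_b"] > out["median_a"]

    def test_small_group_rejected(self):
        a = pd.DataFrame({"d0": [1.0]})
        with pytest.raises(ValueError):
            promoter_stats(a, a)


def test_annotation_partitions_universe(bundle_default, result_default):
    ann = result_default.annotation
    assert set(ann.unique()) <= {"promoter", "exonic", "intronic", "intergenic"}
    assert len(ann) == len(bundle_default.genome.peaks)
    assert ann.notna().all()
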