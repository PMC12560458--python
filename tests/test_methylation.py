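"""bedMethyl parsing, island aggregation, MGMT, differential methylation
and methylation-expression linkage."""

import numpy as np
import pandas as pd
import pytest

import gscresist as g
from gscresist.config import MethylationConfig
from gscresist.methylation import (BedMethylError, combine_strands,
                                   derive_island_gene_map)


def site_frame(rows):
    """rows: (chrom, start, strand, coverage, percent)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "strand",
                                     "coverage", "percent"])
    df["end"] = df["start"] + 1
    return df[["chrom", "start", "end", "strand", "coverage", "percent"]]


def bedmethyl_line(chrom, start, code, cov, pct, strand="+"):
    return "\t".join([chrom, str(start), str(start + 1), code, str(cov),
                      strand, str(start), str(start + 1), "255,0,0",
                      str(cov), str(pct)])


class TestReadBedmethyl:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert g.read_bedmethyl(p).empty

    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("\n".join([
            bedmethyl_line("chr1", 100, "m", 12, 55.5),
            bedmethyl_line("chr1", 200, "m", 4, 0.0, strand="-"),
            bedmethyl_line("chr2", 50, "m", 30, 100.0),
        ]) + "\n")
        rec = g.read_bedmethyl(p)
        assert list(rec["start"]) == [100, 200, 50]
        assert list(rec["percent"]) == [55.5, 0.0, 100.0]
        assert list(rec["coverage"]) == [12, 4, 30]

    def test_non_5mc_codes_skipped(self, tmp_path):
        p = tmp_path / "h.bed"
        p.write_text("\n".join([
            bedmethyl_line("chr1", 100, "m", 10, 40.0),
            bedmethyl_line("chr1", 100, "h", 10, 5.0),  # 5hmC record
        ]) + "\n")
        assert len(g.read_bedmethyl(p)) == 1

    def test_malformed_fraction_limit(self, tmp_path):
        good = [bedmethyl_line("chr1", i, "m", 10, 50.0) for i in range(5)]
        p = tmp_path / "bad.bed"
        p.write_text("\n".join(good + ["garbage line"] * 2) + "\n")
        with pytest.raises(BedMethylError, match="malformed"):
            g.read_bedmethyl(p)
        p2 = tmp_path / "ok.bed"
        p2.write_text("\n".join(good * 4 + ["garbage line"]) + "\n")
        rec = g.read_bedmethyl(p2)
        assert rec.attrs["n_malformed"] == 1


class TestFilterDepth:
    def test_boundary_inclusive(self):
        rec = site_frame([("c", 1, "+", 4, 10.0), ("c", 2, "+", 5, 20.0),
                          ("c", 3, "+", 6, 30.0)])
        out = g.filter_depth(rec, MethylationConfig(min_site_coverage=5))
        assert list(out["start"]) == [2, 3]
        assert out.attrs["n_dropped"] == 1

    def test_matches_enumeration(self, rng):
        covs = rng.integers(0, 20, size=200)
        rec = site_frame([("c", i, "+", int(c), 1.0)
                          for i, c in enumerate(covs)])
        out = g.filter_depth(rec, MethylationConfig(min_site_coverage=5))
        assert len(out) == int((covs >= 5).sum())


class TestIslandMethylation:
    islands = pd.DataFrame({
        "chrom": ["c1", "c1"], "start": [100, 300], "end": [200, 400],
        "island_id": ["I1", "I2"]})

    def test_singleton_and_pair_means(self):
        rec = site_frame([("c1", 150, "+", 10, 40.0),
                          ("c1", 300, "+", 10, 0.0),
                          ("c1", 399, "+", 10, 100.0),
                          ("c1", 400, "+", 10, 77.0)])  # outside (end excl.)
        mat, nmat = g.island_methylation({"s": rec}, self.islands)
        assert mat.loc["I1", "s"] == 40.0
        assert mat.loc["I2", "s"] == 50.0
        assert nmat.loc["I2", "s"] == 2

    def test_uncovered_island_missing_with_warning(self):
        rec = site_frame([("c1", 150, "+", 10, 40.0)])
        with pytest.warns(UserWarning, match="no covered sites"):
            mat, _ = g.island_methylation({"s": rec}, self.islands)
        assert np.isnan(mat.loc["I2", "s"])

    def test_matches_brute_force_scan(self, rng):
        n_isl = 50
        starts = np.arange(n_isl) * 1000
        islands = pd.DataFrame({
            "chrom": "cX", "start": starts, "end": starts + 600,
            "island_id": [f"I{i}" for i in range(n_isl)]})
        pos = rng.integers(0, n_isl * 1000, size=1000)
        pct = rng.uniform(0, 100, size=1000)
        rec = site_frame([("cX", int(p), "+", 10, float(q))
                          for p, q in zip(pos, pct)])
        mat, _ = g.island_methylation({"s": rec}, islands)
        for i in range(n_isl):
            inside = (pos >= starts[i]) & (pos < starts[i] + 600)
            if inside.any():
                assert mat.loc[f"I{i}", "s"] == pytest.approx(
                    pct[inside].mean())
            else:
                assert np.isnan(mat.loc[f"I{i}", "s"])

    def test_record_order_and_split_invariance(self, rng):
        rec = site_frame([("c1", int(p), "+", 10, float(q))
                          for p, q in zip(rng.integers(100, 400, 60),
                                          rng.uniform(0, 100, 60))])
        ref, _ = g.island_methylation({"s": rec}, self.islands)
        shuffled = rec.sample(frac=1, random_state=3).reset_index(drop=True)
        got, _ = g.island_methylation({"s": shuffled}, self.islands)
        pd.testing.assert_frame_equal(ref, got)


class TestMgmt:
    # 1-based inclusive printed bounds -> 0-based [129466684, 129467446)
    LO_0B = 129_466_684
    HI_0B = 129_467_445  # last included position

    def mk(self, pct, positions=None):
        positions = positions or [self.LO_0B, self.HI_0B]
        return site_frame([("chr10", p, "+", 10, pct) for p in positions])

    def test_low_mean_unmethylated(self):
        assert g.mgmt_status(self.mk(0.0))["status"] == "unmethylated"

    def test_cutoff_is_strict(self):
        st = g.mgmt_status(self.mk(22.0))
        assert st["mean_percent"] == 22.0
        assert st["status"] == "unmethylated"
        assert g.mgmt_status(self.mk(22.0 + 1e-9))["status"] == "methylated"

    def test_planted_30_percent_methylated(self):
        assert g.mgmt_status(self.mk(30.0))["status"] == "methylated"

    def test_coordinate_boundaries(self):
        """Both printed end points are inside; one base outside either
        end is not."""
        inside = g.mgmt_status(self.mk(50.0))
        assert inside["n_sites"] == 2
        outside = self.mk(50.0, [self.LO_0B - 1, self.HI_0B + 1])
        assert g.mgmt_status(outside)["status"] == "undetermined"

    def test_no_chr10_records_undetermined(self):
        rec = site_frame([("chr1", 5, "+", 10, 80.0)])
        assert g.mgmt_status(rec)["status"] == "undetermined"


class TestDifferentialIslands:
    def matrix(self, rows, samples):
        return pd.DataFrame(rows, columns=samples,
                            index=[f"I{i}" for i in range(len(rows))])

    def test_extreme_separation_detected_hypo(self, labels_9):
        sens = [40.0] * 4
        res = [10.0] * 5
        jitter = np.array([0.01, -0.01, 0.02, -0.02, 0.0])
        row = {f"GSC-S{i:02d}": sens[i - 1] + jitter[i - 1]
               for i in range(1, 5)}
        row.update({f"GSC-R{i:02d}": res[i - 1] + jitter[i - 1]
                    for i in range(1, 6)})
        mat = pd.DataFrame([row])
        mat.index = ["I0"]
        out = g.differential_islands(mat, labels_9)
        assert bool(out.loc["I0", "significant"])
        assert out.loc["I0", "direction"] == "hypo"  # lower in resistant

    def test_zero_variance_equal_means_p_one(self, labels_9):
        mat = pd.DataFrame([{s: 30.0 for s in labels_9.index}], index=["I0"])
        out = g.differential_islands(mat, labels_9)
        assert out.loc["I0", "pvalue"] == 1.0
        assert out.loc["I0", "t"] == 0.0

    def test_student_matches_scipy_on_fixture(self, labels_9, rng):
        mat = pd.DataFrame(rng.uniform(0, 100, size=(20, 9)),
                           columns=list(labels_9.index))
        out = g.differential_islands(mat, labels_9)
        from scipy.stats import ttest_ind
        res_cols = labels_9[labels_9.group == "resistant"].index
        sen_cols = labels_9[labels_9.group == "sensitive"].index
        for isl in mat.index:
            _, p = ttest_ind(mat.loc[isl, res_cols],
                             mat.loc[isl, sen_cols])
            assert out.loc[isl, "pvalue"] == pytest.approx(p)

    def test_insufficient_group_skipped(self, labels_9):
        mat = pd.DataFrame(
            [{s: (np.nan if s.startswith("GSC-S") else 10.0)
              for s in labels_9.index}], index=["I0"])
        with pytest.warns(UserWarning, match="skipping"):
            out = g.differential_islands(mat, labels_9)
        assert out.empty


class TestLinkExpression:
    def test_planted_inverse_recovered_same_direction_rejected(
            self, labels_9):
        res_cols = [s for s in labels_9.index if s.startswith("GSC-R")]
        sen_cols = [s for s in labels_9.index if s.startswith("GSC-S")]
        dm = pd.DataFrame({
            "mean_resistant": [60.0, 60.0, 30.0],
            "mean_sensitive": [20.0, 20.0, 30.0],
            "significant": [True, True, True],
        }, index=["I_inv", "I_same", "I_flat"])
        dm.index.name = "island_id"
        expr = pd.DataFrame(
            0.0, index=["gInv", "gSame", "gFlat"],
            columns=list(labels_9.index))
        expr.loc["gInv", res_cols] = 1.0
        expr.loc["gInv", sen_cols] = 5.0   # down where methylation up
        expr.loc["gSame", res_cols] = 5.0
        expr.loc["gSame", sen_cols] = 1.0  # same direction
        mapping = {"I_inv": "gInv", "I_same": "gSame", "I_flat": "gFlat"}
        out = g.link_expression(dm, mapping, expr, labels_9)
        assert bool(out.loc["I_inv", "linked"])
        assert not bool(out.loc["I_same", "linked"])
        assert not bool(out.loc["I_flat", "linked"])  # zero sign product

    def test_unmapped_islands_counted(self, labels_9):
        dm = pd.DataFrame({"mean_resistant": [50.0],
                           "mean_sensitive": [10.0],
                           "significant": [True]}, index=["I0"])
        expr = pd.DataFrame(1.0, index=["g"],
                            columns=list(labels_9.index))
        with pytest.warns(UserWarning, match="without a mapped gene"):
            out = g.link_expression(dm, {}, expr, labels_9)
        assert out.empty and out.attrs["n_unmapped"] == 1

    def test_spearman_reported_with_matrix(self, labels_9, rng):
        dm = pd.DataFrame({"mean_resistant": [60.0],
                           "mean_sensitive": [20.0],
                           "significant": [True]}, index=["I0"])
        meth = pd.DataFrame(
            [np.linspace(10, 90, 9)], index=["I0"],
            columns=list(labels_9.index))
        expr = pd.DataFrame(
            [np.linspace(9, 1, 9)], index=["g0"],
            columns=list(labels_9.index))
        out = g.link_expression(dm, {"I0": "g0"}, expr, labels_9,
                                matrix=meth)
        assert out.loc["I0", "spearman_rho"] == pytest.approx(-1.0)


class TestStrandsAndMapping:
    def test_combine_strands_weighted_average(self):
        rec = site_frame([("c", 10, "+", 30, 40.0),
                          ("c", 11, "-", 10, 80.0),
                          ("c", 50, "+", 5, 10.0)])
        out = combine_strands(rec)
        assert len(out) == 2
        merged = out[out["start"] == 10].iloc[0]
        assert merged["coverage"] == 40
        assert merged["percent"] == pytest.approx(50.0)  # (30*40+10*80)/40

    def test_tss_mapping_within_window(self):
        islands = pd.DataFrame({
            "chrom": ["c"], "start": [1000], "end": [2000],
            "island_id": ["I1"]})
        tss = pd.DataFrame({"gene": ["near", "far"], "chrom": ["c", "c"],
                            "pos": [1500, 9000]})
        out = derive_island_gene_map(islands, tss, window=2000)
        assert out == {"I1": "near"}
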