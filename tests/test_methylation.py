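"""CpG context, probe-gene mapping, gene summaries and genome binning."""

import numpy as np
import pandas as pd
import pytest

from tnbc_targets.config import PipelineConfig
from tnbc_targets.diffexpr import EBayesPrior
from tnbc_targets.methylation import (
    annotate_context,
    bin_genome,
    correlate_meth_expression,
    diff_methylation,
    map_probes_to_genes,
    summarize_gene_methylation,
)


def _probes(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions},
        index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
    )


def brute_force_context(probes, islands, shore_bp, shelf_bp):
    labels = []
    for _, probe in probes.iterrows():
        same = islands[islands["chrom"] == probe["chrom"]]
        if same.empty:
            labels.append("open_sea")
            continue
        dist = None
        for _, isl in same.iterrows():
            if isl["start"] <= probe["pos"] < isl["end"]:
                d = 0
            else:
                d = min(abs(probe["pos"] - isl["start"]), abs(probe["pos"] - (isl["end"] - 1)))
            dist = d if dist is None else min(dist, d)
        if dist == 0:
            labels.append("island")
        elif dist <= shore_bp:
            labels.append("shore")
        elif dist <= shelf_bp:
            labels.append("shelf")
        else:
            labels.append("open_sea")
    return pd.Series(labels, index=probes.index, name="context")


class TestContext:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1500, "island"),  # inside [1000, 2000)
            (1000, "island"),  # start is included
            (2000, "shore"),  # end is excluded: distance 1
            (2500, "shore"),  # distance 501
            (3999, "shore"),  # distance 2000, shore boundary inclusive
            (4000, "shelf"),  # distance 2001
            (5999, "shelf"),  # distance 4000, shelf boundary inclusive
            (6000, "open_sea"),  # distance 4001
            (999, "shore"),  # 1 bp left of the island
        ],
    )
    def test_boundary_cases(self, pos, expected):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})
        context = annotate_context(_probes([pos]), islands)
        assert context.iloc[0] == expected

    def test_chromosome_without_islands_is_open_sea(self):
        islands = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        assert annotate_context(_probes([50]), islands).iloc[0] == "open_sea"

    def test_matches_brute_force_on_random_layout(self, rng):
        cfg = PipelineConfig()
        probes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2", "chr3"], size=2000),
                "pos": rng.integers(0, 200_000, size=2000),
            },
            index=pd.Index([f"cg{i}" for i in range(2000)], name="probe_id"),
        )
        starts = rng.integers(0, 195_000, size=150)
        islands = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=150),  # chr3 island-free
                "start": starts,
                "end": starts + rng.integers(200, 3000, size=150),  # overlaps allowed
            }
        )
        fast = annotate_context(probes, islands, cfg)
        slow = brute_force_context(probes, islands, cfg.shore_bp, cfg.shelf_bp)
        pd.testing.assert_series_equal(fast, slow)


class TestProbeGeneMapping:
    def test_single_gene_takes_all_probes(self):
        genes = pd.DataFrame({"gene_id": ["A"], "chrom": ["chr1"], "tss": [5000], "strand": ["+"]})
        out = map_probes_to_genes(_probes([0, 5000, 9999]), genes)
        assert (out["nearest_gene"] == "A").all()
        np.testing.assert_array_equal(out["tss_distance"], [5000, 0, 4999])

    def test_equidistant_tie_goes_to_smaller_gene_id(self):
        genes = pd.DataFrame(
            {"gene_id": ["B", "A"], "chrom": ["chr1", "chr1"], "tss": [1000, 3000], "strand": ["+", "-"]}
        )
        out = map_probes_to_genes(_probes([2000]), genes)
        assert out["nearest_gene"].iloc[0] == "A"

    def test_shared_tss_tie_goes_to_smaller_gene_id(self):
        genes = pd.DataFrame(
            {"gene_id": ["Z", "A"], "chrom": ["chr1", "chr1"], "tss": [1000, 1000], "strand": ["+", "+"]}
        )
        out = map_probes_to_genes(_probes([900]), genes)
        assert out["nearest_gene"].iloc[0] == "A"

    def test_matches_brute_force_on_random_layout(self, rng):
        probes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=1000),
                "pos": rng.integers(0, 50_000, size=1000),
            },
            index=pd.Index([f"cg{i}" for i in range(1000)], name="probe_id"),
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i:03d}" for i in range(200)],
                "chrom": rng.choice(["chr1", "chr2"], size=200),
                "tss": rng.integers(0, 50_000, size=200),  # duplicate TSS possible
                "strand": rng.choice(["+", "-"], size=200),
            }
        )
        out = map_probes_to_genes(probes, genes)
        for _, probe in probes.sample(200, random_state=0).iterrows():
            same = genes[genes["chrom"] == probe["chrom"]]
            dists = (same["tss"] - probe["pos"]).abs()
            best = dists.min()
            expected = same.loc[dists == best, "gene_id"].min()
            assert out.loc[probe.name, "nearest_gene"] == expected
            assert out.loc[probe.name, "tss_distance"] == best


class TestGeneSummary:
    def _annotated(self):
        probes = _probes([100, 200, 300, 9000])
        probes["delta_m"] = [-1.0, -1.0, 1.0, 5.0]
        probes["context"] = ["island", "island", "island", "open_sea"]
        probes["nearest_gene"] = ["A", "A", "A", "A"]
        probes["tss_distance"] = [10, 20, 30, 8000]
        return probes

    def test_mean_of_island_probes(self):
        summary = summarize_gene_methylation(self._annotated())
        assert summary.loc["A", "mean_delta_m"] == pytest.approx(-1 / 3)
        assert summary.loc["A", "n_probes"] == 3

    def test_context_restriction_can_empty_output(self):
        probes = self._annotated()
        probes["context"] = "shore"
        summary = summarize_gene_methylation(probes, restrict_context={"island"})
        assert summary.empty

    def test_tss_distance_filter(self):
        probes = self._annotated()
        summary = summarize_gene_methylation(probes, restrict_context={"island", "open_sea"},
                                             max_tss_distance=25)
        assert summary.loc["A", "n_probes"] == 2


class TestDiffMethylation:
    def test_identical_groups_have_zero_delta(self, rng):
        half = pd.DataFrame(rng.normal(size=(30, 4)), columns=[f"a{i}" for i in range(4)])
        frame = pd.concat([half, half.rename(columns=lambda c: c.replace("a", "b"))], axis=1)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=frame.columns)
        res = diff_methylation(frame, groups, "A", "B", prior=EBayesPrior(1.0, 1.0))
        np.testing.assert_allclose(res["delta_m"], 0.0, atol=1e-12)

    def test_label_swap_negates_delta(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 10)), columns=[f"s{i}" for i in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=frame.columns)
        ab = diff_methylation(frame, groups, "A", "B")
        ba = diff_methylation(frame, groups, "B", "A")
        np.testing.assert_allclose(ab["delta_m"], -ba["delta_m"], atol=1e-12)

    def test_planted_shift_recovered(self, rng):
        n = 50
        frame = pd.DataFrame(rng.normal(0, 0.5, size=(100, 2 * n)),
                             columns=[f"s{i}" for i in range(2 * n)])
        frame.iloc[:20, :n] -= 1.0  # delta of -1 for the first 20 probes
        groups = pd.Series(["A"] * n + ["B"] * n, index=frame.columns)
        res = diff_methylation(frame, groups, "A", "B")
        assert res["delta_m"].iloc[:20].mean() == pytest.approx(-1.0, abs=0.1)


class TestCorrelation:
    def test_perfectly_anti_linear(self):
        summaries = pd.DataFrame({"mean_delta_m": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        de = pd.DataFrame({"log2fc": [-2.0, -4.0, -6.0]}, index=["a", "b", "c"])
        r, n = correlate_meth_expression(summaries, de)
        assert r == pytest.approx(-1.0)
        assert n == 3

    def test_too_few_shared_genes_is_error(self):
        summaries = pd.DataFrame({"mean_delta_m": [1.0]}, index=["a"])
        de = pd.DataFrame({"log2fc": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_meth_expression(summaries, de)

    def test_independent_values_near_zero(self, rng):
        idx = [f"g{i}" for i in range(5000)]
        summaries = pd.DataFrame({"mean_delta_m": rng.normal(size=5000)}, index=idx)
        de = pd.DataFrame({"log2fc": rng.normal(size=5000)}, index=idx)
        r, _ = correlate_meth_expression(summaries, de)
        assert abs(r) < 0.05


class TestBinGenome:
    def test_single_bin_mean(self):
        frame = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30], "value": [1.0, 2.0, 6.0]})
        out = bin_genome(frame, ["value"])
        assert len(out) == 1
        assert out["mean_value"].iloc[0] == pytest.approx(3.0)

    def test_boundary_point_goes_to_higher_bin(self):
        cfg = PipelineConfig(bin_bp=1000)
        frame = pd.DataFrame({"chrom": "chr1", "pos": [999, 1000], "value": [1.0, 5.0]})
        out = bin_genome(frame, ["value"], cfg)
        assert out["mean_value"].tolist() == [1.0, 5.0]
        assert out["bin_start"].tolist() == [0, 1000]

    def test_empty_bins_emitted_as_nan(self):
        cfg = PipelineConfig(bin_bp=100)
        frame = pd.DataFrame({"chrom": "chr1", "pos": [50, 250], "value": [1.0, 2.0]})
        out = bin_genome(frame, ["value"], cfg)
        assert len(out) == 3
        assert np.isnan(out["mean_value"].iloc[1])

    def test_matches_brute_force(self, rng):
        cfg = PipelineConfig(bin_bp=5000)
        frame = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=500),
                "pos": rng.integers(0, 100_000, size=500),
                "value": rng.normal(size=500),
            }
        )
        out = bin_genome(frame, ["value"], cfg)
        for _, row in out.iterrows():
            inside = frame[
                (frame["chrom"] == row["chrom"])
                & (frame["pos"] >= row["bin_start"])
                & (frame["pos"] < row["bin_end"])
            ]
            if inside.empty:
                assert np.isnan(row["mean_value"])
            else:
                assert row["mean_value"] == pytest.approx(inside["value"].mean())

    def test_bins_tile_without_overlap(self, rng):
        out = bin_genome(
            pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 3 * 10**7, 100), "value": 1.0}),
            ["value"],
        )
        assert (out["bin_end"] - out["bin_start"] == PipelineConfig().bin_bp).all()
        assert (out["bin_start"].iloc[1:].to_numpy() == out["bin_end"].iloc[:-1].to_numpy()).all()
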