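"""Counting, RPKM and the two DEG procedures (filter and intersection logic)."""

import numpy as np
import pandas as pd
import pytest

from kskpipe import expression, simulate


def _meta(n_pool=14, n_pos=2):
    return simulate.sample_sheet(
        simulate.SimulationConfig(seed=0, n_genes=1, n_pool_samples=n_pool, n_positions=n_pos)
    )


class TestCounting:
    def test_exact_match_counts(self, transcriptome, small_cfg):
        reads = simulate.generate_reads(
            transcriptome, small_cfg, target=False, sample_label="s1"
        )
        gene = sorted(transcriptome)[0]
        ten = [r for r in reads if r[0].split(":")[1] == gene][:10]
        counts, log = expression.count_reads_exact({"s1": ten}, transcriptome)
        assert counts.loc[gene, "s1"] == 10
        assert counts.drop(index=gene)["s1"].sum() == 0

    def test_unmapped_and_ambiguous_logged(self, transcriptome):
        genes = sorted(transcriptome)
        shared = "ACGT" * 13  # 52 bp planted into two genes
        tr = dict(transcriptome)
        tr[genes[0]] = shared + tr[genes[0]][52:]
        tr[genes[1]] = shared + tr[genes[1]][52:]
        reads = [("amb", shared[:50]), ("unmap", "T" * 50)]
        counts, log = expression.count_reads_exact({"s": reads}, tr)
        assert counts["s"].sum() == 0
        row = log.set_index("sample").loc["s"]
        assert row["ambiguous"] == 1 and row["unmapped"] == 1

    def test_sam_counts_match_brute_force(self, transcriptome, tmp_path):
        import pysam

        genes = sorted(transcriptome)
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": g, "LN": len(transcriptome[g])} for g in genes],
        }
        path = tmp_path / "sample.sam"
        rng = np.random.default_rng(0)
        expected = {g: 0 for g in genes}
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for i in range(200):
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = f"r{i}"
                gi = int(rng.integers(0, len(genes)))
                rec.reference_id = gi
                rec.reference_start = int(rng.integers(0, 100))
                rec.query_sequence = transcriptome[genes[gi]][:50]
                rec.cigarstring = "50M"
                rec.flag = 0 if i % 10 else 4  # every 10th read unmapped
                if rec.flag == 0:
                    expected[genes[gi]] += 1
                sam.write(rec)
        counts, log = expression.count_reads_sam({"s": str(path)}, transcriptome)
        assert counts["s"].to_dict() == expected

    def test_sam_unknown_reference_rejected(self, transcriptome, tmp_path):
        import pysam

        path = tmp_path / "bad.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "not_a_gene", "LN": 100}]}
        with pysam.AlignmentFile(str(path), "w", header=header):
            pass
        with pytest.raises(ValueError, match="absent from transcriptome"):
            expression.count_reads_sam({"s": str(path)}, transcriptome)


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10, 999_990]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        rp = expression.rpkm(counts, lengths)
        assert rp.loc["g1", "s"] == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(300, 3000, size=50), index=counts.index)
        doubled = counts.copy()
        doubled["a"] = counts["a"] * 2
        pd.testing.assert_series_equal(
            expression.rpkm(counts, lengths)["a"], expression.rpkm(doubled, lengths)["a"]
        )

    def test_matches_formula_elementwise(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=list("xyz"),
        )
        lengths = pd.Series(rng.integers(200, 2000, size=20), index=counts.index)
        rp = expression.rpkm(counts, lengths)
        libs = counts.sum(axis=0)
        for g in counts.index:
            for s in counts.columns:
                assert rp.loc[g, s] == pytest.approx(
                    counts.loc[g, s] * 1e9 / (lengths[g] * libs[s])
                )

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero library"):
            expression.rpkm(counts, pd.Series({"g1": 100, "g2": 100}))


class TestBias:
    @pytest.mark.parametrize(
        "a,b,pc,expected",
        [
            (3.0, 3.0, 0.1, 1.0),
            (4.0, 1.0, 0.0, 4.0),
            (0.0, 1.0, 0.1, 11.0),  # (1 + 0.1) / (0 + 0.1), verified by hand
        ],
    )
    def test_closed_form(self, a, b, pc, expected):
        assert expression.bias(a, b, pc) == pytest.approx(expected)

    def test_symmetric(self):
        assert expression.bias(2.0, 9.0) == expression.bias(9.0, 2.0)


class TestComparisonOne:
    def test_recall_on_background_planted_genes(self):
        """log2FC = 3 genes in quiet background are recovered at >= 0.9."""
        cfg = simulate.SimulationConfig(seed=21, n_genes=600)
        genes = [f"g{i + 1:04d}" for i in range(600)]
        up = {g: 3.0 for g in genes[:30]}
        down = {g: 3.0 for g in genes[30:60]}
        truth = simulate.CountSimTruth(de_genes_up=up, de_genes_down=down)
        counts, meta, lengths = simulate.generate_counts(cfg, truth, genes=genes)
        res = expression.comparison_one(counts, lengths, meta)
        tp = len((res.up & set(up)) | (res.down & set(down)))
        assert tp / 60 >= 0.9
        called = res.up | res.down
        assert len((called - set(up)) - set(down)) <= 0.2 * max(1, len(called))

    def test_strong_p_weak_bias_excluded(self):
        """A gene with tiny FDR but bias below 2 never passes the filter."""
        rng = np.random.default_rng(3)
        meta = _meta()
        samples = list(meta["sample"])
        genes = [f"g{i}" for i in range(100)]
        counts = pd.DataFrame(
            rng.poisson(1000, size=(100, len(samples))), index=genes, columns=samples
        )
        tgt = meta.loc[meta.group == "target", "sample"]
        counts.loc["g0", tgt] = int(1000 * 1.5)  # exact 1.5-fold, zero variance
        lengths = pd.Series(1000, index=genes)
        res = expression.comparison_one(counts, lengths, meta)
        row = res.table.set_index("gene").loc["g0"]
        assert row["bias"] < 2.0
        assert "g0" not in res.up | res.down

    def test_empty_group_rejected(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        pool_only = meta[meta.group == "pool"]
        with pytest.raises(ValueError, match=">= 2 samples"):
            expression.comparison_one(counts, lengths, pool_only)


class TestComparisonTwo:
    def test_thirteen_of_fourteen_excluded(self):
        """Significant in 13/14 paired comparisons is not enough."""
        meta = _meta()
        samples = list(meta["sample"])
        genes = [f"g{i}" for i in range(50)]
        counts = pd.DataFrame(1000, index=genes, columns=samples)
        tgt = meta.loc[meta.group == "target", "sample"]
        counts.loc["g0", tgt] = 8000
        # cultivar pool14 carries the same shift, killing its comparison
        cv14 = meta.loc[meta.cultivar == "pool14", "sample"]
        counts.loc["g0", cv14] = 8000
        lengths = pd.Series(1000, index=genes)
        res, ptable, dirtable = expression.comparison_two(counts, lengths, meta)
        sig = sum(
            ptable.loc["g0", cv] < 0.05 for cv in ptable.columns
        )
        assert sig == 13
        assert "g0" not in res.up | res.down
        # and with the offending cultivar's counts reverted, it is included
        counts.loc["g0", cv14] = 1000
        res2, _, _ = expression.comparison_two(counts, lengths, meta)
        assert "g0" in res2.up

    def test_planted_target_specific_gene_included(self, count_fixture):
        counts, meta, lengths, truth = count_fixture
        res, _, _ = expression.comparison_two(
            counts, lengths, meta, lenient=("pool01", "pool02")
        )
        recall = len(res.up & set(truth.de_genes_up)) / len(truth.de_genes_up)
        assert recall >= 0.8

    def test_degenerate_alphas_reduce_to_direction_intersection(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        cultivars = sorted(meta.loc[meta.group == "pool", "cultivar"].unique())
        res, ptable, dirtable = expression.comparison_two(
            counts, lengths, meta, alphas={c: 1.0 for c in cultivars}
        )
        rp = expression.rpkm(counts, lengths)
        tgt = meta.loc[meta.group == "target", "sample"]
        pool = meta.loc[meta.group == "pool", "sample"]
        rpkm_ok = np.maximum(rp[tgt].mean(axis=1), rp[pool].mean(axis=1)) > 1.0
        expected_up = {
            g
            for g in counts.index
            if rpkm_ok[g]
            and (dirtable.loc[g] == 1).all()
            and (ptable.loc[g] < 1.0).all()
        }
        assert res.up == expected_up

    def test_result_shrinks_as_alpha_decreases(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        cultivars = sorted(meta.loc[meta.group == "pool", "cultivar"].unique())
        loose, _, _ = expression.comparison_two(
            counts, lengths, meta, alphas={c: 0.2 for c in cultivars}
        )
        tight, _, _ = expression.comparison_two(
            counts, lengths, meta, alphas={c: 0.01 for c in cultivars}
        )
        assert tight.up <= loose.up and tight.down <= loose.down

    def test_subset_of_per_comparison_significant_union(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        res, ptable, _ = expression.comparison_two(
            counts, lengths, meta, lenient=("pool01", "pool02")
        )
        union_sig = set(ptable.index[(ptable < 0.1).any(axis=1)])
        assert (res.up | res.down) <= union_sig

    def test_missing_position_pairing_rejected(self, count_fixture):
        counts, meta, lengths, _ = count_fixture
        broken = meta[~((meta.cultivar == "pool03") & (meta.position == "#2"))]
        with pytest.raises(ValueError, match="matched branch positions"):
            expression.comparison_two(counts[broken["sample"]], lengths, broken)
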