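import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lsrcnv import genewise as gw
from lsrcnv.segment_io import CNVSegment


def seg(sample, chrom, start, end):
    return CNVSegment(sample, chrom, start, end, 10, "loss", 1e-4)


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestSegmentGeneOverlap:
    def test_partial_overlap_marks_involved(self):
        gcm = gw.map_segments_to_genes(
            [seg("s1", "chr1", 100, 200)], bed([("chr1", 150, 300, "G")])
        )
        assert gcm.matrix.loc["G", "s1"] == 1

    def test_half_open_abutment_not_involved(self):
        gcm = gw.map_segments_to_genes(
            [seg("s1", "chr1", 100, 150)], bed([("chr1", 150, 300, "G")])
        )
        assert gcm.matrix.loc["G", "s1"] == 0

    def test_matches_all_pairs_interval_oracle(self, rng):
        genes = bed(
            [("chr1", int(a), int(a) + int(rng.integers(50, 400)), f"G{i}")
             for i, a in enumerate(rng.integers(0, 3000, 8))]
        )
        segments = [
            seg(f"s{j % 3}", "chr1", int(a), int(a) + int(rng.integers(50, 500)))
            for j, a in enumerate(rng.integers(0, 3000, 15))
        ]
        gcm = gw.map_segments_to_genes(segments, genes)
        for _, g in genes.iterrows():
            for s in gcm.samples:
                expected = any(
                    x.sample_id == s and x.start < g["end"] and g["start"] < x.end
                    for x in segments
                )
                assert gcm.matrix.loc[g["name"], s] == int(expected)

    def test_chromosomes_not_mixed(self):
        gcm = gw.map_segments_to_genes(
            [seg("s1", "chr2", 100, 200)], bed([("chr1", 100, 200, "G")])
        )
        assert gcm.matrix.loc["G", "s1"] == 0


def two_sided_fisher(a, b, c, d):
    """Hypergeometric enumeration: sum of table probabilities <= observed."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def table_prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    obs = table_prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= obs * (1 + 1e-9))


def make_matrix(mat, labels):
    genes = [f"G{i}" for i in range(mat.shape[0])]
    samples = [f"s{j}" for j in range(mat.shape[1])]
    coords = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(len(genes)) * 1000,
         "end": np.arange(len(genes)) * 1000 + 500},
        index=pd.Index(genes, name="name"),
    )
    gcm = gw.GeneCNVMatrix(
        matrix=pd.DataFrame(mat, index=genes, columns=samples), coords=coords
    )
    return gcm, {s: int(l) for s, l in zip(samples, labels)}


class TestGeneFisher:
    def test_perfectly_associated_gene(self):
        # involved in all 5 recurrent and none of 5 non-recurrent samples
        mat = np.zeros((1, 10), dtype=int)
        mat[0, :5] = 1
        gcm, labels = make_matrix(mat, [1] * 5 + [0] * 5)
        table = gw.gene_fisher(gcm, labels)
        assert table["p"].iloc[0] == pytest.approx(2 / math.comb(10, 5), rel=1e-6)

    def test_uninvolved_gene_gets_p_one(self):
        mat = np.zeros((2, 8), dtype=int)
        mat[1, ::2] = 1
        gcm, labels = make_matrix(mat, [0, 1] * 4)
        table = gw.gene_fisher(gcm, labels).set_index("gene")
        assert table.loc["G0", "p"] == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            inv = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] ^= 1
            if inv.min() == inv.max():
                continue
            a = int(((inv == 1) & (y == 1)).sum())
            b = int(((inv == 0) & (y == 1)).sum())
            c = int(((inv == 1) & (y == 0)).sum())
            d = int(((inv == 0) & (y == 0)).sum())
            gcm, labels = make_matrix(inv[None, :], y)
            p = gw.gene_fisher(gcm, labels)["p"].iloc[0]
            assert p == pytest.approx(two_sided_fisher(a, b, c, d), rel=1e-6)

    def test_bh_is_monotone_and_fixed_point(self, rng):
        mat = rng.integers(0, 2, (15, 12))
        y = rng.integers(0, 2, 12)
        y[:2] = [0, 1]
        gcm, labels = make_matrix(mat, y)
        table = gw.gene_fisher(gcm, labels)
        srt = table.sort_values("p")
        assert srt["adjusted_p"].is_monotonic_increasing
        # BH fixed point: all-equal raw p stays unchanged
        same = np.tile(rng.integers(0, 2, 12), (4, 1))
        gcm2, labels2 = make_matrix(same, y)
        t2 = gw.gene_fisher(gcm2, labels2)
        assert np.allclose(t2["adjusted_p"], t2["p"])

    def test_frequencies_bounded(self, rng):
        mat = rng.integers(0, 2, (6, 9))
        gcm, _ = make_matrix(mat, [0, 1] * 4 + [0])
        freq = gw.involvement_frequencies(gcm)
        assert ((freq["frequency"] >= 0) & (freq["frequency"] <= 1)).all()


class TestPathwayKS:
    @staticmethod
    def _table(pvals):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(pvals))], "adjusted_p": pvals}
        )

    def test_enriched_set_matches_exact_enumeration(self, rng):
        pvals = np.concatenate([rng.uniform(0, 0.02, 5), rng.uniform(0.2, 1, 10)])
        table = self._table(pvals)
        inset = [f"G{i}" for i in range(5)]
        out = gw.pathway_ks(table, {"low": inset})
        # oracle: enumerate all C(15,5) assignments of the observed values
        obs_stat = stats.ks_2samp(pvals[:5], pvals[5:]).statistic
        count = total = 0
        for combo in itertools.combinations(range(15), 5):
            mask = np.zeros(15, bool)
            mask[list(combo)] = True
            stat = stats.ks_2samp(pvals[mask], pvals[~mask]).statistic
            total += 1
            if stat >= obs_stat - 1e-12:
                count += 1
        assert out["p"].iloc[0] == pytest.approx(count / total, abs=0.005)
        assert out["p"].iloc[0] < 0.01

    def test_set_of_all_genes_rejected(self, rng):
        table = self._table(rng.uniform(size=6))
        with pytest.raises(ValueError):
            gw.pathway_ks(table, {"all": [f"G{i}" for i in range(6)]})

    def test_tiny_set_rejected(self, rng):
        table = self._table(rng.uniform(size=6))
        with pytest.raises(ValueError):
            gw.pathway_ks(table, {"one": ["G0"]})

    def test_null_set_p_not_extreme(self, rng):
        pvals = rng.uniform(size=40)
        table = self._table(pvals)
        ps = []
        for k in range(20):
            members = [f"G{i}" for i in rng.choice(40, 8, replace=False)]
            ps.append(gw.pathway_ks(table, {"rand": members})["p"].iloc[0])
        # under the null the KS p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) <= 0.25


class TestGMT:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tG1\tG2\tG3\nSET2\tdesc\tG4\tG5\n")
        sets = gw.read_gmt(path)
        assert sets == {"SET1": ["G1", "G2", "G3"], "SET2": ["G4", "G5"]}

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SETONLY\n")
        with pytest.raises(ValueError):
            gw.read_gmt(path)
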