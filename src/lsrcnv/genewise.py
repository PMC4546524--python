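"""Gene-level CNV association and p-value-based gene-set enrichment.

A gene counts as "involved" for a sample when any of that sample's
filtered segments overlaps the gene interval by at least one base
(half-open intervals).  Per-gene association with outcome uses the
two-sided Fisher exact test with Benjamini-Hochberg correction; gene sets
are scored by a two-sample Kolmogorov-Smirnov test on adjusted gene
p-values (in-set vs out-of-set), again BH-corrected across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segment_io import CNVSegment


@dataclass
class GeneCNVMatrix:
    """genes x samples binary involvement matrix with gene coordinates."""

    matrix: pd.DataFrame        # index gene name, columns sample ids, values {0,1}
    coords: pd.DataFrame        # index gene name, columns chrom/start/end

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)


def map_segments_to_genes(
    segments: Sequence[CNVSegment],
    gene_bed: pd.DataFrame,
    states: Sequence[str] = ("loss", "gain"),
) -> GeneCNVMatrix:
    """Mark each (gene, sample) pair whose intervals overlap by >= 1 bp.

    ``gene_bed`` follows segment_io.read_bed (chrom, start, end, name);
    chromosome names are compared verbatim.  Gains and losses are pooled
    unless ``states`` restricts to one.
    """
    samples = sorted({s.sample_id for s in segments})
    genes = gene_bed["name"].tolist()
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)

    by_chrom: dict[str, list[CNVSegment]] = {}
    for s in segments:
        if s.state in states:
            by_chrom.setdefault(s.chrom, []).append(s)

    for gene, chrom, gstart, gend in gene_bed[["name", "chrom", "start", "end"]].itertuples(
        index=False
    ):
        for seg in by_chrom.get(chrom, ()):
            # half-open overlap: [a,b) and [c,d) intersect iff a < d and c < b
            if seg.start < gend and gstart < seg.end:
                mat.loc[gene, seg.sample_id] = 1
    coords = gene_bed.set_index("name")[["chrom", "start", "end"]]
    return GeneCNVMatrix(matrix=mat, coords=coords)


def gene_fisher(gcm: GeneCNVMatrix, labels: Mapping[str, int]) -> pd.DataFrame:
    """Two-sided Fisher exact p per gene (involvement x outcome), BH-adjusted.

    Returns a frame sorted by genomic position with columns
    gene/chrom/pos/p/adjusted_p/minus_log10_p for Manhattan plotting.
    All-zero (or all-one) gene rows get p = 1.
    """
    y = np.array([labels[s] for s in gcm.samples], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("gene association needs both outcome classes")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    pvals = np.ones(len(gcm.genes))
    M = gcm.matrix.to_numpy()
    for i in range(M.shape[0]):
        inv = M[i]
        a = int(((inv == 1) & (y == 1)).sum())
        b = n_pos - a
        c = int(((inv == 1) & (y == 0)).sum())
        d = n_neg - c
        if (a + c) in (0, len(y)):  # constant involvement: no association
            continue
        pvals[i] = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": gcm.genes,
            "chrom": gcm.coords["chrom"].to_numpy(),
            "pos": ((gcm.coords["start"] + gcm.coords["end"]) // 2).to_numpy(),
            "p": pvals,
            "adjusted_p": adj,
        }
    )
    out["minus_log10_p"] = -np.log10(out["p"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def involvement_frequencies(gcm: GeneCNVMatrix) -> pd.DataFrame:
    """Per-gene involvement frequency over the declared sample count."""
    freq = gcm.matrix.mean(axis=1)
    out = gcm.coords.copy()
    out["frequency"] = freq
    return out.reset_index(names="gene")


def pathway_ks(
    gene_adjusted_p: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Two-sample KS test of in-set vs out-of-set adjusted gene p-values,
    BH-corrected across sets; sets are intersected with scored genes first."""
    pmap = gene_adjusted_p.set_index("gene")["adjusted_p"]
    all_genes = set(pmap.index)
    names, pvals, sizes = [], [], []
    for name, members in gene_sets.items():
        inset = sorted(all_genes.intersection(members))
        outset = sorted(all_genes.difference(members))
        if len(inset) < 2:
            raise ValueError(f"gene set {name!r}: fewer than 2 scored genes")
        if not outset:
            raise ValueError(f"gene set {name!r} covers every scored gene")
        stat = stats.ks_2samp(pmap.loc[inset], pmap.loc[outset])
        names.append(name)
        pvals.append(stat.pvalue)
        sizes.append(len(inset))
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"set": names, "n_genes": sizes, "p": pvals, "adjusted_p": adj}
    ).sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
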