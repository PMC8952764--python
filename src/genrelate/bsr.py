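"""BLAST-score-ratio (BSR) gene-homology screening.

Each gene of the reference strain is aligned against a target genome and its
best bit score (the *query* bit score) is divided by the gene's bit score
against its own source genome (the *reference* bit score, a self-match).
The ratio lies in [0, 1]: 1 is a perfect match, 0 means no match at all, and
ratios over 0.4 are called homologs.  Per-category summaries give the
percentage of genes with a homolog in each target genome — the quantity a
relatedness table carries for exoenzymes, toxins, NRPS and PKS genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import KmerIndex, ScoringScheme, find_hsps, index_subject
from .seqs import GenomeSequence

__all__ = [
    "CATEGORIES",
    "GeneRecord",
    "BSRValue",
    "HomologySummary",
    "reference_scores",
    "bsr",
    "homology_matrix",
    "percent_homologous",
    "read_categories",
    "plot_heatmap",
]

CATEGORIES = ("exoenzyme", "toxin", "NRPS", "PKS")

BSR_THRESHOLD = 0.4  # homolog iff ratio strictly greater


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r} has an empty sequence")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"gene {self.gene_id!r}: category {self.category!r} not in "
                f"{CATEGORIES}"
            )


@dataclass
class BSRValue:
    gene_id: str
    genome_id: str
    query_bits: float
    reference_bits: float
    ratio: float

    @property
    def homolog(self) -> bool:
        return self.ratio > BSR_THRESHOLD


@dataclass
class HomologySummary:
    genome_id: str
    category: str
    n_genes: int
    n_homologs: int

    @property
    def percent(self) -> int:
        """Integer percentage, rounded half-up (relatedness-table convention)."""
        return int(np.floor(100.0 * self.n_homologs / self.n_genes + 0.5))


class GeneNotFoundError(ValueError):
    """A gene has no (near-)full-length match in its own source genome."""


def _best_bits(
    gene: GeneRecord, index: KmerIndex, scheme: ScoringScheme
) -> tuple[float, float]:
    """Best bit score of a gene vs an indexed genome and its query coverage."""
    hsps = find_hsps(gene.sequence, index, scheme, query_id=gene.gene_id)
    if not hsps:
        return 0.0, 0.0
    best = hsps[0]
    cov = (best.query_end - best.query_start) / len(gene.sequence)
    return best.bit_score, cov


def reference_scores(
    genes: list[GeneRecord],
    source_genome: GenomeSequence,
    scheme: ScoringScheme = ScoringScheme(),
    min_self_coverage: float = 0.9,
) -> dict[str, float]:
    """Self-match bit score of every gene against its own source genome.

    The best HSP must cover at least ``min_self_coverage`` of the gene —
    anything less signals an annotation/sequence mismatch and raises
    :class:`GeneNotFoundError`.
    """
    index = index_subject(source_genome, scheme.kmer_size)
    out: dict[str, float] = {}
    for gene in genes:
        bits, cov = _best_bits(gene, index, scheme)
        if bits <= 0 or cov < min_self_coverage:
            raise GeneNotFoundError(
                f"gene {gene.gene_id!r} has no near-full-length match in "
                f"source genome {source_genome.id!r} (coverage {cov:.2f})"
            )
        out[gene.gene_id] = bits
    return out


def bsr(
    gene: GeneRecord,
    target: GenomeSequence,
    reference_bits: float,
    scheme: ScoringScheme = ScoringScheme(),
    target_index: KmerIndex | None = None,
) -> BSRValue:
    """Score ratio of one gene against one target genome, clipped to [0, 1]."""
    if reference_bits <= 0:
        raise ValueError("reference_bits must be positive")
    index = target_index or index_subject(target, scheme.kmer_size)
    bits, _ = _best_bits(gene, index, scheme)
    ratio = min(1.0, max(0.0, bits / reference_bits))
    if bits == 0.0:
        ratio = 0.0
    return BSRValue(
        gene_id=gene.gene_id,
        genome_id=target.id,
        query_bits=bits,
        reference_bits=reference_bits,
        ratio=ratio,
    )


def homology_matrix(
    genes: list[GeneRecord],
    genomes: list[GenomeSequence],
    scheme: ScoringScheme = ScoringScheme(),
    reference: dict[str, float] | None = None,
    source_genome: GenomeSequence | None = None,
) -> pd.DataFrame:
    """Dense genes x genomes matrix of BSR ratios (input order preserved).

    ``reference`` maps gene_id -> self-score; if omitted it is computed from
    ``source_genome`` (which must then be given).
    """
    if not genes or not genomes:
        raise ValueError("need at least one gene and one genome")
    if reference is None:
        if source_genome is None:
            raise ValueError("either reference scores or a source genome")
        reference = reference_scores(genes, source_genome, scheme)
    mat = pd.DataFrame(
        0.0,
        index=[g.gene_id for g in genes],
        columns=[g.id for g in genomes],
    )
    for genome in genomes:
        index = index_subject(genome, scheme.kmer_size)
        for gene in genes:
            val = bsr(
                gene, genome, reference[gene.gene_id], scheme,
                target_index=index,
            )
            mat.loc[gene.gene_id, genome.id] = val.ratio
    mat.index.name = "gene"
    mat.columns.name = "genome"
    return mat


def percent_homologous(
    matrix: pd.DataFrame, categories: dict[str, str]
) -> list[HomologySummary]:
    """Per genome x category percentage of genes with ratio > 0.4.

    ``categories`` maps gene_id -> category; every gene in the matrix must be
    categorized.  The result is permutation-invariant in gene order.
    """
    missing = [g for g in matrix.index if g not in categories]
    if missing:
        raise ValueError(f"uncategorized genes: {missing[:5]}")
    out: list[HomologySummary] = []
    for genome_id in matrix.columns:
        for cat in CATEGORIES:
            gene_ids = [g for g in matrix.index if categories[g] == cat]
            if not gene_ids:
                continue
            ratios = matrix.loc[gene_ids, genome_id]
            out.append(
                HomologySummary(
                    genome_id=genome_id,
                    category=cat,
                    n_genes=len(gene_ids),
                    n_homologs=int((ratios > BSR_THRESHOLD).sum()),
                )
            )
    return out


def read_categories(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, category) with a header line."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the BSR matrix as a heat map on a 0-1 scale, 0.4 marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(matrix.columns)), max(4, 0.2 * len(matrix)))
    )
    im = ax.imshow(matrix.values, vmin=0.0, vmax=1.0, aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=5)
    cbar = fig.colorbar(im, ax=ax)
    cbar.ax.axhline(BSR_THRESHOLD, color="red", linewidth=1)
    cbar.set_label("BLAST score ratio (>0.4 = homolog)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
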