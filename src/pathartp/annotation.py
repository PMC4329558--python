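"""Assignment of SNPs to genes via asymmetric flanking windows.

A SNP belongs to a gene when it lies on the same chromosome within the gene
body extended by 20 kb upstream and 10 kb downstream of transcription
(defaults; configurable). Upstream/downstream are strand-aware: for a
minus-strand gene the 20 kb flank extends to the right of the gene end.
``strand_aware=False`` applies 20 kb left / 10 kb right regardless of
strand, for replication of strand-agnostic pipelines. Window ends are
inclusive, and a SNP falling in two genes' windows is assigned to both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dataset import GeneModel, PathwayModel, SnpMeta

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 20_000
DEFAULT_DOWNSTREAM_BP = 10_000


@dataclass
class GeneSnpMap:
    """Bidirectional gene <-> SNP assignment.

    ``snps_by_gene`` keeps position order within each gene; a SNP mapping
    into overlapping windows appears under every matching gene.
    """

    snps_by_gene: dict[str, list[str]]
    genes_by_snp: dict[str, list[str]]

    @property
    def genes_without_snps(self) -> list[str]:
        return [g for g, snps in self.snps_by_gene.items() if not snps]

    @property
    def mapped_snp_ids(self) -> list[str]:
        """Distinct mapped SNPs (each counted once despite multi-gene hits)."""
        return list(self.genes_by_snp.keys())

    @property
    def n_assignments(self) -> int:
        """Total gene-SNP pairs; >= len(mapped_snp_ids) when windows overlap."""
        return sum(len(v) for v in self.snps_by_gene.values())

    def restrict_to_genes(self, gene_names: Iterable[str]) -> "GeneSnpMap":
        keep = set(gene_names)
        snps_by_gene = {g: list(v) for g, v in self.snps_by_gene.items() if g in keep}
        genes_by_snp: dict[str, list[str]] = {}
        for g, snps in snps_by_gene.items():
            for s in snps:
                genes_by_snp.setdefault(s, []).append(g)
        return GeneSnpMap(snps_by_gene, genes_by_snp)

    def to_table(self) -> list[tuple[str, str]]:
        return [(g, s) for g, snps in self.snps_by_gene.items() for s in snps]


def gene_window(
    gene: GeneModel,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    strand_aware: bool = True,
) -> tuple[int, int]:
    """Inclusive [low, high] window around a gene, clipped at position 1."""
    if strand_aware and gene.strand == "-":
        low = gene.start - downstream_bp
        high = gene.end + upstream_bp
    else:
        low = gene.start - upstream_bp
        high = gene.end + downstream_bp
    return max(1, low), high


def map_snps_to_genes(
    snps: Sequence[SnpMeta],
    genes: Sequence[GeneModel],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    strand_aware: bool = True,
) -> GeneSnpMap:
    """Assign every SNP to every gene whose window contains it."""
    snps_by_gene: dict[str, list[str]] = {g.gene_name: [] for g in genes}
    genes_by_snp: dict[str, list[str]] = {}
    ordered = sorted(snps, key=lambda s: (s.chromosome, s.position, s.snp_id))
    for gene in genes:
        low, high = gene_window(gene, upstream_bp, downstream_bp, strand_aware)
        for snp in ordered:
            if snp.chromosome == gene.chromosome and low <= snp.position <= high:
                snps_by_gene[gene.gene_name].append(snp.snp_id)
                genes_by_snp.setdefault(snp.snp_id, []).append(gene.gene_name)
    return GeneSnpMap(snps_by_gene, genes_by_snp)


def exclude_genes(
    pathway: PathwayModel, exclusion_list: Iterable[str]
) -> PathwayModel:
    """Drop named genes (e.g. X-chromosome members) from a pathway.

    Exclusions not present in the pathway are warned about and ignored.
    """
    exclusions = list(exclusion_list)
    absent = [g for g in exclusions if g not in pathway.genes]
    for g in absent:
        logger.warning(
            "exclusion %r is not in pathway %r", g, pathway.pathway_name
        )
    remaining = tuple(g for g in pathway.genes if g not in exclusions)
    if not remaining:
        raise ValueError(
            f"excluding {exclusions} empties pathway {pathway.pathway_name!r}"
        )
    return PathwayModel(pathway.pathway_name, remaining)


def drop_snpless_genes(
    gene_snp_map: GeneSnpMap, pathway: PathwayModel
) -> tuple[PathwayModel, list[str]]:
    """Remove pathway genes with no mapped SNPs; return (pathway, dropped).

    Raises ``ValueError`` when no gene retains a SNP, since the analysis
    pathway would be empty.
    """
    dropped = [
        g for g in pathway.genes if not gene_snp_map.snps_by_gene.get(g)
    ]
    remaining = tuple(g for g in pathway.genes if g not in dropped)
    if not remaining:
        raise ValueError(
            f"every gene in pathway {pathway.pathway_name!r} lost all SNPs"
        )
    for g in dropped:
        logger.info("gene %s has no surviving SNPs; dropped from analysis", g)
    return PathwayModel(pathway.pathway_name, remaining), dropped


def write_gene_snp_map(gene_snp_map: GeneSnpMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsnp\n")
        for gene, snp in gene_snp_map.to_table():
            fh.write(f"{gene}\t{snp}\n")
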