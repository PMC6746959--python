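"""Layer 3: gene mapping and knowledge-based relevance screening.

A replicated region is kept on the higher-confidence list when it meets at
least one of three criteria: (1) it hits a gene highly expressed in the
developing heart; (2) it does not physically overlap any previously reported
disease-associated CNV locus; (3) it is absent from the catalogue of common
CNVs seen in healthy individuals (a DGV-style set).  Criterion 2 is screened
in the novelty direction as stated by its source — novelty counts TOWARD
relevance — which is counter-intuitive enough that an inversion switch is
provided.

"Physically overlapped" is quantified as one-way coverage of the candidate
region by the knowledge-base record (default f_kb = 0.5): a small candidate
inside a megabase syndromic record is covered, while a megabase record
clipping 1 bp of a candidate is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .model import GenomicInterval, fraction_of_a_covered, overlap_bp
from .replication import CnvRegion


@dataclass(frozen=True)
class RelevanceFlags:
    expressed_gene: bool
    novel_vs_chd: bool
    absent_from_dgv: bool
    genes: tuple[str, ...]

    @property
    def relevant(self) -> bool:
        return self.expressed_gene or self.novel_vs_chd or self.absent_from_dgv


def _region_tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)
    return trees


class KnowledgeBase:
    """Flat local knowledge bases: known disease loci, common-CNV catalogue,
    developmentally heart-expressed genes, and gene models."""

    def __init__(
        self,
        chd_known_regions: list[GenomicInterval],
        dgv_common_regions: list[GenomicInterval],
        heart_expressed_genes: set[str],
        gene_models: dict[str, GenomicInterval],
    ) -> None:
        for sym in gene_models:
            if not sym:
                raise ValueError("empty gene symbol in gene models")
        self.chd_known_regions = list(chd_known_regions)
        self.dgv_common_regions = list(dgv_common_regions)
        self.heart_expressed_genes = set(heart_expressed_genes)
        self.gene_models = dict(gene_models)
        self._chd_trees = _region_tree(self.chd_known_regions)
        self._dgv_trees = _region_tree(self.dgv_common_regions)
        self._gene_trees: dict[str, IntervalTree] = {}
        for sym, iv in self.gene_models.items():
            self._gene_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, sym
            )


def map_genes(region: CnvRegion, kb: KnowledgeBase) -> list[str]:
    """Gene symbols whose model overlaps the region by >= 1 bp, by position."""
    tree = kb._gene_trees.get(region.interval.chrom)
    if tree is None:
        return []
    hits = []
    for node in tree.overlap(region.interval.start, region.interval.end + 1):
        sym = node.data
        iv = kb.gene_models[sym]
        if overlap_bp(region.interval, iv) >= 1:
            hits.append((iv.start, iv.end, sym))
    hits.sort()
    return [sym for _, _, sym in hits]


def _covered_by_any(
    region: CnvRegion, trees: dict[str, IntervalTree], f_kb: float
) -> bool:
    tree = trees.get(region.interval.chrom)
    if tree is None:
        return False
    for node in tree.overlap(region.interval.start, region.interval.end + 1):
        if fraction_of_a_covered(region.interval, node.data) >= f_kb:
            return True
    return False


def relevance_flags(
    region: CnvRegion,
    kb: KnowledgeBase,
    f_kb: float = 0.5,
    invert_criterion2: bool = False,
) -> RelevanceFlags:
    """Evaluate the three relevance criteria for one region.

    f_kb is the one-way coverage fraction of the candidate region a
    knowledge-base record must reach to count as "physically overlapping";
    lower it toward 0 to approach any-overlap semantics (f_kb must stay > 0).
    """
    if not 0.0 < f_kb <= 1.0:
        raise ValueError(f"f_kb must be in (0, 1], got {f_kb}")
    genes = tuple(map_genes(region, kb))
    expressed = any(g in kb.heart_expressed_genes for g in genes)
    known_chd = _covered_by_any(region, kb._chd_trees, f_kb)
    novel_vs_chd = known_chd if invert_criterion2 else not known_chd
    absent_from_dgv = not _covered_by_any(region, kb._dgv_trees, f_kb)
    return RelevanceFlags(expressed, novel_vs_chd, absent_from_dgv, genes)


def annotate_regions(
    regions: list[CnvRegion],
    kb: KnowledgeBase,
    f_kb: float = 0.5,
    invert_criterion2: bool = False,
) -> list[CnvRegion]:
    """Fill gene and relevance fields of every region in place; returns regions."""
    for r in regions:
        flags = relevance_flags(r, kb, f_kb, invert_criterion2)
        r.genes = flags.genes
        r.expressed_gene = flags.expressed_gene
        r.novel_vs_chd = flags.novel_vs_chd
        r.absent_from_dgv = flags.absent_from_dgv
        r.relevant = flags.relevant
    return regions


def dgv_novel_de_novo(
    regions: list[CnvRegion],
    kb: KnowledgeBase,
    f_kb: float = 0.5,
    recurrent_only: bool = False,
) -> list[CnvRegion]:
    """De novo regions absent from the common-CNV catalogue.

    With ``recurrent_only`` the list is further restricted to regions with at
    least two distinct case carriers.
    """
    out = []
    for r in regions:
        if not r.de_novo:
            continue
        if _covered_by_any(r, kb._dgv_trees, f_kb):
            continue
        if recurrent_only and r.n_case_carriers < 2:
            continue
        out.append(r)
    return out
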