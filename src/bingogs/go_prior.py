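"""GO-informed initial marker pool.

Maps GO terms -> annotated genes -> SNPs by genomic position, keeps only
terms whose gene regions collectively contain more than ``min_snps``
markers, and merges the survivors into a deduplicated, genomically ordered
candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bingogs.data_io import GeneModel, GenotypeMatrix, GOAnnotationMap

logger = logging.getLogger(__name__)


@dataclass
class TermMarkerIndex:
    """GO-term id -> ordered marker-id list, plus the effective-term subset."""

    term_to_markers: dict[str, list[str]]
    effective_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.effective_terms <= set(self.term_to_markers):
            raise ValueError("effective_terms must be a subset of mapped terms")

    def size_table(self) -> list[tuple[str, int, bool]]:
        """(term, n_markers, effective) rows sorted by descending size."""
        return sorted(
            ((t, len(m), t in self.effective_terms)
             for t, m in self.term_to_markers.items()),
            key=lambda r: (-r[1], r[0]),
        )


def map_terms_to_markers(
    go: GOAnnotationMap,
    genes: Sequence[GeneModel],
    geno: GenotypeMatrix,
    flank_bp: int = 0,
) -> TermMarkerIndex:
    """Assign each SNP to every term with an annotated gene covering it.

    A SNP at 1-based position ``pos`` belongs to a gene iff its 0-based
    coordinate (pos - 1) lies in [start - flank_bp, end + flank_bp); a SNP
    may belong to many terms. Unresolvable gene ids are logged and skipped.
    Raises if no term maps to any marker at all.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_pos: dict[str, np.ndarray] = {}
    chrom_cols: dict[str, np.ndarray] = {}
    chroms = np.asarray([m.chrom for m in geno.markers])
    pos0 = np.asarray([m.pos - 1 for m in geno.markers])
    for c in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == c)
        chrom_pos[c] = pos0[sel]  # already sorted within chrom
        chrom_cols[c] = sel

    n_unresolved = 0
    term_to_markers: dict[str, list[str]] = {}
    marker_ids = geno.marker_ids
    for term, gene_ids in go.term_to_genes.items():
        cols: set[int] = set()
        for gid in sorted(gene_ids):
            gene = gene_by_id.get(gid)
            if gene is None:
                n_unresolved += 1
                continue
            pos_arr = chrom_pos.get(gene.chrom)
            if pos_arr is None:
                continue
            lo = np.searchsorted(pos_arr, gene.start - flank_bp, side="left")
            hi = np.searchsorted(pos_arr, gene.end + flank_bp, side="left")
            cols.update(chrom_cols[gene.chrom][lo:hi].tolist())
        term_to_markers[term] = [marker_ids[j] for j in sorted(cols)]
    if n_unresolved:
        logger.warning("map_terms_to_markers: %d gene ids had no gene model",
                       n_unresolved)
    if not any(term_to_markers.values()):
        raise ValueError("no GO term maps to any marker; prior is uninformative")
    return TermMarkerIndex(term_to_markers=term_to_markers)


def select_effective_terms(
    idx: TermMarkerIndex,
    min_snps: int = 200,
    include_terms: set[str] | None = None,
    exclude_terms: set[str] | None = None,
) -> TermMarkerIndex:
    """Keep terms with strictly more than ``min_snps`` mapped markers.

    Optional curation: restrict to ``include_terms`` and/or drop
    ``exclude_terms`` before applying the size rule (default: no curation).
    """
    effective = set()
    for term, markers in idx.term_to_markers.items():
        if include_terms is not None and term not in include_terms:
            continue
        if exclude_terms is not None and term in exclude_terms:
            continue
        if len(markers) > min_snps:
            effective.add(term)
    if not effective:
        logger.warning("select_effective_terms: no term exceeds %d SNPs", min_snps)
    return TermMarkerIndex(term_to_markers=idx.term_to_markers,
                           effective_terms=effective)


def build_go_pool(idx: TermMarkerIndex, geno: GenotypeMatrix | None = None) -> list[str]:
    """Union of the effective terms' markers, deduplicated, in genomic order."""
    pool: set[str] = set()
    for term in idx.effective_terms:
        pool.update(idx.term_to_markers[term])
    if geno is not None:
        return geno.in_genomic_order(pool)
    # without a matrix, fall back to the order markers appear in any term list
    seen: dict[str, None] = {}
    for term in sorted(idx.effective_terms):
        for mid in idx.term_to_markers[term]:
            if mid in pool:
                seen.setdefault(mid)
    return list(seen)
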