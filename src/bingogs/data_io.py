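"""On-disk formats and the shared in-memory data model.

Genotypes are held as a samples x markers dosage matrix (0/1/2 alt-allele
counts, ``NaN`` for missing) with marker metadata kept coordinate-sorted.
Gene intervals are stored internally as 0-based half-open; user-facing
formats (GFF3, VCF) keep their native conventions at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

_GO_TERM_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic SNP: identifier, 1-based position and its two alleles."""

    id: str
    chrom: str
    pos: int  # 1-based bp
    ref_allele: str = "A"
    alt_allele: str = "T"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")


class GenotypeMatrix:
    """Samples x markers dosage matrix with marker/sample metadata.

    Dosages are alt-allele counts in {0, 1, 2} with ``NaN`` for missing.
    Markers are kept sorted by (chrom, pos); construction re-sorts columns
    if needed. Marker ids must be unique.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        markers: Sequence[MarkerInfo],
        sample_ids: Sequence[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if dosages.shape[1] != len(markers):
            raise ValueError(
                f"{dosages.shape[1]} columns but {len(markers)} marker records"
            )
        if dosages.shape[0] != len(sample_ids):
            raise ValueError(
                f"{dosages.shape[0]} rows but {len(sample_ids)} sample ids"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0,1,2} or missing")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")

        order = sorted(range(len(markers)), key=lambda j: (markers[j].chrom, markers[j].pos))
        if order != list(range(len(markers))):
            dosages = dosages[:, order]
            markers = [markers[j] for j in order]
        self.dosages = dosages
        self.markers = list(markers)
        self.sample_ids = list(sample_ids)
        self._index = {m.id: j for j, m in enumerate(self.markers)}
        self._imputed: np.ndarray | None = None

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def index_of(self, marker_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.asarray([self._index[i] for i in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    # -- views -------------------------------------------------------------
    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.index_of(marker_ids)
        return GenotypeMatrix(
            self.dosages[:, idx], [self.markers[j] for j in idx], self.sample_ids
        )

    def subset_samples(self, rows: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            self.dosages[rows], self.markers, [self.sample_ids[i] for i in rows]
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing cells replaced by the per-marker mean.

        Used only inside numeric kernels (GRM, GWAS, LD); missingness is
        never written back to disk. All-missing markers impute to 0.
        The array is cached and must be treated as read-only.
        """
        if self._imputed is None:
            X = self.dosages
            if np.isnan(X).any():
                col_mean = np.nanmean(
                    np.where(np.isnan(X).all(axis=0), 0.0, 1.0) * X, axis=0
                )
                col_mean = np.nan_to_num(col_mean)
                X = np.where(np.isnan(X), col_mean[None, :], X)
            self._imputed = X
        return self._imputed

    def in_genomic_order(self, marker_ids: Iterable[str]) -> list[str]:
        """Return the given ids sorted by their (chrom, pos) column order."""
        return sorted(marker_ids, key=lambda i: self._index[i])


@dataclass
class PhenotypeTable:
    """Sample x trait phenotype values; ``NaN`` marks per-trait missingness."""

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray  # n_samples x n_traits, float with NaN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(
            len(self.sample_ids), len(self.trait_names)
        )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype table")

    def trait(self, name: str) -> np.ndarray:
        j = self.trait_names.index(name)
        return self.values[:, j]

    def complete_cases(self, name: str) -> tuple[list[str], np.ndarray]:
        """Sample ids and values for samples with a non-missing phenotype."""
        y = self.trait(name)
        keep = np.isfinite(y)
        return [s for s, k in zip(self.sample_ids, keep) if k], y[keep]


@dataclass(frozen=True)
class GeneModel:
    """One gene interval; coordinates are 0-based half-open internally."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GOAnnotationMap:
    """GO-term id -> set of gene ids (already propagated through children)."""

    term_to_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not _GO_TERM_RE.match(term):
                raise ValueError(f"malformed GO term id {term!r}")
            if not genes:
                raise ValueError(f"GO term {term} has an empty gene set")

    def __len__(self) -> int:
        return len(self.term_to_genes)


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK1 bed/bim/fam, or a TSV dosage matrix.

    ``format='plink'`` expects ``path`` to be the shared prefix of the
    .bed/.bim/.fam triplet. Multi-allelic VCF records are skipped with a
    logged warning; only SNPs are kept.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    from cyvcf2 import VCF  # htslib handles plain and bgzipped text alike

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    markers: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = MISSING
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(
            MarkerInfo(id=mid, chrom=var.CHROM, pos=var.POS,
                       ref_allele=var.REF, alt_allele=var.ALT[0])
        )
        columns.append(g)
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    if not columns:
        raise FormatError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(np.column_stack(columns), markers, sample_ids)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    """Minimal PLINK 1.9 bed/bim/fam reader (SNP-major .bed).

    Dosage counts copies of the .bim A1 allele (A1 = alt here), matching
    the 0/1/2 convention of the VCF reader for round-trip fixtures.
    """
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam_df[1].tolist()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    markers = [
        MarkerInfo(id=r[1], chrom=str(r[0]), pos=int(r[3]),
                   ref_allele=r[5], alt_allele=r[4])
        for r in bim_df.itertuples(index=False)
    ]
    n, m = len(sample_ids), len(markers)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise FormatError(f"{bed}: not a SNP-major PLINK1 .bed file")
    bytes_per_marker = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_marker)
    # unpack 2-bit codes, sample-fastest within byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]  # markers x samples
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, MISSING, 1.0, 0.0])
    dosages = lut[codes].T
    return GenotypeMatrix(dosages, markers, sample_ids)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    """TSV: header ``sample_id<TAB>marker1...``; marker ids ``chrom_pos``
    or arbitrary (position then falls back to column order)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    sample_ids = df.iloc[:, 0].tolist()
    markers = []
    for j, name in enumerate(df.columns[1:]):
        parts = name.rsplit("_", 1)
        if len(parts) == 2 and parts[1].isdigit():
            chrom, pos = parts[0], int(parts[1])
        else:
            chrom, pos = "0", j + 1
        markers.append(MarkerInfo(id=name, chrom=chrom, pos=pos))
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(values, markers, sample_ids)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes."""
    path = Path(path)
    chroms: dict[str, int] = {}
    for m in geno.markers:
        chroms[m.chrom] = max(chroms.get(m.chrom, 0), m.pos)
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in chroms.items():
            fh.write(f"##contig=<ID={c},length={ln + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids) + "\n"
        )
        for j, m in enumerate(geno.markers):
            col = geno.dosages[:, j]
            gts = "\t".join(
                "./." if not np.isfinite(g) else code[g] for g in col
            )
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref_allele}\t{m.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK1 bed/bim/fam triplet (A1 = alt allele)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in geno.sample_ids:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for m in geno.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\t{m.alt_allele}\t{m.ref_allele}\n")
    n = geno.n_samples
    inv = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.full(geno.dosages.T.shape, 1, dtype=np.uint8)  # 1 = missing
    for dos, c in inv.items():
        codes[geno.dosages.T == dos] = c
    pad = (-n) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0)
    packed = (
        codes.reshape(geno.n_markers, -1, 4)
        << (np.arange(4) * 2)[None, None, :]
    ).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.marker_ids)
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV with header ``sample_id`` + one column per trait; NA = missing."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    if df.iloc[:, 0].duplicated().any():
        dups = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric trait cell ({exc})") from None
    return PhenotypeTable(
        sample_ids=df.iloc[:, 0].tolist(),
        trait_names=list(df.columns[1:]),
        values=values,
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(pheno.values, columns=pheno.trait_names)
    df.insert(0, "sample_id", pheno.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene intervals from GFF3 (``gene`` rows) or BED4.

    GFF3 1-based inclusive coordinates become 0-based half-open
    (start-1, end); BED is already half-open and passes through.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                if "ID" not in attrs:
                    raise FormatError(f"{path}:{lineno}: gene row lacks ID attribute")
                start, end = int(parts[3]), int(parts[4])
                if start > end:
                    raise FormatError(f"{path}:{lineno}: start > end")
                genes.append(
                    GeneModel(attrs["ID"], parts[0], start - 1, end, parts[6] or ".")
                )
    elif format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: BED4 needs 4 columns")
                start, end = int(parts[1]), int(parts[2])
                if start > end:
                    raise FormatError(f"{path}:{lineno}: start > end")
                strand = parts[5] if len(parts) >= 6 else "."
                genes.append(GeneModel(parts[3], parts[0], start, end, strand))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as GFF3 ``gene`` rows (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbingogs\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# GO annotation map
# ---------------------------------------------------------------------------

def read_go_map(path: str | Path) -> GOAnnotationMap:
    """Two-column TSV (term_id, gene_id); duplicate rows collapse to sets.

    Malformed term ids are skipped with one summary warning.
    """
    term_to_genes: dict[str, set[str]] = {}
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not _GO_TERM_RE.match(parts[0]):
                n_bad += 1
                continue
            term_to_genes.setdefault(parts[0], set()).add(parts[1])
    if n_bad:
        logger.warning("read_go_map: skipped %d malformed rows", n_bad)
    return GOAnnotationMap(term_to_genes)


def write_go_map(go: GOAnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(go.term_to_genes):
            for gene in sorted(go.term_to_genes[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# marker subsets
# ---------------------------------------------------------------------------

def write_marker_subset(
    subset: Sequence[str], path: str | Path, reference: GenotypeMatrix | None = None
) -> None:
    """Write one marker id per line, preserving order.

    If a reference matrix is given, unknown ids raise with the offenders listed.
    """
    if reference is not None:
        unknown = [i for i in subset if i not in reference]
        if unknown:
            raise KeyError(f"ids not in reference matrix: {unknown[:10]}")
    with open(path, "w") as fh:
        for mid in subset:
            fh.write(f"{mid}\n")


def read_marker_subset(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
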