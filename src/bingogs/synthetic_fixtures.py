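"""Desk-scale synthetic genotype/annotation/phenotype fixtures.

Genotypes come from latent-Gaussian LD blocks: within each block, haplotype
liabilities follow a lag-1 autoregressive process with correlation
``within_block_rho`` and are thresholded at per-marker allele frequencies;
two independent haplotypes sum to a dosage. Gene intervals are tiled
non-overlapping across chromosomes, GO terms draw random gene sets whose
mapped-SNP counts straddle the effective-term threshold, and phenotypes are
additive over planted QTNs with the in-sample variance ratio rescaled to an
exact heritability. All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from bingogs.data_io import (
    GeneModel,
    GenotypeMatrix,
    GOAnnotationMap,
    MarkerInfo,
    PhenotypeTable,
    write_gene_models_gff3,
    write_go_map,
    write_phenotypes,
    write_vcf,
)


@dataclass
class SimConfig:
    n_samples: int = 300
    n_markers: int = 5000
    n_chrom: int = 5
    ld_block_len: int = 20
    within_block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 50
    n_terms: int = 12
    qtn_count: int = 30
    qtn_in_go_frac: float = 0.7
    h2: float = 0.7
    qtn_effect: str = "normal"  # or "fixed": equal |effect|, random sign
    seed: int = 0
    marker_spacing_bp: int = 100
    missing_frac: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.qtn_count >= self.n_markers:
            raise ValueError("qtn_count must be below n_markers")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")


DESK = SimConfig()  # default desk-scale preset


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Blocked AR(1) latent-Gaussian haplotypes thresholded to dosages."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = cfg.n_markers // cfg.n_chrom
    extras = cfg.n_markers - per_chrom * cfg.n_chrom
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    thresholds = stats.norm.ppf(freqs)  # latent > -inf .. threshold => allele 1?
    markers: list[MarkerInfo] = []
    j = 0
    for c in range(cfg.n_chrom):
        m_c = per_chrom + (1 if c < extras else 0)
        for k in range(m_c):
            markers.append(
                MarkerInfo(
                    id=f"snp{j:06d}",
                    chrom=f"chr{c + 1}",
                    pos=(k + 1) * cfg.marker_spacing_bp,
                    ref_allele="A",
                    alt_allele="T",
                )
            )
            j += 1

    def _haplotypes() -> np.ndarray:
        """One haplotype per sample: latent AR(1) per block, thresholded."""
        lat = np.empty((cfg.n_samples, cfg.n_markers))
        rho = cfg.within_block_rho
        innov_sd = np.sqrt(1.0 - rho * rho)
        col = 0
        for c in range(cfg.n_chrom):
            m_c = per_chrom + (1 if c < extras else 0)
            done = 0
            while done < m_c:
                blk = min(cfg.ld_block_len, m_c - done)
                z = np.empty((cfg.n_samples, blk))
                z[:, 0] = rng.standard_normal(cfg.n_samples)
                for t in range(1, blk):
                    z[:, t] = rho * z[:, t - 1] + innov_sd * rng.standard_normal(
                        cfg.n_samples
                    )
                lat[:, col : col + blk] = z
                col += blk
                done += blk
        return (lat < thresholds[None, :]).astype(float)

    dosages = _haplotypes() + _haplotypes()
    if cfg.missing_frac > 0:
        mask = rng.random(dosages.shape) < cfg.missing_frac
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages, markers, [f"s{i:04d}" for i in range(cfg.n_samples)])


def simulate_annotation(
    cfg: SimConfig, geno: GenotypeMatrix | None = None
) -> tuple[list[GeneModel], GOAnnotationMap]:
    """Non-overlapping genes tiled across chromosomes + random GO gene sets.

    Term gene-set sizes are spread so that mapped-SNP counts straddle any
    reasonable effective-term threshold at desk scale.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    per_chrom_markers = cfg.n_markers // cfg.n_chrom
    chrom_len = (per_chrom_markers + 1) * cfg.marker_spacing_bp
    genes: list[GeneModel] = []
    per_chrom_genes = max(1, cfg.n_genes // cfg.n_chrom)
    gene_span = chrom_len // (2 * per_chrom_genes)
    g = 0
    for c in range(cfg.n_chrom):
        for k in range(per_chrom_genes):
            if g >= cfg.n_genes:
                break
            start = k * 2 * gene_span
            genes.append(
                GeneModel(
                    gene_id=f"gene{g:04d}",
                    chrom=f"chr{c + 1}",
                    start=start,
                    end=start + gene_span,
                    strand="+" if g % 2 == 0 else "-",
                )
            )
            g += 1
    gene_ids = [gm.gene_id for gm in genes]
    term_to_genes: dict[str, set[str]] = {}
    # term sizes span from 1 gene to most genes so SNP counts straddle thresholds
    sizes = np.linspace(1, max(2, len(gene_ids) - 1), cfg.n_terms).astype(int)
    for t, size in enumerate(sizes):
        pick = rng.choice(len(gene_ids), size=min(size, len(gene_ids)),
                          replace=False)
        term_to_genes[f"GO:{t + 1:07d}"] = {gene_ids[i] for i in pick}
    # one parent term that properly contains the first (child) term's genes
    child = f"GO:{1:07d}"
    parent = f"GO:{cfg.n_terms + 1:07d}"
    extra = set(rng.choice(gene_ids, size=min(3, len(gene_ids)), replace=False))
    term_to_genes[parent] = term_to_genes[child] | extra
    return genes, GOAnnotationMap(term_to_genes)


def simulate_phenotype(
    geno: GenotypeMatrix,
    genes: list[GeneModel],
    go: GOAnnotationMap,
    cfg: SimConfig,
    trait_name: str = "trait",
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Additive phenotype with planted QTNs and exact in-sample heritability.

    ``qtn_in_go_frac`` of QTNs are drawn from markers inside GO-annotated
    genes, the rest anywhere else. Effects are standard normal; the residual
    is orthogonalized against the genetic values and rescaled so
    Var(g)/Var(y) equals ``cfg.h2`` exactly in-sample. Returns the table
    plus a truth table (qtn id, effect, in_go flag).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    annotated_genes = set().union(*go.term_to_genes.values())
    in_go_cols: set[int] = set()
    chroms = np.asarray([m.chrom for m in geno.markers])
    pos0 = np.asarray([m.pos - 1 for m in geno.markers])
    for gm in genes:
        if gm.gene_id not in annotated_genes:
            continue
        hit = (chroms == gm.chrom) & (pos0 >= gm.start) & (pos0 < gm.end)
        in_go_cols.update(np.flatnonzero(hit).tolist())
    out_cols = sorted(set(range(geno.n_markers)) - in_go_cols)
    in_cols = sorted(in_go_cols)

    n_in = int(round(cfg.qtn_in_go_frac * cfg.qtn_count))
    n_out = cfg.qtn_count - n_in
    if n_in > len(in_cols):
        raise ValueError(
            f"requested {n_in} in-gene QTNs but only {len(in_cols)} markers "
            "lie inside GO-annotated genes"
        )
    picks = []
    if n_in:
        picks.extend(rng.choice(in_cols, size=n_in, replace=False).tolist())
    if n_out:
        picks.extend(rng.choice(out_cols, size=min(n_out, len(out_cols)),
                                replace=False).tolist())
    picks = sorted(picks)
    if cfg.qtn_effect == "fixed":
        # equal-magnitude minor effects: a deliberately polygenic architecture
        beta = rng.choice([-1.0, 1.0], size=len(picks))
    else:
        beta = rng.standard_normal(len(picks))

    W = geno.imputed()[:, picks]
    gvals = (W - W.mean(axis=0)) @ beta
    if np.var(gvals) == 0:
        raise ValueError("planted QTNs are all monomorphic; no genetic variance")
    e = rng.standard_normal(geno.n_samples)
    # orthogonalize the residual against g so the variance ratio is exact
    e = e - e.mean()
    gc = gvals - gvals.mean()
    e = e - (e @ gc) / (gc @ gc) * gc
    scale = np.sqrt((1.0 - cfg.h2) / cfg.h2 * np.var(gvals) / np.var(e))
    y = gvals + scale * e

    truth = pd.DataFrame(
        {
            "qtn_id": [geno.markers[j].id for j in picks],
            "effect": beta,
            "in_go": [j in in_go_cols for j in picks],
        }
    )
    pheno = PhenotypeTable(
        sample_ids=list(geno.sample_ids),
        trait_names=[trait_name],
        values=y[:, None],
    )
    return pheno, truth


def simulate_dataset(cfg: SimConfig) -> dict:
    """Genotypes + annotation + phenotype + QTN truth in one call."""
    geno = simulate_genotypes(cfg)
    genes, go = simulate_annotation(cfg, geno)
    pheno, truth = simulate_phenotype(geno, genes, go, cfg)
    return {"geno": geno, "genes": genes, "go": go, "pheno": pheno, "truth": truth}


def write_fixture_dir(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write genotypes.vcf, phenos.tsv, genes.gff3, go_map.tsv, qtn_truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    write_vcf(data["geno"], outdir / "genotypes.vcf")
    write_phenotypes(data["pheno"], outdir / "phenos.tsv")
    write_gene_models_gff3(data["genes"], outdir / "genes.gff3")
    write_go_map(data["go"], outdir / "go_map.tsv")
    data["truth"].to_csv(outdir / "qtn_truth.tsv", sep="\t", index=False)
    return data
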