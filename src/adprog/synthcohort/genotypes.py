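"""Genotype simulation: Balding-Nichols subpopulations and block LD.

Allele frequencies per subpopulation are drawn by the Balding-Nichols
construction: for ancestral frequency p and divergence F, subpopulation
frequencies follow Beta(p (1-F)/F, (1-p)(1-F)/F), giving Var = F p (1-p) and
hence an expected Hudson FST of F. Linkage disequilibrium is produced by a
block-anchor copy process: within each block, haplotype alleles copy the
block anchor with probability 1 - flip_prob and are re-drawn from the block
allele frequency otherwise, so adjacent-SNP correlation is tunable via
flip_prob. All SNPs of a block share the anchor's subpopulation frequencies,
which keeps the configured divergence intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genomics.matrix import GenotypeMatrix
from .config import SimulationConfig


@dataclass
class GenotypeTruth:
    subpop_labels: np.ndarray                 # per-patient subpopulation index
    subpop_freqs: np.ndarray                  # (n_snps, n_subpops)
    block_ids: np.ndarray                     # per-SNP LD block index
    annotation: pd.DataFrame                  # snp_id, chrom, pos, genes, damaging


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Simulate a dosage panel with population structure and LD blocks."""
    rng = config.rng("genotypes")
    n, p = config.n_patients, config.n_snps
    k = config.n_subpops
    lo, hi = config.maf_range
    F = config.fst

    labels = rng.integers(0, k, size=n)
    block_ids = np.arange(p) // config.ld_block_size
    n_blocks = block_ids[-1] + 1

    anc = rng.uniform(lo, hi, size=n_blocks)
    if F > 0:
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        block_freqs = rng.beta(a[:, None], b[:, None], size=(n_blocks, k))
        block_freqs = np.clip(block_freqs, 1e-4, 1 - 1e-4)
    else:
        block_freqs = np.repeat(anc[:, None], k, axis=1)
    subpop_freqs = block_freqs[block_ids]        # (p, k)
    pf = subpop_freqs[:, labels].T               # (n, p) per-patient frequency

    # haplotype-level copy-with-mutation from the block anchor
    block_pf = block_freqs[:, labels].T          # (n, n_blocks)
    dosage = np.zeros((n, p), dtype=float)
    for hap in range(2):
        r = config.rng(f"hap{hap}")
        anchor = (r.random((n, n_blocks)) < block_pf).astype(np.int8)
        fresh = (r.random((n, p)) < pf).astype(np.int8)
        copy = r.random((n, p)) >= config.ld_flip_prob
        alleles = np.where(copy, anchor[:, block_ids], fresh)
        dosage += alleles
    snp_ids = [f"rs{j:06d}" for j in range(p)]
    patient_ids = [f"P{i:04d}" for i in range(n)]
    G = GenotypeMatrix(dosage, snp_ids, patient_ids)

    annotation = _annotate(config, snp_ids, block_ids)
    return G, GenotypeTruth(labels, subpop_freqs, block_ids, annotation)


def _annotate(
    config: SimulationConfig, snp_ids: list[str], block_ids: np.ndarray
) -> pd.DataFrame:
    """Per-SNP annotation: position, mapped genes (one per LD block, with a
    fraction of SNPs mapped to two genes), and a damaging flag."""
    rng = config.rng("annotation")
    p = len(snp_ids)
    n_genes = config.n_genes or max(int(block_ids[-1]) + 1, 1)
    genes = []
    for j in range(p):
        g = f"G{int(block_ids[j]) % n_genes:04d}"
        if rng.random() < 0.1:  # SNPs occasionally map to two genes
            g2 = f"G{rng.integers(0, n_genes):04d}"
            g = g + ";" + g2 if g2 != g else g
        genes.append(g)
    damaging = rng.random(p) < config.damaging_fraction
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, p + 1),
            "genes": genes,
            "damaging": damaging.astype(int),
        }
    )


def make_pathway_gene_sets(config: SimulationConfig) -> dict[str, list[str]]:
    """Random pathway gene sets over the simulated gene universe (GMT-shaped)."""
    rng = config.rng("pathways")
    n_genes = config.n_genes or max(config.n_snps // config.ld_block_size, 1)
    universe = [f"G{i:04d}" for i in range(n_genes)]
    sets: dict[str, list[str]] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(5, max(6, min(40, n_genes))))
        members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
        sets[f"PW{i:03d}"] = [universe[g] for g in sorted(members)]
    return sets
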