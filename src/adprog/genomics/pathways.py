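"""SNP -> gene -> pathway mapping and per-patient pathway functional-impact scores.

The impact score summarizes, for each patient and pathway, the fraction of
pathway map-able SNPs that are both predicted damaging (SIFT deleterious or
PolyPhen at-least-possibly-damaging, consumed as an annotation flag) and
carried by the patient (minor-allele dosage >= 1). Scores lie in [0, 1]; a
missing genotype counts as non-carrier. A dosage-weighted variant (dosage / 2
in the numerator) is available behind ``weighted=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PathwaySNPMap:
    pathway_snps: dict[str, list[str]]            # pathway -> ordered mapped SNP ids
    snp_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_pathways: dict[str, set[str]] = field(default_factory=dict)
    dropped_pathways: list[str] = field(default_factory=list)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def build_pathway_snp_map(
    snp_gene_map: dict[str, set[str] | list[str]],
    pathway_gene_sets: dict[str, list[str] | set[str]],
    panel_snps: list[str] | None = None,
) -> PathwaySNPMap:
    """Map pathways to SNP sets through shared gene membership.

    A SNP mapped to several genes may land in several pathways. Pathways with
    no mapped SNP are dropped (logged). When ``panel_snps`` is given, SNPs
    outside the panel are ignored.
    """
    panel = set(panel_snps) if panel_snps is not None else None
    gene_pathways: dict[str, set[str]] = {}
    for pw, genes in pathway_gene_sets.items():
        for g in genes:
            gene_pathways.setdefault(g, set()).add(pw)
    pathway_snps: dict[str, list[str]] = {pw: [] for pw in pathway_gene_sets}
    snp_genes = {s: set(gs) for s, gs in snp_gene_map.items()}
    for snp, genes in snp_genes.items():
        if panel is not None and snp not in panel:
            continue
        hit = set()
        for g in genes:
            hit |= gene_pathways.get(g, set())
        for pw in hit:
            pathway_snps[pw].append(snp)
    dropped = [pw for pw, snps in pathway_snps.items() if not snps]
    for pw in dropped:
        log.info("pathway %s has no mapped SNPs; dropped", pw)
        del pathway_snps[pw]
    return PathwaySNPMap(pathway_snps, snp_genes, gene_pathways, dropped)


def pathway_impact_scores(
    G: GenotypeMatrix,
    pmap: PathwaySNPMap,
    damaging_flags: dict[str, bool] | pd.Series,
    weighted: bool = False,
) -> pd.DataFrame:
    """Patients x pathways matrix of functional-impact scores in [0, 1].

    score(i, P) = |{SNP in P : damaging and dosage(i, SNP) >= 1}| / |P|
    with |P| the number of map-able SNPs in the pathway (the denominator never
    depends on the patient). ``weighted=True`` replaces the carrier indicator
    by dosage / 2.
    """
    if isinstance(damaging_flags, pd.Series):
        damaging_flags = damaging_flags.astype(bool).to_dict()
    snp_index = {s: j for j, s in enumerate(G.snp_ids)}
    cols = {}
    for pw, snps in pmap.pathway_snps.items():
        missing_flags = [s for s in snps if s not in damaging_flags]
        if missing_flags:
            raise KeyError(f"no damaging flag for SNPs {missing_flags[:5]} in pathway {pw}")
        idx = [snp_index[s] for s in snps if s in snp_index]
        if not idx:
            continue
        dmg = np.array([damaging_flags[s] for s in snps if s in snp_index], dtype=bool)
        block = np.nan_to_num(G.dosages[:, idx], nan=0.0)
        if weighted:
            contrib = (block[:, dmg] / 2.0).sum(axis=1)
        else:
            contrib = (block[:, dmg] >= 1).sum(axis=1)
        cols[pw] = contrib / len(snps)
    return pd.DataFrame(cols, index=G.patient_ids)
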