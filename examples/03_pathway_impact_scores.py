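"""Per-patient SNP pathway functional-impact scores.

Maps SNPs to pathways through shared genes and scores each patient by the
fraction of pathway map-able SNPs that are predicted damaging AND carried
(minor-allele dosage >= 1). Scores live in [0, 1] and become model features.
"""

from adprog.genomics import build_pathway_snp_map, pathway_impact_scores
from adprog.synthcohort import SimulationConfig, make_cohort

cfg = SimulationConfig(n_patients=200, n_snps=1000, n_clinical=10,
                       n_pathways=12, seed=3)
cohort = make_cohort(cfg)

ann = cohort.snp_annotation.set_index("snp_id")
snp_gene = {s: set(str(g).split(";")) for s, g in ann["genes"].items()}
pmap = build_pathway_snp_map(snp_gene, cohort.pathway_gene_sets,
                             panel_snps=cohort.genotypes.snp_ids)
scores = pathway_impact_scores(cohort.genotypes, pmap, ann["damaging"].astype(bool))

print(f"{scores.shape[1]} pathways scored for {scores.shape[0]} patients")
print("pathway set sizes (mapped SNPs):",
      {pw: len(s) for pw, s in list(pmap.pathway_snps.items())[:5]}, "...")
print("\nfirst patients x first pathways:")
print(scores.iloc[:4, :4].round(3))
print(f"\nscore range: [{scores.min().min():.3f}, {scores.max().max():.3f}]")
print("-> a score of e.g. 0.25 means a quarter of that pathway's map-able")
print("   SNPs are damaging variants this patient actually carries.")
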