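"""Genotype QC, relatedness, LD, PCA and pathway-score tests with brute-force audits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from adprog.genomics import (
    GenotypeMatrix,
    build_pathway_snp_map,
    expand_ld_set,
    inbreeding_coeff,
    kinship_mom,
    ld_prune,
    ld_r2,
    pathway_impact_scores,
    pca_top_k,
    relatedness_filter,
    snp_qc_filter,
)
from adprog.synthcohort import SimulationConfig, simulate_genotypes

from conftest import toy_genotypes


# ---------------------------------------------------------------- container
def test_major_allele_columns_are_flipped():
    # second SNP has alt frequency 0.75 -> flipped to minor orientation
    G = toy_genotypes([[0, 2], [0, 2], [1, 1], [0, 1]])
    assert G.maf()[1] <= 0.5
    np.testing.assert_array_equal(G.dosages[:, 1], [0, 0, 1, 1])
    assert G.flipped[1]


def test_invalid_dosage_values_rejected():
    with pytest.raises(ValueError, match="0, 1, 2"):
        toy_genotypes([[0, 3]])


# ---------------------------------------------------------------- QC filter
def test_qc_filter_toy_panel_counts():
    # MAFs approx (0.005, 0.02, 0.3, 0.5, 0.009) via explicit dosage columns
    n = 1000
    rng = np.random.default_rng(0)
    def col(maf):
        d = np.zeros(n)
        k = int(round(2 * maf * n))
        d[:k] = 1
        return d
    D = np.column_stack([col(m) for m in (0.005, 0.02, 0.3, 0.5, 0.009)])
    G = toy_genotypes(D)
    filtered, log = snp_qc_filter(G, maf_min=0.01, miss_max=0.05)
    assert log.n_removed_maf == 2
    assert filtered.n_snps == 3
    assert set(filtered.snp_ids) == {"s1", "s2", "s3"}


def test_qc_filter_removes_high_missingness():
    rng = np.random.default_rng(8)
    D = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
    D[:10, 1] = np.nan  # 10% missing on the second SNP
    G = toy_genotypes(D)
    filtered, _ = snp_qc_filter(G, maf_min=0.01, miss_max=0.05)
    assert filtered.snp_ids == ["s0"]


def test_qc_filter_is_idempotent(panmictic_panel):
    G, _ = panmictic_panel
    once, _ = snp_qc_filter(G)
    twice, log = snp_qc_filter(once)
    assert twice.n_snps == once.n_snps
    assert log.n_removed_maf == 0 and log.n_removed_missing == 0


def test_qc_empty_result_warns_not_raises():
    G = toy_genotypes(np.zeros((50, 2)) + np.tile([0.0, 1.0], (50, 1)) * 0)
    filtered, log = snp_qc_filter(G, maf_min=0.01)
    assert filtered.n_snps == 0 and log.n_kept == 0


# ---------------------------------------------------------------- relatedness
def test_duplicate_individual_has_high_pihat(panmictic_panel):
    G, _ = panmictic_panel
    D = G.dosages.copy()
    D[1] = D[0]
    dup = GenotypeMatrix(D, G.snp_ids, G.patient_ids)
    rep = kinship_mom(dup)
    assert rep.pihat[0, 1] >= 0.95
    # duplicate pair exceeds every unrelated pair
    mask = np.ones_like(rep.pihat, dtype=bool)
    np.fill_diagonal(mask, False)
    mask[0, 1] = mask[1, 0] = False
    assert rep.pihat[0, 1] > rep.pihat[mask].max()


def test_unrelated_pairs_have_low_pihat(panmictic_panel):
    G, _ = panmictic_panel
    rep = kinship_mom(G)
    assert rep.pihat[0, 1] <= 0.05


def test_parent_offspring_pihat(panmictic_panel):
    G, _ = panmictic_panel
    rng = np.random.default_rng(42)
    def gamete(g):
        return np.where(g == 2, 1, np.where(g == 0, 0, rng.integers(0, 2, len(g))))
    child = gamete(G.dosages[0]) + gamete(G.dosages[1])
    D = np.vstack([G.dosages, child[None, :]])
    G2 = GenotypeMatrix(D, G.snp_ids, G.patient_ids + ["child"])
    rep = kinship_mom(G2)
    assert rep.pihat[0, -1] == pytest.approx(0.5, abs=0.1)
    assert rep.pihat[1, -1] == pytest.approx(0.5, abs=0.1)


def test_inbreeding_fully_homozygous_is_one():
    # sample MAF 0.5 everywhere; last individual homozygous at every SNP
    rng = np.random.default_rng(1)
    n, p = 40, 400
    D = np.zeros((n, p))
    D[: n // 2] = 0.0
    D[n // 2 :] = 2.0
    for j in range(p):
        rng.shuffle(D[:, j])
    G = toy_genotypes(D)
    maf = G.maf()
    keep = maf == 0.5
    F = inbreeding_coeff(G.subset(snps=keep))
    np.testing.assert_allclose(F, 1.0, atol=1e-12)


def test_inbreeding_panmictic_mean_near_zero():
    cfg = SimulationConfig(n_patients=500, n_snps=3000, n_subpops=1, fst=0.0,
                           ld_block_size=1, seed=23, n_clinical=0)
    G, _ = simulate_genotypes(cfg)
    F = inbreeding_coeff(G)
    assert abs(F.mean()) < 0.02


def test_inbreeding_requires_polymorphic_snps():
    G = toy_genotypes(np.zeros((10, 3)))
    with pytest.raises(ValueError, match="polymorphic"):
        inbreeding_coeff(G)


def test_relatedness_filter_drops_one_of_duplicate_pair(panmictic_panel):
    G, _ = panmictic_panel
    D = G.dosages.copy()
    D[1] = D[0]
    dup = GenotypeMatrix(D, G.snp_ids, G.patient_ids)
    rep = kinship_mom(dup)
    kept = relatedness_filter(rep)
    assert len({G.patient_ids[0], G.patient_ids[1]} & set(kept)) == 1
    # post-condition: no remaining pair above the threshold
    idx = [rep.patient_ids.index(k) for k in kept]
    sub = rep.pihat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    assert (sub[iu] <= 0.1).all()


def test_relatedness_filter_keeps_unrelated_cohort(panmictic_panel):
    G, _ = panmictic_panel
    rep = kinship_mom(G)
    kept = relatedness_filter(rep)
    assert kept == list(G.patient_ids)


def test_relatedness_filter_drops_inbred_individual(panmictic_panel):
    G, _ = panmictic_panel
    rep = kinship_mom(G)
    rep.inbreeding = rep.inbreeding.copy()
    rep.inbreeding[5] = 0.5
    kept = relatedness_filter(rep)
    assert G.patient_ids[5] not in kept


# ---------------------------------------------------------------- LD
def test_r2_identical_and_anticorrelated_columns():
    g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
    assert ld_r2(g, g) == pytest.approx(1.0)
    assert ld_r2(g, 2 - g) == pytest.approx(1.0)


def test_r2_independent_snps_near_zero():
    rng = np.random.default_rng(3)
    g1 = rng.integers(0, 3, 1000).astype(float)
    g2 = rng.integers(0, 3, 1000).astype(float)
    assert ld_r2(g1, g2) < 0.02


def test_r2_monomorphic_overlap_not_computable():
    g1 = np.array([1, 1, 1, np.nan])
    g2 = np.array([0, 1, 2, 0])
    assert np.isnan(ld_r2(g1, g2))


def test_prune_perfect_block_keeps_one():
    g = np.random.default_rng(0).integers(0, 3, 200).astype(float)
    G = toy_genotypes(np.tile(g[:, None], (1, 10)))
    kept = ld_prune(G, r2_max=0.2, window=50)
    assert len(kept) == 1 and kept[0] == 0


def test_prune_independent_panel_keeps_all():
    cfg = SimulationConfig(n_patients=400, n_snps=100, ld_block_size=1, seed=7,
                           n_subpops=1, fst=0.0, n_clinical=0)
    G, _ = simulate_genotypes(cfg)
    Gq, _ = snp_qc_filter(G)
    kept = ld_prune(Gq, r2_max=0.2, window=50)
    assert len(kept) == Gq.n_snps


def test_prune_postcondition_brute_force_audit(structured_panel):
    G, _ = structured_panel
    sub = G.subset(snps=np.arange(300))
    window = 30
    kept = ld_prune(sub, r2_max=0.2, window=window)
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            i, j = kept[a], kept[b]
            if j - i <= window:
                r2 = ld_r2(sub.dosages[:, i], sub.dosages[:, j])
                assert np.isnan(r2) or r2 < 0.2


def test_expand_ld_set_examples():
    rng = np.random.default_rng(5)
    block = rng.integers(0, 3, 300).astype(float)
    lone = rng.integers(0, 3, 300).astype(float)
    D = np.column_stack([block, block, block, block, block, lone])
    G = toy_genotypes(D)
    # lone seed: unchanged
    assert expand_ld_set(["s5"], G) == ["s5"]
    # seed inside a perfect block of 5: all 5 returned
    assert expand_ld_set(["s2"], G) == ["s0", "s1", "s2", "s3", "s4"]
    with pytest.raises(KeyError, match="sX"):
        expand_ld_set(["sX"], G)


def test_expand_ld_set_audit(structured_panel):
    G, _ = structured_panel
    sub = G.subset(snps=np.arange(100))
    seeds = [sub.snp_ids[0], sub.snp_ids[50]]
    expanded = expand_ld_set(seeds, sub, r2_min=0.8)
    seed_idx = [sub.snp_ids.index(s) for s in seeds]
    for s in expanded:
        if s in seeds:
            continue
        j = sub.snp_ids.index(s)
        best = max(ld_r2(sub.dosages[:, i], sub.dosages[:, j]) for i in seed_idx)
        assert best > 0.8


# ---------------------------------------------------------------- PCA
def test_pca_separates_subpopulations(structured_panel):
    G, truth = structured_panel
    Gq, _ = snp_qc_filter(G)
    pruned = Gq.subset(snps=ld_prune(Gq))
    res = pca_top_k(pruned, k=4)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(res.eigenvectors[:, :1])
    acc = (km.labels_ == truth.subpop_labels).mean()
    assert max(acc, 1 - acc) >= 0.9


def test_pca_no_structure_no_dominant_eigenvalue():
    cfg = SimulationConfig(n_patients=300, n_snps=3000, n_subpops=2, fst=0.0,
                           ld_block_size=1, seed=29, n_clinical=0)
    G, _ = simulate_genotypes(cfg)
    res = pca_top_k(G, k=4)
    assert res.eigenvalues[0] / res.eigenvalues[1] < 1.5


def test_pca_full_rank_reconstruction():
    rng = np.random.default_rng(11)
    G = toy_genotypes(rng.integers(0, 3, (10, 20)).astype(float))
    res = pca_top_k(G, k=9)
    from adprog.genomics.pca import standardize_genotypes
    Z = standardize_genotypes(G)
    Zr = res.eigenvectors @ np.diag(res.singular_values) @ res.loadings.T
    assert np.linalg.norm(Z - Zr) < 1e-8


def test_pca_orthonormal_eigenvectors(structured_panel):
    G, _ = structured_panel
    res = pca_top_k(G.subset(patients=np.arange(200)), k=6)
    V = res.eigenvectors
    assert np.abs(V.T @ V - np.eye(6)).max() < 1e-8
    assert np.all(np.diff(res.eigenvalues) <= 1e-9)
    assert np.all((res.explained_variance > 0) & (res.explained_variance <= 1))


def test_pca_k_too_large_rejected():
    G = toy_genotypes(np.random.default_rng(0).integers(0, 3, (10, 5)).astype(float))
    with pytest.raises(ValueError, match="k="):
        pca_top_k(G, k=8)


def test_ppca_variant_matches_svd_subspace(structured_panel):
    G, truth = structured_panel
    sub = G.subset(patients=np.arange(150), snps=np.arange(1000))
    svd = pca_top_k(sub, k=2)
    ppca = pca_top_k(sub, k=2, method="ppca")
    # same leading subspace up to rotation: principal angles near 0
    s = np.linalg.svd(svd.eigenvectors.T @ ppca.eigenvectors, compute_uv=False)
    assert s.min() > 0.99


# ---------------------------------------------------------------- pathways
def test_pathway_map_hand_counts():
    snp_gene = {"r1": {"g1"}, "r2": {"g2"}, "r3": {"g3"}}
    gmt = {"P1": ["g1", "g2"], "P2": ["g3"]}
    pmap = build_pathway_snp_map(snp_gene, gmt)
    assert sorted(pmap.pathway_snps["P1"]) == ["r1", "r2"]
    assert pmap.pathway_snps["P2"] == ["r3"]


def test_snp_in_two_genes_lands_in_both_pathways():
    pmap = build_pathway_snp_map({"r1": {"g1", "g2"}}, {"P1": ["g1"], "P2": ["g2"]})
    assert pmap.pathway_snps["P1"] == ["r1"] and pmap.pathway_snps["P2"] == ["r1"]


def test_empty_pathway_dropped():
    pmap = build_pathway_snp_map({"r1": {"g1"}}, {"P1": ["g1"], "P2": ["gX"]})
    assert "P2" not in pmap.pathway_snps
    assert pmap.dropped_pathways == ["P2"]


def _score_fixture():
    # 10 SNPs, one pathway of 8 mapped SNPs, 3 flagged damaging
    snps = [f"r{j}" for j in range(10)]
    D = np.zeros((3, 10))
    D[1, [0, 1]] = 1          # patient 1 carries 2 of the 3 damaging SNPs
    D[2, :8] = 1              # patient 2 carries everything in the pathway
    G = toy_genotypes(D, snp_ids=snps)
    pmap = build_pathway_snp_map(
        {s: {"g"} for s in snps[:8]}, {"P": ["g"]}
    )
    flags = {s: (s in ("r0", "r1", "r2")) for s in snps}
    return G, pmap, flags


def test_pathway_scores_hand_counts():
    G, pmap, flags = _score_fixture()
    scores = pathway_impact_scores(G, pmap, flags)
    assert scores.loc["p0", "P"] == 0.0            # carries nothing
    assert scores.loc["p1", "P"] == pytest.approx(2 / 8)
    assert scores.loc["p2", "P"] == pytest.approx(3 / 8)


def test_pathway_scores_upper_bound_all_flagged_and_carried():
    snps = ["a", "b"]
    G = toy_genotypes(np.ones((2, 2)), snp_ids=snps)
    pmap = build_pathway_snp_map({s: {"g"} for s in snps}, {"P": ["g"]})
    scores = pathway_impact_scores(G, pmap, {s: True for s in snps})
    assert (scores["P"] == 1.0).all()


def test_pathway_scores_monotone_in_carried_damaging_alleles():
    G, pmap, flags = _score_fixture()
    base = pathway_impact_scores(G, pmap, flags)
    D2 = G.dosages.copy()
    D2[0, 2] = 1   # patient 0 now carries damaging SNP r2
    G2 = toy_genotypes(D2, snp_ids=G.snp_ids)
    bumped = pathway_impact_scores(G2, pmap, flags)
    assert (bumped.to_numpy() >= base.to_numpy() - 1e-12).all()
    assert bumped.loc["p0", "P"] > base.loc["p0", "P"]


def test_pathway_scores_weighted_variant_uses_dosage():
    snps = ["a", "b"]
    G = toy_genotypes(np.array([[1.0, 0.0], [0.0, 0.0]]), snp_ids=snps,
                      patient_ids=["p0", "p1"])
    pmap = build_pathway_snp_map({s: {"g"} for s in snps}, {"P": ["g"]})
    flags = {"a": True, "b": True}
    carrier = pathway_impact_scores(G, pmap, flags)
    weighted = pathway_impact_scores(G, pmap, flags, weighted=True)
    assert carrier.loc["p0", "P"] == pytest.approx(1 / 2)      # heterozygous carrier
    assert weighted.loc["p0", "P"] == pytest.approx(1 / 4)     # dosage 1/2 over |P|=2


def test_pathway_scores_missing_flag_rejected():
    G, pmap, flags = _score_fixture()
    del flags["r0"]
    with pytest.raises(KeyError, match="damaging"):
        pathway_impact_scores(G, pmap, flags)
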