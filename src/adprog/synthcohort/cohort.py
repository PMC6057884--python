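"""Assemble a full synthetic cohort: genotypes, clinical table, outcomes, truth."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from ..genomics.matrix import GenotypeMatrix
from ..genomics.pathways import write_gmt
from .bn_sampling import random_cpts, random_dag, sample_discrete_bn
from .clinical import simulate_clinical
from .config import SimulationConfig
from .genotypes import GenotypeTruth, make_pathway_gene_sets, simulate_genotypes
from .missing import inject_missingness
from .outcomes import SurvivalOutcome, calibrate_coefficients, simulate_outcomes


@dataclass
class CohortTruth:
    linear_predictor: np.ndarray
    coefficients: dict[str, float]
    dag: nx.DiGraph | None = None
    cpts: dict[str, np.ndarray] | None = None
    subpop_labels: np.ndarray | None = None


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    snp_annotation: pd.DataFrame
    clinical: pd.DataFrame
    roles: dict[str, str]
    outcomes: SurvivalOutcome
    pathway_gene_sets: dict[str, list[str]]
    truth: CohortTruth
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        idx = list(self.clinical.index)
        if idx != list(self.genotypes.patient_ids):
            raise ValueError("clinical and genotype tables disagree on patient index")
        horizon = self.config.horizon_months if self.config else np.inf
        if (self.outcomes.time > horizon + 1e-9).any():
            raise ValueError("event times exceed study horizon")

    # ------------------------------------------------------------------
    def outcome_frame(self) -> pd.DataFrame:
        return self.outcomes.to_frame(index=self.clinical.index)

    def write(self, outdir: str | os.PathLike) -> None:
        """Persist all tables as plain-text artifacts (VCF/CSV/GMT/TSV/YAML)."""
        os.makedirs(outdir, exist_ok=True)
        d = os.fspath(outdir)
        self.genotypes.to_vcf(os.path.join(d, "genotypes.vcf"))
        self.genotypes.to_csv(os.path.join(d, "dosages.csv"))
        self.snp_annotation.to_csv(os.path.join(d, "snp_annotation.tsv"), sep="\t", index=False)
        clin = self.clinical.copy()
        clin.columns = pd.MultiIndex.from_tuples(
            [(c, self.roles[c]) for c in clin.columns], names=["variable", "role"]
        )
        clin.to_csv(os.path.join(d, "clinical.csv"))
        self.outcome_frame().to_csv(os.path.join(d, "outcomes.csv"), index_label="patient_id")
        write_gmt(self.pathway_gene_sets, os.path.join(d, "pathways.gmt"))
        if self.truth.dag is not None:
            with open(os.path.join(d, "truth_dag.tsv"), "w") as fh:
                fh.write("source\ttarget\n")
                for a, b in sorted(self.truth.dag.edges):
                    fh.write(f"{a}\t{b}\n")
        if self.config is not None:
            self.config.to_yaml(os.path.join(d, "config.yaml"))


def make_cohort(
    config: SimulationConfig,
    target_c: float | None = None,
    n_informative_snps: int | None = None,
    min_abs_coefficient: float | None = None,
) -> SyntheticCohort:
    """Generate a complete cohort under one seed.

    Planted hazard: ``config.true_coefficients`` if given, otherwise
    ``config.n_informative`` coefficients split between clinical scores and
    SNP dosages (log hazard ratios alternating in sign, |beta| >= 0.5). With
    ``target_c`` set, coefficients are rescaled by Monte-Carlo calibration so
    the true predictor's concordance hits the target;
    ``min_abs_coefficient`` keeps every planted effect at or above a floor
    even when calibration would shrink it further (the concordance then lands
    slightly above the target).
    """
    G, gtruth = simulate_genotypes(config)
    rng = config.rng("severity")
    severity = rng.standard_normal(config.n_patients)
    clinical, roles = simulate_clinical(config, severity)

    features = clinical.copy()
    dos = G.to_frame()
    features = pd.concat([features, dos], axis=1)

    coefs = dict(config.true_coefficients)
    if not coefs:
        cont_cols = [c for c in clinical.columns if roles.get(c) in ("neuropsych", "imaging")]
        n_snp_inf = (
            n_informative_snps
            if n_informative_snps is not None
            else max(config.n_informative // 2, 0)
        )
        n_clin_inf = config.n_informative - n_snp_inf
        # favor common SNPs so the planted dosage signal is well represented
        maf = G.maf()
        snp_order = np.argsort(-np.nan_to_num(maf))
        chosen_snps = [G.snp_ids[j] for j in snp_order[:n_snp_inf]]
        chosen_clin = cont_cols[:n_clin_inf]
        sign = 1.0
        for name in chosen_clin + chosen_snps:
            coefs[name] = sign * 0.6
            sign = -sign
    if target_c is not None:
        coefs = calibrate_coefficients(features, coefs, config, target_c=target_c)
    if min_abs_coefficient is not None and coefs:
        smallest = min(abs(v) for v in coefs.values())
        if 0 < smallest < min_abs_coefficient:
            coefs = {k: v * min_abs_coefficient / smallest for k, v in coefs.items()}
    outcomes, lp = simulate_outcomes(features, coefs, config)

    if config.missing_rate > 0:
        clinical = inject_missingness(
            clinical, config.missing_rate, seed=int(config.rng("missing").integers(2**31))
        )

    # ground-truth DAG over a small discrete view (used by network-recovery tests)
    dag = random_dag(10, max_in_degree=2, seed=config.rng("dag"))
    cpts = random_cpts(dag, n_levels=3, seed=config.rng("cpts"))

    truth = CohortTruth(
        linear_predictor=lp,
        coefficients=coefs,
        dag=dag,
        cpts=cpts,
        subpop_labels=gtruth.subpop_labels,
    )
    return SyntheticCohort(
        genotypes=G,
        snp_annotation=gtruth.annotation,
        clinical=clinical,
        roles=roles,
        outcomes=outcomes,
        pathway_gene_sets=make_pathway_gene_sets(config),
        truth=truth,
        config=config,
    )
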