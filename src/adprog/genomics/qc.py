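"""SNP-level quality-control filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class QCLog:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_kept: int
    maf_min: float
    miss_max: float


def snp_qc_filter(
    G: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.05
) -> tuple[GenotypeMatrix, QCLog]:
    """Drop SNPs with MAF below ``maf_min`` or missing fraction above ``miss_max``.

    Defaults correspond to the conventional GWAS thresholds MAF >= 1% and
    missing rate <= 5%. Returns the filtered matrix plus a count log. An empty
    result triggers a warning, not an error.
    """
    maf = G.maf()
    miss = G.missing_rate()
    low_maf = np.nan_to_num(maf, nan=0.0) < maf_min
    too_missing = miss > miss_max
    keep = ~(low_maf | too_missing)
    qclog = QCLog(
        n_input=G.n_snps,
        n_removed_maf=int(low_maf.sum()),
        n_removed_missing=int((too_missing & ~low_maf).sum()),
        n_kept=int(keep.sum()),
        maf_min=maf_min,
        miss_max=miss_max,
    )
    if qclog.n_kept == 0:
        log.warning("snp_qc_filter removed every SNP (maf_min=%g, miss_max=%g)", maf_min, miss_max)
    return G.subset(snps=keep), qclog
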