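"""Patients x SNPs dosage container with missingness mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix (0/1/2) with an explicit missingness mask.

    Dosages count occurrences of the minor allele per patient and SNP. The
    constructor enforces minor-allele orientation: any SNP whose observed
    alternate-allele frequency exceeds 0.5 is flipped (dosage -> 2 - dosage)
    so that MAF <= 0.5 holds for every column.

    Parameters
    ----------
    dosages
        float array of shape (n_patients, n_snps); np.nan marks missing calls.
    snp_ids, patient_ids
        unique string identifiers for columns / rows.
    positions
        optional 1-based physical positions (VCF convention); defaults to
        1..n_snps on a single chromosome.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    patient_ids: list[str]
    chrom: list[str] | None = None
    positions: np.ndarray | None = None
    flipped: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (patients x SNPs)")
        n, p = self.dosages.shape
        if len(self.patient_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists do not match dosage dimensions")
        obs = ~np.isnan(self.dosages)
        vals = self.dosages[obs]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("observed dosages must lie in {0, 1, 2}")
        if self.positions is None:
            self.positions = np.arange(1, p + 1, dtype=int)
        else:
            self.positions = np.asarray(self.positions, dtype=int)
        if self.chrom is None:
            self.chrom = ["1"] * p
        # orient to the minor allele
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        self.flipped = freq > 0.5
        if self.flipped.any():
            cols = np.where(self.flipped)[0]
            self.dosages[:, cols] = 2.0 - self.dosages[:, cols]
        self._maf_cache: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over observed calls (cached)."""
        if self._maf_cache is None:
            with np.errstate(invalid="ignore"):
                self._maf_cache = np.nanmean(self.dosages, axis=0) / 2.0
        return self._maf_cache

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    # ------------------------------------------------------------------
    def subset(
        self,
        patients: np.ndarray | list | None = None,
        snps: np.ndarray | list | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given patient / SNP index arrays."""
        pi = np.arange(self.n_patients) if patients is None else np.asarray(patients)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if pi.dtype == bool:
            pi = np.where(pi)[0]
        if si.dtype == bool:
            si = np.where(si)[0]
        return GenotypeMatrix(
            self.dosages[np.ix_(pi, si)].copy(),
            [self.snp_ids[j] for j in si],
            [self.patient_ids[i] for i in pi],
            chrom=[self.chrom[j] for j in si],
            positions=self.positions[si],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.patient_ids, columns=self.snp_ids)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index.astype(str)))

    def to_vcf(self, path) -> None:
        """Write unphased GT records (minor allele coded as ALT)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.patient_ids)
                + "\n"
            )
            code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, sid in enumerate(self.snp_ids):
                gts = [
                    "./." if np.isnan(d) else code[d] for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{self.chrom[j]}\t{int(self.positions[j])}\t{sid}\tA\tG\t.\t.\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a (small, uncompressed) VCF; ALT dosage = count of '1' alleles."""
        snp_ids: list[str] = []
        chrom: list[str] = []
        pos: list[int] = []
        rows: list[list[float]] = []
        patients: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    patients = parts[9:]
                    continue
                chrom.append(parts[0])
                pos.append(int(parts[1]))
                snp_ids.append(parts[2])
                vals = []
                for gt in parts[9:]:
                    allele = gt.split(":")[0]
                    if "." in allele:
                        vals.append(np.nan)
                    else:
                        vals.append(float(sum(int(a) for a in allele.replace("|", "/").split("/"))))
                rows.append(vals)
        dos = np.array(rows, dtype=float).T
        return cls(dos, snp_ids, patients, chrom=chrom, positions=np.array(pos))
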