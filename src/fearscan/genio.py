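"""Genotype I/O and marker quality control.

Genotypes are held as minor-allele dosage (0/1/2, with -1 for missing) in a
samples x variants int8 matrix, the orientation used throughout the pipeline:
2 = homozygous for the minor allele (the "B" / risk allele of the risk-score
stage), 0 = homozygous major.

The on-disk format is the PLINK 1 binary triplet (.bed/.bim/.fam), written
SNP-major with the standard 2-bit encoding.  A1 in the .bim is the minor
allele, so the 2-bit code maps directly onto dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: autosome labels for the dog genome (CanFam numbering)
DOG_AUTOSOMES = tuple(str(c) for c in range(1, 39))

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> minor-allele dosage, with A1 = minor:
#   00 hom A1 -> 2,  01 missing -> -1,  10 het -> 1,  11 hom A2 -> 0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class GenotypeFormatError(ValueError):
    """Malformed or mutually inconsistent PLINK triplet files."""


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix."""

    dosage: np.ndarray  # int8, samples x variants, -1 = missing
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        f = (d.sum(axis=0) / (2.0 * d.count(axis=0))).filled(np.nan)
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[index, :],
            [self.sample_ids[i] for i in index],
            list(self.variant_ids),
        )

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosage[:, index],
            list(self.sample_ids),
            [self.variant_ids[i] for i in index],
        )


@dataclass
class QCReport:
    """Exact accounting of the marker QC cascade; removals sum to the input."""

    n_input: int
    n_removed_nonautosomal: int = 0
    n_removed_mono_or_indel: int = 0
    n_removed_maf: int = 0
    n_removed_callrate: int = 0
    n_removed_prune: int = 0
    n_retained: int = 0

    def check(self) -> None:
        removed = (
            self.n_removed_nonautosomal
            + self.n_removed_mono_or_indel
            + self.n_removed_maf
            + self.n_removed_callrate
            + self.n_removed_prune
        )
        if self.n_input - removed != self.n_retained:
            raise AssertionError(f"QC accounting violated: {self}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet
# ---------------------------------------------------------------------------

def write_genotypes(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    prefix: str | Path,
) -> None:
    """Write .bed/.bim/.fam (SNP-major 2-bit .bed, A1 = minor allele).

    ``variants`` needs columns id/chrom/pos/allele_minor/allele_major;
    ``samples`` needs sample_id and optionally sex.
    """
    prefix = Path(prefix)
    n, m = geno.n_samples, geno.n_variants
    if len(variants) != m or len(samples) != n:
        raise ValueError("variant/sample table lengths do not match genotypes")

    codes = np.empty_like(geno.dosage, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[geno.dosage == dos] = code

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((m, n_bytes), dtype=np.uint8)
        for shift in range(4):
            idx = np.arange(shift, n, 4)
            part = codes[idx, :].T.astype(np.uint8)  # m x len(idx)
            buf[:, : part.shape[1]] |= part << (2 * shift)
        fh.write(buf.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": variants["chrom"].values,
            "id": variants["id"].values,
            "cm": 0,
            "pos": variants["pos"].values,
            "a1": variants["allele_minor"].values,
            "a2": variants["allele_major"].values,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    sex = samples["sex"].map({"F": 2, "M": 1}).fillna(0).astype(int) if "sex" in samples else 0
    fam = pd.DataFrame(
        {
            "fid": samples.get("breed", pd.Series(["0"] * n)).values,
            "iid": samples["sample_id"].values,
            "pat": 0,
            "mat": 0,
            "sex": sex,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)


def read_genotypes(
    bed_path: str | Path,
    bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK 1 triplet; returns (genotypes, variant table, sample table)."""
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed_path}: bad magic bytes (not SNP-major PLINK 1 .bed)")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise GenotypeFormatError(
            f"{bed_path}: {body.size} data bytes, expected {m * n_bytes} "
            f"for {n} samples x {m} variants"
        )
    buf = body.reshape(m, n_bytes)
    codes = np.empty((n, m), dtype=np.uint8)
    for shift in range(4):
        idx = np.arange(shift, n, 4)
        per_byte = (buf >> (2 * shift)) & 0b11  # m x n_bytes
        codes[idx, :] = per_byte[:, : idx.size].T

    dosage = _CODE_TO_DOSAGE[codes]
    geno = GenotypeMatrix(dosage, list(fam["iid"].astype(str)), list(bim["id"].astype(str)))

    variants = pd.DataFrame(
        {
            "id": bim["id"].astype(str),
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int),
            "allele_minor": bim["a1"],
            "allele_major": bim["a2"],
        }
    )
    variants = annotate_variant_stats(geno, variants)
    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"].astype(str),
            "breed": fam["fid"].astype(str),
            "sex": fam["sex"].map({2: "F", 1: "M"}),
        }
    )
    return geno, variants, samples


def annotate_variant_stats(geno: GenotypeMatrix, variants: pd.DataFrame) -> pd.DataFrame:
    """Attach maf / call_rate / polymorphic columns computed from the dosages."""
    variants = variants.copy()
    variants["maf"] = geno.maf()
    variants["call_rate"] = geno.call_rate()
    variants["polymorphic"] = variants["maf"] > 0
    if "indel" not in variants:
        variants["indel"] = False
    return variants


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def qc_filter(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    autosomes_only: bool = True,
    autosomes: tuple[str, ...] = DOG_AUTOSOMES,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Marker QC in fixed order: non-autosomal, monomorphic/indel, MAF, call rate.

    Thresholds are strict (keep MAF > maf_min and call rate > call_rate_min).
    Every input variant is accounted for exactly once, in removal order.
    """
    if len(variants) != geno.n_variants:
        raise ValueError("variant table not aligned with genotype matrix")
    variants = annotate_variant_stats(geno, variants)
    m = geno.n_variants
    report = QCReport(n_input=m)
    alive = np.ones(m, dtype=bool)

    if autosomes_only:
        drop = ~variants["chrom"].astype(str).isin(autosomes).values & alive
        report.n_removed_nonautosomal = int(drop.sum())
        alive &= ~drop

    drop = (~variants["polymorphic"].values | variants["indel"].values) & alive
    report.n_removed_mono_or_indel = int(drop.sum())
    alive &= ~drop

    drop = ~(variants["maf"].values > maf_min) & alive
    report.n_removed_maf = int(drop.sum())
    alive &= ~drop

    drop = ~(variants["call_rate"].values > call_rate_min) & alive
    report.n_removed_callrate = int(drop.sum())
    alive &= ~drop

    report.n_retained = int(alive.sum())
    report.check()
    if report.n_retained == 0:
        warnings.warn("QC removed every variant", stacklevel=2)
    return geno.subset_variants(alive), variants.loc[alive].reset_index(drop=True), report


def qc_filter_manifest(
    variants: pd.DataFrame,
    autosomes: tuple[str, ...] = DOG_AUTOSOMES,
) -> tuple[pd.DataFrame, QCReport]:
    """Category-only QC on a variant manifest (no genotypes): drop non-autosomal
    then monomorphic/indel entries, with exact accounting."""
    m = len(variants)
    report = QCReport(n_input=m)
    alive = np.ones(m, dtype=bool)
    drop = ~variants["chrom"].astype(str).isin(autosomes).values
    report.n_removed_nonautosomal = int(drop.sum())
    alive &= ~drop
    drop = (~variants["polymorphic"].values | variants["indel"].values) & alive
    report.n_removed_mono_or_indel = int(drop.sum())
    alive &= ~drop
    report.n_retained = int(alive.sum())
    report.check()
    return variants.loc[alive].reset_index(drop=True), report


def fill_sporadic_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-variant modal dosage.

    Non-missing entries are untouched.  Ties between equally frequent dosages
    resolve to the smaller dosage.  A variant with no observed calls at all is
    an error (nothing to impute from).
    """
    dosage = geno.dosage.copy()
    miss = dosage == MISSING
    if not miss.any():
        return GenotypeMatrix(dosage, list(geno.sample_ids), list(geno.variant_ids))

    all_missing = miss.all(axis=0)
    if all_missing.any():
        ids = [geno.variant_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"variants with all calls missing cannot be filled: {ids}")

    for j in np.flatnonzero(miss.any(axis=0)):
        col = dosage[:, j]
        obs = col[col != MISSING]
        counts = np.bincount(obs, minlength=3)
        col[col == MISSING] = int(np.argmax(counts))  # argmax -> smallest on ties
    return GenotypeMatrix(dosage, list(geno.sample_ids), list(geno.variant_ids))


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 200,
    step: int = 50,
    r2_max: float = 0.6,
) -> list[str]:
    """Sliding-window LD pruning of dosage correlations (indep-pairwise style).

    Windows of ``window`` variants advance by ``step``.  Within a window, while
    any retained pair has squared Pearson correlation > ``r2_max``, the member
    with the smaller MAF is removed (equal MAF: the later variant).  Returns the
    retained variant ids, in input order.
    """
    if window < 2:
        raise ValueError("window must be >= 2 variants")
    if step < 1:
        raise ValueError("step must be >= 1")

    d = geno.dosage.astype(float)
    if (d == MISSING).any():
        d[geno.dosage == MISSING] = np.nan
    m = geno.n_variants
    maf = geno.maf()
    keep = np.ones(m, dtype=bool)

    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start : start + window]) + start
        if idx.size >= 2:
            sub = d[:, idx]
            if np.isnan(sub).any():
                # pairwise-complete correlations when calls are missing
                with np.errstate(invalid="ignore"):
                    r = pd.DataFrame(sub).corr().values
            else:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(sub, rowvar=False)
            r2 = r**2
            np.fill_diagonal(r2, 0.0)
            local_keep = np.ones(idx.size, dtype=bool)
            while True:
                r2v = np.where(np.outer(local_keep, local_keep), r2, 0.0)
                i, j = np.unravel_index(np.nanargmax(r2v), r2v.shape)
                if not (r2v[i, j] > r2_max):
                    break
                # drop the lower-MAF member; equal MAF -> the later variant
                gi, gj = idx[i], idx[j]
                if maf[gi] < maf[gj]:
                    victim = i
                elif maf[gj] < maf[gi]:
                    victim = j
                else:
                    victim = max(i, j)
                local_keep[victim] = False
            keep[idx] = local_keep
        if start + window >= m:
            break
        start += step

    return [geno.variant_ids[i] for i in np.flatnonzero(keep)]
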