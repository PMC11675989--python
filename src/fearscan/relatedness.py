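"""Genomic relationship matrices, inbreeding coefficients, and the
two-population inbreeding comparison.

The inbreeding coefficient (IBC) is the method-of-moments excess-homozygosity
estimator used by ``plink --het``:

    F_hat = (O_hom - E_hom) / (L - E_hom)

with O_hom the observed homozygote count over an individual's non-missing
markers, L that marker count, and E_hom the Hardy-Weinberg expectation with
the small-sample allele-count correction n/(n-1) applied per marker.
Negative values mean fewer homozygotes than expected under random mating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class Kinship:
    matrix: np.ndarray
    flavor: str  # "centered" | "variance_standardized"
    n_markers_used: int

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.matrix = k

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


@dataclass
class IBCResult:
    sample_ids: list[str]
    f_hat: np.ndarray
    o_hom: np.ndarray
    e_hom: np.ndarray
    n_nonmissing: np.ndarray
    group: str = ""
    n_markers_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group,
                "F_hat": self.f_hat,
                "O_hom": self.o_hom,
                "E_hom": self.e_hom,
                "N_nonmissing": self.n_nonmissing,
            }
        )


@dataclass
class BreedComparisonResult:
    breed: str
    mean_a: float
    var_a: float
    n_a: int
    mean_b: float
    var_b: float
    n_b: int
    f_statistic: float
    f_test_p: float
    variances_unequal: bool
    t_statistic: float
    degrees_of_freedom: float
    t_test_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------

def compute_grm(geno: GenotypeMatrix, flavor: str = "centered") -> Kinship:
    """Genomic relationship matrix from complete dosages.

    centered:              K = (1/m) sum_i (x_i - xbar_i)(x_i - xbar_i)^T
    variance_standardized: markers additionally divided by their dosage SD
                           (monomorphic markers are skipped, with a log line)
    """
    if geno.missing_mask().any():
        raise ValueError("GRM requires complete genotypes; fill missing first")
    if flavor not in ("centered", "variance_standardized"):
        raise ValueError(f"unknown GRM flavor {flavor!r}")
    x = geno.dosage.astype(float)
    xc = x - x.mean(axis=0)
    m = xc.shape[1]
    if flavor == "variance_standardized":
        sd = xc.std(axis=0)
        poly = sd > 0
        n_skipped = int((~poly).sum())
        if n_skipped:
            logger.info("variance-standardized GRM: skipped %d monomorphic markers", n_skipped)
        xc = xc[:, poly] / sd[poly]
        m = xc.shape[1]
    if m < 1:
        raise ValueError("need >= 1 polymorphic marker for a GRM")
    k = xc @ xc.T / m
    k = (k + k.T) / 2
    return Kinship(k, flavor, m)


def grm_pcs(kinship: Kinship, k: int = 2) -> np.ndarray:
    """Top-k principal components of the GRM: eigenvectors scaled by the
    square root of their eigenvalues, sign fixed so the largest-magnitude
    loading in each component is positive."""
    evals, evecs = np.linalg.eigh(kinship.matrix)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > 1e-10 * max(evals[0], 1.0)).sum())
    if k > rank:
        raise ValueError(f"requested {k} PCs but kinship rank is {rank}")
    pcs = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    for j in range(k):
        i_max = np.argmax(np.abs(pcs[:, j]))
        if pcs[i_max, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------

def compute_ibc(geno: GenotypeMatrix, group: str = "") -> IBCResult:
    """Method-of-moments inbreeding coefficients within one group.

    Allele frequencies are estimated within the supplied genotype matrix, so
    pass the already-subset (and per-group QC'd / pruned) cohort.
    """
    n, m = geno.n_samples, geno.n_variants
    if n < 2:
        raise ValueError("IBC needs a group of >= 2 (allele-count correction undefined)")
    d = geno.dosage
    obs = d != MISSING

    allele_n = 2.0 * obs.sum(axis=0)          # non-missing allele count per marker
    if (allele_n < 4).any():
        warnings.warn("markers with <2 genotyped individuals in IBC group", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(obs, d, 0).sum(axis=0) / allele_n
        # per-marker expected homozygosity with n/(n-1) correction
        e_marker = 1.0 - 2.0 * f * (1.0 - f) * (allele_n / (allele_n - 1.0))

    o_hom = ((d == 0) | (d == 2)).sum(axis=1).astype(float)
    e_hom = (obs * e_marker).sum(axis=1)
    L = obs.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_hat = (o_hom - e_hom) / (L - e_hom)
    return IBCResult(
        sample_ids=list(geno.sample_ids),
        f_hat=f_hat,
        o_hom=o_hom,
        e_hom=e_hom,
        n_nonmissing=L,
        group=group,
        n_markers_used=m,
    )


def _two_tailed_f_test(var_a: float, var_b: float, n_a: int, n_b: int) -> tuple[float, float]:
    """Two-tailed F-test of equal variances: ratio of larger to smaller
    sample variance, doubled upper tail."""
    if var_a >= var_b:
        f, dfn, dfd = var_a / var_b, n_a - 1, n_b - 1
    else:
        f, dfn, dfd = var_b / var_a, n_b - 1, n_a - 1
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return f, p


def compare_ibc_summary(
    mean_a: float, var_a: float, n_a: int,
    mean_b: float, var_b: float, n_b: int,
    breed: str = "", alpha: float = 0.05,
) -> BreedComparisonResult:
    """Two-population mean comparison from summary statistics.

    F-test gates the t-test flavor: unequal variances (p < alpha) use Welch's
    t with Welch-Satterthwaite degrees of freedom (not rounded); otherwise the
    pooled-variance t with n_a + n_b - 2 degrees of freedom.  Two-tailed.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 individuals")
    if var_a == 0 and var_b == 0:
        raise ValueError("both groups have zero variance")
    f_stat, f_p = _two_tailed_f_test(var_a, var_b, n_a, n_b)
    unequal = f_p < alpha
    t, p = stats.ttest_ind_from_stats(
        mean_a, np.sqrt(var_a), n_a, mean_b, np.sqrt(var_b), n_b,
        equal_var=not unequal,
    )
    if unequal:
        sa, sb = var_a / n_a, var_b / n_b
        df = (sa + sb) ** 2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return BreedComparisonResult(
        breed=breed,
        mean_a=mean_a, var_a=var_a, n_a=n_a,
        mean_b=mean_b, var_b=var_b, n_b=n_b,
        f_statistic=float(f_stat), f_test_p=float(f_p), variances_unequal=bool(unequal),
        t_statistic=float(t), degrees_of_freedom=float(df), t_test_p=float(p),
    )


def compare_ibc_groups(
    a: IBCResult, b: IBCResult, breed: str = "", alpha: float = 0.05
) -> BreedComparisonResult:
    """F-test-gated t-test comparison of two IBC distributions."""
    fa, fb = np.asarray(a.f_hat, float), np.asarray(b.f_hat, float)
    if np.var(fa, ddof=1) == 0 and np.var(fb, ddof=1) == 0:
        if np.mean(fa) == np.mean(fb):
            # degenerate identical groups: no difference by definition
            return BreedComparisonResult(
                breed=breed,
                mean_a=float(np.mean(fa)), var_a=0.0, n_a=fa.size,
                mean_b=float(np.mean(fb)), var_b=0.0, n_b=fb.size,
                f_statistic=np.nan, f_test_p=1.0, variances_unequal=False,
                t_statistic=0.0, degrees_of_freedom=fa.size + fb.size - 2, t_test_p=1.0,
            )
        raise ValueError("both groups have zero variance")
    return compare_ibc_summary(
        float(np.mean(fa)), float(np.var(fa, ddof=1)), fa.size,
        float(np.mean(fb)), float(np.var(fb, ddof=1)), fb.size,
        breed=breed, alpha=alpha,
    )
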