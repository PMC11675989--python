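"""Kinship-corrected univariate linear mixed-model association.

Per marker: y = W a + x b + u + e, with u ~ N(0, K sg2), e ~ N(0, I se2).
After one eigendecomposition of the centered GRM, the variance ratio
delta = se2/sg2 makes the covariance diagonal in the rotated space; the
restricted likelihood concentrated in delta is maximized by a 1-D search
(log-spaced grid in [1e-5, 1e5] refined by Brent), and b, se(b) follow by
generalized least squares.  The Wald statistic (b/se)^2 is referred to the
1-df chi-square distribution.

Two profiling modes: ``exact`` re-optimizes delta for every marker (the
default); ``fast`` reuses the null-model (covariates-only) ratio for all
markers, EMMAX-style.

The genomic inflation factor is the medians ratio
lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import MISSING, GenotypeMatrix
from .relatedness import Kinship

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # ~0.4549


@dataclass
class ThresholdSet:
    n_variants: int
    bonferroni_p: float
    suggestive_p: float
    reporting_p: float = 4.0e-5

    @property
    def bonferroni_neglog10(self) -> float:
        return -np.log10(self.bonferroni_p)

    @property
    def suggestive_neglog10(self) -> float:
        return -np.log10(self.suggestive_p)


def significance_thresholds(
    n_variants: int, alpha: float = 0.05, reporting_p: float = 4.0e-5
) -> ThresholdSet:
    """Bonferroni alpha/m and suggestive 1/m genome-wide p-value cut-offs."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return ThresholdSet(
        n_variants=n_variants,
        bonferroni_p=alpha / n_variants,
        suggestive_p=1.0 / n_variants,
        reporting_p=reporting_p,
    )


def genomic_inflation(pvals: np.ndarray) -> float:
    """Median-based genomic control lambda from a vector of Wald p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    chi2 = stats.chi2.ppf(1.0 - p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


class _ConcentratedREML:
    """Concentrated restricted log-likelihood in delta for a fixed design."""

    def __init__(self, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
        self.d, self.yr, self.Xr = d, yr, Xr
        self.n, self.p = Xr.shape

    def neg_loglik(self, log10_delta: float) -> float:
        delta = 10.0**log10_delta
        v = self.d + delta
        vi = 1.0 / v
        Xv = self.Xr * vi[:, None]
        XtX = self.Xr.T @ Xv
        try:
            beta = np.linalg.solve(XtX, Xv.T @ self.yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = self.yr - self.Xr @ beta
        rss = float(r * vi @ r)
        if rss <= 0:
            return np.inf
        _, ld_x = np.linalg.slogdet(XtX)
        df = self.n - self.p
        return 0.5 * (df * np.log(rss) + np.log(v).sum() + ld_x)

    def optimize(self, grid: np.ndarray) -> float:
        vals = np.array([self.neg_loglik(g) for g in grid])
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        if lo == hi:
            return 10.0 ** grid[i]
        res = optimize.minimize_scalar(
            self.neg_loglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4},
        )
        return 10.0 ** float(res.x)

    def gls(self, delta: float):
        """(beta, se_beta) for the last design column, plus sigma_g2 hat."""
        v = self.d + delta
        vi = 1.0 / v
        Xv = self.Xr * vi[:, None]
        XtX = self.Xr.T @ Xv
        C = np.linalg.inv(XtX)
        beta = C @ (Xv.T @ self.yr)
        r = self.yr - self.Xr @ beta
        sigma2 = float(r * vi @ r) / (self.n - self.p)
        se = np.sqrt(sigma2 * np.diag(C))
        return beta, se, sigma2


_GRID = np.linspace(-5.0, 5.0, 21)


def lmm_assoc(
    y: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    K: Kinship | np.ndarray,
    variants: pd.DataFrame | None = None,
    W: np.ndarray | None = None,
    mode: str = "exact",
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald tests; returns records sorted by (chrom, pos).

    ``variants`` (id/chrom/pos/alleles/maf) is merged into the output when
    given; otherwise chromosome/position are omitted and input order is kept.
    Monomorphic markers yield NaN statistics and are logged.
    """
    if mode not in ("exact", "fast"):
        raise ValueError(f"unknown mode {mode!r}")
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if geno.n_samples != n:
        raise ValueError("phenotype/genotype sample counts differ")
    if geno.missing_mask().any():
        raise ValueError("fill missing genotypes before association")
    Km = K.matrix if isinstance(K, Kinship) else np.asarray(K, float)
    if W is None:
        W = np.ones((n, 1))

    d, U = np.linalg.eigh((Km + Km.T) / 2)
    d = np.maximum(d, 0.0)
    yr = U.T @ yv
    Wr = U.T @ W
    G = geno.dosage.astype(float)
    Gr = U.T @ G

    null_delta = _ConcentratedREML(d, yr, Wr).optimize(_GRID)

    maf = geno.maf()
    m = geno.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    deltas = np.full(m, np.nan)
    n_mono = 0
    for j in range(m):
        if G[:, j].std() == 0:
            n_mono += 1
            continue
        Xr = np.column_stack([Wr, Gr[:, j]])
        eng = _ConcentratedREML(d, yr, Xr)
        delta = eng.optimize(_GRID) if mode == "exact" else null_delta
        b, s, _ = eng.gls(delta)
        beta[j], se[j] = b[-1], s[-1]
        deltas[j] = delta
    if n_mono:
        logger.info("lmm_assoc: %d monomorphic markers skipped", n_mono)

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = (beta / se) ** 2
        pvals = stats.chi2.sf(wald, 1)

    rec = pd.DataFrame(
        {
            "id": geno.variant_ids,
            "maf": maf,
            "beta": beta,
            "se_beta": se,
            "wald": wald,
            "wald_p": pvals,
            "delta": deltas,  # fitted variance ratio se2/sg2 per marker
        }
    )
    if variants is not None:
        meta_cols = [c for c in ("id", "chrom", "pos", "allele_minor", "allele_major") if c in variants]
        rec = rec.merge(variants[meta_cols], on="id", how="left")
        rec["_chrom_num"] = pd.to_numeric(rec["chrom"], errors="coerce")
        rec = rec.sort_values(["_chrom_num", "pos"]).drop(columns="_chrom_num").reset_index(drop=True)
    return rec


def manhattan_qq_data(
    records: pd.DataFrame, thresholds: ThresholdSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Plot-ready Manhattan and QQ tables from association records.

    Manhattan: cumulative genome coordinate per variant plus -log10 p.
    QQ: expected quantiles -log10((i - 0.5)/m) vs observed, both ascending.
    """
    if len(records) == 0:
        raise ValueError("no association records")
    rec = records.dropna(subset=["wald_p"]).copy()
    if "chrom" in rec:
        rec["_chrom_num"] = pd.to_numeric(rec["chrom"], errors="coerce")
        rec = rec.sort_values(["_chrom_num", "pos"]).reset_index(drop=True)
        offset = 0
        cum = np.empty(len(rec), dtype=np.int64)
        for _, idx in rec.groupby("_chrom_num", sort=True).groups.items():
            idx = np.asarray(idx)
            cum[idx] = rec.loc[idx, "pos"].to_numpy() + offset
            offset = cum[idx].max()
        rec["cum_pos"] = cum
        rec = rec.drop(columns="_chrom_num")
    else:
        rec["cum_pos"] = np.arange(1, len(rec) + 1)
    rec["neglog10_p"] = -np.log10(rec["wald_p"])

    # i-th smallest p pairs with expected quantile (i - 0.5)/m
    p_sorted = np.sort(rec["wald_p"].to_numpy())
    mq = len(p_sorted)
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10((np.arange(1, mq + 1) - 0.5) / mq),
            "observed_neglog10": -np.log10(p_sorted),
        }
    )

    lines = {}
    if thresholds is not None:
        lines = {
            "bonferroni_neglog10": thresholds.bonferroni_neglog10,
            "suggestive_neglog10": thresholds.suggestive_neglog10,
            "reporting_neglog10": -np.log10(thresholds.reporting_p),
        }
    lines["lambda_gc"] = genomic_inflation(rec["wald_p"].to_numpy())
    return rec, qq, lines
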