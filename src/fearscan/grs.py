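"""Genetic risk scores and extremity-group comparisons.

Dogs are binned by their adjusted phenotype: less fearful (> mean + 1 SD,
since higher component scores mean more confident responses), more fearful
(< mean - 1 SD), intermediate otherwise.

Two scores over a chosen SNP panel with estimated effects b_j:

* cGRS (count): the minor allele B is the risk allele; BB counts 2, AB 1,
  AA 0.  For a marker with negative effect size the coding is reversed
  (2 - dosage) so the protective direction counts zero; counts stay in
  {0, 1, 2} and the total in [0, 2M].
* wGRS (weighted): sum of b_j x dosage_j, signed -- a negative-effect risk
  allele subtracts from the score.

Group differences use a one-way linear-model F-test with Tukey-Kramer
adjusted pairwise comparisons (studentized range, valid for unequal group
sizes).  When the effects are estimated in-sample, the separation between
extreme phenotype bins is partly mechanical; the comparison is descriptive,
not out-of-sample validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genio import GenotypeMatrix

BIN_LABELS = ("more_fearful", "intermediate", "less_fearful")


@dataclass
class FearBin:
    labels: pd.Series  # per-dog label, indexed by sample_id
    sd_mult: float
    mean: float
    sd: float

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class GrsComparison:
    anova_f: float
    anova_p: float
    groups: pd.DataFrame             # per-group mean/sd/median/min/max/n
    pairwise: pd.DataFrame           # Tukey-Kramer adjusted comparisons
    density: pd.DataFrame | None = None
    in_sample: bool = True


def bin_by_sd(pheno: pd.Series, sd_mult: float = 1.0) -> FearBin:
    """Three-way extremity binning at mean +/- sd_mult * SD."""
    y = np.asarray(pheno, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 dogs to bin")
    mu, sd = float(np.mean(y)), float(np.std(y))
    if sd == 0:
        raise ValueError("phenotype has zero standard deviation")
    # boundary-inclusive so exactly-at-threshold dogs land in the extreme bins
    lab = np.where(
        y >= mu + sd_mult * sd, "less_fearful",
        np.where(y <= mu - sd_mult * sd, "more_fearful", "intermediate"),
    )
    index = pheno.index if isinstance(pheno, pd.Series) else pd.RangeIndex(y.size)
    return FearBin(labels=pd.Series(lab, index=index), sd_mult=sd_mult, mean=mu, sd=sd)


def _check_effects(geno: GenotypeMatrix, effects: pd.DataFrame, snp_set: list[str]) -> pd.Series:
    if geno.missing_mask().any():
        raise ValueError("risk scores need complete genotypes; fill missing first")
    eff = effects.set_index("id")["beta"] if "id" in effects else effects["beta"]
    missing = [s for s in snp_set if s not in eff.index or not np.isfinite(eff[s])]
    if missing:
        raise ValueError(f"no effect estimate for SNP(s): {missing}")
    absent = [s for s in snp_set if s not in geno.variant_ids]
    if absent:
        raise ValueError(f"SNP(s) not in genotype matrix: {absent}")
    return eff.loc[snp_set]


def compute_cgrs(
    geno: GenotypeMatrix, effects: pd.DataFrame, snp_set: list[str]
) -> pd.Series:
    """Count-based risk score: minor-allele dosage, reverse-coded (2 - dosage)
    at markers with negative effect sizes."""
    eff = _check_effects(geno, effects, snp_set)
    col = {v: i for i, v in enumerate(geno.variant_ids)}
    idx = [col[s] for s in snp_set]
    d = geno.dosage[:, idx].astype(int)
    counts = np.where(eff.values[None, :] < 0, 2 - d, d)
    return pd.Series(counts.sum(axis=1), index=geno.sample_ids, name="cgrs")


def compute_wgrs(
    geno: GenotypeMatrix, effects: pd.DataFrame, snp_set: list[str]
) -> pd.Series:
    """Effect-weighted risk score: sum of beta_j x dosage_j (signed)."""
    eff = _check_effects(geno, effects, snp_set)
    col = {v: i for i, v in enumerate(geno.variant_ids)}
    idx = [col[s] for s in snp_set]
    d = geno.dosage[:, idx].astype(float)
    return pd.Series(d @ eff.values, index=geno.sample_ids, name="wgrs")


def compare_grs_groups(
    scores: pd.Series,
    bins: FearBin,
    mode: str = "two_group",
    alpha: float = 0.05,
    density_grid: int = 200,
) -> GrsComparison:
    """One-way F-test across fear bins with Tukey-Kramer pairwise comparisons.

    mode "two_group" compares the extreme bins only; "three_group" includes
    the intermediate bin.  Groups with < 2 members are dropped with a warning.
    Kernel-density curves per group are emitted for density-plot rendering.
    """
    if mode not in ("two_group", "three_group"):
        raise ValueError(f"unknown mode {mode!r}")
    wanted = ("more_fearful", "less_fearful") if mode == "two_group" else BIN_LABELS
    lab = bins.labels.reindex(scores.index)
    df = pd.DataFrame({"score": scores.values, "group": lab.values}, index=scores.index)
    df = df[df["group"].isin(wanted)].dropna()

    sizes = df["group"].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping group(s) with < 2 members: {small}", stacklevel=2)
        df = df[~df["group"].isin(small)]
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 non-empty groups to compare")

    groups = [g["score"].to_numpy() for _, g in df.groupby("group")]
    f_stat, f_p = stats.f_oneway(*groups)
    if not np.isfinite(f_p):  # degenerate: no between-group variance
        f_stat, f_p = 0.0, 1.0

    summary = (
        df.groupby("group")["score"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1),
             median="median", min="min", max="max")
        .reset_index()
    )

    if np.ptp(df["score"].to_numpy()) == 0:
        # all scores identical: no differences by definition
        pairs = []
        labs = sorted(df["group"].unique())
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                pairs.append({"group1": labs[i], "group2": labs[j],
                              "meandiff": 0.0, "p_adj": 1.0, "reject": False})
        pairwise = pd.DataFrame(pairs)
    else:
        tk = pairwise_tukeyhsd(df["score"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=[c.replace("-", "_") for c in tk.summary().data[0]]
        ).rename(columns={"p_adj": "p_adj"})

    dens_rows = []
    lo, hi = df["score"].min(), df["score"].max()
    span = hi - lo if hi > lo else 1.0
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, density_grid)
    for name, g in df.groupby("group"):
        vals = g["score"].to_numpy(dtype=float)
        if vals.size >= 3 and vals.std() > 0:
            kde = stats.gaussian_kde(vals)
            dens_rows.append(pd.DataFrame({"group": name, "score": grid, "density": kde(grid)}))
    density = pd.concat(dens_rows, ignore_index=True) if dens_rows else None

    return GrsComparison(
        anova_f=float(f_stat), anova_p=float(f_p),
        groups=summary, pairwise=pairwise, density=density,
    )
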