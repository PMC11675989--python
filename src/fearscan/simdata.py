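"""Synthetic multi-breed dog cohorts with known ground truth.

The generator emulates the structure of a commercial-breeding cohort: several
breeds differentiated by drift (Balding-Nichols allele frequencies), excess
within-breed homozygosity (inbreeding), block-wise linkage disequilibrium,
sporadic genotype missingness, and behavioral phenotypes built from facility /
sex / size / age fixed effects plus a polygenic component with a target
heritability and a small set of larger-effect causal SNPs.  Item-level 0/1/2
assessment scores are produced by thresholding the latent component scores, so
the PCA stage has a planted four-component structure to recover.

Breed allele frequencies follow the Balding-Nichols model: given ancestral
frequency p and differentiation Fst, the breed frequency is
Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst), so E[p_breed] = p and
Var[p_breed] = Fst p(1-p).

Inbreeding and LD are generated jointly through haplotype uniforms: each
haplotype carries one latent Uniform(0,1) draw per LD block, refreshed per SNP
with probability 1-ld_copy_prob (comonotone-copula LD, exact per-SNP marginal
frequencies), and the second haplotype of an individual copies the first over
a block with probability F (identity by descent), giving
P(hom minor) = p^2 + F p(1-p) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, annotate_variant_stats

_NUCS = np.array(list("ACGT"))

SIZE_CLASSES = ("XL", "L", "M", "S", "XS")

#: behavioral assessment items and the latent component each one expresses.
#: approach test: three RYG-scored steps, treat taken, touch allowed; then the
#: ten-step reactivity test.  Scale: 0/1/2 except the binary treat/touch items.
ITEM_COMPONENT = {
    "approach": "SF",
    "open": "SF",
    "reach": "SF",
    "treat": "FM",
    "touch": "FM",
    "mat": "NSF",
    "leash": "NSF",
    "cone": "NSF",
    "statue": "NSF",
    "ball": "FM",
    "squeaky": "FM",
    "problem": "FM",
    "umbrella_open": "SR",
    "umbrella_close": "SR",
    "come": "SF",
    "sit": "SF",
    "leash_loop": "NSF",
}
BINARY_ITEMS = ("treat", "touch")
COMPONENTS = ("SF", "FM", "NSF", "SR")
#: components carried into the genetic analyses (food motivation is dropped)
GENETIC_COMPONENTS = ("SF", "NSF", "SR")


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    n_breeds: int = 6
    n_per_breed: int = 100
    n_snps: int = 5000
    n_chromosomes: int = 38
    fst_per_breed: float = 0.1
    inbreeding_per_breed: float = 0.05
    missing_rate: float = 0.01
    n_causal: int = 10
    h2_target: float = 0.3
    poly_frac: float = 0.3
    ld_block_len: int = 5
    ld_copy_prob: float = 0.7
    n_facilities: int = 12
    female_fraction: float = 0.83
    facility_effect_sd: float = 0.5
    sex_effect: float = 0.2
    size_effect_sd: float = 0.3
    age_slope: float = 0.05
    item_noise_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        def _check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise SimConfigError(f"{name}: {msg} (got {getattr(self, name)!r})")

        _check(self.n_breeds >= 1, "n_breeds", "must be >= 1")
        _check(self.n_per_breed >= 1, "n_per_breed", "must be >= 1")
        _check(self.n_snps >= 1, "n_snps", "must be >= 1")
        _check(1 <= self.n_chromosomes <= 38, "n_chromosomes", "must be in 1..38")
        _check(0 <= self.fst_per_breed < 1, "fst_per_breed", "must be in [0,1)")
        _check(
            -0.3 <= self.inbreeding_per_breed <= 0.5,
            "inbreeding_per_breed", "must be in [-0.3, 0.5]",
        )
        _check(0 <= self.missing_rate < 1, "missing_rate", "must be in [0,1)")
        _check(0 <= self.n_causal <= self.n_snps, "n_causal", "must be in 0..n_snps")
        _check(0 <= self.h2_target <= 1, "h2_target", "must be in [0,1]")
        _check(0 <= self.poly_frac <= 1, "poly_frac", "must be in [0,1]")
        _check(self.ld_block_len >= 1, "ld_block_len", "must be >= 1")
        _check(0 <= self.ld_copy_prob <= 1, "ld_copy_prob", "must be in [0,1]")
        if self.h2_target == 1 and self.n_causal == 0:
            raise SimConfigError("h2_target: cannot be 1 with n_causal=0 (no genetic variance)")


@dataclass
class GroundTruth:
    causal_ids: dict = field(default_factory=dict)       # component -> list[str]
    causal_effects: dict = field(default_factory=dict)   # component -> ndarray
    realized_h2: dict = field(default_factory=dict)      # component -> float
    latent: dict = field(default_factory=dict)           # component -> ndarray (n,)
    genetic_value: dict = field(default_factory=dict)    # component -> ndarray (n,)
    true_F_per_individual: np.ndarray | None = None
    fixed_effect_values: pd.DataFrame | None = None


# ---------------------------------------------------------------------------

def _simulate_haplotype_uniforms(rng, n_hap: int, n_snps: int, block_id: np.ndarray,
                                 copy_prob: float) -> np.ndarray:
    """Uniforms with block-comonotone structure: each haplotype shares one
    block-level uniform, refreshed per SNP with probability 1-copy_prob."""
    n_blocks = block_id.max() + 1
    block_u = rng.random((n_hap, n_blocks))
    u = block_u[:, block_id]
    refresh = rng.random((n_hap, n_snps)) >= copy_prob
    u = np.where(refresh, rng.random((n_hap, n_snps)), u)
    return u


def simulate_genotypes(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate genotypes + variant/sample tables for a multi-breed cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_breeds * config.n_per_breed
    m = config.n_snps

    # variant manifest: SNPs spread evenly over autosomes, random spacing
    chrom = np.repeat(
        np.arange(1, config.n_chromosomes + 1),
        int(np.ceil(m / config.n_chromosomes)),
    )[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, config.n_chromosomes + 1):
        sel = chrom == c
        pos[sel] = np.cumsum(rng.integers(5_000, 50_000, size=sel.sum()))
    alleles = np.array([rng.permutation(_NUCS)[:2] for _ in range(m)])
    variant_ids = [f"snp{c}_{p}" for c, p in zip(chrom, pos)]

    p_anc = rng.uniform(0.05, 0.5, size=m)
    fst = config.fst_per_breed
    F = config.inbreeding_per_breed

    block_id = np.empty(m, dtype=np.int64)
    nb = 0
    for c in range(1, config.n_chromosomes + 1):
        sel = np.flatnonzero(chrom == c)
        block_id[sel] = nb + np.arange(sel.size) // config.ld_block_len
        nb = block_id[sel].max() + 1 if sel.size else nb
    n_blocks = int(block_id.max()) + 1

    dosage = np.empty((n, m), dtype=np.int8)
    true_F = np.full(n, F, dtype=float)
    for b in range(config.n_breeds):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            bb = (1 - p_anc) * (1 - fst) / fst
            p_b = np.clip(rng.beta(a, bb), 1e-4, 1 - 1e-4)
        else:
            p_b = p_anc
        nb_ind = config.n_per_breed
        u1 = _simulate_haplotype_uniforms(rng, nb_ind, m, block_id, config.ld_copy_prob)
        u2 = _simulate_haplotype_uniforms(rng, nb_ind, m, block_id, config.ld_copy_prob)
        if F != 0:
            # per-individual, per-block IBD: hap2 copies hap1 over the block
            ibd = rng.random((nb_ind, n_blocks)) < abs(F)
            ibd_snp = ibd[:, block_id]
            if F > 0:
                u2 = np.where(ibd_snp, u1, u2)
            else:
                # heterozygote excess: force the two alleles apart
                u2 = np.where(ibd_snp, 1.0 - u1, u2)
        h1 = (u1 < p_b).astype(np.int8)
        h2 = (u2 < p_b).astype(np.int8)
        rows = slice(b * nb_ind, (b + 1) * nb_ind)
        dosage[rows] = h1 + h2

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = MISSING

    # orient to minor allele
    with np.errstate(invalid="ignore"):
        obs = np.ma.masked_equal(dosage, MISSING)
        freq = (obs.sum(axis=0) / (2.0 * obs.count(axis=0))).filled(0.0)
    flip = freq > 0.5
    flip_cols = np.flatnonzero(flip)
    for j in flip_cols:
        col = dosage[:, j]
        nonmiss = col != MISSING
        col[nonmiss] = 2 - col[nonmiss]
    allele_minor = np.where(flip, alleles[:, 0], alleles[:, 1])
    allele_major = np.where(flip, alleles[:, 1], alleles[:, 0])

    sample_ids = [f"dog{i:04d}" for i in range(n)]
    geno = GenotypeMatrix(dosage, sample_ids, variant_ids)

    variants = pd.DataFrame(
        {
            "id": variant_ids,
            "chrom": chrom.astype(str),
            "pos": pos,
            "allele_minor": allele_minor,
            "allele_major": allele_major,
        }
    )
    variants = annotate_variant_stats(geno, variants)

    breeds = np.repeat([f"breed{b}" for b in range(config.n_breeds)], config.n_per_breed)
    # breeds concentrate in facilities but facilities host several breeds
    facility = rng.integers(0, config.n_facilities, size=n)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age = rng.uniform(1.0, 10.0, size=n)
    breed_size = {f"breed{b}": SIZE_CLASSES[b % len(SIZE_CLASSES)] for b in range(config.n_breeds)}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "breed": breeds,
            "facility": [f"fac{f:02d}" for f in facility],
            "sex": sex,
            "age": age,
            "size_class": [breed_size[b] for b in breeds],
        }
    )

    truth = GroundTruth(true_F_per_individual=true_F)
    return geno, variants, samples, truth


# ---------------------------------------------------------------------------

def simulate_phenotypes(
    geno: GenotypeMatrix,
    samples: pd.DataFrame,
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Latent component scores + item-level 0/1/2 behavior table.

    Per genetic component (SF/NSF/SR): latent = fixed effects + genetic + noise,
    where genetic = causal dosage effects plus a dense polygenic background,
    rescaled so var(genetic)/(var(genetic)+var(noise)) equals h2_target.
    The FM (food-motivation) component is pure nuisance: fixed effects + noise.
    Heritability is defined net of fixed effects, matching a pipeline that
    adjusts phenotypes for fixed effects before REML.
    """
    config.validate()
    if geno.n_samples != len(samples):
        raise ValueError("genotype/sample dimensions disagree")
    rng = np.random.default_rng(config.seed + 1_000_003)
    n, m = geno.n_samples, geno.n_variants
    truth = truth or GroundTruth()

    d = geno.dosage.astype(float)
    d[geno.dosage == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    d_c = d - d.mean(axis=0)

    # fixed-effect values shared across components
    fac_levels = sorted(samples["facility"].unique())
    fac_eff = dict(zip(fac_levels, rng.normal(0, config.facility_effect_sd, len(fac_levels))))
    size_eff = dict(zip(SIZE_CLASSES, rng.normal(0, config.size_effect_sd, len(SIZE_CLASSES))))
    fixed = (
        samples["facility"].map(fac_eff).values
        + np.where(samples["sex"].values == "F", 0.0, config.sex_effect)
        + samples["size_class"].map(size_eff).values
        + config.age_slope * (samples["age"].values - samples["age"].values.mean())
    )
    truth.fixed_effect_values = pd.DataFrame(
        {"sample_id": samples["sample_id"], "fixed_total": fixed}
    )

    latents = {}
    for comp in COMPONENTS:
        if comp == "FM" or config.h2_target == 0 or config.n_causal == 0:
            g = np.zeros(n)
        else:
            causal_idx = rng.choice(m, size=config.n_causal, replace=False)
            effects = rng.normal(0, 1, size=config.n_causal)
            g_causal = d_c[:, causal_idx] @ effects
            # dense polygenic background, a fixed fraction of genetic variance
            g_poly = d_c @ rng.normal(0, 1 / np.sqrt(m), size=m)
            pf = config.poly_frac

            def _std(v: np.ndarray) -> np.ndarray:
                s = np.std(v)
                return v / s if s > 0 else v

            g = np.sqrt(1 - pf) * _std(g_causal) + np.sqrt(pf) * _std(g_poly)
            truth.causal_ids[comp] = [geno.variant_ids[i] for i in causal_idx]
            truth.causal_effects[comp] = effects
        e = rng.normal(0, 1, size=n)
        h2 = config.h2_target if comp != "FM" else 0.0
        sg = np.std(g)
        if h2 > 0 and sg > 0:
            g = g / sg * np.sqrt(h2)
            e = e * np.sqrt(1 - h2)
        else:
            g = np.zeros(n)
        latent = fixed + g + e
        latents[comp] = latent
        var_tot = np.var(g) + np.var(e)
        truth.realized_h2[comp] = float(np.var(g) / var_tot) if var_tot > 0 else 0.0
        truth.latent[comp] = latent
        truth.genetic_value[comp] = g

    # item scores: each item expresses its component's latent plus item noise,
    # discretized at tertiles (binary items at the median)
    behavior = {"sample_id": samples["sample_id"].values}
    for item, comp in ITEM_COMPONENT.items():
        signal = latents[comp] + rng.normal(0, config.item_noise_sd, size=n)
        if item in BINARY_ITEMS:
            behavior[item] = (signal > np.quantile(signal, 0.5)).astype(int)
        else:
            lo, hi = np.quantile(signal, [1 / 3, 2 / 3])
            behavior[item] = np.digitize(signal, [lo, hi]).astype(int)
    behavior = pd.DataFrame(behavior)
    return behavior, truth


# ---------------------------------------------------------------------------

def make_variant_manifest(
    n_total: int,
    n_nonautosomal: int,
    n_mono_or_indel: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant manifest with exact category counts, randomly interleaved.

    Categories: non-autosomal/unmapped (chrom X/Y/MT/un), autosomal
    monomorphic-or-indel, and autosomal polymorphic SNPs (the remainder).
    """
    if min(n_total, n_nonautosomal, n_mono_or_indel) < 0:
        raise ValueError("counts must be non-negative")
    if n_nonautosomal + n_mono_or_indel > n_total:
        raise ValueError("category counts exceed n_total")
    rng = np.random.default_rng(seed)

    n_good = n_total - n_nonautosomal - n_mono_or_indel
    cat = np.array(
        ["nonautosomal"] * n_nonautosomal
        + ["mono_or_indel"] * n_mono_or_indel
        + ["autosomal_poly"] * n_good
    )
    rng.shuffle(cat)

    chrom = np.empty(n_total, dtype=object)
    auto = cat != "nonautosomal"
    chrom[auto] = rng.integers(1, 39, size=auto.sum()).astype(str)
    nonauto = ~auto
    chrom[nonauto] = rng.choice(["X", "Y", "MT", "un"], size=nonauto.sum())

    mono = cat == "mono_or_indel"
    is_indel = mono & (rng.random(n_total) < 0.5)
    return pd.DataFrame(
        {
            "id": [f"var{i:07d}" for i in range(n_total)],
            "chrom": chrom.astype(str),
            "pos": rng.integers(1, 120_000_000, size=n_total),
            "polymorphic": ~(mono & ~is_indel),
            "indel": is_indel,
            "category": cat,
        }
    )
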