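"""Published summary statistics bundled as reproduction inputs.

``BREED_IBC_SUMMARIES`` holds, per breed, the printed mean / variance / n of
SNP-based inbreeding coefficients for two populations of the same breed: a
breed-background reference population (a) and a commercial-breeding cohort
(b).  Feeding these summaries through
:func:`fearscan.relatedness.compare_ibc_summary` reproduces the published
two-tailed t-test p-values, including which rows required Welch's test.

``COHORT`` holds the headline cohort counts (615 genotyped dogs, 509 female)
and the array accounting used by the marker QC stage: 635,984 mapped
variants, of which 15,962 were non-autosomal or unmapped and 126,983 were
monomorphic or indels, leaving 493,039 autosomal polymorphic SNPs.
"""

from __future__ import annotations

import pandas as pd

# columns: breed, mean/var/n for the breed-background (a) and
# commercial-breeding (b) populations, the published two-tailed p, and
# whether the published table flagged the variances as unequal (F-test).
BREED_IBC_SUMMARIES = pd.DataFrame(
    [
        ("American Cocker Spaniel", 0.072092, 0.008133, 16, -0.03392, 0.004166, 34, 1.84e-05, False),
        ("Australian Shepherd", 0.05939, 0.009972, 277, 0.005118, 0.004865, 14, 0.045649, False),
        ("Bichon Frise", 0.045651, 0.006584, 101, -0.02843, 0.008112, 36, 1.1e-05, False),
        ("Bullmastiff", 0.030963, 0.007931, 43, -0.00998, 0.002771, 15, 0.039, True),
        ("Cavalier King Charles Spaniel", 0.045081, 0.007391, 254, 0.019761, 0.00693, 44, 0.071031, False),
        ("French Bulldog", 0.020821, 0.002795, 65, -0.00506, 0.007024, 22, 0.185136, True),
        ("Golden Retriever", 0.055963, 0.010229, 471, 0.003179, 0.006466, 22, 0.016242, False),
        ("Great Dane", 0.049074, 0.013713, 97, -0.02324, 0.001514, 14, 2.65e-05, True),
        ("Labrador Retriever", 0.041517, 0.006761, 1424, 0.085459, 0.007521, 25, 0.008221, False),
        ("Miniature Schnauzer", 0.063033, 0.024241, 364, -0.08533, 0.005618, 20, 3.63e-09, True),
        ("Pomeranian", 0.039109, 0.007194, 51, 0.007014, 0.006416, 15, 0.196967, False),
        ("Shetland Sheepdog", 0.105334, 0.017431, 60, -0.19236, 0.016604, 16, 1.03e-11, False),
        ("Shih Tzu", 0.051114, 0.012371, 93, -0.014, 0.004515, 49, 2.75e-05, True),
        ("Siberian Husky", 0.049934, 0.007221, 131, 0.010516, 0.004038, 24, 0.032169, False),
        ("Toy Poodle", 0.041009, 0.0091, 30, -0.02076, 0.001406, 22, 0.002523, True),
        ("Yorkshire Terrier", 0.052383, 0.014324, 371, -0.00091, 0.003964, 17, 0.003828, True),
    ],
    columns=[
        "breed",
        "mean_a", "var_a", "n_a",
        "mean_b", "var_b", "n_b",
        "published_p", "published_unequal_var",
    ],
)

COHORT = {
    "n_dogs": 615,
    "n_female": 509,
    "n_male": 106,
    "n_gwas_phenotyped": 575,
    "variants_mapped": 635_984,
    "variants_nonautosomal_or_unmapped": 15_962,
    "variants_mono_or_indel": 126_983,
    "variants_autosomal_polymorphic": 493_039,
    "markers_after_qc": 293_519,
}
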