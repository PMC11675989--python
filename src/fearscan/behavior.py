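"""Behavioral component phenotypes: PCA with varimax rotation, KMO sampling
adequacy, regression-method component scores, and fixed-effect adjustment.

The assessment instrument is a stranger-approach test (three RYG-scored steps
plus treat/touch) followed by a ten-step reactivity test, all on 0/1/2 scales.
PCA on the item correlation matrix, followed by Kaiser-normalized varimax
rotation of the retained loadings, yields four interpretable components:
social fear (SF: approach/open/reach), food motivation (FM: treat items),
non-social fear (NSF: mat/leash/cone/statue), and startle response (SR:
umbrella).  FM is computed but excluded from the genetic analyses.

Component scores use the least-squares regression method, S = Z R^-1 L, with
Z the standardized items, R the item correlation matrix, and L the rotated
loadings.  Scores are signed so that higher = less fearful (the confident /
"green"-scored direction loads positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simdata import ITEM_COMPONENT

COMPONENT_LABELS = ("SF", "FM", "NSF", "SR")


@dataclass
class ComponentResult:
    items: list[str]
    loadings: np.ndarray            # items x components, unrotated
    rotated_loadings: np.ndarray    # items x components
    rotation: np.ndarray            # orthonormal rotation matrix
    explained_variance_fraction: np.ndarray
    cumulative_explained: float
    kmo: float
    labels: list[str]               # per-component label
    corr: np.ndarray                # item correlation matrix
    scores: pd.DataFrame | None = None


@dataclass
class AdjustedPhenotype:
    values: pd.Series               # residuals, indexed by sample_id
    retained_effects: list[str]
    candidate_pvalues: dict = field(default_factory=dict)
    design: pd.DataFrame | None = None


# ---------------------------------------------------------------------------

def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax; returns (rotated loadings, rotation matrix)."""
    L = loadings.copy()
    p, k = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    rotated = (L @ R) * h[:, None]
    return rotated, R


def kmo_from_corr(r: np.ndarray) -> float:
    """KMO from an item correlation matrix (see :func:`compute_kmo`)."""
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as err:
        raise ValueError("item correlation matrix is singular") from err
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    q = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def compute_kmo(behavior: pd.DataFrame, items: list[str] | None = None) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    anti-image (partial) correlations from the inverse correlation matrix.
    The two-item case degenerates to exactly 0.5 (q reduces to r itself).
    """
    X = _item_matrix(behavior, items)
    return kmo_from_corr(np.corrcoef(X, rowvar=False))


def _item_matrix(behavior: pd.DataFrame, items: list[str] | None) -> np.ndarray:
    if items is None:
        items = [c for c in behavior.columns if c != "sample_id"]
    X = behavior[items].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [items[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant item column(s): {bad}")
    return X


def fit_pca_varimax(
    behavior: pd.DataFrame,
    n_components: int = 4,
    items: list[str] | None = None,
    item_component: dict[str, str] | None = None,
) -> ComponentResult:
    """Correlation-matrix PCA with Kaiser-normalized varimax rotation.

    Component labels are assigned by which item group has the highest mean
    absolute rotated loading; each component is then signed so its defining
    items load positively (higher score = more confident / less fearful).
    """
    if items is None:
        items = [c for c in behavior.columns if c != "sample_id"]
    if len(items) < 2 or n_components > len(items):
        raise ValueError("need >= 2 items and n_components <= number of items")
    item_component = item_component or ITEM_COMPONENT
    X = _item_matrix(behavior, items)
    r = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    loadings = evecs[:, :n_components] * np.sqrt(evals[:n_components])
    rotated, R = _varimax(loadings)

    explained = evals[:n_components] / len(items)

    # label each component by the best-aligned item group, greedily by strength
    groups: dict[str, list[int]] = {}
    for i, it in enumerate(items):
        groups.setdefault(item_component.get(it, "other"), []).append(i)
    strength = {
        lab: np.abs(rotated[idx, :]).mean(axis=0) for lab, idx in groups.items() if lab != "other"
    }
    labels = [""] * n_components
    taken: set[str] = set()
    pairs = sorted(
        ((s[j], lab, j) for lab, s in strength.items() for j in range(n_components)),
        reverse=True,
    )
    for val, lab, j in pairs:
        if lab in taken or labels[j]:
            continue
        labels[j] = lab
        taken.add(lab)
    for j in range(n_components):
        if not labels[j]:
            labels[j] = f"PC{j + 1}"

    # orient: defining items (green-scored confident responses) load positive
    for j, lab in enumerate(labels):
        idx = groups.get(lab)
        if idx and rotated[idx, j].mean() < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]

    result = ComponentResult(
        items=list(items),
        loadings=loadings,
        rotated_loadings=rotated,
        rotation=R,
        explained_variance_fraction=explained,
        cumulative_explained=float(explained.sum()),
        kmo=compute_kmo(behavior, items),
        labels=labels,
        corr=r,
    )
    result.scores = component_scores(result, behavior)
    return result


def component_scores(result: ComponentResult, behavior: pd.DataFrame) -> pd.DataFrame:
    """Least-squares regression component scores, S = Z R^-1 L (columns mean 0)."""
    X = behavior[result.items].to_numpy(dtype=float)
    if X.shape[1] != len(result.items):
        raise ValueError("behavior table does not match fitted items")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    S = Z @ np.linalg.solve(result.corr, result.rotated_loadings)
    out = pd.DataFrame(S, columns=result.labels)
    if "sample_id" in behavior:
        out.insert(0, "sample_id", behavior["sample_id"].values)
    return out


# ---------------------------------------------------------------------------

def adjust_phenotype(
    scores: pd.Series,
    samples: pd.DataFrame,
    grm_pcs: np.ndarray | None = None,
    alpha: float = 0.05,
    candidates: tuple[str, ...] = ("facility", "sex", "size_class", "age", "PC1", "PC2"),
) -> AdjustedPhenotype:
    """Screen candidate fixed effects one at a time and regress out the
    significant ones; the residuals are the adjusted phenotype.

    Factors (facility, sex, size class) are screened with a model F-test,
    continuous covariates (age, GRM PC1/PC2) with the slope t-test.  If no
    candidate reaches p < alpha, the adjusted phenotype is the mean-centered
    raw score.  Factor levels with a single observation are dropped with a
    warning.
    """
    y = np.asarray(scores, dtype=float)
    n = len(y)
    if len(samples) != n:
        raise ValueError("scores and sample table lengths differ")

    cols: dict[str, np.ndarray | pd.Series] = {}
    for cand in candidates:
        if cand in ("PC1", "PC2"):
            if grm_pcs is None:
                continue
            j = int(cand[2]) - 1
            if j >= grm_pcs.shape[1]:
                continue
            cols[cand] = grm_pcs[:, j]
        elif cand in samples.columns:
            cols[cand] = samples[cand].values
        # silently skip candidates absent from the metadata

    factor_like = {"facility", "sex", "size_class"}
    pvals: dict[str, float] = {}
    designs: dict[str, pd.DataFrame] = {}
    for name, vals in cols.items():
        if name in factor_like:
            ser = pd.Series(vals).astype(str)
            counts = ser.value_counts()
            single = counts[counts < 2].index
            if len(single):
                warnings.warn(
                    f"{name}: dropping single-observation level(s) {sorted(single)}",
                    stacklevel=2,
                )
            mask_keep = ~ser.isin(single)
            dummies = pd.get_dummies(ser.where(mask_keep), drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                continue
            X = sm.add_constant(dummies)
            fit = sm.OLS(y, X).fit()
            pvals[name] = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
            designs[name] = dummies
        else:
            x = np.asarray(vals, dtype=float)
            X = sm.add_constant(x)
            fit = sm.OLS(y, X).fit()
            pvals[name] = float(fit.pvalues[1])
            designs[name] = pd.DataFrame({name: x})

    retained = [name for name in cols if pvals.get(name, 1.0) < alpha]
    if not retained:
        resid = pd.Series(y - y.mean(), index=samples["sample_id"].values, name=scores.name)
        return AdjustedPhenotype(values=resid, retained_effects=[], candidate_pvalues=pvals)

    design = pd.concat([designs[name] for name in retained], axis=1)
    X = sm.add_constant(design.to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    resid = pd.Series(fit.resid, index=samples["sample_id"].values, name=scores.name)
    return AdjustedPhenotype(
        values=resid,
        retained_effects=retained,
        candidate_pvalues=pvals,
        design=design,
    )
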