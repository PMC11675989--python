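"""SNP heritability by average-information REML on the single-GRM animal model.

Model: y = X b + g + e with g ~ N(0, K sg2) and e ~ N(0, I se2); heritability
is h2 = sg2 / (sg2 + se2).  The restricted likelihood is evaluated after a
one-time eigendecomposition of K, making each AI iteration O(n) for the
diagonal parts (plus small p x p solves), and the average-information matrix
provides both the Newton step and, inverted at convergence, the delta-method
standard error of h2.

Variance components are kept positive (floored at 1e-6 * var(y)), matching
the [0,1] reporting convention for h2; steps that would decrease the
restricted log-likelihood are halved until it increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .relatedness import Kinship


@dataclass
class HeritabilityResult:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    log_restricted_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trajectory: list[float] = None  # accepted-iteration log-likelihoods


def reml_loglik_direct(y: np.ndarray, K: np.ndarray, X: np.ndarray,
                       sigma_g2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood by dense matrix inversion (oracle route)."""
    n, p = X.shape
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ld_v + ld_x + r @ Vi @ r) - 0.5 * (n - p) * np.log(2 * np.pi))


class _RotatedREML:
    """REML quantities in the eigenbasis of K (V diagonal)."""

    def __init__(self, y: np.ndarray, K: np.ndarray, X: np.ndarray):
        d, U = np.linalg.eigh((K + K.T) / 2)
        self.d = np.maximum(d, 0.0)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = self.X.shape

    def _core(self, sg2: float, se2: float):
        v = sg2 * self.d + se2
        vi = 1.0 / v
        Xv = self.X * vi[:, None]
        C = np.linalg.inv(self.X.T @ Xv)          # (X' V^-1 X)^-1, p x p
        b = C @ (Xv.T @ self.y)
        Py = vi * self.y - Xv @ (C @ (Xv.T @ self.y))
        return v, vi, Xv, C, Py

    def loglik(self, sg2: float, se2: float) -> float:
        v, vi, Xv, C, Py = self._core(sg2, se2)
        _, ld_x = np.linalg.slogdet(self.X.T @ (self.X * vi[:, None]))
        return float(
            -0.5 * (np.log(v).sum() + ld_x + self.y @ Py)
            - 0.5 * (self.n - self.p) * np.log(2 * np.pi)
        )

    def _apply_P(self, w: np.ndarray, vi: np.ndarray, Xv: np.ndarray, C: np.ndarray) -> np.ndarray:
        return vi * w - Xv @ (C @ (Xv.T @ w))

    def score_ai(self, sg2: float, se2: float):
        """REML score vector and average-information matrix for (sg2, se2)."""
        v, vi, Xv, C, Py = self._core(sg2, se2)
        a_list = (self.d, np.ones(self.n))         # dV/d sg2, dV/d se2 (diagonal)
        # tr(P A) = tr(V^-1 A) - tr(C X'V^-1 A V^-1 X)
        tr_pa = []
        for a in a_list:
            t1 = (a * vi).sum()
            M = self.X.T @ (self.X * (a * vi * vi)[:, None])
            tr_pa.append(t1 - np.trace(C @ M))
        APy = [a * Py for a in a_list]
        PAPy = [self._apply_P(w, vi, Xv, C) for w in APy]
        score = np.array(
            [-0.5 * (tr_pa[i] - self.y @ PAPy[i]) for i in range(2)]
        )
        # note y'P A P y = (A Py)' Py ... use Py' A P A' Py forms for AI
        ai = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ai[i, j] = 0.5 * (APy[i] @ self._apply_P(APy[j], vi, Xv, C))
        return score, ai


def reml_h2(
    y: np.ndarray,
    K: Kinship | np.ndarray,
    X: np.ndarray | None = None,
    max_iter: int = 100,
    param_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> HeritabilityResult:
    """AI-REML estimate of sg2, se2, and h2 = sg2/(sg2+se2) with SE.

    X defaults to an intercept.  Starts from sg2 = se2 = var(y)/2.  Flags
    (without failing) non-convergence and the unidentifiable K = c*I case.

    K is trace-normalized to mean diagonal 1 before fitting, so sg2 is in
    phenotypic-variance units and h2 = sg2/(sg2 + se2) is the fraction of
    phenotypic variance tagged by the markers regardless of GRM scale.
    """
    Km = K.matrix if isinstance(K, Kinship) else np.asarray(K, float)
    Km = Km * (Km.shape[0] / np.trace(Km))
    y = np.asarray(y, dtype=float)
    n = y.size
    if Km.shape != (n, n):
        raise ValueError("kinship and phenotype dimensions disagree")
    if X is None:
        X = np.ones((n, 1))

    identifiable = True
    diag_mean = np.trace(Km) / n
    if np.allclose(Km, diag_mean * np.eye(n), atol=1e-10):
        warnings.warn(
            "kinship is proportional to the identity: sg2 and se2 are not separable",
            stacklevel=2,
        )
        identifiable = False

    eng = _RotatedREML(y, Km, X)
    vy = float(np.var(y, ddof=1))
    floor = 1e-6 * vy
    sg2 = se2 = vy / 2.0
    ll = eng.loglik(sg2, se2)
    trajectory = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai = eng.score_ai(sg2, se2)
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(ai) @ score
        scale = 1.0
        accepted = False
        for _ in range(30):
            new = np.maximum([sg2 + scale * step[0], se2 + scale * step[1]], floor)
            ll_new = eng.loglik(*new)
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            scale /= 2.0
        if not accepted:  # no improving step exists: stationary point
            converged = True
            break
        delta = max(abs(new[0] - sg2), abs(new[1] - se2))
        dll = ll_new - ll
        sg2, se2 = float(new[0]), float(new[1])
        ll = ll_new
        trajectory.append(ll)
        if delta < param_tol or abs(dll) < loglik_tol:
            converged = True
            break

    h2 = sg2 / (sg2 + se2)
    _, ai = eng.score_ai(sg2, se2)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    s = sg2 + se2
    grad = np.array([se2, -sg2]) / s**2
    var_h2 = float(grad @ cov @ grad)
    se_h2 = float(np.sqrt(var_h2)) if var_h2 > 0 else float("nan")

    return HeritabilityResult(
        sigma_g2=sg2,
        sigma_e2=se2,
        h2=float(h2),
        se_h2=se_h2,
        log_restricted_likelihood=float(ll),
        n_iterations=it,
        converged=bool(converged and identifiable),
        loglik_trajectory=trajectory,
    )
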