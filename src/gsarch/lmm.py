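"""REML variance components, (M)GFBLUP prediction, heritability partition.

The model is ``y = 1*mu + sum_s g_s + e`` with one polygenic term per
genomic feature (annotation group), ``g_s ~ N(0, G_s sigma2_s)`` and
``e ~ N(0, I sigma2_e)``.  With a single GRM this is plain GBLUP.  Variance
components are estimated by restricted maximum likelihood using
average-information (AI) updates with expectation-maximization fallback
steps whenever an AI proposal leaves the parameter space.  Prediction of
unphenotyped individuals is the conditional mean of their polygenic terms
given the reference phenotypes under the fitted Gaussian model.

The number of simultaneously fitted GRMs is capped at eight; beyond that
REML becomes poorly conditioned on typical annotation group structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .genomatrix import Grm

__all__ = [
    "VarianceComponents",
    "HeritabilityPartition",
    "reml_fit",
    "blup_predict",
    "partition_h2",
    "enrichment",
]

MAX_GRMS = 8


@dataclass
class VarianceComponents:
    sigma2_groups: np.ndarray          # one variance per GRM, trait units^2
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int
    flat_likelihood: bool = False      # model unidentifiable (e.g. G ~ I)
    group_labels: list[str] = field(default_factory=list)

    @property
    def sigma2_g(self) -> float:
        """Total genetic variance (sum over fitted GRMs)."""
        return float(np.sum(self.sigma2_groups))

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0


@dataclass
class HeritabilityPartition:
    """Per-group share of genetic variance and enrichment."""

    pct_h2: np.ndarray        # percentages, sum to 100
    enrichment: np.ndarray    # pct_h2 / (100 * group_prop)
    group_prop: np.ndarray
    group_labels: list[str] = field(default_factory=list)


def _as_cov_list(grms) -> list[np.ndarray]:
    if isinstance(grms, Grm) or (
        isinstance(grms, np.ndarray) and grms.ndim == 2
    ):
        grms = [grms]
    mats = []
    for g in grms:
        mats.append(g.values if isinstance(g, Grm) else np.asarray(g, float))
    return mats


def reml_fit(
    y: np.ndarray,
    grms,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-4,
    psd_tol: float = 1e-6,
) -> VarianceComponents:
    """AI-REML estimates for one or more GRMs plus a residual.

    Starting values split ``var(y)`` equally across all components.
    Variances are floored at ``1e-8 * var(y)``; a component pinned to the
    floor for three consecutive iterations is reported as exactly zero.
    A singular average-information matrix (confounded covariance
    structures, e.g. a GRM proportional to the identity) raises the
    ``flat_likelihood`` flag instead of failing silently.
    """
    y = np.asarray(y, dtype=float).ravel()
    mats = _as_cov_list(grms)
    k = len(mats)
    if not 1 <= k <= MAX_GRMS:
        raise ValueError(f"number of GRMs must be in [1, {MAX_GRMS}], got {k}")
    n = y.size
    for G in mats:
        if G.shape != (n, n):
            raise ValueError("GRM dimension does not match phenotype length")
        w = np.linalg.eigvalsh(G)
        if w[0] < -1e-6 * max(1.0, w[-1]):
            raise ValueError(f"GRM not PSD (min eigenvalue {w[0]:.3g})")

    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    theta = np.full(k + 1, vary / (k + 1))   # [sigma2_1..k, sigma2_e]
    pinned = np.zeros(k + 1, dtype=int)

    if k == 1:
        # eigen fast path: one O(n^3) decomposition, O(n) per iteration
        d, U = np.linalg.eigh(mats[0])
        yt = U.T @ y
        xt = U.T @ np.ones(n)

        def _stats(th):
            v = th[0] * d + th[1]
            if np.any(v <= 0):
                raise np.linalg.LinAlgError("V not positive definite")
            a = float(np.sum(xt * xt / v))
            b = float(np.sum(xt * yt / v))
            ypy = float(np.sum(yt * yt / v)) - b * b / a
            ll = -0.5 * (float(np.sum(np.log(v))) + np.log(a) + ypy)
            w = (yt - xt * b / a) / v          # P y in the eigenbasis
            cvecs = (d, np.ones(n))
            score = np.empty(2)
            ypcpy = np.empty(2)
            for i, c in enumerate(cvecs):
                tr_pc = float(np.sum(c / v)) - float(np.sum(xt * xt * c
                                                            / v ** 2)) / a
                ypcpy[i] = float(np.sum(c * w * w))
                score[i] = -0.5 * (tr_pc - ypcpy[i])
            AI = np.empty((2, 2))
            for jj, cj in enumerate(cvecs):
                u = cj * w
                pu = (u - xt * float(np.sum(xt * u / v)) / a) / v
                for ii, ci in enumerate(cvecs):
                    AI[ii, jj] = 0.5 * float(np.sum(ci * w * pu))
            return ll, score, AI
    else:
        covs = mats + [np.eye(n)]

        def _stats(th):
            V = sum(t * C for t, C in zip(th, covs))
            cf = linalg.cho_factor(V, lower=True)
            logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
            Vinv = linalg.cho_solve(cf, np.eye(n))
            ones = np.ones(n)
            Vi1 = Vinv @ ones
            xvx = float(ones @ Vi1)
            P = Vinv - np.outer(Vi1, Vi1) / xvx
            Py = P @ y
            ll = -0.5 * (logdetV + np.log(xvx) + float(y @ Py))
            CPy = [C @ Py for C in covs]
            score = np.array([
                -0.5 * (float(np.sum(P * C)) - float(Py @ CPy[i]))
                for i, C in enumerate(covs)
            ])
            PCPy = [P @ vv for vv in CPy]
            AI = 0.5 * np.array(
                [[float(CPy[i] @ PCPy[j]) for j in range(k + 1)]
                 for i in range(k + 1)])
            return ll, score, AI

    ll_old = -np.inf
    ll = -np.inf
    flat = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            ll, score, AI = _stats(theta)
        except np.linalg.LinAlgError:
            flat = True
            break
        cond = np.linalg.cond(AI)
        if not np.isfinite(cond) or cond > 1e10:
            flat = True
        try:
            delta = np.linalg.solve(AI, score)
            prop = theta + delta
        except np.linalg.LinAlgError:
            prop = np.full(k + 1, -1.0)   # force EM step
        if np.any(prop < floor):
            # EM fallback: guaranteed in-bounds update
            # (score_i = -0.5 (tr(P C_i) - y'P C_i P y))
            prop = theta + theta ** 2 * (2.0 * score) / n
        new = np.maximum(prop, floor)
        pinned = np.where(new <= floor * (1 + 1e-12), pinned + 1, 0)
        rel = np.max(np.abs(new - theta) / np.maximum(theta, floor))
        dll = ll - ll_old
        theta = new
        if it > 1 and abs(dll) < tol_loglik and rel < tol_param:
            converged = True
            break
        ll_old = ll
    try:
        ll_final = _stats(theta)[0]
    except np.linalg.LinAlgError:
        ll_final = ll
    out = theta.copy()
    out[pinned >= 3] = 0.0
    labels = [g.mode if isinstance(g, Grm) else f"grm{i}"
              for i, g in enumerate(_iter_grms(grms))]
    return VarianceComponents(
        sigma2_groups=out[:k],
        sigma2_e=float(out[k]),
        loglik=float(ll_final),
        converged=converged and not flat,
        n_iter=it,
        flat_likelihood=flat,
        group_labels=labels,
    )


def _iter_grms(grms):
    return [grms] if isinstance(grms, (Grm, np.ndarray)) else list(grms)


def blup_predict(
    y_ref: np.ndarray,
    grm_full,
    vc: VarianceComponents,
    ref_index: np.ndarray,
    target_index: np.ndarray,
) -> np.ndarray:
    """Conditional-mean genomic values for target individuals.

    ``grm_full`` is one GRM (or a list, for the multi-feature model) over
    reference plus target individuals; ``ref_index``/``target_index`` index
    its rows.  The prediction is ``sum_s sigma2_s G_s[t, r] V_rr^-1
    (y_r - mu_hat)`` with ``mu_hat`` the GLS mean, i.e. the sum of
    per-feature conditional means.
    """
    mats = _as_cov_list(grm_full)
    sig = np.atleast_1d(np.asarray(vc.sigma2_groups, dtype=float))
    if len(mats) != sig.size:
        raise ValueError("number of GRMs does not match variance components")
    ref_index = np.asarray(ref_index)
    target_index = np.asarray(target_index)
    if np.intersect1d(ref_index, target_index).size:
        raise ValueError("reference and target sets must be disjoint")
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    nr = ref_index.size
    V = vc.sigma2_e * np.eye(nr)
    for s2, G in zip(sig, mats):
        V += s2 * G[np.ix_(ref_index, ref_index)]
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular mixed-model coefficient matrix (cond={cond:.3g})")
    cf = linalg.cho_factor(V, lower=True)
    ones = np.ones(nr)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = float(Vi1 @ y_ref) / float(Vi1 @ ones)
    w = linalg.cho_solve(cf, y_ref - mu)
    pred = np.zeros(target_index.size)
    for s2, G in zip(sig, mats):
        pred += s2 * (G[np.ix_(target_index, ref_index)] @ w)
    return pred


def enrichment(pct_h2: np.ndarray, group_prop: np.ndarray) -> np.ndarray:
    """Per-group enrichment: heritability share over variant share.

    ``pct_h2`` is in percent; ``group_prop`` is the fraction of variants in
    the group.  A value above 1 means larger-than-average per-variant
    effects.
    """
    pct_h2 = np.asarray(pct_h2, dtype=float)
    group_prop = np.asarray(group_prop, dtype=float)
    return pct_h2 / (100.0 * group_prop)


def partition_h2(vc: VarianceComponents, group_sizes) -> HeritabilityPartition:
    """%SNP heritability and enrichment per annotation group.

    ``pct_h2_s = 100 * sigma2_s / sum_s sigma2_s`` and
    ``enrichment_s = pct_h2_s / (100 * group_prop_s)``.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    sig = np.atleast_1d(np.asarray(vc.sigma2_groups, dtype=float))
    if sizes.size != sig.size:
        raise ValueError("group_sizes length does not match variance components")
    total = float(sig.sum())
    if total <= 0:
        raise ValueError("all group variances are zero; partition undefined")
    pct = 100.0 * sig / total
    prop = sizes / sizes.sum()
    return HeritabilityPartition(
        pct_h2=pct,
        enrichment=enrichment(pct, prop),
        group_prop=prop,
        group_labels=list(vc.group_labels),
    )
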