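"""GRM-based REML variance components (SNP-heritability, r_g, r_e).

The genetic relationship matrix uses the standard allele-frequency
standardized estimator A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
(2 p_i (1 - p_i)); the same formula is used on and off the diagonal.
Univariate REML fits y ~ N(mu, sg2 A + se2 I) exactly by profiling the
restricted likelihood over the heritability after rotating into the
eigenbasis of A.  Bivariate REML fits the 6-parameter model
vec(Y) ~ N(X b, G (x) A + E (x) I) by average-information updates with
step-halving; in the eigenbasis the 2n x 2n covariance becomes n
independent 2 x 2 blocks d_i G + E, so likelihood, scores and AI terms
are all O(n) per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .synthgen import DosagePanel

RIDGE = 1e-6


class RemlError(RuntimeError):
    pass


class ConvergenceError(RemlError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class Grm:
    matrix: np.ndarray
    ids: np.ndarray
    m_snps: int

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.matrix + RIDGE * np.eye(self.matrix.shape[0])
        d, u = np.linalg.eigh(a)
        if d.min() <= 0:
            raise RemlError("GRM not positive definite after ridge")
        return d, u


def compute_grm(panel: DosagePanel) -> Grm:
    """Allele-frequency standardized relationship matrix from a panel."""
    p = panel.eaf()
    if np.any(p <= 0) or np.any(p >= 1):
        raise AssertionError("monomorphic SNPs must be removed before GRM construction")
    x = panel.dosages.copy()
    mu = 2.0 * p[:, None]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu[:, 0], inds[0])
    z = (x - mu) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    a = z.T @ z / panel.n_snps
    return Grm(matrix=a, ids=panel.iids.copy(), m_snps=panel.n_snps)


def prune_related(grm: Grm, cutoff: float = 0.025) -> np.ndarray:
    """Greedy removal of individuals until no pair exceeds ``cutoff``.

    While any off-diagonal relationship exceeds the cutoff, the
    individual involved in the most such pairs is removed (ties break
    to the later id).  Returns the retained ids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.abs(grm.matrix.copy())
    np.fill_diagonal(a, 0.0)
    alive = np.ones(a.shape[0], dtype=bool)
    over = a > cutoff
    while True:
        counts = np.where(alive, over[:, alive].sum(axis=1), -1)
        if counts.max() <= 0:
            break
        worst = np.flatnonzero(counts == counts.max())[-1]  # later id on ties
        alive[worst] = False
        over[worst, :] = False
        over[:, worst] = False
    return grm.ids[alive]


@dataclass
class VarCompEstimate:
    v_g: float
    se_vg: float
    sigma2_g: float
    sigma2_e: float
    loglik: float
    p_lrt: float
    boundary: bool = False


def _uni_profile_negloglik(h: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """Profiled restricted negative log-likelihood over the h2 ratio."""
    v = h * d + (1.0 - h)
    w = 1.0 / v
    xwx = float(np.sum(xt * xt * w))
    mu = float(np.sum(xt * yt * w)) / xwx
    rss = float(np.sum((yt - mu * xt) ** 2 * w))
    n = d.size
    s2 = rss / (n - 1)
    return 0.5 * (np.sum(np.log(v)) + (n - 1) * np.log(s2) + np.log(xwx) + (n - 1))


def _uni_reml_loglik(sg2: float, se2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    v = sg2 * d + se2
    if np.any(v <= 0):
        return -np.inf
    w = 1.0 / v
    xwx = float(np.sum(xt * xt * w))
    mu = float(np.sum(xt * yt * w)) / xwx
    rss = float(np.sum((yt - mu * xt) ** 2 * w))
    return -0.5 * (float(np.sum(np.log(v))) + np.log(xwx) + rss)


def reml_univariate(y_std: np.ndarray, grm: Grm) -> VarCompEstimate:
    """Exact REML for a single-GRM variance-component model.

    Profiles the restricted likelihood over h = sg2/(sg2+se2) in [0, 1)
    (1-D bounded optimization is exact for this model), recovers the
    variance scale in closed form, takes the SE of h from the observed
    information of (sg2, se2) by the delta method, and tests sg2 = 0
    with the 50:50 chi2(0)/chi2(1) boundary mixture.
    """
    y = np.asarray(y_std, dtype=float)
    d, u = grm.eigen()
    yt = u.T @ y
    xt = u.T @ np.ones_like(y)

    res = optimize.minimize_scalar(
        _uni_profile_negloglik, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        args=(d, yt, xt), options={"xatol": 1e-10},
    )
    h = float(res.x)
    v = h * d + (1.0 - h)
    w = 1.0 / v
    xwx = float(np.sum(xt * xt * w))
    mu = float(np.sum(xt * yt * w)) / xwx
    rss = float(np.sum((yt - mu * xt) ** 2 * w))
    s2 = rss / (d.size - 1)
    sg2, se2 = h * s2, (1.0 - h) * s2
    ll = _uni_reml_loglik(sg2, se2, d, yt, xt)

    # observed information of (sg2, se2) by central differences
    eps = 1e-4 * max(s2, 1e-8)
    H = np.zeros((2, 2))
    pt = np.array([sg2, se2])
    for a in range(2):
        for b in range(a, 2):
            pp = pt.copy(); pp[a] += eps; pp[b] += eps
            pm = pt.copy(); pm[a] += eps; pm[b] -= eps
            mp = pt.copy(); mp[a] -= eps; mp[b] += eps
            mm = pt.copy(); mm[a] -= eps; mm[b] -= eps
            vals = [_uni_reml_loglik(q[0], max(q[1], 1e-12), d, yt, xt) for q in (pp, pm, mp, mm)]
            H[a, b] = H[b, a] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(-H)
        tot = sg2 + se2
        grad = np.array([se2 / tot ** 2, -sg2 / tot ** 2])
        se_vg = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_vg = float("nan")

    # null model sg2 = 0: profile the scale of the plain mean model
    xwx0 = float(np.sum(xt * xt))
    mu0 = float(np.sum(xt * yt)) / xwx0
    s2_0 = float(np.sum((yt - mu0 * xt) ** 2)) / (d.size - 1)
    ll0 = _uni_reml_loglik(0.0, s2_0, d, yt, xt)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p_lrt = 0.5 if lrt == 0 else float(0.5 * stats.chi2.sf(lrt, 1))
    return VarCompEstimate(
        v_g=h, se_vg=se_vg, sigma2_g=sg2, sigma2_e=se2,
        loglik=ll, p_lrt=p_lrt, boundary=h < 1e-8 or h > 1 - 1e-6,
    )


# ---------------------------------------------------------------------------
# bivariate AI-REML
# ---------------------------------------------------------------------------

#: elementary derivative matrices for the 2x2 covariance components,
#: parameter order (sg1, sg2, cg, se1, se2, ce)
_DMATS = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
]


@dataclass
class BivarCompEstimate:
    sigma2_g: tuple[float, float]
    sigma2_e: tuple[float, float]
    c_g: float
    c_e: float
    r_g: float
    r_e: float
    se_rg: float
    se_re: float
    p_rg0: float
    loglik: float
    clipped: bool = False
    trace: list[float] = field(default_factory=list)


class _BivarWorkspace:
    """Rotated data plus O(n) REML likelihood/score/AI evaluations."""

    def __init__(self, Y: np.ndarray, grm: Grm):
        d, u = grm.eigen()
        self.d = d
        self.yt = u.T @ np.asarray(Y, dtype=float)  # (n, 2)
        self.xt = u.T @ np.ones(Y.shape[0])  # (n,)
        self.n = Y.shape[0]

    def _blocks(self, theta: np.ndarray):
        sg1, sg2, cg, se1, se2, ce = theta
        d = self.d
        b11 = sg1 * d + se1
        b22 = sg2 * d + se2
        b12 = cg * d + ce
        det = b11 * b22 - b12 ** 2
        return b11, b12, b22, det

    def pd_ok(self, theta: np.ndarray) -> bool:
        sg1, sg2, cg, se1, se2, ce = theta
        # keep the component matrices (numerically) PSD: an indefinite E
        # combined with near-zero GRM eigenvalues pins the whole fit
        for v1, v2, c in ((sg1, sg2, cg), (se1, se2, ce)):
            if v1 < 0 or v2 < 0 or v1 * v2 - c * c < -1e-8 * max(v1 * v2, 1e-12):
                return False
        b11, _, b22, det = self._blocks(theta)
        return bool(det.min() > 0 and b11.min() > 0 and b22.min() > 0)

    def core(self, theta: np.ndarray):
        """Inverse blocks, projected residual Py, X'V^-1X and loglik."""
        b11, b12, b22, det = self._blocks(theta)
        i11, i12, i22 = b22 / det, -b12 / det, b11 / det
        y1, y2 = self.yt[:, 0], self.yt[:, 1]
        x = self.xt
        # X'V^-1X (2x2) and X'V^-1y (2,) using the block structure
        x2 = x * x
        T = np.array(
            [[np.sum(x2 * i11), np.sum(x2 * i12)], [np.sum(x2 * i12), np.sum(x2 * i22)]]
        )
        xty = np.array(
            [np.sum(x * (i11 * y1 + i12 * y2)), np.sum(x * (i12 * y1 + i22 * y2))]
        )
        try:
            beta = np.linalg.solve(T, xty)
        except np.linalg.LinAlgError:
            return None, T, (None, None), -np.inf
        r1 = y1 - x * beta[0]
        r2 = y2 - x * beta[1]
        py1 = i11 * r1 + i12 * r2
        py2 = i12 * r1 + i22 * r2
        ypy = float(np.sum(y1 * py1 + y2 * py2))
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = -0.5 * (float(np.sum(np.log(det))) + float(np.log(np.linalg.det(T))) + ypy)
        if not np.isfinite(ll):
            ll = -np.inf
        return (i11, i12, i22), T, (py1, py2), ll

    @staticmethod
    def _apply_m(M: np.ndarray, v1: np.ndarray, v2: np.ndarray):
        return M[0, 0] * v1 + M[0, 1] * v2, M[1, 0] * v1 + M[1, 1] * v2

    def score_ai(self, theta: np.ndarray, free: list[int]):
        """REML score vector and average-information matrix (free params)."""
        (i11, i12, i22), T, (py1, py2), ll = self.core(theta)
        d, x = self.d, self.xt
        x2 = x * x
        Tinv = np.linalg.inv(T)
        k = len(free)
        # derivative blocks: factor f (d_i or 1) times elementary matrix M
        facs, mats = [], []
        for idx in free:
            facs.append(d if idx < 3 else np.ones_like(d))
            mats.append(_DMATS[idx % 3])
        # t_k = dV_k Py, per-coordinate
        t1s, t2s = [], []
        for f, M in zip(facs, mats):
            a1, a2 = self._apply_m(M, py1, py2)
            t1s.append(f * a1)
            t2s.append(f * a2)
        # P t_j for each free param
        pts = []
        for t1, t2 in zip(t1s, t2s):
            v1 = i11 * t1 + i12 * t2
            v2 = i12 * t1 + i22 * t2
            xtv = np.array([np.sum(x * v1), np.sum(x * v2)])
            g = Tinv @ xtv
            pts.append((v1 - (i11 * x * g[0] + i12 * x * g[1]),
                        v2 - (i12 * x * g[0] + i22 * x * g[1])))
        score = np.empty(k)
        ai = np.empty((k, k))
        for a in range(k):
            f, M = facs[a], mats[a]
            # tr(V^-1 dV) = sum f * tr(Binv M)
            if M[0, 1] == 0:  # diagonal elementary
                tr_vinv_dv = float(np.sum(f * (i11 if M[0, 0] else i22)))
            else:
                tr_vinv_dv = float(np.sum(f * 2.0 * i12))
            # correction tr(Tinv * X'V^-1 dV V^-1 X)
            # X'V^-1 dV V^-1 X = sum x^2 f * (Binv M Binv)
            if M[0, 1] == 0:
                if M[0, 0]:
                    c11, c12, c22 = i11 * i11, i11 * i12, i12 * i12
                else:
                    c11, c12, c22 = i12 * i12, i12 * i22, i22 * i22
            else:
                c11 = 2.0 * i11 * i12
                c12 = i11 * i22 + i12 * i12
                c22 = 2.0 * i12 * i22
            Ck = np.array(
                [[np.sum(x2 * f * c11), np.sum(x2 * f * c12)],
                 [np.sum(x2 * f * c12), np.sum(x2 * f * c22)]]
            )
            tr_p_dv = tr_vinv_dv - float(np.trace(Tinv @ Ck))
            quad = float(np.sum(py1 * t1s[a] + py2 * t2s[a]))
            score[a] = -0.5 * (tr_p_dv - quad)
            for b in range(k):
                ai[a, b] = 0.5 * float(
                    np.sum(t1s[a] * pts[b][0] + t2s[a] * pts[b][1])
                )
        ai = 0.5 * (ai + ai.T)
        return score, ai, ll


def _fit_bivar(
    ws: _BivarWorkspace,
    theta0: np.ndarray,
    free: list[int],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, list[float], np.ndarray]:
    theta = theta0.copy()
    trace: list[float] = []
    _, _, (_, _), ll = ws.core(theta)
    trace.append(ll)
    ai_last = np.eye(len(free))
    for _ in range(max_iter):
        score, ai, _ = ws.score_ai(theta, free)
        ai_last = ai
        # pseudo-inverse guards against AI rank deficiency at boundary
        # models (e.g. perfectly correlated traits)
        step, *_ = np.linalg.lstsq(ai, score, rcond=1e-8)
        if not np.all(np.isfinite(step)):
            step = score
        cap = 5.0 * (1.0 + float(np.linalg.norm(theta)))
        norm = float(np.linalg.norm(step))
        if norm > cap:
            step = step * (cap / norm)

        def _try(direction):
            d = direction.copy()
            for _half in range(60):
                cand = theta.copy()
                cand[free] = theta[free] + d
                if ws.pd_ok(cand):
                    _, _, _, ll_new = ws.core(cand)
                    if ll_new > ll + 1e-12:
                        return cand, ll_new, _half
                d = d / 2.0
            return None, None, 0

        cand, ll_cand, halved = _try(step)
        if cand is None or halved >= 10:
            # AI step infeasible or squeezed against a constraint: also
            # consider the score direction and single-coordinate moves
            # (the latter crawl along constrained ridges of degenerate
            # models) and keep whichever gains the most
            alternatives = [(cand, ll_cand, halved)] if cand is not None else []
            g = score / max(1.0, float(np.linalg.norm(score)))
            alternatives.append(_try(g))
            scale = 1.0 + float(np.linalg.norm(theta))
            for j in range(len(free)):
                e = np.zeros(len(free))
                e[j] = np.sign(score[j]) * 0.5 * scale
                alternatives.append(_try(e))
            alternatives = [a for a in alternatives if a[0] is not None]
            if not alternatives:
                break  # no feasible improvement: boundary fit
            cand, ll_cand, halved = max(alternatives, key=lambda a: a[1])
        theta = cand
        trace.append(ll_cand)
        # a heavily truncated step can make a tiny gain without being
        # anywhere near the optimum; only full steps signal convergence
        if abs(ll_cand - ll) < tol and halved == 0:
            ll = ll_cand
            break
        ll = ll_cand
    else:
        # monotone but still moving after max_iter: a boundary model
        # (unbounded likelihood) keeps crawling forever, an interior
        # optimum does not
        if len(trace) >= 2 and trace[-1] - trace[-2] < 1e-2:
            pass  # accept the boundary fit
        else:
            raise ConvergenceError("AI-REML did not converge", trace)
    return theta, ll, trace, ai_last


def reml_bivariate(Y: np.ndarray, grm: Grm) -> BivarCompEstimate:
    """Average-information REML for two traits sharing one GRM.

    Start values split each trait's variance equally between the
    genetic and residual components with zero covariances; SEs of the
    genetic and residual correlations come from the inverse AI matrix
    by the delta method; the r_g = 0 test refits with c_g fixed at zero
    and refers twice the log-likelihood difference to chi-square(1).
    """
    Y = np.asarray(Y, dtype=float)
    ok = ~np.isnan(Y).any(axis=1)
    Y = Y[ok]
    if not ok.all():
        raise RemlError("bivariate REML requires complete cases aligned with the GRM")
    ws = _BivarWorkspace(Y, grm)
    v1, v2 = Y[:, 0].var(ddof=1), Y[:, 1].var(ddof=1)
    theta0 = np.array([0.5 * v1, 0.5 * v2, 0.0, 0.5 * v1, 0.5 * v2, 0.0])
    free = list(range(6))
    theta, ll, trace, ai = _fit_bivar(ws, theta0, free)
    sg1, sg2, cg, se1, se2, ce = theta

    clipped = False
    denom_g = np.sqrt(max(sg1, 1e-12) * max(sg2, 1e-12))
    denom_e = np.sqrt(max(se1, 1e-12) * max(se2, 1e-12))
    r_g = cg / denom_g
    r_e = ce / denom_e
    if abs(r_g) > 1.0:
        r_g, clipped = float(np.clip(r_g, -1, 1)), True
    if abs(r_e) > 1.0:
        r_e, clipped = float(np.clip(r_e, -1, 1)), True

    # delta-method SEs from the inverse AI (asymptotic REML information)
    try:
        cov = np.linalg.inv(ai)
        g_rg = np.array([-r_g / (2 * sg1), -r_g / (2 * sg2), 1.0 / denom_g, 0, 0, 0])
        g_re = np.array([0, 0, 0, -r_e / (2 * se1), -r_e / (2 * se2), 1.0 / denom_e])
        se_rg = float(np.sqrt(max(g_rg @ cov @ g_rg, 0.0)))
        se_re = float(np.sqrt(max(g_re @ cov @ g_re, 0.0)))
    except np.linalg.LinAlgError:
        se_rg = se_re = float("nan")

    # LRT for r_g = 0: c_g fixed at zero, all other parameters free
    theta0_null = theta.copy()
    theta0_null[2] = 0.0
    if not ws.pd_ok(theta0_null):
        theta0_null = np.array([0.5 * v1, 0.5 * v2, 0.0, 0.5 * v1, 0.5 * v2, 0.0])
    _, ll0, _, _ = _fit_bivar(ws, theta0_null, [0, 1, 3, 4, 5])
    lrt = max(0.0, 2.0 * (ll - ll0))
    p_rg0 = float(stats.chi2.sf(lrt, 1))

    return BivarCompEstimate(
        sigma2_g=(float(sg1), float(sg2)),
        sigma2_e=(float(se1), float(se2)),
        c_g=float(cg),
        c_e=float(ce),
        r_g=float(r_g),
        r_e=float(r_e),
        se_rg=se_rg,
        se_re=se_re,
        p_rg0=p_rg0,
        loglik=float(ll),
        clipped=clipped,
        trace=trace,
    )


def haseman_elston(y_std: np.ndarray, grm: Grm) -> float:
    """Moment estimator of sg2: regress y_j*y_k on A_jk (off-diagonal)."""
    y = np.asarray(y_std, dtype=float)
    a = grm.matrix
    iu = np.triu_indices(a.shape[0], k=1)
    x = a[iu]
    prod = np.outer(y, y)[iu]
    return float(np.sum(x * prod) / np.sum(x * x))


def phenotypic_correlation(y1: np.ndarray, y2: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its large-sample standard error."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size != y2.size or y1.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if y1.std() == 0 or y2.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(y1, y2)[0, 1])
    se = float(np.sqrt((1.0 - r * r) / (y1.size - 2)))
    return r, se
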