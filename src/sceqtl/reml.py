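"""Restricted maximum-likelihood variance components and variance partitioning.

The mixed model is y = Xβ + Σ_c W_c u_c + ε with u_c ~ N(0, σ²_c I) and
ε ~ N(0, σ²_e I), so Var(y) = Σ_c σ²_c K_c + σ²_e I with the genomic
relationship matrix K_c = W_c W_cᵀ / m_c built from the column-standardized
design W_c (the GCTA convention).  "Variance explained" by a model is
Σ σ²_random / (Σ σ²_random + σ²_e); partitioning a trait between two
random designs (genotype vs expression, or cis vs trans) uses the
difference algebra over the three model fits:

    shared     = R_a + R_b − R_ab
    a_exclusive = R_ab − R_b
    b_exclusive = R_ab − R_a
    residual   = 1 − R_ab

with negative components clipped at zero and the partition re-normalized.

Overall expression heritability orthogonalizes the (normalized) expression
matrix by PCA and takes the eigenvalue-share weighted sum of each
component's heritability: Σ_i (λ_i / Σλ) · R²(PC_i ~ genotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponentModel",
    "VarianceComponentResults",
    "VariancePartition",
    "ExpressionPCA",
    "ConvergenceError",
    "standardize_columns",
    "reml_loglik",
    "partition_fitness",
    "partition_cis_trans",
    "expression_heritability",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = np.asarray(trajectory)


def standardize_columns(W: np.ndarray) -> np.ndarray:
    """Column-standardize a design; zero-variance columns are dropped (logged)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("design must be 2-D")
    sd = W.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d zero-variance design columns", (~keep).sum())
    W = W[:, keep]
    if W.shape[1] == 0:
        raise ValueError("design has no non-constant columns")
    return (W - W.mean(axis=0)) / W[:, :].std(axis=0)


def _grm(W: np.ndarray) -> np.ndarray:
    return W @ W.T / W.shape[1]


def reml_loglik(y, X, Ks, theta) -> float:
    """Restricted log-likelihood at variance components ``theta``.

    ``Ks`` are the random-effect covariance kernels; ``theta`` lists their
    variances followed by the residual variance.  Used directly by the
    fitter and as the target for independent grid-search checks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    V = theta[-1] * np.eye(n)
    for K, t in zip(Ks, theta[:-1]):
        V += t * K
    c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    Vi_y = linalg.cho_solve((c, low), y)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V⁻¹X not positive definite")
    return -0.5 * (logdet_v + logdet_x + float(y @ Py))


class VarianceComponentModel:
    """REML variance-component model for one response and ≥1 random designs.

    Parameters
    ----------
    y : (n,) response (fitness, a gene's expression, or an expression PC).
    random_designs : dict of name → (n × m) design matrix.  Columns are
        standardized internally; zero-variance columns are dropped.
    X : fixed-effect design; defaults to an intercept column.

    ``fit()`` returns a :class:`VarianceComponentResults`.
    """

    def __init__(self, y, random_designs: dict, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        if not random_designs:
            raise ValueError("need at least one random design")
        self.names = list(random_designs)
        self.Ws = {}
        for name, W in random_designs.items():
            W = np.asarray(W, dtype=float)
            if W.shape[0] != n:
                raise ValueError(f"design {name!r} has wrong sample dimension")
            self.Ws[name] = standardize_columns(W)
        self.X = (
            np.ones((n, 1)) if X is None else np.asarray(X, dtype=float).reshape(n, -1)
        )
        if n <= self.X.shape[1]:
            raise ValueError("need n > number of fixed effects")
        self.Ks = [_grm(self.Ws[name]) for name in self.names]

    # -- fitting -----------------------------------------------------------

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> "VarianceComponentResults":
        if len(self.Ks) == 1:
            return self._fit_spectral()
        return self._fit_ai(max_iter, tol)

    def _fit_spectral(self) -> "VarianceComponentResults":
        """Exact 1-component REML via the eigenbasis of K.

        Rotating by the eigenvectors of K diagonalizes V = σ²_g K + σ²_e I,
        so the restricted likelihood profiles down to a 1-D search over the
        heritability ratio — no iteration, no convergence failures.
        """
        y, X = self.y, self.X
        n = len(y)
        K = self.Ks[0]
        lam, U = linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        yr = U.T @ y
        Xr = U.T @ X

        vy = np.var(y)

        def nll(h2):
            # V = s2 * D with D = h2*lam + (1-h2); profile out s2
            d = h2 * lam + (1.0 - h2)
            d = np.clip(d, 1e-12, None)
            Xd = Xr / d[:, None]
            XtViX = Xr.T @ Xd
            beta = np.linalg.solve(XtViX, Xd.T @ yr)
            resid = yr - Xr @ beta
            quad = float(resid @ (resid / d))
            k = X.shape[1]
            s2 = quad / (n - k)
            ll = -0.5 * (
                np.log(d).sum()
                + (n - k) * np.log(s2)
                + np.linalg.slogdet(XtViX)[1]
                + (n - k)
            )
            return -ll

        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                       options={"xatol": 1e-10})
        h2 = float(res.x)
        # boundary refinement: the bounded minimizer cannot land exactly on 0/1
        for cand in (0.0, h2):
            if nll(cand) < nll(h2):
                h2 = cand
        d = np.clip(h2 * lam + (1.0 - h2), 1e-12, None)
        Xd = Xr / d[:, None]
        XtViX = Xr.T @ Xd
        beta = np.linalg.solve(XtViX, Xd.T @ yr)
        resid = yr - Xr @ beta
        s2 = float(resid @ (resid / d)) / (n - X.shape[1])
        theta = np.array([h2 * s2, (1.0 - h2) * s2])
        ll = -nll(h2)
        se = self._ai_se(theta)
        return VarianceComponentResults(
            names=self.names,
            sigma2=dict(zip(self.names, theta[:-1])),
            sigma2_residual=float(theta[-1]),
            se=se,
            loglik=ll,
            trajectory=np.array([ll]),
            converged=True,
            n=n,
            model=self,
        )

    def _pieces(self, theta):
        y, X = self.y, self.X
        n = len(y)
        V = theta[-1] * np.eye(n)
        for K, t in zip(self.Ks, theta[:-1]):
            V += t * K
        c, low = linalg.cho_factor(V, lower=True)
        Vi = linalg.cho_solve((c, low), np.eye(n))
        Vi_X = Vi @ X
        XtViX = X.T @ Vi_X
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
        Py = P @ y
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        ll = -0.5 * (logdet_v + np.linalg.slogdet(XtViX)[1] + float(y @ Py))
        return P, Py, ll

    def _fit_ai(self, max_iter, tol) -> "VarianceComponentResults":
        y = self.y
        n = len(y)
        vy = np.var(y)
        kernels = self.Ks + [np.eye(n)]
        m = len(kernels)
        theta = np.full(m, vy / m)
        floor = 1e-8 * vy
        traj = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            P, Py, ll = self._pieces(theta)
            traj.append(ll)
            if abs(ll - prev) < tol * max(1.0, abs(prev)) and it > 0:
                converged = True
                break
            prev = ll
            KPy = [K @ Py for K in kernels]
            score = np.array(
                [
                    -0.5 * (np.sum(P * K) - float(Py @ KPy[c]))
                    for c, K in enumerate(kernels)
                ]
            )
            PKPy = [P @ v for v in KPy]
            AI = 0.5 * np.array(
                [[float(KPy[a] @ PKPy[b]) for b in range(m)] for a in range(m)]
            )
            # components pinned at the floor with downhill gradient are
            # frozen out of the AI step; near-zero components otherwise make
            # the full Newton-like step overshoot and force an EM crawl
            free = ~((theta <= floor * 4) & (score < 0))
            free[-1] = True  # the residual variance is never frozen
            step_ok = False
            try:
                delta = np.zeros(m)
                idx = np.flatnonzero(free)
                delta[idx] = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
                for factor in (1.0, 0.5, 0.25, 0.1):
                    cand = np.clip(theta + factor * delta, floor, None)
                    _, _, ll_cand = self._pieces(cand)
                    if ll_cand >= ll - 1e-12:
                        theta = cand
                        step_ok = True
                        break
            except np.linalg.LinAlgError:
                pass
            if not step_ok:
                # EM-style fallback step (always uphill, slower)
                em = theta + theta**2 * np.array(
                    [
                        (float(Py @ KPy[c]) - np.sum(P * K)) / n
                        for c, K in enumerate(kernels)
                    ]
                )
                theta = np.clip(em, floor, None)
        else:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations", traj
            )
        se = self._ai_se(theta)
        return VarianceComponentResults(
            names=self.names,
            sigma2=dict(zip(self.names, theta[:-1])),
            sigma2_residual=float(theta[-1]),
            se=se,
            loglik=traj[-1],
            trajectory=np.asarray(traj),
            converged=converged,
            n=n,
            model=self,
        )

    def _ai_se(self, theta) -> dict:
        """Standard errors from the average-information matrix at the optimum."""
        kernels = self.Ks + [np.eye(len(self.y))]
        try:
            P, Py, _ = self._pieces(np.clip(theta, 1e-10, None))
        except np.linalg.LinAlgError:
            return {}
        KPy = [K @ Py for K in kernels]
        PKPy = [P @ v for v in KPy]
        m = len(kernels)
        AI = 0.5 * np.array(
            [[float(KPy[a] @ PKPy[b]) for b in range(m)] for a in range(m)]
        )
        try:
            cov = np.linalg.inv(AI)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return {}
        out = dict(zip(self.names, sd[:-1]))
        out["residual"] = float(sd[-1])
        return out


@dataclass
class VarianceComponentResults:
    """Fitted variance components with uncertainties and diagnostics."""

    names: list
    sigma2: dict
    sigma2_residual: float
    se: dict
    loglik: float
    trajectory: np.ndarray
    converged: bool
    n: int
    model: VarianceComponentModel = field(repr=False, default=None)

    @property
    def sigma2_total(self) -> float:
        return sum(self.sigma2.values()) + self.sigma2_residual

    @property
    def varexp(self) -> float:
        """Fraction of variance explained by all random terms."""
        return sum(self.sigma2.values()) / self.sigma2_total

    def varexp_component(self, name: str) -> float:
        return self.sigma2[name] / self.sigma2_total

    def summary(self) -> str:
        lines = [
            "Variance components (REML)",
            "--------------------------",
            f"n = {self.n}   log-lik = {self.loglik:.3f}   converged = {self.converged}",
        ]
        for name in self.names:
            se = self.se.get(name)
            se_s = f" (SE {se:.4g})" if se is not None else ""
            lines.append(
                f"  sigma2[{name}] = {self.sigma2[name]:.5g}{se_s}"
                f"   fraction = {self.varexp_component(name):.4f}"
            )
        se = self.se.get("residual")
        se_s = f" (SE {se:.4g})" if se is not None else ""
        lines.append(f"  sigma2[residual] = {self.sigma2_residual:.5g}{se_s}")
        lines.append(f"  variance explained = {self.varexp:.4f}")
        return "\n".join(lines)


@dataclass
class VariancePartition:
    """Four-way partition of trait variance between two random designs."""

    a_exclusive: float
    b_exclusive: float
    shared: float
    residual: float
    labels: tuple = ("genotype", "expression")
    se: dict = field(default_factory=dict)
    n: int = 0

    def __post_init__(self):
        total = self.a_exclusive + self.b_exclusive + self.shared + self.residual
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"partition components sum to {total}, not 1")

    def as_dict(self) -> dict:
        return {
            f"{self.labels[0]}_exclusive": self.a_exclusive,
            f"{self.labels[1]}_exclusive": self.b_exclusive,
            "shared": self.shared,
            "residual": self.residual,
        }

    def summary(self) -> str:
        lines = [f"Variance partition (n = {self.n})", "-" * 32]
        for k, v in self.as_dict().items():
            lines.append(f"  {k:>22s}: {v:7.4f}")
        return "\n".join(lines)


def _difference_partition(r_a, r_b, r_ab, labels, n, se=None) -> VariancePartition:
    shared = r_a + r_b - r_ab
    a_ex = r_ab - r_b
    b_ex = r_ab - r_a
    resid = 1.0 - r_ab
    comps = np.array([a_ex, b_ex, shared, resid])
    if np.any(comps < 0):
        logger.info("clipping negative partition components %s", comps)
        comps = np.clip(comps, 0.0, None)
    total = comps.sum()
    if total <= 0:
        comps = np.array([0.0, 0.0, 0.0, 1.0])
    else:
        comps = comps / total
    return VariancePartition(
        a_exclusive=float(comps[0]),
        b_exclusive=float(comps[1]),
        shared=float(comps[2]),
        residual=float(comps[3]),
        labels=labels,
        se=se or {},
        n=n,
    )


def partition_fitness(y, W_g, W_e) -> VariancePartition:
    """Partition trait variance among genotype, expression, shared, residual.

    Fits the genotype-only, expression-only and joint mixed models and
    applies the difference algebra; components are fractions of var(y).
    """
    y = np.asarray(y, dtype=float)
    r_g = VarianceComponentModel(y, {"g": W_g}).fit()
    r_e = VarianceComponentModel(y, {"e": W_e}).fit()
    r_ge = VarianceComponentModel(y, {"g": W_g, "e": W_e}).fit()
    se = {
        "genotype": r_g.se.get("g"),
        "expression": r_e.se.get("e"),
    }
    return _difference_partition(
        r_g.varexp, r_e.varexp, r_ge.varexp, ("genotype", "expression"), len(y), se
    )


def partition_cis_trans(y_gene, W_cis, W_trans) -> VariancePartition:
    """Partition a gene's expression variance between cis- and trans-eQTL.

    A gene with no cis-eQTL has cis fraction exactly 0 by definition; both
    designs empty is an error.
    """
    y = np.asarray(y_gene, dtype=float)
    n_cis = 0 if W_cis is None else np.asarray(W_cis).shape[1]
    n_trans = 0 if W_trans is None else np.asarray(W_trans).shape[1]
    if n_cis == 0 and n_trans == 0:
        raise ValueError("gene has neither cis- nor trans-eQTL")
    if n_cis == 0:
        r_t = VarianceComponentModel(y, {"trans": W_trans}).fit()
        return VariancePartition(
            a_exclusive=0.0,
            b_exclusive=float(r_t.varexp),
            shared=0.0,
            residual=float(1.0 - r_t.varexp),
            labels=("cis", "trans"),
            se={"trans": r_t.se.get("trans")},
            n=len(y),
        )
    if n_trans == 0:
        r_c = VarianceComponentModel(y, {"cis": W_cis}).fit()
        return VariancePartition(
            a_exclusive=float(r_c.varexp),
            b_exclusive=0.0,
            shared=0.0,
            residual=float(1.0 - r_c.varexp),
            labels=("cis", "trans"),
            se={"cis": r_c.se.get("cis")},
            n=len(y),
        )
    r_c = VarianceComponentModel(y, {"cis": W_cis}).fit()
    r_t = VarianceComponentModel(y, {"trans": W_trans}).fit()
    r_ct = VarianceComponentModel(y, {"cis": W_cis, "trans": W_trans}).fit()
    return _difference_partition(
        r_c.varexp, r_t.varexp, r_ct.varexp, ("cis", "trans"), len(y)
    )


@dataclass
class ExpressionPCA:
    """PCA of the expression matrix used to orthogonalize heritability."""

    eigenvalues: np.ndarray
    cumulative_fraction: np.ndarray
    scores: np.ndarray  # samples × PCs
    k: int  # PCs reaching the variance threshold


def expression_heritability(
    expression: np.ndarray,
    W_g: np.ndarray,
    pc_variance_threshold: float = 0.99,
    per_gene: bool = False,
):
    """Overall (PCA-weighted) expression heritability, optionally per gene.

    PCA orthogonalizes the expression matrix; the minimal k PCs reaching
    ``pc_variance_threshold`` of total variance are each fitted against the
    genotype random effect, and the overall heritability is the
    eigenvalue-share weighted sum Σ (λ_i/Σλ)·R²_i.  With the threshold at 1
    and genotype fully determining expression this reduces to 1.

    Returns ``(overall, pca, per_gene_h2)``; ``per_gene_h2`` is None unless
    requested.
    """
    E = np.asarray(expression, dtype=float)
    n = E.shape[0]
    centered = E - E.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total == 0:
        raise ValueError("expression matrix has zero variance")
    cum = np.cumsum(eig) / total
    k = int(np.searchsorted(cum, pc_variance_threshold) + 1)
    k = min(k, len(eig))
    if k >= n:
        raise ValueError("variance threshold requires as many PCs as samples")
    scores = U * s
    overall = 0.0
    for i in range(k):
        res = VarianceComponentModel(scores[:, i], {"g": W_g}).fit()
        overall += (eig[i] / total) * res.varexp
    pca = ExpressionPCA(eig, cum, scores, k)
    per_gene_h2 = None
    if per_gene:
        per_gene_h2 = np.empty(E.shape[1])
        for g in range(E.shape[1]):
            col = E[:, g]
            if col.std() == 0:
                per_gene_h2[g] = np.nan
                continue
            per_gene_h2[g] = VarianceComponentModel(col, {"g": W_g}).fit().varexp
    return float(overall), pca, per_gene_h2
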