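"""L0-penalized, cross-validated stepwise forward search for QTL/eQTL mapping.

The objective is F_o(β) = ‖y − Xβ‖² + λ‖β‖₀: residual sum of squares plus
a per-locus penalty.  The search greedily adds the RSS-minimizing locus
(with a full refit of all effects at every step), runs a single-swap
refinement pass around each local optimum, and stops when no addition
lowers F_o.  λ is chosen by 10-fold cross-validation against held-out
prediction error with a hard floor at log(n) (the BIC penalty, which is
consistent); per-gene eQTL scans use λ = log(n) directly.

All candidate evaluations run on the Gram matrix, so a full scan over
thousands of loci per step costs one small linear solve per candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._utils import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "SparseFitConfig",
    "QTLModel",
    "forward_search",
    "forward_path",
    "cv_lambda",
    "map_qtl",
    "map_eqtl",
    "power_analysis",
]


@dataclass
class SparseFitConfig:
    """Knobs of the sparse scan: folds, model-size cap, refinement, seed."""

    n_folds: int = 10
    max_k: int | None = None  # default min(n/10, 300) at fit time
    refine: bool = True
    refine_sweeps: int = 5
    seed: int = 0

    def resolved_max_k(self, n: int) -> int:
        if self.max_k is not None:
            return self.max_k
        return max(1, min(n // 10, 300))


@dataclass
class QTLModel:
    """A fitted sparse linear model: selected loci, effects, objective."""

    sites: np.ndarray  # ordered selected column indices
    beta: np.ndarray  # effects at the selected sites (centered design)
    intercept: float
    rss: float
    objective: float
    lam: float
    r2: float
    n: int

    @property
    def size(self) -> int:
        return len(self.sites)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.size == 0:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.sites] @ self.beta

    def to_dict(self) -> dict:
        return {
            "sites": [int(s) for s in self.sites],
            "beta": [float(b) for b in self.beta],
            "intercept": self.intercept,
            "rss": self.rss,
            "objective": self.objective,
            "lambda": self.lam,
            "r2": self.r2,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QTLModel":
        return cls(
            np.asarray(d["sites"], dtype=int),
            np.asarray(d["beta"], dtype=float),
            d["intercept"],
            d["rss"],
            d["objective"],
            d["lambda"],
            d["r2"],
            d["n"],
        )

    def summary(self) -> str:
        lines = [
            "Sparse QTL model",
            "----------------",
            f"n = {self.n}   lambda = {self.lam:.3f}   loci = {self.size}",
            f"RSS = {self.rss:.4f}   F_o = {self.objective:.4f}   R2 = {self.r2:.4f}",
        ]
        for s, b in zip(self.sites, self.beta):
            lines.append(f"  site {int(s):>6d}  beta = {b:+.4f}")
        return "\n".join(lines)


class _GramSearch:
    """Forward selection on precomputed Gram statistics."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on n")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("X has non-finite entries")
        self._from_raw(X.shape[0], X.T @ X, X.sum(axis=0), X.T @ y, float(y.sum()),
                       float(y @ y))

    @classmethod
    def from_raw_stats(cls, n, Sxx, sx, Sxy, sy, Syy) -> "_GramSearch":
        """Build from uncentered cross-products (supports fold subtraction)."""
        obj = cls.__new__(cls)
        obj._from_raw(n, Sxx, sx, Sxy, sy, Syy)
        return obj

    def _from_raw(self, n, Sxx, sx, Sxy, sy, Syy):
        self.n, self.p = n, len(sx)
        self.x_mean = sx / n
        self.y_mean = sy / n
        self.G = Sxx - np.outer(sx, sx) / n
        self.b = Sxy - sx * sy / n
        self.yty = max(float(Syy - sy * sy / n), 0.0)
        self.diag = np.diag(self.G).copy()

    def rss(self, S: list) -> float:
        if not S:
            return self.yty
        beta = self._beta(S)
        return max(self.yty - float(self.b[S] @ beta), 0.0)

    def _beta(self, S: list) -> np.ndarray:
        Gs = self.G[np.ix_(S, S)]
        return linalg.solve(Gs, self.b[S], assume_a="pos")

    def best_addition(self, S: list) -> tuple:
        """(site, RSS improvement) of the best single addition to S."""
        if not S:
            denom = np.where(self.diag > 1e-12, self.diag, np.inf)
            gain = self.b**2 / denom
        else:
            Gs = self.G[np.ix_(S, S)]
            cfac = linalg.cho_factor(Gs)
            beta = linalg.cho_solve(cfac, self.b[S])
            Gsa = self.G[S, :]  # k × p
            W = linalg.cho_solve(cfac, Gsa)  # k × p
            num = self.b - beta @ Gsa
            denom = self.diag - np.einsum("kp,kp->p", Gsa, W)
            denom = np.where(denom > 1e-10 * np.maximum(self.diag, 1.0), denom, np.inf)
            gain = num**2 / denom
            gain[S] = -np.inf
        j = int(np.argmax(gain))  # ties resolve to the lowest index
        return j, float(gain[j])

    def refine(self, S: list, max_sweeps: int) -> list:
        """Single-swap local search: replace any selected locus if a strict
        RSS improvement exists; iterate to a local optimum."""
        S = list(S)
        if len(S) < 2:
            return S
        for _ in range(max_sweeps):
            improved = False
            base = self.rss(S)
            for idx in range(len(S)):
                rest = S[:idx] + S[idx + 1 :]
                j, gain = self.best_addition(rest)
                cand_rss = self.rss(rest) - gain
                if j not in S and cand_rss < base - 1e-10:
                    S = rest + [j]
                    base = cand_rss
                    improved = True
            if not improved:
                break
        return S


def _finalize(gram: _GramSearch, S: list, lam: float) -> QTLModel:
    S = list(S)
    rss = gram.rss(S)
    if S:
        beta = gram._beta(S)
        intercept = gram.y_mean - float(gram.x_mean[S] @ beta)
    else:
        beta = np.empty(0)
        intercept = gram.y_mean
    r2 = 1.0 - rss / gram.yty if gram.yty > 0 else 0.0
    return QTLModel(
        sites=np.asarray(S, dtype=int),
        beta=np.asarray(beta, dtype=float),
        intercept=float(intercept),
        rss=float(rss),
        objective=float(rss + lam * len(S)),
        lam=float(lam),
        r2=float(r2),
        n=gram.n,
    )


def forward_search(
    X, y, lam: float, max_k: int | None = None, config: SparseFitConfig | None = None
) -> QTLModel:
    """Greedy L0 forward search at a fixed penalty λ.

    Adds the RSS-minimizing locus (full refit each step), refines by
    single-locus swaps, and stops when no addition lowers the objective
    F_o = RSS + λ·‖β‖₀ or the model-size cap is hit.  A constant response
    returns the intercept-only model.
    """
    config = config or SparseFitConfig()
    gram = _GramSearch(X, y)
    if gram.yty <= 1e-12:
        return _finalize(gram, [], lam)
    if max_k is None:
        max_k = config.resolved_max_k(gram.n)
    S: list = []
    rss = gram.yty
    while len(S) < max_k:
        j, gain = gram.best_addition(S)
        if gain <= lam or not np.isfinite(gain):
            break
        S.append(j)
        if config.refine:
            S = gram.refine(S, config.refine_sweeps)
        new_rss = gram.rss(S)
        assert new_rss <= rss + 1e-8  # F_o strictly decreases by > 0 each step
        rss = new_rss
    return _finalize(gram, S, lam)


def forward_path(
    X, y, max_k: int, config: SparseFitConfig | None = None, lam_floor: float = 0.0
):
    """Greedy path: list of (model sites, RSS) for sizes 0..K plus the
    per-step RSS improvements (the λ thresholds along the path).

    The path stops once an improvement drops to ``lam_floor``: no penalty
    at or above the floor can ever select a longer prefix.
    """
    gram = _GramSearch(X, y)
    models, imps = _path_on_gram(gram, max_k, config, lam_floor)
    return gram, models, imps


def _path_on_gram(
    gram: "_GramSearch", max_k, config: SparseFitConfig | None, lam_floor: float
):
    config = config or SparseFitConfig()
    S: list = []
    rss = gram.yty
    models = [(list(S), rss)]
    improvements = []
    while len(S) < max_k:
        j, gain = gram.best_addition(S)
        if gain <= max(1e-12, lam_floor) or not np.isfinite(gain):
            break
        S.append(j)
        if config.refine:
            S = gram.refine(S, config.refine_sweeps)
        new_rss = gram.rss(S)
        improvements.append(rss - new_rss)
        rss = new_rss
        models.append((list(S), rss))
    return models, np.asarray(improvements)


def _path_prefix_for_lambda(improvements: np.ndarray, lam: float) -> int:
    """Model size selected by λ: stop at the first step whose RSS improvement
    does not exceed λ."""
    for k, imp in enumerate(improvements):
        if imp <= lam:
            return k
    return len(improvements)


def cv_lambda(X, y, config: SparseFitConfig | None = None) -> tuple:
    """Cross-validated penalty: λ* = mean over folds of the per-fold optimum.

    Each fold fits a forward path on its training split; candidate λ values
    (every fold's per-step RSS improvements, floored at log(n_train)) are
    shared across folds, and each fold records the λ whose implied model
    minimizes its held-out prediction error — ties resolved to the largest
    λ, i.e. the sparsest model, so pure-noise responses drive λ* above the
    largest observed noise improvement.  Returns ``(lam_star, per_fold)``.
    """
    config = config or SparseFitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if config.n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < config.n_folds:
        raise ValueError("n must be at least the number of folds")
    rng = as_rng(config.seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, config.n_folds)

    # uncentered cross-products once; per-fold training stats by subtraction
    Sxx = X.T @ X
    sx = X.sum(axis=0)
    Sxy = X.T @ y
    sy = float(y.sum())
    Syy = float(y @ y)

    folds = []
    candidates = set()
    for f in fold_ids:
        Xte, yte = X[f], y[f]
        n_tr = n - len(f)
        floor = np.log(n_tr)
        gram = _GramSearch.from_raw_stats(
            n_tr,
            Sxx - Xte.T @ Xte,
            sx - Xte.sum(axis=0),
            Sxy - Xte.T @ yte,
            sy - float(yte.sum()),
            Syy - float(yte @ yte),
        )
        max_k = config.resolved_max_k(n_tr)
        models, imps = _path_on_gram(gram, max_k, config, lam_floor=floor)
        folds.append((gram, models, imps, Xte, yte, floor))
        candidates.add(floor)
        candidates.update(float(v) for v in imps)
    grid = np.array(sorted(candidates))

    lams = []
    for gram, models, imps, Xte, yte, floor in folds:
        # held-out error per reachable prefix
        errs = np.empty(len(models))
        for k, (sites, _) in enumerate(models):
            model = _finalize(gram, sites, floor)
            errs[k] = float(np.mean((yte - model.predict(Xte)) ** 2))
        usable = grid[grid >= floor]
        fold_errs = np.array(
            [errs[_path_prefix_for_lambda(imps, lam)] for lam in usable]
        )
        best = fold_errs.min()
        # ties to the largest λ: the sparsest model compatible with the data
        lams.append(float(usable[np.flatnonzero(fold_errs <= best + 1e-12)[-1]]))
    lam_star = float(np.mean(lams))
    return lam_star, np.asarray(lams)


def map_qtl(
    genotypes, fitness, config: SparseFitConfig | None = None
) -> QTLModel:
    """QTL mapping: cross-validate λ, then fit the full data at λ*.

    ``genotypes`` is the strain × site consensus panel.  Both genotypes and
    the response are standardized before the scan — the per-locus penalty
    λ = log(n) is a unit-variance-residual (BIC) penalty, so effects come
    out on the standardized scale.
    """
    config = config or SparseFitConfig()
    X = np.asarray(genotypes, dtype=float)
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    y = np.asarray(fitness, dtype=float).ravel()
    if y.std() > 0:
        y = (y - y.mean()) / y.std()
    lam_star, _ = cv_lambda(Xs, y, config)
    lam_star = max(lam_star, np.log(len(y)))
    return forward_search(Xs, y, lam_star, config=config)


def map_eqtl(
    genotypes,
    expression,
    gene_names=None,
    config: SparseFitConfig | None = None,
    lam: float | None = None,
) -> dict:
    """Per-gene eQTL scan at fixed λ = log(n) (the BIC penalty).

    ``expression`` is strain × gene (normalized upstream); each gene is
    additionally standardized to unit variance so the BIC penalty is on
    the scale it assumes.  Genes with zero variance are skipped and
    logged.  Returns {gene: QTLModel}.
    """
    config = config or SparseFitConfig()
    X = np.asarray(genotypes, dtype=float)
    E = np.asarray(expression, dtype=float)
    n = X.shape[0]
    if E.shape[0] != n:
        raise ValueError("genotypes and expression disagree on n")
    if gene_names is None:
        gene_names = [f"G{g:04d}" for g in range(E.shape[1])]
    lam = np.log(n) if lam is None else max(lam, np.log(n))
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    # the genotype Gram matrix is shared by every gene's scan
    Sxx = Xs.T @ Xs
    sx = Xs.sum(axis=0)
    max_k = config.resolved_max_k(n)
    out = {}
    for g, name in enumerate(gene_names):
        col = E[:, g]
        if col.std() == 0:
            logger.info("gene %s has zero expression variance; skipped", name)
            continue
        col = (col - col.mean()) / col.std()
        gram = _GramSearch.from_raw_stats(
            n, Sxx, sx, Xs.T @ col, float(col.sum()), float(col @ col)
        )
        models, _ = _path_on_gram(gram, max_k, config, lam_floor=lam)
        out[name] = _finalize(gram, models[-1][0], lam)
    return out


def power_analysis(
    genotypes,
    expression,
    gene_names,
    sample_sizes,
    seeds,
    config: SparseFitConfig | None = None,
) -> tuple:
    """Detected eQTL signal vs sample size on a gene set.

    For each (size, seed), strains are subsampled without replacement and
    the per-gene eQTL scan re-run; the table records eQTL counts and model
    R² per gene.  Returns ``(table, fits)`` where ``fits`` maps gene →
    scipy ``LinregressResult`` of eQTL count on n (None with one size).
    """
    config = config or SparseFitConfig()
    X = np.asarray(genotypes, dtype=float)
    E = np.asarray(expression, dtype=float)
    n = X.shape[0]
    rows = []
    for size in sample_sizes:
        if size > n:
            raise ValueError(f"sample size {size} exceeds n={n}")
        for seed in seeds:
            rng = as_rng(seed)
            idx = rng.choice(n, size=size, replace=False)
            models = map_eqtl(X[idx], E[idx], gene_names, config)
            for name in gene_names:
                m = models.get(name)
                rows.append(
                    {
                        "gene": name,
                        "n": size,
                        "seed": seed,
                        "n_eqtl": 0 if m is None else m.size,
                        "r2": np.nan if m is None else m.r2,
                    }
                )
    table = pd.DataFrame(rows)
    fits = {}
    for name in gene_names:
        sub = table[table["gene"] == name]
        if sub["n"].nunique() < 2:
            fits[name] = None
        else:
            fits[name] = stats.linregress(sub["n"], sub["n_eqtl"])
    return table, fits
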