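"""Two-state HMM genotyping of pooled single cells from sparse allele counts.

Each haploid cell's genome is a BY/RM mosaic; its chromosome-wise hidden
state sequence is Markov with transition probabilities given by the Haldane
map function on the genetic map.  Observed reads at covered polymorphic
sites pass through an error/swap channel:

    P(read = RM | state) = (1 − s)·[state = RM ? 1 − ε : ε] + s·f_site

where ε is the per-read sequencing/RT error rate, s the index-swap rate and
f_site the pooled RM read frequency (a swapped read comes from the whole
pool, not a fair coin).  Forward–backward gives per-site RM posteriors —
the quantitative genotype used downstream — and also imputes uncovered
sites through the recombination process.  ε, s and a global recombination
scale are estimated from the data by Baum–Welch EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .cross import CellAlleleCounts, GeneticMap

__all__ = [
    "HMMParams",
    "CellPosterior",
    "GenotypeHMM",
    "GenotypeHMMResults",
    "emission_logprob",
    "majority_call",
    "pooled_frequencies",
]

_RMIN = 1e-12  # floor on probabilities inside logs


@dataclass
class HMMParams:
    """Error/swap/recombination parameters of the genotyping HMM.

    rec_scale multiplies the genetic-map distances, so rec_scale = 1 means
    transitions follow the map exactly; pool_freq holds the per-site RM
    read frequency used by the swap channel (defaults to 0.5 everywhere).
    """

    epsilon: float = 0.01
    swap: float = 0.0
    rec_scale: float = 1.0
    pi_rm: float = 0.5
    pool_freq: np.ndarray | None = None

    def validate(self, n_sites: int | None = None) -> None:
        for name in ("epsilon", "swap", "pi_rm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rec_scale < 0:
            raise ValueError("rec_scale must be non-negative")
        if self.pool_freq is not None:
            f = np.asarray(self.pool_freq, dtype=float)
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError("pool frequencies must lie in [0, 1]")
            if n_sites is not None and len(f) != n_sites:
                raise ValueError("pool_freq length does not match the site count")

    def freqs(self, n_sites: int) -> np.ndarray:
        if self.pool_freq is None:
            return np.full(n_sites, 0.5)
        return np.asarray(self.pool_freq, dtype=float)


@dataclass
class CellPosterior:
    """Per-cell RM posteriors (one value per site) and read log-likelihood."""

    p_rm: np.ndarray
    loglik: float


def _channel(eps: float, s: float, f: np.ndarray) -> tuple:
    """Per-read P(read=RM | state) for state BY (index 0) and RM (index 1)."""
    p_by = (1.0 - s) * eps + s * f
    p_rm = (1.0 - s) * (1.0 - eps) + s * f
    return np.clip(p_by, _RMIN, 1 - _RMIN), np.clip(p_rm, _RMIN, 1 - _RMIN)


def emission_logprob(rm_reads, by_reads, state, epsilon, swap, f_site) -> float:
    """Log-probability of (rm, by) read counts given a hidden state.

    Reads are conditionally independent given the state; `state` is "BY"/0
    or "RM"/1.
    """
    if rm_reads < 0 or by_reads < 0:
        raise ValueError("read counts must be non-negative")
    z = 1 if state in (1, "RM", "rm") else 0
    p_by, p_rm = _channel(epsilon, swap, np.asarray(f_site, dtype=float))
    p = p_rm if z == 1 else p_by
    return float(rm_reads * np.log(p) + by_reads * np.log1p(-p))


def pooled_frequencies(counts: CellAlleleCounts) -> np.ndarray:
    """Empirical pooled RM read frequency per site (0.5 where no reads)."""
    rm = np.asarray(counts.rm.sum(axis=0)).ravel().astype(float)
    by = np.asarray(counts.by.sum(axis=0)).ravel().astype(float)
    tot = rm + by
    f = np.full(len(tot), 0.5)
    nz = tot > 0
    f[nz] = rm[nz] / tot[nz]
    return f


def majority_call(counts: CellAlleleCounts) -> np.ndarray:
    """Raw RM read fraction per cell × site; NaN at uncovered sites.

    This is the uncorrected genotype estimate the HMM is compared against.
    """
    rm = counts.rm.toarray().astype(float)
    by = counts.by.toarray().astype(float)
    tot = rm + by
    with np.errstate(invalid="ignore"):
        out = np.where(tot > 0, rm / np.where(tot > 0, tot, 1.0), np.nan)
    return out


class GenotypeHMM:
    """Genotyping model for a set of cells over a genetic map.

    Parameters
    ----------
    counts
        Sparse per-cell RM/BY allele counts.
    gmap
        Genetic map shared with the counts (defaults to ``counts.gmap``).

    ``posteriors(params)`` runs forward–backward at fixed parameters;
    ``fit(start)`` estimates (ε, s, recombination scale) by Baum–Welch and
    returns a :class:`GenotypeHMMResults`.
    """

    def __init__(self, counts: CellAlleleCounts, gmap: GeneticMap | None = None):
        self.counts = counts
        self.gmap = gmap if gmap is not None else counts.gmap
        if self.gmap.n_sites != counts.rm.shape[1]:
            raise ValueError("map/site dimension mismatch")
        self._slices = self.gmap.chrom_slices()
        self._dists = self.gmap.interval_morgans()
        # dense per-chromosome read counts (cells × sites); our problem
        # sizes keep this comfortably small
        self._rm = {c: counts.rm[:, sl].toarray().astype(float) for c, sl in self._slices.items()}
        self._by = {c: counts.by[:, sl].toarray().astype(float) for c, sl in self._slices.items()}

    # -- internals ---------------------------------------------------------

    def _emissions(self, chrom, params: HMMParams) -> np.ndarray:
        """(cells × sites × 2) emission probabilities, rescaled per entry."""
        sl = self._slices[chrom]
        f = params.freqs(self.gmap.n_sites)[sl]
        p_by, p_rm = _channel(params.epsilon, params.swap, f)
        rm, by = self._rm[chrom], self._by[chrom]
        log_e = np.empty(rm.shape + (2,))
        log_e[:, :, 0] = rm * np.log(p_by) + by * np.log1p(-p_by)
        log_e[:, :, 1] = rm * np.log(p_rm) + by * np.log1p(-p_rm)
        m = log_e.max(axis=2, keepdims=True)
        e = np.exp(log_e - m)
        return e, m[:, :, 0]

    def _trans(self, chrom, params: HMMParams) -> np.ndarray:
        d = self._dists[chrom]
        r = 0.5 * (1.0 - np.exp(-2.0 * params.rec_scale * d))
        return np.clip(r, 0.0, 0.5)

    def _forward_backward(self, chrom, params: HMMParams, want_xi: bool = False):
        e, log_shift = self._emissions(chrom, params)
        r = self._trans(chrom, params)
        n_cells, m, _ = e.shape
        pi = np.array([1.0 - params.pi_rm, params.pi_rm])

        alpha = np.empty_like(e)
        scale = np.empty((n_cells, m))
        a = pi[None, :] * e[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for t in range(1, m):
            stay, sw = 1.0 - r[t - 1], r[t - 1]
            prev = alpha[:, t - 1, :]
            a = np.empty_like(prev)
            a[:, 0] = prev[:, 0] * stay + prev[:, 1] * sw
            a[:, 1] = prev[:, 0] * sw + prev[:, 1] * stay
            a *= e[:, t, :]
            scale[:, t] = a.sum(axis=1)
            alpha[:, t, :] = a / scale[:, t, None]

        beta = np.empty_like(e)
        beta[:, m - 1, :] = 1.0
        for t in range(m - 2, -1, -1):
            stay, sw = 1.0 - r[t], r[t]
            nxt = beta[:, t + 1, :] * e[:, t + 1, :]
            b = np.empty_like(nxt)
            b[:, 0] = nxt[:, 0] * stay + nxt[:, 1] * sw
            b[:, 1] = nxt[:, 0] * sw + nxt[:, 1] * stay
            beta[:, t, :] = b / scale[:, t + 1, None]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        loglik = np.log(scale).sum(axis=1) + log_shift.sum(axis=1)

        if not want_xi:
            return gamma, loglik, None
        # expected stay/switch counts per interval, summed over cells
        stay_ct = np.empty(m - 1)
        switch_ct = np.empty(m - 1)
        for t in range(m - 1):
            stay, sw = 1.0 - r[t], r[t]
            nb = beta[:, t + 1, :] * e[:, t + 1, :] / scale[:, t + 1, None]
            a = alpha[:, t, :]
            x00 = a[:, 0] * stay * nb[:, 0]
            x01 = a[:, 0] * sw * nb[:, 1]
            x10 = a[:, 1] * sw * nb[:, 0]
            x11 = a[:, 1] * stay * nb[:, 1]
            stay_ct[t] = x00.sum() + x11.sum()
            switch_ct[t] = x01.sum() + x10.sum()
        return gamma, loglik, (stay_ct, switch_ct)

    # -- public API --------------------------------------------------------

    def posteriors(self, params: HMMParams):
        """Forward–backward RM posteriors for every cell.

        Returns ``(p_rm, loglik)``: a (cells × sites) array of P(state = RM)
        and the per-cell read log-likelihood.  Cells without any read get
        flat posteriors at π_RM (with a warning).
        """
        params.validate(self.gmap.n_sites)
        n_cells = self.counts.n_cells
        post = np.empty((n_cells, self.gmap.n_sites))
        loglik = np.zeros(n_cells)
        for c, sl in self._slices.items():
            gamma, ll, _ = self._forward_backward(c, params)
            post[:, sl] = gamma[:, :, 1]
            loglik += ll
        if np.any(self.counts.coverage() == 0):
            warnings.warn("cells with zero reads received flat posteriors")
        return post, loglik

    def cell_posterior(self, cell_index: int, params: HMMParams) -> CellPosterior:
        post, ll = self.posteriors(params)
        return CellPosterior(post[cell_index], float(ll[cell_index]))

    def loglik(self, params: HMMParams) -> float:
        _, ll = self.posteriors(params)
        return float(ll.sum())

    def fit(
        self,
        start: HMMParams | None = None,
        panel=None,
        estimate: tuple = ("epsilon", "swap", "rec_scale"),
        max_iter: int = 200,
        tol: float = 1e-6,
    ) -> "GenotypeHMMResults":
        """Estimate (ε, s, recombination scale) from the read data.

        Stage one is Baum–Welch EM with pool frequencies held fixed (the
        empirical pooled read frequencies unless ``start.pool_freq`` or a
        ``panel`` supplies them); the total log-likelihood is non-decreasing
        across iterations (generalized EM: every M-step must improve the
        expected complete-data log-likelihood).

        At the breadth of coverage this package targets (~3% of sites per
        cell), ε and s are nearly confounded in a panel whose allele
        frequencies hover around ½: both act through the per-read mismatch
        probability, and the weak per-site frequency deviations that
        separate them are contaminated by the panel's own sampling noise
        and by doublet reads.  When a reference ``panel`` is given, a
        second stage therefore anchors the channel: cells are provisionally
        matched to their nearest panel strain by expected distance, cells
        whose mismatch rate is an outlier (doublets, bad matches) are
        dropped, and (ε, s) are re-estimated by direct likelihood
        maximization with the matched strain's alleles as known states —
        which separates the error channel (state-dependent) from the swap
        channel (pool-frequency-dependent).
        """
        if self.counts.coverage().max(initial=0) < 2:
            raise ValueError("need at least one cell with ≥2 covered sites")
        params = replace(start) if start is not None else HMMParams()
        if params.pool_freq is None:
            if panel is not None:
                params.pool_freq = panel.genotypes.mean(axis=0)
            else:
                params.pool_freq = pooled_frequencies(self.counts)
        params.validate(self.gmap.n_sites)

        rm_tot = np.asarray(self.counts.rm.sum()).item()
        by_tot = np.asarray(self.counts.by.sum()).item()
        degenerate = rm_tot == 0 or by_tot == 0
        if degenerate:
            warnings.warn("all reads report a single allele; estimates are boundary values")

        path = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            # E-step: posteriors + sufficient statistics
            ll_total = 0.0
            a_by = np.zeros(self.gmap.n_sites)  # Σ γ_BY · rm
            b_by = np.zeros(self.gmap.n_sites)  # Σ γ_BY · by
            a_rm = np.zeros(self.gmap.n_sites)
            b_rm = np.zeros(self.gmap.n_sites)
            stays, switches, dists = [], [], []
            for c, sl in self._slices.items():
                gamma, ll, (st, sw) = self._forward_backward(c, params, want_xi=True)
                ll_total += float(ll.sum())
                rm, by = self._rm[c], self._by[c]
                a_by[sl] = (gamma[:, :, 0] * rm).sum(axis=0)
                b_by[sl] = (gamma[:, :, 0] * by).sum(axis=0)
                a_rm[sl] = (gamma[:, :, 1] * rm).sum(axis=0)
                b_rm[sl] = (gamma[:, :, 1] * by).sum(axis=0)
                stays.append(st)
                switches.append(sw)
                dists.append(self._dists[c])
            path.append(ll_total)
            if ll_total - prev < tol * max(1.0, abs(prev)) and it > 0:
                converged = True
                break
            prev = ll_total

            # M-step: emission channel (ε, s)
            f = params.freqs(self.gmap.n_sites)

            def neg_q_em(x):
                eps, s = x
                p_by, p_rm = _channel(eps, s, f)
                q = (
                    a_by * np.log(p_by)
                    + b_by * np.log1p(-p_by)
                    + a_rm * np.log(p_rm)
                    + b_rm * np.log1p(-p_rm)
                ).sum()
                return -q

            x0 = np.array([params.epsilon, params.swap])
            if "epsilon" in estimate or "swap" in estimate:
                b_eps = (1e-6, 0.49) if "epsilon" in estimate else (x0[0], x0[0])
                b_s = (1e-6, 0.95) if "swap" in estimate else (x0[1], x0[1])
                res = optimize.minimize(
                    neg_q_em,
                    np.clip(x0, [b_eps[0], b_s[0]], [b_eps[1], b_s[1]]),
                    method="L-BFGS-B",
                    bounds=[b_eps, b_s],
                )
                if res.fun <= neg_q_em(x0):
                    params.epsilon, params.swap = float(res.x[0]), float(res.x[1])

            # M-step: global recombination scale
            if "rec_scale" in estimate:
                st = np.concatenate(stays) if stays else np.array([])
                sw = np.concatenate(switches) if switches else np.array([])
                d = np.concatenate(dists) if dists else np.array([])
                pos = d > 0
                if pos.any():

                    def neg_q_tr(c):
                        r = 0.5 * (1.0 - np.exp(-2.0 * c * d[pos]))
                        r = np.clip(r, _RMIN, 0.5 - _RMIN)
                        return -(st[pos] * np.log1p(-r) + sw[pos] * np.log(r)).sum()

                    res = optimize.minimize_scalar(
                        neg_q_tr, bounds=(1e-4, 100.0), method="bounded"
                    )
                    if res.fun <= neg_q_tr(params.rec_scale):
                        params.rec_scale = float(res.x)
        if panel is not None and ("epsilon" in estimate or "swap" in estimate):
            params = self._refine_channel_with_panel(params, panel, estimate)
            path.append(self.loglik(params))
        return GenotypeHMMResults(
            model=self,
            params=params,
            loglik_path=np.asarray(path),
            converged=converged,
            n_iter=len(path),
        )

    def _refine_channel_with_panel(self, params, panel, estimate) -> HMMParams:
        """Split ε from s using provisional strain matches as known states."""
        post, _ = self.posteriors(params)
        G = panel.genotypes
        sc = post.sum(axis=1)
        ss = G.sum(axis=1)
        dist = sc[:, None] + ss[None, :] - 2.0 * (post @ G.T)
        best = np.argmin(dist, axis=1)
        alleles = G[best]  # matched strain's hard genotype per cell × site

        rm = self.counts.rm.toarray().astype(float)
        by = self.counts.by.toarray().astype(float)
        tot = rm + by
        # mismatch rate vs matched strain; doublets and spurious matches
        # stick out far above the error/swap channel's rate
        mismatch = np.where(alleles > 0.5, by, rm).sum(axis=1)
        cov = tot.sum(axis=1)
        ok_cov = cov > 0
        rate = np.where(ok_cov, mismatch / np.where(ok_cov, cov, 1), np.nan)
        med = np.nanmedian(rate)
        mad = np.nanmedian(np.abs(rate - med)) + 1e-6
        keep = ok_cov & (rate <= med + 2 * 1.4826 * mad)
        if keep.sum() < 10:
            return params
        f = params.freqs(self.gmap.n_sites)
        is_rm = alleles[keep] > 0.5
        rm_k, by_k = rm[keep], by[keep]
        # per-site sufficient statistics by matched-state allele
        rm_a1 = (rm_k * is_rm).sum(axis=0)
        by_a1 = (by_k * is_rm).sum(axis=0)
        rm_a0 = (rm_k * ~is_rm).sum(axis=0)
        by_a0 = (by_k * ~is_rm).sum(axis=0)

        def nll(x):
            eps, s = x
            p_by, p_rm = _channel(eps, s, f)
            return -(
                rm_a1 * np.log(p_rm)
                + by_a1 * np.log1p(-p_rm)
                + rm_a0 * np.log(p_by)
                + by_a0 * np.log1p(-p_by)
            ).sum()

        b_eps = (1e-6, 0.49) if "epsilon" in estimate else (params.epsilon, params.epsilon)
        b_s = (1e-6, 0.95) if "swap" in estimate else (params.swap, params.swap)
        best_x, best_f = None, np.inf
        for x0 in ([params.epsilon, params.swap], [0.02, 0.02], [0.1, 0.1]):
            x0 = np.clip(x0, [b_eps[0], b_s[0]], [b_eps[1], b_s[1]])
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=[b_eps, b_s])
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
        out = replace(params)
        out.epsilon, out.swap = float(best_x[0]), float(best_x[1])
        return out


@dataclass
class GenotypeHMMResults:
    """Fitted genotyping HMM: estimated parameters and diagnostics."""

    model: GenotypeHMM
    params: HMMParams
    loglik_path: np.ndarray
    converged: bool
    n_iter: int

    def posteriors(self):
        return self.model.posteriors(self.params)

    def summary(self) -> str:
        lines = [
            "Genotyping HMM (Baum-Welch)",
            "---------------------------",
            f"cells:                {self.model.counts.n_cells}",
            f"sites:                {self.model.gmap.n_sites}",
            f"error rate (eps):     {self.params.epsilon:.5f}",
            f"index-swap rate (s):  {self.params.swap:.5f}",
            f"recomb. scale:        {self.params.rec_scale:.4f}",
            f"log-likelihood:       {self.loglik_path[-1]:.3f}",
            f"iterations:           {self.n_iter} (converged={self.converged})",
        ]
        return "\n".join(lines)
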