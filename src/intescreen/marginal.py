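"""Marginal logistic fits per gene per study, and cross-study gene ranking.

The screening statistic for gene j combines the slopes of the M one-gene
logistic regressions

    logit P(Y^m = 1 | x_j^m) = beta_j0^m + beta_j^m x_j^m,   m = 1..M,

each fitted by maximum likelihood on standardized expressions. The default
statistic is the magnitude of the across-study mean slope |sum_m b_jm / K_j|
(K_j = number of studies measuring gene j); L2, max and min magnitude
variants are available. Genes are ranked by the statistic (rank 1 =
largest) and selected either by threshold, by a top fraction/count, or by
the data-dependent stopping rule in :mod:`intescreen.threshold`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import chi2

from .datamodel import MultiStudyCollection, StudyDataset

logger = logging.getLogger("intescreen")

__all__ = [
    "BETA_CAP",
    "MarginalFit",
    "MarginalFitTable",
    "RankingTable",
    "fit_marginal",
    "fit_logistic_columns",
    "fit_collection",
    "rank_mean",
    "rank_variant",
    "select_threshold",
    "select_top",
    "force_include",
    "write_ranking",
]

#: Slope magnitude at which a fit is truncated and flagged as separated.
#: On standardized expressions a slope of 15 corresponds to odds ratios
#: beyond any biologically meaningful effect; capping keeps the ranking
#: statistic finite and monotone in the evidence when a gene perfectly
#: splits the two response classes (common at n ~ 15).
BETA_CAP = 15.0

_MAX_ITER = 50
_LL_TOL = 1e-10


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Bernoulli log-likelihood for linear predictors eta."""
    # log L = sum_i [ y_i eta_i - log(1 + e^{eta_i}) ]
    return (y[:, None] * eta).sum(axis=0) - np.logaddexp(0.0, eta).sum(axis=0)


def fit_logistic_columns(X, y, cap: float = BETA_CAP, max_iter: int = _MAX_ITER,
                         tol: float = _LL_TOL):
    """Fit a two-parameter logistic model to every column of X at once.

    Newton-Raphson from the intercept-only solution, vectorized across
    genes, with per-gene step damping (step halving whenever a step would
    decrease the log-likelihood). Slopes are truncated at ``cap`` and the
    fit flagged separated when the cap binds.

    Returns dict of arrays over columns: beta0, beta, loglik, converged,
    separated, pvalue (likelihood-ratio test against the intercept-only
    model), plus the scalar intercept-only log-likelihood ``loglik0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.shape}, expected {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("response has a single class; marginal logistic MLE does not exist")
    ybar = n1 / n
    ll0 = n1 * np.log(ybar) + (n - n1) * np.log1p(-ybar)

    a = np.full(d, logit(ybar))
    b = np.zeros(d)
    ll = np.full(d, ll0)
    converged = np.zeros(d, dtype=bool)
    active = np.arange(d)

    for _ in range(max_iter):
        if active.size == 0:
            break
        Xa = X[:, active]
        aa, ba = a[active], b[active]
        eta = aa[None, :] + Xa * ba[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (Xa * r).sum(axis=0)
        h00 = w.sum(axis=0)
        wx = w * Xa
        h01 = wx.sum(axis=0)
        h11 = (wx * Xa).sum(axis=0)
        det = np.maximum(h00 * h11 - h01 * h01, 1e-300)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        # cap the step length so a near-singular Hessian cannot fling the
        # iterate; separation then walks to the slope cap in a few steps
        biggest = np.maximum(np.abs(da), np.abs(db))
        shrink = np.minimum(1.0, 4.0 / np.maximum(biggest, 1e-12))
        da *= shrink
        db *= shrink

        new_a = aa + da
        new_b = np.clip(ba + db, -cap, cap)
        new_ll = _bernoulli_loglik(new_a[None, :] + Xa * new_b[None, :], y)
        for _halve in range(12):
            dec = np.flatnonzero(new_ll < ll[active] - 1e-12)
            if dec.size == 0:
                break
            da[dec] *= 0.5
            db[dec] *= 0.5
            ca = aa[dec] + da[dec]
            cb = np.clip(ba[dec] + db[dec], -cap, cap)
            cll = _bernoulli_loglik(ca[None, :] + Xa[:, dec] * cb[None, :], y)
            new_a[dec], new_b[dec], new_ll[dec] = ca, cb, cll
        still_dec = new_ll < ll[active] - 1e-12
        # revert any column that could not improve even after damping
        new_a = np.where(still_dec, aa, new_a)
        new_b = np.where(still_dec, ba, new_b)
        new_ll = np.where(still_dec, ll[active], new_ll)

        delta = new_ll - ll[active]
        a[active], b[active], ll[active] = new_a, new_b, new_ll
        done = (np.abs(delta) < tol) & ~still_dec
        stuck = still_dec
        converged[active[done]] = True
        active = active[~(done | stuck)]

    separated = np.abs(b) >= cap - 1e-9
    converged = converged & ~separated
    pvalue = chi2.sf(np.maximum(2.0 * (ll - ll0), 0.0), df=1)
    return {
        "beta0": a, "beta": b, "loglik": ll, "converged": converged,
        "separated": separated, "pvalue": pvalue, "loglik0": ll0,
    }


@dataclass
class MarginalFit:
    """One gene's marginal logistic fit in one study."""

    beta0: float
    beta: float
    loglik: float
    converged: bool
    separated: bool
    pvalue: float


def fit_marginal(x, y, cap: float = BETA_CAP) -> MarginalFit:
    """Fit the one-gene logistic model for a single standardized column."""
    res = fit_logistic_columns(np.asarray(x, dtype=float)[:, None], y, cap=cap)
    return MarginalFit(
        beta0=float(res["beta0"][0]),
        beta=float(res["beta"][0]),
        loglik=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
        separated=bool(res["separated"][0]),
        pvalue=float(res["pvalue"][0]),
    )


@dataclass
class MarginalFitTable:
    """Per-gene per-study marginal fits over a collection's gene universe.

    Arrays are (n_genes, M); entries for gene/study pairs the study does
    not measure are NaN (False for the boolean flags).
    """

    gene_ids: list
    study_ids: list
    beta0: np.ndarray
    beta: np.ndarray
    loglik: np.ndarray
    pvalue: np.ndarray
    converged: np.ndarray
    separated: np.ndarray
    loglik0: np.ndarray  # per-study intercept-only log-likelihood

    @property
    def available(self) -> np.ndarray:
        return ~np.isnan(self.beta)


def fit_collection(coll: MultiStudyCollection, cap: float = BETA_CAP) -> MarginalFitTable:
    """Fit every (gene, study) marginal logistic model in the collection."""
    d, M = coll.n_genes, coll.M
    beta0 = np.full((d, M), np.nan)
    beta = np.full((d, M), np.nan)
    loglik = np.full((d, M), np.nan)
    pvalue = np.full((d, M), np.nan)
    converged = np.zeros((d, M), dtype=bool)
    separated = np.zeros((d, M), dtype=bool)
    loglik0 = np.zeros(M)
    for m, ds in enumerate(coll.studies):
        if not ds.has_both_classes():
            raise ValueError(f"study {ds.study_id!r} has a single response class")
        cols = coll.study_cols[m]
        avail = cols >= 0
        res = fit_logistic_columns(ds.X[:, cols[avail]], ds.y, cap=cap)
        beta0[avail, m] = res["beta0"]
        beta[avail, m] = res["beta"]
        loglik[avail, m] = res["loglik"]
        pvalue[avail, m] = res["pvalue"]
        converged[avail, m] = res["converged"]
        separated[avail, m] = res["separated"]
        loglik0[m] = res["loglik0"]
        n_sep = int(res["separated"].sum())
        if n_sep:
            logger.debug("study %s: %d separated marginal fit(s) truncated at |beta|=%g",
                         ds.study_id, n_sep, cap)
    return MarginalFitTable(
        gene_ids=list(coll.gene_universe), study_ids=[s.study_id for s in coll.studies],
        beta0=beta0, beta=beta, loglik=loglik, pvalue=pvalue,
        converged=converged, separated=separated, loglik0=loglik0,
    )


@dataclass
class RankingTable:
    """Cross-study ranking of genes by a combined slope statistic."""

    gene_ids: list
    study_ids: list
    per_study_beta: np.ndarray  # (n_genes, M), NaN where unavailable
    statistic: np.ndarray
    K: np.ndarray
    rank: np.ndarray  # 1 = largest statistic; ties broken by gene index
    forced: np.ndarray
    kind: str = "mean"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def order(self) -> np.ndarray:
        """Gene indices from best (rank 1) to worst."""
        return np.argsort(self.rank, kind="stable")


def _assign_ranks(statistic: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(statistic.size), -statistic))
    rank = np.empty(statistic.size, dtype=np.int64)
    rank[order] = np.arange(1, statistic.size + 1)
    return rank


_STAT_KINDS = ("mean", "L2", "max", "min")


def rank_variant(fits: MarginalFitTable, kind: str = "mean") -> RankingTable:
    """Rank genes by a cross-study combination of marginal slopes.

    kind = "mean": |mean over available studies of the signed slopes| —
    sign-discordant effects cancel, so only genes whose direction of
    association replicates score highly. "L2", "max", "min" combine slope
    magnitudes instead and ignore sign agreement.
    """
    if kind not in _STAT_KINDS:
        raise ValueError(f"unknown ranking statistic {kind!r}; choose from {_STAT_KINDS}")
    beta = fits.beta
    avail = fits.available
    K = avail.sum(axis=1)
    keep = K >= 1
    if not np.all(keep):
        logger.warning("excluding %d gene(s) with no available marginal fits", int((~keep).sum()))
    b = np.where(avail, beta, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if kind == "mean":
            stat = np.abs(b.sum(axis=1) / np.maximum(K, 1))
        elif kind == "L2":
            stat = np.sqrt((b * b).sum(axis=1))
        elif kind == "max":
            stat = np.where(avail, np.abs(beta), -np.inf).max(axis=1)
        else:  # min over available studies
            stat = np.where(avail, np.abs(beta), np.inf).min(axis=1)
    gene_ids = [g for g, k in zip(fits.gene_ids, keep) if k]
    stat = stat[keep]
    return RankingTable(
        gene_ids=gene_ids,
        study_ids=list(fits.study_ids),
        per_study_beta=beta[keep],
        statistic=stat,
        K=K[keep],
        rank=_assign_ranks(stat),
        forced=np.zeros(len(gene_ids), dtype=bool),
        kind=kind,
    )


def rank_mean(fits: MarginalFitTable) -> RankingTable:
    """The default integrative ranking: magnitude of the mean slope."""
    return rank_variant(fits, "mean")


def select_threshold(rt: RankingTable, gamma_n: float) -> list:
    """Genes whose statistic reaches the threshold, plus any forced genes."""
    if gamma_n < 0:
        raise ValueError("gamma_n must be nonnegative")
    keep = (rt.statistic >= gamma_n) | rt.forced
    order = rt.order()
    return [rt.gene_ids[i] for i in order if keep[i]]


def _top_count(rt: RankingTable, fraction_or_count) -> int:
    d = rt.n_genes
    if isinstance(fraction_or_count, (int, np.integer)):
        k = int(fraction_or_count)
        if not 1 <= k <= d:
            raise ValueError(f"count must be in [1, {d}], got {k}")
        return k
    f = float(fraction_or_count)
    if not 0 < f <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    return max(1, int(np.floor(f * d + 0.5)))


def select_top(rt: RankingTable, fraction_or_count) -> list:
    """The top-ranked genes (a float selects a fraction, an int a count).

    Forced genes are always included; they enlarge the selection rather
    than displacing ranked genes.
    """
    k = _top_count(rt, fraction_or_count)
    keep = (rt.rank <= k) | rt.forced
    order = rt.order()
    return [rt.gene_ids[i] for i in order if keep[i]]


def force_include(rt: RankingTable, genes) -> RankingTable:
    """Mark validated genes to pass every selection unconditionally."""
    pos = {g: i for i, g in enumerate(rt.gene_ids)}
    unknown = [g for g in genes if g not in pos]
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown}")
    forced = rt.forced.copy()
    for g in genes:
        forced[pos[g]] = True
    return replace(rt, forced=forced)


def write_ranking(rt: RankingTable, path, selected=None) -> None:
    """Write the ranking as TSV (gene, statistic, rank, K, per-study slopes,
    forced, selected)."""
    import pandas as pd

    sel = set(selected) if selected is not None else set()
    df = pd.DataFrame({"gene_id": rt.gene_ids, "statistic": rt.statistic,
                       "rank": rt.rank, "K": rt.K})
    for m, sid in enumerate(rt.study_ids):
        df[f"beta_{sid}"] = rt.per_study_beta[:, m]
    df["forced"] = rt.forced.astype(int)
    if selected is not None:
        df["selected"] = [int(g in sel) for g in rt.gene_ids]
    df.sort_values("rank").to_csv(path, sep="\t", index=False, float_format="%.6g")
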