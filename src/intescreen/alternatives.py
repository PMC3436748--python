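"""Comparator prescreening approaches: single-study, meta-analysis, intensity.

Three families of alternatives to integrative ranking:

* single-study screening — rank by |slope| within one study, ignoring the
  others;
* meta-analysis — screen each study separately, then combine either the
  per-study ranks (rank-sum) or the per-study likelihood-ratio p-values
  (Fisher's chi-square combination);
* the intensity approach — harmonize expression values across studies so
  the samples can be pooled and screened as one large study. Harmonization
  here is per-gene quantile normalization of each study's values onto the
  pooled empirical distribution, a standard cross-platform transform (the
  synthetic stand-in for whichever platform-specific transformation a real
  analysis would use).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .datamodel import MultiStudyCollection, StudyDataset
from .marginal import (BETA_CAP, _assign_ranks, fit_collection,
                       fit_logistic_columns)

logger = logging.getLogger("intescreen")

__all__ = [
    "ComparatorResult",
    "screen_individual",
    "meta_rank_sum",
    "meta_fisher",
    "intensity_screen",
    "pool_studies",
]

_P_FLOOR = 1e-300


@dataclass
class ComparatorResult:
    """A comparator's per-gene score and deterministic ranking.

    ``higher_is_better`` records the orientation of ``score`` (slope
    magnitudes rank descending, rank sums and p-values ascending); the
    ``rank`` array is always 1 = best.
    """

    method: str
    gene_ids: list
    score: np.ndarray
    rank: np.ndarray
    higher_is_better: bool

    def top(self, fraction_or_count) -> list:
        d = len(self.gene_ids)
        if isinstance(fraction_or_count, (int, np.integer)):
            k = int(fraction_or_count)
        else:
            k = max(1, int(np.floor(float(fraction_or_count) * d + 0.5)))
        order = np.argsort(self.rank, kind="stable")
        return [self.gene_ids[i] for i in order[:k]]


def _result(method, gene_ids, score, higher_is_better) -> ComparatorResult:
    oriented = score if higher_is_better else -score
    return ComparatorResult(method=method, gene_ids=list(gene_ids), score=score,
                            rank=_assign_ranks(oriented), higher_is_better=higher_is_better)


def screen_individual(ds: StudyDataset, cap: float = BETA_CAP) -> ComparatorResult:
    """Rank genes by marginal slope magnitude within a single study."""
    if not ds.standardized:
        raise ValueError(f"study {ds.study_id!r} must be standardized")
    res = fit_logistic_columns(ds.X, ds.y, cap=cap)
    return _result("individual", ds.gene_ids, np.abs(res["beta"]), True)


def _complete_genes(coll: MultiStudyCollection):
    mask = coll.availability_mask().all(axis=1)
    if not mask.all():
        logger.warning("%s genes not measured in every study are excluded "
                       "from the all-study comparator", int((~mask).sum()))
    return mask


def meta_rank_sum(coll: MultiStudyCollection, fits=None) -> ComparatorResult:
    """Sum each gene's per-study ranks (by |slope|, average ranks on ties);
    smaller rank sums are better."""
    if fits is None:
        fits = fit_collection(coll)
    mask = _complete_genes(coll)
    absbeta = np.abs(fits.beta[mask])
    per_study_rank = rankdata(-absbeta, axis=0, method="average")
    score = per_study_rank.sum(axis=1)
    gene_ids = [g for g, m in zip(fits.gene_ids, mask) if m]
    return _result("meta_rank", gene_ids, score, False)


def meta_fisher(coll: MultiStudyCollection, fits=None) -> ComparatorResult:
    """Combine per-study likelihood-ratio p-values with Fisher's method:
    X2 = -2 sum_m log p_m ~ chi-square(2M) under the null; rank by the
    combined upper-tail p-value."""
    if fits is None:
        fits = fit_collection(coll)
    mask = _complete_genes(coll)
    p = fits.pvalue[mask]
    n_zero = int((p <= 0).sum())
    if n_zero:
        logger.warning("flooring %d zero p-value(s) at %g before Fisher combination",
                       n_zero, _P_FLOOR)
    p = np.clip(p, _P_FLOOR, 1.0)
    x2 = -2.0 * np.log(p).sum(axis=1)
    combined = chi2.sf(x2, df=2 * coll.M)
    gene_ids = [g for g, m in zip(fits.gene_ids, mask) if m]
    return _result("meta_fisher", gene_ids, combined, False)


def _quantile_to_pooled(values: np.ndarray, pooled_sorted: np.ndarray) -> np.ndarray:
    """Map each column of ``values`` onto the pooled empirical distribution.

    A sample at within-study rank r of n_m is assigned the pooled quantile
    at probability (r - 0.5) / n_m, linearly interpolated between pooled
    order statistics.
    """
    n_m = values.shape[0]
    n_pool = pooled_sorted.shape[0]
    ranks = rankdata(values, axis=0, method="average")
    prob = (ranks - 0.5) / n_m
    pos = np.clip(prob * (n_pool - 1), 0.0, n_pool - 1)
    lo = np.floor(pos).astype(np.int64)
    hi = np.minimum(lo + 1, n_pool - 1)
    frac = pos - lo
    vlo = np.take_along_axis(pooled_sorted, lo, axis=0)
    vhi = np.take_along_axis(pooled_sorted, hi, axis=0)
    return vlo * (1.0 - frac) + vhi * frac


def pool_studies(coll: MultiStudyCollection) -> StudyDataset:
    """Quantile-harmonize every study to the pooled per-gene distribution
    and stack all samples into one dataset (genes measured everywhere)."""
    mask = _complete_genes(coll)
    keep = np.flatnonzero(mask)
    gene_ids = [coll.gene_universe[i] for i in keep]
    mats = [coll.aligned_matrix(m)[:, keep] for m in range(coll.M)]
    pooled_sorted = np.sort(np.concatenate(mats, axis=0), axis=0)
    Xs = [_quantile_to_pooled(Xm, pooled_sorted) for Xm in mats]
    y = np.concatenate([ds.y for ds in coll.studies])
    sample_ids = [s for ds in coll.studies for s in ds.sample_ids]
    # harmonized values inherit the per-study standardization scale; they
    # are not re-standardized, so duplicated studies pool to the same fit
    return StudyDataset(study_id="pooled", X=np.concatenate(Xs, axis=0), y=y,
                        gene_ids=gene_ids, standardized=True, sample_ids=sample_ids)


def intensity_screen(coll: MultiStudyCollection, cap: float = BETA_CAP) -> ComparatorResult:
    """Pool the harmonized studies and rank by single-dataset |slope|."""
    pooled = pool_studies(coll)
    res = fit_logistic_columns(pooled.X, pooled.y, cap=cap)
    return _result("intensity", pooled.gene_ids, np.abs(res["beta"]), True)
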