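"""Operating-characteristic evaluation and the simulation benchmark runner.

A scenario is one truth configuration; the runner simulates independent
replicate collections, screens each with the integrative method and the
comparators, and reports replicate means (with Monte-Carlo standard
errors) of the true-positive counts at fixed selection fractions plus the
stopping-rule size P_opt and its true-positive count T_opt.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alternatives import intensity_screen, meta_fisher, meta_rank_sum, screen_individual
from .marginal import RankingTable, fit_collection, rank_mean
from .simulate import SimulationConfig, simulate_collection
from .threshold import default_grid, select_popt

logger = logging.getLogger("intescreen")

__all__ = ["ScenarioReport", "true_positive_count", "oc_curve", "run_scenario",
           "run_replicate", "METHODS"]

METHODS = ("integrative", "individual", "intensity", "meta", "meta_fisher")


def true_positive_count(selected, truth) -> int:
    """|selected ∩ truth|."""
    return len(set(selected) & set(truth))


def _truth_cumulative(gene_ids, rank, truth) -> np.ndarray:
    """cum[k-1] = true positives among the k best-ranked genes."""
    truth = set(truth)
    is_truth = np.fromiter((g in truth for g in gene_ids), dtype=bool, count=len(gene_ids))
    order = np.argsort(rank, kind="stable")
    return np.cumsum(is_truth[order])


def oc_curve(rt: RankingTable, truth, sizes=None):
    """True positives as a function of the number of top genes selected.

    Returns (sizes, tp) arrays; by default every size 1..d.
    """
    cum = _truth_cumulative(rt.gene_ids, rt.rank, truth)
    if sizes is None:
        sizes = np.arange(1, rt.n_genes + 1)
    sizes = np.asarray(sizes, dtype=np.int64)
    return sizes, cum[sizes - 1]


@dataclass
class ScenarioReport:
    """Replicate-averaged operating characteristics for one scenario."""

    config: SimulationConfig
    n_reps: int
    n_excluded: int
    per_rep: pd.DataFrame
    means: dict
    ses: dict

    def summary_row(self) -> dict:
        row = {"n": self.config.n_m, "n_clusters": self.config.n_clusters,
               "c": self.config.c, "rho": self.config.rho, "reps": self.n_reps,
               "excluded": self.n_excluded}
        row.update(self.means)
        return row


def _rep_seed(base_seed, rep: int):
    if isinstance(base_seed, (tuple, list)):
        return tuple(base_seed) + (rep,)
    return (base_seed, rep)


def run_replicate(cfg: SimulationConfig, methods=METHODS, fractions=(0.05, 0.10, 0.20),
                  tau: float = 0.0, grid_step: int = 100) -> dict:
    """Simulate one collection and evaluate every requested method on it."""
    coll, truth, _ = simulate_collection(cfg)
    out = {}
    fits = fit_collection(coll)
    rt = rank_mean(fits)
    d = rt.n_genes
    counts = {f: max(1, int(np.floor(f * d + 0.5))) for f in fractions}
    if "integrative" in methods:
        cum = _truth_cumulative(rt.gene_ids, rt.rank, truth)
        for f, k in counts.items():
            out[f"T{int(round(f * 100))}"] = int(cum[k - 1])
        path = select_popt(coll, rt, k_grid=default_grid(d, grid_step), tau=tau)
        out["P_opt"] = path.P_opt
        out["T_opt"] = int(cum[path.P_opt - 1])
    k10 = counts.get(0.10, max(1, int(np.floor(0.10 * d + 0.5))))
    if "individual" in methods:
        res = screen_individual(coll.studies[0])
        out["Ind10"] = int(_truth_cumulative(res.gene_ids, res.rank, truth)[k10 - 1])
    if "intensity" in methods:
        res = intensity_screen(coll)
        out["Int10"] = int(_truth_cumulative(res.gene_ids, res.rank, truth)[k10 - 1])
    if "meta" in methods:
        res = meta_rank_sum(coll, fits=fits)
        out["Meta10"] = int(_truth_cumulative(res.gene_ids, res.rank, truth)[k10 - 1])
    if "meta_fisher" in methods:
        res = meta_fisher(coll, fits=fits)
        out["MetaF10"] = int(_truth_cumulative(res.gene_ids, res.rank, truth)[k10 - 1])
    return out


def run_scenario(cfg: SimulationConfig, n_reps: int, methods=METHODS,
                 fractions=(0.05, 0.10, 0.20), tau: float = 0.0,
                 grid_step: int = 100, n_jobs: int = 1) -> ScenarioReport:
    """Replicate the scenario and average the operating characteristics.

    Every replicate runs on its own deterministic random substream derived
    from the scenario seed, so results are identical no matter how the
    replicates are scheduled (``n_jobs`` uses joblib workers when not 1).
    Replicates whose responses degenerate beyond the redraw cap are
    excluded and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfgs = [replace(cfg, seed=_rep_seed(cfg.seed, r)) for r in range(n_reps)]

    def one(rep_cfg, r):
        t0 = time.perf_counter()
        try:
            res = run_replicate(rep_cfg, methods=methods, fractions=fractions,
                                tau=tau, grid_step=grid_step)
        except RuntimeError as err:
            logger.warning("replicate %d excluded: %s", r, err)
            return None
        logger.info("replicate %d done in %.2fs", r, time.perf_counter() - t0)
        return res

    if n_jobs == 1:
        rows = [one(c, r) for r, c in enumerate(cfgs)]
    else:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(c, r) for r, c in enumerate(cfgs))

    kept = [r for r in rows if r is not None]
    n_excluded = n_reps - len(kept)
    if not kept:
        raise RuntimeError("every replicate was excluded")
    per_rep = pd.DataFrame(kept)
    means = {k: float(per_rep[k].mean()) for k in per_rep.columns}
    ses = {k: float(per_rep[k].std(ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else float("nan")
           for k in per_rep.columns}
    return ScenarioReport(config=cfg, n_reps=len(kept), n_excluded=n_excluded,
                          per_rep=per_rep, means=means, ses=ses)
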