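"""AUC scoring against ground truth and the figure-level experiment designs.

The AUC (area under the receiver-operating-characteristic curve) is computed
in its Mann-Whitney rank-sum form with midrank tie handling, so unselected
interactions sharing one tied minimal score are treated correctly: a perfect
ranking scores exactly 1, random scores average 1/2, and all-tied scores give
exactly 1/2. Self pairs are never scored; hidden-unit runs score only pairs
among observed units (no statement is made about indirect interactions
mediated by hidden units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import baselines
from .model import NetworkReconstruction
from .netgen import NetworkSpec, random_hypernetwork, random_indegree_network
from .simulate import SimConfig, simulate

__all__ = ["auc_score", "run_experiment", "EvaluationReport", "DESIGNS"]

DESIGNS = (
    "auc_vs_M", "auc_vs_eta", "auc_vs_ph", "auc_vs_hidden",
    "m095_vs_N", "m095_vs_nin",
)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    npos = int(labels.sum())
    nneg = int(len(labels) - npos)
    if npos == 0 or nneg == 0:
        raise ValueError("AUC undefined: need at least one true link and one non-link")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - npos * (npos + 1) / 2.0) / (npos * nneg))


def auc_score(scores, truth: NetworkSpec, observed=None) -> float:
    """AUC of interaction scores against the ground-truth structure.

    ``scores`` is either an (N, N) matrix (entry [i, j] scoring the link
    j -> i; diagonal excluded) or, for three-point runs, a list of per-target
    dicts mapping unordered pair keys {j, k} to scores (the negative candidate
    set is then all absent unordered pairs, degenerate pairwise keys
    included). ``observed`` restricts scoring to pairs among a subset of
    units.
    """
    if isinstance(scores, np.ndarray):
        N = truth.N
        obs = sorted(observed) if observed is not None else list(range(N))
        if scores.shape == (len(obs), len(obs)):
            sub = scores
        elif scores.shape == (N, N):
            sub = scores[np.ix_(obs, obs)]
        else:
            raise ValueError("score matrix shape matches neither all nor observed units")
        truth_sub = (truth.J[np.ix_(obs, obs)] != 0)
        off = ~np.eye(len(obs), dtype=bool)
        return _rank_auc(sub[off], truth_sub[off])

    # three-point scoring: list of per-target score dicts
    if truth.E is None:
        raise ValueError("hypernetwork scoring needs a NetworkSpec with E")
    N = truth.N
    obs = sorted(observed) if observed is not None else list(range(N))
    all_pairs = [(a, b) for ai, a in enumerate(obs) for b in obs[ai + 1:]]
    svals, labels = [], []
    index_map = {u: t for t, u in enumerate(obs)} if len(scores) == len(obs) else None
    for i in obs:
        d = scores[index_map[i]] if index_map is not None else scores[i]
        true_keys = set(truth.pair_keys(i))
        for key in all_pairs:
            lookup = key if index_map is None else (index_map[key[0]], index_map[key[1]])
            svals.append(d.get(lookup, 0.0))
            labels.append(key in true_keys)
    return _rank_auc(np.asarray(svals, dtype=float), np.asarray(labels, dtype=bool))


@dataclass
class EvaluationReport:
    """Tidy results of one experiment design (one row per measurement)."""

    design: str
    df: pd.DataFrame
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        value = "m095" if "m095" in self.df.columns else "auc"
        by = [c for c in (self.df.columns) if c in
              ("M", "eta", "p_h", "R", "N", "n_in") and self.df[c].nunique() > 1]
        group = (by or ["method"]) + (["method"] if "method" in self.df.columns
                                      and "method" not in (by or []) else [])
        g = self.df.groupby(group)[value]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out


_BASELINES = {
    "corr": lambda ts: baselines.corr_baseline(ts),
    "pcorr": lambda ts: baselines.pcorr_baseline(ts, ridge=1e-4),
    "te": lambda ts: baselines.te_baseline(ts),
}

# basis family appropriate to each model system's coupling class
_FAMILY = {"mm": ("e", 3), "phase_net": ("c", 4), "phase_hyper": ("c", 4),
           "roessler": ("ef", 2)}


def single_run(model: str = "phase_net", N: int = 20, n_in: int = 10,
               M: int = 1000, m: int = 10, eta: float = 0.0, p_h: float = 0.0,
               R: float = 1.0, seed: int = 0, methods=("arni",),
               family: str | None = None, P: int | None = None,
               l_max: int | None = None, tol: float = 1e-4,
               dt: float | None = None) -> dict:
    """Simulate -> infer -> score one network; returns method -> AUC."""
    from .simulate import DEFAULT_DT

    if model == "phase_hyper":
        spec = random_hypernetwork(N, n_in, p_h, seed=seed)
    else:
        spec = random_indegree_network(N, n_in, seed=seed)
    S = max(2, M // m)
    cfg = SimConfig(dt=dt if dt is not None else DEFAULT_DT[model],
                    m=m, S=S, eta=eta, seed=seed)
    ts = simulate(model, spec, cfg)

    observed = None
    if R < 1.0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(77,)))
        n_obs = max(2, int(round(R * N)))
        observed = sorted(rng.choice(N, size=n_obs, replace=False).tolist())
        ts = ts.subset_units(observed)

    fam, p_default = _FAMILY[model]
    fam = family or fam
    P = P or p_default
    out = {}
    for method in methods:
        if method == "arni":
            order = "pairwise_plus_hyper2" if model == "phase_hyper" else "pairwise"
            res = NetworkReconstruction(ts, family=fam, P=P, order=order).fit(
                l_max=l_max, tol=tol, seed=seed)
            if model == "phase_hyper":
                out[method] = auc_score(res.hyper_scores(), spec, observed=observed)
            else:
                out[method] = auc_score(res.score_matrix(), spec, observed=observed)
        else:
            out[method] = auc_score(_BASELINES[method](ts), spec, observed=observed)
    return out


def _m095(probe, m: int, replicates: int, seed: int, m_cap: int = 12800) -> float:
    """Smallest M (multiple of m, within resolution) with mean AUC > 0.95."""
    def mean_auc(M):
        return float(np.mean([probe(M, seed + 1000 * r) for r in range(replicates)]))

    lo, hi = m, 2 * m
    while mean_auc(hi) <= 0.95:
        lo, hi = hi, 2 * hi
        if hi > m_cap:
            return float("nan")
    while hi - lo > m:
        mid = ((lo + hi) // (2 * m)) * m
        if mid in (lo, hi):
            break
        if mean_auc(mid) > 0.95:
            hi = mid
        else:
            lo = mid
    return float(hi)


def run_experiment(design: str, grid, replicates: int = 5, seed: int = 0,
                   methods=("arni",), budget: int | None = None,
                   **kwargs) -> EvaluationReport:
    """Run one figure-level experiment design over a grid with seeded replicates.

    Designs: ``auc_vs_M`` (grid of total sample counts M), ``auc_vs_eta``
    (noise levels), ``auc_vs_ph`` (hypernetwork probabilities), ``auc_vs_hidden``
    (grid of observed fractions R; R = 1 reduces to the plain pipeline),
    ``m095_vs_N`` and ``m095_vs_nin`` (bisect over M for the smallest length
    with mean AUC > 0.95). Keyword arguments override the per-design defaults
    (model, N, n_in, M, m, eta, family, ...).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    grid = list(grid)
    n_sims = len(grid) * replicates * (8 if design.startswith("m095") else 1)
    if budget is not None and n_sims > budget:
        raise ValueError(f"experiment needs ~{n_sims} simulations > budget {budget}")

    defaults = dict(model="phase_net", N=20, n_in=10, M=1000, m=10)
    if design == "auc_vs_ph":
        defaults.update(model="phase_hyper", n_in=5)
    if design == "auc_vs_hidden":
        defaults.update(model="mm", N=100, n_in=10, m=5, M=2000, eta=0.02)
    if design == "m095_vs_nin":
        defaults.update(N=50)
    defaults.update(kwargs)

    rows = []
    var = {"auc_vs_M": "M", "auc_vs_eta": "eta", "auc_vs_ph": "p_h",
           "auc_vs_hidden": "R", "m095_vs_N": "N", "m095_vs_nin": "n_in"}[design]
    for gi, gval in enumerate(grid):
        params = dict(defaults)
        params[var] = gval
        if design.startswith("m095"):
            m = params["m"]

            def probe(M, s, _p=params):
                p = dict(_p)
                p.pop("M", None)
                return single_run(M=M, seed=s, methods=("arni",), **_strip(p))["arni"]

            val = _m095(probe, m, replicates, seed + 131 * gi)
            rows.append(dict(**{var: gval}, m095=val, method="arni"))
        else:
            for r in range(replicates):
                res = single_run(seed=seed + 1000 * r + 131 * gi,
                                 methods=methods, **_strip(params))
                for method, auc in res.items():
                    rows.append(dict(**{var: gval}, replicate=r, method=method,
                                     auc=auc))
    return EvaluationReport(design=design, df=pd.DataFrame(rows),
                            config=dict(defaults, grid=grid,
                                        replicates=replicates, seed=seed))


def _strip(params: dict) -> dict:
    allowed = {"model", "N", "n_in", "M", "m", "eta", "p_h", "R", "family",
               "P", "l_max", "tol", "dt"}
    return {k: v for k, v in params.items() if k in allowed}
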