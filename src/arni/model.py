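"""Greedy block-orthogonal least squares and the reconstruction Model/Results.

Per target unit, the algorithm repeatedly (1) orthogonalizes every unselected
candidate block against the span of the already-selected columns (modified
Gram-Schmidt, applied twice), (2) scores each candidate by the squared-norm
reduction of the training residual achieved by projecting onto the
orthogonalized block, and (3) selects the best block, recording the fitting
cost

    C_i(l) = (1/M_s) sum_m (dx_i,m - dx_hat_i,m(l))^2

on both the training and the validation rows. The fit always contains an
intercept column (constant drive terms such as natural frequencies are not in
the span of the basis families). Selection uses training rows only; the
validation curve is diagnostic (knee detection).

:class:`NetworkReconstruction` is the user-facing model object: construct it
from a :class:`~arni.simulate.TimeSeriesSet`, call :meth:`fit`, and read the
ranked interactions, score matrix, learning curves and knees off the returned
:class:`NetworkReconstructionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .features import DerivativeSet, DesignBlocks, build_blocks, estimate_derivatives
from .simulate import TimeSeriesSet

__all__ = [
    "InferenceResult",
    "KneeResult",
    "infer_unit",
    "cost_curve",
    "detect_knee",
    "NetworkReconstruction",
    "NetworkReconstructionResults",
]

_RANK_RTOL = 1e-10


@dataclass
class KneeResult:
    """Estimated plateau onset l* of an L-shaped learning curve."""

    l_star: int
    confidence: float      # normalized distance-to-chord of the knee point
    confident: bool        # pronounced drop and interior curvature maximum
    flat: bool = False


@dataclass
class InferenceResult:
    """Ranked incoming interactions of one target unit (one component)."""

    target: int
    target_component: int
    ranked: list                  # [(key, step l, train cost, val cost), ...]
    train_costs: np.ndarray       # C_i(l) for l = 0..L on training rows
    val_costs: np.ndarray         # C_i(l) for l = 0..L on validation rows
    coefficients: dict            # key -> raw-scale coefficient array
    coef_labels: dict             # key -> column descriptions
    intercept: float
    stop_reason: str              # max_steps | cost_plateau | residual_tol | degenerate
    n_candidates: int
    m_train: int
    m_val: int

    @property
    def selected_keys(self) -> list:
        return [r[0] for r in self.ranked]

    def knee(self, on: str = "val") -> KneeResult:
        """Knee of the learning curve (validation rows by default)."""
        costs = self.val_costs if (on == "val" and self.m_val > 0) else self.train_costs
        if len(costs) < 4:
            return KneeResult(l_star=0, confidence=0.0, confident=False, flat=True)
        return detect_knee(costs[1:], first_l=1)


def _split_rows(seg_ids: np.ndarray, train_frac: float, seed: int):
    """Train/validation split by whole segments (contiguous rows if only one)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    segs = np.unique(seg_ids)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(42,)))
    if len(segs) == 1:
        n = len(seg_ids)
        cut = max(1, int(round(train_frac * n)))
        cut = min(cut, n - 1) if n > 1 else n
        idx = np.arange(n)
        return idx[:cut], idx[cut:]
    perm = rng.permutation(segs)
    n_tr = max(1, int(round(train_frac * len(segs))))
    n_tr = min(n_tr, len(segs) - 1)
    tr_set = set(perm[:n_tr].tolist())
    mask = np.fromiter((s in tr_set for s in seg_ids), dtype=bool, count=len(seg_ids))
    idx = np.arange(len(seg_ids))
    return idx[mask], idx[~mask]


def _batched_gains(W: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Projection gain of r onto each candidate block in a (k, M, P) stack.

    Uses a batched eigendecomposition-based pseudo-inverse of the Gram
    matrices with a relative rank cutoff, consistent with the rank-revealing
    QR used for the selected block.
    """
    Wt = W.transpose(0, 2, 1)
    g = Wt @ r
    G = Wt @ W
    vals, vecs = np.linalg.eigh(G)
    top = vals[:, -1:]
    keep = vals > np.maximum(top, 0.0) * _RANK_RTOL**2
    safe = np.where(vals > 0, vals, 1.0)
    inv = np.where(keep & (vals > 0), 1.0 / safe, 0.0)
    tmp = (vecs.transpose(0, 2, 1) @ g[..., None])[..., 0]
    coef = (vecs @ (inv * tmp)[..., None])[..., 0]
    return np.sum(g * coef, axis=1)


def _ortho_columns(W: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of W (rank-revealing QR)."""
    if W.shape[1] == 0:
        return W
    Q, R, _ = scipy.linalg.qr(W, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return W[:, :0]
    rank = int(np.sum(diag > _RANK_RTOL * diag[0]))
    return Q[:, :rank]


def infer_unit(
    blocks: DesignBlocks,
    y: np.ndarray,
    seg_ids: np.ndarray | None = None,
    l_max: int | None = None,
    tol: float = 1e-4,
    train_frac: float = 0.6,
    seed: int = 0,
    split: tuple | None = None,
) -> InferenceResult:
    """Greedy block-orthogonal least-squares selection for one target.

    ``split`` may pass precomputed (train_idx, val_idx) row indices (the Model
    shares one segment split across units); otherwise rows are split by whole
    segments using ``train_frac`` and ``seed``. Returns the ranked interaction
    list with train/validation costs per step and the final ordinary
    least-squares coefficients on the selected (unnormalized) blocks.
    """
    y = np.asarray(y, dtype=float)
    if split is not None:
        tr, va = split
    else:
        if seg_ids is None:
            seg_ids = np.zeros(len(y), dtype=int)
        tr, va = _split_rows(seg_ids, train_frac, seed)
    y_tr, y_va = y[tr], y[va]
    Mt, Mv = len(y_tr), len(y_va)

    keys = blocks.usable_keys()
    B_tr = {k: blocks.blocks[k][tr] for k in keys}
    B_va = {k: blocks.blocks[k][va] for k in keys}
    max_cols = max((b.shape[1] for b in B_tr.values()), default=1)

    if l_max is None:
        l_max = min(len(keys), max(1, Mt // max(1, max_cols)))
    l_max = min(l_max, len(keys))

    ones_tr = np.ones(Mt) / np.sqrt(Mt)
    Q = ones_tr[:, None]
    r = y_tr - Q @ (Q.T @ y_tr)
    rss = float(r @ r)
    c0_tr = float(np.mean(y_tr**2)) if Mt else 0.0
    c0_va = float(np.mean(y_va**2)) if Mv else np.nan
    train_costs = [c0_tr]
    val_costs = [c0_va]
    ranked: list = []
    selected: list = []
    coefs: dict = {}
    intercept_val = 0.0
    stop = "max_steps"

    if not keys:
        stop = "degenerate"
        l_max = 0

    floor = max(1e-14 * c0_tr, 1e-300)
    if c0_tr <= floor:
        stop = "residual_tol"
        l_max = 0

    def refit(sel):
        X_tr = np.column_stack([np.ones(Mt)] + [B_tr[k] for k in sel])
        beta, *_ = scipy.linalg.lstsq(X_tr, y_tr, lapack_driver="gelsy")
        if Mv:
            X_va = np.column_stack([np.ones(Mv)] + [B_va[k] for k in sel])
            vc = float(np.mean((y_va - X_va @ beta) ** 2))
        else:
            vc = np.nan
        return beta, vc

    # candidate blocks orthogonalized against the selected span, maintained
    # incrementally (modified Gram-Schmidt, each update applied twice);
    # batched per group of equal column count for vectorized gain evaluation
    groups: dict[int, list] = {}
    for k in keys:
        groups.setdefault(B_tr[k].shape[1], []).append(k)
    stacks = {}
    for ncols, gkeys in groups.items():
        W = np.stack([B_tr[k] for k in gkeys])  # (k, Mt, ncols)
        W -= Q @ (Q.T @ W)
        W -= Q @ (Q.T @ W)
        stacks[ncols] = W
    key_pos = {k: (B_tr[k].shape[1], gi)
               for ncols, gkeys in groups.items() for gi, k in enumerate(gkeys)}
    taken = {ncols: np.zeros(len(gkeys), dtype=bool)
             for ncols, gkeys in groups.items()}

    def _apply_increment(Qw):
        for W in stacks.values():
            W -= Qw @ (Qw.T @ W)
            W -= Qw @ (Qw.T @ W)

    beta = np.zeros(1)
    for l in range(1, l_max + 1):
        best_key, best_gain = None, -np.inf
        for ncols, gkeys in groups.items():
            gains = _batched_gains(stacks[ncols], r)
            gains[taken[ncols]] = -np.inf
            gi = int(np.argmax(gains))
            if gains[gi] > best_gain:
                best_gain, best_key = float(gains[gi]), gkeys[gi]
        if best_key is None or best_gain <= 0:
            stop = "degenerate" if not selected else "cost_plateau"
            break
        if best_gain <= tol * rss:
            stop = "cost_plateau"
            break
        ncols, gi = key_pos[best_key]
        best_Qw = _ortho_columns(stacks[ncols][gi])
        selected.append(best_key)
        taken[ncols][gi] = True
        Q = np.column_stack([Q, best_Qw])
        r = r - best_Qw @ (best_Qw.T @ r)
        rss = float(r @ r)
        _apply_increment(best_Qw)
        tc = rss / Mt
        beta, vc = refit(selected)
        train_costs.append(tc)
        val_costs.append(vc)
        ranked.append((best_key, l, tc, vc))
        if tc <= floor:
            stop = "residual_tol"
            break
    else:
        stop = "max_steps" if selected else stop

    if selected:
        pos = 1
        intercept_val = float(beta[0])
        for k in selected:
            ncols = B_tr[k].shape[1]
            raw = beta[pos:pos + ncols] / blocks.col_norms[k]
            coefs[k] = raw
            pos += ncols

    return InferenceResult(
        target=blocks.target,
        target_component=blocks.target_component,
        ranked=ranked,
        train_costs=np.asarray(train_costs),
        val_costs=np.asarray(val_costs),
        coefficients=coefs,
        coef_labels={k: blocks.col_labels[k] for k in selected},
        intercept=intercept_val,
        stop_reason=stop,
        n_candidates=len(blocks.keys),
        m_train=Mt,
        m_val=Mv,
    )


def cost_curve(result: InferenceResult):
    """Fitting costs (l, train C_i(l), validation C_i(l)) for l = 0..|ranked|.

    l = 0 is the zero predictor, so C_i(0) is the mean squared derivative.
    """
    if result.train_costs.size == 0:
        raise ValueError("empty result")
    return [
        (l, float(result.train_costs[l]), float(result.val_costs[l]))
        for l in range(len(result.train_costs))
    ]


def detect_knee(costs, first_l: int = 1, min_drop: float = 10.0,
                min_distance: float = 0.15) -> KneeResult:
    """Plateau onset of an L-shaped learning curve (distance-to-chord).

    ``costs`` holds the fitting cost for l = first_l, first_l+1, ...; the
    returned l* maximizes the distance of the log-cost point to the chord
    joining the curve's endpoints (ties broken toward smaller l). The knee is
    flagged confident only when it is an interior maximum with a normalized
    chord distance of at least ``min_distance`` and the cost drops by at least
    a factor ``min_drop`` overall — a strictly geometric decay has no interior
    curvature maximum and is reported low-confidence.
    """
    c = np.asarray(costs, dtype=float)
    if c.size < 3:
        raise ValueError("knee detection needs at least 3 curve points")
    c = np.maximum(c, 1e-300)
    logc = np.log(c)
    span = logc.max() - logc.min()
    if span < 1e-12:
        return KneeResult(l_star=0, confidence=0.0, confident=False, flat=True)
    x = np.linspace(0.0, 1.0, c.size)
    ynorm = (logc - logc[-1]) / (logc[0] - logc[-1]) if logc[0] != logc[-1] else (
        (logc - logc.min()) / span)
    # chord from the first to the last point in normalized coordinates
    x0, y0, x1, y1 = x[0], ynorm[0], x[-1], ynorm[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x0) - dx * (ynorm - y0)) / norm
    interior = dist[1:-1]
    if interior.size == 0:
        return KneeResult(l_star=0, confidence=0.0, confident=False, flat=True)
    idx = int(np.argmax(interior)) + 1
    drop = c[0] / c[-1]
    confident = bool(dist[idx] >= min_distance and drop >= min_drop)
    return KneeResult(l_star=first_l + idx, confidence=float(dist[idx]),
                      confident=confident)


class NetworkReconstruction:
    """Model-free reconstruction of direct interactions from a time series.

    Parameters
    ----------
    ts : TimeSeriesSet
        The recorded multivariate dynamics (the sole observational input).
    family : str
        Basis family (see :mod:`arni.features`).
    P : int
        Number of basis functions per family index.
    order : str
        ``"pairwise"`` or ``"pairwise_plus_hyper2"`` (three-point candidates).
    diff_scheme : str
        ``"forward2"`` or ``"central3"`` derivative stencil.
    include_self : bool
        Include the target's own (intrinsic) block among the candidates.

    Examples
    --------
    >>> spec = random_indegree_network(N=20, n_in=10, seed=1)
    >>> ts = simulate_phase(spec, SimConfig(m=10, S=200, seed=1))
    >>> res = NetworkReconstruction(ts, family="c", P=4).fit(seed=1)
    >>> res.auc(spec)
    """

    def __init__(self, ts: TimeSeriesSet, family: str = "c", P: int = 4,
                 order: str = "pairwise", diff_scheme: str = "forward2",
                 include_self: bool = True, rbf_seed: int = 0,
                 max_candidates: int | None = None):
        self.ts = ts
        self.family = family
        self.P = P
        self.order = order
        self.diff_scheme = diff_scheme
        self.include_self = include_self
        self.rbf_seed = rbf_seed
        self.max_candidates = max_candidates

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float, **kwargs):
        """Build from a tidy frame with a ``segment`` column and one column
        per component (scalar units, column order = unit order)."""
        if "segment" not in df.columns:
            raise ValueError("data frame needs a 'segment' column")
        value_cols = [c for c in df.columns if c not in ("segment", "time")]
        segments = [
            g[value_cols].to_numpy(dtype=float)
            for _, g in df.groupby("segment", sort=True)
        ]
        layout = [[i] for i in range(len(value_cols))]
        ts = TimeSeriesSet(segments=segments, dt=dt, unit_layout=layout,
                           meta={"source": "dataframe"})
        return cls(ts, **kwargs)

    def fit(self, l_max: int | None = None, tol: float = 1e-4,
            train_frac: float = 0.6, seed: int = 0) -> "NetworkReconstructionResults":
        """Run derivative estimation + block construction + BOLS per unit.

        Units are processed independently (their reconstructions are
        mathematically independent); one segment-level train/validation split
        is shared across units.
        """
        ds = estimate_derivatives(self.ts, self.diff_scheme)
        split = _split_rows(ds.seg_ids, train_frac, seed)
        units = []
        errors = {}
        for i in range(ds.n_units):
            for comp_idx, col in enumerate(ds.unit_layout[i]):
                try:
                    blocks = build_blocks(
                        ds, i, family=self.family, P=self.P, order=self.order,
                        target_component=comp_idx, include_self=self.include_self,
                        rbf_seed=self.rbf_seed, max_candidates=self.max_candidates,
                    )
                    res = infer_unit(
                        blocks, ds.dxdt[:, col], seg_ids=ds.seg_ids,
                        l_max=l_max, tol=tol, split=split,
                    )
                    units.append(res)
                except Exception as exc:  # keep other units running
                    errors[(i, comp_idx)] = exc
                    warnings.warn(f"unit {i} component {comp_idx} failed: {exc}")
        if not units:
            raise RuntimeError(f"all units failed: {errors}")
        return NetworkReconstructionResults(
            model=self, ds=ds, units=units, errors=errors,
            fit_options=dict(l_max=l_max, tol=tol, train_frac=train_frac, seed=seed),
        )


@dataclass
class NetworkReconstructionResults:
    """Fitted reconstruction: ranked interactions, costs, scores, knees."""

    model: NetworkReconstruction
    ds: DerivativeSet
    units: list            # InferenceResult per (unit, component)
    errors: dict = field(default_factory=dict)
    fit_options: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.ds.n_units

    def unit_results(self, target: int) -> list:
        return [u for u in self.units if u.target == target]

    def score_matrix(self) -> np.ndarray:
        """Pairwise interaction scores: earlier discovery = higher score.

        ``score[i, j]`` ranks candidate j for target i; unselected candidates
        share the tied minimum 0. Multi-component targets pool by the earliest
        selection over components.
        """
        if self.model.order != "pairwise":
            raise ValueError("score_matrix is for pairwise candidate sets")
        N = self.n_units
        S = np.zeros((N, N))
        for u in self.units:
            base = u.n_candidates
            for key, step, _, _ in u.ranked:
                S[u.target, key] = max(S[u.target, key], base - step + 1)
        return S

    def score_matrix_cost(self) -> np.ndarray:
        """Alternative scores: training-cost decrease attributed to each block."""
        if self.model.order != "pairwise":
            raise ValueError("score_matrix_cost is for pairwise candidate sets")
        N = self.n_units
        S = np.zeros((N, N))
        for u in self.units:
            prev = u.train_costs[0]
            for key, step, tc, _ in u.ranked:
                S[u.target, key] = max(S[u.target, key], prev - tc)
                prev = tc
        return S

    def hyper_scores(self) -> list:
        """Per-target dict of unordered-pair candidate scores (three-point runs)."""
        if self.model.order != "pairwise_plus_hyper2":
            raise ValueError("hyper_scores needs order='pairwise_plus_hyper2'")
        out = [dict() for _ in range(self.n_units)]
        for u in self.units:
            base = u.n_candidates
            for key, step, _, _ in u.ranked:
                out[u.target][key] = max(out[u.target].get(key, 0), base - step + 1)
        return out

    def knees(self, on: str = "val") -> list:
        return [u.knee(on=on) for u in self.units]

    def auc(self, spec, observed=None) -> float:
        from .evaluate import auc_score

        if self.model.order == "pairwise_plus_hyper2":
            return auc_score(self.hyper_scores(), spec, observed=observed)
        return auc_score(self.score_matrix(), spec, observed=observed)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.units:
            kn = u.knee()
            rows.append(dict(
                target=u.target + 1,
                component=u.target_component + 1,
                n_selected=len(u.ranked),
                stop_reason=u.stop_reason,
                knee=kn.l_star,
                knee_confident=kn.confident,
                final_train_cost=float(u.train_costs[-1]),
                final_val_cost=float(u.val_costs[-1]),
                first_keys=" ".join(_fmt_key(k) for k in u.selected_keys[:5]),
            ))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        head = (
            "Network reconstruction (block orthogonal least squares)\n"
            f"units: {self.n_units}  samples used: {self.ds.m_eff}  "
            f"family: {self.model.family}  P: {self.model.P}  "
            f"order: {self.model.order}\n"
        )
        return head + df.to_string(index=False)


def _fmt_key(key) -> str:
    if isinstance(key, tuple):
        return "{" + ",".join(str(k + 1) for k in key) + "}"
    return str(key + 1)
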