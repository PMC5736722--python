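"""Derivative estimation and grouped basis-function design blocks.

Each candidate interaction (a unit j, or an unordered pair {j, k} when
three-point interactions are allowed) contributes one *block*: the matrix of
all its basis-function columns evaluated at every retained sample. Blocks are
selected or rejected as a whole by the greedy regression in
:mod:`arni.model`.

Basis families (single index = number of functions P):

====== ==========================================================
family columns per candidate component
====== ==========================================================
a      (x_j - x_i)^p,                       p = 1..P
b      x_i^p1 * x_j^p2,                     1 <= p1 + p2 <= P
c      sin(p (x_j - x_i)), cos(p (x_j - x_i)), p = 1..P
d      1 / (1 + ||(x_i, x_j) - center_p||^2),  P centers
e      x_j^p,                               p = 1..P
f      sin(p x_j), cos(p x_j),              p = 1..P
ef     union of the e and f columns
====== ==========================================================

Families a-d are two-place (they involve the target's own state), e/f are
one-place. The self block (candidate j = i) always uses the one-place
semantics (powers for a/b/d/e, sin/cos for c/f, both for ef); for
multi-component units it additionally contains the degree-2 cross-component
monomials so intrinsic product terms are absorbable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import TimeSeriesSet

__all__ = [
    "DerivativeSet",
    "DesignBlocks",
    "estimate_derivatives",
    "build_blocks",
    "place_rbf_centers",
    "FAMILIES",
]

FAMILIES = ("a", "b", "c", "d", "e", "f", "ef")


@dataclass
class DerivativeSet:
    """States paired with estimated time derivatives, segment boundaries kept."""

    x: np.ndarray          # (M_eff, D_total) retained state rows
    dxdt: np.ndarray       # (M_eff, D_total) matching derivative estimates
    seg_ids: np.ndarray    # (M_eff,) originating segment of each row
    dt: float
    unit_layout: list
    n_skipped: int = 0     # segments too short for the stencil

    @property
    def m_eff(self) -> int:
        return self.x.shape[0]

    @property
    def n_units(self) -> int:
        return len(self.unit_layout)


def estimate_derivatives(ts: TimeSeriesSet, scheme: str = "forward2") -> DerivativeSet:
    """Finite-difference derivative estimates, never straddling segments.

    ``forward2`` pairs (x_{m+1} - x_m)/dt with the state x_m (each segment
    loses its last row); ``central3`` pairs (x_{m+1} - x_{m-1})/(2 dt) with
    x_m (each segment loses both end rows).
    """
    if scheme not in ("forward2", "central3"):
        raise ValueError(f"unknown derivative scheme {scheme!r}")
    need = 2 if scheme == "forward2" else 3
    xs, ds, segs = [], [], []
    skipped = 0
    for k, seg in enumerate(ts.segments):
        if seg.shape[0] < need:
            skipped += 1
            continue
        if scheme == "forward2":
            d = (seg[1:] - seg[:-1]) / ts.dt
            x = seg[:-1]
        else:
            d = (seg[2:] - seg[:-2]) / (2.0 * ts.dt)
            x = seg[1:-1]
        xs.append(x)
        ds.append(d)
        segs.append(np.full(x.shape[0], k))
    if skipped:
        warnings.warn(f"skipped {skipped} segment(s) too short for {scheme}")
    if not xs:
        raise ValueError("no segment long enough for derivative estimation")
    return DerivativeSet(
        x=np.concatenate(xs), dxdt=np.concatenate(ds),
        seg_ids=np.concatenate(segs), dt=ts.dt,
        unit_layout=ts.unit_layout, n_skipped=skipped,
    )


@dataclass
class DesignBlocks:
    """Per-target grouped regressor matrices, one block per candidate key."""

    target: int
    target_component: int
    family: str
    P: int
    order: str
    keys: list                      # candidate keys in canonical order
    blocks: dict                    # key -> (M_eff, P_key) column-normalized matrix
    col_norms: dict                 # key -> norms used for the scaling
    col_labels: dict                # key -> list of column descriptions
    degenerate: set = field(default_factory=set)  # keys with no usable column

    @property
    def m_eff(self) -> int:
        for b in self.blocks.values():
            if b.shape[1]:
                return b.shape[0]
        return 0

    def usable_keys(self) -> list:
        return [k for k in self.keys if k not in self.degenerate]


def place_rbf_centers(ds: DerivativeSet, pair, P: int, seed: int = 0) -> np.ndarray:
    """P radial-basis centers drawn without replacement from observed samples.

    ``pair`` gives the component column indices whose joint observations form
    the candidate's sample cloud; the centers are actual observed points, so
    they lie within the componentwise range of the data by construction.
    """
    cols = np.atleast_1d(np.asarray(pair, dtype=int))
    if P > ds.m_eff:
        raise ValueError(f"cannot place {P} centers from {ds.m_eff} samples")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(int(c) for c in cols))
    )
    rows = rng.choice(ds.m_eff, size=P, replace=False)
    return ds.x[np.ix_(rows, cols)]


def _cols_one_place(v: np.ndarray, family: str, P: int) -> tuple[list, list]:
    cols, labels = [], []
    if family in ("a", "b", "d", "e", "ef"):
        for p in range(1, P + 1):
            cols.append(v ** p)
            labels.append(f"pow{p}")
    if family in ("c", "f", "ef"):
        for p in range(1, P + 1):
            cols.append(np.sin(p * v))
            labels.append(f"sin{p}")
            cols.append(np.cos(p * v))
            labels.append(f"cos{p}")
    return cols, labels


def _cols_two_place(xi: np.ndarray, xj: np.ndarray, family: str, P: int,
                    centers: np.ndarray | None) -> tuple[list, list]:
    cols, labels = [], []
    if family == "a":
        d = xj - xi
        for p in range(1, P + 1):
            cols.append(d ** p)
            labels.append(f"diff{p}")
    elif family == "b":
        for tot in range(1, P + 1):
            for p1 in range(0, tot + 1):
                p2 = tot - p1
                cols.append((xi ** p1) * (xj ** p2))
                labels.append(f"mono{p1}_{p2}")
    elif family == "c":
        d = xj - xi
        for p in range(1, P + 1):
            cols.append(np.sin(p * d))
            labels.append(f"sin{p}d")
            cols.append(np.cos(p * d))
            labels.append(f"cos{p}d")
    elif family == "d":
        if centers is None:
            raise ValueError("family d requires radial-basis centers")
        for p, (ci, cj) in enumerate(centers, start=1):
            cols.append(1.0 / (1.0 + (xi - ci) ** 2 + (xj - cj) ** 2))
            labels.append(f"rbf{p}")
    elif family in ("e", "f", "ef"):
        c1, l1 = _cols_one_place(xj, family, P)
        cols.extend(c1)
        labels.extend(l1)
    else:
        raise ValueError(f"unknown family {family!r}")
    return cols, labels


def _self_block(ds: DerivativeSet, target: int, family: str, P: int) -> tuple[list, list]:
    """One-place basis over the target's own components (+ degree-2 cross terms)."""
    cols, labels = [], []
    comp_cols = ds.unit_layout[target]
    for d, c in enumerate(comp_cols):
        cc, ll = _cols_one_place(ds.x[:, c], family, P)
        cols.extend(cc)
        labels.extend([f"c{d + 1}_{s}" for s in ll])
    if len(comp_cols) > 1:
        for a in range(len(comp_cols)):
            for b in range(a + 1, len(comp_cols)):
                cols.append(ds.x[:, comp_cols[a]] * ds.x[:, comp_cols[b]])
                labels.append(f"c{a + 1}c{b + 1}")
    return cols, labels


def build_blocks(
    ds: DerivativeSet,
    target: int,
    family: str = "c",
    P: int = 4,
    order: str = "pairwise",
    target_component: int = 0,
    include_self: bool = True,
    rbf_centers: dict | None = None,
    rbf_seed: int = 0,
    max_candidates: int | None = None,
) -> DesignBlocks:
    """Grouped regressor blocks for one target unit (and target component).

    ``order="pairwise"`` builds one block per candidate unit j (including the
    self block unless disabled). ``order="pairwise_plus_hyper2"`` builds one
    block per unordered pair {j, k} of distinct units; pairs containing the
    target are the degenerate (pairwise) candidates. Columns are scaled to
    unit Euclidean norm; all-zero columns are dropped and fully degenerate
    blocks flagged unselectable.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if P < 1:
        raise ValueError("P must be >= 1")
    N = ds.n_units
    xi = ds.x[:, ds.unit_layout[target][target_component]]

    blocks, norms, labels_all = {}, {}, {}
    degenerate: set = set()
    keys: list = []

    def finish(key, cols, labels):
        keys.append(key)
        if not cols:
            degenerate.add(key)
            blocks[key] = np.empty((ds.m_eff, 0))
            norms[key] = np.empty(0)
            labels_all[key] = []
            return
        B = np.column_stack(cols)
        nrm = np.linalg.norm(B, axis=0)
        keep = nrm > 1e-12 * max(1.0, float(nrm.max()))
        if not keep.any():
            degenerate.add(key)
        B = B[:, keep] / np.where(nrm[keep] == 0, 1.0, nrm[keep])
        blocks[key] = B
        norms[key] = nrm[keep]
        labels_all[key] = [l for l, k in zip(labels, keep) if k]

    if order == "pairwise":
        for j in range(N):
            if j == target:
                if not include_self:
                    continue
                cols, labels = _self_block(ds, target, family, P)
                finish(j, cols, labels)
                continue
            cols, labels = [], []
            for d, c in enumerate(ds.unit_layout[j]):
                if family == "d":
                    if rbf_centers is not None and (target, j, d) in rbf_centers:
                        centers = rbf_centers[(target, j, d)]
                    else:
                        centers = place_rbf_centers(
                            ds, (ds.unit_layout[target][target_component], c), P,
                            seed=rbf_seed,
                        )
                else:
                    centers = None
                cc, ll = _cols_two_place(xi, ds.x[:, c], family, P, centers)
                cols.extend(cc)
                labels.extend([f"c{d + 1}_{s}" for s in ll])
            finish(j, cols, labels)
    elif order == "pairwise_plus_hyper2":
        if family in ("e", "f"):
            raise ValueError("one-place families cannot represent joint pair couplings")
        if any(len(c) > 1 for c in ds.unit_layout):
            raise ValueError("three-point candidates support scalar units only")
        count = 0
        for a in range(N):
            for b in range(a + 1, N):
                if max_candidates is not None and count >= max_candidates:
                    break
                xa = ds.x[:, ds.unit_layout[a][0]]
                xb = ds.x[:, ds.unit_layout[b][0]]
                if family == "d":
                    key = (a, b)
                    if rbf_centers is not None and key in rbf_centers:
                        centers = rbf_centers[key]
                    else:
                        centers = place_rbf_centers(
                            ds, (ds.unit_layout[a][0], ds.unit_layout[b][0]), P,
                            seed=rbf_seed,
                        )
                else:
                    centers = None
                # convention: difference argument is x_a - x_b (first index of
                # the canonical key minus the second); sin/cos pairs span the
                # same space either way
                cols, labels = _cols_two_place(
                    xb, xa, family, P,
                    centers[:, ::-1] if centers is not None else None)
                finish((a, b), cols, labels)
                count += 1
    else:
        raise ValueError(f"unknown order {order!r}")

    return DesignBlocks(
        target=target, target_component=target_component, family=family, P=P,
        order=order, keys=keys, blocks=blocks, col_norms=norms,
        col_labels=labels_all, degenerate=degenerate,
    )
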