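"""Random networks, hypernetworks and ground-truth dependency structure.

A :class:`NetworkSpec` carries the directed coupling matrix ``J`` (``J[i, j]``
is the weight of the link j -> i) and, for hypernetworks, a family of
second-order coupling matrices ``E[i]`` whose entry ``E[i][j, k]`` quantifies
how strongly units j and k jointly and directly influence unit i.

The ground truth against which reconstructions are scored is the *explicit
dependency matrix* of each unit: a binary vector whose j-th entry is 1 exactly
when the state of unit j appears on the right hand side of unit i's equation
of motion (including intrinsic self-dependencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "DependencyMatrix",
    "random_indegree_network",
    "random_hypernetwork",
    "dependency_matrices",
    "dependency_array",
    "MODELS",
]

MODELS = ("mm", "phase_net", "phase_hyper", "roessler", "glycolysis", "circadian")


def unit_rng(seed: int, unit: int) -> np.random.Generator:
    """Counter-based child generator: independent per unit, order-independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(unit,)))


@dataclass
class NetworkSpec:
    """Ground-truth interaction structure of a simulated system.

    Parameters
    ----------
    N : int
        Number of units.
    J : ndarray of shape (N, N)
        Pairwise coupling weights, ``J[i, j]`` = directed weight from j to i.
    E : dict[int, ndarray] or None
        Optional second-order couplings. ``E[i][j, k]`` is the joint influence
        of the ordered pair (j, k) on unit i; a pairwise link j -> i is encoded
        as the degenerate pair ``E[i][j, i]`` so the hypernetwork coupling form
        reduces exactly to the pairwise one.
    n_in : ndarray of shape (N,)
        Per-unit in-degree (number of incoming interactions).
    self_allowed : bool
        Whether self-links on the diagonal of ``J`` are permitted.
    """

    N: int
    J: np.ndarray
    E: dict[int, np.ndarray] | None = None
    n_in: np.ndarray = field(default=None)
    self_allowed: bool = False

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (self.N, self.N):
            raise ValueError(f"J must be ({self.N}, {self.N}), got {self.J.shape}")
        if not self.self_allowed and np.any(np.diag(self.J) != 0):
            raise ValueError("J has nonzero diagonal but self_allowed is False")
        if self.n_in is None:
            self.n_in = (self.J != 0).sum(axis=1)
            if self.E is not None:
                self.n_in = np.array(
                    [int((self.E.get(i, np.zeros(0)) != 0).sum()) for i in range(self.N)]
                )
        self.n_in = np.asarray(self.n_in, dtype=int)

    @property
    def is_hyper(self) -> bool:
        return self.E is not None

    def pair_keys(self, i: int) -> list[tuple[int, int]]:
        """Canonical unordered interaction keys {j, k} read off ``E[i]``."""
        if self.E is None or i not in self.E:
            return []
        jj, kk = np.nonzero(self.E[i])
        return sorted({(min(j, k), max(j, k)) for j, k in zip(jj.tolist(), kk.tolist())})


@dataclass
class DependencyMatrix:
    """Diagonal of the explicit dependency matrix of one target unit."""

    target: int
    diag: np.ndarray  # length-N binary vector, entry j = 1 iff j acts on target

    def __post_init__(self):
        self.diag = np.asarray(self.diag, dtype=int)
        if not np.isin(self.diag, (0, 1)).all():
            raise ValueError("dependency entries must be 0 or 1")


def random_indegree_network(
    N: int, n_in: int, seed: int, weight_scheme: str = "unit"
) -> NetworkSpec:
    """Directed random network with exactly ``n_in`` in-neighbors per unit.

    In-neighbors of each unit are drawn uniformly without replacement from the
    other units; generation is per-unit seeded so it is deterministic and
    order-independent.

    ``weight_scheme``: ``"unit"`` sets every link weight to 1 (homogeneous
    couplings, matching the 1/n_i normalisation of the simulated systems);
    ``"uniform_range"`` draws weights uniformly from [0.5, 1.0].
    """
    if not 1 <= n_in <= N - 1:
        raise ValueError(f"n_in must satisfy 1 <= n_in <= N-1, got n_in={n_in}, N={N}")
    if weight_scheme not in ("unit", "uniform_range"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    J = np.zeros((N, N))
    for i in range(N):
        rng = unit_rng(seed, i)
        others = np.delete(np.arange(N), i)
        nbrs = rng.choice(others, size=n_in, replace=False)
        if weight_scheme == "unit":
            J[i, nbrs] = 1.0
        else:
            J[i, nbrs] = rng.uniform(0.5, 1.0, size=n_in)
    return NetworkSpec(N=N, J=J, n_in=np.full(N, n_in))


def random_hypernetwork(N: int, n_in: int, p_h: float, seed: int) -> NetworkSpec:
    """Random mixture of pairwise and genuine two-unit (hypernetwork) couplings.

    Each of the ``n_in`` incoming interactions of unit i is, independently with
    probability ``p_h``, a genuine pair {j, k} with j != k != i (stored as an
    ordered entry of ``E[i]``), and otherwise a pairwise link j -> i stored as
    the degenerate pair ``E[i][j, i]``. ``p_h = 0`` reproduces a pure network,
    ``p_h = 1`` a pure hypernetwork.
    """
    if not 0.0 <= p_h <= 1.0:
        raise ValueError("p_h must lie in [0, 1]")
    if N < 3 and p_h > 0:
        raise ValueError("genuine pair interactions need N >= 3")
    max_keys = (N - 1) * (N - 2) // 2 if p_h == 1.0 else (N - 1) * N // 2
    if n_in > max_keys:
        raise ValueError(f"n_in={n_in} exceeds the number of admissible interactions")
    E: dict[int, np.ndarray] = {}
    for i in range(N):
        rng = unit_rng(seed, i)
        Ei = np.zeros((N, N))
        keys: set[tuple[int, int]] = set()
        while len(keys) < n_in:
            if rng.random() < p_h:
                j, k = rng.choice(np.delete(np.arange(N), i), size=2, replace=False)
            else:
                j = rng.choice(np.delete(np.arange(N), i))
                k = i
            key = (min(j, k), max(j, k))
            if key in keys:
                continue
            keys.add(key)
            Ei[j, k] = 1.0
        E[i] = Ei
    return NetworkSpec(N=N, J=np.zeros((N, N)), E=E, n_in=np.full(N, n_in))


# unit-level dependency sets of the two fixed biological systems (0-based);
# read off the right hand sides symbolically, checked against finite-difference
# sensitivities of the simulator RHS in the test suite.
GLYCOLYSIS_DEPS = {
    0: {0, 5},
    1: {0, 1, 4, 5},
    2: {1, 2, 4, 5},
    3: {2, 3, 4, 5, 6},
    4: {1, 3, 4},
    5: {0, 2, 5},
    6: {3, 6},
}
# state order: M_P, P_0, P_1, P_2, M_T, T_0, T_1, T_2, C, C_N
CIRCADIAN_DEPS = {
    0: {0, 9},
    1: {0, 1, 2},
    2: {1, 2, 3},
    3: {2, 3, 7, 8},
    4: {4, 9},
    5: {4, 5, 6},
    6: {5, 6, 7},
    7: {3, 6, 7, 8},
    8: {3, 7, 8, 9},
    9: {8, 9},
}


def dependency_matrices(model: str, spec: NetworkSpec | None = None) -> list[DependencyMatrix]:
    """Exact ground-truth explicit dependency matrices for a model system.

    For the generated systems (``mm``, ``phase_net``, ``phase_hyper``,
    ``roessler``) a :class:`NetworkSpec` is required; the fixed 7-species
    glycolytic and 10-species circadian systems need none. Dependencies are at
    unit level: for multi-component units, entry j is 1 if any component of j
    appears in any component equation of the target.
    """
    if model in ("glycolysis", "circadian"):
        deps = GLYCOLYSIS_DEPS if model == "glycolysis" else CIRCADIAN_DEPS
        n = len(deps)
        out = []
        for i in range(n):
            d = np.zeros(n, dtype=int)
            d[list(deps[i])] = 1
            out.append(DependencyMatrix(target=i, diag=d))
        return out
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if spec is None:
        raise ValueError(f"model {model!r} requires a NetworkSpec")
    N = spec.N
    out = []
    for i in range(N):
        d = np.zeros(N, dtype=int)
        if model in ("mm", "roessler"):
            # intrinsic terms (-x_i; the internal 3-component dynamics) always
            # make the unit depend on itself
            d[i] = 1
            d[spec.J[i] != 0] = 1
        elif model == "phase_net":
            d[spec.J[i] != 0] = 1
            # the coupling argument x_j - x_i involves the unit's own phase
            if d.any():
                d[i] = 1
        elif model == "phase_hyper":
            if spec.E is None:
                raise ValueError("phase_hyper requires a hypernetwork NetworkSpec")
            for j, k in spec.pair_keys(i):
                d[j] = 1
                d[k] = 1
        out.append(DependencyMatrix(target=i, diag=d))
    return out


def dependency_array(model: str, spec: NetworkSpec | None = None) -> np.ndarray:
    """Dependency matrices stacked into one (N, N) binary array, row = target."""
    mats = dependency_matrices(model, spec)
    return np.stack([m.diag for m in mats])
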