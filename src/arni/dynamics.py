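"""Right-hand sides of the five model systems.

All RHS callables are vectorised over a leading batch axis: the state has
shape ``(..., D)`` where ``D`` is the total number of state components, and
the return value has the same shape. Batched evaluation lets the integrator
advance all distributed-sampling segments simultaneously.

Model systems
-------------
``mm``
    Gene-regulation-like kinetics with Michaelis-Menten saturation:
    dx_i/dt = -x_i + (1/n_i) sum_j J_ij x_j / (1 + x_j).
``phase_net`` / ``phase_hyper``
    Phase-coupled oscillators with a two-Fourier-mode coupling
    g(d) = sin(d - 1.05) + 0.33 sin(2 d), applied to phase differences
    x_j - x_i (pairwise) or x_j - x_k (joint two-unit influence on i).
``roessler``
    Coupled chaotic Roessler oscillators, 3 components per unit, coupling
    (1/n_i) sum_j J_ij sin(x_j^1) entering the first component.
``glycolysis``
    Seven-species model of anaerobic glycolytic oscillations in yeast
    (Wolf & Heinrich 2000 parameterisation).
``circadian``
    Ten-variable PER/TIM circadian clock of Drosophila
    (Leloup & Goldbeter 1998 parameterisation).
"""

from __future__ import annotations

import numpy as np

from .netgen import NetworkSpec

__all__ = [
    "phase_coupling",
    "make_rhs",
    "GLYCOLYSIS_PARAMS",
    "CIRCADIAN_PARAMS",
]

PHASE_SHIFT = 1.05
PHASE_MODE2 = 0.33


def phase_coupling(delta: np.ndarray) -> np.ndarray:
    """Two-Fourier-mode coupling function of the phase-oscillator models."""
    return np.sin(delta - PHASE_SHIFT) + PHASE_MODE2 * np.sin(2.0 * delta)


def mm_rhs(spec: NetworkSpec):
    J = spec.J
    n_in = np.maximum(spec.n_in, 1).astype(float)

    def f(x):
        sat = x / (1.0 + x)
        return -x + (sat @ J.T) / n_in

    return f


def phase_net_rhs(spec: NetworkSpec, omega: np.ndarray):
    J = spec.J
    n_in = np.maximum(spec.n_in, 1).astype(float)

    def f(x):
        # delta[..., i, j] = x_j - x_i
        delta = x[..., None, :] - x[..., :, None]
        g = phase_coupling(delta)
        return omega + (J * g).sum(axis=-1) / n_in

    return f


def phase_hyper_rhs(spec: NetworkSpec, omega: np.ndarray):
    if spec.E is None:
        raise ValueError("phase_hyper requires a hypernetwork NetworkSpec")
    n_in = np.maximum(spec.n_in, 1).astype(float)
    # flatten the sparse interaction list: (target, j, k, weight)
    tgt, jj, kk, ww = [], [], [], []
    for i in range(spec.N):
        js, ks = np.nonzero(spec.E[i])
        for j, k in zip(js.tolist(), ks.tolist()):
            tgt.append(i)
            jj.append(j)
            kk.append(k)
            ww.append(spec.E[i][j, k])
    tgt = np.asarray(tgt)
    jj = np.asarray(jj)
    kk = np.asarray(kk)
    ww = np.asarray(ww, dtype=float)

    def f(x):
        out = np.broadcast_to(omega, x.shape).copy()
        terms = ww * phase_coupling(x[..., jj] - x[..., kk]) / n_in[tgt]
        # accumulate along the unit axis (duplicate targets must add up)
        np.add.at(np.moveaxis(out, -1, 0), tgt, np.moveaxis(terms, -1, 0))
        return out

    return f


def roessler_rhs(spec: NetworkSpec):
    J = spec.J
    n_in = np.maximum(spec.n_in, 1).astype(float)
    N = spec.N

    def f(x):
        X = x.reshape(x.shape[:-1] + (N, 3))
        x1, x2, x3 = X[..., 0], X[..., 1], X[..., 2]
        coup = (np.sin(x1) @ J.T) / n_in
        d1 = -x2 - x3 + coup
        d2 = x1 + 0.1 * x2
        d3 = 0.1 + x3 * (x1 - 18.0)
        return np.stack([d1, d2, d3], axis=-1).reshape(x.shape)

    return f


# Wolf & Heinrich (2000) anaerobic glycolysis in yeast; concentrations in mM,
# time in minutes. N is total NAD(H), A total adenine nucleotide.
GLYCOLYSIS_PARAMS = dict(
    J0=2.5, k1=100.0, k2=6.0, k3=16.0, k4=100.0, k5=1.28, k6=12.0,
    K1=0.52, q=4.0, N=1.0, A=4.0, kappa=13.0, psi=0.1, k=1.8,
)


def glycolysis_rhs(params: dict | None = None):
    p = dict(GLYCOLYSIS_PARAMS)
    if params:
        p.update(params)

    def f(x):
        S1, S2, S3, S4, S5, S6, S7 = (x[..., i] for i in range(7))
        v1 = p["k1"] * S1 * S6 / (1.0 + (S6 / p["K1"]) ** p["q"])
        v2 = p["k2"] * S2 * (p["N"] - S5)
        v3 = p["k3"] * S3 * (p["A"] - S6)
        v4 = p["k4"] * S4 * S5
        v6 = p["k6"] * S2 * S5
        ex = p["kappa"] * (S4 - S7)
        d = np.empty_like(x)
        d[..., 0] = p["J0"] - v1
        d[..., 1] = 2.0 * v1 - v2 - v6
        d[..., 2] = v2 - v3
        d[..., 3] = v3 - v4 - ex
        d[..., 4] = v2 - v4 - v6
        d[..., 5] = -2.0 * v1 + 2.0 * v3 - p["k5"] * S6
        d[..., 6] = p["psi"] * ex - p["k"] * S7
        return d

    return f


# Leloup & Goldbeter (1998) PER/TIM Drosophila circadian clock; concentrations
# in nM, time in hours. State order: M_P, P_0, P_1, P_2, M_T, T_0, T_1, T_2,
# C, C_N.
CIRCADIAN_PARAMS = dict(
    vsP=1.1, vsT=1.0, vmP=0.7, vmT=0.7, KmP=0.2, KmT=0.2, KIP=1.0, KIT=1.0,
    ksP=0.9, ksT=0.9, vdP=2.0, vdT=2.0, KdP=0.2, KdT=0.2,
    k1=0.6, k2=0.2, k3=1.2, k4=0.6, kd=0.01, kdC=0.01, kdN=0.01, n=4.0,
    K1P=2.0, K2P=2.0, K3P=2.0, K4P=2.0, K1T=2.0, K2T=2.0, K3T=2.0, K4T=2.0,
    V1P=8.0, V2P=1.0, V3P=8.0, V4P=1.0, V1T=8.0, V2T=1.0, V3T=8.0, V4T=1.0,
)

CIRCADIAN_STATES = ("M_P", "P_0", "P_1", "P_2", "M_T", "T_0", "T_1", "T_2", "C", "C_N")


def circadian_rhs(params: dict | None = None):
    p = dict(CIRCADIAN_PARAMS)
    if params:
        p.update(params)

    def mm(v, s, k):  # Michaelis-Menten flux v * s / (k + s)
        return v * s / (k + s)

    def f(x):
        MP, P0, P1, P2, MT, T0, T1, T2, C, CN = (x[..., i] for i in range(10))
        d = np.empty_like(x)
        rep_p = p["vsP"] * p["KIP"] ** p["n"] / (p["KIP"] ** p["n"] + CN ** p["n"])
        rep_t = p["vsT"] * p["KIT"] ** p["n"] / (p["KIT"] ** p["n"] + CN ** p["n"])
        assoc = p["k3"] * P2 * T2
        d[..., 0] = rep_p - mm(p["vmP"], MP, p["KmP"]) - p["kd"] * MP
        d[..., 1] = (p["ksP"] * MP - mm(p["V1P"], P0, p["K1P"])
                     + mm(p["V2P"], P1, p["K2P"]) - p["kd"] * P0)
        d[..., 2] = (mm(p["V1P"], P0, p["K1P"]) - mm(p["V2P"], P1, p["K2P"])
                     - mm(p["V3P"], P1, p["K3P"]) + mm(p["V4P"], P2, p["K4P"])
                     - p["kd"] * P1)
        d[..., 3] = (mm(p["V3P"], P1, p["K3P"]) - mm(p["V4P"], P2, p["K4P"])
                     - assoc + p["k4"] * C - mm(p["vdP"], P2, p["KdP"])
                     - p["kd"] * P2)
        d[..., 4] = rep_t - mm(p["vmT"], MT, p["KmT"]) - p["kd"] * MT
        d[..., 5] = (p["ksT"] * MT - mm(p["V1T"], T0, p["K1T"])
                     + mm(p["V2T"], T1, p["K2T"]) - p["kd"] * T0)
        d[..., 6] = (mm(p["V1T"], T0, p["K1T"]) - mm(p["V2T"], T1, p["K2T"])
                     - mm(p["V3T"], T1, p["K3T"]) + mm(p["V4T"], T2, p["K4T"])
                     - p["kd"] * T1)
        d[..., 7] = (mm(p["V3T"], T1, p["K3T"]) - mm(p["V4T"], T2, p["K4T"])
                     - assoc + p["k4"] * C - mm(p["vdT"], T2, p["KdT"])
                     - p["kd"] * T2)
        d[..., 8] = assoc - p["k4"] * C - p["k1"] * C + p["k2"] * CN - p["kdC"] * C
        d[..., 9] = p["k1"] * C - p["k2"] * CN - p["kdN"] * CN
        return d

    return f


def make_rhs(model: str, spec: NetworkSpec | None = None,
             params: dict | None = None, omega: np.ndarray | None = None):
    """Return the batched RHS callable for a named model system."""
    if model == "mm":
        return mm_rhs(spec)
    if model == "phase_net":
        return phase_net_rhs(spec, omega)
    if model == "phase_hyper":
        return phase_hyper_rhs(spec, omega)
    if model == "roessler":
        return roessler_rhs(spec)
    if model == "glycolysis":
        return glycolysis_rhs(params)
    if model == "circadian":
        return circadian_rhs(params)
    raise ValueError(f"unknown model {model!r}")
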