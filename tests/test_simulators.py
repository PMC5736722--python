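"""Simulator tests, including an independently coded RHS oracle.

The oracle functions below are literal scalar-loop transcriptions of the model
equations, written separately from the vectorised implementations in
``arni.dynamics``; agreement is required to 1e-12 at random states.
"""

import numpy as np
import pytest

import arni
from arni import dynamics
from arni.netgen import dependency_array


# ---------------------------------------------------------------- oracles

def oracle_mm(x, J, n_in):
    N = len(x)
    out = np.zeros(N)
    for i in range(N):
        s = 0.0
        for j in range(N):
            s += J[i, j] * x[j] / (1.0 + x[j])
        out[i] = -x[i] + s / max(n_in[i], 1)
    return out


def oracle_phase(x, J, n_in, omega):
    N = len(x)
    out = np.zeros(N)
    for i in range(N):
        s = 0.0
        for j in range(N):
            d = x[j] - x[i]
            s += J[i, j] * (np.sin(d - 1.05) + 0.33 * np.sin(2 * d))
        out[i] = omega[i] + s / max(n_in[i], 1)
    return out


def oracle_phase_hyper(x, E, n_in, omega):
    N = len(x)
    out = np.array(omega, dtype=float)
    for i in range(N):
        s = 0.0
        for j in range(N):
            for k in range(N):
                if E[i][j, k] != 0:
                    d = x[j] - x[k]
                    s += E[i][j, k] * (np.sin(d - 1.05) + 0.33 * np.sin(2 * d))
        out[i] += s / max(n_in[i], 1)
    return out


def oracle_roessler(x, J, n_in):
    N = len(x) // 3
    out = np.zeros(3 * N)
    for i in range(N):
        x1, x2, x3 = x[3 * i], x[3 * i + 1], x[3 * i + 2]
        s = 0.0
        for j in range(N):
            s += J[i, j] * np.sin(x[3 * j])
        out[3 * i] = -x2 - x3 + s / max(n_in[i], 1)
        out[3 * i + 1] = x1 + 0.1 * x2
        out[3 * i + 2] = 0.1 + x3 * (x1 - 18.0)
    return out


def oracle_glycolysis(x):
    p = dynamics.GLYCOLYSIS_PARAMS
    S1, S2, S3, S4, S5, S6, S7 = x
    v1 = p["k1"] * S1 * S6 / (1.0 + (S6 / p["K1"]) ** p["q"])
    return np.array([
        p["J0"] - v1,
        2 * v1 - p["k2"] * S2 * (p["N"] - S5) - p["k6"] * S2 * S5,
        p["k2"] * S2 * (p["N"] - S5) - p["k3"] * S3 * (p["A"] - S6),
        p["k3"] * S3 * (p["A"] - S6) - p["k4"] * S4 * S5
        - p["kappa"] * (S4 - S7),
        p["k2"] * S2 * (p["N"] - S5) - p["k4"] * S4 * S5 - p["k6"] * S2 * S5,
        -2 * v1 + 2 * p["k3"] * S3 * (p["A"] - S6) - p["k5"] * S6,
        p["psi"] * p["kappa"] * (S4 - S7) - p["k"] * S7,
    ])


def oracle_circadian(x):
    p = dynamics.CIRCADIAN_PARAMS
    MP, P0, P1, P2, MT, T0, T1, T2, C, CN = x
    n = p["n"]
    return np.array([
        p["vsP"] * p["KIP"] ** n / (p["KIP"] ** n + CN ** n)
        - p["vmP"] * MP / (p["KmP"] + MP) - p["kd"] * MP,
        p["ksP"] * MP - p["V1P"] * P0 / (p["K1P"] + P0)
        + p["V2P"] * P1 / (p["K2P"] + P1) - p["kd"] * P0,
        p["V1P"] * P0 / (p["K1P"] + P0) - p["V2P"] * P1 / (p["K2P"] + P1)
        - p["V3P"] * P1 / (p["K3P"] + P1) + p["V4P"] * P2 / (p["K4P"] + P2)
        - p["kd"] * P1,
        p["V3P"] * P1 / (p["K3P"] + P1) - p["V4P"] * P2 / (p["K4P"] + P2)
        - p["k3"] * P2 * T2 + p["k4"] * C - p["vdP"] * P2 / (p["KdP"] + P2)
        - p["kd"] * P2,
        p["vsT"] * p["KIT"] ** n / (p["KIT"] ** n + CN ** n)
        - p["vmT"] * MT / (p["KmT"] + MT) - p["kd"] * MT,
        p["ksT"] * MT - p["V1T"] * T0 / (p["K1T"] + T0)
        + p["V2T"] * T1 / (p["K2T"] + T1) - p["kd"] * T0,
        p["V1T"] * T0 / (p["K1T"] + T0) - p["V2T"] * T1 / (p["K2T"] + T1)
        - p["V3T"] * T1 / (p["K3T"] + T1) + p["V4T"] * T2 / (p["K4T"] + T2)
        - p["kd"] * T1,
        p["V3T"] * T1 / (p["K3T"] + T1) - p["V4T"] * T2 / (p["K4T"] + T2)
        - p["k3"] * P2 * T2 + p["k4"] * C - p["vdT"] * T2 / (p["KdT"] + T2)
        - p["kd"] * T2,
        p["k3"] * P2 * T2 - p["k4"] * C - p["k1"] * C + p["k2"] * CN
        - p["kdC"] * C,
        p["k1"] * C - p["k2"] * CN - p["kdN"] * CN,
    ])


class TestRhsAgainstOracle:
    """Vectorised RHS implementations vs independent literal transcriptions."""

    def test_networked_models(self):
        rng = np.random.default_rng(0)
        spec = arni.random_indegree_network(N=6, n_in=2, seed=4)
        hspec = arni.random_hypernetwork(N=6, n_in=2, p_h=0.5, seed=4)
        omega = rng.standard_normal(6)
        cases = [
            ("mm", dynamics.make_rhs("mm", spec),
             lambda x: oracle_mm(x, spec.J, spec.n_in), 6, (0.0, 3.0)),
            ("phase_net", dynamics.make_rhs("phase_net", spec, omega=omega),
             lambda x: oracle_phase(x, spec.J, spec.n_in, omega), 6, (-4, 4)),
            ("phase_hyper", dynamics.make_rhs("phase_hyper", hspec, omega=omega),
             lambda x: oracle_phase_hyper(x, hspec.E, hspec.n_in, omega), 6, (-4, 4)),
            ("roessler", dynamics.make_rhs("roessler", spec),
             lambda x: oracle_roessler(x, spec.J, spec.n_in), 18, (-15, 15)),
        ]
        for name, f, oracle, dim, (lo, hi) in cases:
            X = rng.uniform(lo, hi, size=(250, dim))
            batch = f(X)
            for row in range(250):
                expect = oracle(X[row])
                assert np.allclose(batch[row], expect, atol=1e-12), name
                # single-state evaluation agrees with batched
                assert np.allclose(f(X[row]), expect, atol=1e-12), name

    @pytest.mark.parametrize("model,oracle,dim", [
        ("glycolysis", oracle_glycolysis, 7),
        ("circadian", oracle_circadian, 10),
    ])
    def test_fixed_models(self, model, oracle, dim):
        rng = np.random.default_rng(1)
        f = dynamics.make_rhs(model)
        X = rng.uniform(0.05, 3.0, size=(500, dim))
        batch = f(X)
        for row in range(500):
            assert np.allclose(batch[row], oracle(X[row]), atol=1e-12)


class TestPointExamples:
    def test_phase_two_unit_closed_form(self):
        spec = arni.NetworkSpec(N=2, J=np.array([[0.0, 1.0], [0.0, 0.0]]),
                                n_in=np.array([1, 1]))
        f = dynamics.make_rhs("phase_net", spec, omega=np.zeros(2))
        out = f(np.zeros(2))
        assert out[0] == pytest.approx(np.sin(-1.05), abs=1e-14)
        assert out[1] == 0.0

    def test_hyper_equal_phases(self):
        E = {0: np.zeros((3, 3)), 1: np.zeros((3, 3)), 2: np.zeros((3, 3))}
        E[0][1, 2] = 1.0
        spec = arni.NetworkSpec(N=3, J=np.zeros((3, 3)), E=E,
                                n_in=np.array([1, 1, 1]))
        f = dynamics.make_rhs("phase_hyper", spec, omega=np.zeros(3))
        # x_j = x_k makes the second mode vanish: coupling = sin(-1.05)
        out = f(np.array([0.3, 0.7, 0.7]))
        assert out[0] == pytest.approx(np.sin(-1.05), abs=1e-14)

    def test_roessler_coefficients(self):
        spec = arni.NetworkSpec(N=1, J=np.zeros((1, 1)), n_in=np.array([0]))
        f = dynamics.make_rhs("roessler", spec)
        d = f(np.array([1.0, 1.0, 1.0]))
        assert d[1] == pytest.approx(1.1, abs=1e-14)
        d = f(np.array([18.0, 0.0, 5.0]))
        assert d[2] == pytest.approx(0.1, abs=1e-14)

    def test_glycolysis_exchange_symmetry(self):
        f = dynamics.glycolysis_rhs()
        f2 = dynamics.glycolysis_rhs({"kappa": 99.0})
        x = np.array([1.0, 2.0, 0.3, 0.25, 0.2, 1.5, 0.25])  # S4 == S7
        assert np.allclose(f(x), f2(x), atol=1e-14)

    def test_glycolysis_nadh_at_zero_s2(self):
        f = dynamics.glycolysis_rhs()
        p = dynamics.GLYCOLYSIS_PARAMS
        x = np.array([1.0, 0.0, 0.3, 0.25, 0.2, 1.5, 0.1])
        assert f(x)[4] == pytest.approx(-p["k4"] * 0.25 * 0.2, abs=1e-14)

    def test_circadian_complex_at_origin(self):
        f = dynamics.circadian_rhs()
        x = np.ones(10)
        x[8] = x[9] = 0.0  # C = C_N = 0
        assert f(x)[9] == 0.0

    def test_circadian_per_mrna_without_repression(self):
        p = dynamics.CIRCADIAN_PARAMS
        f = dynamics.circadian_rhs()
        x = np.zeros(10)
        x[0] = 0.8  # M_P
        expect = (p["vsP"] - p["vmP"] * 0.8 / (p["KmP"] + 0.8) - p["kd"] * 0.8)
        assert f(x)[0] == pytest.approx(expect, abs=1e-14)


class TestSensitivityOracle:
    """Dependency matrices match finite-difference sensitivities of the RHS."""

    @staticmethod
    def _fd_dependency(f, states, layout, eps=1e-6, thresh=1e-8):
        n_units = len(layout)
        dep = np.zeros((n_units, n_units), dtype=int)
        for x in states:
            for j_unit, cols in enumerate(layout):
                for c in cols:
                    xp, xm = x.copy(), x.copy()
                    xp[c] += eps
                    xm[c] -= eps
                    grad = (f(xp) - f(xm)) / (2 * eps)
                    for i_unit, icols in enumerate(layout):
                        if np.max(np.abs(grad[icols])) > thresh:
                            dep[i_unit, j_unit] = 1
        return dep

    @pytest.mark.parametrize("model", ["glycolysis", "circadian"])
    def test_fixed_systems(self, model):
        rng = np.random.default_rng(3)
        dim = 7 if model == "glycolysis" else 10
        f = dynamics.make_rhs(model)
        states = rng.uniform(0.1, 2.5, size=(100, dim))
        layout = [[i] for i in range(dim)]
        assert np.array_equal(self._fd_dependency(f, states, layout),
                              dependency_array(model))

    def test_generated_systems(self):
        rng = np.random.default_rng(4)
        spec = arni.random_indegree_network(N=6, n_in=2, seed=9)
        omega = rng.standard_normal(6)
        cases = [
            ("mm", dynamics.make_rhs("mm", spec),
             rng.uniform(0.2, 2.0, size=(30, 6)), [[i] for i in range(6)]),
            ("phase_net", dynamics.make_rhs("phase_net", spec, omega=omega),
             rng.uniform(-3, 3, size=(30, 6)), [[i] for i in range(6)]),
            ("roessler", dynamics.make_rhs("roessler", spec),
             rng.uniform(-8, 8, size=(30, 18)),
             [[3 * i, 3 * i + 1, 3 * i + 2] for i in range(6)]),
        ]
        for model, f, states, layout in cases:
            assert np.array_equal(self._fd_dependency(f, states, layout),
                                  dependency_array(model, spec)), model


class TestIntegration:
    def test_decoupled_mm_decays_exponentially(self):
        spec = arni.NetworkSpec(N=4, J=np.zeros((4, 4)))
        x0 = np.array([[0.5, 1.0, 1.5, 2.0]])
        cfg = arni.SimConfig(dt=0.1, m=11, S=1, seed=0, substeps=100,
                             init=lambda rng, S: x0)
        ts = arni.simulate_mm(spec, cfg)
        t = np.arange(11) * 0.1
        expect = x0 * np.exp(-t)[:, None]
        assert np.allclose(ts.segments[0], expect, rtol=1e-6)

    def test_mm_reaches_steady_state(self):
        # the steady state is approached algebraically (the linearization has
        # a zero eigenvalue along the homogeneous mode), so run far out
        spec = arni.random_indegree_network(N=10, n_in=3, seed=0)
        cfg = arni.SimConfig(dt=0.25, m=12000, S=1, seed=0, substeps=2)
        ts = arni.simulate_mm(spec, cfg)
        f = dynamics.make_rhs("mm", spec)
        assert np.max(np.abs(f(ts.segments[0][-1]))) < 1e-6

    def test_sample_counts_and_modes(self):
        spec = arni.random_indegree_network(N=5, n_in=2, seed=1)
        ts = arni.sample("phase_net", spec,
                         arni.SimConfig(dt=0.05, m=10, S=100, seed=1),
                         mode="distributed")
        assert len(ts.segments) == 100 and ts.M == 1000
        ts = arni.sample("phase_net", spec,
                         arni.SimConfig(dt=0.05, m=1000, S=1, seed=1),
                         mode="continuous")
        assert len(ts.segments) == 1 and ts.M == 1000
        with pytest.raises(ValueError):
            arni.sample("phase_net", spec,
                        arni.SimConfig(dt=0.05, m=10, S=2, seed=1),
                        mode="continuous")

    def test_determinism(self):
        spec = arni.random_indegree_network(N=5, n_in=2, seed=1)
        cfg = arni.SimConfig(dt=0.05, m=10, S=20, seed=3, eta=0.1)
        a = arni.simulate_phase(spec, cfg)
        b = arni.simulate_phase(spec, cfg)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa, sb)

    def test_roessler_dimensions(self):
        spec = arni.random_indegree_network(N=20, n_in=5, seed=2)
        ts = arni.simulate_roessler(spec, arni.SimConfig(dt=0.05, m=5, S=3, seed=2))
        assert ts.segments[0].shape == (5, 60)
        assert ts.unit_layout[19] == [57, 58, 59]

    def test_deterministic_convergence_order(self):
        # Heun is second order: halving the internal step shrinks the error ~4x
        spec = arni.random_indegree_network(N=6, n_in=2, seed=6)

        def endpoint(substeps):
            cfg = arni.SimConfig(dt=0.5, m=3, S=1, seed=6, substeps=substeps)
            return arni.simulate_mm(spec, cfg).segments[0][-1]

        ref = endpoint(64)
        e1 = np.max(np.abs(endpoint(4) - ref))
        e2 = np.max(np.abs(endpoint(8) - ref))
        assert e1 / e2 > 2.5

    def test_noise_variance_scaling(self):
        # pure Brownian phases: Var[x(dt) - x(0)] = eta^2 * dt
        spec = arni.NetworkSpec(N=2, J=np.zeros((2, 2)))
        eta, dt = 0.5, 0.1
        cfg = arni.SimConfig(dt=dt, m=2, S=4000, seed=8, eta=eta,
                             omega=np.zeros(2),
                             init=lambda rng, S: np.zeros((S, 2)))
        ts = arni.simulate_phase(spec, cfg)
        X = np.stack(ts.segments)  # (S, 2, 2)
        incr = X[:, 1, :] - X[:, 0, :]
        var = incr.var()
        assert var == pytest.approx(eta**2 * dt, rel=0.1)

    def test_glycolysis_stays_positive(self):
        ts = arni.simulate_glycolysis(arni.SimConfig(dt=0.01, m=50, S=5, seed=2))
        X, _ = ts.stacked()
        assert X.min() >= 0.0

    def test_divergence_guard(self):
        spec = arni.NetworkSpec(N=1, J=np.zeros((1, 1)))
        cfg = arni.SimConfig(dt=0.5, m=50, S=1, seed=0, substeps=1,
                             init=lambda rng, S: np.full((S, 3), 30.0))
        with pytest.raises(arni.IntegrationError):
            arni.simulate_roessler(spec, cfg)
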