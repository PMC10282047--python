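"""Brute-force oracle for the GW objective on tiny instances.

Independent of the package solver: enumerates all permutation couplings
(exact extreme points for uniform equal marginals) and refines a large batch
of random feasible couplings by projected gradient (mirror descent with
Sinkhorn re-projection), returning the best objective found.
"""

import itertools

import numpy as np


def objective(dA, dB, T, p, q):
    cA = 0.5 * p @ (dA ** 2) @ p
    cB = 0.5 * q @ (dB ** 2) @ q
    return float(cA + cB - np.sum((dA @ T @ dB) * T))


def _batch_objective(dA, dB, Ts, p, q):
    cA = 0.5 * p @ (dA ** 2) @ p
    cB = 0.5 * q @ (dB ** 2) @ q
    inner = np.einsum("ij,bjk,kl,bil->b", dA, Ts, dB, Ts, optimize=True)
    return cA + cB - inner


def _batch_project(Ts, p, q, n_iter=60):
    """Alternating marginal scaling of a batch of positive matrices."""
    for _ in range(n_iter):
        Ts *= (p / Ts.sum(axis=2))[:, :, None]
        Ts *= (q / Ts.sum(axis=1))[:, None, :]
    return Ts


def gw_bruteforce(dA, dB, n_random=10_000, n_steps=30, seed=0):
    """Best objective over all permutations and refined random couplings."""
    dA = np.asarray(dA, float)
    dB = np.asarray(dB, float)
    n, m = dA.shape[0], dB.shape[0]
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)

    best = np.inf
    if n == m:
        for perm in itertools.permutations(range(n)):
            T = np.zeros((n, n))
            T[np.arange(n), perm] = 1.0 / n
            best = min(best, objective(dA, dB, T, p, q))

    rng = np.random.default_rng(seed)
    Ts = rng.random((n_random, n, m)) + 1e-3
    Ts = _batch_project(Ts, p, q)
    scale = max(float(np.abs(dA).max() * np.abs(dB).max()), 1e-12)
    for step in range(n_steps):
        G = -2.0 * np.einsum("ij,bjk,kl->bil", dA, Ts, dB, optimize=True)
        eta = 2.0 / (scale * (1.0 + step))
        Ts = Ts * np.exp(-eta * G)
        Ts = _batch_project(Ts, p, q, n_iter=20)
    vals = _batch_objective(dA, dB, Ts, p, q)
    best = min(best, float(vals.min()))

    # polish the most promising candidates with a constrained local optimizer
    top = np.argsort(vals)[:20]
    best = min(best, _slsqp_polish(dA, dB, Ts[top], p, q))
    return best


def _slsqp_polish(dA, dB, starts, p, q):
    """Local minimization over the transport polytope from several starts."""
    from scipy.optimize import minimize

    n, m = dA.shape[0], dB.shape[0]
    cA = 0.5 * p @ (dA ** 2) @ p
    cB = 0.5 * q @ (dB ** 2) @ q

    def fun(x):
        T = x.reshape(n, m)
        M = dA @ T @ dB
        return cA + cB - np.sum(M * T), (-2.0 * M).ravel()

    cons = []
    for i in range(n):
        mask = np.zeros(n * m)
        mask[i * m:(i + 1) * m] = 1.0
        cons.append({"type": "eq", "fun": (lambda x, mk=mask, t=p[i]: x @ mk - t),
                     "jac": (lambda x, mk=mask: mk)})
    for j in range(m - 1):
        mask = np.zeros(n * m)
        mask[j::m] = 1.0
        cons.append({"type": "eq", "fun": (lambda x, mk=mask, t=q[j]: x @ mk - t),
                     "jac": (lambda x, mk=mask: mk)})
    best = np.inf
    for T0 in starts:
        res = minimize(fun, T0.ravel(), jac=True, method="SLSQP",
                       bounds=[(0, 1)] * (n * m), constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-14})
        T = np.clip(res.x.reshape(n, m), 0, None)
        best = min(best, objective(dA, dB, T, p, q))
    return best


def instance_bank(n_instances=20, seed=123):
    """Euclidean distance matrices of random tiny point clouds (2-4 points)."""
    rng = np.random.default_rng(seed)
    bank = []
    for _ in range(n_instances):
        n = int(rng.integers(2, 5))
        pts = rng.normal(size=(n, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        bank.append(D)
    return bank
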