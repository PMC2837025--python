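"""Numerical kernels for penalized Cox partial-likelihood estimation.

All kernels operate on data pre-sorted by descending follow-up time, so
risk-set sums are prefix sums. ``riskend[i]`` is the number of subjects
with T >= T_i (ties included, Breslow convention).

JIT-compiled with numba when available; the same code runs un-jitted.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def prox_bridge(z: float, a: float, lam: float, gamma: float) -> float:
    """Minimize (a/2)(b - z)^2 + lam*|b|^gamma over b, for 0 < gamma < 1.

    The solution is either 0 or the larger stationary point; the boundary
    between the two regimes is available in closed form. For gamma = 1/2
    the stationary point itself is a root of a depressed cubic and is
    computed exactly (half-thresholding operator); other gamma fall back
    to a bisection on the stationarity condition.
    """
    if lam <= 0.0:
        return z
    if a <= 0.0:
        return 0.0
    s = 1.0
    if z < 0.0:
        s = -1.0
        z = -z
    if z == 0.0:
        return 0.0
    # boundary minimizer and the lam at which it ties with 0
    bstar = 2.0 * z * (1.0 - gamma) / (2.0 - gamma)
    lam_thr = a * bstar ** (1.0 - gamma) * (z - bstar) / gamma
    if lam >= lam_thr:
        return 0.0
    if gamma == 0.5:
        # larger root of u^3 - z*u + lam/(2a) = 0 with b = u^2
        q = lam / (2.0 * a)
        arg = -(3.0 * q) / (2.0 * z) * np.sqrt(3.0 / z)
        if arg < -1.0:
            arg = -1.0
        elif arg > 1.0:
            arg = 1.0
        theta = np.arccos(arg)
        u = 2.0 * np.sqrt(z / 3.0) * np.cos(theta / 3.0)
        return s * u * u
    # general gamma: the local minimum lies in (bstar, z); the derivative
    # a*(b - z) + lam*gamma*b^(gamma-1) crosses 0 from below there
    lo = bstar
    hi = z
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = a * (mid - z) + lam * gamma * mid ** (gamma - 1.0)
        if d < 0.0:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    if 0.5 * a * (b - z) ** 2 + lam * b ** gamma < 0.5 * a * z * z:
        return s * b
    return 0.0


@njit(cache=True)
def cox_nll(eta: np.ndarray, delta: np.ndarray, riskend: np.ndarray) -> float:
    """Negative log partial likelihood divided by n (Breslow ties)."""
    n = eta.shape[0]
    emax = eta[0]
    for i in range(1, n):
        if eta[i] > emax:
            emax = eta[i]
    total = 0.0
    csum = 0.0
    p = 0
    for i in range(n):
        while p < riskend[i]:
            csum += np.exp(eta[p] - emax)
            p += 1
        if delta[i] > 0.0:
            c = csum if csum > 1e-150 else 1e-150  # underflowed risk set
            total += eta[i] - (np.log(c) + emax)
    return -total / n


@njit(cache=True)
def cox_grad_hess_diag(eta, delta, riskend):
    """Per-subject gradient u and diagonal Hessian weight w of the
    log partial likelihood (not scaled by n), plus its value.

    u_k = delta_k - e^{eta_k} * A_k,  w_k = e^{eta_k} A_k - e^{2 eta_k} B_k,
    with A_k = sum over deaths whose risk set contains k of 1/S_j and
    B_k the same sum of 1/S_j^2.
    """
    n = eta.shape[0]
    emax = eta[0]
    for i in range(1, n):
        if eta[i] > emax:
            emax = eta[i]
    ew = np.empty(n)
    for i in range(n):
        ew[i] = np.exp(eta[i] - emax)
    # prefix sums of ew give scaled risk-set totals
    addA = np.zeros(n)
    addB = np.zeros(n)
    loglik = 0.0
    csum = 0.0
    p = 0
    for i in range(n):
        while p < riskend[i]:
            csum += ew[p]
            p += 1
        if delta[i] > 0.0:
            c = csum if csum > 1e-150 else 1e-150  # underflowed risk set
            loglik += eta[i] - (np.log(c) + emax)
            addA[riskend[i] - 1] += 1.0 / c
            addB[riskend[i] - 1] += 1.0 / (c * c)
    u = np.empty(n)
    w = np.empty(n)
    accA = 0.0
    accB = 0.0
    for k in range(n - 1, -1, -1):
        accA += addA[k]
        accB += addB[k]
        u[k] = delta[k] - ew[k] * accA
        wk = ew[k] * accA - ew[k] * ew[k] * accB
        if wk < 0.0:
            wk = 0.0
        w[k] = wk
    return u, w, loglik


@njit(cache=True)
def fit_bridge(X, delta, riskend, lam, gamma, beta0, max_outer, tol):
    """Penalized Cox fit by IRLS with coordinate-wise bridge thresholding.

    Outer loop: quadratic expansion of the partial likelihood at the
    current eta (diagonal Hessian). Inner loop: cyclic coordinate descent
    on the penalized weighted least squares, each coordinate solved by
    the exact scalar bridge operator. Step-halving keeps the penalized
    objective non-increasing. Returns (beta, objective, converged, iters).
    """
    n, m = X.shape
    beta = beta0.copy()
    eta = X @ beta
    pen = 0.0
    for j in range(m):
        if beta[j] != 0.0:
            pen += np.abs(beta[j]) ** gamma
    obj = cox_nll(eta, delta, riskend) + lam * pen
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        u, w, _ = cox_grad_hess_diag(eta, delta, riskend)
        # working residual r = z - eta with z = eta + u/w  =>  r = u/w; kept
        # in weighted form: track q_i = w_i * r_i = u_i to avoid 0/0
        beta_new = beta.copy()
        eta_try = eta.copy()
        q = u.copy()
        # inner cyclic passes on the frozen quadratic
        for _inner in range(50):
            delta_max = 0.0
            for j in range(m):
                aj = 0.0
                gj = 0.0
                for i in range(n):
                    aj += w[i] * X[i, j] * X[i, j]
                    gj += X[i, j] * q[i]
                aj /= n
                gj /= n
                if aj <= 1e-12:
                    continue
                zj = beta_new[j] + gj / aj
                bnew = prox_bridge(zj, aj, lam, gamma)
                # trust region against divergence under quasi-separation
                if bnew > 100.0:
                    bnew = 100.0
                elif bnew < -100.0:
                    bnew = -100.0
                diff = bnew - beta_new[j]
                if diff != 0.0:
                    for i in range(n):
                        q[i] -= w[i] * X[i, j] * diff
                    beta_new[j] = bnew
                    ad = np.abs(diff)
                    if ad > delta_max:
                        delta_max = ad
            if delta_max < tol:
                break
        # step-halving safeguard against the frozen-quadratic mismatch
        step = 1.0
        accepted = False
        obj_try = obj
        for _h in range(12):
            pen = 0.0
            for j in range(m):
                b = beta[j] + step * (beta_new[j] - beta[j])
                if b != 0.0:
                    pen += np.abs(b) ** gamma
            for i in range(n):
                s = 0.0
                for j in range(m):
                    s += X[i, j] * (beta[j] + step * (beta_new[j] - beta[j]))
                eta_try[i] = s
            obj_try = cox_nll(eta_try, delta, riskend) + lam * pen
            if obj_try <= obj + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        move = 0.0
        for j in range(m):
            b = beta[j] + step * (beta_new[j] - beta[j])
            d = np.abs(b - beta[j])
            if d > move:
                move = d
            beta[j] = b
        eta[:] = eta_try
        obj = obj_try
        if move < tol:
            converged = True
            break
    # snap half-step leftovers below the zero threshold
    for j in range(m):
        if np.abs(beta[j]) < 1e-10:
            beta[j] = 0.0
    return beta, obj, converged, it


@njit(cache=True)
def fit_bridge_path(X, delta, riskend, lambdas, gamma, max_outer, tol):
    """Warm-started fits along a descending lambda path.

    Returns a (len(lambdas), m) coefficient matrix; row k is the fit at
    lambdas[k], started from the previous row's solution.
    """
    m = X.shape[1]
    out = np.zeros((lambdas.shape[0], m))
    conv = np.zeros(lambdas.shape[0], dtype=np.int64)
    beta = np.zeros(m)
    for k in range(lambdas.shape[0]):
        beta, _obj, ok, _it = fit_bridge(
            X, delta, riskend, lambdas[k], gamma, beta, max_outer, tol
        )
        out[k] = beta
        conv[k] = 1 if ok else 0
    return out, conv
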