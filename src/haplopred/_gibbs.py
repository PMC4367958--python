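"""Numba Gibbs-sampling kernel shared by the BLUP and mixture models.

The model is  y = 1*mu + M g + Z a + eps,  eps_i ~ N(0, sigma2_e / w_i), with
g ~ N(0, I sigma2_g) (BLUP) or a four-component normal mixture with fixed
proportions (mixture), and a ~ N(0, A sigma2_a).  Variance components carry
bounded-uniform priors on (0, vmax].

Implementation notes (constraints, not narration):

* The residual vector ``e`` is maintained incrementally; every scalar update
  adjusts only the records it touches.
* A flat prior on a variance with ``count`` attached effects gives the
  conditional  v^{-count/2} * exp(-S/(2v))  on (0, vmax]; for count >= 3 this
  is an inverse-gamma(count/2 - 1, S/2) drawn directly (redrawn if above
  vmax); for count in {1, 2} the density is not inverse-gamma-proper and a
  log-scale Metropolis step targets it exactly; for count == 0 it is flat, so
  the draw is uniform on the admissible interval.
* The mixture's ordering constraint v1 <= v2 <= v3 <= v4 is enforced by
  rejecting (keeping the previous value on) draws that leave the interval
  bounded by the neighbouring components, which is a valid
  Metropolis-within-Gibbs move; rejections are counted as a diagnostic.
* Column update order is fixed map order for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_VFLOOR = 1e-300


@njit(cache=False)
def _logf_var(v, count, s):
    return -0.5 * count * np.log(v) - s / (2.0 * v)


@njit(cache=False)
def _draw_var(vprev, count, s, lower, upper, step):
    """One update of a variance with flat prior restricted to (lower, upper].

    Returns (value, rejected_flag)."""
    if upper <= lower:
        return vprev, 1
    if count == 0 or s <= _VFLOOR:
        return np.random.uniform(lower, upper), 0
    if count >= 3:
        shape = 0.5 * count - 1.0
        scale = 2.0 / s
        for _ in range(64):
            t = np.random.gamma(shape, scale)
            if t <= 0.0:
                continue
            cand = 1.0 / t
            if lower < cand <= upper:
                return cand, 0
        return vprev, 1
    # count in {1, 2}: Metropolis on log v
    cand = vprev * np.exp(step * np.random.normal(0.0, 1.0))
    if not (lower < cand <= upper):
        return vprev, 1
    logr = (_logf_var(cand, count, s) - _logf_var(vprev, count, s)
            + np.log(cand) - np.log(vprev))
    if np.log(np.random.random()) < logr:
        return cand, 0
    return vprev, 1


@njit(cache=False)
def run_chain(
    y, w, M, Ainv, rec_of_anim,
    n_cycles, burn_in, thin, seed,
    mixture, pi,
    v_comp_init, vg_init, va_init, ve_init, vmax,
    update_variances, keep_samples,
):
    np.random.seed(seed)
    n = y.shape[0]
    q = M.shape[1]
    na = Ainv.shape[0]

    mu = 0.0
    sw = 0.0
    for i in range(n):
        sw += w[i]
        mu += w[i] * y[i]
    mu /= sw
    g = np.zeros(q)
    a = np.zeros(na)
    comp = np.zeros(q, dtype=np.int64)
    vcomp = v_comp_init.copy()
    vg = vg_init
    va = va_init
    ve = ve_init

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    mtm = np.zeros(q)
    for j in range(q):
        acc = 0.0
        for i in range(n):
            acc += w[i] * M[i, j] * M[i, j]
        mtm[j] = acc

    n_kept = 0
    total_kept = (n_cycles - burn_in + thin - 1) // thin
    mu_sum = 0.0
    mu_sq = 0.0
    g_sum = np.zeros(q)
    g_sq = np.zeros(q)
    a_sum = np.zeros(na)
    a_sq = np.zeros(na)
    var_sum = np.zeros(7)   # vg, v1..v4, va, ve
    var_sq = np.zeros(7)
    comp_count = np.zeros((q, 4))
    order_rejects = 0

    dim_keep = total_kept if keep_samples else 1
    mu_s = np.zeros(dim_keep)
    g_s = np.zeros((dim_keep, q if keep_samples else 1))
    a_s = np.zeros((dim_keep, na if keep_samples else 1))
    var_s = np.zeros((total_kept, 7))

    logpi = np.full(4, -np.inf)
    for k in range(4):
        if pi[k] > 0.0:
            logpi[k] = np.log(pi[k])

    for cycle in range(n_cycles):
        # --- mu (flat prior) ---
        r = 0.0
        for i in range(n):
            r += w[i] * (e[i] + mu)
        mean = r / sw
        mu_new = mean + np.random.normal(0.0, 1.0) * np.sqrt(ve / sw)
        delta = mu_new - mu
        for i in range(n):
            e[i] -= delta
        mu = mu_new

        # --- marker / variant effects ---
        for j in range(q):
            gj = g[j]
            if mixture:
                # component indicator given current g_j
                best = -np.inf
                logp = np.empty(4)
                for k in range(4):
                    if logpi[k] == -np.inf:
                        logp[k] = -np.inf
                    else:
                        vk = vcomp[k]
                        logp[k] = logpi[k] - 0.5 * np.log(vk) - gj * gj / (2.0 * vk)
                    if logp[k] > best:
                        best = logp[k]
                tot = 0.0
                for k in range(4):
                    logp[k] = np.exp(logp[k] - best) if logp[k] > -np.inf else 0.0
                    tot += logp[k]
                u = np.random.random() * tot
                acc = 0.0
                kj = 0
                for k in range(4):
                    acc += logp[k]
                    if u <= acc:
                        kj = k
                        break
                comp[j] = kj
                vj = vcomp[kj]
            else:
                vj = vg
            if mtm[j] <= 0.0:
                g_new = np.random.normal(0.0, 1.0) * np.sqrt(vj)
                g[j] = g_new
                continue
            rhs = mtm[j] * gj
            for i in range(n):
                rhs += w[i] * M[i, j] * e[i]
            lam = mtm[j] / ve + 1.0 / vj
            mean = (rhs / ve) / lam
            g_new = mean + np.random.normal(0.0, 1.0) / np.sqrt(lam)
            diff = g_new - gj
            for i in range(n):
                e[i] -= M[i, j] * diff
            g[j] = g_new

        # --- polygenic effects (single site, using A-inverse rows) ---
        for ii in range(na):
            aii = a[ii]
            s = 0.0
            for jj in range(na):
                s += Ainv[ii, jj] * a[jj]
            s -= Ainv[ii, ii] * aii
            prec = Ainv[ii, ii] / va
            rhs = -s / va
            rec = rec_of_anim[ii]
            if rec >= 0:
                prec += w[rec] / ve
                rhs += w[rec] * (e[rec] + aii) / ve
            mean = rhs / prec
            a_new = mean + np.random.normal(0.0, 1.0) / np.sqrt(prec)
            if rec >= 0:
                e[rec] -= a_new - aii
            a[ii] = a_new

        # --- variance components ---
        if update_variances:
            if mixture:
                cnt = np.zeros(4, dtype=np.int64)
                ssq = np.zeros(4)
                for j in range(q):
                    cnt[comp[j]] += 1
                    ssq[comp[j]] += g[j] * g[j]
                for k in range(4):
                    lower = vcomp[k - 1] if k > 0 else _VFLOOR
                    upper = vcomp[k + 1] if k < 3 else vmax
                    cand, rej = _draw_var(vcomp[k], cnt[k], ssq[k], lower, upper, 0.4)
                    vcomp[k] = cand
                    order_rejects += rej
            else:
                sg = 0.0
                for j in range(q):
                    sg += g[j] * g[j]
                vg, _ = _draw_var(vg, q, sg, _VFLOOR, vmax, 0.4)
            sa = 0.0
            for ii in range(na):
                rowdot = 0.0
                for jj in range(na):
                    rowdot += Ainv[ii, jj] * a[jj]
                sa += a[ii] * rowdot
            va, _ = _draw_var(va, na, sa, _VFLOOR, vmax, 0.4)
            se = 0.0
            for i in range(n):
                se += w[i] * e[i] * e[i]
            ve, _ = _draw_var(ve, n, se, _VFLOOR, vmax, 0.4)

        # --- collect ---
        if cycle >= burn_in and (cycle - burn_in) % thin == 0:
            mu_sum += mu
            mu_sq += mu * mu
            for j in range(q):
                g_sum[j] += g[j]
                g_sq[j] += g[j] * g[j]
                comp_count[j, comp[j]] += 1.0
            for ii in range(na):
                a_sum[ii] += a[ii]
                a_sq[ii] += a[ii] * a[ii]
            vrow = np.empty(7)
            vrow[0] = vg
            for k in range(4):
                vrow[1 + k] = vcomp[k]
            vrow[5] = va
            vrow[6] = ve
            for t in range(7):
                var_sum[t] += vrow[t]
                var_sq[t] += vrow[t] * vrow[t]
            var_s[n_kept] = vrow
            if keep_samples:
                mu_s[n_kept] = mu
                for j in range(q):
                    g_s[n_kept, j] = g[j]
                for ii in range(na):
                    a_s[n_kept, ii] = a[ii]
            n_kept += 1

    return (mu_sum, mu_sq, g_sum, g_sq, a_sum, a_sq,
            var_sum, var_sq, comp_count, n_kept, order_rejects,
            mu_s, g_s, a_s, var_s)
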