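"""Numba MCMC kernels for open-population SCR models.

Metropolis-within-Gibbs scheme shared by the Jolly-Seber (data-augmented)
and Cormack-Jolly-Seber samplers:

* alive trajectories ``z[i, :]`` are updated jointly per individual by
  enumerating every valid life history (entry period x last-alive period,
  ``O(T^2)`` states) and drawing from the exact conditional — far better
  mixing than single-site Gibbs when recaptures are sparse;
* ``phi`` and ``gamma_t`` get conjugate Beta draws from the transition
  sufficient statistics under Uniform(0,1) priors (``phi`` falls back to a
  random-walk MH step when intervals are unequal, since ``phi**dt`` breaks
  conjugacy);
* activity centers move by random-walk MH; under the markovian model the
  acceptance ratio includes both neighbouring-step densities and the exact
  truncated-normal normalizing masses, so behaviour near the state-space
  boundary is correct;
* ``lambda0``, ``sigma_p`` and ``sigma_s`` move by log-scale random-walk
  MH with uniform priors on the natural scale (hence the Jacobian terms);
  proposal scales adapt only during burn-in.

The binomial observation likelihood is evaluated without the constant
binomial coefficients, which cancel from every ratio used here.  Detection
uses the complementary log-log form ``p = 1 - exp(-lam0 * g)`` with
``g = exp(-d^2 / (2 sigma_p^2))``, so ``log(1 - p) = -lam0 * g`` exactly —
zero counts cost a single ``exp`` per trap.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# movement model codes
CONSTANT = 0
INDEPENDENT = 1
MARKOVIAN = 2

_SQRT2 = math.sqrt(2.0)


@njit(cache=True, fastmath=True, inline="always")
def _phi_cdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True, fastmath=True, inline="always")
def _log_trunc_mass(mu, sigma, lo, hi):
    m = _phi_cdf((hi - mu) / sigma) - _phi_cdf((lo - mu) / sigma)
    if m <= 0.0:
        return -1e300
    return math.log(m)


@njit(cache=True, fastmath=True)
def _ll_row(i, t, sx_it, sy_it, y, K, tx, ty, lam0, inv2s2):
    """Row log-likelihood (binomial coefficients dropped) for one (i, t)."""
    acc = 0.0
    J = tx.shape[0]
    for j in range(J):
        Kjt = K[j, t]
        if Kjt == 0:
            continue
        dx = sx_it - tx[j]
        dy = sy_it - ty[j]
        ex = (dx * dx + dy * dy) * inv2s2
        yv = y[i, j, t]
        if yv == 0 and ex > 45.0:
            # kernel < 3e-20: contribution below double-precision resolution
            continue
        lg = lam0 * math.exp(-ex)
        acc -= (Kjt - yv) * lg
        if yv > 0:
            onemexp = -math.expm1(-lg)   # = p
            if onemexp <= 0.0:
                return -1e300
            acc += yv * math.log(onemexp)
    return acc


@njit(cache=True, fastmath=True)
def _refresh_ll(ll1, active, sx, sy, y, K, tx, ty, lam0, inv2s2):
    M, T = ll1.shape
    for i in range(M):
        for t in range(T):
            if active[i, t]:
                ll1[i, t] = _ll_row(i, t, sx[i, t], sy[i, t], y, K, tx, ty,
                                    lam0, inv2s2)


@njit(cache=True, fastmath=True)
def _draw_beta(a, b):
    x = np.random.gamma(a, 1.0)
    v = np.random.gamma(b, 1.0)
    return x / (x + v)


@njit(cache=True, fastmath=True)
def _update_z_js(z, ll1, fdet, ldet, lgam, l1gam, lphi, l1phi):
    """Exact joint Gibbs update of each individual's alive trajectory.

    States are (e, l): alive exactly in periods e..l, plus 'never'.  For a
    detected individual only states with e <= first detection and
    l >= last detection have positive probability.
    """
    M, T = z.shape
    c1gam = np.zeros(T + 1)
    for t in range(T):
        c1gam[t + 1] = c1gam[t] + l1gam[t]
    n_states = T * (T + 1) // 2 + 1
    logw = np.empty(n_states)
    es = np.empty(n_states, np.int64)
    ls = np.empty(n_states, np.int64)
    cum = np.zeros(T + 1)
    for i in range(M):
        for t in range(T):
            cum[t + 1] = cum[t] + ll1[i, t]
        e_max = fdet[i] if fdet[i] >= 0 else T - 1
        l_min_det = ldet[i] if ldet[i] >= 0 else 0
        ns = 0
        for e in range(e_max + 1):
            l0 = l_min_det if l_min_det > e else e
            for l in range(l0, T):
                w = c1gam[e] + lgam[e] + (cum[l + 1] - cum[e])
                for t in range(e + 1, l + 1):
                    w += lphi[t]
                if l < T - 1:
                    w += l1phi[l + 1]
                logw[ns] = w
                es[ns] = e
                ls[ns] = l
                ns += 1
        if fdet[i] < 0:   # 'never in the population' is only open to the undetected
            logw[ns] = c1gam[T]
            es[ns] = -1
            ls[ns] = -1
            ns += 1
        mx = logw[0]
        for k in range(1, ns):
            if logw[k] > mx:
                mx = logw[k]
        tot = 0.0
        for k in range(ns):
            logw[k] = math.exp(logw[k] - mx)
            tot += logw[k]
        u = np.random.random() * tot
        pick = ns - 1
        run = 0.0
        for k in range(ns):
            run += logw[k]
            if u <= run:
                pick = k
                break
        e = es[pick]
        l = ls[pick]
        for t in range(T):
            z[i, t] = 1 if (e >= 0 and e <= t <= l) else 0


@njit(cache=True, fastmath=True)
def _update_phi_gamma(z, delta_t, conjugate_phi, phi, tau_phi, lphi, l1phi,
                      lgam, l1gam):
    """Conjugate draws of gamma_t and phi (MH for phi if intervals differ)."""
    M, T = z.shape
    # gamma_t | z  ~ Beta(1 + recruits_t, 1 + available_t - recruits_t)
    for t in range(T):
        avail = 0
        rec = 0
        for i in range(M):
            ever = False
            for u in range(t):
                if z[i, u] == 1:
                    ever = True
                    break
            if not ever:
                avail += 1
                if z[i, t] == 1:
                    rec += 1
        g = _draw_beta(1.0 + rec, 1.0 + avail - rec)
        if g < 1e-12:
            g = 1e-12
        if g > 1.0 - 1e-12:
            g = 1.0 - 1e-12
        lgam[t] = math.log(g)
        l1gam[t] = math.log(1.0 - g)
    # transition sufficient statistics per interval
    surv = np.zeros(T, np.int64)
    died = np.zeros(T, np.int64)
    for i in range(M):
        for t in range(1, T):
            if z[i, t - 1] == 1:
                if z[i, t] == 1:
                    surv[t] += 1
                else:
                    died[t] += 1
    accepted = 0.0
    if conjugate_phi:
        a = 1.0
        b = 1.0
        for t in range(1, T):
            a += surv[t]
            b += died[t]
        phi = _draw_beta(a, b)
        accepted = 1.0
    else:
        prop = phi + np.random.normal() * tau_phi
        if 0.0 < prop < 1.0:
            dlp = 0.0
            for t in range(1, T):
                pn = prop ** delta_t[t - 1]
                po = phi ** delta_t[t - 1]
                dlp += surv[t] * (math.log(pn) - math.log(po))
                dlp += died[t] * (math.log(1.0 - pn) - math.log(1.0 - po))
            if math.log(np.random.random() + 1e-300) < dlp:
                phi = prop
                accepted = 1.0
    if phi < 1e-9:
        phi = 1e-9
    if phi > 1.0 - 1e-9:
        phi = 1.0 - 1e-9
    for t in range(1, T):
        pt = phi ** delta_t[t - 1]
        lphi[t] = math.log(pt)
        l1phi[t] = math.log(1.0 - pt)
    return phi, accepted


@njit(cache=True, fastmath=True)
def _rw_logprior_terms(sx, sy, i, t, px, py, sigma_s,
                       xmin, xmax, ymin, ymax, T, t_lo):
    """Markovian log-prior difference for moving s[i,t] to (px, py).

    Includes the incoming step density (normalizer unchanged) and, when a
    following period exists, the outgoing step density together with the
    change in its truncation mass.
    """
    inv2 = 1.0 / (2.0 * sigma_s * sigma_s)
    d = 0.0
    if t > t_lo:
        dxn = px - sx[i, t - 1]
        dyn = py - sy[i, t - 1]
        dxo = sx[i, t] - sx[i, t - 1]
        dyo = sy[i, t] - sy[i, t - 1]
        d += -(dxn * dxn + dyn * dyn) * inv2 + (dxo * dxo + dyo * dyo) * inv2
    if t < T - 1:
        dxn = sx[i, t + 1] - px
        dyn = sy[i, t + 1] - py
        dxo = sx[i, t + 1] - sx[i, t]
        dyo = sy[i, t + 1] - sy[i, t]
        d += -(dxn * dxn + dyn * dyn) * inv2 + (dxo * dxo + dyo * dyo) * inv2
        d -= _log_trunc_mass(px, sigma_s, xmin, xmax)
        d -= _log_trunc_mass(py, sigma_s, ymin, ymax)
        d += _log_trunc_mass(sx[i, t], sigma_s, xmin, xmax)
        d += _log_trunc_mass(sy[i, t], sigma_s, ymin, ymax)
    return d


@njit(cache=True, fastmath=True)
def _update_centers(z, sx, sy, ll1, active, t_lo, movement, sigma_s, tau_s,
                    ndet_it, y, K, tx, ty, lam0, inv2s2,
                    xmin, xmax, ymin, ymax):
    """Random-walk MH (or prior Gibbs where the likelihood is flat).

    Proposals shrink with the number of detections informing a center
    (conditional SD scales like sigma_p / sqrt(n)), so heavily-detected
    and undetected individuals mix at comparable rates under one globally
    adapted base scale.
    """
    M, T = z.shape
    att = 0.0
    acc = 0.0
    for i in range(M):
        lo = t_lo[i]
        if movement == CONSTANT:
            alive_any = False
            for t in range(lo, T):
                if z[i, t] == 1:
                    alive_any = True
                    break
            if not alive_any:
                # conditional is the uniform prior: direct Gibbs draw
                px = xmin + np.random.random() * (xmax - xmin)
                py = ymin + np.random.random() * (ymax - ymin)
                for t in range(lo, T):
                    sx[i, t] = px
                    sy[i, t] = py
                    ll1[i, t] = _ll_row(i, t, px, py, y, K, tx, ty, lam0,
                                        inv2s2)
                continue
            ntot = 0
            for t in range(lo, T):
                ntot += ndet_it[i, t]
            step = tau_s / math.sqrt(1.0 + ntot)
            px = sx[i, lo] + np.random.normal() * step
            py = sy[i, lo] + np.random.normal() * step
            att += 1.0
            if px < xmin or px > xmax or py < ymin or py > ymax:
                continue
            dll = 0.0
            lnew = np.empty(T)
            for t in range(lo, T):
                lnew[t] = _ll_row(i, t, px, py, y, K, tx, ty, lam0, inv2s2)
                if z[i, t] == 1:
                    dll += lnew[t] - ll1[i, t]
            if math.log(np.random.random() + 1e-300) < dll:
                acc += 1.0
                for t in range(lo, T):
                    sx[i, t] = px
                    sy[i, t] = py
                    ll1[i, t] = lnew[t]
        elif movement == INDEPENDENT:
            for t in range(lo, T):
                if z[i, t] == 0:
                    px = xmin + np.random.random() * (xmax - xmin)
                    py = ymin + np.random.random() * (ymax - ymin)
                    sx[i, t] = px
                    sy[i, t] = py
                    ll1[i, t] = _ll_row(i, t, px, py, y, K, tx, ty, lam0,
                                        inv2s2)
                else:
                    att += 1.0
                    step = tau_s / math.sqrt(1.0 + ndet_it[i, t])
                    px = sx[i, t] + np.random.normal() * step
                    py = sy[i, t] + np.random.normal() * step
                    if px < xmin or px > xmax or py < ymin or py > ymax:
                        continue
                    lnew = _ll_row(i, t, px, py, y, K, tx, ty, lam0, inv2s2)
                    if math.log(np.random.random() + 1e-300) < lnew - ll1[i, t]:
                        acc += 1.0
                        sx[i, t] = px
                        sy[i, t] = py
                        ll1[i, t] = lnew
        else:  # MARKOVIAN
            for t in range(lo, T):
                att += 1.0
                step = tau_s / math.sqrt(1.0 + ndet_it[i, t])
                px = sx[i, t] + np.random.normal() * step
                py = sy[i, t] + np.random.normal() * step
                if px < xmin or px > xmax or py < ymin or py > ymax:
                    continue
                dlp = _rw_logprior_terms(sx, sy, i, t, px, py, sigma_s,
                                         xmin, xmax, ymin, ymax, T, lo)
                lnew = 0.0
                if z[i, t] == 1:
                    lnew = _ll_row(i, t, px, py, y, K, tx, ty, lam0, inv2s2)
                    dlp += lnew - ll1[i, t]
                if math.log(np.random.random() + 1e-300) < dlp:
                    acc += 1.0
                    sx[i, t] = px
                    sy[i, t] = py
                    if z[i, t] == 1:
                        ll1[i, t] = lnew
                    else:
                        ll1[i, t] = _ll_row(i, t, px, py, y, K, tx, ty,
                                            lam0, inv2s2)
    return att, acc


@njit(cache=True, fastmath=True)
def _detection_loglik_alive(z, sx, sy, y, K, tx, ty, lam0, inv2s2):
    M, T = z.shape
    tot = 0.0
    for i in range(M):
        for t in range(T):
            if z[i, t] == 1:
                tot += _ll_row(i, t, sx[i, t], sy[i, t], y, K, tx, ty,
                               lam0, inv2s2)
    return tot


@njit(cache=True, fastmath=True)
def _cached_loglik_alive(z, ll1):
    M, T = z.shape
    tot = 0.0
    for i in range(M):
        for t in range(T):
            if z[i, t] == 1:
                tot += ll1[i, t]
    return tot


@njit(cache=True, fastmath=True)
def _sigma_s_loglik(sx, sy, t_lo, sigma_s, xmin, xmax, ymin, ymax):
    M, T = sx.shape
    inv2 = 1.0 / (2.0 * sigma_s * sigma_s)
    lognorm = -math.log(2.0 * math.pi * sigma_s * sigma_s)
    tot = 0.0
    for i in range(M):
        for t in range(t_lo[i] + 1, T):
            dx = sx[i, t] - sx[i, t - 1]
            dy = sy[i, t] - sy[i, t - 1]
            tot += lognorm - (dx * dx + dy * dy) * inv2
            tot -= _log_trunc_mass(sx[i, t - 1], sigma_s, xmin, xmax)
            tot -= _log_trunc_mass(sy[i, t - 1], sigma_s, ymin, ymax)
    return tot


@njit(cache=True, fastmath=True)
def run_sampler(
    y, K, tx, ty,
    xmin, xmax, ymin, ymax,
    movement, delta_t,
    cjs, first_det,
    z, sx, sy,
    phi, lam0, sigp, sigs,
    lam0_max, sigp_max, sigs_max,
    n_iter, n_burn, thin, seed,
    fix_centers, fix_detection, fix_z,
    out_phi, out_gamma, out_lam0, out_sigp, out_sigs, out_N, out_z, keep_z,
):
    """Run one MCMC chain; fills the ``out_*`` arrays in place.

    ``cjs`` switches to the Cormack-Jolly-Seber variant: entry is fixed at
    each individual's first detection (``first_det``), there is no
    recruitment and no augmentation, and only the post-entry trajectory is
    sampled.  Returns (pct kept, final proposal scales) diagnostics.
    """
    np.random.seed(seed)
    M, T = z.shape
    inv2s2 = 1.0 / (2.0 * sigp * sigp)

    # first/last detected period per individual (-1 if undetected)
    fdet = np.full(M, -1, np.int64)
    ldet = np.full(M, -1, np.int64)
    for i in range(M):
        for t in range(T):
            tot = 0
            for j in range(y.shape[1]):
                tot += y[i, j, t]
            if tot > 0:
                if fdet[i] < 0:
                    fdet[i] = t
                ldet[i] = t

    # first period for which this individual's center/likelihood exists
    t_lo = np.zeros(M, np.int64)
    if cjs:
        for i in range(M):
            t_lo[i] = first_det[i]
    active = np.zeros((M, T), np.bool_)
    for i in range(M):
        for t in range(t_lo[i], T):
            active[i, t] = True

    # detections per individual-period (sets center proposal scales)
    ndet_it = np.zeros((M, T), np.int64)
    for i in range(M):
        for t in range(T):
            for j in range(y.shape[1]):
                ndet_it[i, t] += y[i, j, t]

    ll1 = np.full((M, T), 0.0)
    _refresh_ll(ll1, active, sx, sy, y, K, tx, ty, lam0, inv2s2)

    lgam = np.full(T, math.log(0.2))
    l1gam = np.full(T, math.log(0.8))
    lphi = np.zeros(T)
    l1phi = np.zeros(T)
    conjugate_phi = True
    for t in range(T - 1):
        if delta_t[t] != 1.0:
            conjugate_phi = False
    for t in range(1, T):
        pt = phi ** delta_t[t - 1]
        lphi[t] = math.log(pt)
        l1phi[t] = math.log(1.0 - pt)

    tau_s = 3.0 * sigp
    tau_lam = 0.4
    tau_sigp = 0.15
    tau_sigs = 0.3
    tau_phi = 0.1
    acc_s = 0.0
    att_s = 0.0
    acc_lam = 0.0
    att_lam = 0.0
    acc_sigp = 0.0
    att_sigp = 0.0
    acc_sigs = 0.0
    att_sigs = 0.0
    tau_ridge = 0.3
    acc_ridge = 0.0
    att_ridge = 0.0

    kept = 0
    ll_dirty = False
    for it in range(n_iter):
        # detection parameters changed late last iteration: bring the
        # likelihood cache up to date before it is consumed again
        if ll_dirty:
            _refresh_ll(ll1, active, sx, sy, y, K, tx, ty, lam0, inv2s2)
            ll_dirty = False

        # --- alive trajectories -----------------------------------------
        if fix_z:
            pass
        elif cjs:
            # entry fixed at first detection; sample only the last alive
            # period l >= last detection
            for i in range(M):
                f = first_det[i]
                logw = np.empty(T)
                cum = 0.0
                best = -1e308
                ns = 0
                for l in range(ldet[i], T):
                    w = 0.0
                    for t in range(f + 1, l + 1):
                        w += lphi[t]
                    if l < T - 1:
                        w += l1phi[l + 1]
                    for t in range(f, l + 1):
                        w += ll1[i, t]
                    logw[ns] = w
                    if w > best:
                        best = w
                    ns += 1
                tot = 0.0
                for k_ in range(ns):
                    logw[k_] = math.exp(logw[k_] - best)
                    tot += logw[k_]
                u = np.random.random() * tot
                pick = ns - 1
                run = 0.0
                for k_ in range(ns):
                    run += logw[k_]
                    if u <= run:
                        pick = k_
                        break
                l = ldet[i] + pick
                for t in range(T):
                    z[i, t] = 1 if (f <= t <= l) else 0
        else:
            _update_z_js(z, ll1, fdet, ldet, lgam, l1gam, lphi, l1phi)

        # --- phi, gamma --------------------------------------------------
        if fix_z:
            pass
        elif cjs:
            surv = 0
            died = 0
            if conjugate_phi:
                for i in range(M):
                    for t in range(first_det[i] + 1, T):
                        if z[i, t - 1] == 1:
                            if z[i, t] == 1:
                                surv += 1
                            else:
                                died += 1
                phi = _draw_beta(1.0 + surv, 1.0 + died)
            else:
                prop = phi + np.random.normal() * tau_phi
                if 0.0 < prop < 1.0:
                    dlp = 0.0
                    for i in range(M):
                        for t in range(first_det[i] + 1, T):
                            if z[i, t - 1] == 1:
                                pn = prop ** delta_t[t - 1]
                                po = phi ** delta_t[t - 1]
                                if z[i, t] == 1:
                                    dlp += math.log(pn) - math.log(po)
                                else:
                                    dlp += math.log(1.0 - pn) - math.log(1.0 - po)
                    if math.log(np.random.random() + 1e-300) < dlp:
                        phi = prop
            if phi < 1e-9:
                phi = 1e-9
            if phi > 1.0 - 1e-9:
                phi = 1.0 - 1e-9
            for t in range(1, T):
                pt = phi ** delta_t[t - 1]
                lphi[t] = math.log(pt)
                l1phi[t] = math.log(1.0 - pt)
        else:
            phi, _ = _update_phi_gamma(z, delta_t, conjugate_phi, phi,
                                       tau_phi, lphi, l1phi, lgam, l1gam)

        # --- activity centers --------------------------------------------
        if not fix_centers:
            a1, a2 = _update_centers(z, sx, sy, ll1, active, t_lo, movement,
                                     sigs, tau_s, ndet_it, y, K, tx, ty,
                                     lam0, inv2s2, xmin, xmax, ymin, ymax)
            att_s += a1
            acc_s += a2

        # --- detection parameters ---------------------------------------
        # block scan on alternate iterations; the likelihood cache refresh
        # is deferred to the top of the next iteration
        if not fix_detection and it % 2 == 0:
            cur = _cached_loglik_alive(z, ll1)
            # lambda0: log-scale random walk, Uniform(0, lam0_max) prior
            att_lam += 1.0
            prop = lam0 * math.exp(np.random.normal() * tau_lam)
            if 0.0 < prop < lam0_max:
                new = _detection_loglik_alive(z, sx, sy, y, K, tx, ty,
                                              prop, inv2s2)
                lr = new - cur + math.log(prop / lam0)
                if math.log(np.random.random() + 1e-300) < lr:
                    acc_lam += 1.0
                    lam0 = prop
                    cur = new
                    ll_dirty = True
            # sigma_p
            att_sigp += 1.0
            prop = sigp * math.exp(np.random.normal() * tau_sigp)
            if 0.0 < prop < sigp_max:
                inv_new = 1.0 / (2.0 * prop * prop)
                new = _detection_loglik_alive(z, sx, sy, y, K, tx, ty,
                                              lam0, inv_new)
                lr = new - cur + math.log(prop / sigp)
                if math.log(np.random.random() + 1e-300) < lr:
                    acc_sigp += 1.0
                    sigp = prop
                    inv2s2 = inv_new
                    cur = new
                    ll_dirty = True
            # joint ridge move: lambda0 and sigma_p are strongly negatively
            # correlated (they trade off along constant effective exposure
            # lam0 * sigma_p^2), so scale them in opposite directions
            att_ridge += 1.0
            u = np.random.normal() * tau_ridge
            lam_new = lam0 * math.exp(u)
            sigp_new = sigp * math.exp(-0.5 * u)
            if 0.0 < lam_new < lam0_max and 0.0 < sigp_new < sigp_max:
                inv_new = 1.0 / (2.0 * sigp_new * sigp_new)
                new = _detection_loglik_alive(z, sx, sy, y, K, tx, ty,
                                              lam_new, inv_new)
                lr = new - cur + 0.5 * u
                if math.log(np.random.random() + 1e-300) < lr:
                    acc_ridge += 1.0
                    lam0 = lam_new
                    sigp = sigp_new
                    inv2s2 = inv_new
                    ll_dirty = True

        # --- random-walk SD ----------------------------------------------
        if movement == MARKOVIAN and not fix_centers:
            att_sigs += 1.0
            prop = sigs * math.exp(np.random.normal() * tau_sigs)
            if 0.0 < prop < sigs_max:
                cur = _sigma_s_loglik(sx, sy, t_lo, sigs, xmin, xmax,
                                      ymin, ymax)
                new = _sigma_s_loglik(sx, sy, t_lo, prop, xmin, xmax,
                                      ymin, ymax)
                lr = new - cur + math.log(prop / sigs)
                if math.log(np.random.random() + 1e-300) < lr:
                    acc_sigs += 1.0
                    sigs = prop

        # --- adaptation (burn-in only) -----------------------------------
        if it < n_burn and (it + 1) % 50 == 0:
            delta = min(0.25, 5.0 / math.sqrt(it + 51.0))
            if att_s > 0:
                tau_s *= math.exp(delta if acc_s / att_s > 0.3 else -delta)
            if att_lam > 0:
                tau_lam *= math.exp(
                    delta if acc_lam / att_lam > 0.35 else -delta)
            if att_sigp > 0:
                tau_sigp *= math.exp(
                    delta if acc_sigp / att_sigp > 0.35 else -delta)
            if att_sigs > 0:
                tau_sigs *= math.exp(
                    delta if acc_sigs / att_sigs > 0.35 else -delta)
            if att_ridge > 0:
                tau_ridge *= math.exp(
                    delta if acc_ridge / att_ridge > 0.35 else -delta)
            acc_s = att_s = 0.0
            acc_lam = att_lam = 0.0
            acc_sigp = att_sigp = 0.0
            acc_sigs = att_sigs = 0.0
            acc_ridge = att_ridge = 0.0

        # --- store --------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            out_phi[kept] = phi
            out_lam0[kept] = lam0
            out_sigp[kept] = sigp
            out_sigs[kept] = sigs
            for t in range(T):
                out_gamma[kept, t] = math.exp(lgam[t])
                Nt = 0
                for i in range(M):
                    Nt += z[i, t]
                out_N[kept, t] = Nt
            if keep_z:
                for i in range(M):
                    for t in range(T):
                        out_z[kept, i, t] = z[i, t]
            kept += 1
    return kept, tau_s, tau_lam, tau_sigp, tau_sigs
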