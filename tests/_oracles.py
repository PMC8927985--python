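"""Independent oracles used only by the test suite.

- A plain-numpy right-hand side of the Courtemanche-Ramirez-Nattel atrial
  cell model, integrated with scipy's adaptive stiff solver (LSODA at tight
  tolerance).  This is a separate integration path from the package's
  tabulated Rush-Larsen stepper.
- Brute-force rank statistics: Spearman via explicit average ranks +
  Pearson on ranks; Mann-Whitney p by exhaustive relabeling enumeration;
  Fisher's exact p by direct hypergeometric enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import solve_ivp

R = 8.3143
T = 310.0
F = 96.4867
CM = 100.0
VI = 13668.0
VUP = 1109.52
VREL = 96.48
NAO, KO, CAO = 140.0, 5.4, 1.8


def crn_rhs(t, y, prof, istim_fn):
    """Derivative form of the CRN model. prof = (ik1,incx,ina,ito,ical,ikur)."""
    (v, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vg, w,
     nai, ki, cai, caup, carel) = y
    s_k1, s_ncx, s_na, s_to, s_cal, s_kur = prof
    rtf = R * T / F
    ena = rtf * math.log(NAO / nai)
    ek = rtf * math.log(KO / ki)
    eca = 0.5 * rtf * math.log(CAO / cai)

    ina = s_na * 7.8 * m ** 3 * h * j * (v - ena)
    ik1 = s_k1 * 0.09 * (v - ek) / (1 + math.exp(0.07 * (v + 80)))
    ito = s_to * 0.1652 * oa ** 3 * oi * (v - ek)
    gkur = 0.005 + 0.05 / (1 + math.exp(-(v - 15) / 13))
    ikur = s_kur * gkur * ua ** 3 * ui * (v - ek)
    ikr = 0.029411765 * xr * (v - ek) / (1 + math.exp((v + 15) / 22.4))
    iks = 0.12941176 * xs ** 2 * (v - ek)
    ical = s_cal * 0.12375 * d * f * fca * (v - 65)
    fvrt = F * v / (R * T)
    sigma = (math.exp(NAO / 67.3) - 1) / 7
    fnak = 1 / (1 + 0.1245 * math.exp(-0.1 * fvrt) + 0.0365 * sigma * math.exp(-fvrt))
    inak = 0.59933874 * fnak * (KO / (KO + 1.5)) / (1 + (10.0 / nai) ** 1.5)
    inaca = s_ncx * 1600.0 * (
        math.exp(0.35 * fvrt) * nai ** 3 * CAO
        - math.exp(-0.65 * fvrt) * NAO ** 3 * cai) / (
        (87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1 + 0.1 * math.exp(-0.65 * fvrt)))
    ibna = 0.0006744375 * (v - ena)
    ibca = 0.001131 * (v - eca)
    ipca = 0.275 * cai / (0.0005 + cai)

    irel = 30.0 * u ** 2 * vg * w * (carel - cai)
    itr = (caup - carel) / 180.0
    iup = 0.005 / (1 + 0.00092 / cai)
    iupleak = 0.005 * caup / 15.0
    fn = 1e-12 * VREL * irel - 5e-13 / F * (0.5 * ical - 0.2 * inaca) * CM

    def clamp_exp(x):
        return math.exp(max(-80.0, min(80.0, x)))

    e1 = clamp_exp(-(fn - 3.4175e-13) / 13.67e-16)
    e2 = clamp_exp(-(fn - 6.835e-14) / 13.67e-16)
    u_inf = 1 / (1 + e1)
    v_inf = 1 - 1 / (1 + e2)
    tau_v = 1.91 + 2.09 / (1 + e1)
    fca_inf = 1 / (1 + cai / 0.00035)

    def ab(vv):
        # (alpha, beta) pairs / (inf, tau) pairs for all V-gates
        am = 3.2 if abs(vv + 47.13) < 1e-9 else \
            0.32 * (vv + 47.13) / (1 - math.exp(-0.1 * (vv + 47.13)))
        bm = 0.08 * math.exp(-vv / 11.0)
        if vv >= -40:
            ah, bh = 0.0, 1 / (0.13 * (1 + math.exp(-(vv + 10.66) / 11.1)))
            aj = 0.0
            bj = 0.3 * math.exp(-2.535e-7 * vv) / (1 + math.exp(-0.1 * (vv + 32)))
        else:
            ah = 0.135 * math.exp(-(vv + 80) / 6.8)
            bh = 3.56 * math.exp(0.079 * vv) + 3.1e5 * math.exp(0.35 * vv)
            aj = (-1.2714e5 * math.exp(0.2444 * vv) - 3.474e-5 * math.exp(-0.04391 * vv)) \
                * (vv + 37.78) / (1 + math.exp(0.311 * (vv + 79.23)))
            bj = 0.1212 * math.exp(-0.01052 * vv) / (1 + math.exp(-0.1378 * (vv + 40.14)))
        return am, bm, ah, bh, aj, bj

    am, bm, ah, bh, aj, bj = ab(v)
    a_oa = 0.65 / (math.exp(-(v + 10) / 8.5) + math.exp(-(v - 30) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82) / 17.0))
    oa_inf = 1 / (1 + math.exp(-(v + 20.47) / 17.54))
    tau_oa = 1 / ((a_oa + b_oa) * 3.0)
    a_oi = 1 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    oi_inf = 1 / (1 + math.exp((v + 43.1) / 5.3))
    tau_oi = 1 / ((a_oi + b_oi) * 3.0)
    ua_inf = 1 / (1 + math.exp(-(v + 30.3) / 9.6))
    tau_ua = tau_oa
    a_ui = 1 / (21 + math.exp(-(v - 185) / 28))
    b_ui = math.exp((v - 158) / 16.0)
    ui_inf = 1 / (1 + math.exp((v - 99.45) / 27.48))
    tau_ui = 1 / ((a_ui + b_ui) * 3.0)
    a_xr = 0.0015 if abs(v + 14.1) < 1e-9 else \
        0.0003 * (v + 14.1) / (1 - math.exp(-(v + 14.1) / 5.0))
    b_xr = 7.3898e-5 * 5.1237 if abs(v - 3.3328) < 1e-9 else \
        7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1)
    xr_inf = 1 / (1 + math.exp(-(v + 14.1) / 6.5))
    tau_xr = 1 / (a_xr + b_xr)
    a_xs = 4e-5 * 17 if abs(v - 19.9) < 1e-9 else \
        4e-5 * (v - 19.9) / (1 - math.exp(-(v - 19.9) / 17.0))
    b_xs = 3.5e-5 * 9 if abs(v - 19.9) < 1e-9 else \
        3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1)
    xs_inf = (1 + math.exp(-(v - 19.9) / 12.7)) ** -0.5
    tau_xs = 0.5 / (a_xs + b_xs)
    d_inf = 1 / (1 + math.exp(-(v + 10) / 8.0))
    ed = math.exp(-(v + 10) / 6.24)
    tau_d = 1 / (0.035 * 6.24 * 2) if abs(v + 10) < 1e-9 else \
        (1 - ed) / (0.035 * (v + 10) * (1 + ed))
    f_inf = 1 / (1 + math.exp((v + 28) / 6.9))
    tau_f = 9 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10) ** 2) + 0.02)
    w_inf = 1 - 1 / (1 + math.exp(-(v - 40) / 17.0))
    ew = math.exp(-(v - 7.9) / 5.0)
    tau_w = 6.0 * 0.2 / 1.3 if abs(v - 7.9) < 1e-9 else \
        6.0 * (1 - ew) / ((1 + 0.3 * ew) * (v - 7.9))

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak
            + inaca + ibna + ibca)
    cfac = CM / (F * VI)
    b1 = (2 * inaca - ipca - ical - ibca) * 0.5 * cfac \
        + (VUP * (iupleak - iup) + irel * VREL) / VI
    b2 = 1 + 0.07 * 0.0005 / (cai + 0.0005) ** 2 + 0.05 * 0.00238 / (cai + 0.00238) ** 2

    return [
        -iion + istim_fn(t),
        am * (1 - m) - bm * m,
        ah * (1 - h) - bh * h,
        aj * (1 - j) - bj * j,
        (oa_inf - oa) / tau_oa,
        (oi_inf - oi) / tau_oi,
        (ua_inf - ua) / tau_ua,
        (ui_inf - ui) / tau_ui,
        (xr_inf - xr) / tau_xr,
        (xs_inf - xs) / tau_xs,
        (d_inf - d) / tau_d,
        (f_inf - f) / tau_f,
        (fca_inf - fca) / 2.0,
        (u_inf - u) / 8.0,
        (v_inf - vg) / tau_v,
        (w_inf - w) / tau_w,
        (-3 * inak - 3 * inaca - ibna - ina) * cfac,
        (2 * inak - ik1 - ito - ikur - ikr - iks) * cfac,
        b1 / b2,
        iup - iupleak - itr * VREL / VUP,
        (itr - irel) / (1 + 10.0 * 0.8 / (carel + 0.8) ** 2),
    ]


def reference_paced_trace(profile_arr, cycle_length, n_beats,
                          stim_amplitude=40.0, stim_duration=2.0,
                          y0=None, rtol=1e-8, atol=1e-8):
    """Integrate the CRN model with LSODA through n_beats of pacing.

    Returns (t, V) sampled at 0.5 ms over the full run."""
    from fibwave._kernels import rest_state
    if y0 is None:
        y0 = rest_state()
    stim_times = [k * cycle_length for k in range(n_beats)]

    def istim(t):
        for ts in stim_times:
            if ts <= t < ts + stim_duration:
                return stim_amplitude
        return 0.0

    total = n_beats * cycle_length
    t_eval = np.arange(0.0, total, 0.5)
    # integrate beat by beat so the solver never steps over a stimulus
    ts_all, vs_all = [], []
    y = np.asarray(y0, dtype=float)
    for ts in stim_times:
        for seg in ((ts, ts + stim_duration), (ts + stim_duration, ts + cycle_length)):
            mask = (t_eval >= seg[0]) & (t_eval < seg[1])
            sol = solve_ivp(crn_rhs, seg, y, args=((*profile_arr,), istim),
                            method="LSODA", rtol=rtol, atol=atol,
                            t_eval=t_eval[mask], max_step=stim_duration)
            y = sol.y[:, -1] if sol.y.size else y
            if sol.t.size:
                ts_all.append(sol.t)
                vs_all.append(sol.y[0])
    return np.concatenate(ts_all), np.concatenate(vs_all)


# ---- rank-statistics oracles -------------------------------------------

def average_ranks(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    return float(np.sum(rx * ry) / denom)


def mannwhitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group relabelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = average_ranks(pooled)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    mu = len(x) * len(y) / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            count += 1
    return count / total


def fisher_exact_p(table):
    """Two-sided Fisher p by hypergeometric enumeration (log factorials)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lf = np.zeros(n + 1)
    for i in range(2, n + 1):
        lf[i] = lf[i - 1] + math.log(i)

    def logp(aa):
        bb, cc, dd = r1 - aa, c1 - aa, r2 - (c1 - aa)
        if min(bb, cc, dd) < 0:
            return None
        return (lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]
                - lf[aa] - lf[bb] - lf[cc] - lf[dd])

    p_obs = logp(a)
    total = 0.0
    for aa in range(0, min(r1, c1) + 1):
        lp = logp(aa)
        if lp is not None and lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)
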