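"""Low-level numerics: Courtemanche-Ramirez-Nattel (CRN) human atrial myocyte
model and the anisotropic monodomain finite-difference stepper.

The CRN right-hand side is evaluated with voltage-indexed lookup tables
(steady states and Rush-Larsen decay factors pre-tabulated on a 0.05 mV grid)
so that the tissue loop stays close to memory bandwidth.  Gates advance by
Rush-Larsen exponential integration; concentrations and V by forward Euler.

State layout, one row per node (21 columns):
  0 V [mV], 1 m, 2 h, 3 j, 4 oa, 5 oi, 6 ua, 7 ui, 8 xr, 9 xs,
  10 d, 11 f, 12 fCa, 13 u, 14 v, 15 w,
  16 [Na]i [mM], 17 [K]i, 18 [Ca]i, 19 [Ca]up, 20 [Ca]rel

Remodeling profile layout (6 scale factors):
  0 IK1, 1 INCX (Na/Ca exchanger), 2 INa, 3 Ito, 4 ICaL, 5 IKur
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATE = 21

# physical constants
R_GAS = 8.3143      # J/(mol K)
TEMP = 310.0        # K
FARADAY = 96.4867   # C/mmol
CM = 100.0          # pF
V_I = 13668.0       # um^3
V_UP = 1109.52
V_REL = 96.48
NA_O = 140.0        # mM
K_O = 5.4
CA_O = 1.8

# maximal conductances / fluxes (pA/pF unless noted)
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
I_NAK_MAX = 0.59933874
I_NACA_MAX = 1600.0
I_PCA_MAX = 0.275
G_B_NA = 0.0006744375
G_B_CA = 0.001131

KM_NAI = 10.0
KM_KO = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35

K_REL = 30.0        # 1/ms
K_UP = 0.00092      # mM
I_UP_MAX = 0.005    # mM/ms
CA_UP_MAX = 15.0    # mM
TAU_TR = 180.0      # ms
TAU_F_CA = 2.0
TAU_U = 8.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

KQ10 = 3.0

V_REST = -81.18

# voltage lookup-table grid
TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
TAB_N = int(round((TAB_VMAX - TAB_VMIN) / TAB_DV)) + 1
TAB_ROWS = 30


def rest_state() -> np.ndarray:
    """Published quiescent steady state of the CRN model."""
    return np.array([
        V_REST,
        2.908e-3, 9.649e-1, 9.775e-1,        # m h j
        3.043e-2, 9.992e-1,                  # oa oi
        4.966e-3, 9.986e-1,                  # ua ui
        3.296e-5, 1.869e-2,                  # xr xs
        1.367e-4, 9.996e-1, 7.755e-1,        # d f fCa
        0.0, 1.0, 9.992e-1,                  # u v w
        11.17, 139.0, 1.013e-4,              # Nai Ki Cai
        1.488, 1.488,                        # Caup Carel
    ])


def _safe_ratio(num, den, limit):
    """num/den with the removable singularity replaced by its limit."""
    out = np.where(np.abs(den) < 1e-12, limit, num / np.where(den == 0.0, 1.0, den))
    return out


def build_tables(dt: float) -> np.ndarray:
    """Tabulate gate steady states, Rush-Larsen factors exp(-dt/tau) and the
    purely voltage-dependent current factors on the table voltage grid."""
    v = TAB_VMIN + TAB_DV * np.arange(TAB_N)
    tab = np.empty((TAB_ROWS, TAB_N))

    def rl(tau):
        return np.exp(-dt / tau)

    # m
    am = _safe_ratio(0.32 * (v + 47.13), 1.0 - np.exp(-0.1 * (v + 47.13)), 3.2)
    bm = 0.08 * np.exp(-v / 11.0)
    tab[0] = am / (am + bm)
    tab[1] = rl(1.0 / (am + bm))
    # h
    lo = v < -40.0
    ah = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    bh = np.where(lo, 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                  1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    tab[2] = ah / (ah + bh)
    tab[3] = rl(1.0 / (ah + bh))
    # j
    aj = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    bj = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    tab[4] = aj / (aj + bj)
    tab[5] = rl(1.0 / (aj + bj))
    # oa / oi (transient outward)
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tab[6] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tab[7] = rl(1.0 / ((a + b) * KQ10))
    a = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    tab[8] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))
    tab[9] = rl(1.0 / ((a + b) * KQ10))
    # ua / ui (ultrarapid)
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tab[10] = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))
    tab[11] = rl(1.0 / ((a + b) * KQ10))
    a = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b = np.exp((v - 158.0) / 16.0)
    tab[12] = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))
    tab[13] = rl(1.0 / ((a + b) * KQ10))
    # xr
    a = _safe_ratio(0.0003 * (v + 14.1), 1.0 - np.exp(-(v + 14.1) / 5.0), 0.0015)
    b = _safe_ratio(7.3898e-5 * (v - 3.3328), np.exp((v - 3.3328) / 5.1237) - 1.0,
                    7.3898e-5 * 5.1237)
    tab[14] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))
    tab[15] = rl(1.0 / (a + b))
    # xs
    a = _safe_ratio(4e-5 * (v - 19.9), 1.0 - np.exp(-(v - 19.9) / 17.0), 4e-5 * 17.0)
    b = _safe_ratio(3.5e-5 * (v - 19.9), np.exp((v - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0)
    tab[16] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))
    tab[17] = rl(0.5 / (a + b))
    # d
    tab[18] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))
    e = np.exp(-(v + 10.0) / 6.24)
    tau_d = _safe_ratio(1.0 - e, 0.035 * (v + 10.0) * (1.0 + e),
                        1.0 / (0.035 * 6.24 * 2.0))
    tab[19] = rl(tau_d)
    # f
    tab[20] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))
    tab[21] = rl(9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02))
    # w
    tab[22] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))
    e = np.exp(-(v - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - e), (1.0 + 0.3 * e) * (v - 7.9),
                        6.0 * 0.2 / 1.3)
    tab[23] = rl(tau_w)
    # voltage-only current factors
    tab[24] = G_K1 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tab[25] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    tab[26] = G_KR / (1.0 + np.exp((v + 15.0) / 22.4))
    fvrt = FARADAY * v / (R_GAS * TEMP)
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    tab[27] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * fvrt) + 0.0365 * sigma * np.exp(-fvrt))
    tab[28] = np.exp(GAMMA * fvrt)
    tab[29] = np.exp((GAMMA - 1.0) * fvrt)
    return tab


@njit(cache=True, fastmath={'nsz', 'arcp', 'contract'})
def step_nodes(S, lap, istim, active, tab, dt, prof, fca_rl, u_rl,
               ena_c, ek_c, eca_c, update_e):
    """Advance every active node by one time step of length dt [ms].

    lap:   diffusion term per node [mV/ms]; istim: stimulus [pA/pF].
    Nernst potentials are cached in ena_c/ek_c/eca_c and refreshed when
    update_e is set (the intracellular concentrations drift slowly).
    Returns 0 on success, 1 if the membrane potential left [-200, 100] mV.
    """
    rt_f = R_GAS * TEMP / FARADAY
    inv_dv = 1.0 / TAB_DV
    status = 0
    for k in range(S.shape[0]):
        if not active[k]:
            continue
        vm = S[k, 0]
        if vm < -250.0 or vm > 250.0 or not (vm == vm):
            status = 1
            continue
        x = (vm - TAB_VMIN) * inv_dv
        if x < 0.0:
            x = 0.0
        elif x > TAB_N - 1.001:
            x = TAB_N - 1.001
        i0 = int(x)
        fr = x - i0

        nai = S[k, 16]
        ki = S[k, 17]
        cai = S[k, 18]
        caup = S[k, 19]
        carel = S[k, 20]

        if update_e:
            ena_c[k] = rt_f * np.log(NA_O / nai)
            ek_c[k] = rt_f * np.log(K_O / ki)
            eca_c[k] = 0.5 * rt_f * np.log(CA_O / cai)
        ena = ena_c[k]
        ek = ek_c[k]
        eca = eca_c[k]

        m = S[k, 1]
        h = S[k, 2]
        j = S[k, 3]
        ina = prof[2] * G_NA * m * m * m * h * j * (vm - ena)
        gk1f = tab[24, i0] + fr * (tab[24, i0 + 1] - tab[24, i0])
        ik1 = prof[0] * gk1f * (vm - ek)
        oa = S[k, 4]
        ito = prof[3] * G_TO * oa * oa * oa * S[k, 5] * (vm - ek)
        gkurf = tab[25, i0] + fr * (tab[25, i0 + 1] - tab[25, i0])
        ua = S[k, 6]
        ikur = prof[5] * gkurf * ua * ua * ua * S[k, 7] * (vm - ek)
        gkrf = tab[26, i0] + fr * (tab[26, i0 + 1] - tab[26, i0])
        ikr = gkrf * S[k, 8] * (vm - ek)
        xs = S[k, 9]
        iks = G_KS * xs * xs * (vm - ek)
        fca = S[k, 12]
        ical = prof[4] * G_CAL * S[k, 10] * S[k, 11] * fca * (vm - 65.0)
        ipca = I_PCA_MAX * cai / (0.0005 + cai)
        fnak = tab[27, i0] + fr * (tab[27, i0 + 1] - tab[27, i0])
        t15 = KM_NAI / nai
        inak = I_NAK_MAX * fnak * (K_O / (K_O + KM_KO)) / (1.0 + t15 * np.sqrt(t15))
        expg = tab[28, i0] + fr * (tab[28, i0 + 1] - tab[28, i0])
        expgm1 = tab[29, i0] + fr * (tab[29, i0 + 1] - tab[29, i0])
        nai3 = nai * nai * nai
        inaca = prof[1] * I_NACA_MAX * (expg * nai3 * CA_O - expgm1 * NA_O ** 3 * cai) / (
            (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * expgm1))
        ibna = G_B_NA * (vm - ena)
        ibca = G_B_CA * (vm - eca)

        # SR calcium handling
        u = S[k, 13]
        v_g = S[k, 14]
        w = S[k, 15]
        irel = K_REL * u * u * v_g * w * (carel - cai)
        itr = (caup - carel) / TAU_TR
        iup = I_UP_MAX / (1.0 + K_UP / cai)
        iupleak = I_UP_MAX * caup / CA_UP_MAX

        fn = 1e-12 * V_REL * irel - 5e-13 / FARADAY * (0.5 * ical - 0.2 * inaca) * CM
        a1 = (fn - 3.4175e-13) / 13.67e-16
        if a1 > 80.0:
            a1 = 80.0
        elif a1 < -80.0:
            a1 = -80.0
        e1 = np.exp(-a1)
        a2 = (fn - 6.835e-14) / 13.67e-16
        if a2 > 80.0:
            a2 = 80.0
        elif a2 < -80.0:
            a2 = -80.0
        e2 = np.exp(-a2)
        u_inf = 1.0 / (1.0 + e1)
        v_inf = 1.0 - 1.0 / (1.0 + e2)
        tau_v = 1.91 + 2.09 / (1.0 + e1)

        i_ion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak
                 + inaca + ibna + ibca)
        S[k, 0] = vm + dt * (-i_ion + istim[k] + lap[k])

        # Rush-Larsen gate updates from the tables
        for g in range(12):
            row = 2 * g
            inf = tab[row, i0] + fr * (tab[row, i0 + 1] - tab[row, i0])
            rlf = tab[row + 1, i0] + fr * (tab[row + 1, i0 + 1] - tab[row + 1, i0])
            col = g + 1 if g < 11 else 15   # gates 1..11 then w at col 15
            S[k, col] = inf + (S[k, col] - inf) * rlf
        fca_inf = 1.0 / (1.0 + cai / 0.00035)
        S[k, 12] = fca_inf + (fca - fca_inf) * fca_rl
        S[k, 13] = u_inf + (u - u_inf) * u_rl
        S[k, 14] = v_inf + (v_g - v_inf) * np.exp(-dt / tau_v)

        # concentrations (forward Euler)
        cfac = CM / (FARADAY * V_I)
        S[k, 16] = nai + dt * (-3.0 * inak - 3.0 * inaca - ibna - ina) * cfac
        S[k, 17] = ki + dt * (2.0 * inak - ik1 - ito - ikur - ikr - iks) * cfac
        b1 = (2.0 * inaca - ipca - ical - ibca) * 0.5 * cfac + (
            V_UP * (iupleak - iup) + irel * V_REL) / V_I
        d1 = cai + KM_CMDN
        d2 = cai + KM_TRPN
        b2 = 1.0 + TRPN_MAX * KM_TRPN / (d2 * d2) + CMDN_MAX * KM_CMDN / (d1 * d1)
        S[k, 18] = cai + dt * b1 / b2
        S[k, 19] = caup + dt * (iup - iupleak - itr * V_REL / V_UP)
        dcsq = carel + KM_CSQN
        S[k, 20] = carel + dt * (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN / (dcsq * dcsq))
    return status


@njit(cache=True, fastmath={'nsz', 'arcp', 'contract'})
def diffusion_term(V, wE, wW, wN, wS, cc, gx, gy, cmask, lap):
    """Conservative anisotropic Laplacian ∇·(D∇V) on the flattened ny*nx grid.

    Face weights wE/wW/wN/wS carry the 1/dx^2 factors and vanish across
    no-flux faces (edges, PV openings, ablated nodes).  The fiber cross term
    (coefficient cc = 2*Dxy/(4 dx dy), plus smooth-variation terms gx, gy)
    is only applied where the full 3x3 neighborhood is active (cmask).
    """
    ny, nx = V.shape
    for i in range(ny):
        for j in range(nx):
            v0 = V[i, j]
            acc = 0.0
            if j + 1 < nx:
                acc += wE[i, j] * (V[i, j + 1] - v0)
            if j > 0:
                acc += wW[i, j] * (V[i, j - 1] - v0)
            if i + 1 < ny:
                acc += wN[i, j] * (V[i + 1, j] - v0)
            if i > 0:
                acc += wS[i, j] * (V[i - 1, j] - v0)
            if cmask[i, j]:
                vxy = (V[i + 1, j + 1] - V[i + 1, j - 1]
                       - V[i - 1, j + 1] + V[i - 1, j - 1])
                dvdx = V[i, j + 1] - V[i, j - 1]
                dvdy = V[i + 1, j] - V[i - 1, j]
                acc += cc[i, j] * vxy + gx[i, j] * dvdy + gy[i, j] * dvdx
            lap[i, j] = acc


@njit(cache=True, fastmath={'nsz', 'arcp', 'contract'})
def run_monodomain(S, active, wE, wW, wN, wS, cc, gx, gy, cmask,
                   tab, dt, n_steps, rec_every, Vrec,
                   stim_start, stim_dur, stim_amp, stim_off, stim_nodes,
                   prof, ny, nx):
    """Full time loop.  Records V (float32) every rec_every steps, starting
    with the initial condition.  Returns (status, failed_step); status 1
    flags a numerical blow-up."""
    n = ny * nx
    lap = np.zeros((ny, nx))
    istim = np.zeros(n)
    fca_rl = np.exp(-dt / TAU_F_CA)
    u_rl = np.exp(-dt / TAU_U)
    ena_c = np.zeros(n)
    ek_c = np.zeros(n)
    eca_c = np.zeros(n)
    e_every = max(1, int(round(1.0 / dt)))   # refresh Nernst caches at ~1 ms
    Vgrid = S[:, 0].copy().reshape(ny, nx)
    rec = 0
    for k in range(n):
        Vrec[0, k] = S[k, 0]
    rec = 1
    n_ev = stim_start.shape[0]
    for step in range(n_steps):
        t_mid = (step + 0.5) * dt
        # diffusion on the current V field
        for k in range(n):
            Vgrid[k // nx, k % nx] = S[k, 0]
        diffusion_term(Vgrid, wE, wW, wN, wS, cc, gx, gy, cmask, lap)
        # stimuli: add, step, then clear only touched entries
        touched_lo = -1
        for e in range(n_ev):
            if stim_start[e] <= t_mid < stim_start[e] + stim_dur[e]:
                for q in range(stim_off[e], stim_off[e + 1]):
                    istim[stim_nodes[q]] += stim_amp[e]
                if touched_lo < 0:
                    touched_lo = e
        st = step_nodes(S, lap.reshape(n), istim, active, tab, dt, prof,
                        fca_rl, u_rl, ena_c, ek_c, eca_c,
                        step % e_every == 0)
        if st != 0:
            return 1, step
        if touched_lo >= 0:
            for e in range(n_ev):
                if stim_start[e] <= t_mid < stim_start[e] + stim_dur[e]:
                    for q in range(stim_off[e], stim_off[e + 1]):
                        istim[stim_nodes[q]] = 0.0
        if (step + 1) % rec_every == 0:
            for k in range(n):
                Vrec[rec, k] = S[k, 0]
            rec += 1
    return 0, n_steps
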