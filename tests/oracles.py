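"""Independent oracles used to cross-check the implementation.

Everything here is coded separately from the package internals, on purpose:
plain-Python scalar transcriptions of the seasonal derivative fields, a
classical fixed-step fourth-order Runge-Kutta integrator, and an SIS model
variant with the resistant class deleted (recovery routed directly back to
the susceptible class).  None of it imports the package's rhs/integration
code paths beyond parameter values.
"""

import numpy as np
from scipy.integrate import solve_ivp

# state order: Sr, Ir1, Ir2, Ir3, Rr, Sm, Im1, Im2, Im3, Rm


def beta_values(p):
    """Trade-off evaluated from first principles for each named form."""
    out = []
    for a in p.alpha:
        if p.tradeoff_form == "concave_sqrt":
            out.append(p.cA * (p.cB + a) ** 0.5)
        elif p.tradeoff_form == "ratio":
            out.append(p.cA / (p.cB + a))
        elif p.tradeoff_form == "linear":
            out.append(p.cA * p.cB + a)
        else:
            raise ValueError(p.tradeoff_form)
    return out


def naive_rhs_shared(y, p):
    """Scalar transcription of the shared-season equations."""
    Sr, Ir1, Ir2, Ir3, Rr, Sm, Im1, Im2, Im3, Rm = [float(v) for v in y]
    beta = beta_values(p)
    Ir = [Ir1, Ir2, Ir3]
    Im = [Im1, Im2, Im3]
    N = sum([Sr, Ir1, Ir2, Ir3, Rr, Sm, Im1, Im2, Im3, Rm])
    dens = 1.0 - p.gamma * N
    mu, nu1, b, d, sig = float(p.mu), float(p.nu1), p.b, p.d, p.sigma

    dSr = (
        -sum(beta[i] * Sr * (Ir[i] + Im[i]) for i in range(3))
        + mu * Rr
        + (b * (Sr + Rr) + (b + sig) * sum(Ir)) * dens
        - d * Sr
    )
    dSm = (
        -sum(beta[i] * Sm * (Ir[i] + Im[i]) for i in range(3))
        + mu * Rm
        + (b * (Sm + Rm) + (b + sig) * sum(Im)) * dens
        - d * Sm
    )
    dIr = [
        beta[i] * Sr * (Ir[i] + Im[i]) - nu1 * Ir[i] - (d + p.alpha[i]) * Ir[i]
        for i in range(3)
    ]
    dIm = [
        beta[i] * Sm * (Ir[i] + Im[i]) - nu1 * Im[i] - (d + p.alpha[i]) * Im[i]
        for i in range(3)
    ]
    dRr = nu1 * sum(Ir) - mu * Rr - d * Rr
    dRm = nu1 * sum(Im) - mu * Rm - d * Rm
    return [dSr, dIr[0], dIr[1], dIr[2], dRr, dSm, dIm[0], dIm[1], dIm[2], dRm]


def naive_rhs_separate(y, p):
    """Scalar transcription of the apart-season equations."""
    Sr, Ir1, Ir2, Ir3, Rr, Sm, Im1, Im2, Im3, Rm = [float(v) for v in y]
    beta = beta_values(p)
    Ir = [Ir1, Ir2, Ir3]
    Im = [Im1, Im2, Im3]
    mu, nu1, nu2, d = float(p.mu), float(p.nu1), float(p.nu2), p.d

    dSr = -sum(beta[i] * Sr * Ir[i] for i in range(3)) + mu * Rr - d * Sr
    dSm = -sum(beta[i] * Sm * Im[i] for i in range(3)) + mu * Rm - d * Sm
    dIr = [beta[i] * Sr * Ir[i] - nu1 * Ir[i] - (d + p.alpha[i]) * Ir[i] for i in range(3)]
    dIm = [beta[i] * Sm * Im[i] - nu2 * Im[i] - (d + p.alpha[i]) * Im[i] for i in range(3)]
    dRr = nu1 * sum(Ir) - mu * Rr - d * Rr
    dRm = nu2 * sum(Im) - mu * Rm - d * Rm
    return [dSr, dIr[0], dIr[1], dIr[2], dRr, dSm, dIm[0], dIm[1], dIm[2], dRm]


def rk4_integrate(y, rhs, p, duration, h=1e-4):
    """Classical fixed-step RK4 on a scalar-transcribed field."""
    y = [float(v) for v in y]
    n_steps = int(round(duration / h))
    for _ in range(n_steps):
        k1 = rhs(y, p)
        k2 = rhs([y[i] + 0.5 * h * k1[i] for i in range(10)], p)
        k3 = rhs([y[i] + 0.5 * h * k2[i] for i in range(10)], p)
        k4 = rhs([y[i] + h * k3[i] for i in range(10)], p)
        y = [
            y[i] + h / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
            for i in range(10)
        ]
    return y


def naive_pulse(y, p):
    y = [float(v) for v in y]
    dS, dI, dR = float(p.delta_S), float(p.delta_I), float(p.delta_R)
    y[5] *= 1.0 - dS
    for i in (6, 7, 8):
        y[i] *= 1.0 - dI
    y[9] *= 1.0 - dR
    return y


def rk4_one_year(y, p, h=1e-4):
    """One annual cycle via the fixed-step oracle: T1, pulse, T2, pulse."""
    y = rk4_integrate(y, naive_rhs_shared, p, p.T1, h)
    y = naive_pulse(y, p)
    y = rk4_integrate(y, naive_rhs_separate, p, p.T2, h)
    return naive_pulse(y, p)


# ---------------------------------------------------------------------------
# SIS variant: 8 compartments (Sr, Ir1-3, Sm, Im1-3), no resistant class;
# recovery returns hosts directly to their susceptible compartment.
# ---------------------------------------------------------------------------


def _sis_rhs(t, yflat, beta, alpha, p, nu1, nu2, shared):
    y = yflat.reshape(8, -1)
    Sr, Ir, Sm, Im = y[0], y[1:4], y[4], y[5:8]
    bcol = beta[:, None]
    acol = alpha[:, None]
    out = np.empty_like(y)
    if shared:
        N = y.sum(axis=0)
        dens = 1.0 - p.gamma * N
        pool = Ir + Im
        new_r = bcol * Sr * pool
        new_m = bcol * Sm * pool
        out[0] = (-new_r.sum(axis=0) + nu1 * Ir.sum(axis=0)
                  + (p.b * Sr + (p.b + p.sigma) * Ir.sum(axis=0)) * dens - p.d * Sr)
        out[1:4] = new_r - (nu1 + p.d + acol) * Ir
        out[4] = (-new_m.sum(axis=0) + nu1 * Im.sum(axis=0)
                  + (p.b * Sm + (p.b + p.sigma) * Im.sum(axis=0)) * dens - p.d * Sm)
        out[5:8] = new_m - (nu1 + p.d + acol) * Im
    else:
        new_r = bcol * Sr * Ir
        new_m = bcol * Sm * Im
        out[0] = -new_r.sum(axis=0) + nu1 * Ir.sum(axis=0) - p.d * Sr
        out[1:4] = new_r - (nu1 + p.d + acol) * Ir
        out[4] = -new_m.sum(axis=0) + nu2 * Im.sum(axis=0) - p.d * Sm
        out[5:8] = new_m - (nu2 + p.d + acol) * Im
    return out.ravel()


def sis_winner_map(mu_values, nu1_values, delta_I, p, years, nu2_offset=0.12,
                   threshold=1e-6):
    """Winner per (nu1, mu) cell under the SIS variant (mu plays no role
    beyond being part of the grid shape; recovery is direct I -> S)."""
    nn, _ = np.meshgrid(np.asarray(nu1_values, float),
                        np.asarray(mu_values, float), indexing="ij")
    nu1 = nn.ravel()
    nu2 = nu1 + nu2_offset
    beta = np.array(beta_values(p))
    alpha = np.array(p.alpha)
    y = np.full((8, nu1.size), 100.0)
    dS, dI = float(np.asarray(p.delta_S)), float(delta_I)
    for _ in range(years):
        for shared, dur in ((True, p.T1), (False, p.T2)):
            sol = solve_ivp(
                _sis_rhs, (0.0, dur), y.ravel(),
                args=(beta, alpha, p, nu1, nu2, shared),
                method="RK45", rtol=1e-8, atol=1e-10,
            )
            y = np.maximum(sol.y[:, -1].reshape(8, -1), 0.0)
            y[4] *= 1.0 - dS
            y[5:8] *= 1.0 - dI
    totals = y[1:4] + y[5:8]
    winners = np.argmax(totals, axis=0) + 1
    winners = np.where(totals.max(axis=0) > threshold, winners, 0)
    return winners.reshape(len(nu1_values), len(mu_values))
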