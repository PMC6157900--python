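"""Numba kernel for the 1D arterial-network solver.

All state lives in flat per-node arrays covering every vessel of the tree.
The interior of each vessel is advanced with the two-step (Richtmyer)
Lax-Wendroff scheme on the conservation form of the (A, q) system

    A_t + q_x = 0
    q_t + (q^2/A + gamma * sqrt(A))_x = S(A, q; x)

with gamma(x) = F(x) sqrt(A0(x)) / rho, geometric source terms from the axial
variation of F and A0, and a boundary-layer friction term -cf * q / sqrt(A).
Where the source terms need sqrt(A) at a cell midpoint the mean of the
nodal square roots is used (a consistent second-order discretisation that
lets each sqrt be computed once per node and step).

Boundary nodes are closed by half-cell mass balances coupled to the junction
conditions: at a bifurcation the three boundary flows are solved (Newton, 2x2)
so that continuity of static pressure and exact discrete flow conservation
hold simultaneously with the half-cell continuity updates; a Windkessel
terminal solves the analogous scalar problem against its capacitor pressure.
The scheme conserves the tree's stored volume to round-off by construction.

The wave speed of the tube law p = p_ref + F (1 - sqrt(A0/A)) is
c(A) = sqrt(gamma/2) * A**-0.25.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEG_AREA = 1


@njit(cache=True)
def _p_of_area(A, A0, F, prefc):
    return prefc + F * (1.0 - np.sqrt(A0 / A))


@njit(cache=True, fastmath=True)
def run_cycle(A, q, pc,
              nsteps, dt,
              A0, sqA0, F, gamma, cc, dFdx, dsA0dx,
              A0h, sqA0h, Fh, gammah, dFdxh, dsA0dxh,
              rho, prefc, cf,
              vstart, vlen, vdx,
              jn_pe, jn_d1, jn_d2, jn_vp, jn_vd1, jn_vd2,
              term_node, term_v, R1, R2, Cap, p_out_c,
              inlet_node, qin, qinh,
              rec_every, recA, recq):
    """Advance one cardiac cycle in place.  Returns (status, vin, vout)."""
    N = A.shape[0]
    nv = vstart.shape[0]
    nj = jn_pe.shape[0]
    nt = term_node.shape[0]
    Ah = np.empty(N)
    qh = np.empty(N)
    sqA = np.empty(N)
    f2 = np.empty(N)
    sqAh = np.empty(N)
    f2h = np.empty(N)
    vin = 0.0
    vout = 0.0
    irec = 0
    recA[0, :] = A
    recq[0, :] = q
    for step in range(nsteps):
        # nodal square roots and fluxes (one sqrt per node)
        for i in range(N):
            sqA[i] = np.sqrt(A[i])
            f2[i] = q[i] * q[i] / A[i] + gamma[i] * sqA[i]
        # --- interface half-steps (per vessel) ---
        for v in range(nv):
            s = vstart[v]
            e = s + vlen[v] - 1  # last node
            lam = dt / (2.0 * vdx[v])
            for i in range(s, e):
                Al = A[i]
                Ar = A[i + 1]
                ql = q[i]
                qr = q[i + 1]
                Amean = 0.5 * (Al + Ar)
                qmean = 0.5 * (ql + qr)
                sqm = 0.5 * (sqA[i] + sqA[i + 1])
                Am = Amean - lam * (qr - ql)
                Sm = (dFdxh[i] * (2.0 * sqm * sqA0h[i] - Amean)
                      + 2.0 * Fh[i] * dsA0dxh[i] * sqm) / rho \
                    - cf * qmean / sqm
                qm = qmean - lam * (f2[i + 1] - f2[i]) + 0.5 * dt * Sm
                Ah[i] = Am
                qh[i] = qm
                sq = np.sqrt(Am)
                sqAh[i] = sq
                f2h[i] = qm * qm / Am + gammah[i] * sq
        # --- full step, interior nodes ---
        for v in range(nv):
            s = vstart[v]
            e = s + vlen[v] - 1
            lam = dt / vdx[v]
            for i in range(s + 1, e):
                Ac = 0.5 * (Ah[i - 1] + Ah[i])
                qc = 0.5 * (qh[i - 1] + qh[i])
                sqc = 0.5 * (sqAh[i - 1] + sqAh[i])
                Sc = (dFdx[i] * (2.0 * sqc * sqA0[i] - Ac)
                      + 2.0 * F[i] * dsA0dx[i] * sqc) / rho - cf * qc / sqc
                newA = A[i] - lam * (qh[i] - qh[i - 1])
                q[i] = q[i] - lam * (f2h[i] - f2h[i - 1]) + dt * Sc
                A[i] = newA
                if newA <= 0.0:
                    return STATUS_NEG_AREA, vin, vout
        # --- root inlet: q prescribed, half-cell continuity closes A ---
        i0 = inlet_node
        A[i0] = A[i0] - (2.0 * dt / vdx[0]) * (qh[i0] - qinh[step])
        if A[i0] <= 0.0:
            return STATUS_NEG_AREA, vin, vout
        q[i0] = qin[step + 1]
        vin += qinh[step] * dt
        # --- bifurcations: solve (q_p, q_1, q_2) with q_p = q_1 + q_2 so the
        # half-cell continuity updates give equal static pressures ---
        for j in range(nj):
            pe = jn_pe[j]
            d1 = jn_d1[j]
            d2 = jn_d2[j]
            kp = dt / vdx[jn_vp[j]]
            k1 = dt / vdx[jn_vd1[j]]
            k2 = dt / vdx[jn_vd2[j]]
            # constant parts of the half-cell balances
            bp = A[pe] - kp * (q[pe] - 2.0 * qh[pe - 1])
            b1 = A[d1] - k1 * (2.0 * qh[d1] - q[d1])
            b2 = A[d2] - k2 * (2.0 * qh[d2] - q[d2])
            q1 = q[d1]
            q2 = q[d2]
            ok = True
            for _ in range(60):
                qp = q1 + q2
                Ap = bp - kp * qp
                A1 = b1 + k1 * q1
                A2 = b2 + k2 * q2
                if Ap <= 0.0 or A1 <= 0.0 or A2 <= 0.0:
                    ok = False
                    break
                pp = _p_of_area(Ap, A0[pe], F[pe], prefc)
                p1 = _p_of_area(A1, A0[d1], F[d1], prefc)
                p2 = _p_of_area(A2, A0[d2], F[d2], prefc)
                dpp = F[pe] * sqA0[pe] / (2.0 * Ap * np.sqrt(Ap))
                dp1 = F[d1] * sqA0[d1] / (2.0 * A1 * np.sqrt(A1))
                dp2 = F[d2] * sqA0[d2] / (2.0 * A2 * np.sqrt(A2))
                g1 = pp - p1
                g2 = pp - p2
                # Jacobian of (g1, g2) wrt (q1, q2)
                a11 = -dpp * kp - dp1 * k1
                a12 = -dpp * kp
                a21 = -dpp * kp
                a22 = -dpp * kp - dp2 * k2
                det = a11 * a22 - a12 * a21
                dq1 = -(g1 * a22 - g2 * a12) / det
                dq2 = -(a11 * g2 - a21 * g1) / det
                q1 += dq1
                q2 += dq2
                if abs(dq1) + abs(dq2) < 1e-10 * (abs(q1) + abs(q2) + 1.0):
                    break
            if not ok:
                return STATUS_NEG_AREA, vin, vout
            qp = q1 + q2
            A[pe] = bp - kp * qp
            A[d1] = b1 + k1 * q1
            A[d2] = b2 + k2 * q2
            q[pe] = qp
            q[d1] = q1
            q[d2] = q2
        # --- Windkessel terminals: half-cell continuity against p_c + R1 q ---
        for t in range(nt):
            tn = term_node[t]
            kt = dt / vdx[term_v[t]]
            bt = A[tn] - kt * (q[tn] - 2.0 * qh[tn - 1])
            qold = q[tn]
            qt = qold
            ok = True
            for _ in range(60):
                At = bt - kt * qt
                if At <= 0.0:
                    ok = False
                    break
                pt = _p_of_area(At, A0[tn], F[tn], prefc)
                dpdA = F[tn] * sqA0[tn] / (2.0 * At * np.sqrt(At))
                fres = pt - pc[t] - R1[t] * qt
                dfres = -dpdA * kt - R1[t]
                dq = -fres / dfres
                qt += dq
                if abs(dq) < 1e-12 * (abs(qt) + 1.0):
                    break
            if not ok:
                return STATUS_NEG_AREA, vin, vout
            A[tn] = bt - kt * qt
            q[tn] = qt
            vout += 0.5 * (qold + qt) * dt
            # exact exponential capacitor update with q held over the step
            pinf = p_out_c[t] + qt * R2[t]
            pc[t] = pinf + (pc[t] - pinf) * np.exp(-dt / (R2[t] * Cap[t]))
        if (step + 1) % rec_every == 0:
            irec += 1
            if irec < recA.shape[0]:
                recA[irec, :] = A
                recq[irec, :] = q
    return STATUS_OK, vin, vout
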