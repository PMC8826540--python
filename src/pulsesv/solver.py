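"""1-D pulse propagation on the arterial tree.

Solves the standard 1-D continuity and momentum equations

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -8 pi nu Q/A

with the linear elastic tube law A(P) = A_ref (1 + D (P - P_ref)), for which
the local wave speed is c = sqrt(A / (rho A_ref D)) (Bramwell-Hill
c = 1/sqrt(rho D) at the reference pressure).  Interior nodes advance with a
two-step Lax-Wendroff (MacCormack) scheme on per-segment uniform grids;
boundary nodes are closed by the outgoing Riemann invariants u +/- 2c:

* root      : prescribed inflow Q(t),
* junctions : continuity of pressure and conservation of flow (scalar Newton
              solve on the junction pressure),
* terminals : three-element Windkessel (Z_c in series with R_p || C against a
              fixed venous pressure).

Beats are repeated from a uniform initial state until the root pressure is
periodic (relative L2 difference between consecutive beats below a tolerance).
The time-stepping kernel is numba-compiled; a full simulation of the default
24-segment tree takes tens of milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import SolverError, ValidationError
from .inflow import InflowWave
from .tree import ArterialTree
from .units import CM_TO_M, CM2_TO_M2, MMHG_TO_PA, ML_TO_M3, RES_TO_SI, CAP_TO_SI

__all__ = ["SolverConfig", "PressureFlowField", "simulate"]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the pulse solver."""

    dx_cm: float = 0.5            # target spatial step
    cfl: float = 0.8              # CFL factor for the fixed time step
    conv_tol: float = 1e-3        # beat-to-beat relative L2 tolerance (root pressure)
    max_beats: int = 20
    venous_pressure_mmhg: float = 8.0
    init_pressure_mmhg: float = 80.0
    # wave-speed headroom used when fixing the time step: dt is chosen from the
    # fastest wave speed the run is allowed to reach (evaluated at p_hi) plus a
    # convective margin.  Exceeding it mid-run raises a CFL error.
    p_hi_mmhg: float = 250.0
    u_margin_mps: float = 3.0


@dataclass
class PressureFlowField:
    """Final-beat pressure/flow series at segment endpoints and sites.

    Series are keyed by "root", the measurement sites ("carotid", "brachial",
    "femoral") and segment endpoints ("<segment>:prox", "<segment>:dist").
    Pressures in mmHg, flows in mL/s, volume in mL, times in s relative to the
    start of the recorded beat.
    """

    t: np.ndarray
    dt: float
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    inflow: np.ndarray
    terminal_flows: dict[str, np.ndarray]
    volume: np.ndarray
    volume_start: float
    n_beats_run: int
    periodicity_residual: float
    converged: bool
    site_positions_m: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def conservation_error(self) -> float:
        """Net volume gain per beat as a fraction of the inflow volume.

        (integral of inflow) - (sum of terminal outflow integrals)
        - (change of tree volume over the beat), relative to the stroke
        volume delivered; a periodic, mass-conserving run gives ~0.
        """
        sv = float(np.sum(self.inflow)) * self.dt
        out = sum(float(np.sum(q)) * self.dt for q in self.terminal_flows.values())
        dv = float(self.volume[-1]) - self.volume_start
        return (sv - out - dv) / sv

    def mean_pressure(self, key: str = "root") -> float:
        return float(np.mean(self.pressures[key]))

    def mean_inflow(self) -> float:
        return float(np.mean(self.inflow))


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _wave_q(t, wq, t_period):
    nw = wq.shape[0]
    pos = (t % t_period) / t_period * nw
    i0 = int(pos)
    fr = pos - i0
    if i0 >= nw:
        i0 = nw - 1
        fr = 1.0
    i1 = i0 + 1
    if i1 == nw:
        i1 = 0
    return wq[i0] * (1.0 - fr) + wq[i1] * fr


@njit(cache=True)
def _run(A, Q, aref, dcoef, kc, seg_start, seg_n, seg_dx,
         jn_pnode, jn_c1, jn_c2, term_node, term_zc, term_rp, term_cc, pc,
         rec_idx, volw, wq, t_period, dt, nsteps, max_beats, conv_tol,
         rho, kf, pref, pv, c_limit,
         recP, recQ, qin_rec, qterm_rec, vol_rec):
    nnode = A.shape[0]
    nseg = seg_start.shape[0]
    njun = jn_pnode.shape[0]
    nterm = term_node.shape[0]
    nrec = rec_idx.shape[0]

    p = np.empty(nnode)
    As = np.empty(nnode)
    Qs = np.empty(nnode)
    ps = np.empty(nnode)
    An = np.empty(nnode)
    Qn = np.empty(nnode)
    root_prev = np.zeros(nsteps)
    root_cur = np.zeros(nsteps)

    n_beats = 0
    resid = 1e30
    converged = False
    cfl_seg = -1
    vol0 = 0.0

    for beat in range(max_beats):
        vol0 = 0.0
        for i in range(nnode):
            vol0 += volw[i] * A[i]
        for step in range(nsteps):
            t_new = (step + 1) * dt
            for i in range(nnode):
                p[i] = pref + (A[i] / aref[i] - 1.0) / dcoef[i]

            # predictor (forward differences)
            for s in range(nseg):
                i0 = seg_start[s]
                i1 = i0 + seg_n[s]
                dtdx = dt / seg_dx[s]
                for j in range(i0, i1 - 1):
                    fa = Q[j + 1] - Q[j]
                    fq = Q[j + 1] * Q[j + 1] / A[j + 1] - Q[j] * Q[j] / A[j]
                    As[j] = A[j] - dtdx * fa
                    Qs[j] = (Q[j] - dtdx * fq
                             - dtdx * (A[j] / rho) * (p[j + 1] - p[j])
                             - dt * kf * Q[j] / A[j])
                As[i1 - 1] = A[i1 - 1]
                Qs[i1 - 1] = Q[i1 - 1]
                for j in range(i0, i1):
                    ps[j] = pref + (As[j] / aref[j] - 1.0) / dcoef[j]
                # corrector (backward differences), interior nodes only
                for j in range(i0 + 1, i1 - 1):
                    fa = Qs[j] - Qs[j - 1]
                    fq = Qs[j] * Qs[j] / As[j] - Qs[j - 1] * Qs[j - 1] / As[j - 1]
                    An[j] = 0.5 * (A[j] + As[j]) - 0.5 * dtdx * fa
                    Qn[j] = (0.5 * (Q[j] + Qs[j]) - 0.5 * dtdx * fq
                             - 0.5 * dtdx * (As[j] / rho) * (ps[j] - ps[j - 1])
                             - 0.5 * dt * kf * Qs[j] / As[j])

            # ---- root boundary: prescribed inflow -------------------------
            dx0 = seg_dx[0]
            u0 = Q[0] / A[0]
            c0 = kc[0] * np.sqrt(A[0])
            u1 = Q[1] / A[1]
            c1 = kc[1] * np.sqrt(A[1])
            lam = (c0 - u0) * dt / dx0
            if lam < 0.0:
                lam = 0.0
            if lam > 1.0:
                lam = 1.0
            uf = u0 * (1.0 - lam) + u1 * lam
            cf = c0 * (1.0 - lam) + c1 * lam
            wm = uf - 2.0 * cf
            qin = _wave_q(t_new, wq, t_period)
            a = A[0]
            for _ in range(30):
                sq = np.sqrt(a)
                g = qin / a - 2.0 * kc[0] * sq - wm
                gp = -qin / (a * a) - kc[0] / sq
                da = g / gp
                a -= da
                if a <= 0.0:
                    a = 0.1 * aref[0]
                if abs(da) < 1e-14 * aref[0] + 1e-16:
                    break
            An[0] = a
            Qn[0] = qin
            qin_rec[step] = qin

            # ---- junctions: pressure continuity + flow conservation -------
            for k in range(njun):
                ip = jn_pnode[k]
                sp = 0
                for s in range(nseg):
                    if seg_start[s] <= ip < seg_start[s] + seg_n[s]:
                        sp = s
                        break
                dxp = seg_dx[sp]
                up = Q[ip] / A[ip]
                cp = kc[ip] * np.sqrt(A[ip])
                um = Q[ip - 1] / A[ip - 1]
                cm = kc[ip - 1] * np.sqrt(A[ip - 1])
                lam = (up + cp) * dt / dxp
                if lam < 0.0:
                    lam = 0.0
                if lam > 1.0:
                    lam = 1.0
                uf = up * (1.0 - lam) + um * lam
                cf = cp * (1.0 - lam) + cm * lam
                wp = uf + 2.0 * cf

                ic1 = jn_c1[k]
                ic2 = jn_c2[k]
                nchild = 1 if ic2 < 0 else 2
                wmc1 = 0.0
                wmc2 = 0.0
                for cc in range(nchild):
                    ic = ic1 if cc == 0 else ic2
                    sc = 0
                    for s in range(nseg):
                        if seg_start[s] <= ic < seg_start[s] + seg_n[s]:
                            sc = s
                            break
                    dxc = seg_dx[sc]
                    uc = Q[ic] / A[ic]
                    ccs = kc[ic] * np.sqrt(A[ic])
                    un = Q[ic + 1] / A[ic + 1]
                    cn = kc[ic + 1] * np.sqrt(A[ic + 1])
                    lamc = (ccs - uc) * dt / dxc
                    if lamc < 0.0:
                        lamc = 0.0
                    if lamc > 1.0:
                        lamc = 1.0
                    ufc = uc * (1.0 - lamc) + un * lamc
                    cfc = ccs * (1.0 - lamc) + cn * lamc
                    if cc == 0:
                        wmc1 = ufc - 2.0 * cfc
                    else:
                        wmc2 = ufc - 2.0 * cfc

                # Newton on the common junction pressure
                pj = p[ip]
                for _ in range(30):
                    ap = aref[ip] * (1.0 + dcoef[ip] * (pj - pref))
                    if ap < 0.05 * aref[ip]:
                        ap = 0.05 * aref[ip]
                    cpj = kc[ip] * np.sqrt(ap)
                    f = ap * (wp - 2.0 * cpj)
                    df = aref[ip] * dcoef[ip] * (wp - 3.0 * cpj)
                    for cc in range(nchild):
                        ic = ic1 if cc == 0 else ic2
                        wmc = wmc1 if cc == 0 else wmc2
                        ac = aref[ic] * (1.0 + dcoef[ic] * (pj - pref))
                        if ac < 0.05 * aref[ic]:
                            ac = 0.05 * aref[ic]
                        ccj = kc[ic] * np.sqrt(ac)
                        f -= ac * (wmc + 2.0 * ccj)
                        df -= aref[ic] * dcoef[ic] * (wmc + 3.0 * ccj)
                    dp = f / df
                    pj -= dp
                    if abs(dp) < 1e-10:
                        break
                ap = aref[ip] * (1.0 + dcoef[ip] * (pj - pref))
                An[ip] = ap
                Qn[ip] = ap * (wp - 2.0 * kc[ip] * np.sqrt(ap))
                for cc in range(nchild):
                    ic = ic1 if cc == 0 else ic2
                    wmc = wmc1 if cc == 0 else wmc2
                    ac = aref[ic] * (1.0 + dcoef[ic] * (pj - pref))
                    An[ic] = ac
                    Qn[ic] = ac * (wmc + 2.0 * kc[ic] * np.sqrt(ac))

            # ---- terminals: three-element Windkessel ----------------------
            for k in range(nterm):
                it = term_node[k]
                st = 0
                for s in range(nseg):
                    if seg_start[s] <= it < seg_start[s] + seg_n[s]:
                        st = s
                        break
                dxt = seg_dx[st]
                ut = Q[it] / A[it]
                ct = kc[it] * np.sqrt(A[it])
                um = Q[it - 1] / A[it - 1]
                cm = kc[it - 1] * np.sqrt(A[it - 1])
                lam = (ut + ct) * dt / dxt
                if lam < 0.0:
                    lam = 0.0
                if lam > 1.0:
                    lam = 1.0
                uf = ut * (1.0 - lam) + um * lam
                cf = ct * (1.0 - lam) + cm * lam
                wp = uf + 2.0 * cf
                zc = term_zc[k]
                a = A[it]
                for _ in range(30):
                    sq = np.sqrt(a)
                    cw = kc[it] * sq
                    pa = pref + (a / aref[it] - 1.0) / dcoef[it]
                    g = a * (wp - 2.0 * cw) - (pa - pc[k]) / zc
                    gp = wp - 3.0 * cw - 1.0 / (zc * aref[it] * dcoef[it])
                    da = g / gp
                    a -= da
                    if a <= 0.0:
                        a = 0.1 * aref[it]
                    if abs(da) < 1e-14 * aref[it] + 1e-16:
                        break
                qt = a * (wp - 2.0 * kc[it] * np.sqrt(a))
                An[it] = a
                Qn[it] = qt
                rp = term_rp[k]
                ccap = term_cc[k]
                pc[k] = (pc[k] + dt / ccap * (qt + pv / rp)) / (1.0 + dt / (rp * ccap))
                qterm_rec[k, step] = qt

            # conservative continuity closure at segment-end nodes: the
            # characteristic solves set Q (and the Windkessel/junction
            # coupling); area at the half-cells is re-balanced with the same
            # time-centered face fluxes the interior scheme uses, so tree
            # volume change telescopes exactly to boundary in/outflows.
            for s in range(nseg):
                i0 = seg_start[s]
                iN = i0 + seg_n[s] - 1
                dtdx2 = 2.0 * dt / seg_dx[s]
                flux_l = 0.5 * (Q[i0 + 1] + Qs[i0])
                qb_l = 0.5 * (Q[i0] + Qn[i0])
                An[i0] = A[i0] + dtdx2 * (qb_l - flux_l)
                flux_r = 0.5 * (Q[iN] + Qs[iN - 1])
                qb_r = 0.5 * (Q[iN] + Qn[iN])
                An[iN] = A[iN] + dtdx2 * (flux_r - qb_r)

            # commit
            for i in range(nnode):
                A[i] = An[i]
                Q[i] = Qn[i]
            root_cur[step] = pref + (A[0] / aref[0] - 1.0) / dcoef[0]

            # record (cheap: ~50 nodes)
            for r in range(nrec):
                i = rec_idx[r]
                recP[r, step] = pref + (A[i] / aref[i] - 1.0) / dcoef[i]
                recQ[r, step] = Q[i]
            v = 0.0
            for i in range(nnode):
                v += volw[i] * A[i]
            vol_rec[step] = v

        n_beats = beat + 1

        # CFL / sanity audit on the end-of-beat state
        for s in range(nseg):
            i0 = seg_start[s]
            i1 = i0 + seg_n[s]
            for j in range(i0, i1):
                sp = abs(Q[j] / A[j]) + kc[j] * np.sqrt(A[j])
                if sp * dt / seg_dx[s] > 1.0:
                    cfl_seg = s
        if cfl_seg >= 0:
            break
        if not np.isfinite(root_cur).all():
            cfl_seg = -2
            break

        if beat > 0:
            num = 0.0
            den = 0.0
            for i in range(nsteps):
                d = root_cur[i] - root_prev[i]
                num += d * d
                den += root_cur[i] * root_cur[i]
            resid = np.sqrt(num / den)
            if resid < conv_tol:
                converged = True
        for i in range(nsteps):
            root_prev[i] = root_cur[i]
        if converged:
            break

    return n_beats, resid, converged, cfl_seg, vol0


# --------------------------------------------------------------------------
# tree compilation and the public entry point
# --------------------------------------------------------------------------

def _compile(tree: ArterialTree, config: SolverConfig):
    """Flatten the tree into SI node arrays ordered root-first."""
    order: list[str] = []

    def visit(name):
        order.append(name)
        for c in tree.children_of(name):
            visit(c)

    visit(tree.root)
    segs = {s.name: s for s in tree.segments}
    dx_target = config.dx_cm * CM_TO_M

    seg_start, seg_n, seg_dx = [], [], []
    aref, dcoef = [], []
    pos = 0
    index_of = {}
    for name in order:
        s = segs[name]
        L = s.length_cm * CM_TO_M
        n = max(3, int(round(L / dx_target)) + 1)
        dx = L / (n - 1)
        index_of[name] = (pos, n, dx)
        seg_start.append(pos)
        seg_n.append(n)
        seg_dx.append(dx)
        x = np.linspace(0.0, 1.0, n)
        aref.append((s.area_prox_cm2 + (s.area_dist_cm2 - s.area_prox_cm2) * x)
                    * CM2_TO_M2)
        dcoef.append(np.full(n, s.distensibility_per_mmhg / MMHG_TO_PA))
        pos += n

    aref = np.concatenate(aref)
    dcoef = np.concatenate(dcoef)
    rho = tree.blood_density_kg_m3
    kc = 1.0 / np.sqrt(rho * aref * dcoef)

    jn_pnode, jn_c1, jn_c2 = [], [], []
    for name in order:
        kids = tree.children_of(name)
        if not kids:
            continue
        if len(kids) > 2:
            raise ValidationError(f"junction at {name!r} has {len(kids)} children (max 2)")
        p0, pn, _ = index_of[name]
        jn_pnode.append(p0 + pn - 1)
        jn_c1.append(index_of[kids[0]][0])
        jn_c2.append(index_of[kids[1]][0] if len(kids) == 2 else -1)

    term_names = [n for n in order if segs[n].is_terminal]
    term_node = np.array([index_of[n][0] + index_of[n][1] - 1 for n in term_names])
    term_zc = np.array([tree.terminals[n].r_char_mmhg_s_ml * RES_TO_SI
                        for n in term_names])
    term_rp = np.array([tree.terminals[n].r_periph_mmhg_s_ml * RES_TO_SI
                        for n in term_names])
    term_cc = np.array([tree.terminals[n].c_term_ml_mmhg * CAP_TO_SI
                        for n in term_names])

    # trapezoid volume weights per node
    volw = np.zeros(pos)
    for i0, n, dx in (index_of[name] for name in order):
        volw[i0] += 0.5 * dx
        volw[i0 + n - 1] += 0.5 * dx
        volw[i0 + 1:i0 + n - 1] += dx

    # records: root, sites, segment endpoints
    rec_names, rec_idx = [], []

    def add(nm, idx):
        rec_names.append(nm)
        rec_idx.append(idx)

    add("root", 0)
    site_positions = {}
    for site, (seg_name, frac) in tree.sites.items():
        i0, n, dx = index_of[seg_name]
        j = int(round(frac * (n - 1)))
        add(site, i0 + j)
        upstream = sum(segs[a].length_cm for a in tree.ancestors(seg_name)) * CM_TO_M
        site_positions[site] = upstream + j * dx
    for name in order:
        i0, n, _ = index_of[name]
        add(f"{name}:prox", i0)
        add(f"{name}:dist", i0 + n - 1)

    return dict(
        order=order, index_of=index_of,
        seg_start=np.array(seg_start, dtype=np.int64),
        seg_n=np.array(seg_n, dtype=np.int64),
        seg_dx=np.array(seg_dx),
        aref=aref, dcoef=dcoef, kc=kc,
        jn_pnode=np.array(jn_pnode, dtype=np.int64),
        jn_c1=np.array(jn_c1, dtype=np.int64),
        jn_c2=np.array(jn_c2, dtype=np.int64),
        term_names=term_names, term_node=term_node,
        term_zc=term_zc, term_rp=term_rp, term_cc=term_cc,
        volw=volw, rho=rho,
        rec_names=rec_names, rec_idx=np.array(rec_idx, dtype=np.int64),
        site_positions=site_positions,
    )


def simulate(tree: ArterialTree, inflow: InflowWave,
             config: SolverConfig | None = None) -> PressureFlowField:
    """Run the 1-D model to a periodic steady state and return the final beat."""
    config = config or SolverConfig()
    c = _compile(tree, config)

    # fixed time step from the fastest admissible wave speed
    p_hi = config.p_hi_mmhg * MMHG_TO_PA
    pref = tree.reference_pressure_mmhg * MMHG_TO_PA
    a_hi = c["aref"] * np.maximum(1.0 + c["dcoef"] * (p_hi - pref), 0.2)
    c_hi = c["kc"] * np.sqrt(a_hi) + config.u_margin_mps
    dt_nodes = np.repeat(c["seg_dx"], c["seg_n"]) / c_hi
    dt = config.cfl * float(dt_nodes.min())
    nsteps = int(np.ceil(inflow.t_period / dt))
    dt = inflow.t_period / nsteps

    p0 = config.init_pressure_mmhg * MMHG_TO_PA
    A = c["aref"] * (1.0 + c["dcoef"] * (p0 - pref))
    Q = np.zeros_like(A)
    pc = np.full(len(c["term_names"]), p0)
    pv = config.venous_pressure_mmhg * MMHG_TO_PA
    kf = 8.0 * np.pi * (tree.blood_viscosity_mpa_s * 1e-3) / c["rho"]

    wq = inflow.flow * ML_TO_M3  # sampled wave, SI

    nrec = len(c["rec_names"])
    recP = np.empty((nrec, nsteps))
    recQ = np.empty((nrec, nsteps))
    qin_rec = np.empty(nsteps)
    qterm_rec = np.empty((len(c["term_names"]), nsteps))
    vol_rec = np.empty(nsteps)

    n_beats, resid, converged, cfl_seg, vol0 = _run(
        A, Q, c["aref"], c["dcoef"], c["kc"],
        c["seg_start"], c["seg_n"], c["seg_dx"],
        c["jn_pnode"], c["jn_c1"], c["jn_c2"],
        c["term_node"], c["term_zc"], c["term_rp"], c["term_cc"], pc,
        c["rec_idx"], c["volw"], wq, inflow.t_period, dt, nsteps,
        config.max_beats, config.conv_tol, c["rho"], kf, pref, pv,
        0.0, recP, recQ, qin_rec, qterm_rec, vol_rec)

    if cfl_seg == -2 or not np.isfinite(recP).all():
        raise SolverError("solution diverged (non-finite pressures)")
    if cfl_seg >= 0:
        raise SolverError(
            f"CFL condition violated in segment {c['order'][cfl_seg]!r}")

    t_axis = (np.arange(nsteps) + 1) * dt
    pressures = {nm: recP[i] / MMHG_TO_PA for i, nm in enumerate(c["rec_names"])}
    flows = {nm: recQ[i] / ML_TO_M3 for i, nm in enumerate(c["rec_names"])}
    return PressureFlowField(
        t=t_axis, dt=dt, pressures=pressures, flows=flows,
        inflow=qin_rec / ML_TO_M3,
        terminal_flows={nm: qterm_rec[k] / ML_TO_M3
                        for k, nm in enumerate(c["term_names"])},
        volume=vol_rec / ML_TO_M3, volume_start=vol0 / ML_TO_M3,
        n_beats_run=int(n_beats), periodicity_residual=float(resid),
        converged=bool(converged),
        site_positions_m=c["site_positions"],
        meta={"nsteps_per_beat": nsteps},
    )
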