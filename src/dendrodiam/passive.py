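"""Passive compartmental simulation of a morphology.

Each SWC segment (parent -> node frustum) becomes one compartment; the soma
becomes a single sphere-equivalent compartment.  Membrane conductance and
capacitance come from the frustum's lateral surface area,

    area = pi (r1 + r2) sqrt(L^2 + (r2 - r1)^2),

and the axial resistance of a linearly tapering frustum uses the exact
integral form,

    R_axial = RA * L / (pi r1 r2).

Compartments couple through half-resistances (centre-to-centre), the soma
being isopotential with zero internal resistance.  Integration is backward
Euler (unconditionally stable on stiff trees) with a sparse LU factorization
of the constant-coefficient system; time-varying synaptic conductances are
folded in with a Sherman-Morrison rank-one update, so the factorization is
done once per simulation.

Units: micrometres / ms / mV / nA / pS at every interface, SI internally
(m, s, V, A, S, F).  Conversion table: 1 um = 1e-6 m; 1 ms = 1e-3 s;
1 mV = 1e-3 V; 1 nA = 1e-9 A; 1 pS = 1e-12 S; membrane parameters RM in
Ohm m^2, CM in F/m^2, RA in Ohm m.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .swc import Morphology, SWCStructureError

__all__ = [
    "PassiveParams",
    "CompartmentalModel",
    "StimulusProtocol",
    "ResponseMetrics",
    "build_compartments",
    "simulate",
    "fit_double_exponential",
    "steady_state_deflection",
    "synaptic_response",
    "normalized_difference",
    "response_metrics",
]

UM = 1e-6   # m per um
MS = 1e-3   # s per ms
MV = 1e-3   # V per mV
NA = 1e-9   # A per nA
PS_ = 1e-12  # S per pS


@dataclass(frozen=True)
class PassiveParams:
    """Specific membrane/cytosolic parameters (SI units)."""

    RM: float = 1.6       # Ohm m^2
    CM: float = 0.0186    # F / m^2
    RA: float = 1.98      # Ohm m
    Em: float = -65.0     # mV (resting potential; interfaces use mV)

    def __post_init__(self):
        if self.RM <= 0 or self.CM <= 0 or self.RA <= 0:
            raise ValueError("RM, CM, RA must all be positive")
        if not math.isfinite(self.Em):
            raise ValueError("Em must be finite")

    @property
    def tau_membrane_ms(self) -> float:
        """Isopotential membrane time constant RM*CM, in ms."""
        return self.RM * self.CM / MS


@dataclass
class CompartmentalModel:
    """Passive electrical tree: one soma compartment + one per segment."""

    g_m: np.ndarray          # membrane conductance per compartment, S
    c_m: np.ndarray          # membrane capacitance per compartment, F
    parent: np.ndarray       # parent compartment index (-1 for soma)
    g_axial: np.ndarray      # coupling conductance to parent, S (0 for soma)
    node_of: dict            # SWC node id -> compartment index
    areas: np.ndarray        # membrane areas, m^2
    params: PassiveParams = field(default_factory=PassiveParams)

    @property
    def n(self) -> int:
        return self.g_m.size

    def compartment_of(self, node_id: int) -> int:
        return self.node_of[node_id]

    def total_area(self) -> float:
        return float(self.areas.sum())

    def system_matrices(self):
        """(G, C) with G = diag(g_m) + axial graph Laplacian, C = diag(c_m)."""
        n = self.n
        rows, cols, vals = [], [], []
        diag = self.g_m.copy()
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                g = self.g_axial[i]
                diag[i] += g
                diag[p] += g
                rows += [i, p]
                cols += [p, i]
                vals += [-g, -g]
        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        G = csc_matrix((vals, (rows, cols)), shape=(n, n))
        return G, self.c_m


def _frustum_area_m2(r1_um: float, r2_um: float, L_um: float) -> float:
    slant = math.hypot(L_um, r2_um - r1_um)
    return math.pi * (r1_um + r2_um) * slant * UM * UM


def build_compartments(m: Morphology, p: PassiveParams) -> CompartmentalModel:
    """Discretize a (soma-normalized) morphology into a passive tree.

    Zero-length segments are merged into their parent compartment with a
    warning.  The soma is one isopotential sphere-equivalent compartment
    whose area matches the normalized soma (4 pi r^2).
    """
    soma = m.soma_nodes
    if not soma:
        raise SWCStructureError("no soma to build a soma compartment from")
    soma_r = m.soma_root.radius
    soma_area = 4.0 * math.pi * (soma_r * UM) ** 2

    g_m = [soma_area / p.RM]
    c_m = [soma_area * p.CM]
    parent = [-1]
    half_r = [0.0]  # centre-to-end axial resistance, Ohm (soma isopotential)
    areas = [soma_area]
    node_of: dict[int, int] = {n.node_id: 0 for n in soma}

    order = [n for n in m.nodes if n.type_code != 1]
    # ensure parents come first (SWC order may be shuffled)
    placed = set(node_of)
    pending = list(order)
    guard = 0
    while pending:
        rest = []
        for n in pending:
            if n.parent_id in placed or n.parent_id == -1:
                if n.parent_id == -1:
                    raise SWCStructureError("non-soma root in morphology")
                pn = m.node(n.parent_id)
                L = n.distance_to(pn)
                if L == 0.0:
                    _warnings.warn(
                        f"zero-length segment at node {n.node_id}; merged into parent"
                    )
                    node_of[n.node_id] = node_of[n.parent_id]
                    placed.add(n.node_id)
                    continue
                r2 = n.radius
                r1 = pn.radius if pn.type_code != 1 else n.radius
                area = _frustum_area_m2(r1, r2, L)
                idx = len(g_m)
                g_m.append(area / p.RM)
                c_m.append(area * p.CM)
                parent.append(node_of[n.parent_id])
                r_ax = p.RA * (L * UM) / (math.pi * (r1 * UM) * (r2 * UM))
                half_r.append(r_ax / 2.0)
                areas.append(area)
                node_of[n.node_id] = idx
                placed.add(n.node_id)
            else:
                rest.append(n)
        if len(rest) == len(pending):
            guard += 1
            if guard > 1:
                raise SWCStructureError("unresolvable parent ordering")
        pending = rest

    n_comp = len(g_m)
    g_ax = np.zeros(n_comp)
    for i in range(1, n_comp):
        g_ax[i] = 1.0 / (half_r[i] + half_r[parent[i]])
    model = CompartmentalModel(
        g_m=np.array(g_m), c_m=np.array(c_m),
        parent=np.array(parent, dtype=int), g_axial=g_ax,
        node_of=node_of, areas=np.array(areas), params=p,
    )
    return model


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic/dendritic stimulus: a current step or a dual-exponential synapse.

    ``site`` is a compartment index (use ``model.compartment_of(node_id)``).
    Current: amplitude in nA over [onset, onset+duration] ms.  Synaptic:
    peak conductance gmax in pS, rise/decay time constants in ms, reversal in
    mV; the conductance waveform is normalized so its peak equals gmax.
    """

    kind: str                      # 'current_step' | 'synaptic'
    site: int = 0
    amplitude_nA: float = 0.0
    duration_ms: float = 1.0
    onset_ms: float = 0.0
    gmax_pS: float = 0.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 5.0
    e_rev_mV: float = 5.0

    def __post_init__(self):
        if self.kind not in ("current_step", "synaptic"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "current_step" and self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "synaptic" and not self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("synaptic rise time must be below decay time")


def _syn_conductance_S(stim: StimulusProtocol, t_ms: np.ndarray) -> np.ndarray:
    """Dual-exponential conductance, peak-normalized to gmax."""
    tr, td = stim.tau_rise_ms, stim.tau_decay_ms
    tp = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-tp / td) - math.exp(-tp / tr)
    t = np.maximum(t_ms - stim.onset_ms, 0.0)
    g = (np.exp(-t / td) - np.exp(-t / tr)) / norm
    g[t_ms < stim.onset_ms] = 0.0
    return stim.gmax_pS * PS_ * g


@dataclass
class SimResult:
    t_ms: np.ndarray
    v_mV: dict  # compartment index -> voltage trace, mV


def simulate(
    model: CompartmentalModel,
    stim: StimulusProtocol,
    dt: float = 0.01,
    t_end: float = 100.0,
    record=(0,),
) -> SimResult:
    """Backward-Euler integration of the passive tree from rest (Em).

    ``dt`` and ``t_end`` in ms; ``record`` lists compartment indices whose
    voltage traces (mV) are returned.
    """
    p = model.params
    G, c = model.system_matrices()
    n = model.n
    dt_s = dt * MS
    A = (csc_matrix((c / dt_s, (range(n), range(n))), shape=(n, n)) + G).tocsc()
    lu = splu(A)

    steps = int(round(t_end / dt))
    t_ms = np.arange(steps + 1) * dt
    Em_V = p.Em * MV
    v = np.full(n, Em_V)
    leak = model.g_m * Em_V

    record = tuple(record)
    out = {i: np.empty(steps + 1) for i in record}
    for i in record:
        out[i][0] = v[i]

    if stim.kind == "synaptic":
        g_t = _syn_conductance_S(stim, t_ms)
        e_rev_V = stim.e_rev_mV * MV
        site = stim.site
        e_site = np.zeros(n)
        e_site[site] = 1.0
        z = lu.solve(e_site)  # for Sherman-Morrison
    else:
        i_amp = stim.amplitude_nA * NA
        on, off = stim.onset_ms, stim.onset_ms + stim.duration_ms

    b = np.empty(n)
    for k in range(1, steps + 1):
        t_new = t_ms[k]
        np.multiply(c / dt_s, v, out=b)
        b += leak
        if stim.kind == "current_step":
            if on < t_new <= off + 1e-12:
                b[stim.site] += i_amp
            v = lu.solve(b)
        else:
            g = g_t[k]
            b[site] += g * e_rev_V
            y = lu.solve(b)
            if g != 0.0:
                v = y - (g * y[site] / (1.0 + g * z[site])) * z
            else:
                v = y
        if not np.all(np.isfinite(v)):
            raise ArithmeticError(f"solver divergence at t={t_new} ms")
        for i in record:
            out[i][k] = v[i]
    return SimResult(t_ms, {i: trace / MV for i, trace in out.items()})


@dataclass
class DoubleExpFit:
    tau1: float  # slower, ms
    tau2: float  # faster, ms
    A1: float
    A2: float
    v_inf: float
    degenerate: bool = False  # effectively single-exponential


def fit_double_exponential(t_ms, v_mV, window=None) -> DoubleExpFit:
    """Fit A1 e^{-t/tau1} + A2 e^{-t/tau2} + V_inf to a decaying transient.

    ``window`` is an (start_ms, end_ms) restriction; the fit is initialized
    by log-linear peeling (slow tail first, fast residual second).  Returns
    tau1 >= tau2; flags a degenerate (single-exponential) result instead of
    failing.
    """
    t = np.asarray(t_ms, float)
    v = np.asarray(v_mV, float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if t.size < 10:
        raise ValueError("too few samples in fit window")
    t = t - t[0]
    v_inf0 = v[-1]
    amp = v - v_inf0
    sign = 1.0 if amp[0] >= 0 else -1.0
    amp = amp * sign
    if amp[0] <= 0 or np.max(amp) <= 1e-12:
        raise ValueError("window does not contain a decaying transient")

    # peel: slow component from the tail
    tail = slice(t.size // 2, None)
    pos = amp[tail] > amp[0] * 1e-6
    if pos.sum() >= 2:
        s, b0 = np.polyfit(t[tail][pos], np.log(amp[tail][pos]), 1)
        tau_slow = -1.0 / s if s < 0 else (t[-1] - t[0])
        a_slow = math.exp(b0)
    else:
        tau_slow, a_slow = (t[-1] - t[0]) / 3, amp[0] / 2
    tau_slow = float(np.clip(tau_slow, 1e-3, 10 * (t[-1] + 1e-9)))
    resid = amp - a_slow * np.exp(-t / tau_slow)
    head = resid[: max(5, t.size // 10)]
    tau_fast = max(tau_slow / 10, 1e-3)
    a_fast = max(float(head[0]), amp[0] * 0.05)

    def f(tt, a1, tau1, a2, tau2, vinf):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2) + vinf

    p0 = [a_slow, tau_slow, a_fast, tau_fast, 0.0]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            f, t, amp, p0=p0,
            bounds=([0, 1e-4, 0, 1e-4, -np.inf], [np.inf] * 4 + [np.inf]),
            maxfev=40000,
        )
    a1, tau1, a2, tau2, vinf = popt
    if tau2 > tau1:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    total = a1 + a2
    degenerate = bool(
        total > 0 and (a2 < 1e-3 * total or abs(tau1 - tau2) < 0.01 * tau1)
    )
    return DoubleExpFit(
        tau1=float(tau1), tau2=float(tau2),
        A1=float(sign * a1), A2=float(sign * a2),
        v_inf=float(sign * vinf + v_inf0), degenerate=degenerate,
    )


def steady_state_deflection(
    t_ms, v_mV, baseline_window, plateau_window, dvdt_tol: float = 1e-4
) -> float:
    """mean(plateau) - mean(baseline), in mV; warns if the plateau drifts.

    ``dvdt_tol`` is the allowed |dV/dt| (mV/ms) inside the plateau window.
    """
    t = np.asarray(t_ms, float)
    v = np.asarray(v_mV, float)
    base = v[(t >= baseline_window[0]) & (t <= baseline_window[1])]
    plat_sel = (t >= plateau_window[0]) & (t <= plateau_window[1])
    plat = v[plat_sel]
    if base.size == 0 or plat.size < 2:
        raise ValueError("empty baseline or plateau window")
    dvdt = np.gradient(plat, t[plat_sel])
    if np.max(np.abs(dvdt)) > dvdt_tol:
        _warnings.warn(
            "plateau not fully reached; steady-state estimate may be low"
        )
    return float(plat.mean() - base.mean())


def synaptic_response(
    model: CompartmentalModel,
    syn: StimulusProtocol,
    record_soma: int = 0,
    dt: float = 0.01,
    t_end: float = 60.0,
) -> dict:
    """Peak depolarization (mV above rest) at the input site and the soma."""
    res = simulate(model, syn, dt=dt, t_end=t_end,
                   record=(syn.site, record_soma))
    Em = model.params.Em
    if syn.e_rev_mV < Em:
        _warnings.warn(
            "synaptic reversal below rest: response will be hyperpolarizing"
        )
    return {
        "dendrite_peak_mV": float(np.max(res.v_mV[syn.site]) - Em),
        "soma_peak_mV": float(np.max(res.v_mV[record_soma]) - Em),
    }


@dataclass(frozen=True)
class ResponseMetrics:
    """Passive response summary: double-exponential time constants from a
    brief pulse, steady-state deflection from a prolonged step, and optional
    synaptic peaks."""

    tau1: float            # ms, slower
    tau2: float            # ms, faster
    deltaV: float          # mV
    syn_peak_dendrite: float | None = None
    syn_peak_soma: float | None = None

    def as_dict(self) -> dict:
        d = {"tau1": self.tau1, "tau2": self.tau2, "deltaV": self.deltaV}
        if self.syn_peak_dendrite is not None:
            d["syn_peak_dendrite"] = self.syn_peak_dendrite
        if self.syn_peak_soma is not None:
            d["syn_peak_soma"] = self.syn_peak_soma
        return d


def normalized_difference(pred: ResponseMetrics, orig: ResponseMetrics) -> dict:
    """|pred - orig| / |orig| per metric; identical metrics give 0."""
    out = {}
    for key, o in orig.as_dict().items():
        pv = pred.as_dict().get(key)
        if pv is None:
            continue
        if o == 0:
            raise ZeroDivisionError(f"original metric {key} is zero")
        out[key] = abs(pv - o) / abs(o)
    return out


def response_metrics(
    m: Morphology,
    params: PassiveParams,
    dt: float = 0.01,
    brief=(1.0, 1.5),          # (duration ms, amplitude nA)
    prolonged=(800.0, 0.03),   # (duration ms, amplitude nA) -- 30 pA
    fit_t_end: float = 150.0,
    synapse_node: int | None = None,
) -> ResponseMetrics:
    """Run the standard protocols on a morphology and summarize the response.

    The brief somatic pulse yields tau1/tau2 (double-exponential fit of the
    decay starting 0.2 ms after offset); the prolonged step yields deltaV.
    With ``synapse_node`` set (an SWC node id), a dual-exponential synaptic
    conductance is delivered there and the dendritic/somatic peaks recorded.
    """
    from .swc import normalize_soma

    mn = normalize_soma(m, "three_point")
    model = build_compartments(mn, params)

    onset = 1.0
    dur, amp = brief
    stim = StimulusProtocol("current_step", site=0, amplitude_nA=amp,
                            duration_ms=dur, onset_ms=onset)
    res = simulate(model, stim, dt=dt, t_end=fit_t_end, record=(0,))
    fit = fit_double_exponential(
        res.t_ms, res.v_mV[0], window=(onset + dur + 0.2, fit_t_end)
    )

    dur_l, amp_l = prolonged
    baseline = 5.0
    stim_l = StimulusProtocol("current_step", site=0, amplitude_nA=amp_l,
                              duration_ms=dur_l, onset_ms=baseline)
    dt_long = max(dt, 0.025)
    res_l = simulate(model, stim_l, dt=dt_long,
                     t_end=baseline + dur_l, record=(0,))
    dv = steady_state_deflection(
        res_l.t_ms, res_l.v_mV[0],
        baseline_window=(0.0, baseline - 1.0),
        plateau_window=(baseline + 0.75 * dur_l, baseline + dur_l - 1.0),
    )

    syn_d = syn_s = None
    if synapse_node is not None:
        site = model.compartment_of(synapse_node)
        syn = StimulusProtocol("synaptic", site=site, gmax_pS=10.0,
                               tau_rise_ms=1.0, tau_decay_ms=5.0,
                               e_rev_mV=5.0, onset_ms=1.0)
        peaks = synaptic_response(model, syn, dt=dt)
        syn_d, syn_s = peaks["dendrite_peak_mV"], peaks["soma_peak_mV"]
    return ResponseMetrics(fit.tau1, fit.tau2, dv, syn_d, syn_s)
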