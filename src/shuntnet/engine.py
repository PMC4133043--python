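"""Vectorized network integrator.

A single numba kernel advances the whole two-layer network (layer-one
excitatory ring, layer-one inhibitory cells, layer-two excitatory cells) with
a fixed-step RK4 scheme.  Gating-rate functions are evaluated through lookup
tables built from :mod:`shuntnet.core_dynamics`, so the kernel and the
reference single-neuron implementation share one set of kinetics.

Synaptic conductances are computed from the outgoing gating variables at the
start of each step and decay analytically (factor ``exp(-theta/tau)``) inside
the RK4 substeps; spike increments are applied at step boundaries.  Both
plasticity rules are integrated online (forward Euler on a configurable
stride) when enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from shuntnet.core_dynamics import (
    NeuronParams,
    SynapseParams,
    IntegrationDivergedError,
    alpha_m,
    beta_m,
    alpha_h,
    beta_h,
    alpha_n,
    beta_n,
    mca_inf,
    resting_state,
)

__all__ = ["Simulator", "RunRecord", "build_rate_tables"]

# voltage grid of the rate-function lookup tables
_TAB_VMIN = -130.0
_TAB_VMAX = 70.0
_TAB_STEP = 0.01

# scalar-parameter packing for the kernel
_P_GL_E, _P_GL_I, _P_GNA, _P_GK, _P_GCA, _P_GAHP = 0, 1, 2, 3, 4, 5
_P_VL, _P_VNA, _P_VK, _P_VCA = 6, 7, 8, 9
_P_TAUCA, _P_CAGAIN = 10, 11
_P_TAU_AMPA, _P_TAU_GABA, _P_VIE = 12, 13, 14
_P_FBG_E, _P_FBG_I = 15, 16
_P_FE, _P_FI = 17, 18
_NPAR = 19

# plasticity-parameter packing
_Q_ON, _Q_HEBB, _Q_FFMAX, _Q_FB, _Q_FBMAX, _Q_CA0, _Q_GATE = 0, 1, 2, 3, 4, 5, 6
_NQ = 7


def build_rate_tables() -> np.ndarray:
    """(7, N) table of alpha/beta rates and calcium activation vs voltage."""
    v = np.arange(_TAB_VMIN, _TAB_VMAX + _TAB_STEP / 2, _TAB_STEP)
    return np.ascontiguousarray(
        np.vstack(
            [alpha_m(v), beta_m(v), alpha_h(v), beta_h(v), alpha_n(v), beta_n(v), mca_inf(v)]
        )
    )


_RATE_TABLES: np.ndarray | None = None


def _rate_tables() -> np.ndarray:
    global _RATE_TABLES
    if _RATE_TABLES is None:
        _RATE_TABLES = build_rate_tables()
    return _RATE_TABLES


@njit(cache=True, inline="always")
def _deriv(v, m, h, n, ca, ge, gi, i_ext, gl, gahp, par, tab):
    # table lookup with linear interpolation
    x = (v - _TAB_VMIN) * (1.0 / _TAB_STEP)
    if x < 0.0:
        x = 0.0
    nmax = tab.shape[1] - 2
    if x > nmax:
        x = float(nmax)
    i = int(x)
    f = x - i
    am = tab[0, i] + (tab[0, i + 1] - tab[0, i]) * f
    bm = tab[1, i] + (tab[1, i + 1] - tab[1, i]) * f
    ah = tab[2, i] + (tab[2, i + 1] - tab[2, i]) * f
    bh = tab[3, i] + (tab[3, i + 1] - tab[3, i]) * f
    an = tab[4, i] + (tab[4, i + 1] - tab[4, i]) * f
    bn = tab[5, i] + (tab[5, i + 1] - tab[5, i]) * f
    mca = tab[6, i] + (tab[6, i + 1] - tab[6, i]) * f

    i_leak = gl * (v - par[_P_VL])
    i_na = par[_P_GNA] * m * m * m * h * (v - par[_P_VNA])
    i_k = par[_P_GK] * n * n * n * n * (v - par[_P_VK])
    i_ca = par[_P_GCA] * mca * (v - par[_P_VCA])
    i_ahp = gahp * ca * (v - par[_P_VK])
    i_syn = -par[_P_FE] * ge * (v - 0.0) - par[_P_FI] * gi * (v - par[_P_VIE])
    dv = -(i_leak + i_na + i_k + i_ca + i_ahp) + i_syn + i_ext
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    dca = -par[_P_CAGAIN] * i_ca - ca / par[_P_TAUCA]
    return dv, dm, dh, dn, dca


@njit(cache=True, inline="always")
def _rk4_group(v, m, h, n, ca, ge, gi, i_ext, gl, gahp, par, tab, dt, de_h, de_f, di_h, di_f):
    for k in range(v.shape[0]):
        vv, mm, hh, nn, cc = v[k], m[k], h[k], n[k], ca[k]
        g1e, g1i = ge[k], gi[k]
        d1 = _deriv(vv, mm, hh, nn, cc, g1e, g1i, i_ext[k], gl, gahp, par, tab)
        d2 = _deriv(
            vv + 0.5 * dt * d1[0], mm + 0.5 * dt * d1[1], hh + 0.5 * dt * d1[2],
            nn + 0.5 * dt * d1[3], cc + 0.5 * dt * d1[4],
            g1e * de_h, g1i * di_h, i_ext[k], gl, gahp, par, tab,
        )
        d3 = _deriv(
            vv + 0.5 * dt * d2[0], mm + 0.5 * dt * d2[1], hh + 0.5 * dt * d2[2],
            nn + 0.5 * dt * d2[3], cc + 0.5 * dt * d2[4],
            g1e * de_h, g1i * di_h, i_ext[k], gl, gahp, par, tab,
        )
        d4 = _deriv(
            vv + dt * d3[0], mm + dt * d3[1], hh + dt * d3[2],
            nn + dt * d3[3], cc + dt * d3[4],
            g1e * de_f, g1i * di_f, i_ext[k], gl, gahp, par, tab,
        )
        v[k] = vv + dt / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        mx = mm + dt / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        hx = hh + dt / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        nx = nn + dt / 6.0 * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])
        m[k] = min(max(mx, 0.0), 1.0)
        h[k] = min(max(hx, 0.0), 1.0)
        n[k] = min(max(nx, 0.0), 1.0)
        cx = cc + dt / 6.0 * (d1[4] + 2 * d2[4] + 2 * d3[4] + d4[4])
        ca[k] = cx if cx > 0.0 else 0.0


@njit(cache=True, inline="always")
def _detect_spikes(v, v_prev, last, s_out, spk_t, spk_c, t):
    for k in range(v.shape[0]):
        if v_prev[k] < 0.0 <= v[k] and t - last[k] >= 2.0:
            last[k] = t
            s_out[k] += 1.0
            c = spk_c[k]
            if c < spk_t.shape[1]:
                spk_t[k, c] = t
                spk_c[k] = c + 1


@njit(cache=True)
def _run_kernel(
    n_steps, dt, t0, ramp_steps, bg_e, bg_i, par, tab,
    w_ee, w_ei, w_ie, w_ii, w_ff, w_fb,
    i_ext_e, i_ext_i, i_ext_v2,
    v_e, m_e, h_e, n_e, ca_e,
    v_i, m_i, h_i, n_i, ca_i,
    v_2, m_2, h_2, n_2, ca_2,
    s_e, s_i, s_2, last_e, last_i, last_2,
    qpar, ff_mask, plast_stride,
    rec_stride, mon_g,
    spk_t_e, spk_c_e, spk_t_i, spk_c_i, spk_t_2, spk_c_2,
    v_rec_e, v_rec_i, v_rec_2,
    g_rec, ca2_rec, fb_rec, t_rec,
):
    ne = v_e.shape[0]
    ni = v_i.shape[0]
    nv = v_2.shape[0]
    de_f = np.exp(-dt / par[_P_TAU_AMPA])
    di_f = np.exp(-dt / par[_P_TAU_GABA])
    de_h = np.exp(-0.5 * dt / par[_P_TAU_AMPA])
    di_h = np.exp(-0.5 * dt / par[_P_TAU_GABA])
    zeros_2 = np.zeros(nv)
    vp_e = np.empty(ne)
    vp_i = np.empty(ni)
    vp_2 = np.empty(nv)
    rec_row = 0
    plast_on = qpar[_Q_ON] > 0.5

    for step in range(n_steps):
        t = t0 + step * dt

        # recording (at step start so row 0 is the initial condition)
        if rec_stride > 0 and step % rec_stride == 0:
            t_rec[rec_row] = t
            fbg = 0.0
            for q in range(nv):
                fbg += w_fb[q] * s_2[q]
            fb_rec[rec_row] = fbg
            for q in range(v_rec_e.shape[1]):
                v_rec_e[rec_row, q] = v_e[q]
            for q in range(v_rec_i.shape[1]):
                v_rec_i[rec_row, q] = v_i[q]
            for q in range(v_rec_2.shape[1]):
                v_rec_2[rec_row, q] = v_2[q]
            for q in range(mon_g.shape[0]):
                tgt = mon_g[q]
                grec = 0.0
                for src in range(ne):
                    grec += w_ee[src, tgt] * s_e[src]
                gin = 0.0
                for src in range(ni):
                    gin += w_ie[src, tgt] * s_i[src]
                g_rec[rec_row, q, 0] = grec
                g_rec[rec_row, q, 1] = par[_P_FBG_E] * fbg
                g_rec[rec_row, q, 2] = gin
            for q in range(ca2_rec.shape[1]):
                ca2_rec[rec_row, q] = ca_2[q]
            rec_row += 1

        # stimulus onset ramp
        if ramp_steps > 0 and step < ramp_steps:
            ramp = (step + 1.0) / ramp_steps
        else:
            ramp = 1.0

        # synaptic conductances at step start
        fb_drive = 0.0
        for q in range(nv):
            fb_drive += w_fb[q] * s_2[q]
        ge_e = s_e @ w_ee
        gi_e = s_i @ w_ie
        ge_i = s_e @ w_ei
        gi_i = s_i @ w_ii
        ge_2 = s_e @ w_ff
        for k in range(ne):
            ge_e[k] += par[_P_FBG_E] * fb_drive
        for k in range(ni):
            ge_i[k] += par[_P_FBG_I] * fb_drive

        for k in range(ne):
            vp_e[k] = v_e[k]
        for k in range(ni):
            vp_i[k] = v_i[k]
        for k in range(nv):
            vp_2[k] = v_2[k]

        if ramp < 1.0:
            ie_e = i_ext_e * ramp + bg_e
            ie_i = i_ext_i * ramp + bg_i
            ie_2 = i_ext_v2 * ramp
        else:
            ie_e = i_ext_e + bg_e
            ie_i = i_ext_i + bg_i
            ie_2 = i_ext_v2
        _rk4_group(v_e, m_e, h_e, n_e, ca_e, ge_e, gi_e, ie_e,
                   par[_P_GL_E], par[_P_GAHP], par, tab, dt, de_h, de_f, di_h, di_f)
        _rk4_group(v_i, m_i, h_i, n_i, ca_i, ge_i, gi_i, ie_i,
                   par[_P_GL_I], 0.0, par, tab, dt, de_h, de_f, di_h, di_f)
        _rk4_group(v_2, m_2, h_2, n_2, ca_2, ge_2, zeros_2, ie_2,
                   par[_P_GL_E], par[_P_GAHP], par, tab, dt, de_h, de_f, di_h, di_f)

        # synaptic gating: decay then spike increments
        for k in range(ne):
            s_e[k] *= de_f
        for k in range(ni):
            s_i[k] *= di_f
        for k in range(nv):
            s_2[k] *= de_f

        t_next = t + dt
        _detect_spikes(v_e, vp_e, last_e, s_e, spk_t_e, spk_c_e, t_next)
        _detect_spikes(v_i, vp_i, last_i, s_i, spk_t_i, spk_c_i, t_next)
        _detect_spikes(v_2, vp_2, last_2, s_2, spk_t_2, spk_c_2, t_next)

        # plasticity (forward Euler on a stride)
        if plast_on and (step + 1) % plast_stride == 0:
            dtp = dt * plast_stride
            hebb = qpar[_Q_HEBB] * dtp
            ffmax = qpar[_Q_FFMAX]
            if hebb > 0.0:
                for j in range(ne):
                    cj = ca_e[j]
                    if cj <= 0.0:
                        continue
                    for i2 in range(nv):
                        if ff_mask[j, i2]:
                            w = w_ff[j, i2] + hebb * cj * ca_2[i2]
                            w_ff[j, i2] = w if w < ffmax else ffmax
            fbr = qpar[_Q_FB] * dtp
            if fbr != 0.0:
                fbmax = qpar[_Q_FBMAX]
                ca0 = qpar[_Q_CA0]
                gate = qpar[_Q_GATE]
                for i2 in range(nv):
                    if ca_2[i2] > gate:
                        w = w_fb[i2] + fbr * (ca_2[i2] - ca0)
                        if w < 0.0:
                            w = 0.0
                        elif w > fbmax:
                            w = fbmax
                        w_fb[i2] = w

        # divergence guard
        for k in range(ne):
            if not (-200.0 < v_e[k] < 200.0):
                return step
        for k in range(ni):
            if not (-200.0 < v_i[k] < 200.0):
                return step
        for k in range(nv):
            if not (-200.0 < v_2[k] < 200.0):
                return step
    return -1


@dataclass
class RunRecord:
    """Raw output of one :meth:`Simulator.run` segment (times in ms, absolute)."""

    t0: float
    duration: float
    dt: float
    spikes_v1e: list = field(default_factory=list)
    spikes_v1i: list = field(default_factory=list)
    spikes_v2: list = field(default_factory=list)
    times: np.ndarray | None = None
    v_v1e: np.ndarray | None = None  # (T, n recorded) leading neurons per population
    v_v1i: np.ndarray | None = None
    v_v2: np.ndarray | None = None
    g_monitored: dict | None = None  # v1e index -> (T, 3): recurrent-exc, fb-exc, inh conductance
    ca_v2: np.ndarray | None = None  # (T, n_v2)
    fb_drive: np.ndarray | None = None  # (T,) sum_i w_fb[i] * s_2[i]

    def rates(self, population: str, t_start: float, t_stop: float) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over the absolute window [t_start, t_stop)."""
        spikes = {"v1e": self.spikes_v1e, "v1i": self.spikes_v1i, "v2": self.spikes_v2}[
            population
        ]
        out = np.empty(len(spikes))
        for k, st in enumerate(spikes):
            out[k] = np.count_nonzero((st >= t_start) & (st < t_stop))
        return out * 1000.0 / (t_stop - t_start)


class Simulator:
    """Stateful integrator for one network instance.

    Holds the weight matrices (mutated in place by plasticity) and the full
    dynamic state; successive :meth:`run` calls continue in time until
    :meth:`reset` re-initializes every neuron at its quiescent point.
    """

    def __init__(
        self,
        architecture,
        neuron_e: NeuronParams | None = None,
        neuron_i: NeuronParams | None = None,
        synapse: SynapseParams | None = None,
        dt: float = 0.025,
    ):
        self.arch = architecture
        self.neuron_e = neuron_e or NeuronParams.excitatory()
        self.neuron_i = neuron_i or NeuronParams.inhibitory()
        self.synapse = synapse or SynapseParams()
        self.dt = float(dt)
        self.tab = _rate_tables()
        ne = architecture.n_v1_excitatory
        ni = architecture.n_v1_inhibitory
        nv = architecture.n_v2_excitatory
        self.ne, self.ni, self.nv = ne, ni, nv
        self._rest_e = resting_state(self.neuron_e)
        self._rest_i = resting_state(self.neuron_i)
        cfg = getattr(architecture, "config", None)
        self.bg_e = float(getattr(cfg, "background_current_e", 0.0) or 0.0)
        self.bg_i = float(getattr(cfg, "background_current_i", 0.0) or 0.0)
        self.par = self._pack_params()
        self.t = 0.0
        self.reset()

    @property
    def resting_potential_e(self) -> float:
        return self._rest_e.membrane_potential

    def _pack_params(self) -> np.ndarray:
        p = np.zeros(_NPAR)
        e, i, s = self.neuron_e, self.neuron_i, self.synapse
        p[_P_GL_E] = e.leak_conductance
        p[_P_GL_I] = i.leak_conductance
        p[_P_GNA] = e.sodium_conductance
        p[_P_GK] = e.potassium_conductance
        p[_P_GCA] = e.calcium_conductance
        p[_P_GAHP] = e.ahp_conductance if e.has_ahp else 0.0
        p[_P_VL] = e.leak_reversal
        p[_P_VNA] = e.sodium_reversal
        p[_P_VK] = e.potassium_reversal
        p[_P_VCA] = e.calcium_reversal
        p[_P_TAUCA] = e.calcium_time_constant
        p[_P_CAGAIN] = e.calcium_influx_gain
        p[_P_TAU_AMPA] = s.ampa_time_constant
        p[_P_TAU_GABA] = s.gabaa_time_constant
        p[_P_VIE] = s.inhibitory_reversal
        p[_P_FBG_E] = self.arch.feedback_gain_e
        p[_P_FBG_I] = self.arch.feedback_gain_i
        p[_P_FE] = 1.0
        p[_P_FI] = 1.0
        return p

    def refresh_params(self) -> None:
        """Re-pack scalar parameters after mutating the architecture gains."""
        self.par = self._pack_params()

    def reset(self) -> None:
        """Return every neuron to rest and clear synaptic gating and calcium."""
        ne, ni, nv = self.ne, self.ni, self.nv
        re_, ri_ = self._rest_e, self._rest_i
        self.v_e = np.full(ne, re_.membrane_potential)
        self.m_e = np.full(ne, re_.gating_m)
        self.h_e = np.full(ne, re_.gating_h)
        self.n_e = np.full(ne, re_.gating_n)
        self.ca_e = np.zeros(ne)
        self.v_i = np.full(ni, ri_.membrane_potential)
        self.m_i = np.full(ni, ri_.gating_m)
        self.h_i = np.full(ni, ri_.gating_h)
        self.n_i = np.full(ni, ri_.gating_n)
        self.ca_i = np.zeros(ni)
        self.v_2 = np.full(nv, re_.membrane_potential)
        self.m_2 = np.full(nv, re_.gating_m)
        self.h_2 = np.full(nv, re_.gating_h)
        self.n_2 = np.full(nv, re_.gating_n)
        self.ca_2 = np.zeros(nv)
        self.s_e = np.zeros(ne)
        self.s_i = np.zeros(ni)
        self.s_2 = np.zeros(nv)
        self.last_e = np.full(ne, -1e9)
        self.last_i = np.full(ni, -1e9)
        self.last_2 = np.full(nv, -1e9)
        self.t = 0.0

    def run(
        self,
        duration: float,
        i_ext_e: np.ndarray | None = None,
        i_ext_i: np.ndarray | None = None,
        i_ext_v2: np.ndarray | None = None,
        plasticity=None,
        calcium_target: float = 0.0,
        record: bool = True,
        record_v: int = 0,
        monitor_conductance: tuple = (),
        rec_stride: int = 20,
        ramp: float = 0.0,
    ) -> RunRecord:
        """Advance the network by ``duration`` ms with constant external drive.

        ``plasticity`` is a :class:`shuntnet.plasticity.PlasticityParams` (or
        None to freeze both rules); ``calcium_target`` is the homeostatic
        set-point used by the feedback rule.  ``ramp`` linearly ramps the
        external currents over that many milliseconds from the segment start
        (a hard current step onto a quiescent network fires a synchronized
        population burst that can tip the trained feedback loop into a
        runaway state).  ``record_v`` requests membrane
        traces of that many leading neurons per population;
        ``monitor_conductance`` lists V1 excitatory indices whose synaptic
        conductances (recurrent-excitatory, feedback-excitatory, inhibitory)
        are recorded every ``rec_stride`` steps.
        """
        a = self.arch
        n_steps = int(round(duration / self.dt))
        i_ext_e = np.zeros(self.ne) if i_ext_e is None else np.asarray(i_ext_e, float)
        i_ext_i = np.zeros(self.ni) if i_ext_i is None else np.asarray(i_ext_i, float)
        i_ext_v2 = np.zeros(self.nv) if i_ext_v2 is None else np.asarray(i_ext_v2, float)

        if (
            i_ext_e.shape != (self.ne,)
            or i_ext_i.shape != (self.ni,)
            or i_ext_v2.shape != (self.nv,)
        ):
            raise ValueError("external current vector shape mismatch")
        if not (
            np.all(np.isfinite(i_ext_e))
            and np.all(np.isfinite(i_ext_i))
            and np.all(np.isfinite(i_ext_v2))
        ):
            raise IntegrationDivergedError("non-finite external current")

        qpar = np.zeros(_NQ)
        plast_stride = 1
        if plasticity is not None:
            qpar[_Q_ON] = 1.0
            qpar[_Q_HEBB] = (
                plasticity.hebbian_rate / plasticity.hebbian_time_constant
                if plasticity.feedforward_enabled
                else 0.0
            )
            qpar[_Q_FFMAX] = plasticity.feedforward_ceiling
            qpar[_Q_FB] = (
                plasticity.feedback_rate / plasticity.feedback_time_constant
                if plasticity.feedback_enabled
                else 0.0
            )
            qpar[_Q_FBMAX] = plasticity.feedback_ceiling
            qpar[_Q_CA0] = calcium_target
            qpar[_Q_GATE] = plasticity.calcium_gate * calcium_target
            plast_stride = max(int(plasticity.update_stride), 1)

        eff_stride = rec_stride if record else 0
        n_rec = (n_steps + eff_stride - 1) // eff_stride if eff_stride > 0 else 0
        mon_g = np.asarray(monitor_conductance, dtype=np.int64).reshape(-1)
        nv_rec = min(record_v, self.ne) if record_v else 0
        ni_rec = min(record_v, self.ni) if record_v else 0
        n2_rec = min(record_v, self.nv) if record_v else 0

        max_spk = max(int(duration * 0.4) + 8, 16)
        spk_t_e = np.zeros((self.ne, max_spk))
        spk_t_i = np.zeros((self.ni, max_spk))
        spk_t_2 = np.zeros((self.nv, max_spk))
        spk_c_e = np.zeros(self.ne, np.int64)
        spk_c_i = np.zeros(self.ni, np.int64)
        spk_c_2 = np.zeros(self.nv, np.int64)
        v_rec_e = np.zeros((n_rec, nv_rec))
        v_rec_i = np.zeros((n_rec, ni_rec))
        v_rec_2 = np.zeros((n_rec, n2_rec))
        g_rec = np.zeros((n_rec, mon_g.shape[0], 3))
        ca2_rec = np.zeros((n_rec, self.nv if eff_stride else 0))
        fb_rec = np.zeros(n_rec)
        t_rec = np.zeros(n_rec)

        ramp_steps = int(round(ramp / self.dt))
        bad = _run_kernel(
            n_steps, self.dt, self.t, ramp_steps, self.bg_e, self.bg_i, self.par, self.tab,
            a.w_ee, a.w_ei, a.w_ie, a.w_ii, a.w_ff, a.w_fb,
            i_ext_e, i_ext_i, i_ext_v2,
            self.v_e, self.m_e, self.h_e, self.n_e, self.ca_e,
            self.v_i, self.m_i, self.h_i, self.n_i, self.ca_i,
            self.v_2, self.m_2, self.h_2, self.n_2, self.ca_2,
            self.s_e, self.s_i, self.s_2, self.last_e, self.last_i, self.last_2,
            qpar, a.ff_mask, plast_stride,
            eff_stride, mon_g,
            spk_t_e, spk_c_e, spk_t_i, spk_c_i, spk_t_2, spk_c_2,
            v_rec_e, v_rec_i, v_rec_2,
            g_rec, ca2_rec, fb_rec, t_rec,
        )
        if bad >= 0:
            raise IntegrationDivergedError(
                f"membrane potential diverged at t={self.t + bad * self.dt:.3f} ms"
            )

        rec = RunRecord(
            t0=self.t,
            duration=duration,
            dt=self.dt,
            spikes_v1e=[spk_t_e[k, : spk_c_e[k]].copy() for k in range(self.ne)],
            spikes_v1i=[spk_t_i[k, : spk_c_i[k]].copy() for k in range(self.ni)],
            spikes_v2=[spk_t_2[k, : spk_c_2[k]].copy() for k in range(self.nv)],
        )
        if eff_stride:
            rec.times = t_rec
            rec.ca_v2 = ca2_rec
            rec.fb_drive = fb_rec
            if record_v:
                rec.v_v1e = v_rec_e
                rec.v_v1i = v_rec_i
                rec.v_v2 = v_rec_2
            if mon_g.shape[0]:
                rec.g_monitored = {int(idx): g_rec[:, q, :] for q, idx in enumerate(mon_g)}
        self.t += n_steps * self.dt
        return rec
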