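"""Active membrane: T-type and L-type Ca++ channels, leak, and [Ca++]_i.

Gating follows the Hodgkin-Huxley formalism.  The T-type channel (placed on
OFF-cell terminals) carries one activation and one inactivation gate,
i = gbar * m * h * (Vm - E_eff); the L-type channel (ON-cell terminals)
carries two activation gates, i = gbar * m^2 * h * (Vm - E_eff).  Positive
current is outward.

Because intracellular Ca++ is in the sub-micromolar range, the outward limb
of the Ca++ channel current is largely carried by K+, so the effective
reversal potential is a weighted blend of the dynamically computed Ca++
Nernst potential and a fixed K+ equilibrium potential:

    E_eff = w * (RT/2F) ln([Ca]_o / [Ca]_i) + (1 - w) * E_K

Intracellular calcium integrates the channel current with a surface-to-
volume weight and relaxes back to a residual level with a 1.5 ms time
constant (see ``CalciumModel``).

All gate updates use the exact exponential step
m <- m_inf + (m - m_inf) exp(-dt/tau), which is unconditionally stable for
the stiff tau range involved (sub-microsecond L-type deactivation up to the
292 ms L-type inactivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import (
    CA_FLUX_FACTOR,
    CA_OUT_UM,
    CA_RES_UM,
    CA_TAU_MS,
    FARADAY_C_PER_MOL,
    RT_2F_MV,
    V_REST_MV,
)

__all__ = [
    "t_gate_functions",
    "l_gate_functions",
    "effective_reversal",
    "EffectiveReversal",
    "TTypeChannel",
    "LTypeChannel",
    "CalciumModel",
    "ClampProtocol",
    "run_voltage_clamp",
]


# ---------------------------------------------------------------------------
# gate rate functions
# ---------------------------------------------------------------------------

def t_gate_functions(vm):
    """T-type gating: return (m_inf, tau_m ms, h_inf, tau_h ms) at ``vm`` mV."""
    vm = np.asarray(vm, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(vm - 37.55) / 3.07))
    tau_m = 1.36 + 21.68 / (1.0 + np.exp((vm - 39.96) / 4.11))
    h_inf = 1.0 / (1.0 + np.exp((vm - 8.97) / 8.42))
    tau_h = 65.82 + 0.0023 * np.exp((vm - 80.0) / 4.78)
    return m_inf, tau_m, h_inf, tau_h


def l_gate_functions(vm):
    """L-type gating: return (alpha_m /ms, beta_m /ms, h_inf, tau_h ms).

    alpha_m has a removable singularity at vm = 63 mV; near it the analytic
    limit of x / (1 - exp(-x/10.5)) is used (series to first order).
    """
    vm = np.asarray(vm, dtype=float)
    x = vm - 63.0
    with np.errstate(over="ignore", invalid="ignore"):
        denom = 1.0 - np.exp(-x / 10.5)
        alpha = np.where(
            np.abs(x) < 1e-6,
            0.427 * (10.5 + x / 2.0),       # L'Hopital / series limit
            0.427 * x / np.where(denom == 0.0, np.nan, denom),
        )
    with np.errstate(over="ignore"):
        beta = 0.0406 * np.exp((70.0 - vm) / 12.0)
    h_inf = 1.0 / (1.0 + np.exp(vm / 66.4))
    tau_h = np.full_like(vm, 292.0)
    return alpha, np.minimum(beta, 1e12), h_inf, tau_h


def exp_gate_step(gate, gate_inf, tau, dt):
    """Exact exponential relaxation of a gate over one time step."""
    g = gate_inf + (gate - gate_inf) * np.exp(-dt / tau)
    return np.clip(g, 0.0, 1.0)


# ---------------------------------------------------------------------------
# effective reversal potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectiveReversal:
    """Blend between the Ca++ Nernst potential and a K+ equilibrium potential.

    ``weight`` = 1 reduces to the pure Nernst potential.  Defaults for the two
    channels are chosen so that simulated clamp families reverse in the range
    the channels were characterized at (T around +30 mV, L above +55 mV).
    """

    weight: float = 1.0
    e_k: float = -75.0

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")

    def __call__(self, ca_i, ca_o=CA_OUT_UM):
        return effective_reversal(ca_i, ca_o, self)


def effective_reversal(ca_i, ca_o, rev: EffectiveReversal):
    """Effective Ca-channel reversal potential in mV (25 C)."""
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ca_i <= 0) or ca_o <= 0:
        raise ValueError("concentrations must be positive")
    e_ca = RT_2F_MV * np.log(ca_o / ca_i)
    return rev.weight * e_ca + (1.0 - rev.weight) * rev.e_k


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

@dataclass
class TTypeChannel:
    """Low-voltage-activated, transient (inactivating) Ca++ channel."""

    gbar: float = 0.954                      # mS/cm^2
    reversal: EffectiveReversal = field(
        default_factory=lambda: EffectiveReversal(weight=0.55))
    name: str = "CaT"

    def steady_state(self, vm):
        m_inf, _tm, h_inf, _th = t_gate_functions(vm)
        return m_inf, h_inf

    def step_gates(self, m, h, vm, dt):
        m_inf, tau_m, h_inf, tau_h = t_gate_functions(vm)
        return (exp_gate_step(m, m_inf, tau_m, dt),
                exp_gate_step(h, h_inf, tau_h, dt))

    def open_fraction(self, m, h):
        return m * h

    def current(self, m, h, vm, ca_i=CA_RES_UM):
        """Current density in uA/cm^2 (positive outward)."""
        e_rev = self.reversal(ca_i)
        return self.gbar * self.open_fraction(m, h) * (vm - e_rev)


@dataclass
class LTypeChannel:
    """High-voltage-activated, sustained Ca++ channel (slow 292 ms inactivation)."""

    gbar: float = 1.088                      # mS/cm^2
    reversal: EffectiveReversal = field(
        default_factory=lambda: EffectiveReversal(weight=0.70))
    name: str = "CaL"

    def steady_state(self, vm):
        alpha, beta, h_inf, _th = l_gate_functions(vm)
        return alpha / (alpha + beta), h_inf

    def step_gates(self, m, h, vm, dt):
        alpha, beta, h_inf, tau_h = l_gate_functions(vm)
        tau_m = 1.0 / (alpha + beta)
        m_inf = alpha * tau_m
        return (exp_gate_step(m, m_inf, tau_m, dt),
                exp_gate_step(h, h_inf, tau_h, dt))

    def open_fraction(self, m, h):
        return m * m * h

    def current(self, m, h, vm, ca_i=CA_RES_UM):
        """Current density in uA/cm^2 (positive outward)."""
        e_rev = self.reversal(ca_i)
        return self.gbar * self.open_fraction(m, h) * (vm - e_rev)


# ---------------------------------------------------------------------------
# intracellular calcium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumModel:
    """First-order [Ca++]_i dynamics of a terminal compartment.

    d[Ca]/dt = -(s/v) i_Ca / (2F) - ([Ca] - [Ca]_res) / tau

    with s/v in 1/um, i_Ca in uA/cm^2 and [Ca] in uM.  The step uses the
    exact exponential solution of this linear ODE for piecewise-constant
    current.  ``ca_res`` is the *minimal residual* concentration: strong
    outward transients (whose charge is mostly carried by K+) cannot deplete
    the store below it, so the update is floored there.
    """

    ca_res: float = CA_RES_UM
    tau: float = CA_TAU_MS
    ca_o: float = CA_OUT_UM

    def inflow(self, i_ca, s_over_v):
        """Source term in uM/ms (positive for inward = negative current)."""
        return -CA_FLUX_FACTOR * s_over_v * np.asarray(i_ca, float) / (
            2.0 * FARADAY_C_PER_MOL)

    def steady_state(self, i_ca, s_over_v):
        return self.ca_res + self.tau * self.inflow(i_ca, s_over_v)

    def step(self, ca_i, i_ca, s_over_v, dt):
        if dt <= 0:
            raise ValueError("dt must be positive")
        ca_ss = self.steady_state(i_ca, s_over_v)
        ca = ca_ss + (np.asarray(ca_i, float) - ca_ss) * np.exp(-dt / self.tau)
        return np.maximum(ca, self.ca_res)


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClampProtocol:
    """Step protocol: hold, then one trace per entry of ``steps_mv``."""

    hold_mv: float
    steps_mv: tuple[float, ...]
    step_ms: float
    pre_ms: float = 20.0
    post_ms: float = 50.0
    dt: float = 0.01

    def __post_init__(self):
        if len(self.steps_mv) == 0:
            raise ValueError("clamp protocol needs at least one step")


def run_voltage_clamp(channel, protocol: ClampProtocol,
                      s_over_v: float = 3.3, dynamic_ca: bool = True):
    """Simulate a voltage-clamp family for one channel.

    Gates start at steady state for the holding voltage.  Returns a dict with
    ``t`` (ms) and ``i`` of shape (n_steps, n_times) in uA/cm^2, plus the gate
    and [Ca++]_i trajectories.  ``s_over_v`` defaults to a terminal-sized
    compartment so the dynamic Nernst potential behaves as in the cell model.
    """
    p = protocol
    n_t = int(round((p.pre_ms + p.step_ms + p.post_ms) / p.dt)) + 1
    t = np.arange(n_t) * p.dt
    ca_model = CalciumModel()

    out_i = np.empty((len(p.steps_mv), n_t))
    out_m = np.empty_like(out_i)
    out_h = np.empty_like(out_i)
    out_ca = np.empty_like(out_i)

    for k, v_step in enumerate(p.steps_mv):
        vm = np.where((t >= p.pre_ms) & (t < p.pre_ms + p.step_ms),
                      v_step, p.hold_mv)
        m, h = channel.steady_state(p.hold_mv)
        m, h = float(m), float(h)
        ca = ca_model.ca_res
        for j in range(n_t):
            i_now = float(channel.current(m, h, vm[j], ca))
            out_i[k, j], out_m[k, j], out_h[k, j], out_ca[k, j] = i_now, m, h, ca
            m, h = channel.step_gates(m, h, vm[j], p.dt)
            m, h = float(m), float(h)
            if dynamic_ca:
                ca = float(ca_model.step(ca, i_now, s_over_v, p.dt))
    return {"t": t, "i": out_i, "m": out_m, "h": out_h, "ca": out_ca,
            "steps_mv": np.asarray(p.steps_mv)}
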