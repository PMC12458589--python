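"""Per-region microcircuit: a modified Hodgkin-Huxley subnetwork.

Each of the four modelled regions carries an independent subnetwork of
(by default) 50 conductance-based neurons.  Every neuron follows the
classic Hodgkin-Huxley sodium/potassium/leak membrane equation, extended
with two synaptic conductances:

* an excitatory conductance ``g_E`` receiving feed-forward Poisson
  "kicks" (the stochastic input drive) plus recurrent kicks from
  presynaptic excitatory neurons that spiked, and
* an inhibitory conductance ``g_I`` receiving recurrent kicks from
  presynaptic inhibitory spikers only — there is no stochastic drive on
  the inhibitory conductance.

Each kick is a Dirac delta pushed through the first-order decay
``tau * dg/dt = -g + S * delta(t - s)``, so a kick of size S produces an
instantaneous conductance jump of ``S / tau``.  Per-neuron presynaptic
currents are ``I_E = g_E (E_E - V)`` and ``I_I = g_I (E_I - V)``; their
population means are what the regional membrane equations consume.

Neurons are split into excitatory and inhibitory classes, with directed
Erdos-Renyi presynaptic wiring.  Spikes are rising-edge threshold
crossings with hysteresis and take effect on postsynaptic conductances
within the same Euler step (zero synaptic delay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StateError

# voltage offsets with removable singularities in the alpha functions
_SING_TOL = 1e-9


@dataclass
class MicroParams:
    """Parameters of one region's microcircuit.

    Membrane constants are the modern-convention Hodgkin-Huxley values;
    synaptic kick sizes, decay constants, drive rate, and wiring density
    are config-exposed defaults (units: mV, ms, mS/cm^2, uF/cm^2).
    """

    C: float = 1.0
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.387
    g_Na_max: float = 120.0
    g_K_max: float = 36.0
    g_L_max: float = 0.3
    E_E: float = 0.0
    E_I: float = -80.0
    tau_E: float = 2.0
    tau_I: float = 3.0
    lambda_dr: float = 0.5  # Poisson drive rate, kicks/ms
    S_dr: float = 0.4
    S_EE: float = 0.3  # excitatory kick onto an excitatory target
    S_IE: float = 0.3  # excitatory kick onto an inhibitory target
    S_EI: float = 0.5  # inhibitory kick onto an excitatory target
    S_II: float = 0.5  # inhibitory kick onto an inhibitory target
    V_th: float = -20.0
    n_neurons: int = 50
    frac_excitatory: float = 0.75
    connection_prob: float = 0.2

    def validate(self) -> None:
        if self.C <= 0:
            raise ParameterError(f"C must be > 0, got {self.C}")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ParameterError("synaptic decay constants must be > 0")
        for name in ("S_dr", "S_EE", "S_IE", "S_EI", "S_II"):
            if getattr(self, name) < 0:
                raise ParameterError(f"kick magnitude {name} must be >= 0")
        if not 0 < self.frac_excitatory < 1:
            raise ParameterError(
                f"frac_excitatory must be in (0, 1), got {self.frac_excitatory}"
            )
        if self.E_I >= self.E_E:
            raise ParameterError("E_I must be below E_E")
        if self.lambda_dr < 0:
            raise ParameterError("lambda_dr must be >= 0")
        if self.n_neurons < 1:
            raise ParameterError("n_neurons must be >= 1")


def _vtrap(u, scale):
    """Stable evaluation of u / (1 - exp(-u/scale)) with its removable
    singularity at u = 0 evaluated analytically (limit = scale)."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SING_TOL
    safe = np.where(small, 1.0, u)
    out = np.where(small, scale, safe / (-np.expm1(-safe / scale)))
    return out


def hh_rates(V):
    """Hodgkin-Huxley opening/closing rates at membrane voltage V (mV).

    Returns a dict of the six rate constants (1/ms), using the
    modern-convention rate functions (resting potential near -65 mV)
    consistent with the reversal potentials E_Na = 50, E_K = -77,
    E_L = -54.387.  The removable singularities of alpha_m (at -40 mV)
    and alpha_n (at -55 mV) are evaluated analytically.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise StateError("membrane voltage must be finite")
    return {
        "alpha_m": 0.1 * _vtrap(V + 40.0, 10.0),
        "beta_m": 4.0 * np.exp(-(V + 65.0) / 18.0),
        "alpha_h": 0.07 * np.exp(-(V + 65.0) / 20.0),
        "beta_h": 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0)),
        "alpha_n": 0.01 * _vtrap(V + 55.0, 10.0),
        "beta_n": 0.125 * np.exp(-(V + 65.0) / 80.0),
    }


def gating_steady_state(V):
    """Steady-state gating values m_inf, h_inf, n_inf at voltage V."""
    r = hh_rates(V)
    m = r["alpha_m"] / (r["alpha_m"] + r["beta_m"])
    h = r["alpha_h"] / (r["alpha_h"] + r["beta_h"])
    n = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])
    return m, h, n


@dataclass
class MicroPopulation:
    """State of one region's neuron subnetwork (vectorized over neurons)."""

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    g_E: np.ndarray
    g_I: np.ndarray
    is_excitatory: np.ndarray  # bool, per neuron
    adj_E: np.ndarray  # adj_E[i, j] = 1 if excitatory j is presynaptic to i
    adj_I: np.ndarray  # adj_I[i, j] = 1 if inhibitory j is presynaptic to i
    above_threshold: np.ndarray = field(default=None)  # hysteresis flag

    def __post_init__(self):
        if self.above_threshold is None:
            self.above_threshold = np.zeros(self.V.shape, dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.V.shape[0]

    def validate(self) -> None:
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if np.any(x < 0) or np.any(x > 1):
                raise StateError(f"gating variable {name} left [0, 1]")
        if np.any(self.g_E < 0) or np.any(self.g_I < 0):
            raise StateError("synaptic conductances must be >= 0")
        if np.any(np.diag(self.adj_E)) or np.any(np.diag(self.adj_I)):
            raise StateError("no neuron may be presynaptic to itself")


def excitatory_split(n_neurons: int, frac_excitatory: float) -> int:
    """Number of excitatory neurons: round(N * frac), remainder inhibitory."""
    n_exc = int(round(n_neurons * frac_excitatory))
    return min(max(n_exc, 1), n_neurons - 1) if n_neurons > 1 else n_neurons


def init_population(params: MicroParams, rng: np.random.Generator) -> MicroPopulation:
    """Draw initial conditions and presynaptic wiring for one region.

    Initial voltages are uniform on [-70, -60] mV, gating variables at
    their steady state for the initial voltage, conductances zero.
    Wiring is directed Erdos-Renyi with ``connection_prob`` per ordered
    pair, no self-connections; the first ``round(N * frac_excitatory)``
    neurons are excitatory.
    """
    params.validate()
    N = params.n_neurons
    n_exc = excitatory_split(N, params.frac_excitatory)
    is_exc = np.zeros(N, dtype=bool)
    is_exc[:n_exc] = True
    V0 = rng.uniform(-70.0, -60.0, size=N)
    m0, h0, n0 = gating_steady_state(V0)
    conn = rng.random((N, N)) < params.connection_prob
    np.fill_diagonal(conn, False)
    adj_E = conn & is_exc[np.newaxis, :]
    adj_I = conn & ~is_exc[np.newaxis, :]
    return MicroPopulation(
        V=V0,
        m=m0,
        h=h0,
        n=n0,
        g_E=np.zeros(N),
        g_I=np.zeros(N),
        is_excitatory=is_exc,
        adj_E=adj_E.astype(float),
        adj_I=adj_I.astype(float),
    )


def stack_populations(pops: list[MicroPopulation]) -> MicroPopulation:
    """Concatenate per-region populations into one block-diagonal population.

    The stacked adjacency is block diagonal, so the regions remain
    mutually unconnected (each region's subnetwork is simulated
    independently); stacking only lets the engine advance all regions
    with a single set of vectorized operations.
    """
    ns = [p.n_neurons for p in pops]
    N = sum(ns)
    adj_E = np.zeros((N, N))
    adj_I = np.zeros((N, N))
    ofs = 0
    for p, n in zip(pops, ns):
        adj_E[ofs:ofs + n, ofs:ofs + n] = p.adj_E
        adj_I[ofs:ofs + n, ofs:ofs + n] = p.adj_I
        ofs += n
    return MicroPopulation(
        V=np.concatenate([p.V for p in pops]),
        m=np.concatenate([p.m for p in pops]),
        h=np.concatenate([p.h for p in pops]),
        n=np.concatenate([p.n for p in pops]),
        g_E=np.concatenate([p.g_E for p in pops]),
        g_I=np.concatenate([p.g_I for p in pops]),
        is_excitatory=np.concatenate([p.is_excitatory for p in pops]),
        adj_E=adj_E,
        adj_I=adj_I,
        above_threshold=np.concatenate([p.above_threshold for p in pops]),
    )


def neuron_derivatives(pop: MicroPopulation, params: MicroParams):
    """Right-hand sides dV/dt, dm/dt, dh/dt, dn/dt for every neuron."""
    V, m, h, n = pop.V, pop.m, pop.h, pop.n
    r = hh_rates(V)
    I_ion = (
        params.g_Na_max * m**3 * h * (params.E_Na - V)
        + params.g_K_max * n**4 * (params.E_K - V)
        + params.g_L_max * (params.E_L - V)
    )
    I_syn = pop.g_E * (params.E_E - V) + pop.g_I * (params.E_I - V)
    dV = (I_ion + I_syn) / params.C
    dm = r["alpha_m"] * (1.0 - m) - r["beta_m"] * m
    dh = r["alpha_h"] * (1.0 - h) - r["beta_h"] * h
    dn = r["alpha_n"] * (1.0 - n) - r["beta_n"] * n
    return dV, dm, dh, dn


def draw_poisson_drive(n_neurons: int, lambda_dr: float, dt: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-neuron counts of feed-forward drive events in one step of dt ms."""
    if lambda_dr < 0:
        raise ParameterError("lambda_dr must be >= 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if lambda_dr == 0:
        return np.zeros(n_neurons, dtype=np.int64)
    return rng.poisson(lambda_dr * dt, size=n_neurons)


def detect_threshold_crossings(pop: MicroPopulation, V_th: float) -> np.ndarray:
    """Boolean mask of neurons whose V crossed V_th from below this step.

    Uses the hysteresis flag ``above_threshold`` from the previous step:
    a neuron sitting above threshold does not re-trigger until it has
    fallen below V_th again.  The caller (or :func:`step_population`)
    is responsible for refreshing the flag afterwards.
    """
    return (pop.V >= V_th) & ~pop.above_threshold


def decay_and_kick(pop: MicroPopulation, spiking: np.ndarray,
                   poisson_events: np.ndarray, params: MicroParams,
                   dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One Euler substep of the conductance dynamics, in place.

    Conductances first decay by the explicit-Euler factor
    ``(1 - dt/tau)``, then receive kicks: each Poisson drive event adds
    ``S_dr / tau_E`` to g_E; each presynaptic excitatory spiker adds
    ``S_EE / tau_E`` (excitatory target) or ``S_IE / tau_E`` (inhibitory
    target); each presynaptic inhibitory spiker adds ``S_EI / tau_I`` or
    ``S_II / tau_I`` to g_I.  The drive never touches g_I.

    ``spiking`` may be a boolean mask or an index array.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if dt >= params.tau_E or dt >= params.tau_I:
        import warnings

        warnings.warn(
            "dt is not small against the synaptic decay constants; "
            "explicit Euler decay may be unstable",
            stacklevel=2,
        )
    spike_vec = np.zeros(pop.n_neurons)
    spike_vec[spiking] = 1.0
    pop.g_E *= 1.0 - dt / params.tau_E
    pop.g_I *= 1.0 - dt / params.tau_I
    pop.g_E += params.S_dr / params.tau_E * poisson_events
    if np.any(spike_vec):
        exc_spikes = pop.adj_E @ spike_vec  # per-target excitatory spiker count
        inh_spikes = pop.adj_I @ spike_vec
        S_E = np.where(pop.is_excitatory, params.S_EE, params.S_IE) / params.tau_E
        S_I = np.where(pop.is_excitatory, params.S_EI, params.S_II) / params.tau_I
        pop.g_E += S_E * exc_spikes
        pop.g_I += S_I * inh_spikes
    return pop.g_E, pop.g_I


def average_currents(pop: MicroPopulation, params: MicroParams) -> tuple[float, float]:
    """Population means of the presynaptic currents (uA/cm^2).

    ``I_E_bar = mean_i g_Ei (E_E - V_i)``,
    ``I_I_bar = mean_i g_Ii (E_I - V_i)``.
    """
    if pop.n_neurons == 0:
        raise StateError("cannot average currents over an empty population")
    I_E = float(np.mean(pop.g_E * (params.E_E - pop.V)))
    I_I = float(np.mean(pop.g_I * (params.E_I - pop.V)))
    return I_E, I_I


def step_population(pop: MicroPopulation, params: MicroParams, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Advance the subnetwork one Euler step of dt ms; returns spike mask.

    Order within the step: (1) explicit-Euler advance of V, m, h, n;
    (2) rising-edge spike detection on the new voltages; (3) conductance
    decay followed by Poisson-drive and same-step recurrent kicks.
    """
    dV, dm, dh, dn = neuron_derivatives(pop, params)
    pop.V = pop.V + dV * dt
    pop.m = pop.m + dm * dt
    pop.h = pop.h + dh * dt
    pop.n = pop.n + dn * dt
    spikes = detect_threshold_crossings(pop, params.V_th)
    pop.above_threshold = pop.V >= params.V_th
    events = draw_poisson_drive(pop.n_neurons, params.lambda_dr, dt, rng)
    decay_and_kick(pop, spikes, events, params, dt)
    return spikes
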