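"""Regional membrane equations of the basal-ganglia--thalamus network.

Four single-compartment regional membrane equations (STN, GPi, GPe, TH)
in the Rubin--Terman lineage of basal-ganglia models: sodium, potassium,
leak, low-threshold T-type calcium, high-threshold calcium and
calcium-gated after-hyperpolarization (AHP) currents, first-order gating
kinetics with sigmoidal steady states and voltage-dependent time
constants, and first-order synaptic activation between nuclei.  The
regional voltages additionally feel

* a diffusion term ``-dv_p * (L v)_p`` over the connectome Laplacian,
* the population-averaged presynaptic currents of the region's
  microcircuit,
* a constant bias current ``I_app`` (reduced in the Parkinsonian state
  for STN, GPi and GPe),
* a periodic rectangular sensorimotor-cortex (SMC) pulse train into TH,
* and, when staged, the DBS current (STN and/or GPi).

Connection topology is fixed: GPe->STN, STN->GPi, STN->GPe, GPe->GPi,
GPe->GPe (lateral), GPi->TH.  STN-source currents are excitatory; GPe-
and GPi-source currents are inhibitory.

All conductances are mS/cm^2, voltages mV, currents uA/cm^2, times ms.
The ionic/synaptic functional forms and constants follow the
Rubin--Terman model family and are config-exposed defaults of this
package; bias currents, their disease-state reductions and the AHP
strength are calibrated defaults (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, StateError, ValidationError

REGIONS = ("STN", "GPi", "GPe", "TH")

#: the six modelled inter-nucleus connections, in a fixed order
CONNECTIONS = (
    "GPe->STN",
    "STN->GPi",
    "STN->GPe",
    "GPe->GPi",
    "GPe->GPe",
    "GPi->TH",
)


def sigmoid(x: float, theta: float, sigma: float) -> float:
    """Logistic steady-state curve 1 / (1 + exp(-(x - theta) / sigma)).

    Negative ``sigma`` yields a decreasing (inactivation-type) curve.
    """
    return 1.0 / (1.0 + math.exp(-(x - theta) / sigma))


@dataclass(frozen=True)
class GateKinetics:
    """First-order kinetics of one regional gating variable.

    dx/dt = e * (x_inf(v) - x) / tau(v) with x_inf a sigmoid in v and
    tau(v) one of:

    * ``"sigmoid"``   tau0 + tau1 / (1 + exp(-(v - theta_tau) / sigma_tau))
    * ``"constant"``  tau0
    * ``"exp"``       tau0 + tau1 * exp(-(v - theta_tau) / sigma_tau)
    * ``"hh_inverse"``  1 / (a(v) + b(v)) with a = 0.128 exp(-(v+46)/18),
      b = 4 / (1 + exp(-(v+23)/5)) — the thalamic sodium-inactivation form.

    ``rate_scale`` is the dimensionless rate scaler e_x.
    """

    theta_inf: float
    sigma_inf: float
    rate_scale: float = 1.0
    tau_form: str = "constant"
    tau0: float = 1.0
    tau1: float = 0.0
    theta_tau: float = 0.0
    sigma_tau: float = 1.0

    def x_inf(self, v: float) -> float:
        return sigmoid(v, self.theta_inf, self.sigma_inf)

    def tau(self, v: float) -> float:
        if self.tau_form == "constant":
            return self.tau0
        if self.tau_form == "sigmoid":
            return self.tau0 + self.tau1 * sigmoid(v, self.theta_tau, self.sigma_tau)
        if self.tau_form == "exp":
            return self.tau0 + self.tau1 * math.exp(
                -(v - self.theta_tau) / self.sigma_tau
            )
        if self.tau_form == "hh_inverse":
            a = 0.128 * math.exp(-(v + 46.0) / 18.0)
            b = 4.0 / (1.0 + math.exp(-(v + 23.0) / 5.0))
            return 1.0 / (a + b)
        raise ParameterError(f"unknown tau_form {self.tau_form!r}")

    def derivative(self, x: float, v: float) -> float:
        return self.rate_scale * (self.x_inf(v) - x) / self.tau(v)


@dataclass
class RegionParams:
    """Ionic parameter table for one region (Rubin--Terman-style)."""

    name: str
    cm: float = 1.0
    g_Na: float = 0.0
    E_Na: float = 55.0
    g_K: float = 0.0
    E_K: float = -80.0
    g_L: float = 0.0
    E_L: float = -65.0
    g_T: float = 0.0
    g_Ca: float = 0.0
    E_Ca: float = 140.0  # T and high-threshold Ca reversal (E_T = 0 for TH)
    g_ahp: float = 0.0
    k1: float = 15.0  # half-saturation of the calcium-gated AHP
    # instantaneous activation curves
    theta_m: float = -30.0
    sigma_m: float = 15.0
    theta_a: float = -63.0  # T-current activation (STN/GPe/GPi)
    sigma_a: float = 7.8
    # STN T-current inactivation coupling b_inf(r)
    theta_b: float = 0.4
    sigma_b: float = 0.1
    # calcium pool: dw/dt = e_w * (-I_Ca - I_T - l_w * w)
    e_w: float = 0.0
    l_w: float = 15.0
    gates: dict = field(default_factory=dict)  # name -> GateKinetics
    I_app: float = 0.0
    pd_reduction: float = 0.0
    dv: float = 0.1  # diffusion scale dv_p, 1/ms per unit Laplacian

    def validate(self) -> None:
        if self.cm <= 0:
            raise ParameterError(f"{self.name}: cm must be > 0")
        for g in ("g_Na", "g_K", "g_L", "g_T", "g_Ca", "g_ahp"):
            if getattr(self, g) < 0:
                raise ParameterError(f"{self.name}: {g} must be >= 0")
        if self.pd_reduction < 0:
            raise ParameterError(f"{self.name}: pd_reduction must be >= 0")

    def m_inf(self, v: float) -> float:
        return sigmoid(v, self.theta_m, self.sigma_m)

    def a_inf(self, v: float) -> float:
        return sigmoid(v, self.theta_a, self.sigma_a)

    def b_inf(self, r: float) -> float:
        # zero-shifted so b_inf(0) = 0 exactly
        return sigmoid(r, self.theta_b, self.sigma_b) - sigmoid(
            0.0, self.theta_b, self.sigma_b
        )


@dataclass
class SynapseParams:
    """One inter-nucleus connection: g_syn * s * (v_target - E_syn) with
    first-order activation ds/dt = alpha * H(v_pre) * (1 - s) - beta * s."""

    g_syn: float
    E_syn: float
    alpha: float = 1.0
    beta: float = 0.08
    theta_g: float = -20.0  # presynaptic activation threshold
    sigma_g: float = 5.0

    def H_inf(self, v_pre: float) -> float:
        return sigmoid(v_pre, self.theta_g, self.sigma_g)

    def s_inf(self, v_pre: float) -> float:
        a = self.alpha * self.H_inf(v_pre)
        return a / (a + self.beta)


@dataclass
class SMCParams:
    """Sensorimotor-cortex input: a periodic rectangular pulse train."""

    amplitude: float = 3.5  # uA/cm^2
    pulse_width: float = 5.0  # ms
    period: float = 25.0  # ms
    onset: float = 0.0  # ms offset of the pulse within each period

    def validate(self) -> None:
        if not self.pulse_width < self.period:
            raise ParameterError("SMC pulse_width must be < period")
        if self.amplitude < 0:
            raise ParameterError("SMC amplitude must be >= 0")


def smc_input(t: float, params: SMCParams) -> float:
    """SMC current at time t (ms): ``amplitude`` inside each pulse window
    [k*period + onset, k*period + onset + pulse_width), else 0."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    phase = (t - params.onset) % params.period
    return params.amplitude if 0.0 <= phase < params.pulse_width else 0.0


# ---------------------------------------------------------------------------
# default parameter tables (Rubin--Terman model family; defaults of this
# package, with bias currents and AHP strengths calibrated — see methods)
# ---------------------------------------------------------------------------


def _stn_params() -> RegionParams:
    return RegionParams(
        name="STN",
        g_Na=37.5, E_Na=55.0, g_K=45.0, E_K=-80.0, g_L=2.25, E_L=-60.0,
        g_T=0.5, g_Ca=0.5, E_Ca=140.0, g_ahp=9.0, k1=15.0,
        theta_m=-30.0, sigma_m=15.0, theta_a=-63.0, sigma_a=7.8,
        theta_b=0.4, sigma_b=0.1,
        e_w=5e-5, l_w=22.5,
        gates={
            "h": GateKinetics(-39.0, -3.1, 0.75, "sigmoid", 1.0, 500.0, -57.0, -3.0),
            "n": GateKinetics(-32.0, 8.0, 0.75, "sigmoid", 1.0, 100.0, -80.0, -26.0),
            "r": GateKinetics(-67.0, -2.0, 0.5, "sigmoid", 7.1, 17.5, -68.0, -2.2),
            "c": GateKinetics(-39.0, 8.0, 1.0, "constant", 1.0),
        },
        I_app=25.0, pd_reduction=8.0,
    )


def _pallidal_params(name: str, I_app: float, pd_reduction: float,
                     g_ahp: float, e_h: float = 0.05, e_n: float = 0.1,
                     e_w: float = 1e-4) -> RegionParams:
    return RegionParams(
        name=name,
        g_Na=120.0, E_Na=55.0, g_K=30.0, E_K=-80.0, g_L=0.1, E_L=-65.0,
        g_T=0.5, g_Ca=0.15, E_Ca=120.0, g_ahp=g_ahp, k1=10.0,
        theta_m=-37.0, sigma_m=10.0, theta_a=-57.0, sigma_a=2.0,
        e_w=e_w, l_w=15.0,
        gates={
            "h": GateKinetics(-58.0, -12.0, e_h, "sigmoid", 0.05, 0.27, -40.0, -12.0),
            "n": GateKinetics(-50.0, 14.0, e_n, "sigmoid", 0.05, 0.27, -40.0, -12.0),
            "r": GateKinetics(-70.0, -2.0, 1.0, "constant", 30.0),
            "c": GateKinetics(-35.0, 2.0, 1.0, "constant", 1.0),
        },
        I_app=I_app, pd_reduction=pd_reduction,
    )


def _th_params() -> RegionParams:
    return RegionParams(
        name="TH",
        g_Na=2.5, E_Na=50.0, g_K=5.0, E_K=-90.0, g_L=0.05, E_L=-70.0,
        g_T=5.0, E_Ca=0.0,  # E_Ca doubles as the T-current reversal E_T
        g_Ca=0.0, g_ahp=0.0,
        theta_m=-37.0, sigma_m=7.0,
        # thalamic T-current activation p_inf reuses the a_inf slot
        theta_a=-60.0, sigma_a=6.2,
        gates={
            "h": GateKinetics(-41.0, -4.0, 1.0, "hh_inverse"),
            "r": GateKinetics(-84.0, -4.0, 1.0, "exp", 28.0, 1.0, -25.0, 10.5),
        },
        I_app=0.0, pd_reduction=0.0,
    )


def default_region_params() -> dict:
    """Default parameter tables for the four regions."""
    return {
        "STN": _stn_params(),
        # GPi: a fast tonic firer with slow sodium-inactivation recovery and
        # fast potassium activation, so the high-frequency DBS pulse train
        # drives it toward partial depolarization block and reduces its
        # counted spiking relative to the unstimulated Parkinsonian state
        "GPi": _pallidal_params("GPi", I_app=50.0, pd_reduction=4.0,
                                g_ahp=30.0, e_h=0.01, e_n=0.3, e_w=3e-4),
        "GPe": _pallidal_params("GPe", I_app=12.0, pd_reduction=6.0, g_ahp=10.0),
        "TH": _th_params(),
    }


def default_synapse_params() -> dict:
    """Default parameters of the six inter-nucleus connections."""
    inhib = dict(E_syn=-85.0)
    excit = dict(E_syn=0.0)
    return {
        "GPe->STN": SynapseParams(g_syn=0.5, **inhib),
        "STN->GPi": SynapseParams(g_syn=0.3, **excit),
        "STN->GPe": SynapseParams(g_syn=0.3, **excit),
        "GPe->GPi": SynapseParams(g_syn=0.5, **inhib),
        "GPe->GPe": SynapseParams(g_syn=0.3, **inhib),
        "GPi->TH": SynapseParams(g_syn=0.5, **inhib),
    }


@dataclass
class BGTHParams:
    """Full macro-scale parameter set: regions, connections, SMC input."""

    regions: dict = field(default_factory=default_region_params)
    synapses: dict = field(default_factory=default_synapse_params)
    smc: SMCParams = field(default_factory=SMCParams)

    def validate(self) -> None:
        for name in REGIONS:
            if name not in self.regions:
                raise ValidationError(f"missing region parameter table {name!r}")
            self.regions[name].validate()
        for name in CONNECTIONS:
            if name not in self.synapses:
                raise ValidationError(f"missing synapse parameter table {name!r}")
        self.smc.validate()


def apply_disease_state(params: BGTHParams, pd: int) -> BGTHParams:
    """Return parameters with the disease switch applied.

    ``pd = 0`` (healthy) returns the parameters unchanged; ``pd = 1``
    reduces the constant bias currents of STN, GPi and GPe by each
    region's ``pd_reduction`` (TH is unaffected).  Always operates on the
    pristine base parameters, so the operation is idempotent by
    construction.
    """
    if pd not in (0, 1):
        raise ParameterError(f"pd must be 0 or 1, got {pd!r}")
    if pd == 0:
        return params
    regions = dict(params.regions)
    for name in ("STN", "GPi", "GPe"):
        rp = regions[name]
        regions[name] = replace(rp, I_app=rp.I_app - rp.pd_reduction)
    return BGTHParams(regions=regions, synapses=params.synapses, smc=params.smc)


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------


@dataclass
class RegionEnsemble:
    """Macro-scale state: node voltages, regional gates, synaptic activations.

    ``v`` has one entry per connectome node; the four modelled regions
    occupy nodes 0..3 in the fixed order (STN, GPi, GPe, TH).  Any
    further nodes are passive diffusion-only nodes.
    """

    v: np.ndarray
    gates: dict  # region -> {gate name -> float}; includes "w" where present
    syn: dict  # connection name -> activation s in [0, 1]

    def validate(self) -> None:
        for region, g in self.gates.items():
            for name, x in g.items():
                if name == "w":
                    if x < 0:
                        raise StateError(f"{region}: calcium pool w must be >= 0")
                elif not 0.0 <= x <= 1.0:
                    raise StateError(f"{region}: gate {name} = {x} left [0, 1]")


def init_ensemble(params: BGTHParams, n_nodes: int = 4,
                  v0: float = -65.0) -> RegionEnsemble:
    """Ensemble at rest: all nodes at ``v0``, gates and synapses at their
    steady states for ``v0``, calcium pools at a small positive level."""
    if n_nodes < 4:
        raise ParameterError("connectome must provide at least the 4 region nodes")
    gates = {}
    for region in REGIONS:
        rp = params.regions[region]
        g = {name: kin.x_inf(v0) for name, kin in rp.gates.items()}
        if rp.e_w > 0:
            g["w"] = 0.05
        gates[region] = g
    syn = {name: params.synapses[name].s_inf(v0) for name in CONNECTIONS}
    return RegionEnsemble(v=np.full(n_nodes, float(v0)), gates=gates, syn=syn)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def ionic_currents(v: float, gates: dict, params: RegionParams,
                   region: str) -> dict:
    """Named ionic currents (uA/cm^2) of one region at voltage v.

    Every current has the form g * (gating expression) * (v - E_rev); the
    regional membrane equation subtracts them.  TH carries only I_Na,
    I_K, I_L and I_T (with I_K gated by 0.75*(1 - h) and I_T by the
    instantaneous activation squared times the slow inactivation r).
    """
    if region not in REGIONS:
        raise ParameterError(f"unknown region {region!r}")
    p = params
    out = {}
    if region == "TH":
        h = gates["h"]
        r = gates["r"]
        out["I_Na"] = p.g_Na * p.m_inf(v) ** 3 * h * (v - p.E_Na)
        out["I_K"] = p.g_K * (0.75 * (1.0 - h)) ** 4 * (v - p.E_K)
        out["I_L"] = p.g_L * (v - p.E_L)
        out["I_T"] = p.g_T * p.a_inf(v) ** 2 * r * (v - p.E_Ca)
        return out
    h, n, r, c = gates["h"], gates["n"], gates["r"], gates["c"]
    w = gates.get("w", 0.0)
    out["I_Na"] = p.g_Na * p.m_inf(v) ** 3 * h * (v - p.E_Na)
    out["I_K"] = p.g_K * n**4 * (v - p.E_K)
    out["I_L"] = p.g_L * (v - p.E_L)
    if region == "STN":
        out["I_T"] = p.g_T * p.a_inf(v) ** 3 * p.b_inf(r) ** 2 * (v - p.E_Ca)
    else:
        out["I_T"] = p.g_T * p.a_inf(v) ** 3 * r * (v - p.E_Ca)
    out["I_Ca"] = p.g_Ca * c**2 * (v - p.E_Ca)
    out["I_ahp"] = p.g_ahp * (v - p.E_K) * w / (w + p.k1)
    return out


def gate_derivatives(gates: dict, v: float, params: RegionParams,
                     region: str, currents: dict | None = None) -> dict:
    """Time derivatives of one region's gating variables.

    First-order gates follow dx/dt = e_x (x_inf(v) - x) / tau_x(v); the
    calcium pool follows dw/dt = e_w (-I_Ca - I_T - l_w w), a balance of
    calcium influx through the T and high-threshold calcium currents
    against linear clearance.  ``currents`` may carry a precomputed
    :func:`ionic_currents` result to avoid re-evaluating it.
    """
    out = {name: params.gates[name].derivative(gates[name], v)
           for name in params.gates}
    if "w" in gates:
        cur = currents if currents is not None else ionic_currents(
            v, gates, params, region)
        out["w"] = params.e_w * (-cur["I_Ca"] - cur["I_T"] - params.l_w * gates["w"])
    return out


def synaptic_currents(v: dict, syn: dict, synapses: dict) -> dict:
    """The six inter-nucleus currents, keyed by connection name.

    ``v`` maps region -> voltage; each current is evaluated at its
    *target* region: I = g_syn * s * (v_target - E_syn).
    """
    out = {}
    for name in CONNECTIONS:
        sp = synapses[name]
        target = name.split("->")[1]
        out[name] = sp.g_syn * syn[name] * (v[target] - sp.E_syn)
    return out


def synaptic_current(name: str, v_target: float, s: float,
                     synapses: dict) -> float:
    """One connection's current; raises on a non-modelled connection."""
    if name not in CONNECTIONS:
        raise ParameterError(
            f"connection {name!r} is not part of the modelled topology"
        )
    sp = synapses[name]
    return sp.g_syn * s * (v_target - sp.E_syn)


def synapse_derivatives(v: dict, syn: dict, synapses: dict) -> dict:
    """First-order activation kinetics for every connection (driven by the
    presynaptic voltage sigmoid; zero transmission delay)."""
    out = {}
    for name in CONNECTIONS:
        sp = synapses[name]
        pre = name.split("->")[0]
        s = syn[name]
        out[name] = sp.alpha * sp.H_inf(v[pre]) * (1.0 - s) - sp.beta * s
    return out


#: synaptic currents subtracted in each region's membrane equation
_REGION_SYNAPSES = {
    "STN": ("GPe->STN",),
    "GPi": ("STN->GPi", "GPe->GPi"),
    "GPe": ("STN->GPe", "GPe->GPe"),
    "TH": ("GPi->TH",),
}


def regional_rhs(ensemble: RegionEnsemble, laplacian: np.ndarray,
                 avg_currents: dict, stim_currents: dict, t: float,
                 params: BGTHParams) -> tuple[np.ndarray, dict, dict]:
    """Full macro right-hand side at time t.

    Parameters
    ----------
    avg_currents : dict
        region -> (I_E_bar, I_I_bar), the microcircuit averages.
    stim_currents : dict
        region -> staged DBS current (0 where not targeted).

    Returns ``(dv, gate_derivs, syn_derivs)`` where ``dv`` covers every
    connectome node:

    dv_p/dt = -dv_p (L v)_p + (1/cm) [-(ionic) - (synaptic) + I_app
              (+ I_smc for TH) (+ I_DBS where staged) + I_E_bar + I_I_bar]

    Passive nodes beyond the first four feel only the diffusion term.
    """
    v = ensemble.v
    V = v.shape[0]
    if laplacian.shape != (V, V):
        raise ValidationError(
            f"laplacian shape {laplacian.shape} does not match {V} nodes"
        )
    Lv = laplacian @ v
    vmap = {region: v[i] for i, region in enumerate(REGIONS)}
    syn_cur = synaptic_currents(vmap, ensemble.syn, params.synapses)
    dv = np.empty(V)
    gate_derivs = {}
    for i, region in enumerate(REGIONS):
        rp = params.regions[region]
        gates = ensemble.gates[region]
        currents = ionic_currents(v[i], gates, rp, region)
        ionic = sum(currents.values())
        synaptic = sum(syn_cur[name] for name in _REGION_SYNAPSES[region])
        I_E, I_I = avg_currents[region]
        total = -ionic - synaptic + rp.I_app + I_E + I_I
        total += stim_currents.get(region, 0.0)
        if region == "TH":
            total += smc_input(t, params.smc)
        dv[i] = -rp.dv * Lv[i] + total / rp.cm
        gate_derivs[region] = gate_derivatives(gates, v[i], rp, region,
                                               currents=currents)
    # passive diffusion-only nodes use the default diffusion scale
    dv_extra = 0.1
    for k in range(4, V):
        dv[k] = -dv_extra * Lv[k]
    syn_derivs = synapse_derivatives(vmap, ensemble.syn, params.synapses)
    return dv, gate_derivs, syn_derivs
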