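"""Lockstep micro/macro co-simulation engine.

Advances the coupled system — four 50-neuron Hodgkin-Huxley subnetworks
plus the four regional membrane equations diffusing over the connectome
Laplacian — with explicit Euler steps of ``dt = 0.01`` ms.  Within every
step the microcircuits are updated first (Poisson drive, membrane
advance, spike detection, conductance kicks), their fresh
population-averaged presynaptic currents are handed to the regional
equations, and the regional voltages, gates and synaptic activations are
then advanced with the same dt (synchronous, zero-lag exchange).

In stochastic mode the regional voltages receive an additional
Euler-Maruyama increment ``sigma_i * dW_i`` with ``dW_i ~ N(0, dt)``;
noise never enters the micro-neurons, the gating variables, or the
synaptic activations.  Three independently seeded RNG streams (micro
Poisson drive, micro initial conditions, Wiener increments) keep the
micro trajectory unchanged when noise is toggled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import __version__
from .connectome import Connectome
from .errors import IntegrationError, ParameterError
from .microcircuit import (
    MicroParams,
    init_population,
    stack_populations,
    step_population,
)
from .regions import (
    BGTHParams,
    REGIONS,
    apply_disease_state,
    init_ensemble,
    regional_rhs,
)
from .stimulation import DBSParams, stage_stimulus

logger = logging.getLogger(__name__)

#: per-region noise intensities in region order (STN, GPi, GPe, TH)
DEFAULT_SIGMA = (0.1, 0.4, 0.4, 0.5)

_NO_STIM = {"STN": 0.0, "GPi": 0.0}


@dataclass
class NoiseParams:
    """Additive voltage noise: intensities sigma_1..sigma_4 (mV/sqrt(ms))."""

    sigma: tuple = DEFAULT_SIGMA
    enabled: bool = False

    def __post_init__(self):
        self.sigma = tuple(float(s) for s in self.sigma)
        if len(self.sigma) != 4:
            raise ParameterError("need exactly four noise intensities")
        if any(s < 0 for s in self.sigma):
            raise ParameterError("noise intensities must be >= 0")


@dataclass
class Seeds:
    """Independent seeds for the three random sources."""

    micro: int = 11
    noise: int = 12
    init: int = 13

    @classmethod
    def from_master(cls, seed: int) -> "Seeds":
        """Derive the three stream seeds from one master seed."""
        ss = np.random.SeedSequence(seed)
        micro, noise, init = (int(s.generate_state(1)[0] % 2**31)
                              for s in ss.spawn(3))
        return cls(micro=micro, noise=noise, init=init)


@dataclass
class SimConfig:
    """Everything that defines one co-simulation run."""

    dt: float = 0.01  # ms
    duration: float = 1000.0  # ms
    pd: int = 0
    dbs: DBSParams = field(default_factory=DBSParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_micro: int = 50
    seeds: Seeds = field(default_factory=Seeds)
    record_stride: int = 10  # record every N-th step (0.1 ms at defaults)
    record_rasters: bool = True
    record_currents: bool = True

    def validate(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.duration < self.dt:
            raise ParameterError("duration must be >= dt")
        if self.n_micro < 1:
            raise ParameterError("n_micro must be >= 1")
        if self.pd not in (0, 1):
            raise ParameterError("pd must be 0 or 1")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimResult:
    """Recorded traces and metadata of one run.

    ``v_regions`` rows follow the fixed region order (STN, GPi, GPe, TH);
    all traces share the ``time`` grid.
    """

    time: np.ndarray
    v_regions: np.ndarray  # (4, n_rec)
    spikes: dict  # region -> (n_spikes, 2) array of (neuron_id, time_ms)
    avg_currents: dict  # region -> (2, n_rec) array of (I_E_bar, I_I_bar)
    meta: dict

    def region_trace(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ParameterError(f"unknown region {region!r}")
        return self.v_regions[REGIONS.index(region)]


def euler_step(state: np.ndarray, deriv: np.ndarray, dt: float) -> np.ndarray:
    """One explicit Euler update ``state + deriv * dt`` (componentwise).

    Raises :class:`IntegrationError` naming the first offending component
    if the derivative is non-finite.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    deriv = np.asarray(deriv, dtype=float)
    if not np.all(np.isfinite(deriv)):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(deriv)))[0])
        raise IntegrationError(
            f"non-finite derivative in component {bad}", component=bad
        )
    return state + deriv * dt


def euler_maruyama_step(state: np.ndarray, deriv: np.ndarray,
                        noise: NoiseParams, dt: float,
                        rng: np.random.Generator) -> np.ndarray:
    """One Euler-Maruyama update of a voltage-like state vector.

    ``state + deriv * dt + sigma * dW`` with ``dW ~ N(0, dt)`` drawn
    independently per component.  With all sigma = 0 the result is
    bit-identical to :func:`euler_step` (the zero noise term is still
    added, but adds exactly 0.0).
    """
    out = euler_step(state, deriv, dt)
    sigma = np.asarray(noise.sigma, dtype=float)
    dW = rng.normal(0.0, np.sqrt(dt), size=np.shape(out))
    return out + sigma * dW


def run_cosim(config: SimConfig, connectome: Connectome,
              params: BGTHParams | None = None,
              micro_params: MicroParams | None = None) -> SimResult:
    """Run one full co-simulation and return its recorded result.

    Per step: (1) advance each region's micro subnetwork one Euler step
    (drive draw, membrane advance, rising-edge spike detection, same-step
    conductance kicks); (2) average the presynaptic currents; (3)
    assemble the regional right-hand sides including diffusion, SMC and
    staged DBS; (4) advance the macro state with Euler (deterministic
    mode) or Euler-Maruyama on the regional voltages (stochastic mode).

    Traces are recorded every ``config.record_stride`` steps plus the
    final step.
    """
    config.validate()
    params = params if params is not None else BGTHParams()
    params.validate()
    micro_params = micro_params if micro_params is not None else MicroParams()
    if connectome.n_nodes < 4:
        raise ParameterError("connectome must have at least 4 nodes")
    micro_params = replace(micro_params, n_neurons=config.n_micro)
    run_params = apply_disease_state(params, config.pd)

    rng_micro = np.random.default_rng(config.seeds.micro)
    rng_noise = np.random.default_rng(config.seeds.noise)
    rng_init = np.random.default_rng(config.seeds.init)

    # one seeded population per region, stacked block-diagonally so all
    # four independent subnetworks advance in a single vectorized step
    pops = [init_population(micro_params, rng_init) for _ in REGIONS]
    stacked = stack_populations(pops)
    n_per = micro_params.n_neurons
    ensemble = init_ensemble(run_params, n_nodes=connectome.n_nodes)
    L = connectome.laplacian
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    rec_steps = sorted(set(range(0, n_steps + 1, config.record_stride)) | {n_steps})
    n_rec = len(rec_steps)
    rec_index = {k: i for i, k in enumerate(rec_steps)}

    time = np.array(rec_steps, dtype=float) * dt
    v_rec = np.empty((4, n_rec))
    cur_rec = {region: np.zeros((2, n_rec)) for region in REGIONS}
    spike_times: dict = {region: ([], []) for region in REGIONS}
    noise_on = config.noise.enabled
    sigma = np.asarray(config.noise.sigma, dtype=float)
    sqrt_dt = np.sqrt(dt)

    def record(i_rec: int, avg: dict | None) -> None:
        v_rec[:, i_rec] = ensemble.v[:4]
        if config.record_currents and avg is not None:
            for region in REGIONS:
                cur_rec[region][:, i_rec] = avg[region]

    record(0, None)
    dbs_on = config.dbs.enabled
    for k in range(n_steps):
        t = k * dt
        spiked = step_population(stacked, micro_params, dt, rng_micro)
        I_E_p = (stacked.g_E * (micro_params.E_E - stacked.V)).reshape(4, n_per)
        I_I_p = (stacked.g_I * (micro_params.E_I - stacked.V)).reshape(4, n_per)
        I_E_p = I_E_p.mean(axis=1)
        I_I_p = I_I_p.mean(axis=1)
        avg = {region: (I_E_p[i], I_I_p[i]) for i, region in enumerate(REGIONS)}
        if config.record_rasters and np.any(spiked):
            ids = np.flatnonzero(spiked)
            for i in ids:
                region = REGIONS[i // n_per]
                spike_times[region][0].append(int(i % n_per))
                spike_times[region][1].append(t + dt)
        if dbs_on:
            stim = {region: stage_stimulus(region, t, config.dbs)
                    for region in ("STN", "GPi")}
        else:
            stim = _NO_STIM
        try:
            dv, gate_derivs, syn_derivs = regional_rhs(
                ensemble, L, avg, stim, t, run_params
            )
            v_new = euler_step(ensemble.v, dv, dt)
        except IntegrationError as err:
            raise IntegrationError(
                f"macro integration failed at step {k} (t = {t:.2f} ms): {err}",
                component=err.component, step=k,
            ) from err
        if noise_on:
            dW = rng_noise.normal(0.0, sqrt_dt, size=4)
            v_new[:4] = v_new[:4] + sigma * dW
        ensemble.v = v_new
        for region in REGIONS:
            g = ensemble.gates[region]
            derivs = gate_derivs[region]
            for name in g:
                g[name] += derivs[name] * dt
        for name in ensemble.syn:
            ensemble.syn[name] += syn_derivs[name] * dt
        if (k + 1) in rec_index:
            record(rec_index[k + 1], avg)
        if (k + 1) % 100_000 == 0:
            logger.info("step %d / %d (t = %.1f ms)", k + 1, n_steps, t + dt)

    spikes = {
        region: np.column_stack([
            np.asarray(ids, dtype=float),
            np.asarray(ts, dtype=float),
        ]) if ids else np.empty((0, 2))
        for region, (ids, ts) in spike_times.items()
    }
    meta = {
        "version": __version__,
        "dt": dt,
        "duration": config.duration,
        "n_steps": n_steps,
        "record_stride": config.record_stride,
        "pd": config.pd,
        "dbs": asdict(config.dbs),
        "noise": asdict(config.noise),
        "seeds": asdict(config.seeds),
        "n_micro": config.n_micro,
        "n_nodes": connectome.n_nodes,
        "config_hash": config.config_hash(),
    }
    return SimResult(time=time, v_regions=v_rec, spikes=spikes,
                     avg_currents=cur_rec, meta=meta)
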