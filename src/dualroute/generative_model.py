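"""Neural-mass forward model: source dynamics and the synthetic MEG lead field.

Each source in a :class:`~dualroute.model_space.NetworkModel` is a
three-subpopulation convolution-style neural mass (spiny stellate cells,
pyramidal cells, inhibitory interneurons).  Every synaptic channel is a
critically damped second-order kernel

    x'' = (H/tau) * inflow - (2/tau) * x' - x / tau**2

driven by sigmoid-transformed firing of afferent populations.  Extrinsic
forward connections target the stellate population; backward connections
target the pyramidal and inhibitory populations; intrinsic couplings
``gamma_1..gamma_4`` close the within-source loops.  The sigmoid is centred
so that the resting state (all states zero) is an exact fixed point:
``S(v) = 1/(1+exp(-r(v-v0))) - 1/(1+exp(r*v0))``.

Conduction delays (intrinsic and per-connection) are handled by history
lookup with linear interpolation between integration steps; integration is
fixed-step classical Runge-Kutta (RK4).  The model output per source is the
pyramidal depolarization ``v = x_e - x_i`` scaled by a per-region output
gain, which stands in for the effective dipole moment of the source.

Sensors live on the upper half of a unit sphere; sources sit inside it at a
region-specific eccentricity (1 = superficial).  The synthetic lead field
uses a dipole-in-a-sphere-flavoured gain — a tangential-dipole angular
pattern, inverse-cube distance fall-off and an explicit radial attenuation
``eccentricity**depth_power`` — so that sensitivity to deep structures
(amygdala, hippocampus, colliculus, thalamus) is realistically reduced
relative to superficial cortex.  It is a stand-in geometry, not a head
model; only orderings derived from it are meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_space import NetworkModel, REGION_INFO

__all__ = [
    "NeuralMassParams",
    "StimulusInput",
    "SourceTimeSeries",
    "SensorGeometry",
    "LeadField",
    "SimulationError",
    "CompiledModel",
    "default_params",
    "simulate_sources",
    "default_geometry",
    "build_lead_field",
    "relative_sensitivity",
    "project_to_sensors",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
]


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusInput:
    """Gamma-bump exogenous drive delivered to the input (MGB) nodes.

    ``u(t) = amplitude * s**k * exp(k*(1-s))`` with ``s=(t-onset)/(peak-onset)``
    and shape ``k = ((peak-onset)/dispersion)**2``; it peaks at ``peak_ms``
    with value ``amplitude`` and has width ~``dispersion_ms``.
    """

    onset_ms: float = 0.0
    peak_ms: float = 16.0
    dispersion_ms: float = 8.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.peak_ms > self.onset_ms:
            raise ValueError("stimulus peak_ms must exceed onset_ms")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if self.dispersion_ms <= 0:
            raise ValueError("stimulus dispersion_ms must be > 0")

    def waveform(self, t_ms: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        s = (t - self.onset_ms) / (self.peak_ms - self.onset_ms)
        k = ((self.peak_ms - self.onset_ms) / self.dispersion_ms) ** 2
        out = np.zeros_like(s)
        pos = s > 0
        out[pos] = self.amplitude * np.exp(
            k * (np.log(s[pos]) + 1.0 - s[pos])
        )
        return out


@dataclass
class NeuralMassParams:
    """All dynamical constants and free parameters of one network's masses.

    Synaptic gains ``H_e``/``H_i`` (mV) and time constants ``tau_e``/``tau_i``
    (ms) follow common evoked-response model defaults; ``gamma_1..gamma_4``
    are the intrinsic coupling strengths; ``r``/``v0`` parametrise the firing
    sigmoid.  ``log_gain`` holds one log-multiplier per extrinsic connection
    (keyed like ``ConnectionSpec.key``), applied on top of the
    ``forward_base``/``backward_base`` coupling strengths.
    ``output_log_gain`` holds one log output-gain per region.
    """

    H_e: float = 4.0
    H_i: float = 32.0
    tau_e: float = 4.0
    tau_i: float = 16.0
    gamma_1: float = 50.0
    gamma_2: float = 40.0
    gamma_3: float = 12.0
    gamma_4: float = 12.0
    r: float = 0.56
    v0: float = 6.0
    firing_scale: float = 0.012
    intrinsic_delay_ms: float = 2.0
    forward_base: float = 64.0
    backward_base: float = 32.0
    input_base: float = 1.0
    log_gain: dict = field(default_factory=dict)
    output_log_gain: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.intrinsic_delay_ms < 0:
            raise ValueError("delays must be >= 0")

    def copy(self) -> "NeuralMassParams":
        return replace(
            self,
            log_gain=dict(self.log_gain),
            output_log_gain=dict(self.output_log_gain),
        )


def default_params(model: NetworkModel) -> NeuralMassParams:
    """Parameters at prior expectations: every log-gain at its prior mean."""
    p = NeuralMassParams()
    p.log_gain = {c.key: c.prior_log_gain_mean for c in model.connections}
    p.output_log_gain = {n.region: 0.0 for n in model.nodes}
    return p


@dataclass
class SourceTimeSeries:
    node_labels: tuple
    times_ms: np.ndarray
    values: np.ndarray  # nodes x time, pyramidal depolarization (mV)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_labels), self.times_ms.size):
            raise ValueError("values must be nodes x time")
        dt = np.diff(self.times_ms)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite source values")


# ---------------------------------------------------------------------------
# compiled batched simulator
# ---------------------------------------------------------------------------

_SIGMOID_STATES = 8  # 4 second-order synaptic channels per source


class CompiledModel:
    """A :class:`NetworkModel` lowered to index arrays for batched RK4 runs.

    ``run`` integrates ``B`` parameter vectors simultaneously (one batch row
    per vector), which is what makes finite-difference Jacobians affordable
    during inversion.
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        self.labels = list(model.labels)
        self.n = len(self.labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        self.con_keys = [c.key for c in model.connections]
        self.ncon = len(self.con_keys)
        self.con_src = np.array(
            [idx[c.source_label] for c in model.connections], dtype=int
        )
        self.con_tgt = np.array(
            [idx[c.target_label] for c in model.connections], dtype=int
        )
        self.con_fwd = np.array(
            [c.ctype == "forward" for c in model.connections], dtype=bool
        )
        self.con_delay = np.array(
            [c.delay_ms for c in model.connections], dtype=float
        )
        self.input_mask = np.array(
            [n.is_input for n in model.nodes], dtype=float
        )
        self.regions = [n.region for n in model.nodes]

    # -- parameter resolution -------------------------------------------
    def gain_vector(self, params: NeuralMassParams) -> np.ndarray:
        try:
            return np.array(
                [params.log_gain[k] for k in self.con_keys], dtype=float
            )
        except KeyError as exc:
            raise SimulationError(
                f"params missing log_gain for connection {exc.args[0]}"
            ) from exc

    def output_gain_vector(self, params: NeuralMassParams) -> np.ndarray:
        return np.array(
            [params.output_log_gain.get(reg, 0.0) for reg in self.regions],
            dtype=float,
        )

    # -- integration -----------------------------------------------------
    def run(
        self,
        params: NeuralMassParams,
        stimulus: StimulusInput,
        t_end_ms: float,
        dt_ms: float = 1.0,
        log_gains: np.ndarray | None = None,
        amp_scale: np.ndarray | None = None,
        peak_scale: np.ndarray | None = None,
        output_log_gain: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate and return ``(times_ms, outputs)``, outputs ``(B, n, T)``.

        ``log_gains`` (B, ncon), ``amp_scale``/``peak_scale`` (B,) log-space
        multipliers on the stimulus amplitude and peak latency, and
        ``output_log_gain`` (B, n) override the corresponding entries of
        ``params``/``stimulus`` per batch row; all default to a single row
        taken from ``params``.
        """
        if log_gains is None:
            log_gains = self.gain_vector(params)[None, :]
        log_gains = np.atleast_2d(np.asarray(log_gains, dtype=float))
        B = log_gains.shape[0]
        if log_gains.shape[1] != self.ncon:
            raise SimulationError("log_gains has wrong number of connections")
        amp = stimulus.amplitude * np.exp(
            np.zeros(B) if amp_scale is None else np.asarray(amp_scale)
        )
        peak = (
            stimulus.onset_ms
            + (stimulus.peak_ms - stimulus.onset_ms)
            * np.exp(np.zeros(B) if peak_scale is None else np.asarray(peak_scale))
        )
        if output_log_gain is None:
            out_gain = np.exp(
                np.broadcast_to(self.output_gain_vector(params), (B, self.n))
            )
        else:
            out_gain = np.exp(np.atleast_2d(output_log_gain))

        n = self.n
        dt = float(dt_ms)
        nsteps = int(round(t_end_ms / dt))
        times = np.arange(nsteps + 1) * dt
        # history lookups must never reach ahead of the current step
        positive_delays = [d for d in self.con_delay if d > 0]
        if params.intrinsic_delay_ms > 0:
            positive_delays.append(params.intrinsic_delay_ms)
        if positive_delays and min(positive_delays) < dt:
            raise SimulationError(
                f"integration step {dt} ms exceeds the shortest conduction "
                f"delay {min(positive_delays)} ms; reduce dt_ms"
            )

        # per-connection strengths (B, ncon)
        base = np.where(self.con_fwd, params.forward_base, params.backward_base)
        strength = base[None, :] * np.exp(log_gains)
        # delay groups: connections sharing a delay are gathered together;
        # each group carries 0/1 scatter matrices (ncon_sel x n) so the
        # inflow accumulation is a single matmul per group
        delay_groups = []
        for d in np.unique(self.con_delay):
            sel = np.where(self.con_delay == d)[0]
            scat_f = np.zeros((sel.size, n))
            scat_b = np.zeros((sel.size, n))
            for j, c in enumerate(sel):
                (scat_f if self.con_fwd[c] else scat_b)[j, self.con_tgt[c]] = 1.0
            delay_groups.append((float(d), sel, scat_f, scat_b))

        He, Hi = params.H_e, params.H_i
        te, ti = params.tau_e, params.tau_i
        g1, g2, g3, g4 = (
            params.gamma_1,
            params.gamma_2,
            params.gamma_3,
            params.gamma_4,
        )
        r, v0 = params.r, params.v0
        smax = params.firing_scale
        s0 = 1.0 / (1.0 + np.exp(r * v0))
        d_int = params.intrinsic_delay_ms

        def sigm(v):
            # firing_scale expresses population output in rate units per ms,
            # keeping gamma values of O(10) in the linearly stable regime
            return smax * (1.0 / (1.0 + np.exp(-r * (v - v0))) - s0)

        # history of sigmoid outputs at grid points: (nsteps+1, 3, B, n)
        hist = np.zeros((nsteps + 1, 3, B, n))

        def hist_at(t_query: float) -> np.ndarray:
            """Linear interpolation into the sigmoid history (3, B, n)."""
            if t_query <= 0.0:
                return np.zeros((3, B, n))
            q = t_query / dt
            i0 = int(q)
            frac = q - i0
            if frac == 0.0:
                return hist[i0]
            return (1.0 - frac) * hist[i0] + frac * hist[i0 + 1]

        # stimulus drive per batch row at arbitrary time
        k_shape = ((stimulus.peak_ms - stimulus.onset_ms) / stimulus.dispersion_ms) ** 2

        def drive(t_query: float) -> np.ndarray:
            s = (t_query - stimulus.onset_ms) / (peak - stimulus.onset_ms)
            out = np.zeros(B)
            pos = s > 0
            out[pos] = amp[pos] * np.exp(
                k_shape * (np.log(s[pos]) + 1.0 - s[pos])
            )
            return out

        inv_te2 = 1.0 / te**2
        inv_ti2 = 1.0 / ti**2

        def extrinsic_inflows(t_query: float) -> tuple[np.ndarray, np.ndarray]:
            fwd = np.zeros((B, n))
            bwd = np.zeros((B, n))
            for d, sel, scat_f, scat_b in delay_groups:
                sv = hist_at(t_query - d)[0]  # (B, n) delayed pyramidal rate
                contrib = strength[:, sel] * sv[:, self.con_src[sel]]
                fwd += contrib @ scat_f
                bwd += contrib @ scat_b
            return fwd, bwd

        def stage_inputs(t_query: float):
            """Delayed/exogenous quantities at one stage time (state-free)."""
            if d_int > 0:
                h = hist_at(t_query - d_int)
                intr = (h[0], h[1], h[2])
            else:
                intr = None
            fwd, bwd = extrinsic_inflows(t_query)
            u = drive(t_query)[:, None] * self.input_mask[None, :]
            return intr, fwd, bwd, u

        def deriv(y: np.ndarray, pre) -> np.ndarray:
            x1, x1d = y[:, 0], y[:, 1]
            x2, x2d = y[:, 2], y[:, 3]
            x3, x3d = y[:, 4], y[:, 5]
            x7, x7d = y[:, 6], y[:, 7]
            intr, fwd, bwd, u = pre
            if intr is not None:
                sv, s1, s7 = intr
            else:
                sv = sigm(x2 - x3)
                s1 = sigm(x1)
                s7 = sigm(x7)
            inflow1 = g1 * sv + fwd + params.input_base * u
            inflow2 = g2 * s1 + bwd
            inflow3 = g3 * sv + bwd
            inflow4 = g4 * s7
            dy = np.empty_like(y)
            dy[:, 0] = x1d
            dy[:, 1] = (He / te) * inflow1 - 2.0 * x1d / te - x1 * inv_te2
            dy[:, 2] = x2d
            dy[:, 3] = (He / te) * inflow2 - 2.0 * x2d / te - x2 * inv_te2
            dy[:, 4] = x3d
            dy[:, 5] = (Hi / ti) * inflow4 - 2.0 * x3d / ti - x3 * inv_ti2
            dy[:, 6] = x7d
            dy[:, 7] = (He / te) * inflow3 - 2.0 * x7d / te - x7 * inv_te2
            return dy

        y = np.zeros((B, _SIGMOID_STATES, n))
        out = np.zeros((B, n, nsteps + 1))
        for k in range(nsteps):
            t = k * dt
            pre_0 = stage_inputs(t)
            pre_h = stage_inputs(t + 0.5 * dt)
            pre_1 = stage_inputs(t + dt)
            k1 = deriv(y, pre_0)
            k2 = deriv(y + 0.5 * dt * k1, pre_h)
            k3 = deriv(y + 0.5 * dt * k2, pre_h)
            k4 = deriv(y + dt * k3, pre_1)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(y)):
                bad = np.argwhere(~np.isfinite(y))
                node = self.labels[int(bad[0, 2])]
                raise SimulationError(
                    f"unstable integration: non-finite state at node {node}, "
                    f"t={t + dt:.1f} ms"
                )
            v = y[:, 2] - y[:, 4]
            hist[k + 1, 0] = sigm(v)
            hist[k + 1, 1] = sigm(y[:, 0])
            hist[k + 1, 2] = sigm(y[:, 6])
            out[:, :, k + 1] = v
        return times, out * out_gain[:, :, None]


def simulate_sources(
    model: NetworkModel,
    params: NeuralMassParams,
    stimulus: StimulusInput,
    times_ms: np.ndarray,
    dt_ms: float = 1.0,
    compiled: CompiledModel | None = None,
) -> SourceTimeSeries:
    """Integrate the network and sample pyramidal depolarization at ``times_ms``.

    The internal integration step is ``dt_ms`` (default 1 ms); requested
    output times are linearly interpolated from the integration grid, so a
    coarser observation grid (e.g. 4 ms) reuses the same dynamics.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.ndim != 1 or times_ms.size < 2:
        raise ValueError("times_ms must be a 1-D grid with >= 2 points")
    if times_ms[0] < 0:
        raise ValueError("times_ms must start at or after stimulus onset 0")
    cm = compiled if compiled is not None else CompiledModel(model)
    grid, out = cm.run(params, stimulus, t_end_ms=float(times_ms[-1]), dt_ms=dt_ms)
    vals = _sample_grid(grid, out[0], times_ms)
    return SourceTimeSeries(
        node_labels=tuple(cm.labels), times_ms=times_ms, values=vals
    )


def _sample_grid(
    grid: np.ndarray, values: np.ndarray, times_ms: np.ndarray
) -> np.ndarray:
    """Sample (..., len(grid)) values at times_ms; exact when on-grid."""
    dt = grid[1] - grid[0]
    q = times_ms / dt
    qi = np.rint(q).astype(int)
    if np.allclose(q, qi, atol=1e-9) and qi.max() < grid.size:
        return values[..., qi]
    flat = values.reshape(-1, grid.size)
    res = np.stack([np.interp(times_ms, grid, row) for row in flat])
    return res.reshape(values.shape[:-1] + (times_ms.size,))


# ---------------------------------------------------------------------------
# sensor geometry and lead field
# ---------------------------------------------------------------------------

# canonical angular direction per region (x = right, y = anterior, z = up);
# the left-hemisphere direction mirrors the sign of x
_REGION_DIRECTION = {
    "MGB": (0.25, -0.15, 0.15),
    "A1": (0.95, -0.05, 0.35),
    "A1X": (0.92, -0.25, 0.38),
    "AMY": (0.75, 0.45, 0.05),
    "HIPP": (0.80, 0.10, 0.05),
    "IC": (0.20, -0.40, 0.05),
    "STG": (0.95, 0.15, 0.40),
}


@dataclass
class SensorGeometry:
    channel_labels: tuple
    channel_pos: np.ndarray  # (nch, 3) on the unit sphere, z > 0
    node_labels: tuple
    node_pos: np.ndarray  # (n, 3) inside the sphere
    node_ecc: np.ndarray  # (n,) eccentricity in (0, 1]
    node_ori: np.ndarray  # (n, 3) tangential unit orientation

    def __post_init__(self) -> None:
        self.channel_pos = np.asarray(self.channel_pos, dtype=float)
        self.node_pos = np.asarray(self.node_pos, dtype=float)
        self.node_ecc = np.asarray(self.node_ecc, dtype=float)
        self.node_ori = np.asarray(self.node_ori, dtype=float)
        if np.any(self.node_ecc > 1.0) or np.any(self.node_ecc < 0.0):
            raise ValueError("eccentricities must lie in [0, 1]")


@dataclass
class LeadField:
    channel_labels: tuple
    node_labels: tuple
    gain: np.ndarray  # (nch, n), fT per mV (arbitrary units)
    node_regions: tuple = ()

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.shape != (len(self.channel_labels), len(self.node_labels)):
            raise ValueError("gain must be channels x nodes")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            dead = [l for l, g in zip(self.node_labels, norms) if g == 0]
            raise ValueError(f"all-zero lead-field column(s): {dead}")

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.gain, axis=0)


#: helmet radius relative to the unit head sphere (sensor standoff)
SENSOR_RADIUS = 1.25


def _fibonacci_hemisphere(n: int, radius: float = SENSOR_RADIUS) -> np.ndarray:
    """n roughly equidistant helmet points over the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n  # z in (0, 1): upper hemisphere only
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def default_geometry(
    node_labels: list[str] | tuple,
    n_channels: int = 64,
    eccentricities: dict | None = None,
) -> SensorGeometry:
    """Helmet-style sensor array plus packaged source positions.

    Node labels must be of the form ``REGION_H`` (e.g. ``AMY_L``); positions
    are the packaged per-region directions scaled by the region eccentricity
    (overridable via ``eccentricities``), orientations tangential.
    """
    ecc_table = {reg: e for reg, (_, e) in REGION_INFO.items()}
    if eccentricities:
        ecc_table.update(eccentricities)
    pos, ecc, ori = [], [], []
    for lab in node_labels:
        region, _, hemi = lab.rpartition("_")
        if region not in _REGION_DIRECTION or hemi not in ("L", "R"):
            raise ValueError(f"cannot place node {lab!r}: unknown region")
        d = np.array(_REGION_DIRECTION[region], dtype=float)
        if hemi == "L":
            d = d * np.array([-1.0, 1.0, 1.0])
        d /= np.linalg.norm(d)
        e = ecc_table[region]
        pos.append(e * d)
        ecc.append(e)
        o = np.cross([0.0, 0.0, 1.0], d)
        o /= np.linalg.norm(o)
        ori.append(o)
    chans = _fibonacci_hemisphere(n_channels)
    return SensorGeometry(
        channel_labels=tuple(f"MEG{i:03d}" for i in range(n_channels)),
        channel_pos=chans,
        node_labels=tuple(node_labels),
        node_pos=np.array(pos),
        node_ecc=np.array(ecc),
        node_ori=np.array(ori),
    )


def build_lead_field(
    geometry: SensorGeometry,
    rng_seed: int = 0,
    depth_power: float = 1.0,
    distance_power: float = 2.0,
    orientation_jitter_deg: float = 5.0,
) -> LeadField:
    """Deterministic synthetic lead field for a geometry.

    Gain of node j at channel i:
    ``ecc_j**depth_power * ((c_i - p_j) . o_j) / |c_i - p_j|**(distance_power + 1)``
    — a tangential-dipole angular pattern with inverse-square field decay
    (the numerator contributes one distance power) and explicit radial
    (depth) attenuation, ``depth_power >= 1``.  The seed only controls a
    small orientation jitter emulating anatomical variability.  The matrix
    is normalised so its largest column norm is 1.
    """
    if depth_power < 1.0:
        raise ValueError("depth_power must be >= 1")
    if np.any(geometry.node_ecc <= 0.0):
        silent = [
            l
            for l, e in zip(geometry.node_labels, geometry.node_ecc)
            if e <= 0
        ]
        raise ValueError(
            f"node(s) at sphere centre are silent sources: {silent}"
        )
    rng = np.random.default_rng(rng_seed)
    nch = geometry.channel_pos.shape[0]
    n = len(geometry.node_labels)
    gain = np.empty((nch, n))
    for j in range(n):
        p = geometry.node_pos[j]
        o = geometry.node_ori[j]
        # jitter the orientation within the tangential plane
        ang = np.deg2rad(orientation_jitter_deg) * rng.standard_normal()
        axis = p / np.linalg.norm(p)
        o = (
            o * np.cos(ang)
            + np.cross(axis, o) * np.sin(ang)
            + axis * np.dot(axis, o) * (1 - np.cos(ang))
        )
        diff = geometry.channel_pos - p[None, :]
        dist = np.linalg.norm(diff, axis=1)
        gain[:, j] = (
            geometry.node_ecc[j] ** depth_power
            * (diff @ o)
            / dist ** (distance_power + 1.0)
        )
    gain /= np.abs(np.linalg.norm(gain, axis=0)).max()
    regions = tuple(lab.rpartition("_")[0] for lab in geometry.node_labels)
    return LeadField(
        channel_labels=geometry.channel_labels,
        node_labels=geometry.node_labels,
        gain=gain,
        node_regions=regions,
    )


def relative_sensitivity(
    leadfield: LeadField, target_region: str, reference_region: str = "A1"
) -> float:
    """Sensor sensitivity to a region relative to A1, in percent.

    ``100 * RMS(target column norms) / RMS(reference column norms)``; the
    RMS pools the bilateral columns of each region.  Scale-invariant.
    """
    norms = leadfield.column_norms()
    regions = leadfield.node_regions or tuple(
        lab.rpartition("_")[0] for lab in leadfield.node_labels
    )

    def region_rms(region: str) -> float:
        vals = [g for g, r in zip(norms, regions) if r == region]
        if not vals:
            raise ValueError(f"region {region!r} not present in lead field")
        return float(np.sqrt(np.mean(np.square(vals))))

    return 100.0 * region_rms(target_region) / region_rms(reference_region)


def project_to_sensors(
    sources: SourceTimeSeries, leadfield: LeadField
) -> np.ndarray:
    """Linear observation ``y(t) = L s(t)`` -> (channels, time)."""
    if tuple(sources.node_labels) != tuple(leadfield.node_labels):
        raise ValueError(
            "node labels of sources and lead field do not match: "
            f"{sources.node_labels} vs {leadfield.node_labels}"
        )
    return leadfield.gain @ sources.values


# ---------------------------------------------------------------------------
# TSV + JSON interchange
# ---------------------------------------------------------------------------

def write_timeseries_tsv(path, times_ms, values, labels) -> None:
    df = pd.DataFrame(
        np.column_stack([times_ms, np.asarray(values).T]),
        columns=["time_ms", *labels],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path) -> tuple[np.ndarray, np.ndarray, tuple]:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_ms":
        raise ValueError(f"{path}: first column must be time_ms")
    labels = tuple(df.columns[1:])
    return df["time_ms"].to_numpy(), df[list(labels)].to_numpy().T, labels


def write_leadfield(leadfield: LeadField, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        leadfield.gain,
        index=list(leadfield.channel_labels),
        columns=list(leadfield.node_labels),
    ).to_csv(prefix.with_suffix(".tsv"), sep="\t", float_format="%.10g")
    meta = {
        "channel_labels": list(leadfield.channel_labels),
        "node_labels": list(leadfield.node_labels),
        "node_regions": list(leadfield.node_regions),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_leadfield(prefix) -> LeadField:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    return LeadField(
        channel_labels=tuple(meta["channel_labels"]),
        node_labels=tuple(meta["node_labels"]),
        gain=df.to_numpy(),
        node_regions=tuple(meta["node_regions"]),
    )
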