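"""Variational-Laplace inversion of one network model on one data window.

Fits the forward model ``g(theta)`` (neural-mass simulation projected
through the lead field and reduced to principal spatial modes) to observed
sensor data ``y`` by maximising the Laplace free energy

    F = -(lam/2)||y - g(theta)||^2 + (N/2) ln lam - (N/2) ln 2*pi
        - (1/2)(theta-theta0)' S0^-1 (theta-theta0) - (1/2) ln|S0|
        + (1/2) ln|S_theta|

over parameters ``theta`` (all in log-space) and the noise precision
``lam``.  ``S_theta = (lam J'J + S0^-1)^-1`` with ``J`` the prediction
Jacobian by central finite differences; updates are Gauss-Newton with
Levenberg damping; ``lam`` is re-estimated each outer iteration from its
stationary condition ``lam = N / ||y - g||^2``.  Candidate steps that would
lower F are rejected with increased damping, so the recorded F trace is
non-decreasing by construction, and F at convergence approximates the log
model evidence (accuracy minus complexity) used for model comparison.

Estimable parameters are deliberately few: per-connection log-gains, the
stimulus log-amplitude and log-peak-latency, and one output log-gain per
region; every biophysical constant stays fixed at its default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_space import NetworkModel
from .generative_model import (
    CompiledModel,
    LeadField,
    NeuralMassParams,
    SimulationError,
    SourceTimeSeries,
    StimulusInput,
    default_params,
    simulate_sources,
    _sample_grid,
)

__all__ = [
    "PriorSpec",
    "DataWindow",
    "InversionSettings",
    "InversionResult",
    "InversionError",
    "build_priors",
    "extract_window",
    "invert",
    "accuracy",
    "reconstruct_sources",
]

WINDOW_MIN_MS = 50
WINDOW_MAX_MS = 250
WINDOW_STEP_MS = 10


class InversionError(RuntimeError):
    pass


@dataclass(frozen=True)
class DataWindow:
    """Increasing peristimulus window [0, T]; T on the 50..250 ms decade grid."""

    endpoint_ms: int

    def __post_init__(self) -> None:
        T = self.endpoint_ms
        if not (WINDOW_MIN_MS <= T <= WINDOW_MAX_MS) or T % WINDOW_STEP_MS:
            raise ValueError(
                f"window endpoint {T} ms invalid: must lie in "
                f"[{WINDOW_MIN_MS}, {WINDOW_MAX_MS}] and be a multiple of "
                f"{WINDOW_STEP_MS}"
            )

    def select(self, times_ms: np.ndarray) -> np.ndarray:
        """Boolean mask of samples with 0 <= t <= T (inclusive)."""
        times_ms = np.asarray(times_ms)
        return (times_ms >= 0) & (times_ms <= self.endpoint_ms + 1e-9)


def extract_window(dataset, subject, condition: str, T: int) -> np.ndarray:
    """Contiguous samples 0 <= t <= T of one subject-condition average."""
    win = DataWindow(T)
    dt = dataset.dt_ms
    needed = int(np.floor(T / dt)) + 1  # inclusive selection 0 <= t <= T
    have = int(win.select(dataset.times_ms).sum())
    if needed > dataset.times_ms.size:
        raise ValueError(
            f"window endpoint {T} ms beyond data range "
            f"[0, {dataset.times_ms[-1]:g}] ms at dt={dt:g}"
        )
    assert have == min(needed, dataset.times_ms.size)
    mat = dataset.get(subject, condition)
    return mat[:, win.select(dataset.times_ms)]


@dataclass
class PriorSpec:
    """Gaussian priors over the estimable parameter vector.

    Zero prior variance pins a parameter at its mean (it is excluded from
    the search).  The noise-precision hyperprior is a Gamma(a0, b0); the
    default (a0=1, b0=0) is flat in ``ln lam`` and reduces the stationary
    update to ``lam = N / ||r||^2``.
    """

    names: tuple
    mean: np.ndarray
    variance: np.ndarray
    noise_a0: float = 1.0
    noise_b0: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape or self.mean.ndim != 1:
            raise ValueError("prior mean/variance must be matching vectors")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be >= 0")
        if len(self.names) != self.mean.size:
            raise ValueError("one name per parameter required")


#: prior variances by parameter role
PRIOR_VAR_CONNECTION = 1.0 / 16.0
PRIOR_VAR_INPUT_AMP = 1.0 / 4.0
PRIOR_VAR_INPUT_PEAK = 1.0 / 16.0
PRIOR_VAR_OUTPUT_GAIN = 1.0 / 16.0


def build_priors(model: NetworkModel) -> PriorSpec:
    """Default priors: connection gains from the model document, input
    amplitude/latency, one output gain per region (log-space, mean 0)."""
    names: list[str] = []
    mean: list[float] = []
    var: list[float] = []
    for c in model.connections:
        names.append(f"g:{c.source_label}->{c.target_label}:{c.ctype}")
        mean.append(c.prior_log_gain_mean)
        var.append(c.prior_log_gain_variance)
    names += ["input_amp", "input_peak"]
    mean += [0.0, 0.0]
    var += [PRIOR_VAR_INPUT_AMP, PRIOR_VAR_INPUT_PEAK]
    for region in dict.fromkeys(n.region for n in model.nodes):
        names.append(f"out:{region}")
        mean.append(0.0)
        var.append(PRIOR_VAR_OUTPUT_GAIN)
    return PriorSpec(tuple(names), np.array(mean), np.array(var))


@dataclass
class InversionSettings:
    dt_ms: float = 1.0
    n_modes: int = 8
    tol: float = 0.01
    max_iter: int = 64
    fd_step: float = 1e-3
    max_step_retries: int = 6
    damping_init: float = 1.0
    damping_up: float = 8.0
    damping_down: float = 0.5
    lambda_max: float = 1e12
    stimulus: StimulusInput = field(default_factory=StimulusInput)


@dataclass
class InversionResult:
    names: tuple
    posterior_mean: np.ndarray
    posterior_covariance: np.ndarray
    free_energy: float
    lambda_hat: float
    predicted: np.ndarray  # channels x time, back-projected from modes
    accuracy_r: float
    n_iterations: int
    converged: bool
    f_trace: np.ndarray
    model_id: str = ""
    window_ms: int | None = None

    def param(self, name: str) -> float:
        return float(self.posterior_mean[self.names.index(name)])


def accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation over all flattened channel x time entries."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have the same shape")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero-variance input to accuracy()")
    return float(np.corrcoef(p, o)[0, 1])


class _ForwardOperator:
    """Maps parameter-vector batches to predictions in spatial-mode space."""

    def __init__(
        self,
        model: NetworkModel,
        leadfield: LeadField,
        times_ms: np.ndarray,
        modes: np.ndarray,  # channels x m projection
        settings: InversionSettings,
    ):
        self.cm = CompiledModel(model)
        if tuple(leadfield.node_labels) != tuple(self.cm.labels):
            raise InversionError("lead field does not match model nodes")
        self.times_ms = np.asarray(times_ms, dtype=float)
        self.modes = modes
        self.settings = settings
        self.L_modes = modes.T @ leadfield.gain  # m x nodes
        self.ncon = self.cm.ncon
        # node -> region index for the output-gain block
        self.region_order = list(dict.fromkeys(self.cm.regions))
        self.node_region_idx = np.array(
            [self.region_order.index(r) for r in self.cm.regions]
        )
        self.n_params = self.ncon + 2 + len(self.region_order)

    def split(self, theta: np.ndarray):
        theta = np.atleast_2d(theta)
        ncon = self.ncon
        gains = theta[:, :ncon]
        amp = theta[:, ncon]
        peak = theta[:, ncon + 1]
        out = theta[:, ncon + 2 :][:, self.node_region_idx]
        return gains, amp, peak, out

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """(B, P) parameter batch -> (B, m, T) mode-space predictions."""
        gains, amp, peak, out = self.split(theta)
        grid, src = self.cm.run(
            default_params(self.cm.model),
            self.settings.stimulus,
            t_end_ms=float(self.times_ms[-1]),
            dt_ms=self.settings.dt_ms,
            log_gains=gains,
            amp_scale=amp,
            peak_scale=peak,
            output_log_gain=out,
        )
        src = _sample_grid(grid, src, self.times_ms)
        return np.einsum("mn,bnt->bmt", self.L_modes, src)


def _spatial_modes(data: np.ndarray, n_modes: int) -> np.ndarray:
    """Top left-singular vectors of the channel x time window."""
    u, s, _ = np.linalg.svd(data, full_matrices=False)
    m = min(n_modes, int((s > s[0] * 1e-10).sum()) or 1)
    return u[:, :m]


def invert(
    model: NetworkModel,
    data: np.ndarray,
    times_ms: np.ndarray,
    leadfield: LeadField,
    priors: PriorSpec | None = None,
    settings: InversionSettings | None = None,
) -> InversionResult:
    """Variational-Laplace fit of ``model`` to one channels x time window."""
    settings = settings or InversionSettings()
    priors = priors if priors is not None else build_priors(model)
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise InversionError("non-finite values in data window")
    modes = _spatial_modes(data, settings.n_modes)
    fwd = _ForwardOperator(model, leadfield, times_ms, modes, settings)
    if priors.mean.size != fwd.n_params:
        raise InversionError(
            f"priors carry {priors.mean.size} parameters, model expects "
            f"{fwd.n_params}"
        )
    y = (modes.T @ data).ravel()
    N = y.size

    free = priors.variance > 0
    if not np.any(free):
        raise InversionError("no free parameters (all prior variances zero)")
    ip0 = 1.0 / priors.variance[free]  # diagonal prior precision
    logdet_s0 = float(np.sum(np.log(priors.variance[free])))

    theta = priors.mean.copy()

    def predict_flat(th_batch: np.ndarray) -> np.ndarray:
        return fwd.predict(th_batch).reshape(th_batch.shape[0], -1)

    def jacobian(th: np.ndarray) -> np.ndarray:
        """Central differences over the free parameters: (N, P_free)."""
        h = settings.fd_step
        idx = np.where(free)[0]
        batch = np.repeat(th[None, :], 2 * idx.size, axis=0)
        for j, pi in enumerate(idx):
            batch[2 * j, pi] += h
            batch[2 * j + 1, pi] -= h
        preds = predict_flat(batch)
        return (preds[0::2] - preds[1::2]).T / (2.0 * h)

    def lam_update(rss: float) -> float:
        num = N / 2.0 + priors.noise_a0 - 1.0
        lam = num / max(rss / 2.0 + priors.noise_b0, 1e-300)
        return float(min(max(lam, 1e-12), settings.lambda_max))

    def free_energy(rss: float, lam: float, e: np.ndarray, J: np.ndarray):
        A = lam * (J.T @ J) + np.diag(ip0)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise InversionError("posterior precision not positive definite")
        F = (
            -0.5 * lam * rss
            + 0.5 * N * np.log(lam)
            - 0.5 * N * np.log(2.0 * np.pi)
            - 0.5 * float(e @ (ip0 * e))
            - 0.5 * logdet_s0
            - 0.5 * logdet_a  # ln|S_theta| = -ln|A|
        )
        if priors.noise_b0 > 0 or priors.noise_a0 != 1.0:
            F += (priors.noise_a0 - 1.0) * np.log(lam) - priors.noise_b0 * lam
        return float(F), A

    def evaluate(th: np.ndarray):
        pred = predict_flat(th[None, :])[0]
        r = y - pred
        rss = float(r @ r)
        lam = lam_update(rss)
        J = jacobian(th)
        e = (th - priors.mean)[free]
        F, A = free_energy(rss, lam, e, J)
        return {"theta": th, "pred": pred, "r": r, "rss": rss, "lam": lam,
                "J": J, "e": e, "F": F, "A": A}

    try:
        cur = evaluate(theta)
    except SimulationError as exc:
        raise InversionError(f"forward model failed at prior means: {exc}") from exc

    damping = settings.damping_init
    f_trace = [cur["F"]]
    converged = False
    n_small = 0
    it = 0
    for it in range(1, settings.max_iter + 1):
        accepted = False
        for _ in range(settings.max_step_retries + 1):
            # Gauss-Newton step with Levenberg damping on the free block
            A_damped = cur["A"] + damping * np.diag(np.diag(cur["A"]))
            grad = cur["lam"] * (cur["J"].T @ cur["r"]) - ip0 * cur["e"]
            try:
                step = np.linalg.solve(A_damped, grad)
            except np.linalg.LinAlgError as exc:
                raise InversionError(f"singular system in update: {exc}") from exc
            cand = cur["theta"].copy()
            cand[free] = cand[free] + step
            try:
                nxt = evaluate(cand)
            except SimulationError:
                damping *= settings.damping_up
                continue
            if nxt["F"] >= cur["F"]:
                accepted = True
                break
            damping *= settings.damping_up
        if not accepted:
            break
        dF = nxt["F"] - cur["F"]
        cur = nxt
        f_trace.append(cur["F"])
        damping = max(damping * settings.damping_down, 1e-8)
        n_small = n_small + 1 if dF < settings.tol else 0
        if n_small >= 3:
            converged = True
            break

    post_cov_free = np.linalg.inv(cur["A"])
    post_cov_free = 0.5 * (post_cov_free + post_cov_free.T)
    P = priors.mean.size
    post_cov = np.zeros((P, P))
    ix = np.ix_(np.where(free)[0], np.where(free)[0])
    post_cov[ix] = post_cov_free
    pred_modes = cur["pred"].reshape(modes.shape[1], -1)
    predicted = modes @ pred_modes
    return InversionResult(
        names=tuple(priors.names),
        posterior_mean=cur["theta"],
        posterior_covariance=post_cov,
        free_energy=cur["F"],
        lambda_hat=cur["lam"],
        predicted=predicted,
        accuracy_r=accuracy(predicted, data),
        n_iterations=it,
        converged=converged,
        f_trace=np.array(f_trace),
        model_id=model.model_id,
        window_ms=int(round(times_ms[-1])),
    )


def result_params(
    model: NetworkModel,
    result: InversionResult,
    base: StimulusInput | None = None,
) -> tuple[NeuralMassParams, StimulusInput]:
    """Posterior-mean parameters as simulator inputs.

    ``base`` must be the stimulus template used during the fit
    (``InversionSettings.stimulus``); the posterior amplitude/latency
    parameters are log-multipliers on it.
    """
    params = default_params(model)
    for c in model.connections:
        params.log_gain[c.key] = result.param(
            f"g:{c.source_label}->{c.target_label}:{c.ctype}"
        )
    for region in dict.fromkeys(n.region for n in model.nodes):
        params.output_log_gain[region] = result.param(f"out:{region}")
    base = base or StimulusInput()
    stim = StimulusInput(
        onset_ms=base.onset_ms,
        peak_ms=base.onset_ms
        + (base.peak_ms - base.onset_ms) * np.exp(result.param("input_peak")),
        dispersion_ms=base.dispersion_ms,
        amplitude=base.amplitude * np.exp(result.param("input_amp")),
    )
    return params, stim


def save_inversion_result(
    result: InversionResult, prefix, times_ms: np.ndarray | None = None
) -> None:
    """Serialize a fit: scalars + parameter table as JSON, predicted data
    and the free-energy trace as TSV next to it.

    ``times_ms`` labels the predicted-data columns (defaults to sample
    index when the window grid is not supplied).
    """
    import json
    from pathlib import Path

    from .generative_model import write_timeseries_tsv

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "model_id": result.model_id,
        "window_ms": result.window_ms,
        "free_energy": result.free_energy,
        "lambda_hat": result.lambda_hat,
        "accuracy_r": result.accuracy_r,
        "n_iterations": result.n_iterations,
        "converged": result.converged,
        "posterior": {
            name: {
                "mean": float(m),
                "variance": float(v),
            }
            for name, m, v in zip(
                result.names,
                result.posterior_mean,
                np.diag(result.posterior_covariance),
            )
        },
    }
    prefix.with_suffix(".json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    nt = result.predicted.shape[1]
    if times_ms is None:
        times_ms = np.arange(nt, dtype=float)
    write_timeseries_tsv(
        prefix.parent / f"{prefix.name}_predicted.tsv",
        times_ms,
        result.predicted,
        [f"ch{i:03d}" for i in range(result.predicted.shape[0])],
    )
    write_timeseries_tsv(
        prefix.parent / f"{prefix.name}_ftrace.tsv",
        np.arange(result.f_trace.size, dtype=float),
        result.f_trace[None, :],
        ["free_energy"],
    )


def load_inversion_summary(prefix) -> dict:
    import json
    from pathlib import Path

    return json.loads(Path(prefix).with_suffix(".json").read_text())


def reconstruct_sources(
    model: NetworkModel,
    result: InversionResult,
    times_ms: np.ndarray,
    dt_ms: float = 1.0,
    stimulus: StimulusInput | None = None,
) -> SourceTimeSeries:
    """Forward-simulate at the posterior means (the fitted source activity)."""
    params, stim = result_params(model, result, base=stimulus)
    return simulate_sources(model, params, stim, np.asarray(times_ms, float), dt_ms=dt_ms)
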