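"""Independent oracles used only by the test suite."""

import numpy as np
from scipy.special import logsumexp


def gibbs_rfx(
    log_evidence: np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 6000,
    burn_in: int = 1000,
    seed: int = 0,
) -> dict:
    """Gibbs sampler for the random-effects model-selection hierarchy.

    Alternates sampling per-subject model assignments
    ``z_n ~ Cat(softmax(l_n + ln x))`` and population frequencies
    ``x ~ Dir(alpha0 + counts)``.  Returns Monte Carlo estimates of the
    expected posterior model probabilities E[x] and the exceedance
    probabilities P(x_k > x_j for all j).

    The expected probabilities are Rao-Blackwellised: instead of averaging
    raw Dirichlet draws, the conditional mean ``(alpha0 + counts) / (sum
    alpha0 + n_subjects)`` is averaged over assignment samples, which cuts
    the Monte Carlo error substantially.
    """
    L = np.asarray(log_evidence, dtype=float)
    ns, nm = L.shape
    rng = np.random.default_rng(seed)
    x = np.full(nm, 1.0 / nm)
    xs = np.empty((n_samples, nm))
    cond_means = np.empty((n_samples, nm))
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (nm,))
    for it in range(burn_in + n_samples):
        logp = L + np.log(x)[None, :]
        logp -= logsumexp(logp, axis=1, keepdims=True)
        p = np.exp(logp)
        cum = np.cumsum(p, axis=1)
        u = rng.random(ns)[:, None]
        z = (u > cum).sum(axis=1)
        counts = np.bincount(z, minlength=nm)
        x = rng.dirichlet(a0 + counts)
        if it >= burn_in:
            xs[it - burn_in] = x
            cond_means[it - burn_in] = (a0 + counts) / (a0.sum() + ns)
    winners = np.argmax(xs, axis=1)
    return {
        "expected_prob": cond_means.mean(axis=0),
        "exceedance_prob": np.bincount(winners, minlength=nm) / n_samples,
    }
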