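"""Shared Monte-Carlo oracles for the DFE moment predictions."""

import numpy as np

from pivotdfe.dfe import SlopeDistributionSummary


def draw_param_set(rng):
    """Random slope-ensemble parameters with a known third moment,
    realized through a (possibly reflected) shifted-gamma slope family:
    for gamma(k, theta), var = k theta^2 and m3 = 2 k theta^3."""
    mu_b = rng.uniform(-1.0, 0.5)
    k = rng.uniform(0.5, 8.0)
    theta = rng.uniform(0.05, 0.4)
    sign = rng.choice([-1.0, 1.0])
    params = SlopeDistributionSummary(
        mu_b=mu_b, var_b=k * theta ** 2, gamma_b=sign * 2 * k * theta ** 3,
        var_eta=rng.uniform(0, 5e-4), var_xi=rng.uniform(0, 5e-4))

    def sample(n):
        return mu_b + sign * (rng.gamma(k, theta, size=n) - k * theta)

    return params, sample


def mc_moments(draws, n_batches=100):
    """Batch-mean Monte-Carlo moments (mean, variance, third central
    moment, skewness) with batch-based standard errors."""
    batches = draws.reshape(n_batches, -1)
    mu = batches.mean(axis=1)
    d = batches - batches.mean(axis=1, keepdims=True)
    m2 = (d ** 2).mean(axis=1)
    m3 = (d ** 3).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sk = np.where(m2 > 0, m3 / m2 ** 1.5, 0.0)
    out = {}
    for name, stat in (("mean", mu), ("var", m2), ("m3", m3), ("skew", sk)):
        out[name] = (float(stat.mean()),
                     float(stat.std(ddof=1) / np.sqrt(n_batches)))
    return out
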