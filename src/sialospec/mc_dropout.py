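"""Monte Carlo Dropout uncertainty estimation.

With dropout kept active at inference, T stochastic forward passes yield a
predictive distribution per spectrum:

    y_hat  = (1/T) * sum_t f_t(x)
    Var(y) = (1/T) * sum_t f_t(x)^2  -  y_hat^2      (population form)

The variance is the uncertainty score used by the refinement stage to flag
unreliable training spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral_data import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertaintyReport:
    spectrum_id: str
    y_hat: float
    var_y: float
    T: int


@dataclass
class LinearDropoutNet:
    """Single linear unit with input dropout: a closed-form reference model.

    Stochastic output is (mask * x) @ weights with mask ~ Bernoulli(1-p);
    deterministic output scales inputs by (1-p).  Every moment is exactly
    enumerable, which makes this the calibration oracle for the MCD
    estimator (e.g. weight 2, input 1, p=0.5: outcomes {0, 2}, mean 1,
    variance 1).
    """

    weights: np.ndarray
    dropout_rate: float
    trained: bool = True

    def forward_proba(self, X, stochastic: bool = False, rng=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if not stochastic or self.dropout_rate == 0.0:
            return (1.0 - self.dropout_rate) * (X @ w)
        if rng is None:
            raise ValueError("stochastic pass requires an rng")
        mask = (rng.random(X.shape) >= self.dropout_rate).astype(float)
        return (mask * X) @ w

    def enumerate_moments(self, x: np.ndarray) -> tuple[float, float]:
        """Exact mean and variance of the stochastic output for one input row,
        by exhaustive enumeration of all 2^d dropout masks."""
        x = np.asarray(x, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        d = x.size
        p = self.dropout_rate
        mean = 0.0
        second = 0.0
        for bits in range(2**d):
            mask = np.array([(bits >> i) & 1 for i in range(d)], dtype=float)
            prob = np.prod(np.where(mask == 1.0, 1.0 - p, p))
            out = float((mask * x) @ w)
            mean += prob * out
            second += prob * out * out
        return mean, second - mean**2


def mc_predict(net, data, T: int, seed: int) -> list[UncertaintyReport]:
    """T stochastic forward passes; reproducible from ``seed``.

    ``net`` is any model exposing ``forward_proba(X, stochastic, rng)`` and a
    ``trained`` flag; ``data`` is a SpectrumSet or a raw (n, d) matrix.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not getattr(net, "trained", False):
        raise RuntimeError("network has not been trained")
    if isinstance(data, SpectrumSet):
        X = data.intensities
        ids = data.spectrum_ids
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        ids = [f"x{i}" for i in range(X.shape[0])]

    rng = np.random.default_rng(seed)
    passes = np.empty((T, X.shape[0]))
    for t in range(T):
        passes[t] = np.asarray(net.forward_proba(X, stochastic=True, rng=rng), dtype=float)
    y_hat = passes.mean(axis=0)
    # population variance (1/T)*sum f^2 - y_hat^2, evaluated as the mean
    # squared deviation; degenerate (all-identical) pass sets, e.g. p=0,
    # give exactly zero instead of rounding dust
    var_y = ((passes - y_hat) ** 2).mean(axis=0)
    var_y[np.all(passes == passes[0], axis=0)] = 0.0
    n_clipped = int(np.sum(var_y < 0))
    if n_clipped:
        logger.debug("clipped %d negative MCD variances to 0", n_clipped)
    var_y = np.maximum(var_y, 0.0)
    return [
        UncertaintyReport(spectrum_id=s, y_hat=float(m), var_y=float(v), T=T)
        for s, m, v in zip(ids, y_hat, var_y)
    ]


def rank_by_uncertainty(
    reports: list[UncertaintyReport], group_by: dict[str, str]
) -> dict[str, list[str]]:
    """Per-donor spectrum ids sorted ascending by Var(y), spectrum_id tiebreak."""
    by_id = {r.spectrum_id: r for r in reports}
    donors: dict[str, list[str]] = {}
    for sid, donor in group_by.items():
        if sid not in by_id:
            raise KeyError(f"no uncertainty report for spectrum {sid!r}")
        donors.setdefault(donor, []).append(sid)
    return {
        donor: sorted(ids, key=lambda s: (by_id[s].var_y, s))
        for donor, ids in donors.items()
    }
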