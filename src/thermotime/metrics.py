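"""Goodness-of-fit statistics for paired observed/simulated series.

Sign convention: errors are simulated minus observed, so a negative mean
error means the model runs cooler than the observations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["me", "mae", "rmsd", "r2", "nse", "mia", "compute_all", "METRIC_NAMES"]

METRIC_NAMES = ("me", "mae", "rmsd", "mia", "r2", "nse")


def _paired(observed, simulated):
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated must have equal shape")
    mask = np.isfinite(obs) & np.isfinite(sim)
    obs, sim = obs[mask], sim[mask]
    if obs.size < 2:
        raise ValueError("need at least two finite pairs")
    return obs, sim


def _require_varying(obs):
    if np.ptp(obs) == 0.0:
        raise ValueError("observed series is constant; statistic undefined")


def me(observed, simulated) -> float:
    """Mean error (bias), simulated minus observed, degC."""
    obs, sim = _paired(observed, simulated)
    return float(np.mean(sim - obs))


def mae(observed, simulated) -> float:
    """Mean absolute error, degC."""
    obs, sim = _paired(observed, simulated)
    return float(np.mean(np.abs(sim - obs)))


def rmsd(observed, simulated) -> float:
    """Root mean square deviation, degC."""
    obs, sim = _paired(observed, simulated)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def r2(observed, simulated) -> float:
    """Squared Pearson correlation, in [0, 1]."""
    obs, sim = _paired(observed, simulated)
    _require_varying(obs)
    if np.ptp(sim) == 0.0:
        return 0.0
    return float(np.corrcoef(obs, sim)[0, 1] ** 2)


def nse(observed, simulated) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SS_tot.  1 is perfect; <= 1."""
    obs, sim = _paired(observed, simulated)
    _require_varying(obs)
    return float(1.0 - np.sum((obs - sim) ** 2) / np.sum((obs - obs.mean()) ** 2))


def mia(observed, simulated) -> float:
    """Modified index of agreement (absolute-deviation d1 form), in [0, 1].

    d1 = 1 - sum|obs - sim| / sum(|sim - mean(obs)| + |obs - mean(obs)|).
    Less sensitive to outliers than the squared form; 1 is perfect.
    """
    obs, sim = _paired(observed, simulated)
    _require_varying(obs)
    obar = obs.mean()
    denom = np.sum(np.abs(sim - obar) + np.abs(obs - obar))
    return float(1.0 - np.sum(np.abs(obs - sim)) / denom)


def compute_all(observed, simulated) -> dict[str, float]:
    """All six statistics as a dict keyed by METRIC_NAMES."""
    funcs = {"me": me, "mae": mae, "rmsd": rmsd, "mia": mia, "r2": r2, "nse": nse}
    return {k: funcs[k](observed, simulated) for k in METRIC_NAMES}
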