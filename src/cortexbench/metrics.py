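"""Fit metrics scoring an inversion on a candidate anatomy.

Four metrics are used to judge how well a source model explains the sensor
data: the free energy (returned by the inversion itself), variance explained
(residual-based R^2), channel-hold-out cross-validation error (RMS in fT on
held-out channels), and the maximum noise-normalized projected power of an
LCMV beamformer scan. Only cross-validation error is lower-is-better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import LeadField
from .inversion import EvokedData, invert

HIGHER_IS_BETTER = {
    "free_energy": True,
    "r2": True,
    "cv_error": False,
    "gamma_max": True,
}


@dataclass(frozen=True)
class FitMetricValue:
    """A named metric value with its comparison direction."""

    name: str
    value: float
    higher_is_better: bool


def variance_explained(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Residual-based variance explained, R^2 = (SST - SSR) / SST.

    SSR = ||Y - Y_hat||_F^2, SST = ||Y||_F^2. Can be negative for
    predictions worse than the zero predictor; equals 1 only for an exact
    reconstruction.
    """
    Y = np.asarray(Y, dtype=np.float64)
    Y_hat = np.asarray(Y_hat, dtype=np.float64)
    if Y.shape != Y_hat.shape:
        raise ValueError("Y and Y_hat must have the same shape")
    sst = float(np.sum(Y * Y))
    if sst == 0.0:
        raise ValueError("SST is zero: measured data are identically zero")
    ssr = float(np.sum((Y - Y_hat) ** 2))
    return (sst - ssr) / sst


def channel_rms_error(Y_held: np.ndarray, Y_pred: np.ndarray) -> float:
    """Mean over channels of the per-channel RMS difference (fT).

    The aggregation used by the cross-validation metric: RMS over time per
    held-out channel, averaged over the held-out channels.
    """
    Y_held = np.atleast_2d(np.asarray(Y_held, dtype=np.float64))
    Y_pred = np.atleast_2d(np.asarray(Y_pred, dtype=np.float64))
    if Y_held.shape != Y_pred.shape:
        raise ValueError("held-out data and predictions must have equal shape")
    return float(np.sqrt(np.mean((Y_held - Y_pred) ** 2, axis=1)).mean())


def cross_validation_error(
    Y: np.ndarray | EvokedData,
    L: np.ndarray | LeadField,
    method: str = "EBB",
    n_runs: int = 10,
    holdout_frac: float = 0.1,
    seed: int = 0,
    **invert_kwargs,
) -> float:
    """Channel-hold-out cross-validation error in fT.

    Per run, a seeded random ``holdout_frac`` of channels is excluded, the
    inversion is fully re-optimized on the remaining channels, and the
    held-out channels are predicted from their own lead-field rows and the
    estimated currents. The per-channel RMS differences are averaged over
    held-out channels and over ``n_runs`` independent draws.
    """
    Ymat = Y.Y if isinstance(Y, EvokedData) else np.asarray(Y, dtype=np.float64)
    Lmat = L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=np.float64)
    Nc = Ymat.shape[0]
    n_hold = int(np.floor(holdout_frac * Nc))
    if n_hold < 1:
        raise ValueError("holdout_frac * Nc must be at least one channel")
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_runs):
        held = rng.choice(Nc, size=n_hold, replace=False)
        keep = np.setdiff1d(np.arange(Nc), held)
        res = invert(Ymat[keep], Lmat[keep], method=method, **invert_kwargs)
        errs.append(channel_rms_error(Ymat[held], Lmat[held] @ res.J))
    return float(np.mean(errs))


def normalized_projected_power(
    W: np.ndarray,
    sigma_Y: np.ndarray,
    sigma_eps: np.ndarray,
    return_profile: bool = False,
):
    """Max over sources of beamformer-projected power normalized by noise power.

    Gamma_theta = (w' Sigma_Y w) / (w' Sigma_eps w) per source (column of W);
    returns the maximum, or the full per-source profile when requested.
    """
    W = np.asarray(W, dtype=np.float64)
    sigma_eps = np.asarray(sigma_eps, dtype=np.float64)
    if sigma_eps.ndim == 1:
        sigma_eps = np.diag(sigma_eps)
    num = np.einsum("ij,ik,kj->j", W, sigma_Y, W)
    den = np.einsum("ij,ik,kj->j", W, sigma_eps, W)
    if np.any(den <= 0):
        raise ValueError("zero noise-projected power for some source")
    gamma = num / den
    if return_profile:
        return gamma
    return float(gamma.max())
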