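"""Empirical-Bayes source inversion with covariance components.

The generative model is Y = L J + eps with Gaussian source and sensor noise
covariances expressed as scaled sums of fixed components. Scale
hyperparameters live on a log scale with Gaussian hyperpriors and are
optimized by Fisher scoring on the negative variational free energy

    F = -Nt/2 log|Sigma| - Nt/2 tr(Sigma_Y Sigma^-1) - Nt Nc log(2 pi)/2
        - (lam - v)' Pi (lam - v)/2 - log|Sigma_lam Pi|/2

where Sigma = L Q_alpha L' + Q_eps is the model sensor covariance and
Sigma_Y = Y Y'/Nt the data covariance. The first three terms are exactly the
Gaussian log likelihood of the data under Sigma; the last two penalize
hyperparameter movement away from the prior and account for posterior
hyperparameter uncertainty.

Three source priors are provided: IID (minimum norm), EBB (empirical Bayes
beamformer, diagonal variances from unit-gain beamformer power), and GS
(greedy search over a library of cortical patch priors, added stepwise by
free-energy improvement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.csgraph import dijkstra

from .forward import LeadField
from .mesh import Mesh

DEFAULT_HYPERPRIOR_PREC = 1.0 / 256.0
DEFAULT_MAX_ITER = 128
DEFAULT_TOL_F = 0.01


@dataclass
class EvokedData:
    """Averaged (evoked) sensor data, channels x time, in fT."""

    Y: np.ndarray
    sfreq: float
    n_trials_averaged: int = 1
    channel_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim != 2 or self.Y.shape[1] < 2:
            raise ValueError("Y must be (Nc, Nt) with Nt >= 2")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("non-finite sensor data")
        if self.channel_labels is None:
            self.channel_labels = [f"MEG{k + 1:03d}" for k in range(self.Y.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_times(self) -> int:
        return self.Y.shape[1]


@dataclass
class CovarianceComponent:
    """One fixed covariance basis matrix, at source or sensor level.

    Exactly one of ``diag`` (diagonal weights), ``matrix`` (dense), or
    ``profile`` (rank-1, Q = p p') is set.
    """

    domain: str  # "source" | "sensor"
    diag: np.ndarray | None = None
    matrix: np.ndarray | None = None
    profile: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.domain not in ("source", "sensor"):
            raise ValueError("domain must be 'source' or 'sensor'")
        forms = [x is not None for x in (self.diag, self.matrix, self.profile)]
        if sum(forms) != 1:
            raise ValueError("exactly one of diag/matrix/profile must be given")

    def sensor_matrix(self, L: np.ndarray | None) -> np.ndarray:
        """Materialize at sensor level (source components mapped through L Q L')."""
        if self.domain == "sensor":
            if self.diag is not None:
                return np.diag(self.diag)
            if self.profile is not None:
                return np.outer(self.profile, self.profile)
            return self.matrix
        if L is None:
            raise ValueError("source component needs a lead field to materialize")
        if self.diag is not None:
            return (L * self.diag[None, :]) @ L.T
        if self.profile is not None:
            lp = L @ self.profile
            return np.outer(lp, lp)
        return L @ self.matrix @ L.T

    def qlt(self, L: np.ndarray) -> np.ndarray:
        """Q L' for a source component, shape (Nv, Nc), without forming Q."""
        if self.domain != "source":
            raise ValueError("qlt is defined for source components")
        if self.diag is not None:
            return self.diag[:, None] * L.T
        if self.profile is not None:
            return np.outer(self.profile, L @ self.profile)
        return self.matrix @ L.T


@dataclass
class HyperPosterior:
    """Gaussian posterior over log-scale hyperparameters."""

    lam: np.ndarray  # posterior mean (log scale)
    v: np.ndarray  # prior mean
    Pi: np.ndarray  # prior precision
    Sigma_lam: np.ndarray  # posterior covariance

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.lam)


@dataclass
class InversionResult:
    """Current estimate plus the optimized covariance model and its evidence."""

    J: np.ndarray  # (Nv, Nt) nAm
    Y_hat: np.ndarray  # (Nc, Nt) predicted sensor data
    Q_source: np.ndarray  # diag vector (Nv,) or dense (Nv, Nv)
    Q_eps: np.ndarray  # (Nc, Nc)
    Sigma_alpha: np.ndarray  # (Nc, Nc) model sensor covariance
    F: float
    F_terms: dict
    hyper: HyperPosterior
    method: str
    converged: bool = True
    active_patches: list[int] | None = None


def data_covariance(Y: np.ndarray | EvokedData) -> np.ndarray:
    """Sensor data covariance Sigma_Y = Y Y' / Nt."""
    y = Y.Y if isinstance(Y, EvokedData) else np.asarray(Y, dtype=np.float64)
    return y @ y.T / y.shape[1]


def _as_precision(Pi, m: int) -> np.ndarray:
    Pi = np.asarray(Pi, dtype=np.float64)
    if Pi.ndim == 0:
        return float(Pi) * np.eye(m)
    if Pi.ndim == 1:
        return np.diag(Pi)
    return Pi


def free_energy(
    sigma_Y: np.ndarray,
    sigma_model: np.ndarray,
    Nt: int,
    lam: np.ndarray | None = None,
    v: np.ndarray | None = None,
    Pi: np.ndarray | None = None,
    Sigma_lam: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Negative variational free energy and its per-term breakdown.

    The first three terms equal the Gaussian log likelihood of the Nt data
    samples under ``sigma_model``; the hyperprior terms are included when
    the hyperposterior quantities are given (and the prior precision is
    nonzero — an all-zero Pi denotes an improper flat prior whose terms are
    dropped).
    """
    Nc = sigma_Y.shape[0]
    c, low = cho_factor(sigma_model)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    terms = {
        "complexity": -0.5 * Nt * logdet,
        "accuracy": -0.5 * Nt * float(np.trace(cho_solve((c, low), sigma_Y))),
        "constant": -0.5 * Nt * Nc * np.log(2.0 * np.pi),
        "hyperprior": 0.0,
        "hyperposterior": 0.0,
    }
    if lam is not None and Pi is not None and np.any(Pi != 0.0):
        dl = lam - v
        terms["hyperprior"] = -0.5 * float(dl @ Pi @ dl)
        sign_p, logdet_p = np.linalg.slogdet(Pi)
        sign_s, logdet_s = np.linalg.slogdet(Sigma_lam)
        if sign_p <= 0 or sign_s <= 0:
            raise np.linalg.LinAlgError("hyperposterior covariance not positive definite")
        terms["hyperposterior"] = -0.5 * (logdet_s + logdet_p)
    return float(sum(terms.values())), terms


def _reml_core(
    sigma_Y: np.ndarray,
    sensor_covs: list[np.ndarray],
    Nt: int,
    v: np.ndarray,
    Pi: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol_F: float = DEFAULT_TOL_F,
) -> tuple[HyperPosterior, float, dict, bool]:
    """Fisher-scoring ascent on F over log-scale hyperparameters."""
    m = len(sensor_covs)
    Nc = sigma_Y.shape[0]
    traces = np.array([max(np.trace(C), 1e-300) for C in sensor_covs])
    tr_y = max(np.trace(sigma_Y), 1e-300)
    lam = np.log(tr_y / (m * traces))

    def evaluate(lam_):
        scales = np.exp(np.clip(lam_, -700, 700))
        sigma = sum(s * C for s, C in zip(scales, sensor_covs))
        try:
            c, low = cho_factor(sigma)
        except np.linalg.LinAlgError:
            return None
        iS = cho_solve((c, low), np.eye(Nc))
        S = iS @ sigma_Y
        P = [scales[k] * (iS @ sensor_covs[k]) for k in range(m)]
        g = np.array(
            [
                -0.5 * Nt * np.trace(P[k]) + 0.5 * Nt * np.sum(P[k] * S.T)
                for k in range(m)
            ]
        ) - Pi @ (lam_ - v)
        H = Pi + 0.5 * Nt * np.array(
            [[np.sum(P[k] * P[l].T) for l in range(m)] for k in range(m)]
        )
        # keep H invertible for flat hyperpriors with silent components
        H = H + 1e-8 * np.eye(m)
        Sigma_lam = np.linalg.inv(H)
        Sigma_lam = 0.5 * (Sigma_lam + Sigma_lam.T)
        F, terms = free_energy(sigma_Y, sigma, Nt, lam_, v, Pi, Sigma_lam)
        return dict(F=F, terms=terms, g=g, H=H, Sigma_lam=Sigma_lam, sigma=sigma)

    state = evaluate(lam)
    if state is None:
        raise np.linalg.LinAlgError("initial composite covariance not positive definite")
    damping = 1e-6
    converged = False
    for _ in range(max_iter):
        step = np.linalg.solve(
            state["H"] + damping * np.diag(np.diag(state["H"])), state["g"]
        )
        step = np.clip(step, -8.0, 8.0)
        trial = None
        for _retry in range(16):
            trial = evaluate(lam + step)
            if trial is not None and trial["F"] >= state["F"] - 1e-12:
                break
            damping = max(damping * 8.0, 1e-4)  # damp and retry
            step = np.clip(
                np.linalg.solve(
                    state["H"] + damping * np.diag(np.diag(state["H"])), state["g"]
                ),
                -8.0,
                8.0,
            )
            trial = None
        if trial is None:
            break
        lam = lam + step
        dF = trial["F"] - state["F"]
        state = trial
        damping = max(damping / 8.0, 1e-8)
        if abs(dF) < tol_F:
            converged = True
            break
    if not converged:
        warnings.warn("ReML did not converge within max_iter; returning best estimate")
    hyper = HyperPosterior(lam=lam, v=v, Pi=Pi, Sigma_lam=state["Sigma_lam"])
    return hyper, state["F"], state["terms"], converged


def reml_optimize(
    sigma_Y: np.ndarray,
    L: np.ndarray | None,
    components: list[CovarianceComponent],
    Nt: int,
    hyperprior_mean: float | np.ndarray = 0.0,
    hyperprior_prec: float | np.ndarray = DEFAULT_HYPERPRIOR_PREC,
    max_iter: int = DEFAULT_MAX_ITER,
    tol_F: float = DEFAULT_TOL_F,
) -> tuple[HyperPosterior, float, dict, bool]:
    """Optimize component scale hyperparameters by restricted maximum likelihood.

    Source components are mapped to sensor level through L Q L'. At least one
    sensor-level (noise) component is required. Returns the hyperposterior,
    the free energy with its per-term breakdown, and a convergence flag.
    """
    if not any(c.domain == "sensor" for c in components):
        raise ValueError("at least one sensor-level noise component is required")
    m = len(components)
    v = np.asarray(hyperprior_mean, dtype=np.float64)
    if v.ndim == 0:
        v = np.full(m, float(v))
    Pi = _as_precision(hyperprior_prec, m)
    covs = [c.sensor_matrix(L) for c in components]
    return _reml_core(sigma_Y, covs, Nt, v, Pi, max_iter=max_iter, tol_F=tol_F)


def compute_posterior(
    Y: np.ndarray,
    L: np.ndarray,
    Q_source: np.ndarray,
    Q_eps: np.ndarray,
) -> np.ndarray:
    """Posterior mean current J = Q L' (L Q L' + Q_eps)^-1 Y.

    ``Q_source`` may be a diagonal vector (Nv,) or dense (Nv, Nv);
    ``Q_eps`` a diagonal vector (Nc,) or dense (Nc, Nc). Uses a Cholesky
    solve rather than an explicit inverse.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    Q_source = np.asarray(Q_source, dtype=np.float64)
    Q_eps = np.asarray(Q_eps, dtype=np.float64)
    if Q_source.ndim == 1:
        qlt = Q_source[:, None] * L.T
    else:
        qlt = Q_source @ L.T
    sigma = L @ qlt + (np.diag(Q_eps) if Q_eps.ndim == 1 else Q_eps)
    try:
        c, low = cho_factor(sigma)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "model sensor covariance L Q L' + Q_eps is rank deficient"
        ) from err
    return qlt @ cho_solve((c, low), Y)


def prior_iid(Nv: int) -> CovarianceComponent:
    """Minimum-norm prior: identical independent variance at every source."""
    return CovarianceComponent(domain="source", diag=np.ones(Nv), label="IID")


def prior_ebb(
    L: np.ndarray,
    sigma_Y: np.ndarray,
    ridge: float = 1e-6,
) -> CovarianceComponent:
    """Empirical-Bayes beamformer prior: source variances from projected power.

    With column-normalized lead fields l_i, q_i = (l_i' Sigma_Y^-1 l_i)^-1 —
    the unit-gain beamformer power at source i under an uncorrelated-source
    assumption. A small ridge (``ridge`` x mean diagonal) stabilizes the
    covariance inverse; the component is rescaled to unit trace.
    """
    sigma = sigma_Y + ridge * float(np.mean(np.diag(sigma_Y))) * np.eye(len(sigma_Y))
    try:
        c, low = cho_factor(sigma)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("data covariance rank deficient; raise ridge") from err
    norms = np.linalg.norm(L, axis=0)
    if np.any(norms == 0):
        raise ValueError("lead field has an all-zero column")
    Ln = L / norms[None, :]
    q = 1.0 / np.einsum("ij,ij->j", Ln, cho_solve((c, low), Ln))
    q = q / q.sum()
    return CovarianceComponent(domain="source", diag=q, label="EBB")


def _geodesic_distances(mesh: Mesh, sources: np.ndarray) -> np.ndarray:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    nv = mesh.n_vertices
    g = sparse.coo_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(nv, nv),
    ).tocsr()
    return dijkstra(g, directed=False, indices=sources)


def make_patch_library(
    mesh: Mesh,
    Np: int = 64,
    sigma_patch: float = 10.0,
    seed: int = 0,
) -> list[CovarianceComponent]:
    """Library of rank-1 cortical patch priors for the greedy search.

    Np seed vertices are spread quasi-uniformly by farthest-point sampling on
    graph geodesics (first seed drawn with ``seed``); each patch profile
    decays as exp(-d/sigma_patch) with geodesic distance d from its seed.
    """
    if Np < 1:
        raise ValueError("need at least one patch")
    if Np > mesh.n_vertices:
        raise ValueError("more patches than vertices")
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(mesh.n_vertices))]
    dmin = _geodesic_distances(mesh, np.array(seeds[:1]))[0]
    for _ in range(Np - 1):
        nxt = int(np.argmax(dmin))  # ties: first index wins
        seeds.append(nxt)
        dmin = np.minimum(dmin, _geodesic_distances(mesh, np.array([nxt]))[0])
    dists = _geodesic_distances(mesh, np.array(seeds))
    patches = []
    for p, s in enumerate(seeds):
        profile = np.exp(-dists[p] / sigma_patch)
        patches.append(
            CovarianceComponent(domain="source", profile=profile, label=f"patch{s}")
        )
    return patches


def greedy_search_invert(
    Y: np.ndarray | EvokedData,
    L: np.ndarray | LeadField,
    patches: list[CovarianceComponent],
    hyperprior_prec: float = DEFAULT_HYPERPRIOR_PREC,
    tol_F: float = DEFAULT_TOL_F,
    max_patches: int = 8,
    max_iter: int = DEFAULT_MAX_ITER,
) -> InversionResult:
    """Forward greedy selection of patch priors by free-energy improvement.

    Starts from the noise-only model and repeatedly adds the candidate patch
    whose inclusion (after re-optimizing all hyperparameters) most increases
    F; stops when the best improvement falls below ``tol_F`` or
    ``max_patches`` patches are active.
    """
    if not patches:
        raise ValueError("empty patch library")
    Ymat = Y.Y if isinstance(Y, EvokedData) else np.asarray(Y, dtype=np.float64)
    Lmat = L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=np.float64)
    Nc, Nt = Ymat.shape
    sigma_Y = Ymat @ Ymat.T / Nt
    noise = CovarianceComponent(domain="sensor", diag=np.ones(Nc), label="noise")
    cand_covs = [p.sensor_matrix(Lmat) for p in patches]
    noise_cov = noise.sensor_matrix(None)

    def run(active_idx):
        covs = [noise_cov] + [cand_covs[i] for i in active_idx]
        m = len(covs)
        v = np.zeros(m)
        Pi = _as_precision(hyperprior_prec, m)
        return _reml_core(sigma_Y, covs, Nt, v, Pi, max_iter=max_iter, tol_F=tol_F)

    active: list[int] = []
    hyper, F_best, terms, conv = run(active)
    while len(active) < max_patches:
        best = (None, F_best)
        for i in range(len(patches)):
            if i in active:
                continue
            _, F_i, _, _ = run(active + [i])
            if F_i > best[1]:
                best = (i, F_i)
        if best[0] is None or best[1] - F_best < tol_F:
            break
        active.append(best[0])
        hyper, F_best, terms, conv = run(active)

    scales = hyper.scales
    Q_eps = scales[0] * np.eye(Nc)
    Nv = Lmat.shape[1]
    Q_source = np.zeros((Nv, Nv))
    for k, i in enumerate(active):
        p = patches[i].profile
        Q_source += scales[k + 1] * np.outer(p, p)
    sigma_alpha = noise_cov * scales[0] + sum(
        scales[k + 1] * cand_covs[i] for k, i in enumerate(active)
    )
    if active:
        J = compute_posterior(Ymat, Lmat, Q_source, Q_eps)
    else:
        J = np.zeros((Nv, Nt))
    return InversionResult(
        J=J,
        Y_hat=Lmat @ J,
        Q_source=Q_source,
        Q_eps=Q_eps,
        Sigma_alpha=sigma_alpha,
        F=F_best,
        F_terms=terms,
        hyper=hyper,
        method="GS",
        converged=conv,
        active_patches=active,
    )


def lcmv_weights(
    L: np.ndarray,
    sigma_Y: np.ndarray,
    regularization: float = 0.05,
) -> np.ndarray:
    """Unit-gain LCMV beamformer weights, one column per source.

    w_i = Sigma^-1 l_i / (l_i' Sigma^-1 l_i) with Sigma the (ridge-
    regularized) data covariance; w_i' l_i = 1 holds exactly by construction.
    """
    sigma = sigma_Y + regularization * float(np.mean(np.diag(sigma_Y))) * np.eye(
        len(sigma_Y)
    )
    c, low = cho_factor(sigma)
    sl = cho_solve((c, low), L)
    denom = np.einsum("ij,ij->j", L, sl)
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("non-positive beamformer denominator")
    return sl / denom[None, :]


def invert(
    Y: np.ndarray | EvokedData,
    L: np.ndarray | LeadField,
    method: str = "EBB",
    mesh: Mesh | None = None,
    Np: int = 64,
    sigma_patch: float = 10.0,
    patch_seed: int = 0,
    hyperprior_prec: float = DEFAULT_HYPERPRIOR_PREC,
    tol_F: float = DEFAULT_TOL_F,
    max_iter: int = DEFAULT_MAX_ITER,
    max_patches: int = 8,
    temporal_projection: bool = False,
    projection_variance: float = 0.99,
    patches: list[CovarianceComponent] | None = None,
) -> InversionResult:
    """Run one source inversion (IID, EBB or GS) and return its full result.

    With ``temporal_projection`` the data are projected onto the leading
    temporal SVD modes retaining ``projection_variance`` of the variance and
    the effective Nt becomes the retained mode count.
    """
    Ymat = Y.Y if isinstance(Y, EvokedData) else np.asarray(Y, dtype=np.float64)
    Lmat = L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=np.float64)
    if Ymat.shape[0] != Lmat.shape[0]:
        raise ValueError("channel count mismatch between data and lead field")
    if temporal_projection:
        _, sv, vt = np.linalg.svd(Ymat, full_matrices=False)
        keep = int(np.searchsorted(np.cumsum(sv**2) / np.sum(sv**2), projection_variance) + 1)
        Ymat = Ymat @ vt[:keep].T

    method = method.upper()
    Nc, Nt = Ymat.shape
    Nv = Lmat.shape[1]
    sigma_Y = Ymat @ Ymat.T / Nt

    if method == "GS":
        if patches is None:
            if mesh is None:
                raise ValueError("GS needs a mesh (or an explicit patch library)")
            patches = make_patch_library(mesh, Np=Np, sigma_patch=sigma_patch, seed=patch_seed)
        return greedy_search_invert(
            Ymat,
            Lmat,
            patches,
            hyperprior_prec=hyperprior_prec,
            tol_F=tol_F,
            max_patches=max_patches,
            max_iter=max_iter,
        )

    if method == "IID":
        source = prior_iid(Nv)
    elif method == "EBB":
        source = prior_ebb(Lmat, sigma_Y)
    else:
        raise ValueError(f"unknown method {method!r} (expected IID, EBB or GS)")
    noise = CovarianceComponent(domain="sensor", diag=np.ones(Nc), label="noise")
    hyper, F, terms, conv = reml_optimize(
        sigma_Y,
        Lmat,
        [source, noise],
        Nt,
        hyperprior_prec=hyperprior_prec,
        max_iter=max_iter,
        tol_F=tol_F,
    )
    scales = hyper.scales
    Q_source = scales[0] * source.diag
    Q_eps = scales[1] * np.eye(Nc)
    J = compute_posterior(Ymat, Lmat, Q_source, Q_eps)
    sigma_alpha = (Lmat * Q_source[None, :]) @ Lmat.T + Q_eps
    return InversionResult(
        J=J,
        Y_hat=Lmat @ J,
        Q_source=Q_source,
        Q_eps=Q_eps,
        Sigma_alpha=sigma_alpha,
        F=F,
        F_terms=terms,
        hyper=hyper,
        method=method,
        converged=conv,
    )
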