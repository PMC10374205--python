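"""Truncated stick-breaking Gaussian Dirichlet-process mixture (DPM).

The model clusters participants on their food-group frequency vectors
x_i in R^d.  A Dirichlet process prior with concentration alpha and a
normal-inverse-gamma base distribution G0 is truncated at K components via
its stick-breaking representation:

    v_k ~ Beta(1, alpha),   w_k = v_k * prod_{j<k} (1 - v_j),
    sigma2_kj ~ InvGamma(a0, b0),   mu_kj | sigma2_kj ~ N(m0_j, sigma2_kj/kappa0),
    z_i | w ~ Categorical(w),       x_i | z_i = k ~ N(mu_k, diag(sigma2_k)).

Component covariances are diagonal.  Inference is a blocked Gibbs sampler
cycling allocations -> stick fractions -> component parameters ->
concentration, with all density arithmetic in the log domain.  Retained
iterations are relabeled (label-switching correction) before averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import defaults
from .config import DPMConfig

__all__ = [
    "FFQMatrix",
    "DPMState",
    "DPMPosterior",
    "stick_breaking_weights",
    "sample_allocations",
    "update_sticks",
    "update_components",
    "update_concentration",
    "fit_dpm",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class FFQMatrix:
    """n x d matrix of weekly food-group consumption frequencies."""

    values: np.ndarray
    group_names: tuple[str, ...] = defaults.FOOD_GROUPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("frequencies must be >= 0")
        self.group_names = tuple(self.group_names)
        if len(self.group_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.group_names)} group names for "
                f"{self.values.shape[1]} columns"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups=defaults.FOOD_GROUPS) -> "FFQMatrix":
        missing = [g for g in groups if g not in df.columns]
        if missing:
            raise ValueError(f"missing food-group columns: {missing}")
        return cls(df[list(groups)].to_numpy(float), tuple(groups))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class DPMState:
    """One configuration of the truncated sampler."""

    sticks: np.ndarray          # (K-1,) in (0, 1)
    weights: np.ndarray         # (K,) simplex
    means: np.ndarray           # (K, d)
    variances: np.ndarray       # (K, d), diagonal covariances
    allocations: np.ndarray     # (n,) component indices in [0, K)
    alpha: float

    def validate(self) -> None:
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be a simplex (sum 1 within 1e-12)")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be > 0")
        K = len(self.weights)
        if self.allocations.size and (
            self.allocations.min() < 0 or self.allocations.max() >= K
        ):
            raise ValueError("allocations out of range")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class DPMPosterior:
    """Posterior summaries averaged over relabeled retained iterations.

    ``means`` / ``variances`` are on the original data scale; ``means_fit`` /
    ``variances_fit`` on the (possibly z-scored) fitting scale.  Component
    parameter summaries average only iterations at which the component was
    occupied, so prior noise from empty components never pollutes them.
    """

    weights: np.ndarray               # (K,) posterior-mean weights
    means: np.ndarray                 # (K, d) original scale
    variances: np.ndarray             # (K, d) original scale
    means_fit: np.ndarray
    variances_fit: np.ndarray
    allocation_probs: np.ndarray      # (n, K), rows sum to 1
    occupancy: np.ndarray             # (K,) mean number of allocated subjects
    occupied_count: int               # mode over retained iterations
    occupied_trace: np.ndarray        # per-iteration occupied-component count
    alpha_trace: np.ndarray
    mean_trace: np.ndarray            # (n_retained, K, d), relabeled, fit scale
    occupancy_trace: np.ndarray       # (n_retained, K) counts
    group_names: tuple[str, ...] = defaults.FOOD_GROUPS
    column_means: np.ndarray | None = None   # standardization constants
    column_sds: np.ndarray | None = None
    config: DPMConfig | None = field(default=None, repr=False)

    @property
    def occupied_components(self) -> np.ndarray:
        """Components that attract at least one MAP-assigned participant."""
        return np.unique(np.argmax(self.allocation_probs, axis=1))


def stick_breaking_weights(v: np.ndarray) -> np.ndarray:
    """Map K-1 stick fractions to K mixture weights.

    w_k = v_k * prod_{j<k}(1 - v_j); the last weight absorbs the remainder
    prod_{j<K}(1 - v_j), so the result sums to 1 exactly up to float error.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("stick fractions must lie in [0, 1]")
    K = len(v) + 1
    w = np.empty(K)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - v)])
    w[:-1] = v * remaining[:-1]
    w[-1] = remaining[-1]
    return w


def _log_density_matrix(X: np.ndarray, state: DPMState) -> np.ndarray:
    """(n, K) matrix of log w_k + log N(x_i | mu_k, diag(sigma2_k))."""
    var = state.variances
    const = 0.5 * np.sum(np.log(var) + _LOG_2PI, axis=1)
    diff = X[:, None, :] - state.means[None, :, :]
    with np.errstate(divide="ignore", over="ignore"):
        quad = 0.5 * np.einsum("nkd,kd->nk", diff * diff, 1.0 / var)
        logw = np.log(state.weights)
    return logw[None, :] - const[None, :] - quad


def sample_allocations(
    data: FFQMatrix | np.ndarray, state: DPMState, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw component allocations z_i ~ Categorical over k of
    w_k * N(x_i | mu_k, sigma2_k), computed in the log domain.

    Returns (allocations, allocation-probability matrix).
    """
    X = data.values if isinstance(data, FFQMatrix) else np.asarray(data, float)
    logp = _log_density_matrix(X, state)
    norm = logsumexp(logp, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        raise FloatingPointError(
            f"all component densities vanished for row(s) {np.where(bad)[0].tolist()}"
        )
    probs = np.exp(logp - norm[:, None])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(X))
    z = (u[:, None] > cum).sum(axis=1)
    return z.astype(int), probs


def update_sticks(
    allocations: np.ndarray, alpha: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate stick-fraction update: v_k ~ Beta(1 + n_k, alpha + n_{>k})."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    counts = np.bincount(allocations, minlength=K).astype(float)
    tail = counts[::-1].cumsum()[::-1]  # tail[k] = sum_{j >= k} n_j
    a = 1.0 + counts[: K - 1]
    b = alpha + tail[1:K]
    v = rng.beta(a, b)
    # guard against numerically degenerate draws
    return np.clip(v, 1e-12, 1.0 - 1e-12)


def update_components(
    X: np.ndarray,
    allocations: np.ndarray,
    config: DPMConfig,
    K: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate diagonal normal-inverse-gamma update of (means, variances).

    Per component k and dimension j, with n_k allocated points of mean
    xbar_kj and within-component sum of squares S_kj:

        sigma2_kj ~ InvGamma(a0 + n_k/2,
                             b0 + S_kj/2 + kappa0 n_k (xbar_kj - m0_j)^2
                                            / (2 (kappa0 + n_k)))
        mu_kj ~ N((kappa0 m0_j + n_k xbar_kj) / (kappa0 + n_k),
                  sigma2_kj / (kappa0 + n_k))

    Empty components are drawn from the base distribution.
    """
    n, d = X.shape
    a0, b0 = config.variance_prior
    kappa0 = config.base_scale
    m0 = np.broadcast_to(np.asarray(config.base_mean, float), (d,))

    counts = np.bincount(allocations, minlength=K).astype(float)
    sums = np.zeros((K, d))
    sqsums = np.zeros((K, d))
    np.add.at(sums, allocations, X)
    np.add.at(sqsums, allocations, X**2)

    nk = counts[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = np.where(nk > 0, sums / np.maximum(nk, 1.0), 0.0)
    S = sqsums - nk * xbar**2  # within-component sum of squares
    S = np.maximum(S, 0.0)

    kn = kappa0 + nk
    shape = a0 + nk / 2.0
    scale = b0 + 0.5 * S + kappa0 * nk * (xbar - m0[None, :]) ** 2 / (2.0 * kn)
    variances = scale / rng.gamma(shape, 1.0, size=(K, d))
    post_mean = (kappa0 * m0[None, :] + nk * xbar) / kn
    means = rng.normal(post_mean, np.sqrt(variances / kn))
    return means, variances


def update_concentration(
    sticks: np.ndarray,
    alpha_prior: tuple[float, float],
    rng: np.random.Generator,
    fixed_alpha: float | None = None,
) -> float:
    """Conjugate Gamma update of the DP concentration:
    alpha ~ Gamma(a + K - 1, b - sum_{k<K} log(1 - v_k))."""
    if fixed_alpha is not None:
        return float(fixed_alpha)
    a, b = alpha_prior
    v = np.asarray(sticks, float)
    ok = v < 1.0
    if not np.all(ok):
        warnings.warn(
            "stick fraction equal to 1 excluded from concentration update",
            RuntimeWarning,
            stacklevel=2,
        )
        v = v[ok]
    rate = b - np.sum(np.log1p(-v))
    shape = a + len(sticks)  # K - 1 stick fractions
    return float(rng.gamma(shape, 1.0 / rate))


def _label_swap_moves(
    sticks: np.ndarray,
    z: np.ndarray,
    probs: np.ndarray,
    alpha: float,
    K: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Metropolis label-permutation moves for the truncated sampler.

    Without them, a large cluster that lands in a late slot is stuck there:
    the stick prior prefers big weights early, middle sticks are forced
    small, and the concentration posterior inflates (observed: alpha ~ 6 for
    two clear clusters).  One descending sweep of adjacent-pair swaps lets
    big clusters bubble to the front.

    Interior pairs (k, k+1) swap contents together with their sticks; the
    acceptance probability is min{1, (1-v_{k+1})^{n_k} / (1-v_k)^{n_{k+1}}}.
    The last pair (K-2, K-1) swaps contents and redraws the stick from its
    full conditional; the marginal acceptance ratio reduces to
    B(1+n_{K-1}, alpha+n_{K-2}) / B(1+n_{K-2}, alpha+n_{K-1}).
    """
    from scipy.special import betaln

    counts = np.bincount(z, minlength=K)

    def swap_slots(k: int) -> None:
        sel_k = z == k
        sel_k1 = z == k + 1
        z[sel_k] = k + 1
        z[sel_k1] = k
        probs[:, [k, k + 1]] = probs[:, [k + 1, k]]
        counts[k], counts[k + 1] = counts[k + 1], counts[k]

    # last pair: content swap with a conditional stick redraw
    a, b = counts[K - 2], counts[K - 1]
    log_ratio = betaln(1 + b, alpha + a) - betaln(1 + a, alpha + b)
    if math.log(rng.random()) < log_ratio:
        swap_slots(K - 2)
        sticks[K - 2] = float(
            np.clip(
                rng.beta(1 + counts[K - 2], alpha + counts[K - 1]),
                1e-12,
                1.0 - 1e-12,
            )
        )
    # interior pairs, descending so late clusters can travel to the front
    for k in range(K - 3, -1, -1):
        nk, nk1 = counts[k], counts[k + 1]
        log_ratio = nk * math.log1p(-sticks[k + 1]) - nk1 * math.log1p(-sticks[k])
        if math.log(rng.random()) < log_ratio:
            swap_slots(k)
            sticks[k], sticks[k + 1] = sticks[k + 1], sticks[k]
    return sticks, z, probs


def _greedy_match(current: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Greedy nearest-mean matching.  Returns a permutation ``perm`` such
    that ``current[perm[s]]`` plays the role of reference slot ``s``."""
    K = current.shape[0]
    D = np.linalg.norm(current[:, None, :] - reference[None, :, :], axis=2)
    perm = np.full(K, -1, dtype=int)
    used_cur = np.zeros(K, bool)
    used_ref = np.zeros(K, bool)
    for _ in range(K):
        masked = np.where(
            used_cur[:, None] | used_ref[None, :], np.inf, D
        )
        k_cur, k_ref = np.unravel_index(np.argmin(masked), masked.shape)
        perm[k_ref] = k_cur
        used_cur[k_cur] = True
        used_ref[k_ref] = True
    return perm


def fit_dpm(data: FFQMatrix | np.ndarray, config: DPMConfig) -> DPMPosterior:
    """Run the blocked Gibbs sampler and return averaged posterior summaries.

    The sweep order is allocations -> sticks -> components -> concentration.
    After burn-in, every ``thin``-th iteration is relabeled against running
    reference means (greedy nearest-mean matching) and accumulated; the
    allocation-probability matrix is the average of per-iteration allocation
    probabilities.  Fully reproducible given ``config.seed``.
    """
    if isinstance(data, FFQMatrix):
        X_raw = data.values
        group_names = data.group_names
    else:
        # raw matrices (e.g. test fixtures) bypass FFQ-specific invariants
        X_raw = np.asarray(data, float)
        if X_raw.ndim != 2 or not np.all(np.isfinite(X_raw)):
            raise ValueError("data must be a finite 2-D matrix")
        group_names = tuple(f"group_{j}" for j in range(X_raw.shape[1]))
    n, d = X_raw.shape
    K = config.truncation_K
    rng = np.random.default_rng(config.seed)

    if config.standardize:
        col_means = X_raw.mean(axis=0)
        col_sds = X_raw.std(axis=0, ddof=0)
        col_sds = np.where(col_sds > 0, col_sds, 1.0)
        X = (X_raw - col_means) / col_sds
    else:
        col_means = np.zeros(d)
        col_sds = np.ones(d)
        X = X_raw

    alpha = (
        config.fixed_alpha
        if config.fixed_alpha is not None
        else config.alpha_prior[0] / config.alpha_prior[1]
    )
    if config.init == "kmeans":
        # k-means allocation init: in 12 dimensions, empty components drawn
        # from the base distribution essentially never land on a small
        # far-away cluster, so a random start can leave such clusters
        # unrecoverable; k-means seeds the sweep with data-adapted blocks.
        from scipy.cluster.vq import kmeans2

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, z = kmeans2(X, min(K, n), minit="++", seed=rng)
        z = np.asarray(z, dtype=int)
        # relabel init clusters by decreasing size: the stick prior favors
        # big weights early, and a large cluster consolidating in the last
        # (remainder) slot is a sticky low-quality mode of the truncated
        # sampler that inflates the concentration posterior
        order = np.argsort(-np.bincount(z, minlength=K), kind="stable")
        z = np.argsort(order, kind="stable")[z]
    else:
        z = rng.integers(0, K, size=n)
    means, variances = update_components(X, z, config, K, rng)
    sticks = update_sticks(z, alpha, K, rng)
    weights = stick_breaking_weights(sticks)
    state = DPMState(sticks, weights, means, variances, z, alpha)

    n_retained = config.n_samples
    total = config.n_burnin + n_retained * config.thin

    probs_sum = np.zeros((n, K))
    weight_sum = np.zeros(K)
    mean_sum = np.zeros((K, d))
    var_sum = np.zeros((K, d))
    occ_iters = np.zeros(K)
    occupancy_sum = np.zeros(K)
    occupied_trace = np.empty(n_retained, dtype=int)
    alpha_trace = np.empty(n_retained)
    mean_trace = np.empty((n_retained, K, d))
    occupancy_trace = np.empty((n_retained, K))

    ref_means: np.ndarray | None = None
    ref_counts = np.zeros(K)
    kept = 0

    for it in range(total):
        z, probs = sample_allocations(X, state, rng)
        sticks = update_sticks(z, state.alpha, K, rng)
        sticks, z, probs = _label_swap_moves(sticks, z, probs, state.alpha, K, rng)
        state.allocations = z
        state.sticks = sticks
        state.weights = stick_breaking_weights(sticks)
        state.means, state.variances = update_components(X, z, config, K, rng)
        state.alpha = update_concentration(
            state.sticks, config.alpha_prior, rng, config.fixed_alpha
        )

        if not (
            np.all(np.isfinite(state.means))
            and np.all(np.isfinite(state.variances))
            and np.all(np.isfinite(state.weights))
            and math.isfinite(state.alpha)
        ):
            raise RuntimeError(f"non-finite values in chain at iteration {it}")

        retained = it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0
        if not retained:
            continue

        counts = np.bincount(z, minlength=K).astype(float)
        if ref_means is None:
            # order components by occupancy so big clusters land at low indices
            perm = np.argsort(-counts, kind="stable")
        else:
            perm = _greedy_match(state.means, ref_means)
        w_r = state.weights[perm]
        mu_r = state.means[perm]
        var_r = state.variances[perm]
        counts_r = counts[perm]
        probs_r = probs[:, perm]

        occ = counts_r > 0
        if ref_means is None:
            ref_means = mu_r.copy()
            ref_counts = occ.astype(float)
        else:
            upd = occ
            ref_counts_new = ref_counts + upd
            with np.errstate(invalid="ignore"):
                ref_means[upd] = (
                    ref_means[upd] * ref_counts[upd, None] + mu_r[upd]
                ) / ref_counts_new[upd, None]
            ref_counts = ref_counts_new

        probs_sum += probs_r
        weight_sum += w_r
        mean_sum[occ] += mu_r[occ]
        var_sum[occ] += var_r[occ]
        occ_iters += occ
        occupancy_sum += counts_r
        occupied_trace[kept] = int(occ.sum())
        alpha_trace[kept] = state.alpha
        mean_trace[kept] = mu_r
        occupancy_trace[kept] = counts_r
        kept += 1

    denom = np.maximum(occ_iters, 1.0)[:, None]
    means_fit = mean_sum / denom
    variances_fit = var_sum / denom
    never = occ_iters == 0
    means_fit[never] = np.broadcast_to(
        np.asarray(config.base_mean, float), (d,)
    )
    variances_fit[never] = config.variance_prior[1] / max(
        config.variance_prior[0] - 1.0, 1e-6
    )

    counts_mode = np.bincount(occupied_trace).argmax()

    return DPMPosterior(
        weights=weight_sum / n_retained,
        means=col_means[None, :] + col_sds[None, :] * means_fit,
        variances=col_sds[None, :] ** 2 * variances_fit,
        means_fit=means_fit,
        variances_fit=variances_fit,
        allocation_probs=probs_sum / n_retained,
        occupancy=occupancy_sum / n_retained,
        occupied_count=int(counts_mode),
        occupied_trace=occupied_trace,
        alpha_trace=alpha_trace,
        mean_trace=mean_trace,
        occupancy_trace=occupancy_trace,
        group_names=group_names,
        column_means=col_means,
        column_sds=col_sds,
        config=config,
    )
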