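"""Multistate Bennett acceptance ratio (MBAR) estimation and reweighting.

Given reduced potentials u_kn (dimensionless, inverse temperature and any
restraint terms folded in) of every sample n evaluated under every state k,
the MBAR self-consistency equations

    f_i = −ln Σ_n exp(−u_in) / Σ_k N_k exp(f_k − u_kn)

yield statistically optimal relative free energies f_k, with f_0 = 0 by
convention.  The solver runs self-consistent iteration as a warm start and
then Newton steps on the equivalent convex objective; everything is
computed through log-sum-exp and is overflow-safe.  Uncertainties come
from a per-state block bootstrap.  Physical units enter only at reporting
time, via the kT factor in :func:`free_energy_difference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ReducedPotentialMatrix",
    "MBARResult",
    "TargetWeights",
    "solve_mbar",
    "compute_weights",
    "free_energy_difference",
    "compose_cycle",
    "bootstrap_uncertainty",
    "solve_mbar_f",
]


@dataclass
class ReducedPotentialMatrix:
    """K x N matrix of reduced potentials plus per-state sample counts."""

    u_kn: np.ndarray
    N_k: np.ndarray
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.N_k = np.asarray(self.N_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be a K x N matrix")
        K, N = self.u_kn.shape
        if self.N_k.shape != (K,):
            raise ValueError("N_k must have one entry per state")
        if np.any(self.N_k < 0) or self.N_k.sum() != N:
            raise ValueError("N_k must be non-negative and sum to N")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")
        if not self.state_names:
            self.state_names = [f"state{k}" for k in range(K)]
        if len(self.state_names) != K:
            raise ValueError("state_names length must equal K")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u_kn.shape[1]

    def state_index(self, state: int | str) -> int:
        if isinstance(state, str):
            try:
                return self.state_names.index(state)
            except ValueError:
                raise KeyError(f"unknown state {state!r}") from None
        return int(state)

    def sample_blocks(self) -> list[np.ndarray]:
        """Column index blocks per originating state (N_k layout)."""
        edges = np.concatenate([[0], np.cumsum(self.N_k)])
        return [np.arange(edges[k], edges[k + 1]) for k in range(self.n_states)]


@dataclass
class MBARResult:
    """Relative dimensionless free energies; f_0 = 0 by convention."""

    f_k: np.ndarray
    converged: bool
    residual: float
    n_iter: int = 0
    bootstrap_se: np.ndarray | None = None
    state_names: list[str] = field(default_factory=list)

    def state_index(self, state: int | str) -> int:
        if isinstance(state, str):
            try:
                return self.state_names.index(state)
            except ValueError:
                raise KeyError(f"unknown state {state!r}") from None
        return int(state)


@dataclass
class TargetWeights:
    """Normalized per-sample weights in a chosen target ensemble."""

    w_n: np.ndarray
    target_state: str

    def __post_init__(self) -> None:
        self.w_n = np.asarray(self.w_n, dtype=float)
        if np.any(self.w_n < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.w_n.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _log_denominator(u_kn: np.ndarray, f_k: np.ndarray, log_N_k: np.ndarray
                     ) -> np.ndarray:
    """log Σ_k N_k exp(f_k − u_kn), per sample."""
    return logsumexp(f_k[:, None] - u_kn + log_N_k[:, None], axis=0)


def _sci_update(u_kn: np.ndarray, f_k: np.ndarray, log_N_k: np.ndarray
                ) -> np.ndarray:
    log_denom = _log_denominator(u_kn, f_k, log_N_k)
    f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
    return f_new - f_new[0]


def solve_mbar(
    u: ReducedPotentialMatrix,
    tol: float = 1e-8,
    max_iter: int = 10000,
    f_init: np.ndarray | None = None,
    n_sci_warmup: int = 30,
) -> MBARResult:
    """Solve the MBAR self-consistency equations.

    Self-consistent iteration is used for ``n_sci_warmup`` sweeps, then
    Newton's method on the convex maximum-likelihood objective takes over;
    if Newton stalls, self-consistent iteration continues up to
    ``max_iter``.  Non-convergence flags the result instead of raising.
    """
    if u.n_states < 2:
        raise ValueError("MBAR needs at least two states")
    if np.any(u.N_k == 0):
        raise ValueError("every state must contribute at least one sample")
    u_kn = u.u_kn
    log_N_k = np.log(u.N_k.astype(float))
    if f_init is None:
        f = np.zeros(u.n_states)
    else:
        f = np.array(f_init, dtype=float)
        n_sci_warmup = min(n_sci_warmup, 3)  # warm start: go to Newton quickly
    f -= f[0]

    n_iter = 0
    for _ in range(n_sci_warmup):
        f_new = _sci_update(u_kn, f, log_N_k)
        n_iter += 1
        if np.max(np.abs(f_new - f)) <= tol:
            return MBARResult(f_new, True, _residual(u_kn, f_new, log_N_k),
                              n_iter, state_names=list(u.state_names))
        f = f_new

    f = _newton(u_kn, f, u.N_k, log_N_k, tol)
    res = _residual(u_kn, f, log_N_k)
    while res > tol and n_iter < max_iter:
        f = _sci_update(u_kn, f, log_N_k)
        n_iter += 1
        res = _residual(u_kn, f, log_N_k)
    return MBARResult(f, res <= tol, res, n_iter,
                      state_names=list(u.state_names))


def _residual(u_kn: np.ndarray, f: np.ndarray, log_N_k: np.ndarray) -> float:
    return float(np.max(np.abs(_sci_update(u_kn, f, log_N_k) - f)))


def _newton(u_kn: np.ndarray, f: np.ndarray, N_k: np.ndarray,
            log_N_k: np.ndarray, tol: float, max_steps: int = 60) -> np.ndarray:
    """Newton iterations on the convex MBAR objective (f_0 fixed at 0)."""
    N = u_kn.shape[1]
    for _ in range(max_steps):
        log_denom = _log_denominator(u_kn, f, log_N_k)
        # W_kn = N_k exp(f_k − u_kn) / denom_n; rows sum over n to N_k at optimum
        log_W = f[:, None] - u_kn + log_N_k[:, None] - log_denom[None, :]
        W = np.exp(log_W)
        g = W.sum(axis=1) - N_k                       # gradient wrt f
        H = np.diag(W.sum(axis=1)) - W @ W.T          # Hessian
        g1, H1 = g[1:], H[1:, 1:]
        try:
            step = np.linalg.solve(H1 + 1e-12 * N * np.eye(len(g1)), g1)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        f = f.copy()
        f[1:] -= step
        if np.max(np.abs(step)) <= 0.1 * tol:
            break
    return f - f[0]


# ---------------------------------------------------------------------------
# Reweighting and cycle composition
# ---------------------------------------------------------------------------

def compute_weights(
    u: ReducedPotentialMatrix,
    result: MBARResult,
    target: int | str | np.ndarray,
) -> TargetWeights:
    """Per-sample weights in a target ensemble.

    ``target`` is a state name/index (uses that row of u_kn) or an explicit
    reduced-potential row evaluated on every sample.  The special name
    ``"mixture"`` weights samples in the sampled mixture distribution.
    """
    if not result.converged:
        raise ValueError("MBAR result not converged; refusing to reweight")
    log_N_k = np.log(u.N_k.astype(float))
    log_denom = _log_denominator(u.u_kn, result.f_k, log_N_k)
    if isinstance(target, str) and target == "mixture":
        # u_mix = −ln Σ (N_k/N) e^{f_k − u_kn}: the weights cancel exactly
        log_w = np.full(u.n_samples, -np.log(u.n_samples))
        name = "mixture"
    elif isinstance(target, np.ndarray):
        if target.shape != (u.n_samples,):
            raise ValueError("explicit u_target row has wrong length")
        log_w = -target - log_denom
        name = "explicit"
    else:
        k = u.state_index(target)
        log_w = -u.u_kn[k] - log_denom
        name = u.state_names[k]
    log_w -= logsumexp(log_w)
    return TargetWeights(np.exp(log_w), target_state=name)


def free_energy_difference(result: MBARResult, i: int | str, j: int | str,
                           kT: float = 1.0) -> float:
    """ΔG(i→j) = kT (f_j − f_i)."""
    return float(kT * (result.f_k[result.state_index(j)]
                       - result.f_k[result.state_index(i)]))


def compose_cycle(result: MBARResult, end_state_a: int | str,
                  end_state_b: int | str, common_reference: int | str,
                  kT: float = 1.0) -> float:
    """ΔG(a→b) through a common reference: the reference cancels exactly."""
    leg_a = free_energy_difference(result, common_reference, end_state_a, kT)
    leg_b = free_energy_difference(result, common_reference, end_state_b, kT)
    return leg_b - leg_a


# ---------------------------------------------------------------------------
# Bootstrap uncertainties
# ---------------------------------------------------------------------------

def _moving_block_resample(block: np.ndarray, block_length: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Circular moving-block resample of one state's time-ordered columns."""
    n = len(block)
    if n == 0:
        return block
    L = max(1, min(block_length, n))
    n_blocks = int(np.ceil(n / L))
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(L)[None, :]) % n
    return block[idx.ravel()[:n]]


def bootstrap_uncertainty(
    u: ReducedPotentialMatrix,
    estimator: Callable[..., float | np.ndarray],
    n_boot: int = 200,
    seed: int | None = None,
    f_init: np.ndarray | None = None,
    block_length: int | None = None,
    synchronized: bool = False,
) -> np.ndarray:
    """Standard error of an estimator by per-state moving-block bootstrap.

    Within each state's time-ordered column block (the N_k layout),
    circular contiguous blocks of ``block_length`` samples (default: one
    twentieth of the state's series) are resampled with replacement,
    preserving the N_k counts; block resampling keeps the estimate honest
    when each series is autocorrelated.  With ``synchronized`` (requires
    equal N_k) the same block positions are used in every state, which
    additionally preserves the cross-state correlation created by replica
    exchange.  ``estimator`` is called as ``estimator(matrix, f_init=...)``
    when it accepts a warm start, else ``estimator(matrix)``.  Returns the
    element-wise standard deviation over replicates.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap replicates")
    if synchronized and len(set(u.N_k.tolist())) != 1:
        raise ValueError("synchronized resampling needs equal N_k")
    rng = np.random.default_rng(seed)
    blocks = u.sample_blocks()
    values = []
    for _ in range(n_boot):
        if synchronized:
            t = _moving_block_resample(
                np.arange(u.N_k[0]),
                block_length or max(1, int(u.N_k[0]) // 20), rng)
            cols = np.concatenate([b[t] for b in blocks])
        else:
            cols = np.concatenate([
                _moving_block_resample(
                    b, block_length or max(1, len(b) // 20), rng)
                for b in blocks
            ])
        rep = ReducedPotentialMatrix(u.u_kn[:, cols], u.N_k.copy(),
                                     list(u.state_names))
        try:
            values.append(estimator(rep, f_init=f_init))
        except TypeError:
            values.append(estimator(rep))
    arr = np.asarray(values, dtype=float)
    return arr.std(axis=0, ddof=1)


def solve_mbar_f(u: ReducedPotentialMatrix,
                 f_init: np.ndarray | None = None) -> np.ndarray:
    """Convenience estimator: the f_k vector (for bootstrap_uncertainty)."""
    return solve_mbar(u, f_init=f_init).f_k


def statistical_inefficiency(series: np.ndarray, mintime: int = 3) -> float:
    """g = 1 + 2 τ from the normalized autocorrelation (positive part)."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    var = float(x @ x) / n
    if var == 0 or n < 2:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = float(x[:-t] @ x[t:]) / ((n - t) * var)
        if c <= 0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def thin_series(series: np.ndarray) -> np.ndarray:
    """Indices of approximately uncorrelated samples in a time series.

    Optional pre-processing for correlated input; the shipped surrogate
    sampler thins during sampling, so this is off the default path.
    """
    g = statistical_inefficiency(series)
    return np.arange(0, len(series), max(1, int(np.ceil(g))))
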