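"""Comparison denoisers: EEMD-ICA, EEMD-CCA and wavelet thresholding.

All three are single-channel strategies.  The EEMD-based pair first expands
the trial into a multichannel matrix of intrinsic mode functions (IMFs) plus
residue — ensemble EMD averages the decomposition over many noise-perturbed
copies of the signal to suppress mode mixing — and then applies a blind
source separation step:

* EEMD-ICA runs FastICA on the IMF matrix and keeps the source most
  correlated with a supplied reference waveform (note this selection step
  uses the reference, i.e. the evaluation target, as the method itself
  prescribes).
* EEMD-CCA computes the first canonical variate between the IMF matrix and
  its one-sample delay; temporally structured activity is maximally
  autocorrelated and broadband artifacts are not.

Wavelet thresholding shrinks detail coefficients with the universal soft
threshold sqrt(2 ln N) * sigma_hat, sigma_hat estimated from the finest
detail level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.linalg import solve_banded


@dataclass(frozen=True)
class EemdConfig:
    """Ensemble EMD parameters: 100 ensembles, noise at 0.2 x signal SD."""

    n_ensembles: int = 100
    noise_std: float = 0.2
    max_imfs: int = 8
    sift_sd_threshold: float = 0.2
    max_sift_iters: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class ImfStack:
    """IMFs (k x T) plus residue of a 1-D decomposition."""

    imfs: np.ndarray
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def as_channels(self) -> np.ndarray:
        """IMFs and residue stacked as a (k+1) x T multichannel matrix."""
        return np.vstack([self.imfs, self.residue[None, :]])


class ConvergenceError(RuntimeError):
    """FastICA failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_iter: int, delta: float):
        super().__init__(message)
        self.n_iter = n_iter
        self.delta = delta


# ---------------------------------------------------------------------------
# EMD / EEMD
# ---------------------------------------------------------------------------

def _natural_cubic_eval(xk: np.ndarray, yk: np.ndarray,
                        xq: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (xk, yk), evaluated at xq.

    A lean tridiagonal solve for the knot second derivatives; xk must be
    strictly increasing with at least two knots.  Kept minimal because the
    sifting loop calls it tens of thousands of times per ensemble.
    """
    n = xk.size
    if n == 2:
        return np.interp(xq, xk, yk)
    h = np.diff(xk)
    slope = np.diff(yk) / h
    # interior second derivatives, natural boundary (m0 = m_{n-1} = 0)
    ab = np.zeros((3, n - 2))
    ab[0, 1:] = h[1:-1]
    ab[1] = 2.0 * (h[:-1] + h[1:])
    ab[2, :-1] = h[1:-1]
    m = np.zeros(n)
    m[1:-1] = solve_banded((1, 1), ab, 6.0 * np.diff(slope))
    i = np.clip(np.searchsorted(xk, xq, side="right") - 1, 0, n - 2)
    dx = xq - xk[i]
    hi = h[i]
    a = yk[i]
    b = slope[i] - hi * (2.0 * m[i] + m[i + 1]) / 6.0
    c = m[i] / 2.0
    d = (m[i + 1] - m[i]) / (6.0 * hi)
    return a + dx * (b + dx * (c + dx * d))


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at the ends."""
    n = x.size
    pos = idx.astype(float)
    vals = x[idx]
    # mirror up to two extrema across each end to tame boundary swings
    if len(idx) > 1:
        k = min(2, len(idx) - 1)
        left_pos, left_val = -pos[1:k + 1][::-1], vals[1:k + 1][::-1]
        right_pos = 2 * (n - 1) - pos[-k - 1:-1][::-1]
        right_val = vals[-k - 1:-1][::-1]
    else:
        left_pos, left_val = pos[:1] - 1, vals[:1]
        right_pos, right_val = pos[-1:] + 1, vals[-1:]
    p = np.concatenate([left_pos, pos, right_pos])
    v = np.concatenate([left_val, vals, right_val])
    order = np.argsort(p)
    p, v = p[order], v[order]
    keep = np.concatenate([[True], np.diff(p) > 0])
    return _natural_cubic_eval(p[keep], v[keep], np.arange(n, dtype=float))


def _sift_1d(x: np.ndarray) -> np.ndarray | None:
    """One 1-D sift; None when fewer than 2 maxima or 2 minima remain."""
    mid = x[1:-1]
    maxima = np.flatnonzero((mid > x[:-2]) & (mid > x[2:])) + 1
    minima = np.flatnonzero((mid < x[:-2]) & (mid < x[2:])) + 1
    if len(maxima) < 2 or len(minima) < 2:
        return None
    mean = 0.5 * (_envelope(x, maxima) + _envelope(x, minima))
    return x - mean


def emd(signal: np.ndarray, sd_threshold: float = 0.2,
        max_imfs: int = 8, max_sift_iters: int = 12) -> ImfStack:
    """Plain empirical mode decomposition of a 1-D signal.

    Sifting stops per IMF when the Cauchy-type criterion
    sum((h_prev - h)^2 / h_prev^2) < sd_threshold is met; the whole
    decomposition stops when the residue is monotone (fewer than two maxima
    or minima).  Completeness is exact by construction.
    """
    x = np.asarray(signal, dtype=float)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        h_prev = residue
        h = _sift_1d(h_prev)
        if h is None:
            break
        for _ in range(max_sift_iters - 1):
            mask = np.abs(h_prev) >= 1e-12
            sd = float(np.sum(((h_prev - h)[mask] / h_prev[mask]) ** 2))
            if sd < sd_threshold:
                break
            h_prev = h
            h_next = _sift_1d(h_prev)
            if h_next is None:
                break
            h = h_next
        imfs.append(h)
        residue = residue - h
    if not imfs:
        return ImfStack(imfs=np.empty((0, x.size)), residue=residue)
    return ImfStack(imfs=np.vstack(imfs), residue=residue)


def eemd(signal: np.ndarray, config: EemdConfig = EemdConfig()) -> ImfStack:
    """Ensemble EMD: average the IMFs of many noise-perturbed decompositions.

    Each of the ``n_ensembles`` realisations adds fresh white Gaussian noise
    with SD ``noise_std * std(signal)``, decomposes by plain EMD, and the
    IMFs are averaged index-by-index (shorter decompositions contribute
    zeros at the missing indices; their residue is folded into the ensemble
    residue).  Deterministic for a fixed seed.
    """
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(config.seed)
    sigma = config.noise_std * x.std()
    acc_imfs = np.zeros((config.max_imfs, x.size))
    acc_res = np.zeros(x.size)
    max_k = 0
    for _ in range(config.n_ensembles):
        noisy = x + rng.normal(0.0, sigma, size=x.size) if sigma > 0 else x
        stack = emd(noisy, config.sift_sd_threshold, config.max_imfs,
                    config.max_sift_iters)
        k = stack.n_imfs
        max_k = max(max_k, k)
        if k:
            acc_imfs[:k] += stack.imfs
        acc_res += stack.residue
    inv = 1.0 / config.n_ensembles
    return ImfStack(imfs=acc_imfs[:max_k] * inv, residue=acc_res * inv)


# ---------------------------------------------------------------------------
# FastICA
# ---------------------------------------------------------------------------

def fastica(X: np.ndarray, n_components: int | None = None, *,
            max_iter: int = 500, tol: float = 1e-7,
            seed: int = 0,
            on_nonconvergence: str = "raise") -> tuple[np.ndarray, np.ndarray]:
    """Symmetric fixed-point ICA with the log-cosh contrast.

    ``X`` has channels as rows.  The data are centred and whitened by
    eigendecomposition of the covariance; the orthogonal unmixing rotation is
    estimated by the negentropy-maximising fixed point g = tanh, with
    symmetric decorrelation each step.  Returns ``(S, W)`` with ``S = W @
    (X - mean)``; rows of ``S`` have unit variance.

    Raises ``ValueError`` if the data rank is below ``n_components`` and
    :class:`ConvergenceError` if the rotation does not converge
    (``on_nonconvergence="warn"`` downgrades that to a warning and returns
    the last iterate — mixtures of merely quasi-independent channels, such
    as IMF stacks, routinely stall at a small residual delta).
    """
    X = np.asarray(X, dtype=float)
    n_ch, n_t = X.shape
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed the channel count")
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n_t
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[n_components - 1] <= 1e-10 * max(evals[0], 1e-300):
        raise ValueError(
            f"data rank below n_components={n_components} "
            f"(eigenvalue {evals[n_components - 1]:.3e})")
    K = (evecs[:, :n_components] /
         np.sqrt(evals[:n_components])).T  # whitening matrix
    Z = K @ Xc

    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n_components, n_components))

    def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
        s, u = np.linalg.eigh(w @ w.T)
        return (u / np.sqrt(s)) @ u.T @ w

    W = _sym_decorrelate(W)
    delta = np.inf
    for it in range(max_iter):
        WZ = W @ Z
        g = np.tanh(WZ)
        g_prime = (1.0 - g * g).mean(axis=1)
        W_new = _sym_decorrelate(g @ Z.T / n_t - g_prime[:, None] * W)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W))
                                    - 1.0)))
        W = W_new
        if delta < tol:
            break
    else:
        if on_nonconvergence == "warn":
            import warnings

            warnings.warn(
                f"FastICA stopped after {max_iter} iterations with "
                f"delta {delta:.3e}; returning the last iterate",
                RuntimeWarning, stacklevel=2)
        else:
            raise ConvergenceError(
                f"FastICA did not converge in {max_iter} iterations "
                f"(last delta {delta:.3e})", max_iter, delta)
    unmixing = W @ K
    return unmixing @ Xc, unmixing


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def cca(X1: np.ndarray, X2: np.ndarray, ridge: float = 1e-8
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All canonical variates/correlations of two channel-major matrices.

    Solved by SVD of the whitened cross-covariance
    C11^{-1/2} C12 C22^{-1/2}; a ridge of ``ridge * trace`` is added to each
    covariance block to keep the whitening well posed.  Returns
    ``(variates, rhos, W1, W2)`` with variates ordered by descending rho.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must have equal temporal length")
    n_t = X1.shape[1]
    X1c = X1 - X1.mean(axis=1, keepdims=True)
    X2c = X2 - X2.mean(axis=1, keepdims=True)
    C11 = X1c @ X1c.T / n_t
    C22 = X2c @ X2c.T / n_t
    C12 = X1c @ X2c.T / n_t
    for C in (C11, C22):
        tr = np.trace(C)
        if tr <= 0:
            raise ValueError("singular covariance block (zero trace)")
        C += ridge * tr * np.eye(C.shape[0])

    def _inv_sqrt(C: np.ndarray) -> np.ndarray:
        s, u = np.linalg.eigh(C)
        if s.min() <= 0:
            raise ValueError("covariance not positive definite; "
                             "increase the ridge")
        return (u / np.sqrt(s)) @ u.T

    S1, S2 = _inv_sqrt(C11), _inv_sqrt(C22)
    U, rhos, Vt = np.linalg.svd(S1 @ C12 @ S2)
    W1 = S1 @ U
    W2 = S2 @ Vt.T
    variates = W1.T @ X1c
    return variates, np.clip(rhos, 0.0, 1.0), W1, W2


def cca_first_variate(X1: np.ndarray, X2: np.ndarray,
                      ridge: float = 1e-8) -> tuple[np.ndarray, float]:
    """First canonical variate of X1 and its canonical correlation with X2."""
    variates, rhos, _, _ = cca(X1, X2, ridge)
    return variates[0], float(rhos[0])


# ---------------------------------------------------------------------------
# Denoisers
# ---------------------------------------------------------------------------

def _ls_rescale(source: np.ndarray, trial: np.ndarray,
                reference: np.ndarray) -> np.ndarray:
    """Sign-align a BSS output to the reference, then least-squares scale it.

    BSS amplitudes are arbitrary; the correlation metric is scale-invariant,
    so this only restores a plottable amplitude.
    """
    s = np.asarray(source, dtype=float)
    c = np.corrcoef(s, reference)[0, 1]
    if np.isfinite(c) and c < 0:
        s = -s
    denom = float(np.dot(s, s))
    if denom > 0:
        alpha = abs(float(np.dot(trial, s)) / denom)
        if alpha > 0:
            s = alpha * s
    return s


def eemd_ica_denoise(trial: np.ndarray, reference: np.ndarray,
                     eemd_cfg: EemdConfig = EemdConfig()) -> np.ndarray:
    """EEMD-ICA: unmix the IMF matrix, keep the source closest to the reference."""
    trial = np.asarray(trial, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != trial.shape:
        raise ValueError("reference must have the trial's length")
    X = eemd(trial, eemd_cfg).as_channels()
    # drop numerically dead channels (e.g. an all-but-constant residue)
    keep = X.std(axis=1) > 1e-12 * max(X.std(), 1e-300)
    X = X[keep]
    n_t = X.shape[1]
    cov = (X - X.mean(axis=1, keepdims=True))
    evals = np.linalg.eigvalsh(cov @ cov.T / n_t)
    rank = int(np.sum(evals > 1e-10 * evals.max()))
    n_comp = min(rank, X.shape[0])
    # IMF channels are only quasi-independent, so the fixed point can stall
    # at a tiny delta for some initialisations: retry a few seeds, then
    # accept the near-converged iterate.
    S = None
    for attempt in range(3):
        try:
            S, _ = fastica(X, n_components=n_comp, tol=1e-5, max_iter=1000,
                           seed=eemd_cfg.seed + attempt)
            break
        except ConvergenceError:
            continue
    if S is None:
        S, _ = fastica(X, n_components=n_comp, tol=1e-5, max_iter=1000,
                       seed=eemd_cfg.seed, on_nonconvergence="warn")
    corrs = [abs(np.corrcoef(s, reference)[0, 1]) for s in S]
    best = S[int(np.argmax(corrs))]
    return _ls_rescale(best, trial, reference)


def eemd_cca_denoise(trial: np.ndarray,
                     eemd_cfg: EemdConfig = EemdConfig()) -> np.ndarray:
    """EEMD-CCA: first canonical variate of the IMF matrix vs its delay.

    ``X2`` is the one-sample delay of the IMF matrix ``X1``; the variate is
    computed on the overlapping columns 1..T-1 and front-padded with its
    first value so the output keeps the trial's length.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.size < 3:
        raise ValueError("trial too short for delayed CCA")
    X = eemd(trial, eemd_cfg).as_channels()
    keep = X.std(axis=1) > 1e-12 * max(X.std(), 1e-300)
    X = X[keep]
    v, _ = cca_first_variate(X[:, 1:], X[:, :-1])
    v = np.concatenate([[v[0]], v])
    ref = np.asarray(trial, dtype=float)
    return _ls_rescale(v, trial, ref)


def wavelet_threshold_denoise(trial: np.ndarray, wavelet: str = "db4",
                              level: int | None = None) -> np.ndarray:
    """Universal soft-threshold wavelet shrinkage of a 1-D signal.

    Decomposes to level ``floor(log2 N) - 2`` (at least 1) with db4, soft-
    thresholds every detail level at sqrt(2 ln N) * sigma_hat where
    sigma_hat = median(|d1|)/0.6745, and reconstructs.  Approximation
    coefficients are untouched, so slow ERP components pass through.
    """
    x = np.asarray(trial, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("signal too short for wavelet denoising")
    if level is None:
        level = max(1, int(np.floor(np.log2(n))) - 2)
    level = min(level, pywt.dwt_max_level(n, wavelet))
    coeffs = pywt.wavedec(x, wavelet, level=level)
    d1 = coeffs[-1]
    sigma = float(np.median(np.abs(d1)) / 0.6745)
    thr = sigma * np.sqrt(2.0 * np.log(n))
    if thr > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                                for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet)[:n]
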