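"""Per-hashtag cutoff calling from bimodal normalized signal.

For each hashtag the normalized signal across cells is (approximately) a
mixture of a background mode and a true-positive mode. The pipeline here is:

1. **Reshape** (only when more than four hashtags are pooled): because a
   hashtag's true positives are roughly ``1/N`` of all cells, the background
   peak dominates and drags the mixture fit. Cells below an empirical
   low-signal bound ``c`` are sorted ascending and thinned to every
   ``theta = floor(N/2)``-th value; every value at or above ``c`` is kept.
2. **Fit** a two-component univariate Gaussian mixture by EM.
3. **Cutoff**: with components ``N(mu1, sigma1^2)`` and ``N(mu2, sigma2^2)``,
   ``mu1 < mu2``, the threshold separating background from positive is

       cutoff = mu1 + (sigma1^(1/n) / (sigma1^(1/n) + sigma2^(1/n))) * (mu2 - mu1)

   with rank ``n`` (default 2). The mixing factor lies strictly in (0, 1),
   so the cutoff always falls strictly between the two means.
4. **Validate**: a cutoff below the empirical floor (1.5 for CLR, 3 for log
   normalization) is replaced by the global minimum of a linearly
   interpolated density of the signal between the two fitted means.

The EM is fully deterministic: components are initialized by a hard split
at the median, updated with closed-form M-steps, and relabeled so
``mu1 < mu2`` after fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import NormalizedMatrix
from .errors import DegenerateFitError, ValidationError

logger = logging.getLogger(__name__)

#: Empirical low-signal bound per normalization method: doubles as the
#: reshape threshold ``c`` and the cutoff validation floor.
EMPIRICAL_FLOORS = {"clr": 1.5, "log": 3.0}

#: Minimum points required for a two-component fit.
MIN_FIT_POINTS = 20

_SIGMA_COLLAPSE = 1e-6  # relative to the signal SD
_WEIGHT_COLLAPSE = 1e-3


@dataclass(frozen=True)
class ReshapeConfig:
    """Controls the low-signal thinning applied before mixture fitting.

    ``theta`` is ``floor(n_hashtags / 2)``; thinning is enabled only when
    more than four hashtags are pooled, since with few hashtags the
    positive fraction per hashtag is large enough for a direct fit.
    """

    n_hashtags: int
    empirical_cutoff: float = 1.5

    def __post_init__(self):
        if self.n_hashtags < 1:
            raise ValidationError("n_hashtags must be positive")

    @property
    def theta(self) -> int:
        return self.n_hashtags // 2

    @property
    def enabled(self) -> bool:
        return self.n_hashtags > 4

    @classmethod
    def for_method(cls, n_hashtags: int, method: str) -> "ReshapeConfig":
        return cls(n_hashtags=n_hashtags, empirical_cutoff=EMPIRICAL_FLOORS[method])


@dataclass(frozen=True)
class HashtagFit:
    """Record of one hashtag's mixture fit and derived cutoff.

    ``mu1 < mu2`` for a successful two-component fit; on a degenerate fit
    (component collapse) both means equal the single-Gaussian mean, the
    cutoff is the empirical floor and ``cutoff_adjusted`` is set.
    """

    mu1: float
    sigma1: float
    weight1: float
    mu2: float
    sigma2: float
    weight2: float
    cutoff: float
    rank: int = 2
    cutoff_adjusted: bool = False
    converged: bool = True
    degenerate: bool = False
    n_points_fit: int = 0


@dataclass(frozen=True)
class CutoffSet:
    """Per-hashtag map of :class:`HashtagFit`, in hashtag order."""

    fits: dict[str, HashtagFit] = field(default_factory=dict)

    def __getitem__(self, hashtag: str) -> HashtagFit:
        return self.fits[hashtag]

    def __contains__(self, hashtag: str) -> bool:
        return hashtag in self.fits

    def __iter__(self):
        return iter(self.fits)

    def __len__(self) -> int:
        return len(self.fits)

    def cutoffs(self) -> dict[str, float]:
        return {h: f.cutoff for h, f in self.fits.items()}

    def to_frame(self):
        import pandas as pd

        rows = []
        for h, f in self.fits.items():
            rows.append(
                {
                    "hashtag": h,
                    "mu1": f.mu1,
                    "sigma1": f.sigma1,
                    "weight1": f.weight1,
                    "mu2": f.mu2,
                    "sigma2": f.sigma2,
                    "weight2": f.weight2,
                    "cutoff": f.cutoff,
                    "rank": f.rank,
                    "cutoff_adjusted": f.cutoff_adjusted,
                    "converged": f.converged,
                    "degenerate": f.degenerate,
                    "n_points_fit": f.n_points_fit,
                }
            )
        return pd.DataFrame(rows)


def reshape_low_signals(signal: np.ndarray, cfg: ReshapeConfig) -> np.ndarray:
    """Thin the low-signal tail so the background peak cannot swamp the fit.

    Values below ``cfg.empirical_cutoff`` are sorted ascending and only the
    values at 1-based positions ``1, 1 + theta, 1 + 2*theta, ...`` (while
    the position does not exceed the number of low values) are kept; every
    value at or above the bound is always retained. With four or fewer
    hashtags the signal is returned unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValidationError("empty signal")
    if not np.isfinite(signal).all():
        raise ValidationError("signal must be finite")
    if not cfg.enabled:
        return signal.copy()
    c = cfg.empirical_cutoff
    neg = np.sort(signal[signal < c])
    pos = signal[signal >= c]
    # positions 1, 1+theta, ... <= Card(neg), i.e. 0-based stride slicing
    sampled = neg[:: cfg.theta] if neg.size else neg
    return np.concatenate([sampled, pos])


def fit_two_gaussians(
    signal: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, float, float, float, float, bool]:
    """Maximum-likelihood two-component Gaussian mixture via EM.

    Initialization is a hard split at the median followed by closed-form
    M-steps, which makes the fit deterministic; ``seed`` is accepted for
    interface symmetry with stochastic fitters but is not consumed.
    Convergence is declared when the relative log-likelihood change
    ``|ll - ll_prev| / max(1, |ll|)`` drops below ``tol``.

    Returns
    -------
    (mu1, sigma1, weight1, mu2, sigma2, weight2, converged)
        Components ordered so ``mu1 < mu2``.

    Raises
    ------
    DegenerateFitError
        When a component's SD collapses below ``1e-6`` of the signal SD or
        a weight below ``1e-3``; the error carries the single-Gaussian
        (mean, SD) fallback.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < MIN_FIT_POINTS:
        raise ValidationError(
            f"need at least {MIN_FIT_POINTS} points for a mixture fit, got {x.size}"
        )
    if not np.isfinite(x).all():
        raise ValidationError("signal must be finite")
    sd_all = float(x.std())
    mean_all = float(x.mean())
    if sd_all == 0.0:
        raise DegenerateFitError("constant signal", mu=mean_all, sigma=0.0)

    # hard split at the median, then closed-form M-step
    med = float(np.median(x))
    lower = x[x <= med]
    upper = x[x > med]
    if lower.size == 0 or upper.size == 0:
        raise DegenerateFitError(
            "median split produced an empty component", mu=mean_all, sigma=sd_all
        )
    mu = np.array([lower.mean(), upper.mean()])
    sigma = np.array([lower.std(), upper.std()])
    sigma = np.maximum(sigma, _SIGMA_COLLAPSE * sd_all)
    w = np.array([lower.size, upper.size], dtype=float) / x.size

    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step: responsibilities via log-sum-exp
        logp = (
            np.log(w)[None, :]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sigma)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])

        # M-step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(var)

        if (sigma < _SIGMA_COLLAPSE * sd_all).any() or (w < _WEIGHT_COLLAPSE).any():
            raise DegenerateFitError(
                "mixture component collapsed during EM", mu=mean_all, sigma=sd_all
            )
        if abs(ll - ll_prev) / max(1.0, abs(ll)) < tol:
            converged = True
            break
        ll_prev = ll

    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    return (
        float(mu[0]),
        float(sigma[0]),
        float(w[0]),
        float(mu[1]),
        float(sigma[1]),
        float(w[1]),
        converged,
    )


def compute_cutoff(
    mu1: float, sigma1: float, mu2: float, sigma2: float, rank: int = 2
) -> float:
    """Threshold between background ``N(mu1, sigma1^2)`` and positive ``N(mu2, sigma2^2)``.

    ``cutoff = mu1 + (sigma1^(1/n) / (sigma1^(1/n) + sigma2^(1/n))) * (mu2 - mu1)``
    with rank ``n >= 1``. The weight on the gap is strictly inside (0, 1),
    so the cutoff lies strictly between the means; as ``n`` grows both
    n-th roots tend to 1 and the cutoff tends to the midpoint.
    """
    if mu1 >= mu2:
        raise ValidationError(f"component means must satisfy mu1 < mu2 ({mu1} >= {mu2})")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValidationError("component SDs must be positive")
    if rank < 1:
        raise ValidationError("rank must be >= 1")
    r1 = sigma1 ** (1.0 / rank)
    r2 = sigma2 ** (1.0 / rank)
    return mu1 + (r1 / (r1 + r2)) * (mu2 - mu1)


def validate_cutoff(
    cutoff: float,
    signal: np.ndarray,
    mu1: float,
    mu2: float,
    floor: float,
    n_grid: int = 512,
) -> tuple[float, bool]:
    """Guard against an implausibly low cutoff.

    A cutoff at or above ``floor`` is returned unchanged. Below the floor,
    the signal density between the two fitted means is approximated by a
    histogram (Sturges bins) linearly interpolated between bin centers on a
    ``n_grid``-point even grid over ``[mu1, mu2]``, and the grid point of
    minimum density becomes the cutoff. With fewer than 10 signal values in
    the window the floor itself is used, with a warning.
    """
    if mu1 >= mu2:
        raise ValidationError("mu1 < mu2 required")
    if cutoff >= floor:
        return float(cutoff), False
    signal = np.asarray(signal, dtype=float)
    window = signal[(signal >= mu1) & (signal <= mu2)]
    if window.size < 10:
        logger.warning(
            "cutoff %.3f below floor %.3f but only %d signal values between the "
            "component means; falling back to the floor",
            cutoff,
            floor,
            window.size,
        )
        return float(floor), True
    edges = np.histogram_bin_edges(window, bins="sturges")
    counts, _ = np.histogram(window, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.linspace(mu1, mu2, n_grid)
    density = np.interp(grid, centers, counts.astype(float))
    return float(grid[int(np.argmin(density))]), True


def call_cutoffs(
    norm: NormalizedMatrix,
    rank: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    empirical_floor: float | None = None,
) -> CutoffSet:
    """Run the full per-hashtag pipeline: reshape, fit, cutoff, validate.

    ``empirical_floor`` defaults to the normalization method's bound (1.5
    for CLR, 3 for log) and doubles as the low-signal reshape threshold.
    A hashtag whose mixture fit degenerates gets the floor as its cutoff,
    flagged as adjusted, with a logged warning. Deterministic given inputs.
    """
    floor = EMPIRICAL_FLOORS[norm.method] if empirical_floor is None else empirical_floor
    cfg = ReshapeConfig(n_hashtags=norm.n_hashtags, empirical_cutoff=floor)
    fits: dict[str, HashtagFit] = {}
    for j, hashtag in enumerate(norm.hashtag_names):
        signal = norm.values[:, j]
        reshaped = reshape_low_signals(signal, cfg)
        try:
            mu1, s1, w1, mu2, s2, w2, conv = fit_two_gaussians(
                reshaped, seed=seed, tol=tol, max_iter=max_iter
            )
        except DegenerateFitError as exc:
            logger.warning(
                "hashtag %s: degenerate mixture fit (%s); cutoff set to floor %.3f",
                hashtag,
                exc,
                floor,
            )
            fits[hashtag] = HashtagFit(
                mu1=exc.mu,
                sigma1=exc.sigma,
                weight1=0.5,
                mu2=exc.mu,
                sigma2=exc.sigma,
                weight2=0.5,
                cutoff=float(floor),
                rank=rank,
                cutoff_adjusted=True,
                converged=False,
                degenerate=True,
                n_points_fit=int(reshaped.size),
            )
            continue
        raw_cutoff = compute_cutoff(mu1, s1, mu2, s2, rank=rank)
        cutoff, adjusted = validate_cutoff(raw_cutoff, signal, mu1, mu2, floor)
        fits[hashtag] = HashtagFit(
            mu1=mu1,
            sigma1=s1,
            weight1=w1,
            mu2=mu2,
            sigma2=s2,
            weight2=w2,
            cutoff=cutoff,
            rank=rank,
            cutoff_adjusted=adjusted,
            converged=conv,
            degenerate=False,
            n_points_fit=int(reshaped.size),
        )
    return CutoffSet(fits)
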