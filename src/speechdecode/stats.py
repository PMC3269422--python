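"""Resampling statistics shared by the decoding and encoding models.

Correlation coefficients are aggregated on the Fisher-z scale, parameter
uncertainty is quantified by the standard deviation across Monte Carlo
resamples (the "resampled SE"), significance of individual parameters is
screened by the t-ratio (mean / resampled SE), and multiplicity is handled
with Benjamini-Hochberg false-discovery-rate selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError

__all__ = [
    "ResampleEstimate",
    "RandomizationResult",
    "fisher_mean",
    "fisher_z",
    "fisher_inverse",
    "randomization_test",
    "fdr_select",
    "resample_stats",
    "bonferroni_alpha",
    "one_sample_t",
]


@dataclass
class ResampleEstimate:
    """Per-parameter summary of a set of resampled estimates.

    ``se`` is the standard deviation over resamples (ddof=1) and ``t_ratio``
    is ``mean / se``; entries where ``se == 0`` have an undefined t-ratio and
    are reported as NaN.
    """

    mean: np.ndarray
    se: np.ndarray
    t_ratio: np.ndarray
    n_resamples: int


@dataclass
class RandomizationResult:
    """Outcome of a trial-shuffling randomization test.

    ``p`` follows the plug-in rule (proportion of null statistics >= observed,
    which can be exactly zero); ``p_conservative`` is the (k+1)/(n+1) variant
    that is bounded away from zero.
    """

    p: float
    p_conservative: float
    observed: float
    n_shuffles: int

    def __float__(self) -> float:  # convenience for numeric comparisons
        return float(self.p)


_R_CLIP = 1.0 - 1e-12


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh transform with |r| = 1 clipped (a warning is emitted)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlations at |r| >= 1 clipped before Fisher transform")
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    return np.arctanh(r)


def fisher_inverse(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def fisher_mean(rs) -> float:
    """Average correlations on the Fisher-z scale and transform back.

    NaN entries (e.g. zero-variance channels) are excluded.
    """
    rs = np.asarray(rs, dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        raise InvalidInputError("fisher_mean requires at least one finite correlation")
    return float(np.tanh(np.mean(fisher_z(rs))))


def _paired_correlation(recons, originals) -> float:
    """Fisher-averaged Pearson r over (reconstruction, original) pairs."""
    rs = []
    for a, b in zip(recons, originals):
        a = np.asarray(a, float).ravel()
        b = np.asarray(b, float).ravel()
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    if not rs:
        raise InvalidInputError("no variable trial pairs to correlate")
    return fisher_mean(rs)


def randomization_test(
    observed: float,
    reconstructions,
    originals,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> RandomizationResult:
    """Trial-shuffling null for a correlation statistic.

    The pairing between reconstructed and original trials is permuted
    ``n_shuffles`` times; each shuffle yields the Fisher-averaged correlation
    over the shuffled pairs. ``p`` is the proportion of null statistics
    greater than or equal to the observed value.
    """
    n = len(reconstructions)
    if n < 2 or len(originals) != n:
        raise InvalidInputError("randomization test needs >= 2 matched trial pairs")
    if n_shuffles < 100:
        warnings.warn("n_shuffles < 100 gives a coarse p-value resolution")
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    recons = [np.asarray(r, float) for r in reconstructions]
    for i in range(n_shuffles):
        perm = rng.permutation(n)
        # resample until the permutation moves at least one trial
        null[i] = _paired_correlation([recons[k] for k in perm], originals)
    k = int(np.sum(null >= observed))
    return RandomizationResult(
        p=k / n_shuffles,
        p_conservative=(k + 1) / (n_shuffles + 1),
        observed=float(observed),
        n_shuffles=n_shuffles,
    )


def fdr_select(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection; returns a boolean mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def resample_stats(estimates: np.ndarray) -> ResampleEstimate:
    """Mean, resampled SE, and t-ratio for a [n_resamples x n_params] matrix."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.ndim == 1:
        estimates = estimates[:, None]
    n = estimates.shape[0]
    if n < 2:
        raise InvalidInputError("resample_stats requires >= 2 resamples")
    mean = estimates.mean(axis=0)
    se = estimates.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.nan)
    return ResampleEstimate(mean=mean, se=se, t_ratio=t, n_resamples=n)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Simple alpha/m family-wise threshold."""
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return alpha / m


def one_sample_t(values, popmean: float = 0.0):
    """One-sample t test against a fixed mean (thin scipy wrapper)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("one_sample_t requires >= 2 values")
    res = sps.ttest_1samp(values, popmean)
    return float(res.statistic), float(res.pvalue)
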