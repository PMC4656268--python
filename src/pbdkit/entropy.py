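"""Shannon and Tsallis entropies of discrete distributions.

The Tsallis entropy E_q = (sum_k p_k**q - 1) / (1 - q) generalises Shannon
entropy with a single real parameter q (the nonextensivity degree) and
recovers it, in natural-log units, in the limit q -> 1.  For a pair of
independent systems it is pseudo-additive:

    E_q(X + Y) = E_q(X) + E_q(Y) + (1 - q) E_q(X) E_q(Y)

so q < 1 gives a subextensive entropy, q = 1 the usual extensive (Shannon)
entropy and q > 1 a superextensive one.  Subextensive entropies suit
signals with long-range correlation, such as textured brain tissue.

This module also provides the estimator that turns a block of wavelet
coefficients into the discrete distribution those entropies consume.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, ValidationError

_NORM_TOL = 1e-8


def _validate_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size < 1:
        raise ValidationError("probability vector must have at least one state")
    if not np.all(np.isfinite(p)):
        raise ValidationError("probability vector contains non-finite values")
    if np.any(p < 0):
        raise ValidationError("probability vector contains negative entries")
    total = p.sum()
    if abs(total - 1.0) > _NORM_TOL:
        raise ValidationError(f"probabilities sum to {total}, expected 1")
    return p


def shannon_entropy(dist: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy -sum p_k log(p_k), base-2 (bits) by default.

    Zero-probability states contribute nothing (the 0 log 0 := 0
    convention).  The result lies in [0, log(Z)] for Z states.
    """
    p = _validate_dist(dist)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def tsallis_entropy(dist: np.ndarray, q: float) -> float:
    """Tsallis entropy of order ``q``.

    For q != 1 this is (sum_k p_k**q - 1)/(1 - q), summed over all states
    (zero-probability states are skipped, which matters only for q <= 0).
    At exactly q = 1 the analytic limit is returned: Shannon entropy in
    natural-log units.
    """
    p = _validate_dist(dist)
    q = float(q)
    if q == 1.0:
        return shannon_entropy(p, base=np.e)
    nz = p[p > 0]
    return float((np.sum(nz**q) - 1.0) / (1.0 - q))


def entropic_regime(q: float) -> str:
    """Classify ``q``: "subextensive" (q<1), "extensive" (q=1), "superextensive" (q>1)."""
    if q < 1:
        return "subextensive"
    if q > 1:
        return "superextensive"
    return "extensive"


def pseudo_additivity_residual(dist_x: np.ndarray, dist_y: np.ndarray, q: float) -> float:
    """Residual of the pseudo-additivity identity for independent systems.

    Builds the joint distribution of two independent systems as the outer
    product of their marginals and returns

        E_q(joint) - [E_q(X) + E_q(Y) + (1 - q) E_q(X) E_q(Y)]

    which is identically zero up to floating-point error.  At q = 1 the
    cross term vanishes and the identity reduces to Shannon additivity.
    Exported as a documentation/verification utility.
    """
    px = _validate_dist(dist_x)
    py = _validate_dist(dist_y)
    joint = np.outer(px, py).ravel()
    ex, ey = tsallis_entropy(px, q), tsallis_entropy(py, q)
    return float(tsallis_entropy(joint, q) - (ex + ey + (1.0 - q) * ex * ey))


def coeffs_to_distribution(
    subband: np.ndarray, estimator: str = "energy", bins: int = 256
) -> np.ndarray:
    """Estimate a discrete probability distribution from a coefficient block.

    ``estimator="energy"`` (default): p_k = c_k**2 / sum_j c_j**2 over all
    coefficients — the normalised-energy convention of the wavelet-entropy
    literature.  An all-zero block yields the degenerate distribution
    (1, 0, ..., 0), so its entropy is zero.

    ``estimator="histogram"``: a ``bins``-bin normalised histogram of the
    coefficient values (greylevel-style binning over the block's value
    range; a constant block puts all mass in one bin).
    """
    c = np.asarray(subband, dtype=float).ravel()
    if c.size == 0:
        raise ValidationError("subband is empty")
    if not np.all(np.isfinite(c)):
        raise ValidationError("subband contains non-finite coefficients")
    if estimator == "energy":
        energy = c**2
        total = energy.sum()
        if total == 0.0:
            p = np.zeros(c.size)
            p[0] = 1.0
            return p
        return energy / total
    if estimator == "histogram":
        if bins < 1:
            raise ConfigurationError(f"bins must be >= 1, got {bins}")
        counts, _ = np.histogram(c, bins=bins)
        return counts / c.size
    raise ConfigurationError(
        f"unknown estimator {estimator!r}; expected 'energy' or 'histogram'"
    )
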