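"""Robust, non-parametric estimation of the log-normal null from a scan.

A genome-wide G' vector is a mixture of the null (non-QTL regions) and
contaminating QTL components with higher means.  The null parameters are
estimated so that contamination in the right tail has little influence:

1. work on x = ln G' (approximately normal under the null);
2. measure spread by the *left* median absolute deviation -- the MAD of
   deviations at or below the median, scaled by 1.4826 so it estimates a
   normal standard deviation -- which ignores the QTL-inflated right tail;
3. flag upper outliers by Hampel's rule, x > median + g * leftMAD with
   g = 5.2 (the conventional limit for normal data, roughly a one-sided
   z > 3.5 cut);
4. trim the flagged observations;
5. recover (mu, sigma) from the trimmed sample via the log-normal
   identities median = exp(mu) and mode = exp(mu - sigma^2), using a
   robust mode estimator on the unlogged values.

Because the median of a contaminated sample sits to the right of the
null centre, the procedure errs conservative in the presence of QTLs.
"""

from __future__ import annotations

import logging

import numpy as np

from .nulldist import NullModel

logger = logging.getLogger(__name__)

#: scale factor making the MAD consistent for a normal standard deviation
MAD_CONSISTENCY = 1.4826
#: conventional Hampel outlier limit for normally distributed data
HAMPEL_G = 5.2


def left_mad(values, scale: float = MAD_CONSISTENCY) -> float:
    """Median absolute deviation over observations at or below the median."""
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    lower = x[x <= med]
    return float(scale * np.median(np.abs(lower - med)))


def hampel_outliers(values, g: float = HAMPEL_G, side: str = "upper") -> np.ndarray:
    """Boolean mask of outliers by Hampel's rule with a left-MAD spread.

    'upper' flags x > median + g * leftMAD (the one-sided test used when
    contamination is known to inflate the right tail only); 'two_sided'
    also flags the symmetric lower limit.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations to flag outliers")
    if g <= 0:
        raise ValueError("outlier limit g must be positive")
    med = np.median(x)
    spread = left_mad(x)
    mask = x > med + g * spread
    if side == "two_sided":
        mask |= x < med - g * spread
    elif side != "upper":
        raise ValueError("side must be 'upper' or 'two_sided'")
    return mask


def half_sample_mode(values) -> float:
    """Robust mode: recursively take the shortest half of the sorted sample.

    Ties between equally short halves are broken toward the lower-indexed
    half, making the estimator deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("empty sample")
    while len(x) > 3:
        h = (len(x) + 1) // 2
        widths = x[h - 1:] - x[: len(x) - h + 1]
        x = x[np.argmin(widths):][:h]
    if len(x) == 3:
        return float(x[1]) if (x[1] - x[0]) <= (x[2] - x[1]) else float(0.5 * (x[1] + x[2]))
    return float(np.mean(x))


def grid_mode(values, bins: int = 512) -> float:
    """Histogram-based mode estimator (optional alternative to the HSM)."""
    x = np.asarray(values, dtype=float)
    hist, edges = np.histogram(x, bins=bins)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def estimate_null_robust(gprime, g: float = HAMPEL_G, mode_estimator: str = "hsm",
                         min_sites: int = 100) -> NullModel:
    """Fit the log-normal null to a G' vector by the 5-step robust procedure.

    Zero values (possible on nearly empty windows) are dropped with a
    logged count before taking logs.  Raises ``ValueError`` when the null
    spread is not estimable (degenerate input, or mode >= median).
    """
    v = np.asarray(gprime, dtype=float)
    n_zero = int(np.sum(v <= 0))
    if n_zero:
        logger.info("dropping %d non-positive G' values before log transform", n_zero)
        v = v[v > 0]
    if len(v) < 3:
        raise ValueError("too few positive G' values to estimate a null")
    if len(v) < min_sites:
        logger.warning("only %d sites; robust null estimate will be unstable", len(v))
    if np.ptp(v) == 0:
        raise ValueError("all G' values identical; null not estimable")

    logs = np.log(v)
    keep = ~hampel_outliers(logs, g=g, side="upper")
    trimmed = v[keep]

    mu = float(np.log(np.median(trimmed)))  # = median of trimmed logs
    if mode_estimator == "hsm":
        mode = half_sample_mode(trimmed)
    elif mode_estimator == "grid":
        mode = grid_mode(trimmed)
    else:
        raise ValueError("mode_estimator must be 'hsm' or 'grid'")
    sigma2 = mu - float(np.log(mode))
    if sigma2 <= 0:
        raise ValueError("robust mode exceeds the median; null spread not estimable")
    return NullModel.from_mu_sigma(mu, float(np.sqrt(sigma2)))
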