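"""Inverse-variance fixed-effect pooling, shared by panel dedup and model meta-analysis."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def se_from_p(log_or: float, p: float) -> float:
    """Back out a standard error from an effect and its two-sided p-value.

    Uses |z| = Phi^-1(1 - p/2), SE = |log_or| / |z|. Returns ``nan`` when the
    SE is undefined (p >= 1, p <= 0, or a null effect), which callers treat as
    "exclude this entry".
    """
    if not (0.0 < p < 1.0) or log_or == 0.0:
        return float("nan")
    z = stats.norm.isf(p / 2.0)
    if not np.isfinite(z) or z <= 0.0:
        return float("nan")
    return abs(log_or) / z


def pool_fixed_effect(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling.

    Parameters
    ----------
    betas, ses
        Effect estimates on a common (e.g. log-odds) scale and their
        standard errors. Entries with non-finite or non-positive SE are
        dropped with a warning.

    Returns
    -------
    (beta, se, p)
        Pooled estimate ``sum(w*b)/sum(w)`` with ``w = 1/se^2``, pooled
        ``se = sum(w)^-0.5`` and the two-sided normal p-value of beta/se.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be 1-D arrays of equal length")
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0.0)
    if not ok.all():
        logger.warning("dropping %d entr(ies) with undefined SE from pooling", (~ok).sum())
    if not ok.any():
        raise DegenerateInputError("no entry with a defined standard error to pool")
    b, s = betas[ok], ses[ok]
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, p
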