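"""Small shared statistical helpers."""
from __future__ import annotations

import numpy as np
from scipy import special

#: Two-sided 97.5% standard-normal quantile used for every Wald interval.
Z95 = 1.959964

#: Natural log of 2 — converts log-odds-of-liability effects to per-doubling units.
LN2 = float(np.log(2.0))


def two_sided_p(beta, se):
    """Two-sided normal p-value for beta/se, vectorized, underflow-safe."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta / se)
    p = 2.0 * special.ndtr(-z)
    # p in (0, 1]: clamp exact underflow to the smallest positive double
    p = np.where(p == 0.0, 5e-324, p)
    return p if p.ndim else float(p)


def z_from_p(pval):
    """Two-sided standard-normal quantile |z| at p, computed on the log scale.

    Never overflows for any representable p in (0, 1).
    """
    pval = np.asarray(pval, dtype=float)
    with np.errstate(divide="ignore"):
        z = -special.ndtri_exp(np.log(pval) - np.log(2.0))
    return z if z.ndim else float(z)
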