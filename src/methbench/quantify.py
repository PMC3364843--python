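"""Quantification of Infinium methylation: beta values, M values and the
logistic conversion between the two.

For a CpG with methylated-probe intensity ``methy`` and unmethylated-probe
intensity ``unmethy`` (both clamped at zero; background subtraction can make
them negative):

    beta = max(methy, 0) / (max(methy, 0) + max(unmethy, 0) + 100)
    M    = log2( (max(methy, 0) + 1) / (max(unmethy, 0) + 1) )

The offsets 100 and 1 are definitional constants of the two measures, not
tuning parameters.  Because typical total intensities exceed 1,000 the
offsets are small relative to the signal, and the two measures are related
approximately by the logistic map M = log2(beta / (1 - beta)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import IntensityPair, MethylationMatrix

#: offset in the beta-value denominator (definitional)
BETA_OFFSET = 100.0
#: offset added to each intensity in the M-value ratio (definitional)
M_OFFSET = 1.0


def compute_beta(pair: IntensityPair) -> MethylationMatrix:
    """Beta values from an intensity pair: methylated fraction of total signal."""
    methy = np.maximum(pair.methy.to_numpy(dtype=float), 0.0)
    unmethy = np.maximum(pair.unmethy.to_numpy(dtype=float), 0.0)
    beta = methy / (methy + unmethy + BETA_OFFSET)
    return MethylationMatrix(
        pd.DataFrame(beta, index=pair.feature_ids, columns=pair.sample_ids), "beta"
    )


def compute_m(pair: IntensityPair) -> MethylationMatrix:
    """M values from an intensity pair: log2 methylated/unmethylated ratio."""
    methy = np.maximum(pair.methy.to_numpy(dtype=float), 0.0)
    unmethy = np.maximum(pair.unmethy.to_numpy(dtype=float), 0.0)
    m = np.log2((methy + M_OFFSET) / (unmethy + M_OFFSET))
    return MethylationMatrix(
        pd.DataFrame(m, index=pair.feature_ids, columns=pair.sample_ids), "M"
    )


def beta_to_m(beta, clamp: float | None = None):
    """Logit (base 2) transform: M = log2(beta / (1 - beta)).

    Parameters
    ----------
    beta
        Array-like of beta values, strictly inside (0, 1) unless ``clamp``
        is given.
    clamp
        If supplied, beta values are first clamped into
        [clamp, 1 - clamp]; otherwise values at 0 or 1 raise, since an
        infinite M almost always signals a data problem upstream.
    """
    arr = np.asarray(beta, dtype=float)
    if clamp is not None:
        if not 0 < clamp < 0.5:
            raise ValueError("clamp must lie in (0, 0.5)")
        arr = np.clip(arr, clamp, 1.0 - clamp)
    elif np.any((arr <= 0) | (arr >= 1)):
        raise ValueError(
            "beta values at or outside (0, 1) produce infinite M; pass clamp= to opt in"
        )
    return np.log2(arr / (1.0 - arr))


def m_to_beta(m):
    """Inverse logistic transform: beta = 2^M / (2^M + 1)."""
    arr = np.asarray(m, dtype=float)
    # expit formulated to avoid overflow for large |M|
    out = np.empty_like(arr, dtype=float)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    out[~pos] = np.exp2(arr[~pos]) / (1.0 + np.exp2(arr[~pos]))
    return out


def convert_measure(matrix: MethylationMatrix, to: str, clamp: float = 1e-6) -> MethylationMatrix:
    """Convert a matrix between the beta and M measures (no-op if already there)."""
    if to == matrix.measure:
        return matrix
    if to == "M":
        values = beta_to_m(matrix.values.to_numpy(), clamp=clamp)
    elif to == "beta":
        values = m_to_beta(matrix.values.to_numpy())
    else:
        raise ValueError(f"unknown measure {to!r}")
    return MethylationMatrix(
        pd.DataFrame(values, index=matrix.feature_ids, columns=matrix.sample_ids), to
    )
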