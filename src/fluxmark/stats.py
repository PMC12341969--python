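"""Small statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as _scipy_stats


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    result = _scipy_stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)
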