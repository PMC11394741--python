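"""Nonparanormal (Gaussian-copula) transformation of expression data.

Gaussian SEM assumes multivariate normality.  RNA-seq expression, even
after normalization, rarely satisfies it.  Under a Gaussian copula each
gene is a monotone warp of a latent Gaussian, and replacing observed
values by normal scores of their (shrunken) empirical ranks recovers the
latent scale up to location: the transform is exactly invariant to any
strictly monotone per-gene map of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionData

__all__ = ["NpnParams", "npn_transform", "default_truncation"]


def default_truncation(n: int) -> float:
    """Shrunken-ECDF truncation bound: 1 / (4 n^(1/4) sqrt(pi log n))."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


@dataclass
class NpnParams:
    """Truncation probability applied to the empirical ranks before the
    normal-quantile map; ``None`` means the n-dependent default rule."""

    truncation: float | None = None

    def resolve(self, n: int) -> float:
        delta = self.truncation if self.truncation is not None else default_truncation(n)
        if not 0.0 < delta < 0.5:
            raise ValueError(f"truncation must lie in (0, 0.5), got {delta}")
        return delta


def npn_transform(data: ExpressionData, params: NpnParams | None = None) -> ExpressionData:
    """Rank-based Gaussianization, gene by gene.

    Each gene's values are replaced by ``qnorm`` of its empirical CDF
    (average ranks over n+1, clipped to [delta, 1-delta]), then rescaled to
    unit sample variance.  Output marginals are approximately standard
    normal; Pearson correlations of the output estimate the latent Gaussian
    correlations of the copula.

    Zero-variance genes cannot be ranked meaningfully and raise an error
    listing the offending genes; the caller filters them.
    """
    params = params or NpnParams()
    n = data.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    zero_var = data.zero_variance_genes()
    if zero_var:
        raise ValueError(f"zero-variance genes (filter before transforming): {zero_var}")
    delta = params.resolve(n)
    x = data.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)  # average ranks for ties
    u = np.clip(ranks / (n + 1.0), delta, 1.0 - delta)
    z = stats.norm.ppf(u)
    z = z / z.std(axis=1, ddof=1, keepdims=True)
    return ExpressionData(
        pd.DataFrame(z, index=data.values.index, columns=data.values.columns),
        data.group.copy(),
    )
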