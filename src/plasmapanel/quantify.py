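"""Peptide-to-protein quantification and normality diagnostics.

Label-free peptide intensities are log2-transformed, quantile-normalized
across samples, and rolled up to one protein-level intensity per sample as a
weighted average of the protein's peptides (equal or inverse-variance
weights).  A one-sample Kolmogorov-Smirnov normality test and a Q-Q table
export support the distributional diagnostics that motivate permutation
(rather than parametric) testing downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)

ROLLUP_WEIGHTS = ("equal", "inverse-variance")


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Base-2 logarithm of a raw-scale matrix.

    Zeros are replaced by half the smallest positive value in the matrix
    (logged); negative values are an error.  NaNs pass through.
    """
    if m.scale != "raw":
        raise ValueError("log2_transform expects a raw-scale matrix")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    if np.any(vals == 0):
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError("matrix contains no positive values")
        floor = positive.min() / 2.0
        n_zero = int((vals == 0).sum())
        logger.warning("replaced %d zero intensities by %.4g (half the "
                       "smallest positive value)", n_zero, floor)
        vals = np.where(vals == 0, floor, vals)
    out = pd.DataFrame(np.log2(vals), index=m.values.index,
                       columns=m.values.columns)
    return m.with_values(out, scale="log2")


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Force every sample column to the common per-rank mean distribution.

    After normalization all columns share one multiset of values (the means
    across columns of the rank-ordered values) and within-column rank order
    is preserved.  Ties within a column receive the mean of the rank-means
    they span.  A single-column input is returned unchanged with a warning.
    Accepts an :class:`IntensityMatrix` or a bare DataFrame (returned in
    kind).
    """
    frame = m if isinstance(m, pd.DataFrame) else m.values
    if frame.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        out_df = frame.copy()
        return out_df if isinstance(m, pd.DataFrame) else m.with_values(out_df)
    vals = frame.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(rank_means)])
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        lo = stats.rankdata(col, method="min").astype(int)
        hi = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
    df = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return df if isinstance(m, pd.DataFrame) else m.with_values(df)


def rollup_proteins(m: IntensityMatrix, peptide_map: pd.DataFrame,
                    weights: str = "equal") -> IntensityMatrix:
    """Aggregate a peptide-level log2 matrix to protein level.

    Each protein/sample value is the weighted average of the protein's
    peptide values in that sample.  ``weights="equal"`` averages plainly;
    ``weights="inverse-variance"`` weights each peptide by the reciprocal of
    its across-sample variance (peptides measured more consistently count
    more), normalized to sum to one within each protein.
    """
    if weights not in ROLLUP_WEIGHTS:
        raise ValueError(f"weights must be one of {ROLLUP_WEIGHTS}")
    mapping = dict(zip(peptide_map.iloc[:, 0].astype(str),
                       peptide_map.iloc[:, 1].astype(str)))
    unmapped = [p for p in m.values.index if p not in mapping]
    if unmapped:
        raise ValueError(f"peptides missing from map: {unmapped[:10]}"
                         + ("..." if len(unmapped) > 10 else ""))
    protein_of = m.values.index.map(mapping)

    if weights == "equal":
        rolled = m.values.groupby(protein_of).mean()
    else:
        w = m.values.var(axis=1, ddof=1).to_numpy()
        # zero-variance peptides would get infinite weight; clamp to the
        # smallest positive variance observed (or equal weights if none)
        pos = w[w > 0]
        if pos.size and (w == 0).any():
            logger.warning("inverse-variance rollup: %d zero-variance "
                           "peptides clamped", int((w == 0).sum()))
            w = np.where(w == 0, pos.min(), w)
        elif not pos.size:
            logger.warning("inverse-variance rollup: all variances zero; "
                           "using equal weights")
            w = np.ones_like(w)
        inv = 1.0 / w
        weighted = m.values.mul(inv, axis=0)
        rolled = weighted.groupby(protein_of).sum().div(
            pd.Series(inv, index=m.values.index).groupby(protein_of).sum(),
            axis=0)
    rolled = rolled.sort_index()
    return m.with_values(rolled)


@dataclasses.dataclass
class NormalityReport:
    """One-sample Kolmogorov-Smirnov test against a normal reference."""

    D: float
    p_value: float
    n: int
    mean: float
    sd: float
    estimated_params: bool

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"key": ["D", "p_value", "n", "ref_mean", "ref_sd",
                              "estimated_params"],
                      "value": [self.D, self.p_value, self.n, self.mean,
                                self.sd, self.estimated_params]}
                     ).to_csv(path, sep="\t", index=False)


def ks_normality_test(values, mean: float | None = None,
                      sd: float | None = None) -> NormalityReport:
    """Kolmogorov-Smirnov distance of the empirical CDF from a normal CDF.

    Reference parameters default to the sample mean and (ddof=1) standard
    deviation; pass ``mean``/``sd`` to test against a fixed normal.  The
    p-value uses the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    n = x.size
    if n < 1:
        raise ValueError("at least one value required")
    estimated = mean is None or sd is None
    mu = float(np.mean(x)) if mean is None else float(mean)
    if sd is None:
        sigma = float(np.std(x, ddof=1)) if n > 1 else 0.0
        if sigma == 0.0:
            raise ValueError("zero-variance input with estimated parameters")
    else:
        sigma = float(sd)
        if sigma <= 0:
            raise ValueError("reference sd must be positive")
    d = float(stats.kstest(x, "norm", args=(mu, sigma)).statistic)
    p = float(special.kolmogorov(np.sqrt(n) * d))
    return NormalityReport(D=d, p_value=p, n=n, mean=mu, sd=sigma,
                           estimated_params=estimated)


def qq_export(values, mean: float | None = None,
              sd: float | None = None) -> pd.DataFrame:
    """Normal Q-Q table: (probability, theoretical quantile, observed).

    Rows are ordered by the plotting positions (i - 0.5)/n; the theoretical
    column holds the reference-normal quantiles at those probabilities and
    the observed column the sorted data.  Writable as TSV for plotting.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("at least two values required")
    mu = float(np.mean(x)) if mean is None else float(mean)
    sigma = float(np.std(x, ddof=1)) if sd is None else float(sd)
    if sigma <= 0:
        raise ValueError("reference sd must be positive")
    prob = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"prob": prob,
                         "theoretical": stats.norm.ppf(prob, mu, sigma),
                         "observed": np.sort(x)})
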