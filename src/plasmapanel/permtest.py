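"""Per-protein two-sample permutation testing with PFER/FDR summaries.

For each protein a two-sample statistic (pooled-variance t by default) is
computed between case and control samples, and its p-value is the proportion
of group relabelings whose statistic is at least as extreme in absolute
value as the observed one.  Relabelings are either all C(n, n_case) distinct
assignments (exhaustive mode) or independent uniform random assignments
(Monte-Carlo mode); ``auto`` picks exhaustive whenever the full enumeration
is no larger than the requested Monte-Carlo count.

Multiplicity is summarized the way the underlying method defines it: the
per-family Type 1 error rate PFER = (number of tests) x alpha, and the
nominal FDR = PFER / (number declared significant).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)

STAT_KINDS = ("pooled_t", "welch_t", "mean_difference")
MODES = ("montecarlo", "exhaustive", "auto")

DEFAULT_N_PERM = 100_000
DEFAULT_ALPHA = 0.001


def two_sample_statistic(case, control, kind: str = "pooled_t") -> float:
    """Case-minus-control statistic for one protein.

    ``pooled_t`` is the equal-variance two-sample t, ``welch_t`` the
    unequal-variance form, ``mean_difference`` the plain difference of group
    means.  Positive values mean higher intensity in cases
    (over-expression).  A zero pooled variance under the t kinds falls back
    to the mean difference with a warning.
    """
    if kind not in STAT_KINDS:
        raise ValueError(f"kind must be one of {STAT_KINDS}")
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    min_n = 1 if kind == "mean_difference" else 2
    if x.size < min_n or y.size < min_n:
        raise ValueError(f"each group needs at least {min_n} values for {kind}")
    diff = x.mean() - y.mean()
    if kind == "mean_difference":
        return float(diff)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    n1, n2 = x.size, y.size
    if kind == "pooled_t":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    else:
        se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        logger.warning("zero pooled variance; falling back to mean difference")
        return float(diff)
    return float(diff / math.sqrt(se2))


def _masked_stats(X: np.ndarray, masks: np.ndarray, kind: str) -> np.ndarray:
    """Statistics for every column of a (n_samples, B) 0/1 case-mask matrix.

    Returns a (n_proteins, B) array.  Permuted splits with zero pooled
    variance give +/-inf for a non-zero mean difference and 0 otherwise,
    which is the correct limit for the exceedance comparison.
    """
    n = X.shape[1]
    n1 = int(masks[:, 0].sum())
    n2 = n - n1
    S1 = X @ masks
    m1 = S1 / n1
    m2 = (X.sum(axis=1, keepdims=True) - S1) / n2
    diff = m1 - m2
    if kind == "mean_difference":
        return diff
    Q1 = (X * X) @ masks
    Q2 = (X * X).sum(axis=1, keepdims=True) - Q1
    ss1 = Q1 - n1 * m1 * m1
    ss2 = Q2 - n2 * m2 * m2
    # guard tiny negative values from cancellation
    np.maximum(ss1, 0.0, out=ss1)
    np.maximum(ss2, 0.0, out=ss2)
    if kind == "pooled_t":
        se2 = (ss1 + ss2) / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2)
    else:
        se2 = ss1 / (n1 - 1) / n1 + ss2 / (n2 - 1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t[(se2 == 0.0) & (diff == 0.0)] = 0.0
    return t


def _constant_rows(X: np.ndarray) -> np.ndarray:
    return np.ptp(X, axis=1) == 0.0


def permutation_pvalues(m: IntensityMatrix, kind: str = "pooled_t",
                        n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                        mode: str = "auto", add_one: bool = False,
                        strict: bool = False,
                        chunk_size: int = 4096) -> pd.DataFrame:
    """Permutation p-values for every protein of a protein-level matrix.

    Returns a DataFrame indexed by protein id with columns ``statistic``
    (observed, case minus control), ``p_value``, ``direction`` ("over",
    "under", or "" for a zero difference) and ``n_permutations`` (the number
    of relabelings evaluated).

    The p-value is the plain proportion of relabelings with
    ``|T_perm| >= |T_obs|``; ``add_one=True`` applies (b+1)/(B+1) smoothing,
    ``strict=True`` uses a strict ``>`` exceedance comparison instead.
    Constant proteins are tested with the mean-difference statistic (their
    p-value is 1 under the ``>=`` rule).  Identical seeds give identical
    results.
    """
    if kind not in STAT_KINDS:
        raise ValueError(f"kind must be one of {STAT_KINDS}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    case_cols = m.case_columns
    control_cols = m.control_columns
    ordered = case_cols + control_cols
    X = m.values[ordered].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("permutation testing requires a complete matrix")
    n1, n2 = len(case_cols), len(control_cols)
    n = n1 + n2
    min_n = 1 if kind == "mean_difference" else 2
    if n1 < min_n or n2 < min_n:
        raise ValueError(f"each group needs at least {min_n} samples for {kind}")

    const = _constant_rows(X)
    if const.any() and kind != "mean_difference":
        logger.warning("%d constant proteins tested with mean difference",
                       int(const.sum()))

    total = math.comb(n, n1)
    exhaustive = mode == "exhaustive" or (mode == "auto" and total <= n_perm)

    identity_mask = np.zeros(n)
    identity_mask[:n1] = 1.0

    def stats_for(masks: np.ndarray) -> np.ndarray:
        out = _masked_stats(X, masks, kind)
        if const.any() and kind != "mean_difference":
            out[const] = _masked_stats(X[const], masks, "mean_difference")
        return out

    obs = stats_for(identity_mask[:, None])[:, 0]

    abs_obs = np.abs(obs)
    # Tie-aware exceedance: relabelings whose statistic is mathematically
    # equal to the observed one can land a last-ulp away depending on the
    # evaluation path; values within this tolerance are treated as ties
    # (counted under >=, excluded under strict >).  Distinct relabelings on
    # continuous data sit far outside it.
    tie_tol = np.where(np.isfinite(abs_obs), 1e-9 * (1.0 + abs_obs), 0.0)
    lo_thresh = abs_obs - tie_tol
    hi_thresh = abs_obs + tie_tol

    def cmp(perm_abs: np.ndarray) -> np.ndarray:
        if strict:
            return perm_abs > hi_thresh[:, None]
        return perm_abs >= lo_thresh[:, None]

    exceed = np.zeros(X.shape[0], dtype=np.int64)

    if exhaustive:
        # The identity assignment (and, for equal group sizes, its mirror)
        # has |T| mathematically equal to the observed value; count it
        # analytically so exhaustive p-values are exact rather than at the
        # mercy of last-ulp float differences between evaluation paths.
        identity_idx = frozenset(range(n1))
        mirror_idx = frozenset(range(n1, n)) if n1 == n2 else None
        analytic = 0
        combos = itertools.combinations(range(n), n1)
        evaluated = 0
        while True:
            block = list(itertools.islice(combos, chunk_size))
            if not block:
                break
            masks = np.zeros((n, len(block)))
            skip_cols = []
            for b, combo in enumerate(block):
                masks[list(combo), b] = 1.0
                fs = frozenset(combo)
                if fs == identity_idx or (mirror_idx is not None and fs == mirror_idx):
                    skip_cols.append(b)
            perm = np.abs(stats_for(masks))
            hits = cmp(perm)
            if skip_cols:
                hits[:, skip_cols] = False
                analytic += len(skip_cols) if not strict else 0
            exceed += hits.sum(axis=1)
            evaluated += len(block)
        exceed += analytic
        denom = evaluated
    else:
        rng = np.random.default_rng(seed)
        remaining = n_perm
        while remaining > 0:
            b = min(chunk_size, remaining)
            order = np.argsort(rng.random((b, n)), axis=1)
            masks = np.zeros((n, b))
            rows = order[:, :n1]
            masks[rows.ravel(), np.repeat(np.arange(b), n1)] = 1.0
            perm = np.abs(stats_for(masks))
            exceed += cmp(perm).sum(axis=1)
            remaining -= b
        denom = n_perm

    if add_one:
        p = (exceed + 1) / (denom + 1)
    else:
        p = exceed / denom

    direction = np.where(obs > 0, "over", np.where(obs < 0, "under", ""))
    result = pd.DataFrame({
        "statistic": obs,
        "p_value": p,
        "direction": direction,
        "n_permutations": denom,
    }, index=pd.Index(m.values.index, name="protein_id"))
    logger.info("permutation test: %d proteins, %s mode, %d relabelings, "
                "statistic=%s", len(result),
                "exhaustive" if exhaustive else "montecarlo", denom, kind)
    return result


def pfer(n_tested: int, alpha: float) -> float:
    """Per-family Type 1 error rate: expected false positives across the
    family, (number of tests) x alpha."""
    if n_tested < 0:
        raise ValueError("n_tested must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return n_tested * alpha

def fdr_nominal(pfer_value: float, n_declared: int) -> float:
    """Nominal FDR: PFER divided by the declared-significant count; NaN when
    nothing is declared."""
    if n_declared < 0:
        raise ValueError("n_declared must be non-negative")
    if n_declared == 0:
        return float("nan")
    return pfer_value / n_declared


@dataclasses.dataclass
class SignificanceSummary:
    """Study-level summary of a significance selection."""

    n_tested: int
    alpha: float
    n_significant: int
    n_over: int
    n_under: int
    pfer: float
    fdr_nominal: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"key": ["n_tested", "alpha", "n_significant", "n_over",
                              "n_under", "pfer", "fdr_nominal"],
                      "value": [self.n_tested, self.alpha, self.n_significant,
                                self.n_over, self.n_under, self.pfer,
                                self.fdr_nominal]}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignificanceSummary":
        kv = dict(pd.read_csv(path, sep="\t").itertuples(index=False))
        return cls(n_tested=int(float(kv["n_tested"])), alpha=float(kv["alpha"]),
                   n_significant=int(float(kv["n_significant"])),
                   n_over=int(float(kv["n_over"])),
                   n_under=int(float(kv["n_under"])), pfer=float(kv["pfer"]),
                   fdr_nominal=float(kv["fdr_nominal"]))


def select_significant(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
                       ) -> tuple[SignificanceSummary, pd.DataFrame]:
    """Flag proteins with p <= alpha and summarize PFER / nominal FDR.

    Returns the summary and a copy of ``results`` with a ``significant``
    boolean column.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    flagged = results.copy()
    flagged["significant"] = flagged["p_value"] <= alpha
    sig = flagged[flagged["significant"]]
    n_tested = len(flagged)
    n_sig = len(sig)
    pfer_value = pfer(n_tested, alpha)
    summary = SignificanceSummary(
        n_tested=n_tested, alpha=alpha, n_significant=n_sig,
        n_over=int((sig["direction"] == "over").sum()),
        n_under=int((sig["direction"] == "under").sum()),
        pfer=pfer_value, fdr_nominal=fdr_nominal(pfer_value, n_sig))
    return summary, flagged


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[], float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in ("statistic", "p_value"):
        df[col] = df[col].astype(float)
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(str).str.lower() == "true"
    return df
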