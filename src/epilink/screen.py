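"""Peak-phenotype Spearman screen with BH false-discovery-rate control.

Each peak's accessibility row is tested for monotone association with the
per-sample epithelial proportion. P-values come from exhaustive permutation
enumeration for very small cohorts (n <= 8), from the t-distribution
approximation with n-2 degrees of freedom otherwise, or from seeded
Monte-Carlo permutation when requested for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CombinatorialExplosionError,
    InsufficientCohortError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

log = logging.getLogger(__name__)

EXHAUSTIVE_MAX_N = 8
_TIE_EPS = 1e-12


def _checked_ranks(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InvalidArgumentError(f"need n >= 3 samples, got {len(x)}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return stats.rankdata(x), stats.rankdata(y)


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    rx, ry = _checked_ranks(x, y)
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=4)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _perm_rhos(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Spearman rho for ry against every permutation of rx."""
    perms = _permutation_matrix(len(rx))
    px = rx[perms]  # (n!, n)
    px_c = px - px.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(px_c, axis=1) * np.linalg.norm(ry_c)
    return (px_c @ ry_c) / denom


def _t_approx_pvalue(rho: float, n: int) -> float:
    denom = max(1.0 - rho * rho, 1e-300)
    t = rho * math.sqrt((n - 2) / denom)
    return min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_pvalue(x, y, method: str = "auto", n_permutations: int = 100_000,
                    seed: int = 0) -> float:
    """Two-tailed p-value for the Spearman correlation of x and y.

    ``exhaustive`` enumerates all n! permutations (refused for n > 8);
    ``approximate`` uses the t approximation with df = n - 2; ``montecarlo``
    draws seeded random permutations; ``auto`` picks exhaustive for n <= 8 and
    approximate otherwise.
    """
    rx, ry = _checked_ranks(x, y)
    n = len(rx)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exhaustive" if n <= EXHAUSTIVE_MAX_N else "approximate"
    if method == "exhaustive":
        if n > EXHAUSTIVE_MAX_N:
            raise CombinatorialExplosionError(
                f"exhaustive enumeration of {n}! permutations refused (n > {EXHAUSTIVE_MAX_N})")
        rhos = _perm_rhos(rx, ry)
        return float(np.mean(np.abs(rhos) >= abs(rho) - _TIE_EPS))
    if method == "approximate":
        return _t_approx_pvalue(rho, n)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        chunk = 20_000
        done = 0
        ry_c = ry - ry.mean()
        denom_y = np.linalg.norm(ry_c)
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            perm = rng.permuted(np.tile(rx, (k, 1)), axis=1)
            pc = perm - perm.mean(axis=1, keepdims=True)
            rhos = (pc @ ry_c) / (np.linalg.norm(pc, axis=1) * denom_y)
            hits += int(np.sum(np.abs(rhos) >= abs(rho) - _TIE_EPS))
            done += k
        return (hits + 1) / (n_permutations + 1)
    raise InvalidArgumentError(f"unknown method {method!r}")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InvalidArgumentError("pvals must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def align_samples(matrix: pd.DataFrame, cohort: pd.DataFrame,
                  min_shared: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join matrix columns with cohort samples, sorted ids for determinism."""
    shared = sorted(set(matrix.columns) & set(cohort["sample_id"]))
    if len(shared) < min_shared:
        raise InsufficientCohortError(
            f"only {len(shared)} shared samples (need >= {min_shared})")
    cohort = cohort.set_index("sample_id").loc[shared].reset_index()
    return matrix[shared], cohort


def _rowwise_spearman(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman of every row against y; constant rows get NaN."""
    ranks = stats.rankdata(values, axis=1)
    ry = stats.rankdata(y)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    row_norm = np.linalg.norm(rc, axis=1)
    constant = row_norm == 0
    row_norm[constant] = 1.0
    rho = (rc @ yc) / (row_norm * np.linalg.norm(yc))
    rho[constant] = np.nan
    return rho, constant


def screen_peaks(acc: pd.DataFrame, cohort: pd.DataFrame, alpha: float = 0.05,
                 peaks: pd.DataFrame | None = None, method: str = "approximate",
                 rho_threshold: float | None = None,
                 n_permutations: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Screen every peak for Spearman association with the epithelial proportion.

    Returns one row per peak with columns peak_id, (chrom/start/end when
    ``peaks`` is given), rho, p_value, fdr, direction, significant. Peaks with
    constant accessibility have undefined correlation: they are reported with
    NaN statistics, excluded from the BH universe, and never significant.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError("alpha must be in [0, 1]")
    acc, cohort = align_samples(acc, cohort)
    y = cohort["proportion"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedCorrelationError("epithelial proportion is constant across samples")
    values = acc.to_numpy(dtype=float)
    n = values.shape[1]

    rho, constant = _rowwise_spearman(values, y)
    n_constant = int(constant.sum())
    if n_constant:
        log.warning("%d peaks with constant accessibility dropped from testing", n_constant)

    testable = ~constant
    p = np.full(len(rho), np.nan)
    if method in ("approximate", "auto") and n > EXHAUSTIVE_MAX_N or method == "approximate":
        r = rho[testable]
        denom = np.maximum(1.0 - r * r, 1e-300)
        t = r * np.sqrt((n - 2) / denom)
        p[testable] = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    else:
        idx = np.flatnonzero(testable)
        for i in idx:
            p[i] = spearman_pvalue(values[i], y, method=method,
                                   n_permutations=n_permutations, seed=seed + i)

    fdr = np.full(len(rho), np.nan)
    fdr[testable] = bh_fdr(p[testable])

    significant = np.zeros(len(rho), dtype=bool)
    significant[testable] = fdr[testable] < alpha
    if rho_threshold is not None:
        significant &= np.abs(np.nan_to_num(rho)) > rho_threshold

    direction = np.where(np.isnan(rho), "undefined",
                         np.where(rho >= 0, "positive", "negative"))
    out = pd.DataFrame({
        "peak_id": acc.index,
        "rho": rho,
        "p_value": p,
        "fdr": fdr,
        "direction": direction,
        "significant": significant,
    })
    if peaks is not None:
        coords = peaks.set_index("peak_id")[["chrom", "start", "end"]]
        out = out.join(coords, on="peak_id")
        out = out[["peak_id", "chrom", "start", "end", "rho", "p_value", "fdr",
                   "direction", "significant"]]
    return out


def screen_counts(results: pd.DataFrame) -> dict:
    """Summary counts of a screen result table."""
    sig = results[results["significant"]]
    return {
        "peaks_total": int(len(results)),
        "peaks_tested": int(results["p_value"].notna().sum()),
        "significant": int(len(sig)),
        "positive": int((sig["rho"] > 0).sum()),
        "negative": int((sig["rho"] < 0).sum()),
    }
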