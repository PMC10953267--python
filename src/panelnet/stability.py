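"""Bootstrap accuracy and stability machinery.

Three procedures, all reproducible bit-for-bit from (data, config, master
seed):

* nonparametric bootstrap of edge weights — resample rows with replacement,
  refit, percentile 95% confidence intervals;
* case-drop bootstrap correlation-stability (CS) coefficient — the largest
  proportion of cases that can be dropped while subsample centralities still
  correlate >= 0.7 with the full-sample centralities with >= 95% probability
  (CS < 0.25 flags unstable centrality ordering; >= 0.5 is comfortable);
* bootstrap difference tests — two estimands differ when the percentile
  interval of their replicate-wise differences excludes zero.

Estimators are passed in as callables ``estimator(data, seed) -> dict`` so
the same machinery serves GGM edges, CLPN edges, and any centrality vector;
replicate seeds are derived deterministically from the master seed and the
replicate index, so serial and parallel execution agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed, rng_from
from .errors import ConfigurationError, EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "CSResult",
    "bootstrap_edges",
    "case_drop_cs",
    "difference_test",
    "difference_matrix",
]

DEFAULT_DROP_GRID = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75)


def _resample(data, idx):
    if isinstance(data, (tuple, list)):
        return type(data)(np.asarray(a)[idx] for a in data)
    return np.asarray(data)[idx]


def _n_rows(data) -> int:
    if isinstance(data, (tuple, list)):
        lens = {len(a) for a in data}
        if len(lens) != 1:
            raise ConfigurationError("row-aligned data parts have differing lengths")
        return lens.pop()
    return len(data)


def bootstrap_edges(data, estimator, n_boot: int = 1000, seed: int = 0,
                    max_failure_rate: float = 0.05):
    """Nonparametric bootstrap of every estimand an estimator returns.

    ``estimator(data, seed) -> mapping of estimand name -> value``.  ``data``
    may be a single row-matrix or a tuple of row-aligned matrices (resampled
    jointly).  Returns ``(summary, replicates)``: the summary has one row per
    estimand with the full-sample point estimate, bootstrap mean, and
    2.5/97.5 percentile interval; ``replicates`` is the n_boot x n_estimands
    frame used by the difference tests.

    Replicate-level fit failures are logged and skipped; more than
    ``max_failure_rate`` of them is an error.
    """
    n = _n_rows(data)
    point = pd.Series(estimator(data, derive_seed(seed, 0, 0)), dtype=float)
    reps = []
    failures = 0
    for r in range(n_boot):
        rng = rng_from(seed, 1, r)
        idx = rng.integers(0, n, size=n)
        try:
            est = estimator(_resample(data, idx), derive_seed(seed, 2, r))
        except EstimationError as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            continue
        reps.append(pd.Series(est, dtype=float))
    if failures > max_failure_rate * n_boot:
        raise EstimationError(
            f"{failures}/{n_boot} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )
    replicates = pd.DataFrame(reps).reset_index(drop=True)
    summary = pd.DataFrame({
        "estimand": point.index,
        "point": point.to_numpy(),
        "boot_mean": replicates.mean().reindex(point.index).to_numpy(),
        "ci_low": replicates.quantile(0.025).reindex(point.index).to_numpy(),
        "ci_high": replicates.quantile(0.975).reindex(point.index).to_numpy(),
        "n_boot": len(replicates),
    })
    return summary, replicates


@dataclass
class CSResult:
    """Correlation-stability coefficient and the per-drop-level evidence."""

    centrality_index: str
    cs: float
    drop_grid: tuple
    correlation_threshold: float = 0.7
    probability_threshold: float = 0.95
    detail: pd.DataFrame = field(default_factory=pd.DataFrame)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either vector is (near-)constant.

    A constant centrality vector carries no ordering information, so its
    correlation with anything is treated as a stability failure, not NaN.
    """
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_cs(data, centrality_fn, drop_grid=DEFAULT_DROP_GRID,
                 n_boot: int = 250, seed: int = 0,
                 correlation_threshold: float = 0.7,
                 probability_threshold: float = 0.95,
                 index_name: str = "centrality") -> CSResult:
    """Case-drop bootstrap CS coefficient for a centrality function.

    ``centrality_fn(data, seed) -> 1-d centrality vector`` (node order fixed).
    For each drop proportion q (ascending), ``n_boot`` subsamples of
    ``(1-q)*n`` rows are drawn without replacement; the level passes when the
    proportion of subsample centralities correlating >= ``correlation_threshold``
    with the full-sample centralities is >= ``probability_threshold``.  The
    search stops at the first failing level (the decision is monotone by
    construction) and CS is the largest passing proportion, or 0.
    """
    n = _n_rows(data)
    drop_grid = tuple(sorted(drop_grid))
    if round((1 - drop_grid[-1]) * n) < 25:
        raise ConfigurationError(
            f"n={n} too small: dropping {drop_grid[-1]:.0%} leaves fewer than 25 rows"
        )
    full = np.asarray(centrality_fn(data, derive_seed(seed, 0, 0)), float)
    cs = 0.0
    rows = []
    for li, q in enumerate(drop_grid):
        n_sub = int(round((1 - q) * n))
        ok = 0
        for r in range(n_boot):
            rng = rng_from(seed, 10 + li, r)
            idx = rng.choice(n, size=n_sub, replace=False)
            sub = np.asarray(centrality_fn(_resample(data, idx),
                                           derive_seed(seed, 20 + li, r)), float)
            if _safe_corr(full, sub) >= correlation_threshold:
                ok += 1
        prop = ok / n_boot
        passed = prop >= probability_threshold
        rows.append({"drop_proportion": q, "n_sub": n_sub,
                     "prop_correlated": prop, "passed": passed})
        if not passed:
            break
        cs = q
    if cs == 0.0:
        logger.warning("case-drop CS: even the smallest drop proportion failed; CS = 0")
    return CSResult(centrality_index=index_name, cs=cs, drop_grid=drop_grid,
                    correlation_threshold=correlation_threshold,
                    probability_threshold=probability_threshold,
                    detail=pd.DataFrame(rows))


def difference_test(replicates: pd.DataFrame, estimand_a: str, estimand_b: str,
                    alpha: float = 0.05):
    """Paired bootstrap difference test.

    Significant iff the (alpha/2, 1-alpha/2) percentile interval of the
    replicate-wise differences excludes zero.  Returns
    ``(significant, ci_low, ci_high)``.
    """
    for e in (estimand_a, estimand_b):
        if e not in replicates.columns:
            raise ConfigurationError(f"estimand {e!r} not found in bootstrap replicates")
    diffs = replicates[estimand_a] - replicates[estimand_b]
    lo = float(diffs.quantile(alpha / 2))
    hi = float(diffs.quantile(1 - alpha / 2))
    significant = bool(lo > 0 or hi < 0)
    return significant, lo, hi


def difference_matrix(replicates: pd.DataFrame, estimands=None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Symmetric 0/1 matrix of pairwise bootstrap difference-test results."""
    estimands = list(estimands) if estimands is not None else list(replicates.columns)
    m = pd.DataFrame(0, index=estimands, columns=estimands, dtype=int)
    for i, a in enumerate(estimands):
        for b in estimands[i + 1:]:
            sig, _, _ = difference_test(replicates, a, b, alpha)
            m.loc[a, b] = m.loc[b, a] = int(sig)
    return m
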