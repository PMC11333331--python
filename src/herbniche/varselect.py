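"""Collinearity screening of environmental variables.

Strongly correlated covariate pairs (|r| at or above a threshold, 0.8 by
default) inflate model variance and blur variable-importance readings, so
only the higher-contribution member of each correlated pair is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geodata import EnvStack


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray          # symmetric, unit diagonal (NaN where undefined)
    n_used: np.ndarray     # jointly valid sample count per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


def pairwise_correlation(samples: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation on pairwise-complete rows.

    A constant variable has no defined correlation with anything; its
    off-diagonal entries are reported as NaN with a warning rather than 0.
    """
    names = list(samples.columns)
    k = len(names)
    X = samples.to_numpy(dtype=float)
    r = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    constant = []
    for i in range(k):
        r[i, i] = 1.0
        n_used[i, i] = int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(ok.sum())
            n_used[i, j] = n_used[j, i] = n
            if n < 3:
                continue
            xi, xj = X[ok, i], X[ok, j]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                if si == 0 and names[i] not in constant:
                    constant.append(names[i])
                if sj == 0 and names[j] not in constant:
                    constant.append(names[j])
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    if constant:
        warnings.warn(
            f"constant variables have undefined correlations: {constant}",
            stacklevel=2,
        )
    return CorrelationMatrix(names=names, r=r, n_used=n_used)


def correlation_from_stack(
    stack: EnvStack, max_cells: int = 10_000, seed: int = 0
) -> CorrelationMatrix:
    """Correlations over a seeded random sample of jointly valid cells."""
    table = stack.table()
    if len(table) > max_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(table), size=max_cells, replace=False)
        table = table.iloc[np.sort(idx)]
    return pairwise_correlation(table)


def select_uncorrelated(
    corr: CorrelationMatrix,
    contributions: dict[str, float],
    threshold: float = 0.8,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy retention in descending contribution order.

    A variable is kept iff |r| < threshold against every already-kept
    variable.  Returns the retained names and a drop log with, for each
    dropped variable, the kept variable that excluded it.  Ties in
    contribution break by variable-name order, so the outcome is
    deterministic.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    missing = [n for n in corr.names if n not in contributions]
    if missing:
        raise ConfigurationError(f"missing contributions for variables: {missing}")

    order = sorted(corr.names, key=lambda n: (-contributions[n], n))
    idx = {n: i for i, n in enumerate(corr.names)}
    kept: list[str] = []
    log_rows = []
    for name in order:
        blocker = None
        for k in kept:
            rv = corr.r[idx[name], idx[k]]
            if np.isfinite(rv) and abs(rv) >= threshold:
                blocker = k
                break
        if blocker is None:
            kept.append(name)
        else:
            log_rows.append(
                {
                    "dropped": name,
                    "kept_by": blocker,
                    "r": float(corr.r[idx[name], idx[blocker]]),
                    "contribution": contributions[name],
                }
            )
    drop_log = pd.DataFrame(log_rows, columns=["dropped", "kept_by", "r", "contribution"])
    return kept, drop_log
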