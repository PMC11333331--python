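"""Model assessment: AUC, variable contributions, permutation importance,
jackknife gains and response curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError
from .geodata import EnvStack, OccurrenceSet
from .maxent import BackgroundSample, MaxEnt, fit_maxent, presence_covariates, sample_background


def auc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve by the Mann–Whitney pair-counting estimate.

    Equivalent to the fraction of (positive, negative) pairs where the
    positive scores higher, with ties counting one half.  Computed via
    midranks so it stays O((n+m) log(n+m)).
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def contributions(model: MaxEnt) -> dict[str, float]:
    """Percent contribution per variable, from the fit's gain attribution."""
    if not hasattr(model, "contributions_"):
        raise ConfigurationError("model carries no gain trajectory; fit it first")
    return dict(model.contributions_)


def permutation_importance(
    model: MaxEnt,
    presence_rows: pd.DataFrame,
    background_rows: pd.DataFrame,
    seed: int = 0,
    n_repeats: int = 1,
) -> dict[str, float]:
    """Drop in training AUC when each variable is permuted, as percents.

    The variable's column is shuffled jointly across presence + background
    (one permutation by default), the model re-scores both sets, and the
    AUC drops are normalised to sum to 100.
    """
    rng = np.random.default_rng(seed)
    cols = model.variable_names_
    full = pd.concat([presence_rows[cols], background_rows[cols]], ignore_index=True)
    m = len(presence_rows)
    base_scores = model.predict_raw(full)
    base_auc = auc(base_scores[:m], base_scores[m:])
    drops = {}
    for name in cols:
        vals = []
        for _ in range(n_repeats):
            perm = full.copy()
            perm[name] = rng.permutation(perm[name].to_numpy())
            s = model.predict_raw(perm)
            vals.append(base_auc - auc(s[:m], s[m:]))
        drops[name] = max(float(np.mean(vals)), 0.0)
    total = sum(drops.values())
    if total <= 0:
        k = len(drops)
        return {n: 100.0 / k for n in drops}
    return {n: 100.0 * v / total for n, v in drops.items()}


@dataclass
class JackknifeResult:
    """Regularised training gains of with-only / without / full models."""

    gains: pd.DataFrame  # index variable, columns gain_only, gain_without
    gain_full: float
    errors: dict = field(default_factory=dict)

    def top_driver(self) -> str:
        """Variable with the highest single-variable training gain."""
        return str(self.gains["gain_only"].idxmax())


def jackknife(
    occurrences: OccurrenceSet,
    stack: EnvStack,
    seed: int = 0,
    n_background: int = 10_000,
    **maxent_kwargs,
) -> JackknifeResult:
    """Per-variable with-only and leave-one-out training gains.

    The reported gain is the (unpenalised) training gain
    (1/m) Σ log q(x_i) + ln(n_background): the improvement in average
    presence log-probability over the uniform background distribution.
    """
    pres = presence_covariates(occurrences, stack)
    bg = sample_background(stack, n=n_background, seed=seed)
    return jackknife_from_rows(pres, bg, **maxent_kwargs)


def jackknife_from_rows(
    presence_rows: pd.DataFrame,
    background: BackgroundSample | pd.DataFrame,
    **maxent_kwargs,
) -> JackknifeResult:
    bg_df = background.X if isinstance(background, BackgroundSample) else background
    variables = list(bg_df.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    errors: dict[str, Exception] = {}

    def gain_of(cols: list[str]) -> float:
        model = fit_maxent(presence_rows[cols], bg_df[cols], **maxent_kwargs)
        return model.training_gain_

    full = gain_of(variables)
    rows = {}
    for v in variables:
        entry = {}
        for key, cols in (("gain_only", [v]), ("gain_without", [c for c in variables if c != v])):
            try:
                entry[key] = gain_of(cols)
            except Exception as exc:  # keep going for the other variables
                errors[f"{v}:{key}"] = exc
                entry[key] = np.nan
        rows[v] = entry
    gains = pd.DataFrame(rows).T[["gain_only", "gain_without"]]
    return JackknifeResult(gains=gains, gain_full=full, errors=errors)


def response_curve(
    model: MaxEnt,
    variable: str,
    n_points: int = 100,
    threshold: float | None = 0.55,
) -> pd.DataFrame:
    """Marginal response: sweep one variable over its observed range with
    every other variable held at its background mean.

    Returns a DataFrame with columns ``value`` and ``p`` (logistic output);
    if ``threshold`` is given, ``attrs['above_threshold']`` holds the first
    and last swept value with p > threshold (or None).
    """
    names = model.variable_names_
    if variable not in names:
        raise ValueError(f"unknown variable {variable!r}")
    fs = model.feature_set_
    j = names.index(variable)
    grid = np.linspace(fs.lo[j], fs.hi[j], n_points)
    base = np.asarray(model.background_mean_, dtype=float)
    X = np.tile(base, (n_points, 1))
    X[:, j] = grid
    p = model.predict(X)
    df = pd.DataFrame({"value": grid, "p": p})
    if threshold is not None:
        above = grid[p > threshold]
        df.attrs["above_threshold"] = (
            (float(above[0]), float(above[-1])) if len(above) else None
        )
    return df


def evaluation_report(
    model: MaxEnt,
    presence_rows: pd.DataFrame,
    background_rows: pd.DataFrame,
    test_rows: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """AUCs plus both percent-importance tables, as a plain dict."""
    s_pres = model.predict_raw(presence_rows[model.variable_names_])
    s_bg = model.predict_raw(background_rows[model.variable_names_])
    report = {
        "auc_train": auc(s_pres, s_bg),
        "contributions": contributions(model),
        "permutation_importance": permutation_importance(
            model, presence_rows, background_rows, seed=seed
        ),
    }
    if test_rows is not None and len(test_rows):
        report["auc_test"] = auc(model.predict_raw(test_rows[model.variable_names_]), s_bg)
    return report
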