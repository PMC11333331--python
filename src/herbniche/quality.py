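"""Environment → metabolite quality modelling and zoning.

Per-compound contents at sampled sites are regressed on ecological factors
(stepwise OLS, AIC/BIC), predicted over the environmental stack, min–max
normalised within the suitable region, averaged into a single quality
score, and graded with Jenks natural breaks to yield the quality zoning
map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, EmptyDomainError
from .geodata import EnvStack, RasterGrid
from .zoning import jenks_breaks

COMPOUND_ORDER = ("Hyp", "Rt", "Ch.a", "Cyn", "Isa A")
# Cyn shows no clear environmental correlation and is excluded from the
# default quality overlay.
DEFAULT_ZONING_COMPOUNDS = ("Hyp", "Rt", "Ch.a", "Isa A")


@dataclass
class CompoundPanel:
    """Per-site compound contents (mg/g) with site coordinates."""

    sites: pd.DataFrame      # columns id, lon, lat
    contents: pd.DataFrame   # index site id, columns compounds

    def __post_init__(self) -> None:
        if (self.contents.to_numpy(dtype=float) < 0).any():
            raise ValueError("contents must be nonnegative")
        if not set(self.sites["id"]) == set(self.contents.index):
            raise ValueError("site ids and content rows do not correspond 1:1")
        ordered = [c for c in COMPOUND_ORDER if c in self.contents.columns]
        others = [c for c in self.contents.columns if c not in ordered]
        self.contents = self.contents[ordered + others]


def build_panel(
    sites: pd.DataFrame,
    contents: pd.DataFrame | None = None,
    matrix=None,
    standards: dict | None = None,
    sample_mass_g: float = 1.0,
    extract_volume_mL: float = 50.0,
) -> CompoundPanel:
    """Assemble a panel either from a ready content table or from a
    common-peak matrix plus quantification standards."""
    if contents is None:
        if matrix is None or standards is None:
            raise ConfigurationError("supply either contents or (matrix, standards)")
        from .fingerprint import quantify

        contents = quantify(matrix, standards, sample_mass_g, extract_volume_mL)
    missing = set(sites["id"]) ^ set(contents.index)
    if missing:
        raise ValueError(f"unmatched sample ids: {sorted(missing)}")
    return CompoundPanel(sites=sites.reset_index(drop=True), contents=contents)


class StepwiseLinearRegression(BaseEstimator, RegressorMixin):
    """Stepwise OLS factor selection (forward, backward, or both).

    At each step the single add/remove move with the best criterion
    (AIC or BIC) improvement is taken; the search stops when no move
    improves.  Rank-deficient candidate designs are skipped with a
    warning.

    Attributes
    ----------
    selected_ : list of str
        Retained factor names.
    coef_ : ndarray, intercept_ : float
    r2_ : float, aic_ : float
    """

    def __init__(self, direction: str = "both", criterion: str = "AIC"):
        self.direction = direction
        self.criterion = criterion

    def _score(self, res) -> float:
        return res.aic if self.criterion.upper() == "AIC" else res.bic

    def fit(self, X: pd.DataFrame, y):
        if self.direction not in ("forward", "backward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.criterion.upper() not in ("AIC", "BIC"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        candidates = list(X.columns)

        def fit_ols(cols: list[str]):
            design = sm.add_constant(X[cols], has_constant="add") if cols else sm.add_constant(
                pd.DataFrame(index=X.index)
            )
            if cols and np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
                return None
            return sm.OLS(y, design).fit()

        current = candidates.copy() if self.direction == "backward" else []
        res = fit_ols(current)
        best = self._score(res)
        improved = True
        while improved:
            improved = False
            moves = []
            if self.direction in ("forward", "both"):
                moves += [("add", v) for v in candidates if v not in current]
            if self.direction in ("backward", "both"):
                moves += [("drop", v) for v in current]
            best_move = None
            for kind, v in moves:
                cols = current + [v] if kind == "add" else [c for c in current if c != v]
                r = fit_ols(cols)
                if r is None:
                    import warnings

                    warnings.warn(f"skipping rank-deficient step with factor {v!r}", stacklevel=2)
                    continue
                s = self._score(r)
                if s < best - 1e-10:
                    best, best_move, res = s, (kind, v, cols), r
            if best_move is not None:
                current = best_move[2]
                improved = True
                # an (essentially) exact fit cannot be improved; adding more
                # factors only chases numerically meaningless likelihood gains
                if res.ssr <= 1e-10 * (np.sum((y - y.mean()) ** 2) + 1e-30):
                    break

        self.selected_ = current
        params = res.params
        self.intercept_ = float(params.get("const", 0.0))
        self.coef_ = np.array([params[c] for c in current], dtype=float)
        self.r2_ = float(res.rsquared) if current else 0.0
        self.aic_ = float(res.aic)
        self.bic_ = float(res.bic)
        self._result = res
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        X = pd.DataFrame(X)
        if self.selected_:
            return self.intercept_ + X[self.selected_].to_numpy(dtype=float) @ self.coef_
        return np.full(len(X), self.intercept_)


def stepwise_fit(
    panel: CompoundPanel,
    env_table: pd.DataFrame,
    compound: str,
    direction: str = "both",
    criterion: str = "AIC",
) -> StepwiseLinearRegression:
    """Fit one compound's content on the site-level ecological factors."""
    if compound not in panel.contents.columns:
        raise ConfigurationError(f"unknown compound {compound!r}")
    n, k = len(env_table), env_table.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n sites > factors + 2 (n={n}, factors={k})")
    y = panel.contents.loc[env_table.index, compound].to_numpy(dtype=float)
    return StepwiseLinearRegression(direction=direction, criterion=criterion).fit(env_table, y)


def correlation_table(panel: CompoundPanel, env_table: pd.DataFrame) -> pd.DataFrame:
    """Compound × factor Pearson r with two-sided p (t-test), long format
    with significance stars at 0.05 / 0.01."""
    if len(env_table) < 4:
        raise ValueError("need at least 4 sites")
    rows = []
    for comp in panel.contents.columns:
        y = panel.contents.loc[env_table.index, comp].to_numpy(dtype=float)
        for fac in env_table.columns:
            x = env_table[fac].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"compound": comp, "factor": fac, "r": np.nan, "p": np.nan, "sig": "const"})
                continue
            r, p = stats.pearsonr(y, x)
            sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append({"compound": comp, "factor": fac, "r": float(r), "p": float(p), "sig": sig})
    return pd.DataFrame(rows)


def predict_content_raster(
    model: StepwiseLinearRegression, stack: EnvStack, name: str = "content"
) -> tuple[RasterGrid, int]:
    """Cell-wise β·x + intercept over valid cells; negative predictions are
    floored at 0 and counted."""
    missing = [v for v in model.selected_ if v not in stack.names]
    if missing:
        raise ValueError(f"stack missing layers: {missing}")
    table = stack.table()
    pred = model.predict(table)
    n_floored = int((pred < 0).sum())
    pred = np.maximum(pred, 0.0)
    g = stack.grid
    out = np.full(g.values.shape, g.nodata)
    rows = table.index.get_level_values("row").to_numpy()
    cols = table.index.get_level_values("col").to_numpy()
    out[rows, cols] = pred
    return g.copy_with(out, name=name), n_floored


@dataclass
class QualityZoningMap:
    score: RasterGrid              # [0, 1] quality score within the suitable region
    grades: RasterGrid             # Jenks classes over the scored cells
    breaks: tuple[float, ...]
    provenance: dict = field(default_factory=dict)


def overlay_quality_zoning(
    content_rasters: dict[str, RasterGrid],
    suitability: RasterGrid,
    mask_threshold: float = 0.2,
    k_grades: int = 4,
    weights: dict[str, float] | None = None,
) -> QualityZoningMap:
    """Overlay predicted content surfaces with habitat suitability.

    Each content raster is min–max normalised over the region with
    suitability >= ``mask_threshold``; a degenerate (constant) raster
    scores 0.5 by convention.  The quality score is the (optionally
    weighted) mean of the normalised contents, graded by Jenks natural
    breaks into ``k_grades`` classes.  Cells below the threshold are
    nodata in both outputs.
    """
    if not content_rasters:
        raise ValueError("need at least one content raster")
    region = suitability.mask & (suitability.values >= mask_threshold)
    for name, g in content_rasters.items():
        if not g.same_grid(suitability):
            raise ValueError(f"content raster {name!r} not on the suitability grid")
        region &= g.mask
    if not region.any():
        raise EmptyDomainError("no cells above the suitability mask threshold")

    if weights is None:
        weights = {name: 1.0 for name in content_rasters}
    total_w = sum(weights[n] for n in content_rasters)
    score = np.zeros(region.sum())
    for name, g in content_rasters.items():
        v = g.values[region]
        lo, hi = v.min(), v.max()
        norm = np.full_like(v, 0.5) if hi <= lo else (v - lo) / (hi - lo)
        score += weights[name] / total_w * norm

    out_score = np.full(suitability.values.shape, suitability.nodata)
    out_score[region] = score
    score_grid = suitability.copy_with(out_score, name="quality_score")

    if len(np.unique(score)) >= k_grades:
        breaks = tuple(jenks_breaks(score, k_grades))
    else:
        breaks = ()
    codes = np.searchsorted(np.asarray(breaks), out_score, side="right") if breaks else np.zeros_like(out_score)
    out_grade = np.where(region, codes.astype(float), suitability.nodata)
    grade_grid = suitability.copy_with(out_grade, name="quality_grade")
    return QualityZoningMap(
        score=score_grid,
        grades=grade_grid,
        breaks=breaks,
        provenance={"mask_threshold": mask_threshold, "k_grades": k_grades, "weights": weights},
    )
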