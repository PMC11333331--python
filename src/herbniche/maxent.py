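"""Presence-background maximum-entropy species distribution model.

The model estimates the Gibbs distribution q(x) ∝ exp(λ·f(x)) over the
background cells that maximises entropy subject to matching the presence
means of the features, which is equivalent to maximising the L1-penalised
average presence log-likelihood

    (1/m) Σ_presence log q(x_i)  −  Σ_j β_j |λ_j|.

Feature classes are linear, quadratic, pairwise product and hinge
(forward + reverse on a fixed knot grid), each scaled to [0, 1] on the
training data.  Per-feature penalties β_j follow the canonical default
schedule (interpolated by presence count per feature class, scaled by the
feature's presence standard deviation and 1/√m).  The fit is a full-gradient
proximal (FISTA-style) convex optimisation; the stopping rule is the change
in regularised training gain.

The estimator follows the scikit-learn protocol: ``fit(X, y)`` with
``y = 1`` for presence rows and ``y = 0`` for background rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, EmptyDomainError
from .geodata import EnvStack, OccurrenceSet, RasterGrid, extract_values

# canonical default regularisation schedule: presence-count grid -> multiplier
_BETA_SCHEDULE = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "product": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
}


class FeatureSet:
    """Maps raw covariate rows to the model's [0, 1] feature space."""

    def __init__(
        self,
        variable_names: list[str],
        lo: np.ndarray,
        hi: np.ndarray,
        feature_classes: tuple[str, ...],
        n_hinge_knots: int,
    ):
        self.variable_names = list(variable_names)
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.feature_classes = tuple(feature_classes)
        self.n_hinge_knots = int(n_hinge_knots)
        # knots strictly inside (0, 1) in scaled space
        self.knots = (np.arange(1, self.n_hinge_knots + 1)) / (self.n_hinge_knots + 1)
        self._build_index()

    def _build_index(self) -> None:
        """Per-feature bookkeeping: name, class, contributing variable indices."""
        v = len(self.variable_names)
        names, classes, var_idx = [], [], []
        if "linear" in self.feature_classes:
            for i, n in enumerate(self.variable_names):
                names.append(n)
                classes.append("linear")
                var_idx.append((i,))
        if "quadratic" in self.feature_classes:
            for i, n in enumerate(self.variable_names):
                names.append(f"{n}^2")
                classes.append("quadratic")
                var_idx.append((i,))
        if "product" in self.feature_classes:
            for i in range(v):
                for j in range(i + 1, v):
                    names.append(f"{self.variable_names[i]}*{self.variable_names[j]}")
                    classes.append("product")
                    var_idx.append((i, j))
        if "hinge" in self.feature_classes:
            for i, n in enumerate(self.variable_names):
                for k in self.knots:
                    names.append(f"hinge({n},{k:.4f})")
                    classes.append("hinge")
                    var_idx.append((i,))
                for k in self.knots:
                    names.append(f"rhinge({n},{k:.4f})")
                    classes.append("hinge")
                    var_idx.append((i,))
        self.feature_names = names
        self.feature_class = np.array(classes)
        self.feature_vars = var_idx

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((X - self.lo) / span, 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.variable_names):
            raise ValueError(
                f"expected {len(self.variable_names)} variables, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values")
        Z = self.scale(X)
        blocks = []
        if "linear" in self.feature_classes:
            blocks.append(Z)
        if "quadratic" in self.feature_classes:
            blocks.append(Z * Z)
        if "product" in self.feature_classes:
            v = Z.shape[1]
            prods = [Z[:, i] * Z[:, j] for i in range(v) for j in range(i + 1, v)]
            if prods:
                blocks.append(np.stack(prods, axis=1))
        if "hinge" in self.feature_classes:
            k = self.knots[None, :]
            for col in range(Z.shape[1]):
                z = Z[:, col : col + 1]
                blocks.append(np.clip((z - k) / (1.0 - k), 0.0, 1.0))
            for col in range(Z.shape[1]):
                z = Z[:, col : col + 1]
                blocks.append(np.clip((k - z) / k, 0.0, 1.0))
        F = np.concatenate(blocks, axis=1)
        if "hinge" in self.feature_classes:
            # reorder hinge blocks to match _build_index (per variable: fwd then rev)
            F = self._reorder_hinges(F, Z.shape[1])
        return F

    def _reorder_hinges(self, F: np.ndarray, v: int) -> np.ndarray:
        n_base = self.n_features - 2 * v * self.n_hinge_knots
        base = F[:, :n_base]
        h = self.n_hinge_knots
        fwd = F[:, n_base : n_base + v * h]
        rev = F[:, n_base + v * h :]
        parts = [base]
        for i in range(v):
            parts.append(fwd[:, i * h : (i + 1) * h])
            parts.append(rev[:, i * h : (i + 1) * h])
        return np.concatenate(parts, axis=1)


class MaxEnt(BaseEstimator):
    """L1-regularised maximum-entropy presence-background model.

    Parameters
    ----------
    feature_classes : tuple of str
        Any of ``linear``, ``quadratic``, ``product``, ``hinge``.
    n_hinge_knots : int
        Knots per variable and direction for hinge features.
    max_iter : int
        Optimisation iteration cap (default 500).
    tol : float
        Stop when the regularised training gain improves by less than this
        (default 1e-5).
    reg_multiplier : float
        Global scale on the per-feature penalties.
    add_samples_to_background : bool
        Duplicate presence rows into the background, the conventional
        presence-background setup.

    Attributes
    ----------
    lambda_ : ndarray
        Fitted feature weights.
    entropy_ : float
        Entropy H of the fitted distribution over the background.
    log_partition_ : float
        log Z over the (possibly augmented) background.
    gain_trajectory_ : ndarray
        Regularised training gain after each accepted iteration.
    contributions_ : dict
        Percent contribution per input variable (sums to 100).
    """

    def __init__(
        self,
        feature_classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge"),
        n_hinge_knots: int = 50,
        max_iter: int = 500,
        tol: float = 1e-5,
        reg_multiplier: float = 1.0,
        add_samples_to_background: bool = True,
    ):
        self.feature_classes = feature_classes
        self.n_hinge_knots = n_hinge_knots
        self.max_iter = max_iter
        self.tol = tol
        self.reg_multiplier = reg_multiplier
        self.add_samples_to_background = add_samples_to_background

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X, names = _as_array(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values in X")
        pres = X[y == 1]
        bg = X[y == 0]
        if len(pres) < 2:
            raise ValueError("need at least 2 presence rows")
        if len(bg) < 2:
            raise ValueError("need at least 2 background rows")
        if self.add_samples_to_background:
            bg = np.vstack([bg, pres])

        self.variable_names_ = names or [f"x{i}" for i in range(X.shape[1])]
        both = np.vstack([pres, bg])
        fs = FeatureSet(
            self.variable_names_,
            both.min(axis=0),
            both.max(axis=0),
            tuple(self.feature_classes),
            self.n_hinge_knots,
        )
        self.feature_set_ = fs
        Fp = fs.transform(pres)
        Fb = fs.transform(bg)
        m, B = len(Fp), len(Fb)

        beta = self._penalties(fs, Fp, m)
        self.reg_beta_ = beta

        fbar = Fp.mean(axis=0)
        lam = np.zeros(fs.n_features)
        logB = np.log(B)

        def smooth(l):
            s = Fb @ l
            lz = logsumexp(s)
            return lz - fbar @ l, s, lz

        def gain(l, g_smooth):
            return -g_smooth + logB - beta @ np.abs(l)

        g0, s, lz = smooth(lam)
        gains = [gain(lam, g0)]
        contrib = np.zeros(fs.n_features)
        step = 1.0
        z = lam.copy()
        t_acc = 1.0
        small_steps = 0  # momentum can make single improvements tiny; require a run
        self.converged_ = False
        for it in range(self.max_iter):
            gz, sz, lzz = smooth(z)
            q = np.exp(sz - lzz)
            grad = Fb.T @ q - fbar
            # backtracking proximal step from z
            while True:
                cand = _soft_threshold(z - step * grad, step * beta)
                gc, sc, lzc = smooth(cand)
                diff = cand - z
                if gc <= gz + grad @ diff + (diff @ diff) / (2 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-12:
                    cand, gc = z, gz
                    break
            new_gain = gain(cand, gc)
            # FISTA momentum with restart on non-improvement
            t_next = (1 + np.sqrt(1 + 4 * t_acc**2)) / 2
            if new_gain < gains[-1]:
                z = lam.copy()
                t_acc = 1.0
                step *= 0.5  # overshoot: damp to avoid limit-cycling
                if step < 1e-11:
                    break
                continue
            delta = cand - lam
            w = np.abs(delta * grad)
            inc = new_gain - gains[-1]
            if inc > 0:
                contrib += inc * (w / w.sum() if w.sum() > 0 else 1.0 / len(w))
            z = cand + ((t_acc - 1) / t_next) * delta
            lam = cand
            t_acc = t_next
            gains.append(new_gain)
            step = min(step * 2.0, 1e6)
            if inc < self.tol:
                # confirm stationarity (KKT residual of the L1 problem) so a
                # single tiny momentum step cannot stop the fit prematurely
                q_l = np.exp(sc - lzc)
                grad_l = Fb.T @ q_l - fbar
                kkt = np.max(
                    np.where(
                        lam != 0,
                        np.abs(grad_l + np.sign(lam) * beta),
                        np.maximum(np.abs(grad_l) - beta, 0.0),
                    )
                )
                small_steps += 1
                if kkt < self.tol**0.75 or small_steps >= 50:
                    self.converged_ = True
                    break
            else:
                small_steps = 0
        if not self.converged_ and self.max_iter > 0:
            warnings.warn("maxent fit stopped at max_iter without converging", stacklevel=2)

        self.lambda_ = lam
        g_final, s_final, lz_final = smooth(lam)
        self.log_partition_ = float(lz_final)
        q = np.exp(s_final - lz_final)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
        self.gain_trajectory_ = np.asarray(gains[1:] if len(gains) > 1 else gains)
        self.training_gain_ = float(gains[-1] + beta @ np.abs(lam))  # unpenalised
        self.n_background_ = B
        self.n_presence_ = m
        self.background_mean_ = bg.mean(axis=0)
        self._contrib_raw_ = contrib
        self.contributions_ = self._variable_contributions(contrib)
        self.n_iter_ = len(gains) - 1
        return self

    def _penalties(self, fs: FeatureSet, Fp: np.ndarray, m: int) -> np.ndarray:
        sd = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(fs.n_features)
        sd = np.clip(sd, 1e-3, None)
        beta = np.empty(fs.n_features)
        for cls, (grid, mult) in _BETA_SCHEDULE.items():
            sel = fs.feature_class == cls
            if sel.any():
                lam_cls = np.interp(m, grid, mult)
                beta[sel] = lam_cls * sd[sel] / np.sqrt(m)
        return beta * self.reg_multiplier

    def _variable_contributions(self, contrib: np.ndarray) -> dict[str, float]:
        per_var = {n: 0.0 for n in self.variable_names_}
        for c, vars_ in zip(contrib, self.feature_set_.feature_vars):
            share = c / len(vars_)
            for vi in vars_:
                per_var[self.variable_names_[vi]] += share
        total = sum(per_var.values())
        if total <= 0:
            k = len(per_var)
            return {n: 100.0 / k for n in per_var}
        return {n: 100.0 * v / total for n, v in per_var.items()}

    # -- prediction ---------------------------------------------------------

    def predict_raw(self, X) -> np.ndarray:
        """Raw (Gibbs) probabilities normalised over the training background."""
        check_is_fitted(self, "lambda_")
        X, _ = _as_array(X, expect=self.variable_names_)
        F = self.feature_set_.transform(X)
        return np.exp(F @ self.lambda_ - self.log_partition_)

    def predict(self, X) -> np.ndarray:
        """Logistic suitability p = e^H q / (1 + e^H q), τ = 0.5."""
        q = self.predict_raw(X)
        eh = np.exp(self.entropy_)
        return eh * q / (1.0 + eh * q)

    predict_logistic = predict


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _as_array(X, expect: list[str] | None = None):
    if isinstance(X, pd.DataFrame):
        if expect is not None:
            missing = [n for n in expect if n not in X.columns]
            if missing:
                raise ValueError(f"missing model variables: {missing}")
            X = X[expect]
        return X.to_numpy(dtype=float), list(X.columns)
    return np.atleast_2d(np.asarray(X, dtype=float)), None


# ---------------------------------------------------------------------------
# Background sampling / convenience wrappers
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSample:
    points: np.ndarray          # (n, 2) lon/lat of sampled cell centers
    X: pd.DataFrame             # covariate rows
    n: int
    seed: int


def sample_background(stack: EnvStack, n: int = 10_000, seed: int = 0) -> BackgroundSample:
    """Uniform without-replacement sample of valid cells (reproducible)."""
    table = stack.table()
    total = len(table)
    if total == 0:
        raise EmptyDomainError("no jointly valid cells to sample background from")
    if n >= total:
        if n > total:
            warnings.warn(
                f"requested {n} background points but only {total} valid cells; taking all",
                stacklevel=2,
            )
        chosen = table
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(total, size=n, replace=False))
        chosen = table.iloc[idx]
    rows = chosen.index.get_level_values("row").to_numpy()
    cols = chosen.index.get_level_values("col").to_numpy()
    g = stack.grid
    pts = np.column_stack([g.lon_centers()[cols], g.lat_centers()[rows]])
    return BackgroundSample(points=pts, X=chosen.reset_index(drop=True), n=len(chosen), seed=seed)


def fit_maxent(
    presence_rows: pd.DataFrame,
    background: BackgroundSample | pd.DataFrame,
    max_iter: int = 500,
    tol: float = 1e-5,
    reg_multiplier: float = 1.0,
    **kwargs,
) -> MaxEnt:
    """Fit a :class:`MaxEnt` from presence and background covariate tables."""
    bg = background.X if isinstance(background, BackgroundSample) else background
    cols = list(bg.columns)
    X = pd.concat([presence_rows[cols], bg], ignore_index=True)
    y = np.r_[np.ones(len(presence_rows)), np.zeros(len(bg))]
    model = MaxEnt(max_iter=max_iter, tol=tol, reg_multiplier=reg_multiplier, **kwargs)
    return model.fit(X, y)


def predict_suitability_raster(model: MaxEnt, stack: EnvStack, name: str = "suitability") -> RasterGrid:
    """Logistic suitability over all valid cells of the stack."""
    table = stack.table()[model.variable_names_]
    p = model.predict(table)
    g = stack.grid
    out = np.full(g.values.shape, g.nodata)
    rows = table.index.get_level_values("row").to_numpy()
    cols = table.index.get_level_values("col").to_numpy()
    out[rows, cols] = p
    return g.copy_with(out, name=name)


def presence_covariates(occurrences: OccurrenceSet, stack: EnvStack) -> pd.DataFrame:
    """Covariate rows at occurrence points (nearest cell); nodata rows dropped."""
    df = extract_values(stack, occurrences.points, method="nearest")
    ok = ~df["has_nodata"]
    return df.loc[ok, stack.names].reset_index(drop=True)


def bootstrap_ensemble(
    occurrences: OccurrenceSet,
    stack: EnvStack,
    reps: int = 100,
    train_fraction: float = 0.75,
    seed: int = 0,
    n_background: int = 10_000,
    **maxent_kwargs,
) -> tuple[RasterGrid, list[float], list[MaxEnt]]:
    """Bootstrap-replicated fit with held-out test AUC per replicate.

    Each replicate permutes the occurrences, takes the first
    ``train_fraction`` as a pool, resamples that pool with replacement to
    the same size as the training set, and scores the held-out remainder
    against the background sample with the rank-based AUC.  The ensemble
    map is the cell-wise mean of the replicates' logistic predictions.
    """
    from .evaluation import auc

    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    pres = presence_covariates(occurrences, stack)
    if len(pres) < 8:
        raise ValueError("need at least 8 occurrences with valid covariates")
    bg = sample_background(stack, n=n_background, seed=seed)
    table = stack.table()
    rng = np.random.default_rng(seed)
    m = len(pres)
    n_train = max(2, int(round(train_fraction * m)))
    acc = np.zeros(len(table))
    aucs: list[float] = []
    models: list[MaxEnt] = []
    for _ in range(reps):
        perm = rng.permutation(m)
        pool = perm[:n_train]
        test = perm[n_train:]
        train_idx = rng.choice(pool, size=n_train, replace=True)
        model = fit_maxent(pres.iloc[train_idx], bg, **maxent_kwargs)
        models.append(model)
        acc += model.predict(table[model.variable_names_])
        if len(test) > 0:
            p_test = model.predict(pres.iloc[test])
            p_bg = model.predict(bg.X)
            aucs.append(auc(p_test, p_bg))
    g = stack.grid
    out = np.full(g.values.shape, g.nodata)
    rows = table.index.get_level_values("row").to_numpy()
    cols = table.index.get_level_values("col").to_numpy()
    out[rows, cols] = acc / reps
    return g.copy_with(out, name="suitability_mean"), aucs, models
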