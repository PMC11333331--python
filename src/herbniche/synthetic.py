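"""Synthetic inputs with known ground truth.

Every stage of the pipeline is exercised on data whose generating law is
retained (:class:`SyntheticTruth`), so recovery can be asserted: smooth
correlated environmental fields (spectral Gaussian-field synthesis),
presence points drawn from a known logistic suitability law, chromatograms
as Gaussian peaks over a drifting baseline, and compound contents with a
known linear environmental dependence.  All randomness flows through
``numpy.random.default_rng(seed)``, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDomainError
from .fingerprint import Chromatogram
from .geodata import EnvStack, OccurrenceSet, RasterGrid
from .quality import CompoundPanel

# Default scene: the seven retained drivers of the study system, with a
# dominant cold-limit variable (bio6) and annual precipitation (bio12),
# plus some strongly collinear extra layers to exercise screening.
DEFAULT_LAYERS = ("bio4", "bio6", "bio12", "elev", "s_oc", "srad2", "srad4")
DEFAULT_TRUE_BETA = {"bio6": 2.5, "bio12": 1.5, "bio4": -0.8}
# Negative intercept restricts the species to roughly a tenth of the
# landscape, matching the restricted prevalence and high discriminability
# of a real specialist's range.
DEFAULT_TRUE_INTERCEPT = -5.0


@dataclass
class SyntheticTruth:
    seed: int
    true_beta: dict[str, float] = field(default_factory=dict)
    true_surface: RasterGrid | None = None
    peak_spec: list | None = None
    content_beta: dict[str, dict[str, float]] | None = None
    noise: dict[str, float] = field(default_factory=dict)


def gaussian_field(
    nrows: int,
    ncols: int,
    correlation_length: float = 10.0,
    seed: int = 0,
    name: str = "field",
    xll: float = 100.0,
    yll: float = 25.0,
    cellsize: float = 0.05,
) -> RasterGrid:
    """Mean-0, sd-1 smooth random field by spectral synthesis.

    White noise is filtered in Fourier space with a Gaussian kernel of the
    given correlation length (in cells) and standardised.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("dims must be >= 8")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((nrows, ncols))
    fy = np.fft.fftfreq(nrows)[:, None]
    fx = np.fft.fftfreq(ncols)[None, :]
    kernel = np.exp(-2 * (np.pi * correlation_length) ** 2 * (fx**2 + fy**2))
    fld = np.real(np.fft.ifft2(np.fft.fft2(white) * np.sqrt(kernel)))
    fld = (fld - fld.mean()) / fld.std()
    return RasterGrid(
        name=name, xll=xll, yll=yll, cellsize=cellsize, nodata=-9999.0, values=fld
    )


def make_env_stack(
    k: int | None = None,
    cross_corr_matrix: np.ndarray | None = None,
    seed: int = 0,
    nrows: int = 100,
    ncols: int = 100,
    correlation_length: float = 10.0,
    names: tuple[str, ...] | None = None,
    **grid_kwargs,
) -> EnvStack:
    """Mix independent Gaussian fields through a Cholesky factor so the
    layers carry a prescribed cross-correlation structure."""
    if names is None:
        if k is None and cross_corr_matrix is not None:
            k = np.asarray(cross_corr_matrix).shape[0]
        names = DEFAULT_LAYERS if k is None else tuple(f"v{i + 1}" for i in range(k))
    k = len(names)
    if cross_corr_matrix is None:
        cross_corr_matrix = np.eye(k)
    C = np.asarray(cross_corr_matrix, dtype=float)
    if C.shape != (k, k) or not np.allclose(C, C.T):
        raise ValueError("cross_corr_matrix must be symmetric k×k")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("cross_corr_matrix must be positive-definite") from exc
    fields = np.stack(
        [
            gaussian_field(
                nrows, ncols, correlation_length, seed=seed * 1000 + i, **grid_kwargs
            ).values
            for i in range(k)
        ]
    )
    mixed = np.einsum("ij,jrc->irc", L, fields)
    template = gaussian_field(nrows, ncols, correlation_length, seed=seed * 1000, **grid_kwargs)
    layers = [template.copy_with(mixed[i], name=names[i]) for i in range(k)]
    return EnvStack(layers)


def suitability_surface(
    stack: EnvStack, true_beta: dict[str, float], intercept: float = 0.0
) -> RasterGrid:
    """Logistic suitability law p = σ(β₀ + Σ β_v x_v) over the stack."""
    g = stack.grid
    lin = np.full(g.values.shape, float(intercept))
    for name, b in true_beta.items():
        lin += b * stack[name].values
    from scipy.special import expit

    p = expit(lin)
    out = np.where(stack.mask, p, g.nodata)
    return g.copy_with(out, name="true_suitability")


def simulate_occurrences(
    stack: EnvStack,
    true_beta: dict[str, float],
    n: int = 298,
    seed: int = 0,
    species: str = "Lonicera japonica",
    intercept: float = 0.0,
) -> OccurrenceSet:
    """Presence points sampled with probability ∝ logistic(β₀ + β·x),
    jittered uniformly within their cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    surface = suitability_surface(stack, true_beta, intercept)
    m = stack.mask
    w = surface.values[m].astype(float)
    if not np.any(w > 0):
        raise EmptyDomainError("degenerate suitability law: all-zero weights")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(m)
    idx = rng.choice(len(rows), size=n, replace=True, p=w)
    g = stack.grid
    lon = g.lon_centers()[cols[idx]] + (rng.random(n) - 0.5) * g.cellsize
    lat = g.lat_centers()[rows[idx]] + (rng.random(n) - 0.5) * g.cellsize
    return OccurrenceSet(species=species, points=np.column_stack([lon, lat]))


def simulate_chromatogram(
    peak_spec: list[tuple[float, float, float]],
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
    duration: float = 50.0,
    rate: float = 10.0,
    sample_id: str = "synthetic",
) -> Chromatogram:
    """Sum of Gaussian peaks (RT min, width-σ min, area) + linear drift +
    white noise, sampled at ``rate`` points per minute over a 50-min run."""
    for rt, width, area in peak_spec:
        if not 0 <= rt <= duration:
            raise ValueError(f"peak RT {rt} outside run duration {duration}")
    t = np.arange(0.0, duration, 1.0 / rate)
    s = np.zeros_like(t)
    for rt, width, area in peak_spec:
        s += area / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / width) ** 2)
    s += drift * t
    if noise_sd > 0:
        s += np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return Chromatogram(
        sample_id=sample_id,
        time=t,
        signal=s,
        meta={"wavelength_nm": 245, "column_temp_C": 38, "flow_mL_min": 1, "injection_uL": 10},
    )


def simulate_contents(
    env_at_sites: pd.DataFrame,
    content_beta: dict[str, dict[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    intercepts: dict[str, float] | None = None,
) -> CompoundPanel:
    """Contents = β·x + intercept + Gaussian noise, floored at 0."""
    rng = np.random.default_rng(seed)
    n = len(env_at_sites)
    intercepts = intercepts or {}
    data = {}
    for comp, betas in content_beta.items():
        y = np.full(n, intercepts.get(comp, 5.0))
        for fac, b in betas.items():
            y = y + b * env_at_sites[fac].to_numpy(dtype=float)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, n)
        data[comp] = np.maximum(y, 0.0)
    contents = pd.DataFrame(data, index=env_at_sites.index)
    sites = pd.DataFrame(
        {
            "id": list(env_at_sites.index),
            "lon": env_at_sites["lon"].to_numpy() if "lon" in env_at_sites else np.zeros(n),
            "lat": env_at_sites["lat"].to_numpy() if "lat" in env_at_sites else np.zeros(n),
        }
    )
    return CompoundPanel(sites=sites, contents=contents)


def default_scene(
    seed: int = 0,
    nrows: int = 100,
    ncols: int = 100,
    n_occurrences: int = 298,
    correlation_length: float = 10.0,
) -> tuple[EnvStack, OccurrenceSet, SyntheticTruth]:
    """The standard seven-layer synthetic study scene.

    bio6 dominates the (logistic) suitability law, bio12 is secondary, and
    the cross-correlation structure includes moderately collinear pairs,
    echoing the collinearity of real bioclimatic layers.
    """
    names = DEFAULT_LAYERS
    k = len(names)
    C = np.eye(k)
    pairs = {("bio4", "bio6"): -0.4, ("srad2", "srad4"): 0.6, ("bio12", "s_oc"): 0.3}
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), r in pairs.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    stack = make_env_stack(
        cross_corr_matrix=C,
        seed=seed,
        nrows=nrows,
        ncols=ncols,
        correlation_length=correlation_length,
        names=names,
    )
    occ = simulate_occurrences(
        stack, DEFAULT_TRUE_BETA, n=n_occurrences, seed=seed + 1,
        intercept=DEFAULT_TRUE_INTERCEPT,
    )
    truth = SyntheticTruth(
        seed=seed,
        true_beta=dict(DEFAULT_TRUE_BETA),
        true_surface=suitability_surface(stack, DEFAULT_TRUE_BETA, DEFAULT_TRUE_INTERCEPT),
    )
    return stack, occ, truth


def fingerprint_scene(
    n_samples: int = 11,
    n_common: int = 21,
    n_spurious: int = 2,
    noise_sd: float = 0.05,
    shift_sd: float = 0.03,
    seed: int = 0,
) -> tuple[list[Chromatogram], SyntheticTruth]:
    """Chromatogram set with ``n_common`` shared peaks plus per-sample
    spurious peaks and small retention-time shifts."""
    rng = np.random.default_rng(seed)
    rts = np.sort(rng.uniform(3.0, 47.0, n_common))
    # enforce >= 1 min separation so shared peaks stay resolvable
    for i in range(1, n_common):
        rts[i] = max(rts[i], rts[i - 1] + 1.0)
    base_areas = rng.uniform(20.0, 120.0, n_common)
    widths = rng.uniform(0.06, 0.12, n_common)
    chroms = []
    for s in range(n_samples):
        shift = rng.normal(0.0, shift_sd)
        areas = base_areas * rng.lognormal(0.0, 0.15, n_common)
        spec = [(rts[i] + shift, widths[i], areas[i]) for i in range(n_common)]
        for _ in range(n_spurious):
            extra_rt = rng.uniform(3.0, 47.0)
            if np.min(np.abs(rts - extra_rt)) > 1.0:
                spec.append((extra_rt, 0.08, rng.uniform(5.0, 15.0)))
        chroms.append(
            simulate_chromatogram(
                spec,
                noise_sd=noise_sd,
                drift=0.01,
                seed=seed * 100 + s,
                sample_id=f"S{s + 1}",
            )
        )
    truth = SyntheticTruth(seed=seed, peak_spec=[(float(r), float(w), float(a)) for r, w, a in zip(rts, widths, base_areas)])
    return chroms, truth
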