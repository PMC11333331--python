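"""HPLC fingerprint post-processing.

Takes detector traces (time/intensity), finds and integrates peaks,
corrects retention-time drift against a reference sample, assembles the
samples × common-peaks area matrix, and scores each sample against a
reference fingerprint with the congruence (cosine) coefficient — the
standard similarity measure for herbal chromatographic fingerprints.
Marker compounds for *Lonicera japonica* Flos: chlorogenic acid (Ch.a),
rutin (Rt), hyperoside (Hyp), cynaroside (Cyn), isochlorogenic acid A
(Isa A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import AlignmentError, ConfigurationError

MARKER_COMPOUNDS = ("Ch.a", "Rt", "Hyp", "Cyn", "Isa A")


@dataclass
class Chromatogram:
    """One detector trace: time in minutes (strictly increasing), signal in
    arbitrary units, plus acquisition metadata (wavelength nm, column
    temperature °C, flow mL/min, injection µL)."""

    sample_id: str
    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_csv(cls, path, sample_id: str | None = None) -> "Chromatogram":
        df = pd.read_csv(path)
        if sample_id is None:
            import os

            sample_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(sample_id=sample_id, time=df.iloc[:, 0].to_numpy(), signal=df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "signal": self.signal}).to_csv(path, index=False)


@dataclass
class PeakTable:
    """Detected peaks of one sample, sorted by retention time."""

    sample_id: str
    peaks: pd.DataFrame  # retention_time, area, height, left, right


@dataclass
class CommonPeakMatrix:
    """samples × common-peaks area matrix; every entry observed in every
    sample.  ``compounds`` maps an identified peak column to its compound."""

    areas: pd.DataFrame                    # index sample_id, columns peak labels
    peak_rts: dict[str, float]             # column -> reference retention time
    compounds: dict[str, str] = field(default_factory=dict)

    @property
    def n_common(self) -> int:
        return self.areas.shape[1]


def detect_peaks(
    chrom: Chromatogram, min_height: float = 1.0, min_prominence: float = 0.5
) -> PeakTable:
    """Find local maxima above height/prominence thresholds and integrate.

    Peak bounds sit at the flanking signal minima (valleys); the area is
    the trapezoidal integral of the signal minus the straight baseline
    drawn between the bounds.
    """
    if len(chrom.signal) == 0:
        raise ValueError("empty signal")
    if min_height <= 0 or min_prominence <= 0:
        raise ValueError("thresholds must be > 0")
    idx, _ = find_peaks(chrom.signal, height=min_height, prominence=min_prominence)
    rows = []
    t, s = chrom.time, chrom.signal
    for k, apex in enumerate(idx):
        lo = idx[k - 1] if k > 0 else 0
        hi = idx[k + 1] if k + 1 < len(idx) else len(s) - 1
        left = lo + int(np.argmin(s[lo : apex + 1]))
        right = apex + int(np.argmin(s[apex : hi + 1]))
        if right <= left:
            continue
        seg_t, seg_s = t[left : right + 1], s[left : right + 1]
        baseline = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_s[0], seg_s[-1]])
        area = float(np.trapezoid(seg_s - baseline, seg_t))
        if area <= 0:
            continue
        rows.append(
            {
                "retention_time": float(t[apex]),
                "area": area,
                "height": float(s[apex]),
                "left": float(t[left]),
                "right": float(t[right]),
            }
        )
    df = pd.DataFrame(rows, columns=["retention_time", "area", "height", "left", "right"])
    return PeakTable(sample_id=chrom.sample_id, peaks=df.sort_values("retention_time").reset_index(drop=True))


def _piecewise_correction(sample_rts: np.ndarray, anchors_sample, anchors_ref) -> np.ndarray:
    """Map sample retention times onto the reference time axis through the
    matched anchor pairs (identity beyond the outermost anchors)."""
    if len(anchors_sample) == 0:
        return sample_rts
    anchors_sample = np.asarray(anchors_sample, dtype=float)
    anchors_ref = np.asarray(anchors_ref, dtype=float)
    order = np.argsort(anchors_sample)
    asamp, aref = anchors_sample[order], anchors_ref[order]
    corrected = np.interp(sample_rts, asamp, aref)
    # constant-offset extrapolation outside the anchor span
    below = sample_rts < asamp[0]
    above = sample_rts > asamp[-1]
    corrected[below] = sample_rts[below] + (aref[0] - asamp[0])
    corrected[above] = sample_rts[above] + (aref[-1] - asamp[-1])
    return corrected


def align_and_match(
    peak_tables: list[PeakTable],
    reference_sample: str,
    rt_tolerance: float = 0.2,
    anchor_rts: list[float] | None = None,
    n_anchors: int = 5,
) -> CommonPeakMatrix:
    """Retention-time correction plus common-peak matching.

    Anchors (default: the reference's ``n_anchors`` largest peaks, or an
    explicit retention-time list such as the five identified marker
    compounds) are matched greedily to each sample's nearest peak within
    ``rt_tolerance``; a piecewise-linear correction through the matched
    pairs maps every sample onto the reference time axis.  Each reference
    peak then claims the nearest corrected sample peak within tolerance,
    and only columns matched in every sample are kept as common peaks.
    Areas are never altered by the correction.
    """
    if len(peak_tables) < 2:
        raise ValueError("need at least 2 samples")
    by_id = {pt.sample_id: pt for pt in peak_tables}
    if reference_sample not in by_id:
        raise ValueError(f"reference sample {reference_sample!r} not among inputs")
    ref = by_id[reference_sample].peaks
    if anchor_rts is None:
        anchor_rts = (
            ref.nlargest(min(n_anchors, len(ref)), "area")["retention_time"]
            .sort_values()
            .tolist()
        )
    ref_rts = ref["retention_time"].to_numpy()
    peak_labels = [f"P{i + 1}" for i in range(len(ref_rts))]

    area_rows: dict[str, dict[str, float]] = {}
    for pt in peak_tables:
        rts = pt.peaks["retention_time"].to_numpy()
        if len(rts) == 0:
            raise AlignmentError(f"sample {pt.sample_id!r} has no peaks to align")
        # greedy nearest-anchor matching within tolerance
        asamp, aref = [], []
        used = set()
        for a in anchor_rts:
            dist = np.abs(rts - a)
            if used:
                dist[list(used)] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= rt_tolerance:
                asamp.append(rts[j])
                aref.append(a)
                used.add(j)
        if pt.sample_id != reference_sample and len(asamp) == 0:
            raise AlignmentError(
                f"sample {pt.sample_id!r}: no anchor peaks matched within {rt_tolerance} min"
            )
        corrected = (
            rts if pt.sample_id == reference_sample else _piecewise_correction(rts, asamp, aref)
        )
        # each reference peak claims its nearest corrected sample peak
        row: dict[str, float] = {}
        taken: set[int] = set()
        order = np.argsort([np.abs(corrected - r).min() for r in ref_rts])
        for oi in order:
            r = ref_rts[oi]
            dist = np.abs(corrected - r)
            for j in np.argsort(dist):
                if j in taken:
                    continue
                if dist[j] <= rt_tolerance:
                    row[peak_labels[oi]] = float(pt.peaks["area"].iloc[j])
                    taken.add(int(j))
                break
        area_rows[pt.sample_id] = row

    df = pd.DataFrame(area_rows).T
    common = [c for c in peak_labels if c in df.columns and df[c].notna().all()]
    df = df[common]
    rt_map = {lab: float(ref_rts[peak_labels.index(lab)]) for lab in common}
    return CommonPeakMatrix(areas=df, peak_rts=rt_map)


def reference_fingerprint(matrix: CommonPeakMatrix, method: str = "median") -> pd.Series:
    """Column-wise reference area vector (median or mean across samples)."""
    if method not in ("median", "mean"):
        raise ValueError(f"method must be 'median' or 'mean', got {method!r}")
    return matrix.areas.median() if method == "median" else matrix.areas.mean()


def congruence_similarity(a, b) -> float:
    """Congruence (cosine) coefficient a·b / (‖a‖‖b‖), in [0, 1] for
    nonnegative area vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def correlation_similarity(a, b) -> float:
    """Pearson-correlation alternative similarity mode."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(np.corrcoef(a, b)[0, 1])


def similarity_matrix(
    matrix: CommonPeakMatrix,
    reference: pd.Series | None = None,
    method: str = "congruence",
) -> pd.DataFrame:
    """Symmetric sample × sample similarity table with unit diagonal; if a
    reference fingerprint is given it is appended as row/column ``C``."""
    sim_fn = congruence_similarity if method == "congruence" else correlation_similarity
    A = matrix.areas
    ids = list(A.index)
    vectors = {i: A.loc[i].to_numpy() for i in ids}
    if reference is not None:
        vectors["C"] = np.asarray(reference, dtype=float)
        ids = ids + ["C"]
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            s = sim_fn(vectors[a], vectors[b])
            out.iloc[i, j] = out.iloc[j, i] = s
    return out


def rsd_percent(values) -> float:
    """Relative standard deviation, % — sample (n−1) sd over the mean."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


def quantify(
    matrix: CommonPeakMatrix,
    standards: dict[str, tuple[float, float]],
    sample_mass_g: float = 1.0,
    extract_volume_mL: float = 50.0,
) -> pd.DataFrame:
    """One-point external-standard quantification, mg/g per sample.

    ``standards`` maps compound -> (peak area of the standard injection,
    standard concentration in mg/mL); each compound must be mapped to a
    common-peak column via ``matrix.compounds``.

    content = area_sample / area_std × conc_std × volume / mass.
    """
    peak_of = {comp: col for col, comp in matrix.compounds.items()}
    rows = {}
    for comp, (area_std, conc_std) in standards.items():
        if comp not in peak_of:
            raise ConfigurationError(f"compound {comp!r} not mapped to a common peak")
        col = peak_of[comp]
        rows[comp] = (
            matrix.areas[col] / area_std * conc_std * extract_volume_mL / sample_mass_g
        )
    return pd.DataFrame(rows)
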