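"""Spectral preprocessing: region exclusion, probabilistic quotient
normalization (PQN), recursive segment peak alignment (RSPA), and
mean-centring / unit-variance scaling.

The default chain for human urine is: exclude the residual-water window
(4.7-4.9 ppm), PQN against the cohort median spectrum, RSPA to the median,
then unit-variance scaling.  All steps operate on a
:class:`~nmrmetab.spectra_io.SpectraMatrix` and are orientation-agnostic
(index-based), so whether ppm runs up or down never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spectra_io import SpectraMatrix

__all__ = [
    "RegionSet",
    "AlignmentParams",
    "ScalingState",
    "DEFAULT_HUMAN_EXCLUSION",
    "exclude_regions",
    "pqn_normalize",
    "rspa_align",
    "scale_uv",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]


@dataclass
class RegionSet:
    """Union of closed ppm intervals ``(low, high)``; overlap is allowed."""

    regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = [(float(lo), float(hi)) for lo, hi in self.regions]
        for lo, hi in self.regions:
            if not lo < hi:
                raise ValueError(f"region low must be < high, got ({lo}, {hi})")

    @classmethod
    def from_strings(cls, specs: list[str]) -> "RegionSet":
        """Parse ``"low:high"`` strings, e.g. ``["4.7:4.9"]``."""
        regions = []
        for s in specs:
            lo, _, hi = s.partition(":")
            regions.append((float(lo), float(hi)))
        return cls(regions)

    def mask(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean mask: True where ppm falls inside the union of regions."""
        m = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.regions:
            m |= (ppm >= lo) & (ppm <= hi)
        return m


#: Residual-water window excluded from all human-urine analyses.
DEFAULT_HUMAN_EXCLUSION = RegionSet([(4.7, 4.9)])


def exclude_regions(matrix: SpectraMatrix, regions: RegionSet) -> SpectraMatrix:
    """Drop every column whose ppm lies inside the union of ``regions``."""
    m = regions.mask(matrix.ppm)
    if m.all():
        raise ValueError("region set would remove every column")
    if not m.any():
        return matrix.copy()
    keep = ~m
    return SpectraMatrix(matrix.ppm[keep], matrix.intensities[:, keep], list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# probabilistic quotient normalization


def pqn_normalize(
    matrix: SpectraMatrix,
    reference: str | np.ndarray = "median",
    eps: float | None = None,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Divide each spectrum by its most probable quotient to a reference.

    The quotient of sample i is the median of ``x_i / reference`` over
    columns where the reference exceeds ``eps``; the default
    ``eps = 0.05 * max(reference)`` restricts the quotient to signal-bearing
    columns so near-zero baseline/noise columns cannot dominate the median
    of ratios.  ``reference`` is the column-wise median spectrum
    (``"median"``), a sample id, or an explicit vector.  Returns the
    normalized matrix and the per-sample quotient vector, which estimates
    the per-sample dilution factor up to a common constant.
    """
    if isinstance(reference, str):
        if reference == "median":
            if matrix.n_samples < 2:
                raise ValueError('reference="median" needs at least 2 samples')
            ref = np.median(matrix.intensities, axis=0)
        else:
            ref = matrix.row(reference).copy()
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (matrix.n_points,):
            raise ValueError("reference vector length does not match the ppm grid")
    if eps is None:
        eps = 0.05 * float(np.max(ref)) if np.any(ref > 0) else 0.0
    usable = ref > eps
    if not usable.any():
        raise ValueError("reference spectrum has no usable (positive) columns")
    quotients = np.empty(matrix.n_samples)
    for i, sid in enumerate(matrix.sample_ids):
        ratios = matrix.intensities[i, usable] / ref[usable]
        q = float(np.median(ratios))
        if not np.isfinite(q) or q <= 0:
            raise ValueError(f"sample {sid!r} has no usable quotient (median ratio {q!r})")
        quotients[i] = q
    normalized = matrix.intensities / quotients[:, None]
    return SpectraMatrix(matrix.ppm.copy(), normalized, list(matrix.sample_ids)), quotients


# ---------------------------------------------------------------------------
# recursive segment peak alignment


@dataclass
class AlignmentParams:
    """RSPA tuning knobs.

    ``max_shift_points``: largest integer shift tried per segment.  ``None``
    means "2% of the segment length, floor 5", so allowed shifts scale down
    as the recursion narrows; an explicit value applies to every segment
    (capped at segment length - 1).  ``improvement_min`` is the minimum
    cross-correlation gain over the unshifted segment for a shift to be
    accepted.  ``n_iter`` repeats the whole pass; with a pooled reference the
    reference is recomputed between passes, which sharpens it considerably
    once the first pass has removed most of the misalignment.

    Shift estimation is coarse-to-fine: in early passes both the reference
    and the spectrum are Gaussian-smoothed (initial sd ``smooth_sd_points``,
    quartered each pass) before cross-correlation, while the accepted shifts
    are applied to the raw spectrum.  Without smoothing, a sharp line
    correlates best with the tallest bump of the pooled reference — which
    for misaligned cohorts is a noisy mode of the shift distribution —
    whereas the smoothed profile is unimodal and centred.  ``None`` picks
    half the smallest-segment shift limit.
    """

    max_shift_points: int | None = None
    min_segment_points: int = 64
    recursion_depth_max: int = 12
    improvement_min: float = 0.0
    n_iter: int = 3
    smooth_sd_points: float | None = None

    def __post_init__(self) -> None:
        if self.max_shift_points is not None and self.max_shift_points < 0:
            raise ValueError("max_shift_points must be >= 0")
        if self.min_segment_points < 8:
            raise ValueError("min_segment_points must be >= 8")
        if self.recursion_depth_max < 0:
            raise ValueError("recursion_depth_max must be >= 0")
        if self.improvement_min < 0:
            raise ValueError("improvement_min must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.smooth_sd_points is not None and self.smooth_sd_points < 0:
            raise ValueError("smooth_sd_points must be >= 0")

    def shift_limit(self, seg_len: int) -> int:
        if self.max_shift_points is None:
            lim = max(5, int(round(0.02 * seg_len)))
        else:
            lim = self.max_shift_points
        return min(lim, seg_len - 1)


def _shift_segment(seg: np.ndarray, s: int) -> np.ndarray:
    """Shift by s points (positive = toward higher index), edge-padded."""
    if s == 0:
        return seg
    out = np.empty_like(seg)
    if s > 0:
        out[:s] = seg[0]
        out[s:] = seg[:-s]
    else:
        out[s:] = seg[-1]
        out[:s] = seg[-s:]
    return out


def _corr(a: np.ndarray, b_centered: np.ndarray, b_norm: float) -> float:
    ac = a - a.mean()
    an = float(np.linalg.norm(ac))
    if an == 0.0 or b_norm == 0.0:
        return 0.0
    return float(np.dot(ac, b_centered)) / (an * b_norm)


def _best_shift(seg: np.ndarray, ref_seg: np.ndarray, max_shift: int, improvement_min: float) -> int:
    """Integer shift maximizing Pearson correlation with the reference.

    Ties are broken toward the smaller |shift| (hence toward 0), and the
    winning shift is accepted only if it improves on the unshifted
    correlation by at least ``improvement_min``.
    """
    bc = ref_seg - ref_seg.mean()
    bn = float(np.linalg.norm(bc))
    base = _corr(seg, bc, bn)
    best_s, best_c = 0, base
    for mag in range(1, max_shift + 1):
        for s in (-mag, mag):
            c = _corr(_shift_segment(seg, s), bc, bn)
            if c > best_c:
                best_c, best_s = c, s
    if best_s != 0 and best_c - base < improvement_min:
        return 0
    return best_s


def _align_recursive(
    x: np.ndarray,
    ref: np.ndarray,
    lo: int,
    hi: int,
    depth: int,
    params: AlignmentParams,
    shifts: list[tuple[int, int, int]],
) -> None:
    n = hi - lo
    if n < params.min_segment_points:
        return
    limit = params.shift_limit(n)
    s = _best_shift(x[lo:hi], ref[lo:hi], limit, params.improvement_min) if limit > 0 else 0
    if s != 0:
        x[lo:hi] = _shift_segment(x[lo:hi], s)
    shifts.append((lo, hi, s))
    if depth >= params.recursion_depth_max or n < 2 * params.min_segment_points:
        return
    # Split at the reference's minimum-intensity point within the middle
    # third, so segment boundaries fall between peaks and are shared by all
    # samples.
    third = n // 3
    mid = ref[lo + third : hi - third]
    split = lo + third + int(np.argmin(mid))
    _align_recursive(x, ref, lo, split, depth + 1, params, shifts)
    _align_recursive(x, ref, split, hi, depth + 1, params, shifts)


def rspa_align(
    matrix: SpectraMatrix,
    reference: str | np.ndarray = "mean",
    params: AlignmentParams | None = None,
) -> tuple[SpectraMatrix, dict[str, list[tuple[int, int, int]]]]:
    """Align every spectrum to a reference by recursive segment shifting.

    ``reference`` is the cohort mean spectrum (default; for a symmetric
    shift distribution the mean profile's centre of mass sits at the true
    line position, making it the least biased anchor), the cohort
    ``"median"`` spectrum, a sample id, or an explicit vector.  With a
    pooled reference the reference is recomputed between passes.

    Each spectrum is recursively segmented; each segment is shifted by the
    integer offset (within the per-segment limit) that maximizes Pearson
    cross-correlation with the reference, points shifted off either end
    being filled by edge-value padding, and segments are split at the
    reference's minimum-intensity point in their middle third.  The total
    number of points never changes.  Returns the aligned matrix and a
    ShiftMap: per sample, the list of ``(start, stop, shift)`` segment
    records in visiting order, concatenated over passes.
    """
    params = params or AlignmentParams()
    if params.min_segment_points > matrix.n_points:
        raise ValueError(
            f"min_segment_points ({params.min_segment_points}) exceeds "
            f"n_points ({matrix.n_points})"
        )
    if isinstance(reference, str) and reference not in ("median", "mean"):
        fixed_ref = matrix.row(reference).copy()
        pooled = None
    elif isinstance(reference, np.ndarray):
        fixed_ref = np.asarray(reference, dtype=float)
        if fixed_ref.shape != (matrix.n_points,):
            raise ValueError("reference vector length does not match the ppm grid")
        pooled = None
    else:
        if matrix.n_samples < 2:
            raise ValueError(f'reference={reference!r} needs at least 2 samples')
        fixed_ref = None
        pooled = np.mean if reference == "mean" else np.median
    X = matrix.intensities.copy()
    shift_map: dict[str, list[tuple[int, int, int]]] = {sid: [] for sid in matrix.sample_ids}
    s0 = params.smooth_sd_points
    if s0 is None:
        s0 = 0.5 * params.shift_limit(min(params.min_segment_points, matrix.n_points))
    for it in range(params.n_iter):
        ref = pooled(X, axis=0) if fixed_ref is None else fixed_ref
        sd = s0 / (4.0**it)
        ref_est = gaussian_filter1d(ref, sd) if sd >= 0.5 else ref
        for i, sid in enumerate(matrix.sample_ids):
            segs: list[tuple[int, int, int]] = []
            if sd >= 0.5:
                est = gaussian_filter1d(X[i], sd)
                _align_recursive(est, ref_est, 0, matrix.n_points, 0, params, segs)
                for lo, hi, s in segs:  # replay estimated shifts on raw data
                    if s != 0:
                        X[i, lo:hi] = _shift_segment(X[i, lo:hi], s)
            else:
                _align_recursive(X[i], ref_est, 0, matrix.n_points, 0, params, segs)
            shift_map[sid].extend(segs)
    return SpectraMatrix(matrix.ppm.copy(), X, list(matrix.sample_ids)), shift_map


# ---------------------------------------------------------------------------
# unit-variance scaling


@dataclass
class ScalingState:
    """Column means/SDs (n-1 denominator) and surviving column indices."""

    column_means: np.ndarray
    column_sds: np.ndarray
    kept_columns: np.ndarray

    @property
    def kept_means(self) -> np.ndarray:
        return self.column_means[self.kept_columns]

    @property
    def kept_sds(self) -> np.ndarray:
        return self.column_sds[self.kept_columns]


def fit_scaler(X: np.ndarray) -> ScalingState:
    """Learn column means and SDs; zero-variance columns are marked dropped."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("scaling needs at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    if kept.size == 0:
        raise ValueError("all columns have zero variance")
    return ScalingState(means, sds, kept)


def apply_scaler(X: np.ndarray, state: ScalingState) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != state.column_means.size:
        raise ValueError(
            f"column count {X.shape[1]} does not match scaler ({state.column_means.size})"
        )
    return (X[:, state.kept_columns] - state.kept_means) / state.kept_sds


def invert_scaler(X_scaled: np.ndarray, state: ScalingState) -> np.ndarray:
    """Back-transform scaled data onto the kept columns (exact inverse)."""
    return X_scaled * state.kept_sds + state.kept_means


def scale_uv(matrix: SpectraMatrix) -> tuple[SpectraMatrix, ScalingState]:
    """Mean-centre and scale each column to unit variance.

    Zero-variance columns are dropped (recorded in the returned
    :class:`ScalingState`), and the ppm axis is restricted to the kept
    columns so loadings can be mapped back to chemical shifts.
    """
    state = fit_scaler(matrix.intensities)
    scaled = apply_scaler(matrix.intensities, state)
    return (
        SpectraMatrix(matrix.ppm[state.kept_columns], scaled, list(matrix.sample_ids)),
        state,
    )
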