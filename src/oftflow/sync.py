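"""Non-gated cardiac-cycle synchronization.

The scan pattern acquires, without any gating, one longitudinal b-mode
sequence along the tube and a stack of cross-sectional sequences, each
starting at an unknown cardiac phase.  This module reconstructs a single
normalized cardiac cycle (100 frames by default) from such data:

1. m-modes are extracted along pixel lines at mutually corresponding
   positions of the longitudinal and cross-sectional sequences;
2. the cardiac period is estimated per m-mode with the string-length
   method (fold by candidate period, minimize phase-ordered polyline
   length);
3. each m-mode is pooled into one normalized cycle of ``n_bins`` phase
   bins;
4. the circular shift between each cross-sectional pooled m-mode and the
   longitudinal reference is found by normalized cross-correlation;
5. residual slice-to-slice misalignment is measured on horizontal
   m-modes of the re-sequenced stack, accumulated along the slice axis,
   and smoothed (the cumulative-phase correction curve);
6. images and Doppler planes are re-sequenced onto the common cycle and
   interpolated to ``n_out`` frames.

Phase conventions: the cardiac cycle is normalized to [0, 1); all shifts
are circular.  ``phase_shift(a, b)`` returns a shift ``s`` (in pooled
bins) such that column ``(j + s) mod n_bins`` of ``b`` matches column
``j`` of ``a``; equivalently ``np.roll(b, -s, axis=1) ~ a``.  If the
reference sequence starts at cycle phase ``o_a`` and the other at
``o_b``, the recovered shift is ``(o_a - o_b) mod 1`` cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np


class SyncError(RuntimeError):
    """Raised when synchronization cannot proceed (e.g. flat m-mode)."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class BModeSequence:
    """Time series of 2-D structural image frames at a fixed plane.

    ``frames`` has shape (time, depth, width); the beam axis is the
    image vertical (depth) axis.  Frames are uniformly spaced at 1/fps.
    """

    frames: np.ndarray
    fps: float
    acquisition_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, depth, width)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least two frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class DopplerSequence(BModeSequence):
    """Signed beam-axis velocity planes (mm/s) co-registered with a
    :class:`BModeSequence` of identical shape and timing."""


@dataclass(frozen=True)
class LineSpec:
    """A pixel line within a b-mode frame.

    orientation 'vertical' selects column ``index`` (profile along
    depth); 'horizontal' selects row ``index`` (profile along width).
    """

    orientation: Literal["vertical", "horizontal"]
    index: int
    slice_index: int | None = None


@dataclass
class MMode:
    """Motion-in-time image: one pixel line per frame, stacked.

    ``matrix`` has shape (pixels_along_line, time); column ``j`` is the
    specified line of frame ``j``.
    """

    matrix: np.ndarray
    line_spec: LineSpec
    fps: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("m-mode matrix must be 2-D")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PhaseSchedule:
    """Result of synchronization: the common period and per-slice shifts.

    per_slice_shift is in cycles in [0, 1), relative to the longitudinal
    reference; cumulative_curve is the smoothed cumulative residual
    phase correction along the slice axis, in pooled frames (1/n_bins of
    a cycle each).
    """

    period_frames: float
    per_slice_shift: np.ndarray
    cumulative_curve: np.ndarray
    n_bins: int = 200
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CumulativeCurve:
    """Neighbor-shift accumulation along the slice axis with smoothing."""

    raw: np.ndarray            # cumulative phase (pooled bins), per slice
    smoothed: np.ndarray       # robust low-order fit of ``raw``
    neighbor_shifts: np.ndarray  # wrapped pairwise shifts, len n_slices-1
    outlier_slices: np.ndarray  # indices where |raw - fit| > threshold
    ambiguous_slices: np.ndarray  # neighbor shifts near half a cycle


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def extract_mmode(seq: BModeSequence, line_spec: LineSpec) -> MMode:
    """Stack one pixel line from every frame into an m-mode matrix."""
    n_t, n_depth, n_width = seq.frames.shape
    if line_spec.orientation == "vertical":
        if not 0 <= line_spec.index < n_width:
            raise IndexError(f"column {line_spec.index} outside width {n_width}")
        mat = seq.frames[:, :, line_spec.index].T
    elif line_spec.orientation == "horizontal":
        if not 0 <= line_spec.index < n_depth:
            raise IndexError(f"row {line_spec.index} outside depth {n_depth}")
        mat = seq.frames[:, line_spec.index, :].T
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    return MMode(matrix=mat.copy(), line_spec=line_spec, fps=seq.fps)


def _normalized(mat: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance copy; raises on (near) constant input.

    Normalizing first makes every downstream estimator invariant to
    affine intensity transforms of the m-mode.
    """
    m = np.asarray(mat, dtype=float)
    sd = m.std()
    if not np.isfinite(sd) or sd < 1e-12 * (1.0 + abs(m.mean())):
        raise SyncError("m-mode has no intensity variation (flat signal)")
    return (m - m.mean()) / sd


def _string_length(X: np.ndarray, period: float) -> float:
    """Total phase-ordered polyline length for one candidate period.

    Columns are mapped to phases (i mod p)/p, sorted by phase, and the
    Euclidean lengths of consecutive (phase, column-vector) segments are
    summed.  Column distances are scaled by 1/sqrt(n_pixels) so the two
    coordinates are commensurate.
    """
    n_pix, n = X.shape
    phases = np.mod(np.arange(n), period) / period
    order = np.argsort(phases, kind="stable")
    ph = phases[order]
    cols = X[:, order]
    dph = np.diff(ph)
    dcol2 = np.sum(np.diff(cols, axis=1) ** 2, axis=0) / n_pix
    return float(np.sum(np.sqrt(dph**2 + dcol2)))


def estimate_period(
    mmode: MMode,
    search_range_frames: tuple[float, float],
    grid_step: float = 0.1,
) -> float:
    """String-length period estimate in frames (real-valued).

    Grid search over candidate periods followed by parabolic refinement
    around the minimum of the normalized string length.  The candidate
    range must lie within (2, n_frames/2) so that at least two full
    cycles are folded and the first harmonic (2T) is excluded.
    """
    X = _normalized(mmode.matrix)
    n = X.shape[1]
    lo, hi = search_range_frames
    if not (2.0 < lo < hi <= n / 2.0):
        raise ValueError(
            f"search range {search_range_frames} must lie within (2, {n / 2})"
        )
    candidates = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    # Baseline: string length of the temporally ordered sequence.
    dcol2 = np.sum(np.diff(X, axis=1) ** 2, axis=0) / X.shape[0]
    baseline = float(np.sum(np.sqrt((1.0 / (n - 1)) ** 2 + dcol2)))
    lengths = np.array([_string_length(X, p) for p in candidates]) / baseline
    k = int(np.argmin(lengths))
    best = candidates[k]
    if 0 < k < len(candidates) - 1:
        y0, y1, y2 = lengths[k - 1], lengths[k], lengths[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            best = best + 0.5 * grid_step * (y0 - y2) / denom
    return float(best)


def pool_cycle(mmode: MMode, period_frames: float, n_bins: int = 200) -> MMode:
    """Fold an m-mode into one normalized cycle of ``n_bins`` phase bins.

    Column i is assigned to bin floor(((i mod p)/p) * n_bins); each bin
    holds the mean of its columns; empty bins are filled by circular
    linear interpolation between the nearest populated bins.
    """
    if period_frames <= 0:
        raise ValueError("period must be positive")
    mat = mmode.matrix
    n_pix, n = mat.shape
    phases = np.mod(np.arange(n), period_frames) / period_frames
    # epsilon guards against i/p*p rounding just below an integer bin edge
    bins = np.floor(phases * n_bins + 1e-9).astype(int) % n_bins
    sums = np.zeros((n_pix, n_bins))
    counts = np.zeros(n_bins)
    np.add.at(sums.T, bins, mat.T)
    np.add.at(counts, bins, 1.0)
    filled = counts > 0
    pooled = np.empty_like(sums)
    pooled[:, filled] = sums[:, filled] / counts[filled]
    if not filled.all():
        pooled[:, ~filled] = _circular_fill(pooled, filled)
    period_s = period_frames / mmode.fps
    return MMode(matrix=pooled, line_spec=mmode.line_spec, fps=n_bins / period_s)


def _circular_fill(pooled: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of empty phase bins."""
    n_bins = filled.size
    idx_filled = np.flatnonzero(filled)
    if idx_filled.size == 0:
        raise SyncError("no populated phase bins")
    out = []
    for j in np.flatnonzero(~filled):
        after = idx_filled[np.searchsorted(idx_filled, j) % idx_filled.size]
        before = idx_filled[np.searchsorted(idx_filled, j) - 1]
        gap = (after - before) % n_bins
        if gap == 0:  # single populated bin
            out.append(pooled[:, after])
            continue
        t = ((j - before) % n_bins) / gap
        out.append((1 - t) * pooled[:, before] + t * pooled[:, after])
    return np.column_stack(out)


def _circular_ncc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """NCC of matrices a, b over all circular column lags.

    Entry s is the normalized correlation of a with b advanced by s
    columns: sum_j a[:, j] * b[:, (j + s) mod n].
    """
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    corr = np.fft.irfft(np.conj(fa) * fb, n=a.shape[1], axis=1).sum(axis=0)
    norm = np.linalg.norm(a) * np.linalg.norm(b)
    if norm == 0:
        raise SyncError("cannot correlate constant m-modes")
    return corr / norm


def phase_shift(pooled_a: MMode, pooled_b: MMode) -> float:
    """Circular shift (in pooled bins) aligning ``pooled_b`` to ``pooled_a``.

    Maximizes normalized cross-correlation over all circular lags on
    mean-subtracted matrices, with parabolic sub-bin refinement of the
    peak.  Ties are broken toward the smallest absolute circular shift.
    Returns a value in [0, n_bins).
    """
    a = pooled_a.matrix
    b = pooled_b.matrix
    if a.shape != b.shape:
        raise ValueError("pooled m-modes must share shape (same bin count)")
    A = _normalized(a)
    B = _normalized(b)
    ncc = _circular_ncc(A, B)
    n = ncc.size
    best = np.flatnonzero(ncc >= ncc.max() - 1e-12)
    wrapped = np.where(best > n / 2, best - n, best)
    s0 = int(best[np.argmin(np.abs(wrapped))])
    y0, y1, y2 = ncc[(s0 - 1) % n], ncc[s0], ncc[(s0 + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
    shift = (s0 + delta) % n
    if n - shift < 1e-9:  # wrap float noise back to 0
        shift = 0.0
    return float(shift)


def wrap_to_half(shift: float, n_bins: int) -> float:
    """Map a circular shift in bins to the interval [-n_bins/2, n_bins/2)."""
    return float((shift + n_bins / 2.0) % n_bins - n_bins / 2.0)


def refine_and_smooth(
    cross_pooled: Sequence[MMode],
    outlier_bins: float = 5.0,
    poly_degree: int = 3,
    half_cycle_margin: float = 0.1,
    overrides: dict[int, float] | None = None,
) -> CumulativeCurve:
    """Accumulate neighbor phase shifts along the slice axis and smooth.

    Pairwise shifts between adjacent (already coarsely aligned) slices
    are wrapped to [-n_bins/2, n_bins/2), accumulated, and fitted with a
    robust low-order polynomial; slices whose cumulative value deviates
    from the fit by more than ``outlier_bins`` are replaced by the fit
    and the fit recomputed.  ``overrides`` maps slice index to a manual
    cumulative value (pooled bins), standing in for the interactive
    correction step.  Neighbor shifts with magnitude within
    ``half_cycle_margin`` * n_bins of half a cycle are flagged as
    unwrap-ambiguous.
    """
    if len(cross_pooled) < 2:
        raise ValueError("need at least two slices")
    n_bins = cross_pooled[0].n_columns
    shifts = np.array(
        [
            wrap_to_half(phase_shift(cross_pooled[k], cross_pooled[k + 1]), n_bins)
            for k in range(len(cross_pooled) - 1)
        ]
    )
    ambiguous = np.flatnonzero(
        np.abs(shifts) > (0.5 - half_cycle_margin) * n_bins
    )
    raw = np.concatenate(([0.0], np.cumsum(shifts)))
    work = raw.copy()
    if overrides:
        for k, v in overrides.items():
            work[k] = v
    # robust pre-pass: isolated spikes are replaced by the running median
    # before the least-squares fit, so one corrupted slice cannot drag
    # the polynomial
    from scipy.ndimage import median_filter as _medfilt

    baseline = _medfilt(work, size=3, mode="nearest")
    outliers = np.flatnonzero(np.abs(work - baseline) > outlier_bins)
    work[outliers] = baseline[outliers]
    x = np.arange(work.size, dtype=float)
    deg = min(poly_degree, work.size - 1)
    fit = np.polynomial.Polynomial.fit(x, work, deg)(x)
    return CumulativeCurve(
        raw=raw,
        smoothed=fit,
        neighbor_shifts=shifts,
        outlier_slices=outliers,
        ambiguous_slices=ambiguous,
    )


def resequence(
    seq: BModeSequence,
    period_frames: float,
    shift_bins: float,
    n_out: int = 100,
    n_bins: int = 200,
) -> BModeSequence:
    """Pool a sequence onto the normalized cycle and re-sample it.

    Output frame j corresponds to cycle phase j/n_out of the reference;
    it is the circular linear interpolation of the pooled input at bin
    position (j * n_bins / n_out + shift_bins) mod n_bins.  Works
    identically for image and Doppler sequences (type preserved).
    """
    n_t, n_depth, n_width = seq.frames.shape
    flat = MMode(
        matrix=seq.frames.reshape(n_t, -1).T,
        line_spec=LineSpec("vertical", 0),
        fps=seq.fps,
    )
    pooled = pool_cycle(flat, period_frames, n_bins=n_bins).matrix
    pos = (np.arange(n_out) * n_bins / n_out + shift_bins) % n_bins
    i0 = np.floor(pos).astype(int) % n_bins
    i1 = (i0 + 1) % n_bins
    t = pos - np.floor(pos)
    frames = ((1 - t) * pooled[:, i0] + t * pooled[:, i1]).T
    frames = frames.reshape(n_out, n_depth, n_width)
    period_s = period_frames / seq.fps
    return type(seq)(frames=frames, fps=n_out / period_s)


# ---------------------------------------------------------------------------
# dataset-level orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyncedDataset:
    """Synchronized 4-D reconstruction: one normalized cycle.

    ``volume`` has shape (n_out, depth, width, n_slices); ``doppler``
    matches.  Frame t of every slice corresponds to the same cardiac
    phase t/n_out (referenced to the longitudinal sequence's cycle).
    """

    volume: np.ndarray
    doppler: np.ndarray
    schedule: PhaseSchedule
    fps_equivalent: float


def synchronize_dataset(
    longitudinal: BModeSequence,
    cross_images: Sequence[BModeSequence],
    cross_doppler: Sequence[DopplerSequence],
    slice_columns: np.ndarray | None = None,
    period_search: tuple[float, float] | None = None,
    n_bins: int = 200,
    n_out: int = 100,
    outlier_bins: float = 5.0,
) -> SyncedDataset:
    """Full synchronization of a cross-sectional stack to the longitudinal
    reference.

    ``slice_columns[k]`` is the longitudinal image column corresponding
    to cross-sectional slice k (defaults to column k).  The period is
    estimated per m-mode with the string-length method and the median
    over all m-modes is used as the consensus period; each sequence is
    pooled with the consensus.
    """
    n_slices = len(cross_images)
    if slice_columns is None:
        slice_columns = np.arange(n_slices)
    if period_search is None:
        n = longitudinal.n_frames
        period_search = (n / 10.0, n / 2.0)

    long_mmodes = [
        extract_mmode(longitudinal, LineSpec("vertical", int(c), None))
        for c in slice_columns
    ]
    cross_center = [seq.frames.shape[2] // 2 for seq in cross_images]
    cross_mmodes = [
        extract_mmode(seq, LineSpec("vertical", c, k))
        for k, (seq, c) in enumerate(zip(cross_images, cross_center))
    ]
    periods = np.array(
        [estimate_period(m, period_search) for m in long_mmodes + cross_mmodes]
    )
    period = float(np.median(periods))

    pooled_long = [pool_cycle(m, period, n_bins) for m in long_mmodes]
    pooled_cross = [pool_cycle(m, period, n_bins) for m in cross_mmodes]
    coarse = np.array(
        [phase_shift(a, b) for a, b in zip(pooled_long, pooled_cross)]
    )

    # Residual refinement on horizontal center-line m-modes of the
    # coarsely aligned stack.
    aligned = [
        resequence(seq, period, s, n_out=n_bins, n_bins=n_bins)
        for seq, s in zip(cross_images, coarse)
    ]
    center_rows = [seq.frames.shape[1] // 2 for seq in aligned]
    horiz = [
        pool_cycle(
            extract_mmode(seq, LineSpec("horizontal", r, k)), float(n_bins), n_bins
        )
        for k, (seq, r) in enumerate(zip(aligned, center_rows))
    ]
    curve = refine_and_smooth(horiz, outlier_bins=outlier_bins)
    # The cumulative neighbor curve mixes residual per-slice jitter with
    # the smooth physical inlet->outlet contraction-wave lag; only the
    # non-smooth part (raw - smoothed) is a synchronization error, and
    # only where it clears the outlier threshold is it trustworthy
    # (small residuals are dominated by waveform-shape bias between
    # neighboring slices, not by misalignment).
    jitter = curve.raw - curve.smoothed
    correction = np.where(np.abs(jitter) > outlier_bins, jitter, 0.0)
    final = coarse + correction

    vol = np.stack(
        [
            resequence(seq, period, s, n_out=n_out, n_bins=n_bins).frames
            for seq, s in zip(cross_images, final)
        ],
        axis=-1,
    )
    dop = np.stack(
        [
            resequence(seq, period, s, n_out=n_out, n_bins=n_bins).frames
            for seq, s in zip(cross_doppler, final)
        ],
        axis=-1,
    )
    schedule = PhaseSchedule(
        period_frames=period,
        per_slice_shift=np.mod(final / n_bins, 1.0),
        cumulative_curve=curve.smoothed,
        n_bins=n_bins,
        diagnostics={
            "pooled_mmode_pair_mid": (
                pooled_long[n_slices // 2].matrix,
                pooled_cross[n_slices // 2].matrix,
            ),
            "coarse_shift_bins": coarse,
            "neighbor_shifts": curve.neighbor_shifts,
            "raw_cumulative": curve.raw,
            "outlier_slices": curve.outlier_slices,
            "ambiguous_slices": curve.ambiguous_slices,
            "period_estimates": periods,
        },
    )
    period_s = period / longitudinal.fps
    return SyncedDataset(
        volume=vol, doppler=dop, schedule=schedule, fps_equivalent=n_out / period_s
    )


def validate_sync(
    long_doppler: DopplerSequence,
    synced: SyncedDataset,
    slice_columns: np.ndarray | None = None,
    n_points: int = 4,
    min_amplitude: float = 1e-9,
) -> list[dict]:
    """Cross-validate synchronization against the longitudinal Doppler data.

    At ``n_points`` corresponding locations along the tube, the vertical
    velocity-vs-phase curve of the longitudinal dataset (pooled on its
    own cycle) is compared with the curve of the synchronized
    cross-sectional stack at the same location.  Reports peak circular
    cross-correlation, optimal lag (in output frames), and RMS
    difference per point; locations with no Doppler signal are excluded
    with a warning entry.
    """
    n_out, depth, width, n_slices = synced.doppler.shape
    if slice_columns is None:
        slice_columns = np.arange(n_slices)
    period = synced.schedule.period_frames
    picks = np.unique(
        np.linspace(0, n_slices - 1, n_points).round().astype(int)
    )
    reports: list[dict] = []
    for k in picks:
        col = int(slice_columns[k])
        mm = extract_mmode(long_doppler, LineSpec("vertical", col, None))
        pooled = pool_cycle(mm, period, n_bins=n_out).matrix
        row = depth // 2
        ref_curve = pooled[row, :]
        test_curve = synced.doppler[:, row, width // 2, k]
        if max(np.abs(ref_curve).max(), np.abs(test_curve).max()) < min_amplitude:
            reports.append(
                {"slice": int(k), "excluded": True, "reason": "no Doppler signal"}
            )
            continue
        a = ref_curve - ref_curve.mean()
        b = test_curve - test_curve.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom < min_amplitude:
            reports.append(
                {"slice": int(k), "excluded": True, "reason": "constant curve"}
            )
            continue
        ncc = np.fft.irfft(
            np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=n_out
        ) / denom
        lag = int(np.argmax(ncc))
        lag_wrapped = lag - n_out if lag > n_out / 2 else lag
        reports.append(
            {
                "slice": int(k),
                "excluded": False,
                "peak_correlation": float(ncc.max()),
                "lag_frames": float(lag_wrapped),
                "rms_difference": float(
                    np.sqrt(np.mean((ref_curve - test_curve) ** 2))
                ),
            }
        )
    return reports
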