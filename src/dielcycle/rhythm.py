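"""Cyclic-expression detection by DFT with Welch averaging.

The detector scores each gene's expression vector for 24-h periodicity.
The vector is split into day-length segments (by default every day-length
subset, i.e. maximally overlapping windows stepping one sample at a time,
so no particular subset biases the average), each segment is mean-centred
and Fourier-transformed, the squared-magnitude spectrum of each segment is
min-max normalized to [0, 1] over the non-DC components, and the normalized
spectra are averaged.  The *cyclic score* is the averaged value at the
component whose period equals the day length; a score of 1 means the 24-h
component dominated every segment.  Significance is calibrated empirically
by scoring randomly permuted expression vectors and thresholding at a top
percentile of that null distribution.

Period, amplitude and phase of called genes are read off the full-length
spectrum: period from the dominant component refined by quadratic
interpolation on log-power, amplitude as ``2|y_k|/N``, and phase as the ZT
at which the fitted cosine peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .layout import SamplingLayout

__all__ = [
    "upper_quartile_normalize",
    "dft_spectrum",
    "cyclic_score",
    "cyclic_scores",
    "NullDistribution",
    "null_score_distribution",
    "threshold_at_top_percentile",
    "call_cycling",
    "fit_cyclic_parameters",
    "assign_phase_cluster",
    "detect_cycling",
]


def upper_quartile_normalize(
    matrix: ExpressionMatrix, reference: float | None = None
) -> ExpressionMatrix:
    """Scale each sample so its upper quartile equals a common reference.

    The upper quartile is computed over genes with a nonzero value in that
    sample; the default reference is the mean of the per-sample quartiles,
    which keeps the matrix on its original scale.
    """
    arr = matrix.to_array()
    uq = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        nz = arr[:, j][arr[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {matrix.values.columns[j]!r} is all zero")
        uq[j] = np.percentile(nz, 75)
    ref = float(np.mean(uq)) if reference is None else float(reference)
    scaled = arr * (ref / uq)[None, :]
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=matrix.gene_ids, columns=matrix.values.columns),
        matrix.layout,
    )


def dft_spectrum(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Fourier transform of one mean-centred segment.

    Returns ``(y, power)`` where ``y`` holds the complex components
    ``y_k = sum_n x_n exp(-2*pi*i*k*n/M)`` of the mean-centred segment and
    ``power[k] = |y_k|**2`` for ``k = 0..M//2`` (real-input symmetry makes
    the upper half redundant).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must have at least 2 points")
    x = x - x.mean()
    y = np.fft.fft(x)
    power = np.abs(y[: x.size // 2 + 1]) ** 2
    return y, power


def _segment_starts(layout: SamplingLayout, overlap: float) -> tuple[list[int], int]:
    m = layout.points_per_day
    if layout.n_points < m:
        raise ValueError("vector does not cover a full day")
    step = max(1, int(round(m * (1 - overlap))))
    starts = list(range(0, layout.n_points - m + 1, step))
    if starts[-1] != layout.n_points - m:
        starts.append(layout.n_points - m)
    return starts, m


def cyclic_scores(
    arr: np.ndarray, layout: SamplingLayout, overlap: float = 1.0
) -> np.ndarray:
    """Vectorized cyclic score for a genes x samples array."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[1] != layout.n_points:
        raise ValueError("array width does not match layout")
    starts, m = _segment_starts(layout, overlap)
    half = m // 2
    acc = np.zeros((arr.shape[0], half))  # components k = 1..m//2
    for s in starts:
        seg = arr[:, s : s + m]
        seg = seg - seg.mean(axis=1, keepdims=True)
        power = np.abs(np.fft.rfft(seg, axis=1)[:, 1 : half + 1]) ** 2
        lo = power.min(axis=1, keepdims=True)
        hi = power.max(axis=1, keepdims=True)
        rng = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(rng > 0, (power - lo) / rng, 0.0)
        acc += norm
    # segment span = one day, so k=1 is the day-length component
    return acc[:, 0] / len(starts)


def cyclic_score(
    gene_vector: np.ndarray, layout: SamplingLayout, overlap: float = 1.0
) -> float:
    """Cyclic score of a single expression vector (0 for constant vectors)."""
    return float(cyclic_scores(np.asarray(gene_vector)[None, :], layout, overlap)[0])


@dataclass
class NullDistribution:
    """Cyclic scores of order-randomized expression vectors."""

    scores: np.ndarray  # sorted ascending
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("null scores must lie in [0, 1]")


def null_score_distribution(
    matrix: ExpressionMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
    overlap: float = 1.0,
) -> NullDistribution:
    """Score randomly permuted expression vectors to build the null.

    Each draw picks a gene row at random and permutes its values uniformly
    over sample positions, destroying temporal structure while keeping the
    value distribution.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    arr = matrix.to_array()
    if arr.shape[0] == 0:
        raise ValueError("empty matrix")
    rng = np.random.default_rng(seed)
    rows = arr[rng.integers(0, arr.shape[0], size=n_permutations)]
    order = np.argsort(rng.random(rows.shape), axis=1)
    permuted = np.take_along_axis(rows, order, axis=1)
    scores = cyclic_scores(permuted, matrix.layout, overlap)
    return NullDistribution(scores, n_permutations, seed)


def threshold_at_top_percentile(null: NullDistribution, top_pct: float) -> float:
    """Score exceeded by the top ``top_pct`` percent of null scores.

    Implemented as the k-th largest order statistic with
    ``k = ceil(n * top_pct / 100)``, so calling genes at the returned
    threshold marks a fraction ``top_pct/100`` of the null as positive.
    """
    if not 0 < top_pct < 100:
        raise ValueError("top_pct must be in (0, 100)")
    n = null.scores.size
    k = int(np.ceil(n * top_pct / 100.0))
    if k < 1:
        import warnings

        warnings.warn("too few null scores for requested resolution")
        k = 1
    return float(null.scores[n - k])


def call_cycling(
    scores: np.ndarray, threshold: float, null: NullDistribution | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Call genes cycling at ``score >= threshold``; empirical p per gene.

    p is the add-one-smoothed fraction of null scores at or above the gene's
    score, ``(r + 1)/(n + 1)``, never exactly zero.
    """
    scores = np.asarray(scores, dtype=float)
    is_cycling = scores >= threshold
    if null is None:
        return is_cycling, np.full(scores.shape, np.nan)
    n = null.scores.size
    r = n - np.searchsorted(null.scores, scores, side="left")
    p = (r + 1) / (n + 1)
    return is_cycling, p


def fit_cyclic_parameters(
    gene_vector: np.ndarray, layout: SamplingLayout
) -> tuple[float, float, float]:
    """Estimate (period, amplitude, phase) from the full-length spectrum.

    The dominant non-DC component k* of the mean-centred power spectrum sets
    the raw period T/k*; a quadratic fit to log-power over (k*-1, k*, k*+1)
    refines it off the discrete grid.  Amplitude is ``2|y_k*|/N`` and phase
    is the ZT of the fitted cosine's peak, in [0, day_length).
    """
    x = np.asarray(gene_vector, dtype=float)
    n = x.size
    t_total = n * layout.interval_hours
    y, power = dft_spectrum(x)
    half = n // 2
    k = int(np.argmax(power[1 : half + 1])) + 1
    kf = float(k)
    # quadratic refinement on log-power; skipped at the spectrum edges or
    # when a neighbour has (numerically) zero power
    if 1 <= k - 1 and k + 1 <= half:
        trio = power[k - 1 : k + 2]
        if np.all(trio > 1e-12 * power[k]):
            ln = np.log(trio)
            denom = ln[0] - 2 * ln[1] + ln[2]
            if denom < 0:
                delta = 0.5 * (ln[0] - ln[2]) / denom
                kf = k + float(np.clip(delta, -0.5, 0.5))
    period = t_total / kf
    amplitude = 2.0 * np.abs(y[k]) / n
    theta = -np.angle(y[k])  # x ~ A cos(2*pi*k*n/N - theta) peaks at theta
    phase = (theta / (2 * np.pi)) * (t_total / k)
    phase = float(np.mod(phase, layout.day_length_hours))
    return float(period), float(amplitude), phase


def assign_phase_cluster(gene_row: np.ndarray, layout: SamplingLayout) -> float:
    """ZT bin of peak expression after averaging the appended days.

    Ties are broken toward the earlier ZT.
    """
    x = np.asarray(gene_row, dtype=float)
    folded = x.reshape(layout.n_days, layout.points_per_day).mean(axis=0)
    return float(np.argmax(folded) * layout.interval_hours)


def detect_cycling(
    matrix: ExpressionMatrix,
    top_percentile: float = 2.0,
    n_permutations: int = 10_000,
    seed: int = 0,
    overlap: float = 1.0,
    null: NullDistribution | None = None,
) -> pd.DataFrame:
    """Run the full detection stage and return a per-gene fits table.

    Columns: ``score, p, is_cycling, period, amplitude, phase,
    phase_cluster`` (fit parameters are NaN for genes not called cycling).
    """
    arr = matrix.to_array()
    scores = cyclic_scores(arr, matrix.layout, overlap)
    if null is None:
        null = null_score_distribution(matrix, n_permutations, seed, overlap)
    threshold = threshold_at_top_percentile(null, top_percentile)
    called, p = call_cycling(scores, threshold, null)
    period = np.full(arr.shape[0], np.nan)
    amplitude = np.full(arr.shape[0], np.nan)
    phase = np.full(arr.shape[0], np.nan)
    cluster = np.full(arr.shape[0], np.nan)
    for i in np.flatnonzero(called):
        period[i], amplitude[i], phase[i] = fit_cyclic_parameters(
            arr[i], matrix.layout
        )
        cluster[i] = assign_phase_cluster(arr[i], matrix.layout)
    fits = pd.DataFrame(
        {
            "score": scores,
            "p": p,
            "is_cycling": called,
            "period": period,
            "amplitude": amplitude,
            "phase": phase,
            "phase_cluster": cluster,
        },
        index=matrix.gene_ids,
    )
    fits.attrs["threshold"] = threshold
    return fits
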