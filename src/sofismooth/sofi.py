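"""Second-order SOFI cumulants at zero time lag, with the batching baseline.

Super-resolution optical fluctuation imaging (SOFI) computes temporal
cumulants of the mean-subtracted pixel traces of a blinking-emitter movie.
At second order and zero time lag the auto-cumulant of a pixel is the
population variance of its trace, and the cross-cumulant of two pixels is
their covariance.  Cross-cumulants of neighboring physical pixels populate
"virtual" pixels halfway between them, yielding an image on a 2x-refined
grid of shape (2h-1, 2w-1): positions with both indices even are physical
pixels (auto-cumulants), the rest are virtual.  Diagonal virtual pixels
average the two available diagonal pixel pairs.  No distance factor,
flat-fielding or deconvolution is applied.

Batching is the baseline trend-correction: cumulants are computed on short
consecutive blocks of frames (each with its own mean) and averaged, which
partially suppresses slow trends such as photobleaching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .whittaker import SmoothingSpec, detrend_stack

__all__ = [
    "SofiImage",
    "second_order_autocumulant",
    "second_order_crosscumulant",
    "sofi_batched",
    "sofi_pipeline",
]


@dataclass
class SofiImage:
    """A second-order cumulant image on the 2x-refined virtual-pixel grid.

    ``values`` has shape (2h-1, 2w-1); entries may be negative (cumulants of
    noisy data) and are never clipped.  ``source`` records which pipeline
    produced the image.
    """

    values: np.ndarray
    source: str = "raw"
    order: int = 2
    batch_size: int | None = None
    metadata: dict | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _delta(stack: np.ndarray) -> np.ndarray:
    """Mean-subtract each pixel trace over time."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames x height x width)")
    if stack.shape[0] < 2:
        raise ValueError(f"need >= 2 frames for cumulants, got {stack.shape[0]}")
    return stack - stack.mean(axis=0)


def second_order_autocumulant(stack: np.ndarray) -> np.ndarray:
    """Per-pixel <dF^2>: population variance (1/n) of each pixel trace."""
    dF = _delta(stack)
    return np.mean(dF * dF, axis=0)


def second_order_crosscumulant(stack: np.ndarray) -> SofiImage:
    """Auto- and cross-cumulants on the (2h-1) x (2w-1) virtual-pixel grid.

    Horizontal/vertical virtual pixels hold the covariance of the two
    flanking physical pixels; diagonal virtual pixels average the two
    diagonal pair covariances.
    """
    dF = _delta(stack)
    n, h, w = dF.shape
    if h < 2 or w < 2:
        raise ValueError(f"need height, width >= 2 for cross-cumulants, got {h}x{w}")
    out = np.empty((2 * h - 1, 2 * w - 1))
    out[::2, ::2] = np.mean(dF * dF, axis=0)
    out[::2, 1::2] = np.mean(dF[:, :, :-1] * dF[:, :, 1:], axis=0)
    out[1::2, ::2] = np.mean(dF[:, :-1, :] * dF[:, 1:, :], axis=0)
    diag_main = np.mean(dF[:, :-1, :-1] * dF[:, 1:, 1:], axis=0)
    diag_anti = np.mean(dF[:, 1:, :-1] * dF[:, :-1, 1:], axis=0)
    out[1::2, 1::2] = 0.5 * (diag_main + diag_anti)
    return SofiImage(values=out, source="raw")


def sofi_batched(stack: np.ndarray, batch_size: int) -> SofiImage:
    """Mean of per-batch cross-cumulant images over consecutive frame blocks.

    Each batch is mean-subtracted on its own, which is what makes batching a
    (partial) trend correction.  A trailing remainder shorter than
    ``batch_size`` is dropped with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if batch_size < 2 or batch_size > n:
        raise ValueError(
            f"batch_size={batch_size} must satisfy 2 <= batch_size <= n_frames={n}"
        )
    n_batches = n // batch_size
    if n % batch_size:
        warnings.warn(
            f"dropping trailing {n % batch_size} frames not filling a "
            f"batch of {batch_size}",
            stacklevel=2,
        )
    acc = None
    for b in range(n_batches):
        img = second_order_crosscumulant(stack[b * batch_size : (b + 1) * batch_size])
        acc = img.values if acc is None else acc + img.values
    return SofiImage(values=acc / n_batches, source="batched", batch_size=batch_size)


def sofi_pipeline(
    stack: np.ndarray,
    mode: str = "none",
    *,
    batch_size: int | None = None,
    smoothing: SmoothingSpec | str = "auto",
) -> SofiImage:
    """End-to-end second-order SOFI with the chosen trend correction.

    mode ``"none"``: cumulants of the raw stack; ``"batch"``: batched
    cumulants (requires ``batch_size``); ``"whittaker"``: Whittaker
    detrending followed by cumulants of the corrected stack.
    """
    if mode == "none":
        img = second_order_crosscumulant(stack)
        img.source = "raw"
        return img
    if mode == "batch":
        if batch_size is None:
            raise ValueError("mode='batch' requires batch_size")
        return sofi_batched(stack, batch_size)
    if mode == "whittaker":
        corrected, trend, lam = detrend_stack(stack, smoothing)
        img = second_order_crosscumulant(corrected)
        img.source = "trend_corrected"
        img.metadata = {"smoothing_lambda": lam, "difference_order": trend.difference_order}
        return img
    raise ValueError(f"unknown mode {mode!r}; expected none, batch or whittaker")
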