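"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately written as explicit index loops (or dense
double-loop convolution) so that it shares no code path with the package
implementation it validates.
"""

from __future__ import annotations

import numpy as np


def loop_masked_mean(image: np.ndarray, mask: np.ndarray) -> float:
    total = 0.0
    count = 0
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                total += float(image[i, j])
                count += 1
    return total / count


def loop_local_contrast(arr: np.ndarray, window: int, operator: str) -> np.ndarray:
    half = window // 2
    padded = np.pad(arr, half, mode="symmetric")
    out = np.zeros_like(arr, dtype=np.float64)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            patch = padded[i:i + window, j:j + window]
            if operator == "std":
                out[i, j] = np.std(patch, ddof=1)
            else:
                out[i, j] = patch.max() - patch.min()
    return out


def dense_convolve_symmetric(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense double-loop correlation-style convolution, symmetric padding.

    Matches scipy.ndimage.convolve(mode="reflect") for the symmetric
    kernels used by the pipeline.
    """
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="symmetric")
    out = np.zeros_like(image, dtype=np.float64)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for u in range(kernel.shape[0]):
                for v in range(kernel.shape[1]):
                    acc += kernel[u, v] * padded[i + u, j + v]
            out[i, j] = acc
    return out


def closed_form_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """1 - 6*sum(d^2)/(n*(n^2-1)); valid for distinct values only."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    n = len(x)
    return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))
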