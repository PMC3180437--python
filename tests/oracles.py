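"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's code paths: Gaussian smoothing is an
explicit truncated-kernel double loop with symmetric padding, and the
fitting means are plain Python accumulation loops.
"""

import math

import numpy as np


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def blur_explicit(img: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian smoothing by explicit double-loop summation."""
    k1 = gaussian_kernel_1d(sigma)
    radius = len(k1) // 2
    kernel = np.outer(k1, k1)
    padded = np.pad(img, radius, mode="symmetric")
    out = np.zeros_like(np.asarray(img, dtype=np.float64))
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            acc = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    acc += kernel[dr + radius, dc + radius] * padded[
                        r + dr + radius, c + dc + radius
                    ]
            out[r, c] = acc
    return out


def heaviside_explicit(x: np.ndarray, epsilon: float) -> np.ndarray:
    return 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(np.asarray(x) / epsilon))


def fitting_means_explicit(I, phi, epsilon):
    """Inside/outside Heaviside-weighted means by plain accumulation."""
    h = heaviside_explicit(phi, epsilon)
    num1 = den1 = num2 = den2 = 0.0
    for r in range(I.shape[0]):
        for c in range(I.shape[1]):
            num1 += h[r, c] * I[r, c]
            den1 += h[r, c]
            num2 += (1.0 - h[r, c]) * I[r, c]
            den2 += 1.0 - h[r, c]
    return num1 / den1, num2 / den2


def spf_explicit(I, phi, sigma, epsilon):
    """Signed pressure force by explicit smoothing and normalization."""
    f1, f2 = fitting_means_explicit(I, phi, epsilon)
    num = blur_explicit(np.asarray(I, dtype=np.float64), sigma) - 0.5 * (f1 + f2)
    peak = np.max(np.abs(num))
    return num / peak if peak > 0 else np.zeros_like(num)


def edge_potential_explicit(I, sigma):
    """Edge potential via explicit smoothing and central differences."""
    sm = blur_explicit(np.asarray(I, dtype=np.float64), sigma)
    gr = np.gradient(sm, axis=0)
    gc = np.gradient(sm, axis=1)
    return 1.0 / (1.0 + np.hypot(gr, gc))
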