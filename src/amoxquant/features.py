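"""Color-moment feature extraction.

Each preprocessed crop is summarized by nine numbers: for each of the R,
G, B channels, the first color moment (mean intensity), the second
(root of the central second moment, i.e. population standard deviation)
and the third (signed cube root of the central third moment, a skewness
measure in intensity units). These are the Stricker–Orengo color moments;
keeping all three orders in intensity units makes the 9-vector directly
comparable across images.

Feature order is channel-major and fixed:
``[R:M1, R:M2, R:M3, G:M1, G:M2, G:M3, B:M1, B:M2, B:M3]``.
"""

from __future__ import annotations

import numpy as np

from .synthetic import WellImage

__all__ = ["FEATURE_NAMES", "color_moments", "feature_matrix"]

FEATURE_NAMES: tuple[str, ...] = (
    "m_r1", "m_r2", "m_r3",
    "m_g1", "m_g2", "m_g3",
    "m_b1", "m_b2", "m_b3",
)


def color_moments(img: WellImage | np.ndarray) -> np.ndarray:
    """The 9-element color-moment descriptor of an RGB image.

    Per channel: M1 = mean, M2 = sqrt(mean((p - M1)^2)),
    M3 = cbrt(mean((p - M1)^3)) with the sign preserved.
    """
    px = img.pixels if isinstance(img, WellImage) else np.asarray(img)
    px = px.astype(float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got shape {px.shape}")
    if px.shape[0] * px.shape[1] == 0:
        raise ValueError("empty image")

    flat = px.reshape(-1, 3)
    m1 = flat.mean(axis=0)
    centered = flat - m1
    m2 = np.sqrt(np.mean(centered ** 2, axis=0))
    m3 = np.cbrt(np.mean(centered ** 3, axis=0))
    return np.column_stack([m1, m2, m3]).reshape(-1)  # channel-major


def feature_matrix(images) -> np.ndarray:
    """Stack color-moment vectors of an image sequence into an n×9 matrix."""
    return np.array([color_moments(im) for im in images], dtype=float)
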