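"""Colocalization of two-channel images: Pearson, Costes threshold, Manders.

Pearson correlation is computed on unthresholded masked pixels. Manders
fractions use automatic Costes thresholds: fit an orthogonal (total least
squares) regression ch2 = a*ch1 + b over the masked pixels, then walk t1
down from the channel-1 maximum (with t2 = a*t1 + b) until the pixels below
both thresholds are uncorrelated (Pearson <= 0). The Manders numerators
count intensity in pixels above threshold in *both* channels — the common
Costes-style dialect; the classic single-channel-threshold dialect is
available via ``dialect='classic'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImagePair:
    """Two same-shape intensity images plus an analysis mask (cell outline)."""

    ch1: np.ndarray
    ch2: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("channel shapes differ")
        if self.mask is not None and self.mask.shape != self.ch1.shape:
            raise ValueError("mask shape differs from channels")
        if np.any(self.ch1 < 0) or np.any(self.ch2 < 0):
            raise ValueError("intensities must be >= 0")

    def pixels(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.ch1.ravel().astype(float), self.ch2.ravel().astype(float)
        m = self.mask.astype(bool)
        if not m.any():
            raise ValueError("empty mask")
        return self.ch1[m].astype(float), self.ch2[m].astype(float)


@dataclass
class ColocResult:
    pearson: float
    t1: float
    t2: float
    slope: float
    intercept: float
    m1: float | None
    m2: float | None
    n_pixels_analyzed: int
    threshold_warning: bool = False
    manders_flag: str = ""

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def pearson(pair: ImagePair) -> float:
    """Pearson correlation over masked, unthresholded pixels."""
    x, y = pair.pixels()
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a channel")
    return float(np.corrcoef(x, y)[0, 1])


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal regression y = a*x + b via the principal axis."""
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    sxx, syy, sxy = (u * u).mean(), (v * v).mean(), (u * v).mean()
    if sxy == 0 and sxx >= syy:
        a = 0.0
    else:
        # larger eigenvalue of the 2x2 covariance; direction = eigenvector
        diff = syy - sxx
        a = (diff + np.hypot(diff, 2 * sxy)) / (2 * sxy) if sxy != 0 else np.inf
    if not np.isfinite(a):
        raise ValueError("degenerate (vertical) regression line")
    return float(a), float(my - a * mx)


def costes_thresholds(pair: ImagePair,
                      step: float | None = None) -> tuple[float, float, float, float, bool]:
    """Costes automatic threshold pair (t1, t2) plus the fitted line (a, b).

    Scans t1 downward from max(ch1); at each step the below-threshold pixel
    set (ch1 < t1 and ch2 < t2) must be decorrelated (Pearson <= 0) for the
    scan to stop. Returns ``(t1, t2, a, b, warning)`` where ``warning`` is
    set when the scan exhausts the intensity range without satisfying the
    criterion (then the minimum intensity is returned).
    """
    x, y = pair.pixels()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a channel")
    a, b = _tls_line(x, y)
    if step is None:
        integral = (np.allclose(x, np.round(x))
                    and np.allclose(y, np.round(y)))
        step = 1.0 if integral else (x.max() - x.min()) / 1000.0
        if step <= 0:
            step = 1.0
    t1 = float(x.max())
    t_min = float(x.min())
    while t1 > t_min:
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        if below.sum() >= 2:
            bx, by = x[below], y[below]
            if bx.std() > 0 and by.std() > 0:
                r = np.corrcoef(bx, by)[0, 1]
            else:
                r = 0.0
            if r <= 0:
                return t1, float(t2), a, b, False
        t1 -= step
    return t_min, float(a * t_min + b), a, b, True


def manders(pair: ImagePair, t1: float, t2: float,
            dialect: str = "costes") -> tuple[float | None, float | None, str]:
    """Manders fractions M1, M2 above the threshold pair.

    ``costes`` dialect: the numerator sums channel intensity over pixels
    above threshold in both channels, the denominator over pixels above that
    channel's own threshold. ``classic`` dialect: the numerator condition is
    only on the *other* channel, the denominator is the whole masked image.
    Returns ``(m1, m2, flag)``; a fraction is None (with a flag) when its
    denominator is empty.
    """
    x, y = pair.pixels()
    above1 = x > t1
    above2 = y > t2
    flag = ""
    if dialect == "costes":
        num1 = x[above1 & above2].sum()
        num2 = y[above1 & above2].sum()
        den1 = x[above1].sum()
        den2 = y[above2].sum()
    elif dialect == "classic":
        num1 = x[above2].sum()
        num2 = y[above1].sum()
        den1 = x.sum()
        den2 = y.sum()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    m1 = m2 = None
    if den1 > 0:
        m1 = float(num1 / den1)
    else:
        flag += "m1_undefined;"
    if den2 > 0:
        m2 = float(num2 / den2)
    else:
        flag += "m2_undefined;"
    return m1, m2, flag


def analyze_pair(pair: ImagePair, dialect: str = "costes") -> ColocResult:
    """Full analysis: Pearson (unthresholded) + Costes-thresholded Manders."""
    r = pearson(pair)
    t1, t2, a, b, warn = costes_thresholds(pair)
    m1, m2, flag = manders(pair, t1, t2, dialect)
    x, _ = pair.pixels()
    return ColocResult(pearson=r, t1=t1, t2=t2, slope=a, intercept=b,
                       m1=m1, m2=m2, n_pixels_analyzed=int(x.size),
                       threshold_warning=warn, manders_flag=flag)
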