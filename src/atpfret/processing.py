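"""The quantification chain for dual-channel FRET recordings.

Order is fixed and enforced through provenance tags: per-channel background
subtraction, then the YFP/CFP ratio, then (optionally) photobleach
correction by curve fitting on stimulus-free windows, then normalization to
a pre-stimulus baseline. Frames that become unphysical (non-positive
corrected intensity) are flagged invalid and propagate as flags — they are
never interpolated or silently dropped.

Bleach correction fits a mono-exponential ``A*exp(-k*t)`` to the ratio in
quiescent windows and divides it out, preserving the amplitude at t = 0.
The mono-exponential-on-the-ratio model is the minimal correction that is
testable against ground truth; a per-channel variant is available via
``correct_bleach_channels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .fluorescence import DualChannelTrace, SyntheticStack

BLEACH_RATE_FLOOR = 1e-6  # 1/s; fitted rates below this are treated as zero


@dataclass
class RatioTrace:
    """Background-corrected YFP/CFP ratio time series for one cell."""

    time: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    cell_id: str = "cell0"
    compartment: str = "mito"
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    baseline_mean: float | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.ratio) == len(self.valid)):
            raise ValueError("time, ratio, valid must be equal length")

    def window_mask(self, window: tuple[float, float],
                    valid_only: bool = True) -> np.ndarray:
        t0, t1 = window
        m = (self.time >= t0) & (self.time <= t1)
        return m & self.valid if valid_only else m

    def copy_with(self, **kw) -> "RatioTrace":
        import dataclasses
        return dataclasses.replace(self, **kw)


def subtract_background(trace: DualChannelTrace,
                        bg_cfp: float | None = None,
                        bg_yfp: float | None = None) -> DualChannelTrace:
    """Subtract per-channel background; flag non-positive frames invalid.

    Backgrounds default to the estimates carried by the trace; passing
    explicit values overrides them.
    """
    bg_c = trace.bg_cfp_est if bg_cfp is None else bg_cfp
    bg_y = trace.bg_yfp_est if bg_yfp is None else bg_yfp
    if bg_c is None or bg_y is None:
        raise ValueError("trace carries no background estimate and none given")
    if bg_c < 0 or bg_y < 0:
        raise ValueError("backgrounds must be >= 0")
    cfp = trace.cfp - bg_c
    yfp = trace.yfp - bg_y
    valid = trace.valid & (cfp > 0) & (yfp > 0)
    return DualChannelTrace(
        time=trace.time.copy(), cfp=cfp, yfp=yfp,
        bg_cfp_est=0.0, bg_yfp_est=0.0,
        cell_id=trace.cell_id, compartment=trace.compartment,
        valid=valid,
        provenance=trace.provenance + ("background_subtracted",),
    )


def compute_ratio(trace: DualChannelTrace) -> RatioTrace:
    """YFP/CFP ratio on valid frames; requires background-subtracted input."""
    if "background_subtracted" not in trace.provenance:
        raise ValueError("compute_ratio requires background-subtracted input "
                         "(run subtract_background first)")
    ratio = np.full(len(trace.time), np.nan)
    v = trace.valid
    ratio[v] = trace.yfp[v] / trace.cfp[v]
    return RatioTrace(
        time=trace.time.copy(), ratio=ratio, valid=v.copy(),
        cell_id=trace.cell_id, compartment=trace.compartment,
        provenance=trace.provenance + ("ratio",),
    )


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of A*exp(-k*t), k constrained >= 0."""
    a0 = float(np.mean(y))
    # crude slope-based initial rate, clipped into the bound
    k0 = 0.0
    if len(t) > 1 and a0 > 0:
        span = t[-1] - t[0]
        if span > 0 and y[0] > 0 and y[-1] > 0:
            k0 = max(np.log(y[0] / y[-1]) / span, 0.0)
    popt, _ = curve_fit(lambda tt, a, k: a * np.exp(-k * tt), t, y,
                        p0=(a0, k0), bounds=([0.0, 0.0], [np.inf, np.inf]),
                        maxfev=10000)
    return float(popt[0]), float(popt[1])


def correct_bleach(rt: RatioTrace,
                   quiescent_windows: list[tuple[float, float]],
                   min_frames: int = 10) -> tuple[RatioTrace, tuple[float, float]]:
    """Fit and divide out a mono-exponential bleach trend.

    The fit uses only frames inside ``quiescent_windows`` (windows without a
    stimulus, derived from the protocol). The correction divides the whole
    trace by ``exp(-k t)``, leaving the t = 0 amplitude unchanged. If the
    fitted rate is below ``BLEACH_RATE_FLOOR`` the trace is returned as-is
    (still tagged, so provenance shows the step ran).

    Returns the corrected trace and the fitted ``(A, k)``.
    """
    if "ratio" not in rt.provenance:
        raise ValueError("correct_bleach expects a ratio trace")
    sel = np.zeros(len(rt.time), dtype=bool)
    for w in quiescent_windows:
        sel |= rt.window_mask(w)
    if sel.sum() < min_frames:
        raise ValueError(
            f"need >= {min_frames} valid frames in quiescent windows, "
            f"got {int(sel.sum())}")
    A, k = _fit_exponential(rt.time[sel], rt.ratio[sel])
    prov = rt.provenance + ("bleach_corrected",)
    if k < BLEACH_RATE_FLOOR:
        return rt.copy_with(provenance=prov), (A, k)
    corrected = rt.ratio / np.exp(-k * rt.time)
    return rt.copy_with(ratio=corrected, provenance=prov), (A, k)


def correct_bleach_channels(trace: DualChannelTrace,
                            quiescent_windows: list[tuple[float, float]],
                            min_frames: int = 10) -> DualChannelTrace:
    """Per-channel variant: fit and divide the bleach trend in each channel.

    Config alternative to the default per-ratio correction; expects a
    background-subtracted dual-channel trace.
    """
    if "background_subtracted" not in trace.provenance:
        raise ValueError("subtract background before bleach correction")
    sel = np.zeros(len(trace.time), dtype=bool)
    for t0, t1 in quiescent_windows:
        sel |= (trace.time >= t0) & (trace.time <= t1) & trace.valid
    if sel.sum() < min_frames:
        raise ValueError("insufficient valid frames in quiescent windows")
    out = {}
    for name in ("cfp", "yfp"):
        y = getattr(trace, name)
        _, k = _fit_exponential(trace.time[sel], y[sel])
        out[name] = y / np.exp(-k * trace.time) if k >= BLEACH_RATE_FLOOR else y
    return DualChannelTrace(
        time=trace.time.copy(), cfp=out["cfp"], yfp=out["yfp"],
        bg_cfp_est=trace.bg_cfp_est, bg_yfp_est=trace.bg_yfp_est,
        cell_id=trace.cell_id, compartment=trace.compartment,
        valid=trace.valid.copy(),
        provenance=trace.provenance + ("bleach_corrected_channels",),
    )


def normalize_trace(rt: RatioTrace,
                    baseline_window: tuple[float, float]) -> RatioTrace:
    """Divide by the mean ratio over the pre-stimulus baseline window."""
    m = rt.window_mask(baseline_window)
    if m.sum() < 3:
        raise ValueError("baseline window must contain >= 3 valid frames")
    base = float(np.mean(rt.ratio[m]))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return rt.copy_with(
        ratio=rt.ratio / base, normalized=True,
        baseline_window=baseline_window, baseline_mean=base,
        provenance=rt.provenance + ("normalized",),
    )


def process_trace(trace: DualChannelTrace,
                  baseline_window: tuple[float, float],
                  quiescent_windows: list[tuple[float, float]] | None = None,
                  bg_cfp: float | None = None,
                  bg_yfp: float | None = None) -> RatioTrace:
    """Full chain: background -> ratio -> (bleach) -> normalize."""
    sub = subtract_background(trace, bg_cfp, bg_yfp)
    rt = compute_ratio(sub)
    if quiescent_windows:
        rt, _ = correct_bleach(rt, quiescent_windows)
    return normalize_trace(rt, baseline_window)


# ---------------------------------------------------------------------------
# ROI handling for image stacks
# ---------------------------------------------------------------------------

def segment_rois(frames: np.ndarray, channel: int = 1,
                 min_area: int = 30) -> np.ndarray:
    """Otsu-threshold the temporal-mean image and label connected components.

    ``frames`` has axes (T, H, W, C). Small components are dropped and the
    remaining labels renumbered contiguously from 1.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label

    if frames.ndim != 4:
        raise ValueError("frames must be (T, H, W, C)")
    mean_img = frames[..., channel].mean(axis=0)
    if np.allclose(mean_img, mean_img.flat[0]):
        raise ValueError("no foreground: image is uniform")
    thr = threshold_otsu(mean_img)
    fg = mean_img > thr
    if not fg.any():
        raise ValueError("no foreground above Otsu threshold")
    lab = cc_label(fg, connectivity=2)
    out = np.zeros_like(lab)
    nxt = 1
    for i in range(1, lab.max() + 1):
        sel = lab == i
        if sel.sum() >= min_area:
            out[sel] = nxt
            nxt += 1
    if nxt == 1:
        raise ValueError("no ROI above the minimum area")
    return out


def extract_roi_traces(stack: SyntheticStack | np.ndarray,
                       mask: np.ndarray,
                       time: np.ndarray | None = None) -> list[DualChannelTrace]:
    """Mean channel intensity per ROI and frame; background from non-ROI pixels.

    The per-frame background estimate is the median over label-0 pixels of
    each channel, averaged over frames (a single scalar per channel, matching
    the constant-background acquisition model).
    """
    if isinstance(stack, SyntheticStack):
        frames, t = stack.frames, stack.time
    else:
        frames = stack
        if time is None:
            raise ValueError("time grid required for bare arrays")
        t = time
    if frames.shape[1:3] != mask.shape:
        raise ValueError("mask shape does not match frames")
    labels = [int(v) for v in np.unique(mask) if v > 0]
    if not labels:
        raise ValueError("mask contains no ROI labels")
    bg_pix = mask == 0
    bg_cfp = float(np.median(frames[:, bg_pix, 0], axis=1).mean()) if bg_pix.any() else 0.0
    bg_yfp = float(np.median(frames[:, bg_pix, 1], axis=1).mean()) if bg_pix.any() else 0.0
    traces = []
    for lab in labels:
        sel = mask == lab
        if not sel.any():
            raise ValueError(f"ROI {lab} is empty")
        traces.append(DualChannelTrace(
            time=t.copy(),
            cfp=frames[:, sel, 0].mean(axis=1),
            yfp=frames[:, sel, 1].mean(axis=1),
            bg_cfp_est=bg_cfp, bg_yfp_est=bg_yfp,
            cell_id=f"roi{lab}", compartment="mito",
            provenance=("extracted",),
        ))
    return traces
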