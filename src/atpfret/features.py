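"""Per-cell scalar features of processed ratio traces.

These are the summaries reported per cell in this kind of experiment:
basal level, transient peak height after a stimulus, onset of the
subsequent decrease, depletion minimum, the signed maximal change relative
to baseline (the fingerprint axes), and the full width at half maximum of a
transient peak.

Conventions (package choices where the literature leaves them open):

* ``max_change`` is the signed excursion of largest magnitude relative to
  the baseline mean — both directions compete, the winner keeps its sign.
* ``onset_time`` is a threshold rule: the first time after the stimulus at
  which the normalized trace has dropped to ``1 - max(3*sigma, 0.01)`` or
  lower and stays there for at least ``persistence`` consecutive valid
  frames.
* ``peak_width`` is the FWHM with linear interpolation between frames (the
  half level is ``basal + peak_amp * width_fraction``).

Invalid frames never contribute; a cell whose analysis window contains more
than ``max_invalid_fraction`` invalid frames is QC-failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .processing import RatioTrace
from .protocols import PerfusionProtocol


@dataclass
class FeatureConfig:
    """Tunables of the feature rules."""

    onset_sigma_mult: float = 3.0
    onset_min_drop: float = 0.01       # normalized units
    onset_persistence: int = 3         # consecutive frames below threshold
    width_fraction: float = 0.5        # FWHM by default
    baseline_span: float = 60.0        # s before the first stimulus
    max_invalid_fraction: float = 0.2


@dataclass
class CellFeatures:
    """Scalar summaries for one cell under one protocol."""

    cell_id: str
    compartment: str
    basal: float
    peak_amp: float | None = None
    onset_time: float | None = None
    min_level: float | None = None
    delta_glc: float | None = None
    delta_oligo: float | None = None
    peak_width: float | None = None
    qc_pass: bool = True
    qc_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id, "compartment": self.compartment,
            "basal": self.basal, "peak_amp": self.peak_amp,
            "onset_time_s": self.onset_time, "min_level": self.min_level,
            "delta_glc": self.delta_glc, "delta_oligo": self.delta_oligo,
            "peak_width_s": self.peak_width, "qc_pass": self.qc_pass,
            "qc_flags": ";".join(self.qc_flags),
        }


def _window_values(rt: RatioTrace, window, min_frames=1):
    m = rt.window_mask(window)
    if m.sum() < min_frames:
        raise ValueError(
            f"window {window} holds {int(m.sum())} valid frames, "
            f"need >= {min_frames}")
    return rt.time[m], rt.ratio[m]


def basal_level(rt: RatioTrace, window: tuple[float, float]) -> float:
    """Mean ratio over the pre-stimulus window (>= 3 valid frames)."""
    _, y = _window_values(rt, window, min_frames=3)
    return float(np.mean(y))


def peak_amplitude(rt: RatioTrace, stimulus_window: tuple[float, float],
                   basal: float,
                   onset: float | None = None) -> float:
    """Transient peak height over basal, floored at zero.

    The search window runs from the stimulus to the earlier of the window
    end or the onset of decrease (so a deep late minimum cannot mask the
    early transient's absence).
    """
    t0, t1 = stimulus_window
    if onset is not None:
        t1 = min(t1, onset)
    _, y = _window_values(rt, (t0, t1))
    return float(max(np.max(y) - basal, 0.0))


def onset_time(rt: RatioTrace, stimulus_time: float,
               noise_sd_est: float = 0.0,
               config: FeatureConfig | None = None) -> float | None:
    """First sustained drop below baseline after the stimulus, or None.

    Requires a normalized trace. Threshold: ``1 - max(k*sigma, min_drop)``;
    the trace must stay below it for ``persistence`` consecutive valid
    frames starting at the reported time.
    """
    cfg = config or FeatureConfig()
    if not rt.normalized:
        raise ValueError("onset_time requires a normalized trace")
    thr = 1.0 - max(cfg.onset_sigma_mult * noise_sd_est, cfg.onset_min_drop)
    m = (rt.time >= stimulus_time) & rt.valid
    t = rt.time[m]
    below = rt.ratio[m] <= thr
    # first index from which `persistence` consecutive valid frames are below
    count = 0
    for i, b in enumerate(below):
        count = count + 1 if b else 0
        if count >= cfg.onset_persistence:
            return float(t[i - cfg.onset_persistence + 1])
    return None


def depletion_minimum(rt: RatioTrace, window: tuple[float, float]) -> float:
    """Minimum ratio over valid frames in the window."""
    _, y = _window_values(rt, window)
    return float(np.min(y))


def max_change(rt: RatioTrace, window: tuple[float, float],
               baseline_window: tuple[float, float]) -> float:
    """Signed excursion of largest magnitude relative to the baseline mean."""
    if baseline_window[1] > window[0]:
        raise ValueError("baseline window must precede the analysis window")
    base = basal_level(rt, baseline_window)
    _, y = _window_values(rt, window)
    dev = y - base
    return float(dev[np.argmax(np.abs(dev))])


def peak_width(rt: RatioTrace, stimulus_window: tuple[float, float],
               basal: float,
               config: FeatureConfig | None = None) -> float | None:
    """Full width of the transient at ``width_fraction`` of its amplitude.

    Linear interpolation locates the first upward and last downward crossing
    of the half level; None when there is no positive peak.
    """
    cfg = config or FeatureConfig()
    t, y = _window_values(rt, stimulus_window)
    amp = np.max(y) - basal
    if amp <= 0:
        return None
    half = basal + cfg.width_fraction * amp
    above = y >= half
    if not above.any():
        return None
    i_first = int(np.argmax(above))
    i_last = len(above) - 1 - int(np.argmax(above[::-1]))
    # interpolate the crossings just outside the above-half run
    t_rise = t[i_first]
    if i_first > 0:
        y0, y1 = y[i_first - 1], y[i_first]
        t_rise = t[i_first - 1] + (half - y0) / (y1 - y0) * (t[i_first] - t[i_first - 1])
    t_fall = t[i_last]
    if i_last < len(t) - 1:
        y0, y1 = y[i_last], y[i_last + 1]
        if y1 != y0:
            t_fall = t[i_last] + (y0 - half) / (y0 - y1) * (t[i_last + 1] - t[i_last])
    return float(max(t_fall - t_rise, 0.0))


# ---------------------------------------------------------------------------
# Protocol-driven extraction
# ---------------------------------------------------------------------------

def _qc(rt: RatioTrace, windows: list[tuple[float, float]],
        cfg: FeatureConfig) -> tuple[bool, tuple[str, ...]]:
    flags = []
    for w in windows:
        m = rt.window_mask(w, valid_only=False)
        if m.sum() == 0:
            continue
        frac = 1.0 - rt.valid[m].mean()
        if frac > cfg.max_invalid_fraction:
            flags.append(f"invalid_frames:{w[0]:g}-{w[1]:g}s:{frac:.2f}")
    return (len(flags) == 0), tuple(flags)


def extract_features(rt: RatioTrace, protocol: PerfusionProtocol,
                     noise_sd_est: float = 0.0,
                     config: FeatureConfig | None = None) -> CellFeatures:
    """Compute the feature set appropriate to a protocol.

    The protocol supplies the windows: baseline = the final ``baseline_span``
    seconds before the first buffer change; the removal window = the first
    stretch without the metabolizable hexose; the oligomycin window = from
    drug onset to protocol end, with its own pre-drug baseline (final
    ``baseline_span`` seconds before onset).
    """
    cfg = config or FeatureConfig()
    if not rt.normalized:
        raise ValueError("extract_features expects a normalized trace")
    base_w = protocol.baseline_window(cfg.baseline_span)
    stim_t = protocol.first_change_time()
    removal = protocol.removal_windows()
    rem_w = removal[0] if removal else None
    oligo_t = protocol.oligomycin_onset()

    windows = [base_w] + ([rem_w] if rem_w else [])
    qc_pass, qc_flags = _qc(rt, windows, cfg)

    basal = basal_level(rt, base_w)
    feats = CellFeatures(cell_id=rt.cell_id, compartment=rt.compartment,
                         basal=basal, qc_pass=qc_pass, qc_flags=qc_flags)
    if rem_w is not None:
        onset = onset_time(rt, rem_w[0], noise_sd_est, cfg)
        feats.onset_time = onset
        feats.peak_amp = peak_amplitude(rt, rem_w, basal, onset)
        feats.min_level = depletion_minimum(rt, rem_w)
        feats.peak_width = peak_width(rt, rem_w, basal, cfg)
        # fingerprint x-axis: maximal change during the hexose-free phase
        # before any drug is applied
        glc_end = rem_w[1] if oligo_t is None else min(rem_w[1], oligo_t)
        if glc_end > rem_w[0]:
            feats.delta_glc = max_change(rt, (rem_w[0], glc_end), base_w)
    if oligo_t is not None and oligo_t > stim_t:
        pre_oligo = (max(0.0, oligo_t - cfg.baseline_span), oligo_t)
        feats.delta_oligo = max_change(
            rt, (oligo_t, protocol.total_duration), pre_oligo)
    elif oligo_t is not None:
        # drug from the very first change: basal window serves as reference
        feats.delta_oligo = max_change(
            rt, (oligo_t, protocol.total_duration), base_w)
    return feats


def features_table(features: list[CellFeatures]):
    """Features as a tidy DataFrame, one row per cell."""
    import pandas as pd
    return pd.DataFrame([f.as_dict() for f in features])
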