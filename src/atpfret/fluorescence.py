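"""Forward model: ATP trajectories -> dual-channel FRET sensor measurements.

The ATeam-style sensor is a two-state binder: ATP occupancy follows a Hill
curve, and occupancy sets the FRET efficiency. The microscope records donor
(CFP, 480 nm) and acceptor (YFP, 535 nm) emission simultaneously; occupancy
quenches the donor (factor ``1 - kappa*f``) and boosts sensitized acceptor
emission (``gamma + f``, where ``gamma`` is the occupancy-independent
acceptor baseline from direct excitation and bleed-through). Channels bleach
exponentially at their own rates, sit on additive background, and carry
Gaussian read noise.

Sensor affinities are calibration choices, not measurements: the
compartment-specific dissociation constants are picked so the cytosolic
sensor operates near saturation (cytosolic ATP is high and stable), the
mitochondrial sensor mid-dynamic-range (where the perfusion protocols
produce their largest ratio swings), and the ER sensor in its lower range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bioenergetics import SimTrace

COMPARTMENTS = ("cyto", "mito", "er")


@dataclass(frozen=True)
class SensorModel:
    """Equilibrium binding model of one FRET ATP sensor."""

    kd: float          # apparent ATP affinity (mM)
    hill: float = 2.0  # Hill coefficient
    r_min: float = 0.2  # ratio at zero ATP
    r_max: float = 4.0  # ratio at saturating ATP

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.hill <= 0:
            raise ValueError("kd and hill must be > 0")
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")

    @property
    def saturation(self) -> float:
        """ATP (mM) at 90% occupancy — upper edge of the useful range."""
        return self.kd * 9.0 ** (1.0 / self.hill)


#: Per-compartment sensor defaults (apparent affinities are calibrated).
DEFAULT_SENSORS: dict[str, SensorModel] = {
    "cyto": SensorModel(kd=1.3),
    "mito": SensorModel(kd=2.0),
    "er": SensorModel(kd=1.0),
}

#: Donor quench depth and acceptor baseline of the channel model.
KAPPA = 0.7
GAMMA = 0.2


@dataclass(frozen=True)
class AcquisitionModel:
    """Detector and photophysics parameters of the recording."""

    gain_cfp: float = 1000.0     # counts per expression unit
    gain_yfp: float = 1000.0
    bg_cfp: float = 80.0         # background counts
    bg_yfp: float = 60.0
    bleach_rate_donor: float = 0.0     # 1/s
    bleach_rate_acceptor: float = 0.0  # 1/s
    noise_sd: float = 0.0        # additive Gaussian read noise, counts
    dt: float = 1.0              # frame interval, s
    kappa: float = KAPPA         # donor quench efficiency at full occupancy
    gamma: float = GAMMA         # acceptor emission at zero occupancy

    def __post_init__(self) -> None:
        vals = (self.gain_cfp, self.gain_yfp, self.bg_cfp, self.bg_yfp,
                self.bleach_rate_donor, self.bleach_rate_acceptor,
                self.noise_sd, self.gamma)
        if any(v < 0 for v in vals):
            raise ValueError("acquisition parameters must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.kappa < 1:
            raise ValueError("kappa must be in [0, 1)")

    def replace(self, **kw) -> "AcquisitionModel":
        return replace(self, **kw)


@dataclass
class DualChannelTrace:
    """Per-cell CFP/YFP intensity time series with background estimates."""

    time: np.ndarray
    cfp: np.ndarray
    yfp: np.ndarray
    bg_cfp_est: float
    bg_yfp_est: float
    cell_id: str = "cell0"
    compartment: str = "mito"
    valid: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.time), dtype=bool)
        if not (len(self.time) == len(self.cfp) == len(self.yfp)
                == len(self.valid)):
            raise ValueError("time, channels and valid must be equal length")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


# ---------------------------------------------------------------------------
# Sensor response
# ---------------------------------------------------------------------------

def occupancy(atp, sensor: SensorModel):
    """Fractional sensor occupancy at ATP concentration (Hill binding)."""
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise ValueError("atp must be >= 0")
    a = atp ** sensor.hill
    return a / (sensor.kd ** sensor.hill + a)


def ratio_from_occupancy(f, sensor: SensorModel):
    """Idealized sensor ratio, linear in occupancy between r_min and r_max."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("occupancy must be in [0, 1]")
    return sensor.r_min + f * (sensor.r_max - sensor.r_min)


def channel_means(f, acq: AcquisitionModel, expression: float = 1.0,
                  t=0.0):
    """Noise-free channel intensities (cfp, yfp) incl. bleach and background."""
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    cfp = (acq.gain_cfp * expression * (1.0 - acq.kappa * f)
           * np.exp(-acq.bleach_rate_donor * t) + acq.bg_cfp)
    yfp = (acq.gain_yfp * expression * (acq.gamma + f)
           * np.exp(-acq.bleach_rate_acceptor * t) + acq.bg_yfp)
    return cfp, yfp


def ideal_ratio(atp, sensor: SensorModel, acq: AcquisitionModel):
    """Ground-truth background-free YFP/CFP ratio for given ATP levels.

    This is the quantity the processing chain should recover from rendered
    channels after background subtraction (and bleach correction).
    """
    f = occupancy(atp, sensor)
    return (acq.gain_yfp * (acq.gamma + f)) / (acq.gain_cfp * (1.0 - acq.kappa * f))


def invert_ratio(r, sensor: SensorModel, acq: AcquisitionModel):
    """Recover ATP (mM) from a background-free YFP/CFP ratio.

    Inverts the channel model for occupancy, then the Hill curve. Only valid
    below sensor saturation; occupancy is clipped to [0, 1).
    """
    r = np.asarray(r, dtype=float)
    g = acq.gain_cfp / acq.gain_yfp
    f = (r * g - acq.gamma) / (1.0 + acq.kappa * r * g)
    f = np.clip(f, 0.0, 1.0 - 1e-12)
    return sensor.kd * (f / (1.0 - f)) ** (1.0 / sensor.hill)


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def render_trace(sim: SimTrace, compartment: str,
                 sensor: SensorModel | None = None,
                 acq: AcquisitionModel | None = None,
                 expression: float = 1.0,
                 seed: int | np.random.Generator = 0,
                 cell_id: str = "cell0") -> DualChannelTrace:
    """Render one compartment of a simulated cell into CFP/YFP counts.

    Deterministic for a fixed seed; the true background values are stored on
    the trace (as a real analysis would estimate them from cell-free image
    regions).
    """
    sensor = sensor or DEFAULT_SENSORS[compartment]
    acq = acq or AcquisitionModel()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    f = occupancy(sim.atp(compartment), sensor)
    cfp, yfp = channel_means(f, acq, expression, sim.time)
    if acq.noise_sd > 0:
        cfp = cfp + rng.normal(0.0, acq.noise_sd, size=cfp.shape)
        yfp = yfp + rng.normal(0.0, acq.noise_sd, size=yfp.shape)
    return DualChannelTrace(
        time=sim.time.copy(), cfp=cfp, yfp=yfp,
        bg_cfp_est=acq.bg_cfp, bg_yfp_est=acq.bg_yfp,
        cell_id=cell_id, compartment=compartment,
        provenance=("rendered",),
    )


# ---------------------------------------------------------------------------
# Image-stack rendering (fixtures for ROI extraction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackGeometry:
    """Field-of-view layout for synthetic stacks."""

    height: int = 96
    width: int = 96
    radius_range: tuple[float, float] = (7.0, 11.0)
    margin: int = 2         # minimum gap between cells and to the border
    max_tries: int = 2000


@dataclass
class SyntheticStack:
    """Rendered two-channel time-lapse with ground truth attached.

    ``frames`` has axes (time, height, width, channel); channel 0 is CFP,
    channel 1 YFP. ``truth_masks`` labels each cell footprint with a
    contiguous positive integer; 0 is background.
    """

    frames: np.ndarray
    truth_masks: np.ndarray
    truth_traces: list[DualChannelTrace]
    time: np.ndarray
    acq: AcquisitionModel
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return int(self.truth_masks.max())

    def save_tiff(self, path) -> None:
        """Write as multi-page TIFF, axis order TCYX."""
        import tifffile
        arr = np.moveaxis(self.frames, 3, 1).astype(np.float32)
        tifffile.imwrite(path, arr, metadata={"axes": "TCYX"})


def _place_ellipses(n: int, geom: StackGeometry, rng) -> list[tuple]:
    """Random non-overlapping axis-aligned ellipses; raises if impossible."""
    placed: list[tuple] = []
    tries = 0
    while len(placed) < n:
        if tries >= geom.max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells in "
                f"{geom.height}x{geom.width} after {geom.max_tries} tries")
        tries += 1
        ry = rng.uniform(*geom.radius_range)
        rx = rng.uniform(*geom.radius_range)
        cy = rng.uniform(ry + geom.margin, geom.height - ry - geom.margin)
        cx = rng.uniform(rx + geom.margin, geom.width - rx - geom.margin)
        ok = all(
            (cy - oy) ** 2 + (cx - ox) ** 2
            > (max(ry, rx) + max(ory, orx) + geom.margin) ** 2
            for oy, ox, ory, orx in placed)
        if ok:
            placed.append((cy, cx, ry, rx))
    return placed


def render_image_stack(sims: list[SimTrace], compartment: str = "mito",
                       sensor: SensorModel | None = None,
                       acq: AcquisitionModel | None = None,
                       geom: StackGeometry | None = None,
                       expression: float | list[float] = 1.0,
                       seed: int = 0) -> SyntheticStack:
    """Draw each cell as a uniform ellipse and render the time-lapse stack.

    Per-pixel Gaussian noise of ``acq.noise_sd`` counts; backgrounds are the
    acquisition model's constants. Deterministic per seed.
    """
    if not sims:
        raise ValueError("need at least one simulated cell")
    sensor = sensor or DEFAULT_SENSORS[compartment]
    acq = acq or AcquisitionModel()
    geom = geom or StackGeometry()
    rng = np.random.default_rng(seed)
    n = len(sims)
    expr = (list(expression) if isinstance(expression, (list, tuple, np.ndarray))
            else [float(expression)] * n)
    if len(expr) != n:
        raise ValueError("expression list must match number of cells")

    time = sims[0].time
    if any(not np.array_equal(s.time, time) for s in sims[1:]):
        raise ValueError("all cells must share one time grid")

    masks = np.zeros((geom.height, geom.width), dtype=np.int32)
    yy, xx = np.mgrid[0:geom.height, 0:geom.width]
    for i, (cy, cx, ry, rx) in enumerate(_place_ellipses(n, geom, rng), 1):
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        masks[inside] = i

    # noise-free per-cell channel time series (background excluded: it is a
    # field-wide additive term)
    traces = []
    noiseless_acq = acq.replace(noise_sd=0.0)
    for i, (sim, e) in enumerate(zip(sims, expr)):
        tr = render_trace(sim, compartment, sensor, noiseless_acq, e,
                          seed=0, cell_id=f"cell{i}")
        traces.append(tr)

    T = time.size
    frames = np.empty((T, geom.height, geom.width, 2), dtype=float)
    frames[..., 0] = acq.bg_cfp
    frames[..., 1] = acq.bg_yfp
    for i, tr in enumerate(traces, 1):
        sel = masks == i
        # subtract the background already included by render_trace, keep
        # the cell's own signal only
        frames[:, sel, 0] = (tr.cfp - acq.bg_cfp)[:, None] + acq.bg_cfp
        frames[:, sel, 1] = (tr.yfp - acq.bg_yfp)[:, None] + acq.bg_yfp
    if acq.noise_sd > 0:
        frames = frames + rng.normal(0.0, acq.noise_sd, size=frames.shape)

    return SyntheticStack(frames=frames, truth_masks=masks,
                          truth_traces=traces, time=time.copy(), acq=acq,
                          seed=seed)


# ---------------------------------------------------------------------------
# Colocalization fixtures
# ---------------------------------------------------------------------------

def render_coloc_pair(shape: tuple[int, int] = (64, 64),
                      overlap_fraction: float = 0.5,
                      n_signal: int = 400,
                      fg_intensity: float = 200.0,
                      bg_intensity: float = 10.0,
                      noise_sd: float = 0.0,
                      seed: int = 0):
    """Two single-channel images with a known overlapping signal support.

    ``n_signal`` pixels carry signal in each channel; a fraction
    ``overlap_fraction`` of them is shared between the channels, the rest is
    channel-specific. Returns ``(ch1, ch2, truth)`` where ``truth`` holds the
    pixel-counted ground-truth Manders fractions (intensity-weighted, which
    for uniform foregrounds equals the pixel-count fraction).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    h, w = shape
    n_pix = h * w
    n_shared = int(round(n_signal * overlap_fraction))
    n_only = n_signal - n_shared
    if n_shared + 2 * n_only > n_pix:
        raise ValueError("image too small for requested signal pixels")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_pix, size=n_shared + 2 * n_only, replace=False)
    shared = idx[:n_shared]
    only1 = idx[n_shared:n_shared + n_only]
    only2 = idx[n_shared + n_only:]

    ch1 = np.full(n_pix, bg_intensity, dtype=float)
    ch2 = np.full(n_pix, bg_intensity, dtype=float)
    ch1[shared] = fg_intensity
    ch1[only1] = fg_intensity
    ch2[shared] = fg_intensity
    ch2[only2] = fg_intensity
    ch1 = ch1.reshape(shape)
    ch2 = ch2.reshape(shape)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, size=shape)
        ch2 = ch2 + rng.normal(0.0, noise_sd, size=shape)

    denom = n_signal * fg_intensity
    truth = {
        "m1": n_shared * fg_intensity / denom if denom else float("nan"),
        "m2": n_shared * fg_intensity / denom if denom else float("nan"),
        "n_shared": n_shared,
        "n_signal": n_signal,
    }
    return ch1, ch2, truth
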