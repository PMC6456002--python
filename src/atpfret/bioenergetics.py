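"""Compartmental model of subcellular ATP dynamics under perfusion protocols.

The model tracks six pools in a single cell: intracellular free hexose
(split into a metabolizable, glucose-derived pool and a non-metabolizable
mannose/2-DG pool), the corresponding hexose 6-phosphate (H6P) pools,
and ATP in the cytosol, the mitochondrial matrix, and the ER lumen.

Mechanistic skeleton
--------------------
* Facilitated hexose transport: first-order equilibration of intracellular
  hexose toward the perfusate concentration (rate ``v_glut``).
* Outer-membrane hexokinase, reversible mass action,
  ``v_HK = k_hk_f * hexose * ATP_m - k_hk_r * H6P * ADP_m``.
  The enzyme draws on (and, in reverse, refills) the *mitochondrial* ATP
  pool, reflecting its coupling to the outer-membrane VDAC. A reservoir of
  H6P built up while a hexose is present therefore fuels a transient
  mitochondrial ATP rise once the hexose is withdrawn. The ATP source is
  switchable to the cytosol for sensitivity analysis (``hk_atp_source``).
* Downstream glycolysis consumes only glucose-derived H6P
  (``v_glyc = k_gly * h6p_glc``) and yields ``y_atp`` cytosolic ATP per H6P;
  mannose- and 2-DG-derived H6P are dead-end pools, and 2-DG in the
  perfusate additionally blocks downstream glycolysis altogether.
* ANT exchange moves ATP down the *occupancy* gradient,
  ``k_ant * a_tot_m * (ATP_c/a_tot_c - ATP_m/a_tot_m)``: the antiporter swaps
  ATP against counter-transported ADP, so flux stops when the receiving
  pool has no free adenine left.
* The ATP synthase term
  ``s_oligo * (v_ox * s_anti * ADP_m/a_tot_m - k_hyd * ATP_m)`` runs forward
  (OXPHOS, ``v_ox``) or in reverse (ATP hydrolysis, ``k_hyd``); oligomycin
  blocks both directions (``s_oligo = 0``), antimycin A only the respiratory
  production (``s_anti = 0``).
* Glycolytic ATP production is likewise mass-action in free cytosolic ADP
  (``y_atp * v_glyc * ADP_c/a_tot_c``), and a small hexose-independent
  cytosolic production ``v_base_c * ADP_c/a_tot_c`` lumps the energy-stress
  response (AMPK-activated fallback substrates) that keeps cytosolic ATP
  from collapsing outright during starvation.
* Linear compartment ATP consumption, and linear ER import/consumption.

ADP is implicit through conservation, ``ADP_x = a_tot_x - ATP_x``. Every
flux that phosphorylates ADP carries the free-fraction factor above; this
keeps ``0 <= ATP_x <= a_tot_x`` an exact dynamical invariant rather than a
clipped one, and gives the model a single, globally attracting basal state.
No rate constant here is a measured quantity: the named archetypes are
calibrated so the model reproduces the qualitative single-cell phenomenology
(transient mitochondrial peak on hexose withdrawal, deeper depletion under
2-DG, opposite oligomycin responses of glycolytic vs oxidative cells).

Units: mM, seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .protocols import PerfusionProtocol, Segment

_RATE_FIELDS = (
    "v_glut", "k_hk_f", "k_hk_r", "k_gly", "v_ox", "k_hyd", "k_ant",
    "k_cons_c", "k_cons_m", "k_er_in", "k_er_cons", "v_base_c",
)


@dataclass(frozen=True)
class CellArchetype:
    """Rate-parameter set defining one metabolic setting.

    Rates are per second (bimolecular rates per mM per second), pools in mM.
    ``hk_atp_source`` selects which ATP pool the hexokinase reaction draws on
    ('mito' implements the outer-membrane coupling hypothesis; 'cyto' is the
    conventional alternative, kept for sensitivity analysis).
    """

    label: str
    v_glut: float       # hexose transport equilibration rate (1/s)
    k_hk_f: float       # forward hexokinase rate (1/(mM*s))
    k_hk_r: float       # reverse hexokinase rate (1/(mM*s))
    k_gly: float        # downstream glycolytic drain of glucose-H6P (1/s)
    y_atp: float        # cytosolic ATP yield per glucose-H6P (dimensionless)
    v_ox: float         # OXPHOS ATP production (mM/s)
    k_hyd: float        # reverse-mode synthase hydrolysis rate (1/s)
    k_ant: float        # ANT exchange rate (1/s)
    k_cons_c: float     # cytosolic ATP consumption (1/s)
    k_cons_m: float     # matrix ATP consumption (1/s)
    k_er_in: float      # ER ATP import (1/s)
    k_er_cons: float    # ER ATP consumption (1/s)
    a_tot_c: float      # cytosolic adenine pool (mM)
    a_tot_m: float      # matrix adenine pool (mM)
    v_base_c: float = 0.0  # hexose-independent cytosolic ATP production (mM/s)
    hk_atp_source: str = "mito"

    def __post_init__(self) -> None:
        for f in _RATE_FIELDS + ("y_atp",):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.a_tot_c <= 0 or self.a_tot_m <= 0:
            raise ValueError("adenine pools must be > 0")
        if self.hk_atp_source not in ("mito", "cyto"):
            raise ValueError("hk_atp_source must be 'mito' or 'cyto'")

    def scaled_hk(self, alpha: float) -> "CellArchetype":
        """Archetype with both hexokinase rates scaled by ``alpha`` (models
        partial HK1/2 knockdown)."""
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        return dataclasses.replace(
            self, k_hk_f=self.k_hk_f * alpha, k_hk_r=self.k_hk_r * alpha,
            label=f"{self.label}*hk{alpha:g}")

    def replace(self, **kw) -> "CellArchetype":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Named archetypes.  Calibrated, not measured: chosen so basal steady state
# sits at plausible mM levels (cytosol > matrix > ER under glucose) and the
# qualitative protocol responses of the corresponding cell type emerge.
# ---------------------------------------------------------------------------

#: Warburg-type cancer cell: large hexokinase flux cycling through the
#: mitochondrial ATP pool (big H6P reservoir -> withdrawal peak), low
#: respiration, net reverse-mode ATP synthase. The large ``y_atp`` is an
#: effective yield: it lumps everything downstream of H6P (including
#: oxidation of glycolytic pyruvate) into one cytosolic production term.
HELA_LIKE = CellArchetype(
    label="hela_like",
    v_glut=0.04, k_hk_f=1.6e-4, k_hk_r=3.8e-4, k_gly=5.4e-4, y_atp=28.2,
    v_ox=1.2e-4, k_hyd=8.0e-4, k_ant=3.4e-3,
    k_cons_c=5.0e-5, k_cons_m=1.8e-3, k_er_in=6.0e-5, k_er_cons=3.0e-4,
    a_tot_c=6.0, a_tot_m=5.0, v_base_c=2.97e-3,
)

#: Pancreatic beta-cell-like: oxidative, mitochondrial ATP dominated by
#: OXPHOS (forward-mode synthase), little hexokinase traffic on the matrix
#: pool; mitochondria feed the cytosol.
BETA_LIKE = CellArchetype(
    label="beta_like",
    v_glut=0.04, k_hk_f=2.0e-5, k_hk_r=5.0e-4, k_gly=3.44e-3, y_atp=3.0,
    v_ox=1.15e-2, k_hyd=5.0e-5, k_ant=1.6e-3,
    k_cons_c=5.0e-5, k_cons_m=8.0e-4, k_er_in=6.0e-5, k_er_cons=2.6e-4,
    a_tot_c=6.0, a_tot_m=5.0, v_base_c=3.0e-4,
)

#: Young wild-type fibroblast: glycolytic, close to the cancer-cell setting
#: but with slightly more respiration and a smaller withdrawal peak.
MEF_YOUNG_LIKE = HELA_LIKE.replace(label="mef_young_like",
                                   k_hk_f=1.3e-4, v_ox=3.0e-4,
                                   k_hyd=7.0e-4, v_base_c=3.2e-3)

#: Senescent fibroblast: shifted toward oxidative phosphorylation.
MEF_OLD_LIKE = BETA_LIKE.replace(label="mef_old_like",
                                 k_hk_f=3.0e-5, v_ox=0.95e-2,
                                 k_cons_m=7.0e-4, v_base_c=4.0e-4)

#: Mitofusin-2 knockout fibroblast: oxidative setting with the strongest
#: oligomycin sensitivity of the set.
MFN2_KO_LIKE = BETA_LIKE.replace(label="mfn2_ko_like",
                                 k_hk_f=4.0e-5, v_ox=1.3e-2,
                                 k_cons_m=9.5e-4)

ARCHETYPES: dict[str, CellArchetype] = {
    a.label: a for a in (HELA_LIKE, BETA_LIKE, MEF_YOUNG_LIKE, MEF_OLD_LIKE,
                         MFN2_KO_LIKE)
}


def get_archetype(name: str) -> CellArchetype:
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown archetype {name!r}; available: {sorted(ARCHETYPES)}") from None


# ---------------------------------------------------------------------------
# Fluxes and right-hand side
# ---------------------------------------------------------------------------

def hk_flux(glc_c: float, h6p: float, atp_m: float, adp_m: float,
            arch: CellArchetype, hexose: str = "glucose") -> float:
    """Reversible hexokinase flux (mM/s, positive = phosphorylation).

    Mass action in substrate and nucleotide on both sides:
    ``k_hk_f*glc_c*atp_m - k_hk_r*h6p*adp_m``. The ``hexose`` identity does
    not alter the rate law (glucose, mannose and 2-DG are all substrates);
    it matters only downstream, where non-glucose H6P cannot be metabolized.
    """
    if min(glc_c, h6p, atp_m, adp_m) < 0:
        raise ValueError("hk_flux inputs must be non-negative")
    return arch.k_hk_f * glc_c * atp_m - arch.k_hk_r * h6p * adp_m


# state vector layout
_IDX = {"hex_g": 0, "hex_n": 1, "h6p_g": 2, "h6p_n": 3,
        "atp_c": 4, "atp_m": 5, "atp_er": 6}
N_STATE = 7


def _rhs_factory(arch: CellArchetype, seg: Segment):
    """Right-hand side for one protocol segment (piecewise-constant drive)."""
    ext_g = seg.hexose_conc if seg.hexose == "glucose" else 0.0
    ext_n = seg.hexose_conc if seg.hexose in ("mannose", "dg2") else 0.0
    s_oligo = 0.0 if seg.oligomycin else 1.0
    s_anti = 0.0 if seg.antimycin else 1.0
    # 2-DG in the bath poisons downstream glycolysis entirely
    k_gly = 0.0 if seg.hexose == "dg2" else arch.k_gly
    hk_on_mito = arch.hk_atp_source == "mito"
    (v_glut, k_hk_f, k_hk_r, y_atp, v_ox, k_hyd, k_ant, k_cons_c, k_cons_m,
     k_er_in, k_er_cons, a_tot_c, a_tot_m, v_base_c) = (
        arch.v_glut, arch.k_hk_f, arch.k_hk_r, arch.y_atp, arch.v_ox,
        arch.k_hyd, arch.k_ant, arch.k_cons_c, arch.k_cons_m, arch.k_er_in,
        arch.k_er_cons, arch.a_tot_c, arch.a_tot_m, arch.v_base_c)

    def rhs(t, y):
        hex_g, hex_n, h6p_g, h6p_n, atp_c, atp_m, atp_er = y
        atp_hk = atp_m if hk_on_mito else atp_c
        # ADP is implicit (a_tot - ATP); the floor keeps the reverse reaction
        # from running on a (numerically) negative nucleotide pool
        adp_hk = max((a_tot_m - atp_m) if hk_on_mito else (a_tot_c - atp_c), 0.0)
        v_hk_g = k_hk_f * hex_g * atp_hk - k_hk_r * h6p_g * adp_hk
        v_hk_n = k_hk_f * hex_n * atp_hk - k_hk_r * h6p_n * adp_hk
        v_hk = v_hk_g + v_hk_n
        v_glyc = k_gly * h6p_g
        free_c = max(1.0 - atp_c / a_tot_c, 0.0)
        free_m = max(1.0 - atp_m / a_tot_m, 0.0)
        ant = k_ant * a_tot_m * (atp_c / a_tot_c - atp_m / a_tot_m)
        syn = s_oligo * (v_ox * s_anti * free_m - k_hyd * atp_m)
        d_atp_c = ((y_atp * v_glyc + v_base_c) * free_c - ant
                   - k_cons_c * atp_c - k_er_in * atp_c)
        d_atp_m = ant + syn - k_cons_m * atp_m
        if hk_on_mito:
            d_atp_m -= v_hk
        else:
            d_atp_c -= v_hk
        return (
            v_glut * (ext_g - hex_g) - v_hk_g,
            v_glut * (ext_n - hex_n) - v_hk_n,
            v_hk_g - v_glyc,
            v_hk_n,
            d_atp_c,
            d_atp_m,
            k_er_in * atp_c - k_er_cons * atp_er,
        )

    return rhs


@dataclass
class SimTrace:
    """Ground-truth trajectories of one simulated cell on the output grid."""

    time: np.ndarray          # s, strictly increasing
    glc_c: np.ndarray         # total intracellular free hexose (mM)
    h6p: np.ndarray           # total hexose 6-phosphate (mM)
    atp_c: np.ndarray         # cytosolic ATP (mM)
    atp_m: np.ndarray         # matrix ATP (mM)
    atp_er: np.ndarray        # ER ATP (mM)
    protocol: PerfusionProtocol
    archetype: CellArchetype
    states: np.ndarray | None = None   # full (T, 7) state history

    def atp(self, compartment: str) -> np.ndarray:
        try:
            return {"cyto": self.atp_c, "mito": self.atp_m,
                    "er": self.atp_er}[compartment]
        except KeyError:
            raise KeyError(f"unknown compartment {compartment!r}") from None

    def to_frame(self, cell_id: str = "cell0"):
        """Tidy long-format table (time_s, variable, value_mM, cell_id)."""
        import pandas as pd
        parts = []
        for name in ("glc_c", "h6p", "atp_c", "atp_m", "atp_er"):
            parts.append(pd.DataFrame({
                "time_s": self.time, "variable": name,
                "value_mM": getattr(self, name), "cell_id": cell_id}))
        return pd.concat(parts, ignore_index=True)


DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Pre-protocol equilibration horizon (s) under the first segment's buffer.
EQUILIBRATION_S = 40000.0


def _integrate(arch: CellArchetype, seg: Segment, y0, t0, t1, t_eval,
               rtol, atol):
    sol = solve_ivp(_rhs_factory(arch, seg), (t0, t1), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed on segment "
                           f"[{t0}, {t1}]: {sol.message}")
    return sol


def initial_state(arch: CellArchetype, seg: Segment,
                  rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                  horizon: float = EQUILIBRATION_S) -> np.ndarray:
    """Basal state: the model relaxed under ``seg``'s buffer for ``horizon`` s.

    Obtained by integration from a generic interior state, so a cell starts
    its recording at (numerical) steady state, as in a perfusion experiment
    where cells equilibrate in loading buffer before acquisition.
    """
    y0 = np.array([seg.hexose_conc if seg.hexose == "glucose" else 0.0,
                   seg.hexose_conc if seg.hexose in ("mannose", "dg2") else 0.0,
                   0.5, 0.0,
                   0.5 * arch.a_tot_c, 0.5 * arch.a_tot_m, 0.5])
    eq_seg = Segment(0.0, horizon, seg.hexose, seg.hexose_conc,
                     seg.oligomycin, seg.antimycin)
    sol = _integrate(arch, eq_seg, y0, 0.0, horizon, None, rtol, atol)
    return np.clip(sol.y[:, -1], 0.0, None)


def simulate_cell(arch: CellArchetype, protocol: PerfusionProtocol,
                  dt_out: float = 1.0, rtol: float = DEFAULT_RTOL,
                  atol: float = DEFAULT_ATOL,
                  y0: Sequence[float] | None = None) -> SimTrace:
    """Integrate the compartment model through a perfusion protocol.

    The drive is piecewise constant, so the system is integrated segment by
    segment (LSODA, stiff-safe) and sampled on a uniform ``dt_out`` grid
    mimicking the imaging cadence. Unless ``y0`` is given, the cell starts
    from the equilibrated basal state of the first segment's buffer.
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    grid = np.arange(0.0, protocol.total_duration + dt_out / 2, dt_out)
    y = (np.asarray(y0, dtype=float) if y0 is not None
         else initial_state(arch, protocol.segments[0], rtol, atol))
    if y.shape != (N_STATE,):
        raise ValueError(f"y0 must have {N_STATE} entries")

    states = np.empty((grid.size, N_STATE))
    filled = np.zeros(grid.size, dtype=bool)
    if grid[0] == 0.0:
        states[0] = y
        filled[0] = True
    for seg in protocol.segments:
        in_seg = (grid > seg.t_start) & (grid <= seg.t_end)
        t_eval = grid[in_seg]
        # always integrate to the segment end to hand off the exact state
        t_pts = (t_eval if t_eval.size and t_eval[-1] == seg.t_end
                 else np.append(t_eval, seg.t_end))
        sol = _integrate(arch, seg, y, seg.t_start, seg.t_end, t_pts,
                         rtol, atol)
        states[in_seg] = sol.y[:, :t_eval.size].T
        filled |= in_seg
        y = sol.y[:, -1]
    if not filled.all():
        raise RuntimeError("output grid not fully covered by protocol")

    # clip solver-tolerance negatives / pool overshoots
    tol = 100 * atol + 1e-12
    if states.min() < -tol:
        raise RuntimeError("state went negative beyond solver tolerance")
    states = np.clip(states, 0.0, None)
    for col, cap in ((4, arch.a_tot_c), (5, arch.a_tot_m)):
        if states[:, col].max() > cap + tol:
            raise RuntimeError("adenine pool exceeded beyond solver tolerance")
        states[:, col] = np.minimum(states[:, col], cap)

    return SimTrace(
        time=grid,
        glc_c=states[:, 0] + states[:, 1],
        h6p=states[:, 2] + states[:, 3],
        atp_c=states[:, 4], atp_m=states[:, 5], atp_er=states[:, 6],
        protocol=protocol, archetype=arch, states=states,
    )


def sample_population(arch: CellArchetype, n: int, cv: float,
                      seed: int | np.random.Generator) -> list[CellArchetype]:
    """Draw ``n`` archetype variants with log-normal cell-to-cell variability.

    Every rate parameter is multiplied independently by a log-normal factor
    with median 1 and coefficient of variation ``cv``; pool sizes and the
    stoichiometric yield stay fixed. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if cv == 0:
        return [arch.replace(label=f"{arch.label}#{i}") for i in range(n)]
    sigma = np.sqrt(np.log1p(cv * cv))
    cells = []
    for i in range(n):
        factors = np.exp(sigma * rng.standard_normal(len(_RATE_FIELDS)))
        kw = {f: getattr(arch, f) * factors[j]
              for j, f in enumerate(_RATE_FIELDS)}
        cells.append(arch.replace(label=f"{arch.label}#{i}", **kw))
    return cells


def is_glycolytic(arch: CellArchetype, glucose_mm: float = 10.0) -> bool:
    """Net reverse-mode synthase at basal steady state (consumes matrix ATP)?"""
    seg = Segment(0.0, 1.0, "glucose", glucose_mm)
    y = initial_state(arch, seg)
    return arch.v_ox < arch.k_hyd * y[_IDX["atp_m"]]
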