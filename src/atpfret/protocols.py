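"""Perfusion protocols: timed buffer segments driving simulation and analysis.

A protocol is an ordered, contiguous list of buffer segments. Each segment
carries the hexose identity and concentration of the perfusate plus drug
flags (oligomycin blocks the F1FO ATP synthase in both directions, antimycin A
abolishes respiratory ATP production). The same object defines the stimulus
timeline for the ODE simulator and the analysis windows (baseline, removal,
drug) for feature extraction.

Times are seconds throughout; concentrations are mM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

HEXOSES = ("glucose", "mannose", "dg2", "none")

#: Hexoses that feed glycolysis after phosphorylation. Mannose 6-phosphate and
#: 2-deoxyglucose 6-phosphate are dead ends; 2-DG additionally inhibits
#: downstream glycolysis.
METABOLIZABLE = frozenset({"glucose"})

PROTOCOL_NAMES = (
    "glucose_removal",
    "glucose_removal_readd",
    "dg2_substitution",
    "mannose_switch",
    "mannose_switch_oligo",
    "repeated_depletion",
    "oligo_then_glc_removal",
    "glc_removal_then_oligo",
)

#: Standard perfusate concentrations (mM) and drug doses (uM, metadata only).
BASELINE_GLUCOSE_MM = 10.0
DG2_MM = 10.0
MANNOSE_MM = 10.0
OLIGOMYCIN_UM = 2.0
ANTIMYCIN_UM = 2.5


@dataclass(frozen=True)
class Segment:
    """One buffer condition held for ``[t_start, t_end)`` seconds."""

    t_start: float
    t_end: float
    hexose: str = "glucose"
    hexose_conc: float = BASELINE_GLUCOSE_MM
    oligomycin: bool = False
    antimycin: bool = False

    def __post_init__(self) -> None:
        if self.hexose not in HEXOSES:
            raise ValueError(f"unknown hexose {self.hexose!r}; expected one of {HEXOSES}")
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if self.hexose_conc < 0:
            raise ValueError("hexose_conc must be >= 0")
        if self.hexose == "none" and self.hexose_conc != 0:
            raise ValueError("hexose='none' requires hexose_conc == 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PerfusionProtocol:
    """Contiguous sequence of buffer segments covering [0, total_duration]."""

    segments: tuple[Segment, ...]
    name: str = "custom"
    drug_doses_um: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.segments[0].t_start != 0:
            raise ValueError("first segment must start at t = 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.t_start != a.t_end:
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def total_duration(self) -> float:
        return self.segments[-1].t_end

    def segment_at(self, t: float) -> Segment:
        """Segment active at time ``t`` (right-open; the final end is inclusive)."""
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        if t == self.total_duration:
            return self.segments[-1]
        raise ValueError(f"t={t} outside protocol [0, {self.total_duration}]")

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    # -- analysis windows -------------------------------------------------

    def first_change_time(self) -> float:
        """Time of the first buffer switch (end of the initial baseline)."""
        return self.segments[0].t_end

    def baseline_window(self, span: float = 60.0) -> tuple[float, float]:
        """Final ``span`` seconds of the pre-stimulus baseline segment."""
        t1 = self.first_change_time()
        return (max(0.0, t1 - span), t1)

    def windows_where(self, predicate) -> list[tuple[float, float]]:
        """Merged time windows of consecutive segments satisfying ``predicate``."""
        out: list[tuple[float, float]] = []
        for seg in self.segments:
            if predicate(seg):
                if out and out[-1][1] == seg.t_start:
                    out[-1] = (out[-1][0], seg.t_end)
                else:
                    out.append((seg.t_start, seg.t_end))
        return [(a, b) for a, b in out]

    def removal_windows(self) -> list[tuple[float, float]]:
        """Windows where the metabolizable hexose has been taken away."""
        return self.windows_where(lambda s: s.hexose != "glucose")

    def oligomycin_onset(self) -> float | None:
        for seg in self.segments:
            if seg.oligomycin:
                return seg.t_start
        return None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "name": self.name,
            "drug_doses_um": dict(self.drug_doses_um),
            "segments": [
                {
                    "t_start": s.t_start,
                    "t_end": s.t_end,
                    "hexose": s.hexose,
                    "hexose_conc": s.hexose_conc,
                    "oligomycin": s.oligomycin,
                    "antimycin": s.antimycin,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerfusionProtocol":
        segs = tuple(Segment(**{k: v for k, v in s.items()}) for s in d["segments"])
        return cls(segments=segs, name=d.get("name", "custom"),
                   drug_doses_um=d.get("drug_doses_um", {}))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PerfusionProtocol":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def _seg(t0, t1, hexose="glucose", conc=BASELINE_GLUCOSE_MM, oligo=False, anti=False):
    if hexose == "none":
        conc = 0.0
    return Segment(t0, t1, hexose, conc, oligo, anti)


def make_protocol(name: str, **overrides) -> PerfusionProtocol:
    """Build one of the named perfusion protocols.

    All protocols start with a 300 s baseline in 10 mM glucose. Durations can
    be overridden via keyword arguments (``baseline_s``, ``removal_s``,
    ``readd_s``, ``drug_s``, ``post_s``, ``glucose_mm``).

    Parameters
    ----------
    name
        One of ``glucose_removal`` (baseline then sugar-free),
        ``glucose_removal_readd`` (removal then glucose readdition),
        ``dg2_substitution`` (glucose replaced by 10 mM 2-deoxyglucose),
        ``mannose_switch`` (glucose -> 10 mM mannose -> sugar-free),
        ``mannose_switch_oligo`` (same, oligomycin from the mannose trough on),
        ``repeated_depletion`` (three removal episodes separated by short
        readditions), ``oligo_then_glc_removal`` (oligomycin before and during
        removal) and ``glc_removal_then_oligo`` (the two-phase fingerprint
        protocol: removal, then oligomycin while sugar-free).
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}")

    # per-protocol default phase durations (s), chosen to match the pacing of
    # the corresponding perfusion experiments: slow-depletion protocols run
    # long enough for the post-peak decline to resolve, the two-phase
    # fingerprint protocol depletes fully before the drug phase
    defaults = {
        "glucose_removal": {"removal_s": 1800.0},
        "glucose_removal_readd": {"removal_s": 900.0, "drug_s": 600.0},
        "dg2_substitution": {"removal_s": 900.0},
        "mannose_switch": {"removal_s": 1800.0, "post_s": 900.0},
        "mannose_switch_oligo": {"removal_s": 1800.0, "drug_s": 600.0,
                                 "post_s": 900.0},
        "repeated_depletion": {"removal_s": 900.0, "readd_s": 100.0},
        "oligo_then_glc_removal": {"drug_s": 600.0, "removal_s": 900.0},
        "glc_removal_then_oligo": {"removal_s": 3600.0, "drug_s": 900.0},
    }[name]

    def take(key, fallback):
        return float(overrides.pop(key, defaults.get(key, fallback)))

    base = take("baseline_s", 300.0)
    removal = take("removal_s", 900.0)
    readd = take("readd_s", 200.0)
    drug = take("drug_s", 600.0)
    post = take("post_s", 600.0)
    glc = float(overrides.pop("glucose_mm", BASELINE_GLUCOSE_MM))
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    if glc < 0:
        raise ValueError("glucose_mm must be >= 0")

    doses: dict[str, float] = {}
    segs: list[Segment]
    if name == "glucose_removal":
        segs = [_seg(0, base, conc=glc), _seg(base, base + removal, "none")]
    elif name == "glucose_removal_readd":
        segs = [
            _seg(0, base, conc=glc),
            _seg(base, base + removal, "none"),
            _seg(base + removal, base + removal + drug, conc=glc),
        ]
    elif name == "dg2_substitution":
        segs = [_seg(0, base, conc=glc), _seg(base, base + removal, "dg2", DG2_MM)]
    elif name == "mannose_switch":
        t1 = base + removal
        segs = [
            _seg(0, base, conc=glc),
            _seg(base, t1, "mannose", MANNOSE_MM),
            _seg(t1, t1 + post, "none"),
        ]
    elif name == "mannose_switch_oligo":
        # oligomycin added once mitochondrial ATP has reached its trough in
        # mannose, kept present through the sugar-free phase
        t1 = base + removal
        segs = [
            _seg(0, base, conc=glc),
            _seg(base, t1 - drug, "mannose", MANNOSE_MM),
            _seg(t1 - drug, t1, "mannose", MANNOSE_MM, oligo=True),
            _seg(t1, t1 + post, "none", oligo=True),
        ]
        doses["oligomycin"] = OLIGOMYCIN_UM
    elif name == "repeated_depletion":
        segs = [_seg(0, base, conc=glc)]
        t = base
        for _ in range(3):
            segs.append(_seg(t, t + removal / 2, "none"))
            t += removal / 2
            segs.append(_seg(t, t + readd, conc=glc))
            t += readd
        doses = {}
    elif name == "oligo_then_glc_removal":
        segs = [
            _seg(0, base, conc=glc),
            _seg(base, base + drug, conc=glc, oligo=True),
            _seg(base + drug, base + drug + removal, "none", oligo=True),
        ]
        doses["oligomycin"] = OLIGOMYCIN_UM
    else:  # glc_removal_then_oligo — the fingerprint protocol
        segs = [
            _seg(0, base, conc=glc),
            _seg(base, base + removal, "none"),
            _seg(base + removal, base + removal + drug, "none", oligo=True),
        ]
        doses["oligomycin"] = OLIGOMYCIN_UM

    return PerfusionProtocol(segments=tuple(segs), name=name, drug_doses_um=doses)


def with_antimycin(protocol: PerfusionProtocol, from_time: float | None = None) -> PerfusionProtocol:
    """Add antimycin A to every segment at/after ``from_time`` (default: where
    oligomycin is present, mirroring the combined-inhibitor condition)."""
    segs = []
    for seg in protocol.segments:
        on = seg.oligomycin if from_time is None else seg.t_start >= from_time
        segs.append(replace(seg, antimycin=seg.antimycin or on))
    doses = dict(protocol.drug_doses_um)
    doses["antimycin"] = ANTIMYCIN_UM
    return PerfusionProtocol(tuple(segs), name=protocol.name + "+antimycin",
                             drug_doses_um=doses)
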