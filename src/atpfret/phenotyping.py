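"""Two-axis metabolic fingerprint, classification, and group statistics.

Each cell contributes one point: the maximal normalized mitochondrial ratio
change upon glucose removal (x) against the maximal change upon oligomycin
(y). Cells that lose ATP mainly on glucose removal are glycolytic; cells
that lose it mainly on ATP-synthase inhibition are oxidative. The numeric
rule (threshold ``tau`` on the dominant axis) is this package's
operationalization of a distinction the field usually draws by eye.

Group comparisons follow the conventional choices for this kind of data:
unpaired Student's t test (equal variance) for two groups, one-way ANOVA
with Tukey's HSD for three or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import CellFeatures

CLASS_LABELS = ("glycolytic", "oxidative", "intermediate")
DEFAULT_TAU = 0.1  # normalized ratio units


def summarize_group(values) -> dict:
    """Mean, SD (n-1), SEM and n of one group of scalars."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    n = int(x.size)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {"mean": float(np.mean(x)), "sd": sd,
            "sem": sd / np.sqrt(n), "n": n}


@dataclass
class FingerprintTable:
    """Per-cell fingerprint points plus per-group summary statistics."""

    points: pd.DataFrame          # cell_id, group, delta_glc, delta_oligo
    summaries: pd.DataFrame       # group, axis, mean, sd, sem, n

    def group_centroid(self, group: str) -> tuple[float, float]:
        s = self.summaries[self.summaries["group"] == group]
        return (float(s[s.axis == "delta_glc"]["mean"].iloc[0]),
                float(s[s.axis == "delta_oligo"]["mean"].iloc[0]))


def build_fingerprint(features: list[CellFeatures],
                      groups: dict[str, str] | str | None = None) -> FingerprintTable:
    """Assemble the (delta_glc, delta_oligo) table with group summaries.

    ``groups`` maps cell_id to a group label (or gives one label for all
    cells). Every cell must carry both deltas — i.e. come from a protocol
    with both a glucose-removal and an oligomycin phase.
    """
    rows = []
    for f in features:
        if f.delta_glc is None or f.delta_oligo is None:
            raise ValueError(
                f"cell {f.cell_id}: fingerprint needs both delta_glc and "
                "delta_oligo (two-phase protocol)")
        if isinstance(groups, dict):
            g = groups.get(f.cell_id, "all")
        else:
            g = groups or "all"
        rows.append({"cell_id": f.cell_id, "group": g,
                     "delta_glc": f.delta_glc, "delta_oligo": f.delta_oligo})
    if not rows:
        raise ValueError("no cells")
    points = pd.DataFrame(rows)
    summ = []
    for g, sub in points.groupby("group"):
        for axis in ("delta_glc", "delta_oligo"):
            s = summarize_group(sub[axis])
            s.update(group=g, axis=axis,
                     flag="single_cell" if s["n"] == 1 else "")
            summ.append(s)
    return FingerprintTable(points=points, summaries=pd.DataFrame(summ))


def classify_setting(table: FingerprintTable | pd.DataFrame,
                     method: str = "rule", tau: float = DEFAULT_TAU,
                     seed: int = 0) -> pd.Series:
    """Label each cell glycolytic / oxidative / intermediate.

    ``rule``: glycolytic if |delta_glc| > |delta_oligo| and delta_glc < -tau;
    oxidative if |delta_oligo| > |delta_glc| and delta_oligo < -tau;
    otherwise intermediate.

    ``cluster``: 2-means on standardized coordinates with deterministic
    seeding; the cluster whose centroid has the lower delta_glc is called
    glycolytic, the other oxidative (no intermediates).
    """
    pts = table.points if isinstance(table, FingerprintTable) else table
    if len(pts) < 2:
        raise ValueError("need at least 2 cells to classify")
    dg = pts["delta_glc"].to_numpy(float)
    do = pts["delta_oligo"].to_numpy(float)
    if method == "rule":
        labels = np.full(len(pts), "intermediate", dtype=object)
        glyc = (np.abs(dg) > np.abs(do)) & (dg < -tau)
        oxi = (np.abs(do) > np.abs(dg)) & (do < -tau)
        labels[glyc] = "glycolytic"
        labels[oxi] = "oxidative"
    elif method == "cluster":
        from scipy.cluster.vq import kmeans2
        X = np.c_[dg, do]
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        _, assign = kmeans2(X, 2, seed=seed, minit="++")
        m0 = dg[assign == 0].mean() if (assign == 0).any() else np.inf
        m1 = dg[assign == 1].mean() if (assign == 1).any() else np.inf
        glyc_cluster = 0 if m0 < m1 else 1
        labels = np.where(assign == glyc_cluster, "glycolytic", "oxidative")
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(labels, index=pts.index, name="setting")


def compare_groups(groups: dict[str, "np.ndarray | list"],
                   equal_var: bool = True) -> dict:
    """t test (two groups) or one-way ANOVA + Tukey HSD (three or more).

    Returns a dict with the omnibus statistic and, for >= 3 groups, the
    Tukey-adjusted pairwise p-values.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        return {"test": "t" if equal_var else "welch_t",
                "statistic": float(t), "p_value": float(p),
                "groups": names}
    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    pairs = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairs[f"{names[i]} vs {names[j]}"] = {
                "difference": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adj": float(tk.pvalue[i, j]),
            }
    return {"test": "anova+tukey", "statistic": float(f),
            "p_value": float(p), "pairwise": pairs, "groups": names}
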