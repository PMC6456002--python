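"""Two-axis metabolic fingerprint across all archetypes.

Runs the two-phase protocol (glucose removal, then oligomycin while
glucose-free) for populations of every archetype, builds the per-cell
(delta_glc, delta_oligo) fingerprint, classifies the metabolic setting of
each cell, and summarizes groups. Glycolytic settings (cancer-like, young
fibroblast) land at strongly negative delta_glc; oxidative settings
(beta-cell-like, senescent and mitofusin-2-null fibroblasts) at strongly
negative delta_oligo.

Writes results/fingerprint_points.csv, results/fingerprint_groups.csv and a
scatter figure.
"""

import sys
from pathlib import Path

from atpfret.bioenergetics import ARCHETYPES
from atpfret.pipeline import RunConfig, run_synthetic_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240904
N_PER_GROUP = 15


def main():
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(
        populations={name: N_PER_GROUP for name in ARCHETYPES},
        cv=0.3, seed=SEED, dt_out=2.0)
    bundle = run_synthetic_experiment(cfg)

    pts = bundle.fingerprint
    pts.to_csv(OUT / "fingerprint_points.csv", index=False)
    bundle.fingerprint_summaries.to_csv(OUT / "fingerprint_groups.csv",
                                        index=False)

    print(f"{len(pts)} cells, classification agreement with generating "
          f"archetype: {100 * bundle.stats['classification_agreement']:.1f}%")
    for g, sub in pts.groupby("group"):
        print(f"  {g:16s} delta_glc {sub.delta_glc.mean():+.3f} "
              f"delta_oligo {sub.delta_oligo.mean():+.3f}  "
              f"settings: {dict(sub.setting.value_counts())}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        colors = {"hela_like": "tab:blue", "beta_like": "tab:red",
                  "mef_young_like": "tab:cyan", "mef_old_like": "tab:orange",
                  "mfn2_ko_like": "tab:brown"}
        for g, sub in pts.groupby("group"):
            ax.scatter(sub.delta_glc, sub.delta_oligo, s=18, alpha=0.7,
                       color=colors[g], label=g)
            ax.errorbar(sub.delta_glc.mean(), sub.delta_oligo.mean(),
                        xerr=sub.delta_glc.std(), yerr=sub.delta_oligo.std(),
                        color=colors[g], marker="+", ms=14, capsize=3, lw=1.5)
        ax.axhline(0, c="gray", lw=0.5)
        ax.axvline(0, c="gray", lw=0.5)
        ax.set(xlabel="max mito ratio change on glucose removal",
               ylabel="max mito ratio change on oligomycin")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(OUT / "fingerprint_scatter.png", dpi=150)
    except Exception as e:
        print(f"(figure skipped: {e})", file=sys.stderr)


if __name__ == "__main__":
    main()
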