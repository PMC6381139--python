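#!/usr/bin/env python
"""OSER monomerism, group comparison, flow overlap and phase lifetimes.

Summarises whorl counts per FP with bootstrap 95% CIs, compares the
panel's mean whorl counts with Tukey HSD (alpha 0.01), demonstrates the
histogram-overlap statistic on a simulated two-population flow
experiment, and converts example FLIM phase shifts to lifetimes.
Writes results/oser_summary.csv and results/tukey.csv.
"""

import argparse
import math
from pathlib import Path

import numpy as np

from fpchar.assays import overlap_percent, oser_summary, phase_lifetime, tukey_hsd
from fpchar.pipeline import default_panel
from fpchar.tables import read_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    lines = ["fp_name,mean_whorls,frac_with_whorl,ci95_frac_lo,ci95_frac_hi,n_cells"]
    groups = {}
    for fp in default_panel():
        recs = read_table(args.indir / f"oser_{fp.name}.csv", "oser")
        groups[fp.name] = [r.whorl_count for r in recs]
        s = oser_summary(recs)
        lines.append(f"{fp.name},{s.mean_whorls_per_cell!r},{s.frac_cells_with_whorl!r},"
                     f"{s.ci95_frac[0]!r},{s.ci95_frac[1]!r},{s.n_cells}")
        print(f"{fp.name}: {s.mean_whorls_per_cell:.2f} whorls/cell, "
              f"{100 * s.frac_cells_with_whorl:.0f}% of cells with a whorl "
              f"(95% CI {100 * s.ci95_frac[0]:.0f}-{100 * s.ci95_frac[1]:.0f}%)")
    (args.outdir / "oser_summary.csv").write_text("\n".join(lines) + "\n")

    table = tukey_hsd(groups, alpha=0.01)
    table.to_csv(args.outdir / "tukey.csv", index=False)
    n_sig = int(table["significant"].sum())
    print(f"Tukey HSD (alpha 0.01): {n_sig} of {len(table)} pairs differ")

    # flow-style overlap: a dim background population vs an induced one
    rng = np.random.default_rng(args.seed)
    wt = rng.lognormal(mean=6.0, sigma=0.4, size=5000)
    tagged = rng.lognormal(mean=8.0, sigma=0.4, size=5000)
    ovl = overlap_percent(wt, tagged)
    print(f"simulated induced-vs-background flow overlap: {ovl:.1f}% "
          "(small overlap = separable populations)")

    for tau_ns in (2.5, 3.0, 4.0):
        phase = math.atan(2 * math.pi * 75.1e6 * tau_ns * 1e-9)
        m = phase_lifetime(phase, 75.1e6)
        print(f"phase {phase:.3f} rad at 75.1 MHz -> tau_phi {m.lifetime_ns:.2f} ns")


if __name__ == "__main__":
    main()
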