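#!/usr/bin/env python
"""Practical brightness and day-to-day variation of the simulated panel.

Reads the per-cell intensity tables written by 01_simulate_panel.py,
computes the per-cell own/control ratio (exposure-normalized) for every
FP, and writes median/quartile summaries plus the day-to-day CV to
results/brightness.csv.
"""

import argparse
from pathlib import Path

from fpchar.brightness import day_to_day_cv, practical_brightness
from fpchar.pipeline import default_panel
from fpchar.tables import read_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/brightness.csv"))
    args = ap.parse_args()

    lines = ["fp_name,median,q1,q3,n_cells,daily_cv"]
    for fp in default_panel():
        cells = read_table(args.indir / f"cells_{fp.name}.csv", "cells")
        s = practical_brightness(cells, fp.own_channel, fp.control_channel)
        cv = day_to_day_cv(cells, fp.own_channel, fp.control_channel)
        lines.append(f"{fp.name},{s.median!r},{s.q1!r},{s.q3!r},{s.n_cells},{cv!r}")
        print(f"{fp.name}: median ratio {s.median:.3f} "
              f"(IQR {s.q1:.3f}-{s.q3:.3f}, n={s.n_cells}), daily CV {cv:.3f}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text("\n".join(lines) + "\n")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
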