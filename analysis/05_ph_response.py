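#!/usr/bin/env python
"""pH-quenching analysis: offset-Hill fits per FP.

Reads the simulated titrations, normalizes to the peak-fluorescence pH,
fits the offset-Hill model, and writes pKa, Hill coefficient, offset and
pH50 to results/ph_response.csv.
"""

import argparse
from pathlib import Path

from fpchar.ph import fit_hill, normalize_titration
from fpchar.pipeline import default_panel
from fpchar.tables import read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/ph_response.csv"))
    args = ap.parse_args()

    fits = []
    for fp in default_panel():
        (ser,) = read_table(args.indir / f"titration_{fp.name}.csv", "titration")
        if not ser.normalized:
            ser = normalize_titration(ser)
        hf = fit_hill(ser)
        fits.append((fp.name, hf))
        p50 = "undefined (offset >= 0.5)" if hf.ph50 is None else f"{hf.ph50:.2f}"
        print(f"{fp.name}: pKa {hf.pKa:.2f}, Hill {hf.hill:.2f}, "
              f"offset {hf.offset:.2f}, pH50 {p50}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_table(fits, args.out, "hillfit")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
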