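"""Tabulate the simulated rpoB substitution spectra per strain.

Window-filters each strain's call set to positions 1516-1717, collapses calls
to the six base-pair substitution classes, and reports class counts with
percentages, transition/transversion composition, and mutagenic hotspots
(positions carrying >= 5% of all calls). Writes results/spectrum_<strain>.tsv
and a combined results/spectrum_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from polfid import io
from polfid.spectra import SUBSTITUTION_CLASSES, filter_window, find_hotspots, tabulate_spectrum


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--inputs", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    combined = []
    for calls_path in sorted(args.inputs.glob("calls_*.tsv")):
        strain = calls_path.stem.replace("calls_", "")
        table = tabulate_spectrum(filter_window(io.read_calls(calls_path)))
        pct = table.percents
        rows = [{"bp_change": c, "count": table.counts[c], "percent": round(pct[c], 1)}
                for c in SUBSTITUTION_CLASSES]
        rows += [
            {"bp_change": "transitions", "count": table.transitions,
             "percent": round(table.transition_percent, 1)},
            {"bp_change": "transversions", "count": table.transversions,
             "percent": round(table.transversion_percent, 1)},
            {"bp_change": "total", "count": table.total, "percent": 100.0},
        ]
        pd.DataFrame(rows).to_csv(args.out / f"spectrum_{strain}.tsv", sep="\t", index=False)
        hotspots = find_hotspots(table, 0.05)
        combined.append({"strain": strain, "total": table.total,
                         "transversion_pct": round(table.transversion_percent, 1),
                         "hotspots": ",".join(map(str, hotspots))})
        print(f"{strain}: {table.total} in-window calls, "
              f"{table.transversion_percent:.1f}% transversions, hotspots {hotspots}")
    pd.DataFrame(combined).to_csv(args.out / "spectrum_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
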