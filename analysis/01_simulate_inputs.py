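"""Generate the synthetic raw inputs for the three downstream analyses.

Emulates a four-strain replication-fidelity study: a wild-type replicase and
three active-site variants (S759C, S759N, S759T) that differ in base-
substitution rate, in genome-embedded ribonucleotide load (visible as nicked
DNA on denaturing gels in an RER-deficient background), and in mutation
spectrum. Ground-truth parameters mirror the magnitudes such studies report:
repair-proficient rif-resistance rates of roughly 2, 3.4, 14 and 6 x 1e-9 per
cell per generation, and 457 / 1049 / 3854 / 803 ribonucleotides per genome.

Writes delimited-text inputs under results/simulated/.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polfid import io
from polfid.simulate import (
    SimConfig,
    render_gel_lane,
    simulate_fluctuation_counts,
    simulate_lane_fragments,
    simulate_substitution_calls,
)

NT = 2.0e8  # final cells per culture
GENOME = 9_280_000

# per-cell per-generation mutation rates (x1e-9) driving the fluctuation sims
TRUE_RATES_1E9 = {"dnaE_wt": 2.04, "dnaE_S759C": 3.44, "dnaE_S759N": 14.0, "dnaE_S759T": 6.11}

# ribonucleotides per genome in the RER-deficient background; baseline nicking
# (shearing + residual breaks) is shared by every lane
RIBOS_PER_GENOME = {"dnaE_wt": 457, "dnaE_S759C": 1049, "dnaE_S759N": 3854, "dnaE_S759T": 803}
BASELINE_RHO = 1e-5
N_GELS = 4
LADDER = [48500.0, 20000.0, 10000.0, 5000.0, 2000.0, 1000.0]

# six-class substitution probabilities per strain (order CG->GC, CG->AT,
# CG->TA, AT->TA, AT->CG, AT->GC) and spectral hotspot positions
CLASS_COUNTS = {
    "dnaE_wt": (2, 8, 9, 89, 174, 20),
    "dnaE_S759C": (5, 15, 12, 316, 10, 13),
    "dnaE_S759N": (0, 0, 104, 140, 3, 80),
    "dnaE_S759T": (0, 5, 106, 152, 1, 80),
}
HOTSPOTS = {
    "dnaE_wt": (1687, 1714, 1715),
    "dnaE_S759C": (1547, 1577, 1714),
    "dnaE_S759N": (1714,),
    "dnaE_S759T": (1546, 1691, 1714),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # --- fluctuation counts ------------------------------------------------
    counts = {}
    for strain, rate in TRUE_RATES_1E9.items():
        cfg = SimConfig(seed=args.seed, n_cultures=30, m_true=rate * 1e-9 * NT, Nt=int(NT))
        counts[strain] = simulate_fluctuation_counts(cfg, rng).tolist()
    io.write_counts(out / "counts.tsv", counts)
    pd.DataFrame(
        [{"label": s, "epsilon": 1.0, "Nt": NT} for s in counts]
    ).to_csv(out / "meta.tsv", sep="\t", index=False)
    print(f"fluctuation: 30 cultures x {len(counts)} strains -> {out/'counts.tsv'}")

    # --- gel lanes, N_GELS replicate gels ----------------------------------
    base = SimConfig(seed=args.seed, G=GENOME)
    for gel in range(N_GELS):
        lanes, lane_cfg = [], {}
        for i in range(2):
            lanes.append(render_gel_lane(np.asarray(LADDER), base, rng,
                                         label=f"M{i+1}", uniform_mass=True))
        for i in range(2):  # RER-proficient baseline lanes
            cfg = replace(base, rho=BASELINE_RHO)
            name = f"rnhB_wt_{i+1}"
            lanes.append(render_gel_lane(simulate_lane_fragments(cfg, rng), cfg, rng,
                                         label=name))
            lane_cfg[name] = {"genotype": "dnaE_wt", "rnhB": "wt"}
        for strain, ribos in RIBOS_PER_GENOME.items():
            cfg = replace(base, rho=BASELINE_RHO + ribos / GENOME)
            name = f"{strain}_drnhB"
            lanes.append(render_gel_lane(simulate_lane_fragments(cfg, rng), cfg, rng,
                                         label=name))
            lane_cfg[name] = {"genotype": strain, "rnhB": "delta"}
        io.write_lane_profiles(out / f"gel{gel+1}_lanes.tsv", lanes)
        with open(out / f"gel{gel+1}_config.yaml", "w") as fh:
            yaml.safe_dump({"marker_lanes": ["M1", "M2"], "ladder_sizes": LADDER,
                            "lanes": lane_cfg, "sz_min": 500.0,
                            "genome_size": float(GENOME)}, fh)
    print(f"gels: {N_GELS} replicate gels x 8 lanes -> {out}/gel*_lanes.tsv")

    # --- substitution calls ------------------------------------------------
    for strain, class_counts in CLASS_COUNTS.items():
        total = sum(class_counts)
        probs = tuple(c / total for c in class_counts)
        weights = {p: 1.0 for p in range(1516, 1718)}
        for h in HOTSPOTS[strain]:
            weights[h] = 40.0
        cfg = SimConfig(seed=args.seed, class_probs=probs, position_weights=weights)
        calls = simulate_substitution_calls(cfg, total, rng)
        io.write_calls(out / f"calls_{strain}.tsv", calls)
    print(f"spectra: per-strain call tables -> {out}/calls_<strain>.tsv")


if __name__ == "__main__":
    main()
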