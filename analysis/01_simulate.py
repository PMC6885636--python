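#!/usr/bin/env python
"""Generate the synthetic study conditions.

Stand-ins for the (undeposited) microsecond trajectories of the sGC
catalytic domain: a wild-type-like ensemble mostly in the inactive
state, an activating-mutant-like ensemble mostly in the active state
along the same planted collective mode, and Bernoulli contact-flicker
streams with planted contact-probability changes.  Multi-model PDBs and
ground truth go to scratch/sim/ (they are bulky and regenerable); a
small summary lands in results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gcensemble.structure_io import write_frames_pdb
from gcensemble.synthetic_data import (
    ContactFlickerSpec,
    make_toy_heterodimer,
    TwoStateSpec,
    generate_contact_flicker,
    generate_two_state,
    write_fixture_assay_table,
)

SEED = 2024
N_FRAMES = 600
OUT = Path("scratch/sim")
RESULTS = Path("results")

CONDITIONS = {
    # label -> fraction of frames in the active-like state B
    "WT": 0.15,
    "double_mutant": 0.55,
    "triple_mutant": 0.9,
}

PLANTED_PAIRS = {  # (pair) -> (p_WT, p_mutant)
    (("A", 2), ("B", 2)): (0.9, 0.3),
    (("A", 4), ("B", 4)): (0.2, 0.8),
    (("A", 6), ("B", 6)): (0.5, 0.5),
    (("A", 8), ("B", 8)): (0.05, 0.6),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    rows = []
    truth: dict = {"conditions": {}, "planted_pairs": {}}
    displacement = None
    for i, (label, weight) in enumerate(CONDITIONS.items()):
        # shared base_seed: all conditions move along the same planted
        # collective mode; only the state mixture differs
        spec = TwoStateSpec(
            n_residues=10, separation=3.0, weight=weight, sigma=0.3,
            n_frames=N_FRAMES, seed=SEED + i, base_seed=SEED, label=label,
        )
        sample = generate_two_state(spec)
        write_frames_pdb(sample.ensemble, OUT / f"{label}.pdb")
        displacement = sample.displacement
        truth["conditions"][label] = {
            "weight": weight,
            "state_b_fraction": float(sample.state_labels.mean()),
            "seed": spec.seed,
        }
        rows.append(
            {"condition": label, "planted_weight": weight,
             "realised_state_b_fraction": float(sample.state_labels.mean()),
             "n_frames": N_FRAMES}
        )
        print(f"{label}: {N_FRAMES} frames, state-B fraction "
              f"{sample.state_labels.mean():.3f} (planted {weight})")
    truth["displacement"] = displacement.tolist()
    # the undisplaced base conformation doubles as the inactive reference
    write_frames_pdb(make_toy_heterodimer(10, seed=SEED), OUT / "reference.pdb")

    flicker = ContactFlickerSpec(
        pair_probabilities={
            "WT": {p: v[0] for p, v in PLANTED_PAIRS.items()},
            "mutant": {p: v[1] for p, v in PLANTED_PAIRS.items()},
        },
        n_frames=2000, n_residues=10, seed=SEED,
    )
    sample = generate_contact_flicker(flicker)
    for label, ens in sample.ensembles.items():
        write_frames_pdb(ens, OUT / f"flicker_{label}.pdb")
    truth["planted_pairs"] = {
        f"{a[0]}{a[1]}-{b[0]}{b[1]}": {"p_WT": v[0], "p_mutant": v[1],
                                       "planted_df": v[1] - v[0]}
        for (a, b), v in PLANTED_PAIRS.items()
    }
    write_fixture_assay_table(OUT / "assay_table.csv")
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    pd.DataFrame(rows).to_csv(RESULTS / "simulation_summary.csv", index=False,
                              lineterminator="\n")
    print(f"ground truth and ensembles under {OUT}/")


if __name__ == "__main__":
    main()
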