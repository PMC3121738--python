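#!/usr/bin/env python
"""Procrustes consistency of velocity-acceleration phase trajectories.

Compares every pair of same-finger, same-performer trajectories within each
event-region type.  Expected structure: keypress movements (key-constrained)
are the most self-similar, attacks intermediate, at-rest incidental motion
the least.  Requires results/trajectories.csv from script 02.
"""

from pathlib import Path

from pianokin.cli import _read_trajectories
from pianokin.similarity import consistency_by_region

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    trajs = _read_trajectories(OUT)
    table = consistency_by_region(trajs)
    table.reset_index().to_csv(OUT / "consistency.csv", index=False)
    print("mean Procrustes similarity by region type:")
    print(table.round(4).to_string())
    order = table["mean_similarity"]
    assert order["keypress"] >= order["attack"] > order["at_rest"], \
        "expected keypress >= attack > at_rest"
    print("ordering keypress >= attack > at_rest confirmed")


if __name__ == "__main__":
    main()
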