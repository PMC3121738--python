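#!/usr/bin/env python
"""Where along the normalized stroke do performers differ?

Pointwise functional ANOVA of the velocity and acceleration curves across
performers, per region type, with unadjusted (alpha = .05) and conservative
(alpha = .001) masks.  The significant portions define the classifier's
input features (script 05).  Requires results/trajectories.csv.
"""

from pathlib import Path

import pandas as pd

from pianokin.cli import _read_trajectories
from pianokin.fanova import pointwise_fanova

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    trajs = _read_trajectories(OUT)
    rows = []
    for label in ("attack", "keypress", "at_rest"):
        sub = [t for t in trajs if t.label == label]
        res = pointwise_fanova(sub, [t.performer_id for t in sub],
                               alphas=(0.05, 0.001))
        for ch, chres in res.channels.items():
            for a in (0.05, 0.001):
                rows.append({"region": label, "channel": ch, "alpha": a,
                             "significant_fraction": chres.significant_fraction[a],
                             "df_between": res.df_between,
                             "df_within": res.df_within})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "fanova.csv", index=False)
    print("fraction of the event region where performers differ (per channel):")
    print(table.pivot_table(index=["region", "channel"], columns="alpha",
                            values="significant_fraction").round(3).to_string())


if __name__ == "__main__":
    main()
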