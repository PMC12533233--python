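#!/usr/bin/env python
"""Detection power and false-positive rate over replicate experiments.

Repeats the whole simulate-to-compare pipeline across seeds: with the
default weak coupling the one-tailed real>pseudo contrast should detect
synchrony in nearly every replicate; with coupling removed the two-sided
test should reject at roughly its nominal level.  Writes
results/replicate_power.csv.
"""

from pathlib import Path

import pandas as pd

from plantsync.experiments import replicate_fractions

ROOT = Path(__file__).resolve().parent.parent / "results"
N_REPLICATES = 50
SEED = 424242


def main() -> None:
    coupled = replicate_fractions(N_REPLICATES, seed=SEED)
    null = replicate_fractions(N_REPLICATES, seed=SEED + 1, coupling_k=0.0)
    df = pd.DataFrame(
        [
            {"condition": "coupled", "power": coupled["power"], "type_i": coupled["type_i"]},
            {"condition": "uncoupled", "power": null["power"], "type_i": null["type_i"]},
        ]
    )
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "replicate_power.csv", index=False)
    print(df.to_string(index=False))
    print(
        f"\ncoupled: one-tailed p<0.05 with delta>0 in {100*coupled['power']:.0f}% "
        f"of {N_REPLICATES} replicates; uncoupled: two-sided p<0.05 in "
        f"{100*null['type_i']:.0f}%"
    )


if __name__ == "__main__":
    main()
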