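"""Estimate the mark rate from simulated group sightings.

Groups are partitioned at the 20-animal threshold: large fully photographed
groups feed the image-proportion estimator (method 1), small groups the
distinct-individuals-per-animal estimator (method 2); the final rate is
their unweighted mean.  At the study's true rate of 0.30 both methods
should land on ~0.30, mirroring the agreement seen in the field data.
"""

from pathlib import Path

import pandas as pd

import spinnerpop as sp

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sightings = sp.simulate_sightings(theta=0.30, n_groups=116, seed=SEED)
    large, small, excluded = sp.partition_groups(sightings)
    t1, t2 = sp.theta1(large), sp.theta2(small)
    combined = sp.combine_mark_rates([t1, t2])
    table = pd.DataFrame([
        {"method": e.method, "theta_hat": e.theta_hat, "se": e.se, "n": e.n}
        for e in (t1, t2, combined)])
    table.to_csv(OUT / "mark_rate.csv", index=False)
    print(f"groups: {len(large)} large (>20), {len(small)} small, "
          f"{len(excluded)} excluded")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"combined mark rate: {combined.theta_hat:.3f}")


if __name__ == "__main__":
    main()
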