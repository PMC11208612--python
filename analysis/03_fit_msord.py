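"""Fit the open-robust-design model suite and select by AICc.

Fits a small suite of structures spanning the three emigration regimes on
the dataset from 01_simulate_study.py, ranks them by AICc with Akaike
weights, and writes the derived per-season marked abundance, transition
probabilities (with complements) and residence times for the best model.
The generating process has temporary emigration, so both emigration
structures should rank far above the no-emigration model (on a single
realization the one-parameter random structure can edge out the Markovian
one by AICc); the survival estimate should sit near the generating 0.95.
"""

from pathlib import Path

import spinnerpop as sp

ROOT = Path(__file__).resolve().parents[1] / "results"
SUITE = [
    "S(.) p(.) pent(.) phi(.) psi(Markovian,constant)",
    "S(.) p(.) pent(.) phi(.) psi(random,constant)",
    "S(.) p(.) pent(.) phi(.) psi(none)",
]


def main() -> None:
    design = sp.study_design()
    matrix = sp.read_inp(ROOT / "data" / "capture_histories.inp", design)
    fits = []
    for i, spec in enumerate(SUITE):
        st = sp.ModelStructure.from_string(spec)
        fit = sp.fit_msord(matrix, st, seed=i, n_restarts=2)
        print(f"{st.label()}: logL={fit.loglik:.2f} K={fit.K} "
              f"AICc={fit.aicc:.1f} converged={fit.converged}")
        fits.append(fit)
    rank = sp.rank_models(fits)
    rank.to_csv(ROOT / "msord_model_rank.csv", index=False)
    print(rank.to_string(index=False))

    best = max(fits, key=lambda f: -f.aicc)
    est, ses = best.natural_estimates(), best.natural_ses()
    print(f"best model: {best.structure.label()}")
    print(f"apparent survival S = {est['S[1->2]']:.3f} "
          f"(SE {ses['S[1->2]']:.3f})")
    sp.derive_abundance(best, matrix).to_csv(
        ROOT / "msord_marked_abundance.csv", index=False)
    if best.structure.emigration != "none":
        sp.derived_transitions(best).to_csv(
            ROOT / "msord_transitions.csv", index=False)
    res = sp.residence_time(best)
    print("residence time (secondary occasions per season):",
          [round(float(r), 2) for r in res[:3]], "...")


if __name__ == "__main__":
    main()
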