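#!/usr/bin/env python
"""Find the most desirable extended-release composition under the surrogate.

Maximizes the importance-weighted geometric-mean desirability of the four
release goals (at most 30/60/70 % released at 2/4/6 h, at least 80 % at 8 h;
importances 2/2/3/3) over the bounded mixture simplex, using the surrogate
trained in 05_train_surrogate.py.  The surrogate-predicted release of the
optimum is then verified against the noiseless ground-truth model the study
was simulated from, via f1/f2/R².  Writes results/optimal_formulation.csv.
"""

import pathlib

import pandas as pd
import yaml

from printopt.ann import load_mlp
from printopt.desirability import EXTENDED_RELEASE_GOALS, optimize_formulation
from printopt.profiles import (
    ProfileComparison,
    f1_difference,
    f2_similarity,
    r2_obs_pred,
    similarity_verdict,
)
from printopt.synthetic import GroundTruthModel, simulate_dissolution

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    model_path = ROOT / "surrogate" / "model.json"
    truth_path = ROOT / "synthetic" / "truth.yaml"
    if not model_path.exists():
        raise SystemExit("run analysis/05_train_surrogate.py first")
    mlp = load_mlp(model_path)
    result = optimize_formulation(mlp, goals=EXTENDED_RELEASE_GOALS, seed=SEED)
    c = result.composition
    print(
        f"optimal composition: PEGDA {c.pegda:.2f} %, PEG 400 {c.peg400:.2f} %, "
        f"water {c.water:.2f} % (overall D = {result.overall_D:.4f})"
    )
    for t, v, d in zip(result.profile_times, result.predicted_profile,
                       result.per_goal_d):
        print(f"  {t:g} h: predicted {v:5.2f} % released (d = {d:.3f})")

    with open(truth_path, "r", encoding="utf-8") as fh:
        truth = GroundTruthModel(**yaml.safe_load(fh))
    noiseless = simulate_dissolution(
        c, result.profile_times,
        GroundTruthModel(**{**truth.__dict__, "noise_sd": 0.0}),
    )
    cmp = ProfileComparison(
        result.profile_times, noiseless.released, result.predicted_profile
    )
    f1, f2 = f1_difference(cmp), f2_similarity(cmp)
    print(
        f"surrogate vs ground truth at the optimum: f1={f1:.2f} f2={f2:.2f} "
        f"R2={r2_obs_pred(cmp):.4f} -> {similarity_verdict(f1, f2)}"
    )
    pd.DataFrame([{
        "pegda": round(c.pegda, 2), "peg400": round(c.peg400, 2),
        "water": round(c.water, 2), "overall_D": round(result.overall_D, 4),
        **{f"pred_{t:g}h": round(v, 2)
           for t, v in zip(result.profile_times, result.predicted_profile)},
        "f1_vs_truth": round(f1, 2), "f2_vs_truth": round(f2, 2),
    }]).to_csv(ROOT / "optimal_formulation.csv", index=False)
    print(f"wrote {ROOT / 'optimal_formulation.csv'}")


if __name__ == "__main__":
    main()
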