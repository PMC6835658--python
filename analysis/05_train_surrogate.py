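#!/usr/bin/env python
"""Train the composition-to-release surrogate on the simulated study.

Replays the trial-and-error architecture search on the synthetic data: the
eleven formulations are split 8/2/1 into training, validation and test sets,
networks with 1-3 hidden layers of 4-10 linear units are trained with
momentum backpropagation, and the winner (minimum validation RMS) is
evaluated on the held-out formulation.  The trained network is saved as a
JSON weight bundle for the optimization step.
Writes results/surrogate/model.json and leaderboard.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from printopt import io as pio
from printopt.ann import MLPConfig, architecture_search, forward, save_mlp

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    syn = ROOT / "synthetic"
    if not (syn / "profiles.csv").exists():
        raise SystemExit("run analysis/03_simulate_study.py first")
    formulations = pio.load_formulation_table(syn / "formulations.csv")
    profiles = pio.load_profiles(syn / "profiles.csv")
    times = profiles[formulations[0].id].times
    X = np.array([f.components for f in formulations])
    Y = np.array([profiles[f.id].released for f in formulations])

    rng = np.random.default_rng(SEED)
    order = rng.permutation(len(formulations))
    train, val, test = order[:8], order[8:10], order[10:]
    template = MLPConfig(
        layer_sizes=(3, 8, Y.shape[1]), activations=("linear", "linear"),
        learning_rate=0.2, momentum=0.6, max_epochs=4000, patience=500,
        seed=SEED,
    )
    mlp, config, leaderboard = architecture_search(
        X[train], Y[train], X[val], Y[val],
        hidden_layer_counts=(1, 2, 3), nodes_per_layer=range(4, 11),
        template=template, times=times,
    )
    board = pd.DataFrame(leaderboard)
    out = ROOT / "surrogate"
    out.mkdir(parents=True, exist_ok=True)
    board.to_csv(out / "leaderboard.csv", index=False)
    save_mlp(mlp, out / "model.json")

    pred = np.atleast_2d(forward(mlp, X[test]))
    obs = Y[test]
    test_r2 = float(np.corrcoef(obs.ravel(), pred.ravel())[0, 1] ** 2)
    best = board.loc[board["rms"].idxmin()]
    print(
        f"searched {len(board)} architectures; best: "
        f"{int(best['hidden_layers'])} hidden layer(s) x {int(best['nodes'])} "
        f"nodes, validation RMS {best['rms']:.4f}, R2 {best['r2']:.4f}"
    )
    print(f"held-out formulation R2 (obs vs pred, {obs.size} points): {test_r2:.4f}")
    print(f"wrote {out / 'model.json'} and leaderboard.csv")


if __name__ == "__main__":
    main()
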