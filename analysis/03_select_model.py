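"""Select a regressor by the composite score over the nine-family roster.

Runs the seeded fivefold-CV grid search for the biomass response and
writes the metric-by-family leaderboard, then cross-checks the composite
formula against the published benchmark leaderboard it mirrors.
"""

from pathlib import Path

from algaeopt.dataio import encode_features, read_experiment_csv
from algaeopt.model_eval import (DEFAULT_GRIDS, DEFAULT_ROSTER, grid_search,
                                 leaderboard_frame, w_new)
from algaeopt.reference import PUBLISHED_LEADERBOARD

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20241


def main():
    table = read_experiment_csv(OUT / "experiment.csv")
    enc = encode_features(table)
    y = table["biomass"].to_numpy(dtype=float)
    res = grid_search(DEFAULT_ROSTER, DEFAULT_GRIDS, enc.X, y, k=5,
                      seed=SEED)
    lb = leaderboard_frame(res.leaderboard)
    lb.to_csv(OUT / "leaderboard_biomass.csv")
    print("biomass leaderboard (CV means):")
    print(lb.round(3).to_string())
    print(f"\nselected: {res.best.label()}")
    print("holdout metrics:", {k: round(v, 3)
                               for k, v in res.holdout_metrics.as_dict().items()})

    print("\npublished-benchmark composite scores recomputed from their "
          "printed inputs:")
    for fam, (r2t, r2v, mae, rmse, mse, rep) in PUBLISHED_LEADERBOARD.items():
        print(f"  {fam:16s} computed {w_new(r2t, r2v, mae, rmse, mse):.3f} "
              f"reported {rep:.3f}")


if __name__ == "__main__":
    main()
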