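"""Rank environmental-factor importance per genus and response.

Refits the forest on the unreduced encoded features for every (genus,
response), pools indicator importances into the colour factor, and
reports the top factor per response, per genus and averaged over genera.
Also locates the best observed condition per (genus, response).
"""

from pathlib import Path

import pandas as pd

from algaeopt.dataio import RESPONSE_COLUMNS, read_experiment_csv
from algaeopt.importance import (find_optimal_conditions, importance_table,
                                 profiles_frame, rank_factors)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20242


def main():
    table = read_experiment_csv(OUT / "experiment.csv")
    profiles = importance_table(table, seed=SEED)
    profiles_frame(profiles).to_csv(OUT / "importance.csv", index=False)
    top = rank_factors(profiles)
    top.to_csv(OUT / "top_factors.csv", index=False)

    avg = top[top["genus"] == "average"]
    print("top factor per response, averaged over genera:")
    print(avg[["response", "top_factor", "score"]].round(3)
          .to_string(index=False))

    rows = []
    for genus in sorted(table["genus"].unique()):
        for response in RESPONSE_COLUMNS:
            oc = find_optimal_conditions(table, response, genus)
            rows.append({"genus": genus, "response": response,
                         **oc.condition, "mean": oc.mean_response,
                         "n": oc.n_observations})
    optimal = pd.DataFrame(rows)
    optimal.to_csv(OUT / "optimal_conditions.csv", index=False)
    best = optimal[optimal["response"] == "biomass"]
    print("\nbest observed biomass condition per genus:")
    print(best.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
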