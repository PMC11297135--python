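#!/usr/bin/env python
"""Train the two proxy committees (pH and total alkalinity) on the
labeled training table: ten Bayesian-regularized networks per target,
sharing one 90/10 train/test split and differing only in their weight
initialization.

Writes the serialized models and a member-by-member test-metrics table
(MAE/MSE/RMSE/r2 rows for members 1..10, the ensemble, and the [H+]
ensemble derived from the pH one) to results/models/.
"""

from pathlib import Path

from riacarb import brnn
from riacarb.pipeline import summarize_table1
from riacarb.tableio import read_table

DATA = Path("results/data")
OUT = Path("results/models")
SEEDS = {"ph": 11, "ta": 12}
HIDDEN = {"ph": [14, 5], "ta": [20]}  # scaled-down widths, ratio as in the full design
MAX_ITER = 60


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    training = read_table(DATA / "training.csv")
    models = {}
    for target in ("ph", "ta"):
        model = brnn.train_ensemble(training, target, hidden=HIDDEN[target],
                                    seed=SEEDS[target], max_iter=MAX_ITER)
        model.save(OUT / f"model_{target}.json")
        models[target] = model
        m = model.ensemble_metrics
        print(f"{target}: ensemble test MAE {m.mae:.4g}  RMSE {m.rmse:.4g}  "
              f"r2 {m.r2:.3f} "
              f"(best member RMSE {min(x.rmse for x in model.member_metrics):.4g})")
    tab = summarize_table1(models["ph"], models["ta"])
    tab.to_csv(OUT / "test_metrics.csv", index=False)
    print(f"wrote member/ensemble statistics -> {OUT / 'test_metrics.csv'}")


if __name__ == "__main__":
    main()
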