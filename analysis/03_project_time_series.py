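#!/usr/bin/env python
"""Apply the trained committees to the weekly predictor table,
producing 26-year weekly pH and TA series at every station x depth
bin, plus the hydrogen-ion series 10**(9 - pH).

Writes results/series/predicted_series.csv.
"""

from pathlib import Path

from riacarb import brnn
from riacarb.carbonate import ph_to_h
from riacarb.tableio import read_table

DATA = Path("results/data")
MODELS = Path("results/models")
OUT = Path("results/series")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prediction = read_table(DATA / "prediction.csv")
    out = prediction.drop(columns=["ph", "ta_umol_kg"])
    for target in ("ph", "ta"):
        model = brnn.EnsembleModel.load(MODELS / f"model_{target}.json")
        out[target] = brnn.predict_ensemble(model, prediction)
    out["h"] = ph_to_h(out["ph"])
    out.to_csv(OUT / "predicted_series.csv", index=False)
    print(f"projected {len(out)} weekly rows "
          f"(pH {out['ph'].min():.3f}..{out['ph'].max():.3f}, "
          f"[H+] {out['h'].min():.2f}..{out['h'].max():.2f} nmol/kg)")


if __name__ == "__main__":
    main()
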