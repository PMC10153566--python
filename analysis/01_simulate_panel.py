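#!/usr/bin/env python
"""Generate the synthetic 19-city x 2010-2018 health-resource panel.

Writes the panel, its ground truth (true inefficiency and frontier flags)
and the role schema under results/.  A second panel with a 2013-style
one-period output shock is written alongside, for the dip analysis in
02_score_efficiency.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from healthdea import GeneratorConfig, generate_panel, write_panel

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260922


def write(panel, truth, stem: str) -> None:
    write_panel(panel, OUT / f"{stem}.csv")
    gt = pd.DataFrame(truth.inefficiency, index=panel.dmus,
                      columns=[str(t) for t in panel.periods])
    gt.insert(0, "frontier", truth.frontier)
    gt.to_csv(OUT / f"{stem}_ground_truth.csv", index_label="city")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    panel, truth = generate_panel(cfg)
    write(panel, truth, "panel")

    shocked_cfg = GeneratorConfig(seed=SEED, shock_period=2013)
    shocked, shocked_truth = generate_panel(shocked_cfg)
    write(shocked, shocked_truth, "panel_shock2013")

    sch = panel.schema
    with open(OUT / "schema.yaml", "w") as fh:
        yaml.safe_dump(
            {"inputs": list(sch.input_names), "outputs": list(sch.output_names),
             "covariates": list(sch.covariate_names), "dmu_column": sch.dmu_column,
             "period_column": sch.period_column, "units": sch.units},
            fh,
        )

    print(f"panel: {panel.n} cities x {panel.T} years, seed {SEED}")
    print(f"frontier cities (true inefficiency = 0): {int(truth.frontier.sum())} of {panel.n}")
    print("2018 input means :", np.round(panel.X[:, -1, :].mean(axis=0), 1))
    print("2018 output means:", np.round(panel.Y[:, -1, :].mean(axis=0), 1))
    print(f"wrote panel.csv, panel_shock2013.csv, ground truths and schema.yaml to {OUT}")


if __name__ == "__main__":
    main()
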