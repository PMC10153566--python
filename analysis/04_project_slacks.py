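#!/usr/bin/env python
"""Input-redundancy / output-shortage optimisation plan for the final year.

For every city scoring below 1 in 2018, reports how much of each input could
be shed and each output expanded (SBM slacks), in amounts and as percentages
of the observed values.

Run 01_simulate_panel.py first.
"""

from pathlib import Path

from healthdea import RTS, projection_report, read_panel, read_schema

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    schema = read_schema(OUT / "schema.yaml")
    panel = read_panel(OUT / "panel.csv", schema)
    year = panel.periods[-1]

    report = projection_report(panel, year, RTS.VRS)
    report.rounded().to_csv(OUT / f"projection_{year}.csv")

    tab = report.table
    print(f"{len(tab)} of {panel.n} cities are below the frontier in {year}")
    pct_cols = [c for c in tab.columns if c.endswith("_pct")]
    means = tab[pct_cols].mean().round(2)
    print("mean redundancy/shortage percentages among sub-frontier cities:")
    print(means.to_string())
    biggest = means.idxmax()
    print(f"largest average adjustment: {biggest} ({means[biggest]:.2f}%)")
    print(f"wrote projection_{year}.csv to {OUT}")


if __name__ == "__main__":
    main()
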