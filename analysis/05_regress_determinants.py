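#!/usr/bin/env python
"""Second-stage Tobit regression of efficiency scores on the covariates.

Pools all city-years, regresses the combined super-efficiency score on the
standardized covariates with a left-censored-at-zero Tobit, and writes the
coefficient table.  The generator's inefficiency link loads negatively on
income, population density and education (so their efficiency coefficients
are positive in truth), but with only 19 distinct cities, covariates that
are cross-correlated and constant within city, pooling 171 city-years
recovers that pattern only roughly — the same identification caveat that
applies to the published two-stage analysis.

Run 01_simulate_panel.py first.
"""

from pathlib import Path

import numpy as np

from healthdea import RTS, TobitSpec, fit_tobit, read_panel, read_schema, score_matrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    schema = read_schema(OUT / "schema.yaml")
    panel = read_panel(OUT / "panel.csv", schema)

    mat = score_matrix(panel, RTS.VRS)
    y = mat.scores.ravel()
    Z = panel.Z.reshape(-1, schema.p)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    keep = ~np.isnan(y)
    X = np.c_[np.ones(int(keep.sum())), Z[keep]]

    fit = fit_tobit(X, y[keep], TobitSpec(lower_limit=0.0),
                    names=("constant", *schema.covariate_names))
    table = fit.summary_frame().round(3)
    table.to_csv(OUT / "tobit.csv", index_label="variable")

    print(f"N = {fit.n_obs} city-years, {fit.n_censored_low} left-censored")
    print(table.to_string())
    print(f"Log-likelihood {fit.loglik:.3f}   LR X2 {fit.lr_chi2:.2f}   Prob>X2 {fit.lr_p:.4g}")
    sig = table.index[(table["p"] < 0.05).fillna(False)].tolist()
    print(f"covariates significant at 5%: {[s for s in sig if s != 'constant']}")
    print("true inefficiency loadings (negative = raises efficiency): "
          "income -0.15, density -0.20, education -0.15, pgdp 0, urbanization 0")
    print("(only 19 distinct covariate draws stand behind the 171 rows, so "
          "single-panel estimates are noisy; exact recovery is checked on the "
          "latent-Gaussian generator instead)")
    print(f"wrote tobit.csv to {OUT}")


if __name__ == "__main__":
    main()
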