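"""Published reference tables, transcribed as plain CSV.

Two tables from the published Sichuan health-resource efficiency study are
packaged so that its summary statistics can be recomputed without the
underlying yearbook data (which were never deposited in machine-readable
form):

* ``sichuan_super_sbm_scores.csv`` — the super-efficiency SBM score of each
  of 19 prefecture-level cities for each year 2010-2018 (171 cells), plus
  the published arithmetic Mean row and column.
* ``sichuan_malmquist_indices.csv`` — the five Malmquist indices (EFFCH,
  TECHCH, PECH, SECH, TFPCH) per adjacent year pair, plus the published
  geometric Mean row.

Values are stored exactly as printed (3 decimals).  One known quirk of the
source: its text states the lowest 2018 score belonged to Guang'an (0.80)
while the score table itself shows Leshan 0.801 < Guang'an 0.861; the
transcription keeps the table values.
"""

from importlib import resources

import numpy as np
import pandas as pd

from ..sbm_efficiency import ScoreMatrix

__all__ = ["load_score_table", "load_malmquist_table", "score_matrix_from_fixture"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_score_table() -> pd.DataFrame:
    """Full published score table (cities x years, incl. printed Mean row/col)."""
    return _read("sichuan_super_sbm_scores.csv").set_index("city")


def score_matrix_from_fixture() -> ScoreMatrix:
    """The 19 x 9 score cells as a ScoreMatrix (printed means stripped)."""
    df = load_score_table()
    cells = df.drop(index="Mean").drop(columns="Mean")
    return ScoreMatrix.from_scores(
        cells.to_numpy(dtype=float),
        dmus=tuple(cells.index),
        periods=tuple(int(c) for c in cells.columns),
    )


def load_malmquist_table(include_mean: bool = False) -> pd.DataFrame:
    """Published per-pair Malmquist indices; Mean row excluded by default."""
    df = _read("sichuan_malmquist_indices.csv").set_index("pair")
    if not include_mean:
        df = df.drop(index="Mean")
    return df.astype(float)


def published_malmquist_mean() -> pd.Series:
    """The printed Mean row of the index table."""
    return _read("sichuan_malmquist_indices.csv").set_index("pair").loc["Mean"].astype(float)


def geometric_mean(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(v))))
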