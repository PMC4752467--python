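"""Bundled reference dataset: published measurements for 23 production
batches of an herbal injectable, used as worked examples and test inputs.

``marker_contents.csv`` holds per-batch contents (mg/L) of the seven marker
compounds (UR, AD, CGA, CFA, CCA, LGR, LG), with the literal ``ND`` for
not-detected, plus off-line IC50 values (mg/mL).

``sqfm_values.csv`` holds the per-wavelength similarity triples
(S_m, P_m %, alpha) and assigned grades at 260/265/330/335/350 nm, the
root-mean-square integrated rows, and the reference-fingerprint (``RFP``)
self-evaluation column.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

MARKERS = ["UR", "AD", "CGA", "CFA", "CCA", "LGR", "LG"]
WAVELENGTHS = [260, 265, 330, 335, 350]


def _read(name: str) -> pd.DataFrame:
    with resources.files("fingerqc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_marker_contents(include_ic50: bool = False) -> pd.DataFrame:
    """Batch x marker content table (mg/L); ND becomes NaN."""
    df = _read("marker_contents.csv").set_index("batch_id")
    df = df.apply(pd.to_numeric, errors="coerce")
    return df if include_ic50 else df[MARKERS]


def load_sqfm_values(channel: int | str | None = None) -> pd.DataFrame:
    """Published similarity values; ``channel`` selects one wavelength or
    ``"integrated"``; the ``RFP`` rows are the reference self-evaluation."""
    df = _read("sqfm_values.csv")
    if channel is not None:
        df = df[df["channel"].astype(str) == str(channel)].reset_index(drop=True)
    return df
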