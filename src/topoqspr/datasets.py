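"""Bundled study data: five anticancer sulfonamide derivatives.

The packaged fixture carries the degree-pair edge partitions of the five
hydrogen-suppressed molecular graphs together with each compound's melting
point (°C) and formula weight.  ``REPORTED_INDEX_VALUES`` holds the
previously reported descriptor table for the same compounds (2-decimal
floats); :func:`reported_deltas` lists every cell where recomputation from
the partitions disagrees with the reported value beyond rounding, so that no
divergence is silent.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .graph import CompoundRecord, load_compounds
from .indices import INDEX_IDS, index_table

__all__ = [
    "load_sulfonamides",
    "REPORTED_INDEX_VALUES",
    "reported_deltas",
    "REPORTED_TOLERANCE",
]

#: Previously reported descriptor values per compound (report-table layout).
#: Integer-weight indices (M1, M2, HM, F) are exact; the remaining columns
#: were reported rounded to 2 decimals with occasional arithmetic slips.
REPORTED_INDEX_VALUES = pd.DataFrame(
    [
        [136, 162, 5.58, 11.18, 714, 390, 64.17, 12.01, 12.22, 25.38, 19.82],
        [186, 222, 7.19, 14.39, 996, 552, 87.09, 15.56, 16.03, 33.61, 26.67],
        [172, 204, 6.54, 13.09, 930, 522, 79.67, 14.4, 14.63, 30.38, 24.76],
        [150, 180, 6.33, 12.49, 780, 420, 72.66, 13.2, 13.67, 28.62, 21.82],
        [170, 211, 6.35, 12.71, 954, 532, 78.86, 13.98, 14.21, 29.5, 23.94],
    ],
    index=pd.RangeIndex(1, 6, name="compound_no"),
    columns=list(INDEX_IDS),
)

#: Max |recomputed − reported| compatible with 2-d.p. reporting whose rounding
#: direction is not always consistent.
REPORTED_TOLERANCE = 0.015


def load_sulfonamides() -> list[CompoundRecord]:
    """The five study compounds, partition + properties, in report order."""
    with resources.as_file(
        resources.files("topoqspr.data") / "sulfonamides.json"
    ) as path:
        return load_compounds(path)


def reported_deltas(compounds: list[CompoundRecord] | None = None) -> pd.DataFrame:
    """Cells of the descriptor table where recomputation from the edge
    partitions differs from the reported value by more than
    :data:`REPORTED_TOLERANCE`.

    Returns a DataFrame with columns ``compound_no``, ``index``, ``reported``,
    ``recomputed``, ``delta``.
    """
    if compounds is None:
        compounds = load_sulfonamides()
    recomputed = index_table(compounds)
    rows = []
    for i, (_, rec_row) in enumerate(recomputed.iterrows(), start=1):
        for idx in INDEX_IDS:
            reported = float(REPORTED_INDEX_VALUES.loc[i, idx])
            value = float(rec_row[idx])
            if abs(value - reported) > REPORTED_TOLERANCE:
                rows.append(
                    {
                        "compound_no": i,
                        "index": idx,
                        "reported": reported,
                        "recomputed": value,
                        "delta": value - reported,
                    }
                )
    return pd.DataFrame(
        rows, columns=["compound_no", "index", "reported", "recomputed", "delta"]
    )
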