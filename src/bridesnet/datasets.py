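"""Published reference inputs bundled with the package.

The wood-turtle population-graph study that motivates this package printed
its per-site attribute panel (19 sampling sites along the St. Lawrence
River: sample size, expected heterozygosity, estimated census size,
element-occurrence rank) and the summary grid of its stepwise-selection
runs. The underlying genotypes were never deposited, so these printed
tables are the only study inputs that can be redistributed; they drive the
scenario construction and the complexity/node-count correlation.
"""

from __future__ import annotations

import pandas as pd

from .genio import PopulationAttributes

__all__ = [
    "wood_turtle_attributes",
    "wood_turtle_attribute_table",
    "selection_node_counts",
    "MODEL_LABELS",
    "MODEL_COMPLEXITIES",
]

# Id, N, HE, PSize, EO — north-shore sites first, then south-shore.
_ATTRIBUTE_ROWS = [
    ("GA2", 12, 0.65, 75, "BC"),
    ("GA3", 31, 0.72, 2000, "A"),
    ("GA4", 7, 0.63, 250, "B"),
    ("GA5", 15, 0.62, 2000, "AB"),
    ("LA1", 11, 0.701, 50, "BC"),
    ("LO1", 21, 0.754, 50, "B"),
    ("MD1", 18, 0.724, 100, "B"),
    ("SM1", 56, 0.771, 250, "AB"),
    ("BE1", 24, 0.634, 100, "B"),
    ("DC1", 17, 0.736, 50, "AB"),
    ("MA1", 9, 0.68, 20, "BC"),
    ("MA2", 10, 0.625, 30, "AB"),
    ("MA3", 25, 0.75, 25, "AB"),
    ("MI1", 20, 0.73, 500, "AB"),
    ("MI2", 20, 0.71, 30, "BC"),
    ("MI3", 6, 0.74, 100, "B"),
    ("SF1", 6, 0.74, 25, "AB"),
    ("SF3", 6, 0.61, 6, "C"),
    ("SF4", 13, 0.73, 25, "BC"),
]

#: Weighting schemes of the published selection runs, in column order.
MODEL_LABELS = ("S1", "B3S1", "B1S3", "B1R-1D-1S1", "B3D1E2S3")

#: Number of nonzero weights of each scheme, same order.
MODEL_COMPLEXITIES = (1, 2, 2, 4, 4)

# Minimal number of added nodes per scenario x model; None marks runs in
# which no node was worth adding under the scheme.
_NODE_COUNTS = {
    "A_P": (1, 3, 3, 3, 4),
    "A_R": (None, 1, 1, 3, 6),
    "B_P": (None, 3, 3, 5, 5),
    "B_R": (1, 1, 1, 2, 3),
    "C_P": (2, 2, 2, 5, 5),
    "C_R": (None, 2, 2, 2, 4),
}


def wood_turtle_attributes() -> list[PopulationAttributes]:
    """The 19 sampled populations as attribute records."""
    return [
        PopulationAttributes(id=i, n=n, he=he, psize=ps, eo=eo)
        for i, n, he, ps, eo in _ATTRIBUTE_ROWS
    ]


def wood_turtle_attribute_table() -> pd.DataFrame:
    """Same panel as a DataFrame with columns Id, N, HE, PSize, EO."""
    return pd.DataFrame(
        _ATTRIBUTE_ROWS, columns=["Id", "N", "HE", "PSize", "EO"]
    )


def selection_node_counts() -> pd.DataFrame:
    """Published minimal added-node counts, scenarios × weighting schemes.

    NaN marks scenario/model pairs for which no node improved the score.
    """
    return pd.DataFrame.from_dict(
        {k: [float("nan") if v is None else v for v in row]
         for k, row in _NODE_COUNTS.items()},
        orient="index",
        columns=list(MODEL_LABELS),
    )
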