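"""Shape-based foil selection in a concept-embedding space.

In a four-alternative identification task, the three wrong answers
(foils) are made hard by choosing concepts whose *shape* resembles the
true concept: concepts are projected onto the shape-related dimensions
of a similarity embedding and the nearest Euclidean neighbours of the
true concept become the foils.

Embeddings are pandas DataFrames: one row per concept (index = concept
name), one named column per embedding dimension.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: The 13 shape-related dimensions of the 49-dimensional THINGS concept
#: embedding used for foil selection.
SHAPE_DIMENSIONS: tuple[str, ...] = (
    "disc-shaped",
    "course pattern",
    "paper-related/text-related",
    "long-thin",
    "powdery/fine-scale pattern",
    "spherical",
    "repetitiveness",
    "flat/patterned",
    "thin/flat",
    "stringy",
    "has beams/support",
    "has grating",
    "cylindrical/conical",
)


def load_embedding(path) -> pd.DataFrame:
    """Read a concept embedding from CSV (first column = concept names)."""
    table = pd.read_csv(path, index_col=0)
    return validate_embedding(table)


def validate_embedding(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate concept names: {dupes}")
    if table.columns.has_duplicates:
        raise ValueError("duplicate dimension names")
    values = table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("embedding contains non-finite values")
    return table


def project_shape(
    table: pd.DataFrame, subspace: Sequence[str] = SHAPE_DIMENSIONS
) -> pd.DataFrame:
    """Restrict an embedding to the named dimensions, order preserved.

    Dimension names are matched case-insensitively against the table's
    columns; unknown names raise an error listing every miss.
    """
    lookup = {str(c).strip().lower(): c for c in table.columns}
    resolved, missing = [], []
    for name in subspace:
        key = str(name).strip().lower()
        if key in lookup:
            resolved.append(lookup[key])
        else:
            missing.append(name)
    if missing:
        raise KeyError(f"dimensions not found in embedding: {missing}")
    return table.loc[:, resolved]


def select_foils(concept: str, table: pd.DataFrame, k: int = 3) -> list[str]:
    """The k concepts nearest to ``concept`` in Euclidean distance.

    The query concept itself is excluded; results are ordered by
    increasing distance, ties broken alphabetically by concept name.
    Raw embedding values are used (no standardization).
    """
    validate_embedding(table)
    if concept not in table.index:
        raise KeyError(f"concept {concept!r} not in embedding")
    if k < 1 or k > len(table) - 1:
        raise ValueError(
            f"k={k} out of range for an embedding of {len(table)} concepts"
        )
    query = table.loc[[concept]].to_numpy(dtype=np.float64)
    others = table.drop(index=concept)
    dists = cdist(query, others.to_numpy(dtype=np.float64))[0]
    order = sorted(range(len(others)), key=lambda i: (dists[i], str(others.index[i])))
    return [str(others.index[i]) for i in order[:k]]


def foil_table(
    table: pd.DataFrame,
    concepts: Sequence[str] | None = None,
    k: int = 3,
    subspace: Sequence[str] | None = SHAPE_DIMENSIONS,
) -> pd.DataFrame:
    """Foils for many concepts at once.

    Projects onto ``subspace`` first (pass None to use all dimensions),
    then selects k nearest-neighbour foils per concept. Returns a frame
    with columns ``concept, foil1 .. foilk``.
    """
    projected = table if subspace is None else project_shape(table, subspace)
    if concepts is None:
        concepts = list(projected.index)
    rows = []
    for concept in concepts:
        foils = select_foils(concept, projected, k)
        rows.append({"concept": concept, **{f"foil{i+1}": f for i, f in enumerate(foils)}})
    return pd.DataFrame(rows)
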