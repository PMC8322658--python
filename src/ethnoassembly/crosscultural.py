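"""Cross-cultural knowledge similarity via the Jaccard Index.

Two cultures' ethnobotanical knowledge of a genus is compared by the
species sets they use: JI_AB = 100 * |A n B| / |A u B|.  The default
species set pools all non-toxic use domains (the comparison is over
"species used", not species-by-category); per-domain matrices are
available through the ``domains`` argument.  Pairs where both sets are
empty are reported as null (0/0 is "no data", not "no overlap").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .usedata import UseMatrix

__all__ = ["JaccardMatrix", "species_set", "jaccard", "jaccard_matrix"]

DEFAULT_DOMAINS = ("food", "medicinal", "ritual", "cosmetic")


def species_set(
    matrix: UseMatrix,
    culture: str,
    domains: Sequence[str] = DEFAULT_DOMAINS,
) -> set[str]:
    """Species with at least one report by ``culture`` in the selected domains."""
    if culture not in matrix.culture_order:
        raise KeyError(f"unknown culture {culture!r}")
    df = matrix.counts
    mask = (df["culture"] == culture) & df["domain"].isin(domains)
    return set(df.loc[mask, "species"])


def jaccard(set_a: set, set_b: set) -> float | None:
    """JI = 100 * |A n B| / |A u B|; None when both sets are empty (0/0)."""
    union = len(set_a | set_b)
    if union == 0:
        return None
    return 100.0 * len(set_a & set_b) / union


@dataclass
class JaccardMatrix:
    """Symmetric culture x culture JI matrix on [0, 100] (NaN = 0/0 pair)."""

    cultures: list[str]
    values: pd.DataFrame
    species_sets: dict[str, set[str]]

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"culture_a": a, "culture_b": b, "ji": self.values.loc[a, b]}
            for a, b in itertools.combinations(self.cultures, 2)
        ]
        return pd.DataFrame(rows, columns=["culture_a", "culture_b", "ji"])

    def isolated_cultures(self) -> list[str]:
        """Cultures sharing no species with any other culture."""
        out = []
        for c in self.cultures:
            off = self.values.loc[c].drop(c)
            if len(off) and (off.fillna(0) == 0).all():
                out.append(c)
        return out


def jaccard_matrix(
    matrix: UseMatrix,
    domains: Sequence[str] = DEFAULT_DOMAINS,
    *,
    order: str = "lexicographic",
) -> JaccardMatrix:
    """All pairwise JI values between the cultures of a use matrix.

    ``order`` controls the output culture ordering: ``lexicographic``
    (default) or ``dendrogram`` (average-linkage leaf order on JI distance,
    so similar cultures sit adjacently in heatmaps).
    """
    cultures = list(matrix.culture_order)
    if len(cultures) < 2:
        raise ValueError("need at least 2 cultures for pairwise comparison")
    sets = {c: species_set(matrix, c, domains) for c in cultures}

    values = pd.DataFrame(np.nan, index=cultures, columns=cultures)
    for c in cultures:
        if sets[c]:
            values.loc[c, c] = 100.0
    for a, b in itertools.combinations(cultures, 2):
        ji = jaccard(sets[a], sets[b])
        v = math.nan if ji is None else ji
        values.loc[a, b] = v
        values.loc[b, a] = v

    if order == "dendrogram":
        cultures = _leaf_order(values.fillna(0.0))
        values = values.loc[cultures, cultures]
    elif order != "lexicographic":
        raise ValueError(f"unknown ordering {order!r}")
    return JaccardMatrix(cultures=cultures, values=values, species_sets=sets)


def _leaf_order(values: pd.DataFrame) -> list[str]:
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    dist = (100.0 - values.to_numpy()) / 100.0
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    return [values.index[i] for i in leaves_list(linkage)]
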