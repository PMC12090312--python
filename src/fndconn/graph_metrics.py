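"""Weighted degree (node strength) and link bookkeeping on connectome matrices.

The weighted degree of node i is the sum of the weights of all links
incident to i,

    WD_i = sum_{j != i} w_ij,

used on FA-weighted connectomes as an integrative index of the
microstructural integrity of the white matter originating in region i.
Per subject the 84 WD values form one 1x84 vector.

Links are the 84*83/2 = 3486 unordered region pairs, enumerated row-major
over the strict upper triangle; each node participates in exactly 83
candidate links. This canonical order is fixed so result tables are
comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome_io import N_REGIONS, SubjectConnectome, region_names

N_LINKS = N_REGIONS * (N_REGIONS - 1) // 2  # 3486
LINKS_PER_NODE = N_REGIONS - 1  # 83


def link_index_pairs() -> np.ndarray:
    """All unordered node pairs (i, j), i < j, in canonical row-major order.

    Returns an array of shape (3486, 2).
    """
    iu = np.triu_indices(N_REGIONS, k=1)
    return np.column_stack(iu)


def weighted_degree(conn: SubjectConnectome) -> "WDVector":
    """Weighted degree of every node: values[i] = sum_{j != i} matrix[i, j].

    Summation is strictly left-to-right per row (cumsum), so the result is
    bit-identical to a naive sequential loop over j.
    """
    values = np.cumsum(conn.matrix, axis=1)[:, -1]
    return WDVector(subject_id=conn.subject_id, values=values)


@dataclass
class WDVector:
    """One subject's 84 weighted-degree values, in canonical node order."""

    subject_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_REGIONS,):
            raise ValueError(f"WD vector must have length {N_REGIONS}")


def wd_table(connectomes: Sequence[SubjectConnectome]) -> pd.DataFrame:
    """Subjects x 84 weighted-degree table with region-name columns."""
    rows = [weighted_degree(c).values for c in connectomes]
    ids = [c.subject_id for c in connectomes]
    return pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="subject_id"),
                        columns=region_names())


def write_wd_table(wd: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wd.to_csv(path, sep="\t", float_format="%.10g")
    return path


@dataclass
class LinkTable:
    """Subjects x 3486 link-weight table in canonical link order.

    ``values[s, l]`` is subject s's weight on the link ``pairs[l] = (i, j)``.
    """

    subject_ids: list[str]
    weight_kind: str
    values: np.ndarray = field(repr=False)
    pairs: np.ndarray = field(default_factory=link_index_pairs, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), N_LINKS):
            raise ValueError(f"link table must be n_subjects x {N_LINKS}")

    def link_names(self) -> list[tuple[str, str]]:
        names = region_names()
        return [(names[i], names[j]) for i, j in self.pairs]


def link_values(connectomes: Sequence[SubjectConnectome]) -> LinkTable:
    """Extract per-subject upper-triangle link weights.

    All connectomes must share one weight kind; mixing kinds is an error.
    """
    kinds = {c.weight_kind for c in connectomes}
    if len(kinds) != 1:
        raise ValueError(f"mixed weight kinds {sorted(kinds)}; link_values needs exactly one")
    iu = np.triu_indices(N_REGIONS, k=1)
    values = np.stack([c.matrix[iu] for c in connectomes])
    return LinkTable(subject_ids=[c.subject_id for c in connectomes],
                     weight_kind=kinds.pop(), values=values)


def matrix_from_link_row(row: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric 84x84 matrix whose upper triangle is ``row``."""
    mat = np.zeros((N_REGIONS, N_REGIONS))
    iu = np.triu_indices(N_REGIONS, k=1)
    mat[iu] = row
    return mat + mat.T


def node_incidence_matrix() -> np.ndarray:
    """Boolean (84, 3486) incidence: entry [k, l] is True iff node k is an endpoint of link l."""
    pairs = link_index_pairs()
    inc = np.zeros((N_REGIONS, N_LINKS), dtype=bool)
    inc[pairs[:, 0], np.arange(N_LINKS)] = True
    inc[pairs[:, 1], np.arange(N_LINKS)] = True
    return inc
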