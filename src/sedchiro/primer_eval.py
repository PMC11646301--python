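"""Amplicon taxonomic-resolution screen via pairwise percent distances.

Whether a short barcode fragment can separate species is judged from the
pairwise p-distances among aligned reference inserts: if every
interspecific distance exceeds a resolution threshold (8% by default),
species-level assignment inside that marker is considered reliable.
Distances are raw p-distances with pairwise deletion — sites where either
sequence carries a gap or N are excluded per pair — expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_RESOLUTION_THRESHOLD = 8.0  # percent


@dataclass
class DistanceMatrix:
    """Symmetric percent-distance matrix with record labels.

    Entries are in [0, 100]; pairs with zero comparable sites are NaN and
    listed in ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def pairwise_pdistance(aligned: Mapping[str, str] | Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Percent p-distance with pairwise deletion over aligned sequences.

    ``aligned`` maps labels to equal-length sequences (gaps ``-`` allowed).
    distance(i, j) = 100 * differing sites / compared sites, where sites
    with a gap or N in either sequence are excluded for that pair.
    """
    items = list(aligned.items()) if isinstance(aligned, Mapping) else list(aligned)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [k for k, _ in items]
    seqs = [v.upper() for _, v in items]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned to equal length")

    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    valid = ~np.isin(arr, [b"-", b"N", b"."])
    n = len(seqs)
    values = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                values[i, j] = values[j, i] = np.nan
                undefined.append((labels[i], labels[j]))
                continue
            diffs = int((arr[i][both] != arr[j][both]).sum())
            d = 100.0 * diffs / comparable
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, undefined)


def min_interspecific_distance(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    threshold: float = DEFAULT_RESOLUTION_THRESHOLD,
) -> tuple[float, pd.DataFrame]:
    """Minimum distance over pairs of labels from different species.

    Returns the minimum percent distance and a per-pair report of all
    interspecific pairs, with a ``below_threshold`` flag for pairs under
    the resolution threshold.  All labels must be mapped to a species;
    raises if no interspecific pair exists.
    """
    missing = [l for l in matrix.labels if l not in species_of]
    if missing:
        raise ValueError(f"labels without species mapping: {missing}")
    rows = []
    for i, a in enumerate(matrix.labels):
        for j in range(i + 1, len(matrix.labels)):
            b = matrix.labels[j]
            if species_of[a] == species_of[b]:
                continue
            d = matrix.values[i, j]
            rows.append(
                {
                    "label_a": a,
                    "label_b": b,
                    "species_a": species_of[a],
                    "species_b": species_of[b],
                    "distance_pct": d,
                    "below_threshold": bool(d < threshold),
                }
            )
    if not rows:
        raise ValueError("no interspecific pair among the labels")
    report = pd.DataFrame(rows)
    return float(report["distance_pct"].min()), report
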