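"""Morphotype crosswalk, incidence matrices, DCA and sharing reports.

SedDNA taxa and chitinous-remain counts live in different taxonomies:
molecular assignments are Linnaean names, remains are larval morphotypes
(often genus- or species-group level).  A crosswalk table translates
assignments to morphotypes (species rows first, genus fallback; taxa
without a described larva are dropped and reported).  All abundances are
reduced to presence-absence before ordination with detrended
correspondence analysis, since read counts and head-capsule counts are
not comparable quantities.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Lineage


# ---------------------------------------------------------------------------
# Morphotype crosswalk
# ---------------------------------------------------------------------------


@dataclass
class MorphotypeCrosswalk:
    """(taxon name, rank) -> morphotype lookup with genus fallback."""

    entries: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for (name, rank), morpho in self.entries.items():
            if not morpho:
                raise ValueError(f"empty morphotype for ({name}, {rank})")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MorphotypeCrosswalk":
        required = {"taxon", "rank", "morphotype"}
        if not required <= set(df.columns):
            raise ValueError(f"crosswalk needs columns {sorted(required)}")
        entries: dict[tuple[str, str], str] = {}
        for row in df.itertuples(index=False):
            key = (row.taxon, row.rank)
            if key in entries:
                raise ValueError(f"duplicate crosswalk key {key}")
            entries[key] = row.morphotype
        return cls(entries)

    @classmethod
    def read_tsv(cls, path) -> "MorphotypeCrosswalk":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def lookup(self, name: str, rank: str) -> Optional[str]:
        hit = self.entries.get((name, rank))
        if hit is not None:
            return hit
        if rank == "species":
            genus = name.split()[0]
            return self.entries.get((genus, "genus"))
        return None


def translate(
    taxa_by_sample: Mapping[str, Iterable[tuple[str, str]]],
    crosswalk: MorphotypeCrosswalk,
) -> tuple[dict[str, set[str]], list[tuple[str, str]]]:
    """Translate per-sample (taxon, rank) detections to morphotype sets.

    Species missing from the table fall back to their genus row; taxa
    absent at both ranks are dropped and returned in the dropped list
    (deduplicated, input order).
    """
    detections: dict[str, set[str]] = {}
    dropped: list[tuple[str, str]] = []
    seen_dropped: set[tuple[str, str]] = set()
    for sample, taxa in taxa_by_sample.items():
        morphos: set[str] = set()
        for name, rank in taxa:
            m = crosswalk.lookup(name, rank)
            if m is None:
                if (name, rank) not in seen_dropped:
                    seen_dropped.add((name, rank))
                    dropped.append((name, rank))
            else:
                morphos.add(m)
        detections[sample] = morphos
    return detections, dropped


def taxa_from_assignments(
    assignments,
    abundance: pd.DataFrame,
) -> dict[str, list[tuple[str, str]]]:
    """Per-sample (taxon, rank) detections from ESV assignments + counts.

    ``abundance`` is the ESV x sample table; an assigned ESV contributes
    its deepest name/rank to every sample where its count is positive.
    """
    by_esv = {a.esv_id: a for a in assignments}
    out: dict[str, list[tuple[str, str]]] = {s: [] for s in abundance.columns}
    for esv_id, row in abundance.iterrows():
        a = by_esv.get(esv_id)
        if a is None or not a.assigned:
            continue
        rank = a.lineage.assignment_rank()
        name = a.lineage.deepest_name()
        for sample in abundance.columns:
            if row[sample] > 0:
                out[sample].append((name, rank))
    return out


# ---------------------------------------------------------------------------
# Incidence matrix
# ---------------------------------------------------------------------------


def build_incidence(counts: pd.DataFrame) -> pd.DataFrame:
    """Presence-absence transform; all-zero taxon columns are removed."""
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    binary = (counts > 0).astype(int)
    return binary.loc[:, binary.sum(axis=0) > 0]


def incidence_from_detections(detections: Mapping[str, set[str]]) -> pd.DataFrame:
    taxa = sorted(set().union(*detections.values())) if detections else []
    rows = {s: [1 if t in d else 0 for t in taxa] for s, d in detections.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa)


# ---------------------------------------------------------------------------
# Correspondence analysis / DCA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Sample/taxon scores on four axes with eigenvalues and axis lengths."""

    sample_scores: pd.DataFrame
    species_scores: pd.DataFrame
    eigenvalues: np.ndarray
    axis_lengths: np.ndarray
    detrended: bool = True
    rescaled: bool = True


def downweight(matrix: pd.DataFrame, fraction: float = 5.0) -> pd.DataFrame:
    """Hill's downweighting of rare taxa (iweigh = 1).

    Taxa whose abundance total is below max_total / fraction are
    downweighted in proportion to their total.
    """
    totals = matrix.sum(axis=0).astype(float)
    threshold = totals.max() / fraction
    weights = np.minimum(1.0, totals / threshold)
    return matrix * weights


def _ca_svd(Y: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain CA by SVD: eigenvalues plus row/column principal coordinates."""
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    k = n_axes
    eig = s[:k] ** 2
    rows = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
    cols = (Vt[:k].T * s[:k]) / np.sqrt(c)[:, None]
    return eig, rows, cols


def _weighted_normalize(x: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float]:
    x = x - np.sum(r * x) / r.sum()
    norm = np.sqrt(np.sum(r * x * x) / r.sum())
    if norm == 0:
        return x, 0.0
    return x / norm, norm


def _detrend_by_segments(
    x: np.ndarray,
    prev: np.ndarray,
    r: np.ndarray,
    segments: int,
    smooth_passes: int = 2,
) -> np.ndarray:
    """Subtract the smoothed within-segment means of x along prev.

    The previous axis is cut into equal segments; r-weighted segment
    means of x are interpolated across empty segments, smoothed with a
    (1,2,1)/4 running average, and subtracted.  Smoothing keeps the
    operation well-posed when segments hold few samples (subtracting raw
    per-segment means would annihilate the scores outright).
    """
    lo, hi = float(prev.min()), float(prev.max())
    if hi <= lo:
        return x - np.sum(r * x) / r.sum()
    edges = np.linspace(lo, hi, segments + 1)
    idx = np.clip(np.searchsorted(edges, prev, side="right") - 1, 0, segments - 1)
    wsum = np.bincount(idx, weights=r, minlength=segments)
    xsum = np.bincount(idx, weights=r * x, minlength=segments)
    means = np.full(segments, np.nan)
    occupied = wsum > 0
    means[occupied] = xsum[occupied] / wsum[occupied]
    # linear interpolation across empty segments, edge-extended
    pos = np.arange(segments, dtype=float)
    means = np.interp(pos, pos[occupied], means[occupied])
    for _ in range(smooth_passes):
        padded = np.concatenate(([means[0]], means, [means[-1]]))
        means = (padded[:-2] + 2.0 * padded[1:-1] + padded[2:]) / 4.0
    return x - means[idx]


def _extract_detrended_axis(
    Y: np.ndarray,
    prev_axes: list[np.ndarray],
    segments: int,
    init: Optional[np.ndarray] = None,
    max_iter: int = 999,
    tol: float = 1e-10,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One reciprocal-averaging axis, detrended against previous axes."""
    rowsum = Y.sum(axis=1)
    colsum = Y.sum(axis=0)
    n = Y.shape[0]
    x = np.arange(n, dtype=float) if init is None else init.astype(float)
    for p in prev_axes:
        x = _detrend_by_segments(x, p, rowsum, segments)
    x, norm = _weighted_normalize(x, rowsum)
    if norm == 0:
        x, _ = _weighted_normalize(np.arange(n, dtype=float), rowsum)
    eig = 0.0
    for _ in range(max_iter):
        u = (Y.T @ x) / colsum
        x_new = (Y @ u) / rowsum
        for p in prev_axes:
            x_new = _detrend_by_segments(x_new, p, rowsum, segments)
        x_new, eig = _weighted_normalize(x_new, rowsum)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    u = (Y.T @ x) / colsum
    return eig, x, u


def _rescale_axis(
    Y: np.ndarray, x: np.ndarray, u: np.ndarray, eig: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scale an axis to SD units of species turnover.

    Species scores are first deshrunk (reciprocal averaging contracts
    them by the eigenvalue), then the axis is scaled so the mean
    (row-weighted) within-sample dispersion of species scores equals
    one.  This is a single global scaling, not Hill's segment-wise
    nonlinear rescaling; axis lengths are therefore approximate SD units.
    """
    rowsum = Y.sum(axis=1)
    u_ds = u / eig if eig > 0 else u
    centroids = (Y @ u_ds) / rowsum
    disp = (Y * (u_ds[None, :] - centroids[:, None]) ** 2).sum(axis=1) / rowsum
    sigma = np.sqrt(np.sum(rowsum * disp) / rowsum.sum())
    if sigma == 0:
        return x, u_ds
    return x / sigma, u_ds / sigma


def dca(
    matrix: pd.DataFrame,
    downweight_rare: bool = True,
    segments: int = 26,
    rescale: bool = True,
    detrend: bool = True,
    n_axes: int = 4,
) -> OrdinationResult:
    """Detrended correspondence analysis of an incidence/abundance matrix.

    Axis 1 is the first correspondence-analysis axis; higher axes are
    extracted by reciprocal averaging with detrending-by-segments
    (default 26) against all previous axes.  With ``rescale`` the axes
    are expressed in SD units of species turnover.  With ``detrend`` and
    ``rescale`` both off the result is plain CA (eigenvalues
    non-increasing).  Requires >= 3 samples and >= 3 taxa and no empty
    sample row.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples and 3 taxa")
    empty = matrix.index[matrix.sum(axis=1) == 0].tolist()
    if empty:
        raise ValueError(f"samples with no taxa: {empty}")
    work = downweight(matrix.astype(float)) if downweight_rare else matrix.astype(float)
    Y = work.values.astype(float)
    k = min(n_axes, Y.shape[0] - 1, Y.shape[1] - 1)

    eig_ca, rows_ca, cols_ca = _ca_svd(Y, k)
    rowsum = Y.sum(axis=1)
    colsum = Y.sum(axis=0)

    eigs = np.zeros(n_axes)
    X = np.zeros((Y.shape[0], n_axes))
    U = np.zeros((Y.shape[1], n_axes))
    if not detrend:
        eigs[:k] = eig_ca
        X[:, :k] = rows_ca
        U[:, :k] = cols_ca
    else:
        # axis 1: CA axis in Hill-standardized form
        x1, _ = _weighted_normalize(rows_ca[:, 0], rowsum)
        eigs[0] = eig_ca[0]
        X[:, 0] = x1
        U[:, 0] = (Y.T @ x1) / colsum
        prev = [x1]
        for ax in range(1, k):
            init, _ = _weighted_normalize(rows_ca[:, ax], rowsum)
            e, x, u = _extract_detrended_axis(Y, prev, segments, init=init)
            eigs[ax] = e
            X[:, ax] = x
            U[:, ax] = u
            prev.append(x)

    if rescale:
        for ax in range(k):
            X[:, ax], U[:, ax] = _rescale_axis(Y, X[:, ax], U[:, ax], eigs[ax])

    lengths = X.max(axis=0) - X.min(axis=0)
    axes = [f"DCA{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        sample_scores=pd.DataFrame(X, index=matrix.index, columns=axes),
        species_scores=pd.DataFrame(U, index=work.columns, columns=axes),
        eigenvalues=eigs,
        axis_lengths=lengths,
        detrended=detrend,
        rescaled=rescale,
    )


# ---------------------------------------------------------------------------
# Sharing / proportion reports
# ---------------------------------------------------------------------------


def venn_counts(sets_by_method: Mapping[str, set]) -> dict[str, int]:
    """Exact region cardinalities of a 2- or 3-set Venn partition.

    Keys are '&'-joined sorted method names; each region counts elements
    in exactly those sets.
    """
    names = sorted(sets_by_method)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts needs 2 or 3 sets")
    universe = set().union(*sets_by_method.values())
    regions: dict[str, int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set(universe)
            for n in combo:
                inside &= sets_by_method[n]
            for n in names:
                if n not in combo:
                    inside -= sets_by_method[n]
            regions["&".join(combo)] = len(inside)
    return regions


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator with half-up rounding."""
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    value = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def control_report(
    control_abundance: pd.DataFrame,
    assignments,
    real_taxa: set[str],
) -> pd.DataFrame:
    """Tabulate field-control ESVs: reads, database match, real-sample overlap.

    ``control_abundance`` is an ESV x control-sample count table; an ESV
    with no assigned lineage is reported as ``no_match``.  A matched taxon
    also present in ``real_taxa`` (taxa detected in sediment samples) is
    flagged as an overlap.
    """
    by_esv = {a.esv_id: a for a in assignments}
    rows = []
    for esv_id, counts in control_abundance.iterrows():
        total = int(counts.sum())
        if total == 0:
            continue
        a = by_esv.get(esv_id)
        taxon = a.lineage.deepest_name() if (a is not None and a.assigned) else None
        rows.append(
            {
                "esv_id": esv_id,
                "reads": total,
                "match": taxon if taxon else "no_match",
                "overlaps_real_samples": bool(taxon and taxon in real_taxa),
            }
        )
    return pd.DataFrame(rows, columns=["esv_id", "reads", "match", "overlaps_real_samples"])
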