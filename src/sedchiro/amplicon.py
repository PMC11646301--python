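"""Paired-read processing into denoised exact sequence variants (ESVs).

The chain mirrors a standard amplicon workflow for degraded-template
metabarcoding: merge read pairs on their overlap, strip linked/anchored
primers, quality-filter on length, expected errors and mean Phred,
dereplicate across samples, denoise with d=1 single-linkage swarm
clustering (fastidious grafting of low-abundance clusters), remove
perfect two-parent chimeras (uchime3-style abundance-skew criterion) and
stop-codon-bearing numts, and finally re-map the quality-filtered reads
to the surviving ESVs with a one-difference budget to rebuild per-sample
abundances.  All stages are deterministic given sorted inputs; a stage
log records the read/record funnel.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .refdb import PrimerSet, match_primer, revcomp

INVERTEBRATE_MITO_TABLE = 5


@dataclass
class QualityRead:
    """A read with per-base Phred scores (Phred+33 origin)."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 93
        ):
            raise ValueError(f"read {self.read_id}: Phred out of [0, 93]")

    @property
    def mean_q(self) -> float:
        return float(self.qualities.mean())

    @property
    def expected_errors(self) -> float:
        return float(np.sum(10.0 ** (-self.qualities / 10.0)))


@dataclass
class Unique:
    """A dereplicated exact sequence with per-sample abundances."""

    sequence: str
    abundance_by_sample: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.abundance_by_sample.values())


@dataclass
class ESV:
    """A denoised exact sequence variant."""

    esv_id: str
    sequence: str
    abundance_by_sample: dict[str, int]

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_sample.values())


class StageLog:
    """Funnel log: one row per stage with in/out counts and reasons."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record(
        self,
        stage: str,
        n_in: int,
        n_out: int,
        reasons: Mapping[str, int] | None = None,
        conserved: bool = True,
    ) -> None:
        """``conserved`` marks stages where n_in = n_out + rejections holds;
        unit-changing stages (reads -> uniques -> clusters) set it False."""
        self.rows.append(
            {
                "stage": stage,
                "n_in": n_in,
                "n_out": n_out,
                "reasons": dict(reasons or {}),
                "conserved": conserved,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            reasons = ";".join(f"{k}={v}" for k, v in sorted(r["reasons"].items()))
            rows.append({**{k: r[k] for k in ("stage", "n_in", "n_out")}, "reasons": reasons})
        return pd.DataFrame(rows, columns=["stage", "n_in", "n_out", "reasons"])

    def check_conservation(self) -> None:
        """Assert n_in = n_out + sum(reason counts) for conserved stages."""
        for r in self.rows:
            if not r["conserved"]:
                continue
            lost = sum(r["reasons"].values())
            if r["n_in"] != r["n_out"] + lost:
                raise AssertionError(
                    f"stage {r['stage']}: {r['n_in']} != {r['n_out']} + {lost}"
                )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pairs(
    r1: QualityRead,
    r2: QualityRead,
    min_overlap: int = 50,
    max_diffs: int = 10,
) -> tuple[Optional[QualityRead], Optional[str]]:
    """Merge a read pair on the best overlap; returns (read, reason).

    R2 is reverse-complemented, then the overlap length maximizing the
    number of matching positions is chosen by offset scan.  The merge is
    accepted iff that overlap is >= ``min_overlap`` with <= ``max_diffs``
    mismatches.  Consensus takes the higher-quality base at conflicts;
    merged quality is max(q1, q2) at agreements and |q1 - q2| at
    conflicts.
    """
    s1 = r1.sequence.upper()
    s2 = revcomp(r2.sequence)
    q1 = r1.qualities
    q2 = r2.qualities[::-1]
    a = _encode(s1)
    b = _encode(s2)
    l1, l2 = len(a), len(b)
    best_ov, best_matches = 0, -1
    for ov in range(1, min(l1, l2) + 1):
        matches = int(np.count_nonzero(a[l1 - ov :] == b[:ov]))
        if matches > best_matches or (matches == best_matches and ov > best_ov):
            best_matches, best_ov = matches, ov
    ov = best_ov
    if ov < min_overlap:
        return None, "overlap_too_short"
    mismatches = ov - best_matches
    if mismatches > max_diffs:
        return None, "too_many_diffs"

    h1, h2 = s1[l1 - ov :], s2[:ov]
    oq1, oq2 = q1[l1 - ov :], q2[:ov]
    cons_bases = []
    cons_quals = np.empty(ov, dtype=np.int16)
    for i in range(ov):
        if h1[i] == h2[i]:
            cons_bases.append(h1[i])
            cons_quals[i] = max(oq1[i], oq2[i])
        else:
            cons_bases.append(h1[i] if oq1[i] >= oq2[i] else h2[i])
            cons_quals[i] = abs(int(oq1[i]) - int(oq2[i]))
    merged_seq = s1[: l1 - ov] + "".join(cons_bases) + s2[ov:]
    merged_q = np.concatenate([q1[: l1 - ov], cons_quals, q2[ov:]])
    return QualityRead(r1.read_id, merged_seq, merged_q, sample=r1.sample), None


# ---------------------------------------------------------------------------
# Primer trimming (linked, 5'-anchored)
# ---------------------------------------------------------------------------


def trim_primers(
    read: QualityRead,
    primers: PrimerSet,
    error_rate: float = 0.1,
) -> tuple[Optional[QualityRead], Optional[str]]:
    """Remove an anchored forward primer and a linked 3' reverse primer.

    The forward primer must match at position 0 with at most
    floor(error_rate * length) mismatches (degenerate-aware); the reverse
    complement of the reverse primer must match flush at the 3' end.
    Reads lacking either site are rejected (linked semantics).
    """
    seq = read.sequence.upper()
    flen = primers.forward.length
    rlen = primers.reverse.length
    if len(seq) < flen + rlen:
        return None, "no_forward_anchor"
    fbudget = int(error_rate * flen)
    rbudget = int(error_rate * rlen)
    if match_primer(seq[:flen], primers.forward) > fbudget:
        return None, "no_forward_anchor"
    tail = seq[-rlen:]
    if match_primer(revcomp(tail), primers.reverse) > rbudget:
        return None, "no_reverse"
    return (
        QualityRead(
            read.read_id,
            seq[flen : len(seq) - rlen],
            read.qualities[flen : len(seq) - rlen],
            sample=read.sample,
        ),
        None,
    )


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


def quality_filter(
    read: QualityRead,
    expected_len: int,
    len_tolerance: int = 10,
    max_ee: float = 1.0,
    min_mean_q: float = 30.0,
) -> tuple[bool, Optional[str]]:
    """Keep iff length within +/- tolerance, EE < max_ee and mean Q >= min."""
    if abs(len(read.sequence) - expected_len) > len_tolerance:
        return False, "length_out_of_window"
    if read.expected_errors >= max_ee:
        return False, "expected_errors"
    if read.mean_q < min_mean_q:
        return False, "low_mean_q"
    return True, None


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------


def dereplicate(reads: Iterable[QualityRead]) -> list[Unique]:
    """Exact-sequence grouping across samples.

    Output sorted by total abundance descending, ties broken by
    lexicographic sequence order.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for read in reads:
        counts[read.sequence.upper()][read.sample] += 1
    uniques = [Unique(seq, dict(c)) for seq, c in counts.items()]
    uniques.sort(key=lambda u: (-u.total, u.sequence))
    return uniques


# ---------------------------------------------------------------------------
# Swarm d=1 denoising
# ---------------------------------------------------------------------------


def _edit_distance(a: str, b: str, k: int) -> int:
    """Levenshtein distance, capped: returns k+1 when distance > k."""
    if a == b:
        return 0
    res = edlib.align(a, b, task="distance", k=k)
    d = res["editDistance"]
    return d if d != -1 else k + 1


def denoise_d1(
    uniques: Sequence[Unique],
    fastidious: bool = True,
    boundary: int = 3,
) -> tuple[list[ESV], dict[str, str]]:
    """Single-linkage swarm clustering at d=1 with fastidious grafting.

    Clusters grow by chaining: starting from the most abundant unassigned
    unique, any unassigned unique at edit distance <= 1 (substitutions and
    single-base indels) from a cluster member joins the cluster.  With
    ``fastidious``, a cluster whose total abundance is below ``boundary``
    is grafted onto a large cluster when any of its members lies within
    edit distance <= 2 of a large-cluster member.  Each cluster's
    representative is its most abundant member (ties: lexicographically
    smallest sequence); cluster abundances are summed per sample.

    Returns the ESV list (sorted by total abundance desc, sequence asc)
    and a map from member sequence to representative ESV id.
    """
    uniques = sorted(uniques, key=lambda u: (-u.total, u.sequence))
    n = len(uniques)
    assigned = [False] * n
    clusters: list[list[int]] = []
    for seed in range(n):
        if assigned[seed]:
            continue
        members = [seed]
        assigned[seed] = True
        frontier = [seed]
        while frontier:
            new_frontier = []
            for m in frontier:
                for j in range(n):
                    if assigned[j]:
                        continue
                    if _edit_distance(uniques[m].sequence, uniques[j].sequence, 1) <= 1:
                        assigned[j] = True
                        members.append(j)
                        new_frontier.append(j)
            frontier = new_frontier
        clusters.append(members)

    if fastidious:
        totals = [sum(uniques[i].total for i in c) for c in clusters]
        large = [ci for ci, t in enumerate(totals) if t >= boundary]
        small = [ci for ci, t in enumerate(totals) if t < boundary]
        for ci in small:
            graft_target = None
            for li in large:
                for i in clusters[ci]:
                    for j in clusters[li]:
                        if _edit_distance(
                            uniques[i].sequence, uniques[j].sequence, 2
                        ) <= 2:
                            graft_target = li
                            break
                    if graft_target is not None:
                        break
                if graft_target is not None:
                    break
            if graft_target is not None:
                clusters[graft_target].extend(clusters[ci])
                clusters[ci] = []
        clusters = [c for c in clusters if c]

    esvs: list[ESV] = []
    membership: dict[str, str] = {}
    for members in clusters:
        rep = min(members, key=lambda i: (-uniques[i].total, uniques[i].sequence))
        abund: Counter = Counter()
        for i in members:
            abund.update(uniques[i].abundance_by_sample)
        esvs.append(ESV("", uniques[rep].sequence, dict(abund)))
        for i in members:
            membership[uniques[i].sequence] = uniques[rep].sequence
    esvs.sort(key=lambda e: (-e.total_abundance, e.sequence))
    seq_to_id = {}
    for k, esv in enumerate(esvs, start=1):
        esv.esv_id = f"esv_{k}"
        seq_to_id[esv.sequence] = esv.esv_id
    membership = {seq: seq_to_id[rep] for seq, rep in membership.items()}
    return esvs, membership


# ---------------------------------------------------------------------------
# Chimera removal (uchime3-style perfect two-parent criterion)
# ---------------------------------------------------------------------------


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def is_perfect_chimera(query: str, parents: Sequence[str]) -> bool:
    """True iff query == prefix(A) + suffix(B) for distinct parents A, B
    with a crossover point strictly inside the query."""
    L = len(query)
    lcp = [_common_prefix_len(query, p) for p in parents]
    lcs = [_common_suffix_len(query, p) for p in parents]
    for i, p_a in enumerate(parents):
        if lcp[i] == 0:
            continue
        for j, p_b in enumerate(parents):
            if i == j or lcs[j] == 0:
                continue
            # need 1 <= k <= L-1 with k <= lcp[i] and L-k <= lcs[j]
            if min(lcp[i], L - 1) + min(lcs[j], L - 1) >= L:
                return True
    return False


def detect_chimeras(
    esvs: Sequence[ESV],
    abundance_skew: float = 16.0,
) -> tuple[list[ESV], list[ESV]]:
    """Flag ESVs exactly reconstructable from two higher-abundance parents.

    ESVs are processed in decreasing abundance; candidate parents are the
    already-retained ESVs whose abundance is at least ``abundance_skew``
    times the query's.  Returns (retained, flagged).
    """
    ordered = sorted(esvs, key=lambda e: (-e.total_abundance, e.sequence))
    retained: list[ESV] = []
    flagged: list[ESV] = []
    for esv in ordered:
        parents = [
            r.sequence
            for r in retained
            if r.total_abundance >= abundance_skew * esv.total_abundance
        ]
        if len(parents) >= 2 and is_perfect_chimera(esv.sequence, parents):
            flagged.append(esv)
        else:
            retained.append(esv)
    return retained, flagged


# ---------------------------------------------------------------------------
# Numt filtering (stop codons, invertebrate mitochondrial code)
# ---------------------------------------------------------------------------


def has_stop_codon(
    sequence: str,
    frame_offset: int = 0,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> Optional[bool]:
    """Translate the forward frame; None if too short for one codon."""
    coding = sequence[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    if len(coding) < 3:
        return None
    protein = str(Seq(coding).translate(table=genetic_code))
    return "*" in protein


def filter_numts(
    esvs: Sequence[ESV],
    frame_offset: int = 0,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> tuple[list[ESV], list[ESV], Counter]:
    """Remove ESVs with an in-frame stop codon (likely numts/pseudogenes).

    Under the invertebrate mitochondrial code (table 5) AGA/AGG encode
    serine, so only genuine stops (TAA/TAG) disqualify a sequence.
    Sequences too short to hold a codon after the offset are removed with
    their own reason.
    """
    retained: list[ESV] = []
    removed: list[ESV] = []
    reasons: Counter = Counter()
    for esv in esvs:
        verdict = has_stop_codon(esv.sequence, frame_offset, genetic_code)
        if verdict is None:
            removed.append(esv)
            reasons["too_short_to_translate"] += 1
        elif verdict:
            removed.append(esv)
            reasons["stop_codon"] += 1
        else:
            retained.append(esv)
    return retained, removed, reasons


# ---------------------------------------------------------------------------
# Read-to-ESV mapping
# ---------------------------------------------------------------------------


def map_reads(
    reads: Iterable[QualityRead],
    esvs: Sequence[ESV],
    max_diffs: int = 1,
) -> tuple[pd.DataFrame, int]:
    """Assign each read to its closest ESV within ``max_diffs`` edits.

    Ties go to the higher-abundance ESV, then lexicographically smaller
    sequence.  Returns the rebuilt ESV x sample abundance table and the
    number of unmapped reads.
    """
    order = sorted(
        range(len(esvs)),
        key=lambda i: (-esvs[i].total_abundance, esvs[i].sequence),
    )
    table: dict[str, Counter] = {esv.esv_id: Counter() for esv in esvs}
    unmapped = 0
    exact = {esvs[i].sequence: esvs[i].esv_id for i in order[::-1]}
    for read in reads:
        seq = read.sequence.upper()
        hit = exact.get(seq)
        if hit is None:
            best_d, best_i = max_diffs + 1, None
            for i in order:
                d = _edit_distance(seq, esvs[i].sequence, max_diffs)
                if d < best_d:
                    best_d, best_i = d, i
                    if d == 0:
                        break
            if best_i is not None and best_d <= max_diffs:
                hit = esvs[best_i].esv_id
        if hit is None:
            unmapped += 1
        else:
            table[hit][read.sample] += 1
    samples = sorted({s for c in table.values() for s in c})
    df = pd.DataFrame(
        [[table[e.esv_id].get(s, 0) for s in samples] for e in esvs],
        index=[e.esv_id for e in esvs],
        columns=samples,
        dtype=int,
    )
    return df, unmapped
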