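"""Global-alignment taxonomic assignment with best-hit, LCA and 95% rules.

Each ESV is aligned globally (Needleman-Wunsch, affine gaps) against every
curated reference amplicon.  Hits at >= 90% identity are ranked by
(e-value asc, identity desc, bit score desc, gap openings asc, mismatches
asc); all hits tied on the full key are best hits.  If best hits disagree
taxonomically the lowest common ancestor becomes the assignment, and any
species-level assignment whose best identity is below 95% is set back to
genus.  Identity excludes terminal-gap columns (usearch-style).

Scoring constants (match +2, mismatch -4, gap open -10, extend -1) and
the Karlin-Altschul constants used to express raw scores as bit scores
and e-values are package defaults, all configurable; under global
alignment of near-equal-length sequences the e-value/bit-score ordering
is monotone in raw score, so the ranking criteria are well defined
whatever the constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import Align

from .refdb import ReferenceRecord
from .taxonomy import Lineage, lca

# Karlin-Altschul constants for bit-score / e-value conversion (recorded
# configuration values, not fitted to any dataset).
KA_LAMBDA = 0.625
KA_K = 0.41
DEFAULT_SEARCH_SPACE = 1e6


@dataclass(frozen=True)
class Hit:
    """One query-reference alignment in blast6-like terms."""

    esv_id: str
    ref_id: str
    identity: float
    mismatches: int
    gap_openings: int
    alignment_length: int
    bit_score: float
    e_value: float
    raw_score: float = 0.0

    def rank_key(self) -> tuple:
        return (
            self.e_value,
            -self.identity,
            -self.bit_score,
            self.gap_openings,
            self.mismatches,
        )


@dataclass
class TaxAssignment:
    """Final lineage for one ESV with assignment provenance."""

    esv_id: str
    lineage: Lineage
    best_identity: float
    n_best_hits: int
    demoted_from_species: bool = False

    @property
    def assigned(self) -> bool:
        return not self.lineage.is_empty()


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    query: str,
    subject: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    esv_id: str = "query",
    ref_id: str = "subject",
    search_space: float = DEFAULT_SEARCH_SPACE,
) -> Hit:
    """Optimal global alignment of two sequences, reported as a Hit.

    identity = matching columns / (alignment length - terminal-gap
    columns) * 100.  Gap openings count maximal gap runs anywhere in the
    alignment; mismatches count substitution columns.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    query = query.upper()
    subject = subject.upper()
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    aln = alignments[0]
    row_q, row_s = str(aln[0]), str(aln[1])
    L = len(row_q)

    # terminal gap columns: leading/trailing columns where either row is gapped
    start = 0
    while start < L and (row_q[start] == "-" or row_s[start] == "-"):
        start += 1
    end = L
    while end > start and (row_q[end - 1] == "-" or row_s[end - 1] == "-"):
        end -= 1

    matches = mismatches = 0
    gap_openings = 0
    in_gap_q = in_gap_s = False
    for i in range(L):
        cq, cs = row_q[i], row_s[i]
        if cq == "-":
            if not in_gap_q:
                gap_openings += 1
            in_gap_q = True
        else:
            in_gap_q = False
        if cs == "-":
            if not in_gap_s:
                gap_openings += 1
            in_gap_s = True
        else:
            in_gap_s = False
        if cq != "-" and cs != "-":
            if cq == cs:
                matches += 1
            else:
                mismatches += 1
    internal = max(end - start, 1)
    identity = 100.0 * matches / internal
    raw = float(aln.score)
    bits = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)
    e_value = search_space * 2.0 ** (-bits)
    return Hit(
        esv_id=esv_id,
        ref_id=ref_id,
        identity=identity,
        mismatches=mismatches,
        gap_openings=gap_openings,
        alignment_length=L,
        bit_score=bits,
        e_value=e_value,
        raw_score=raw,
    )


def search(
    esv_id: str,
    esv_sequence: str,
    refdb: Sequence[ReferenceRecord],
    min_identity: float = 90.0,
    max_hits: int = 5000,
    **align_kwargs,
) -> list[Hit]:
    """All references at >= min_identity, ranked, truncated to max_hits."""
    hits = []
    for ref in refdb:
        hit = global_align(
            esv_sequence, ref.sequence, esv_id=esv_id, ref_id=ref.seq_id, **align_kwargs
        )
        if hit.identity >= min_identity:
            hits.append(hit)
    hits.sort(key=lambda h: (h.rank_key(), h.ref_id))
    return hits[:max_hits]


def assign(
    hits: Sequence[Hit],
    lineages: Mapping[str, Lineage],
    species_threshold: float = 95.0,
    esv_id: Optional[str] = None,
) -> TaxAssignment:
    """Best-hit filtering, LCA of ties, and the 95% species threshold.

    ``lineages`` maps ref_id to a sanitized lineage.  An empty hit list
    yields an unassigned result (empty lineage).
    """
    if not hits:
        return TaxAssignment(esv_id or "", Lineage.empty(), 0.0, 0)
    eid = esv_id or hits[0].esv_id
    best_key = min(h.rank_key() for h in hits)
    best = [h for h in hits if h.rank_key() == best_key]
    lineage = lca(lineages[h.ref_id] for h in best)
    best_identity = max(h.identity for h in best)
    demoted = False
    if lineage.assignment_rank() == "species" and best_identity < species_threshold:
        lineage = lineage.truncate_to("genus")
        demoted = True
    return TaxAssignment(eid, lineage, best_identity, len(best), demoted)


def assign_all(
    esvs,
    refdb: Sequence[ReferenceRecord],
    min_identity: float = 90.0,
    species_threshold: float = 95.0,
    max_hits: int = 5000,
    **align_kwargs,
) -> list[TaxAssignment]:
    """Search + assign for every ESV against a curated amplicon database."""
    lineages = {r.seq_id: r.lineage for r in refdb}
    out = []
    for esv in esvs:
        hits = search(
            esv.esv_id, esv.sequence, refdb,
            min_identity=min_identity, max_hits=max_hits, **align_kwargs,
        )
        out.append(
            assign(hits, lineages, species_threshold=species_threshold, esv_id=esv.esv_id)
        )
    return out


def assignments_to_frame(assignments: Sequence[TaxAssignment]) -> pd.DataFrame:
    from .taxonomy import RANKS

    rows = []
    for a in assignments:
        rows.append(
            {
                "esv_id": a.esv_id,
                "rank": a.lineage.assignment_rank() or "unassigned",
                **{r: (a.lineage[r] or "") for r in RANKS},
                "best_identity": round(a.best_identity, 2),
                "n_best_hits": a.n_best_hits,
                "demoted": a.demoted_from_species,
            }
        )
    return pd.DataFrame(rows)
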