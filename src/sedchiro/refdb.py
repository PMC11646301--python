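"""Reference-database curation and in-silico PCR with degenerate primers.

A raw CO1 reference set (FASTA + lineage TSV) is curated — length filter,
internal-N filter, exact dereplication with LCA-merged lineages — and then
restricted to the amplicon a primer pair would produce: both strands are
scanned for the forward primer and the reverse complement of the reverse
primer, allowing a configurable mismatch budget, and the insert between
the primer sites is kept only if its length falls inside the expected
window.  Untrimmable records are discarded with a reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .taxonomy import Lineage, lca, sanitize_lineage

# IUPAC degenerate nucleotide codes plus inosine (I), which pairs with all
# four bases.  Values are frozensets of concrete bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    # inosine pairs universally; its complement is equivalent to N
    "I": "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot complement base {exc}") from exc


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC/inosine primer string with mismatch-counting semantics."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid codes {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())

    @property
    def length(self) -> int:
        return len(self.bases)

    def mismatches(self, window: str) -> int:
        return match_primer(window, self)


def match_primer(window: str, primer: DegeneratePrimer) -> int:
    """Count mismatches of ``window`` against a degenerate primer.

    A position matches at zero cost when the window base is in the primer
    character's allowed set.  An N in the window mismatches every primer
    character except N/I (whose allowed set contains all bases — but an
    ambiguous subject base is unknown, so it only gets a free pass where
    the primer accepts anything).
    """
    if len(window) != primer.length:
        raise ValueError(
            f"window length {len(window)} != primer length {primer.length}"
        )
    mm = 0
    for wb, pb in zip(window.upper(), primer.bases):
        allowed = IUPAC[pb]
        if wb == "N":
            if len(allowed) != 4:
                mm += 1
        elif wb not in allowed:
            mm += 1
    return mm


@dataclass(frozen=True)
class PrimerSet:
    """A named primer pair with its expected amplicon geometry.

    ``expected_amplicon_len`` is the full fragment including primers;
    ``expected_insert_len`` is the primer-trimmed length used by the
    in-silico PCR length window and the read quality filter.
    ``reading_frame_offset`` gives the insert's codon phase for the
    stop-codon numt screen.
    """

    name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    expected_amplicon_len: int
    expected_insert_len: int
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.reading_frame_offset not in (0, 1, 2):
            raise ValueError("reading_frame_offset must be 0, 1 or 2")
        implied = (
            self.expected_amplicon_len
            - self.forward.length
            - self.reverse.length
        )
        # allow a small declared discrepancy (the tolerance is the length
        # window used downstream), but catch gross inconsistencies
        if abs(implied - self.expected_insert_len) > 10:
            raise ValueError(
                f"primer set {self.name}: insert length {self.expected_insert_len}"
                f" inconsistent with amplicon arithmetic {implied}"
            )


#: Chironomidae-specific pair targeting a 181 bp CO1 fragment (139 bp insert).
CH_PRIMERS = PrimerSet(
    name="CH",
    forward=DegeneratePrimer("CH181F", "TAATYTTYTTYATRGTNATRCC"),
    reverse=DegeneratePrimer("CH181R", "CCNGTICCIGCHCCRTTTTC"),
    expected_amplicon_len=181,
    expected_insert_len=139,
    reading_frame_offset=0,
)

#: Freshwater-invertebrate universal pair, 254 bp fragment (205 bp insert).
FWH_PRIMERS = PrimerSet(
    name="FWH",
    forward=DegeneratePrimer("fwhF2", "GGDACWGGWTGAACWGTWTAYCCHCC"),
    reverse=DegeneratePrimer("fwhR2n", "GTRATWGCHCCDGCTARWACWGG"),
    expected_amplicon_len=254,
    expected_insert_len=205,
    reading_frame_offset=0,
)

PRIMER_SETS = {"CH": CH_PRIMERS, "FWH": FWH_PRIMERS}


@dataclass
class ReferenceRecord:
    """A reference sequence with its (possibly unsanitized) lineage."""

    seq_id: str
    sequence: str
    lineage: Lineage
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.seq_id}: empty sequence")


@dataclass
class RejectionLog:
    """Per-reason rejection counts plus (seq_id, reason) detail rows."""

    reasons: Counter = field(default_factory=Counter)
    details: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def reject(self, seq_id: str, reason: str) -> None:
        self.reasons[reason] += 1
        self.details.append((seq_id, reason))

    @property
    def total(self) -> int:
        return sum(self.reasons.values())


def curate_references(
    records: Iterable[ReferenceRecord],
    min_length: int = 200,
) -> tuple[list[ReferenceRecord], RejectionLog]:
    """Length/N filters plus exact dereplication with LCA-merged lineages.

    Terminal Ns are stripped before any test.  Exact duplicate sequences
    collapse into a single record whose lineage is the LCA of the merged
    records' sanitized lineages and whose id is the first seen.
    """
    log = RejectionLog()
    kept: list[ReferenceRecord] = []
    records = list(records)
    if not records:
        log.warnings.append("curate_references: empty input")
        return [], log
    for rec in records:
        seq = rec.sequence.strip("N")
        if len(seq) < min_length:
            log.reject(rec.seq_id, "too_short")
            continue
        if "N" in seq:
            log.reject(rec.seq_id, "internal_N")
            continue
        kept.append(ReferenceRecord(rec.seq_id, seq, rec.lineage, rec.source))

    by_seq: dict[str, list[ReferenceRecord]] = {}
    order: list[str] = []
    for rec in kept:
        if rec.sequence not in by_seq:
            order.append(rec.sequence)
        by_seq.setdefault(rec.sequence, []).append(rec)

    out: list[ReferenceRecord] = []
    for seq in order:
        group = by_seq[seq]
        merged_lineage = lca(sanitize_lineage(r.lineage) for r in group)
        if len(group) > 1:
            log.reasons["duplicate"] += len(group) - 1
            for dup in group[1:]:
                log.details.append((dup.seq_id, "duplicate"))
        out.append(
            ReferenceRecord(group[0].seq_id, seq, merged_lineage, group[0].source)
        )
    return out, log


@dataclass(frozen=True)
class AmpliconResult:
    """Outcome of in-silico PCR on one record."""

    seq_id: str
    insert: Optional[str]
    reason: Optional[str] = None
    strand: str = "+"

    @property
    def accepted(self) -> bool:
        return self.insert is not None


def _scan_primer(seq: str, primer: DegeneratePrimer, max_mismatch: int) -> list[int]:
    """All start positions where ``primer`` matches with ≤ max_mismatch."""
    hits = []
    L = primer.length
    for i in range(len(seq) - L + 1):
        if match_primer(seq[i : i + L], primer) <= max_mismatch:
            hits.append(i)
    return hits


def _match_revcomp_primer(window: str, primer: DegeneratePrimer) -> int:
    # mismatches of a window against the reverse complement of a primer ==
    # mismatches of the window's revcomp against the primer itself
    return match_primer(revcomp(window), primer)


def _pcr_one_strand(
    seq: str,
    primers: PrimerSet,
    max_mismatch: int,
    length_tolerance: int,
) -> tuple[Optional[str], Optional[str]]:
    """Return (insert, reason). Leftmost forward site, nearest qualifying
    reverse site downstream."""
    fwd_sites = _scan_primer(seq, primers.forward, max_mismatch)
    if not fwd_sites:
        return None, "no_forward"
    rlen = primers.reverse.length
    lo = primers.expected_insert_len - length_tolerance
    hi = primers.expected_insert_len + length_tolerance
    saw_reverse = False
    for f in fwd_sites:
        insert_start = f + primers.forward.length
        for r in range(insert_start, len(seq) - rlen + 1):
            window = seq[r : r + rlen]
            if _match_revcomp_primer(window, primers.reverse) <= max_mismatch:
                saw_reverse = True
                insert = seq[insert_start:r]
                if lo <= len(insert) <= hi:
                    return insert, None
        # leftmost forward site rule: do not fall through to later forward
        # sites unless this one had no reverse partner at all
        if saw_reverse:
            return None, "length_out_of_window"
    return None, "no_reverse"


def insilico_pcr(
    record: ReferenceRecord,
    primers: PrimerSet,
    max_mismatch: int = 1,
    length_tolerance: int = 10,
    log: Optional[RejectionLog] = None,
) -> AmpliconResult:
    """Extract the primer-defined insert from a reference sequence.

    Scans the plus strand, then the minus strand; if both yield a
    qualifying amplicon the plus-strand hit wins and a warning is logged.
    """
    seq = record.sequence.upper()
    plus, plus_reason = _pcr_one_strand(seq, primers, max_mismatch, length_tolerance)
    minus, minus_reason = _pcr_one_strand(
        revcomp(seq), primers, max_mismatch, length_tolerance
    )
    if plus is not None:
        if minus is not None and log is not None:
            log.warnings.append(
                f"{record.seq_id}: amplicon on both strands; keeping plus"
            )
        return AmpliconResult(record.seq_id, plus, strand="+")
    if minus is not None:
        return AmpliconResult(record.seq_id, minus, strand="-")
    reason = plus_reason if plus_reason != "no_forward" else (minus_reason or "no_forward")
    if log is not None:
        log.reject(record.seq_id, reason)
    return AmpliconResult(record.seq_id, None, reason=reason)


def build_amplicon_db(
    records: Iterable[ReferenceRecord],
    primers: PrimerSet,
    min_length: int = 200,
    max_mismatch: int = 1,
    length_tolerance: int = 10,
) -> tuple[list[ReferenceRecord], RejectionLog]:
    """Curate then restrict to primer-specific amplicon inserts.

    The returned records carry the trimmed insert as their sequence and
    the curated (sanitized, LCA-merged) lineage.
    """
    curated, log = curate_references(records, min_length=min_length)
    out = []
    for rec in curated:
        res = insilico_pcr(rec, primers, max_mismatch, length_tolerance, log=log)
        if res.accepted:
            out.append(ReferenceRecord(rec.seq_id, res.insert, rec.lineage, rec.source))
    return out, log
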