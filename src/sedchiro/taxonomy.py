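"""Ranked-lineage data model, uncertainty-word sanitization and LCA.

Taxonomic annotations of CO1 reference sequences are carried as fixed
seven-rank Linnaean lineages (kingdom .. species).  Reference databases
mined from GenBank/BOLD contain open-nomenclature names ("Tanytarsus sp.",
"Cladotanytarsus gr. mancus") that cannot be trusted at the rank they
occupy; :func:`sanitize_lineage` truncates such annotations back to the
last trustable rank.  When several equally good database hits disagree,
:func:`lca` resolves them to their lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Fixed rank list, highest to lowest.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Default open-nomenclature markers that invalidate a name (token-wise match).
DEFAULT_UNCERTAINTY_MARKERS: tuple[str, ...] = ("sp.", "aff.", "gr.", "var.")

_TRAILING_PUNCT = ".,;:"


def _norm(name: str) -> str:
    """Collapse internal whitespace and strip; used before any comparison."""
    return " ".join(name.split())


@dataclass(frozen=True)
class Lineage:
    """An ordered assignment over :data:`RANKS`; absent ranks are ``None``.

    Invariant: no internal gaps — if a rank is present, all higher ranks
    are present.  Species names are binomials whose first token equals the
    genus field.
    """

    names: tuple[Optional[str], ...]
    source_id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} ranks, got {len(self.names)}"
            )
        normed = tuple(
            _norm(n) if isinstance(n, str) and _norm(n) else None
            for n in self.names
        )
        object.__setattr__(self, "names", normed)
        seen_absent = False
        for name in normed:
            if name is None:
                seen_absent = True
            elif seen_absent:
                raise ValueError(f"internal gap in lineage {normed}")

    @classmethod
    def of(cls, source_id: Optional[str] = None, **ranks: Optional[str]) -> "Lineage":
        unknown = set(ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks: {sorted(unknown)}")
        return cls(tuple(ranks.get(r) for r in RANKS), source_id=source_id)

    @classmethod
    def empty(cls) -> "Lineage":
        return cls((None,) * len(RANKS))

    def __getitem__(self, rank: str) -> Optional[str]:
        return self.names[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        """Number of present ranks (leading prefix length)."""
        for i, name in enumerate(self.names):
            if name is None:
                return i
        return len(self.names)

    def assignment_rank(self) -> Optional[str]:
        """Deepest present rank name, or None for an empty lineage."""
        d = self.depth
        return RANKS[d - 1] if d else None

    def deepest_name(self) -> Optional[str]:
        d = self.depth
        return self.names[d - 1] if d else None

    def is_empty(self) -> bool:
        return self.depth == 0

    def truncate(self, depth: int) -> "Lineage":
        """Keep the first ``depth`` ranks, clearing everything below."""
        return Lineage(
            self.names[:depth] + (None,) * (len(RANKS) - depth),
            source_id=self.source_id,
        )

    def truncate_to(self, rank: str) -> "Lineage":
        return self.truncate(RANKS.index(rank) + 1)

    def as_dict(self) -> dict[str, Optional[str]]:
        return dict(zip(RANKS, self.names))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return ";".join(n or "" for n in self.names).rstrip(";")


def _name_has_marker(name: str, markers: Sequence[str]) -> bool:
    lowered = [m.lower() for m in markers]
    stripped = [m.rstrip(_TRAILING_PUNCT) for m in lowered]
    for token in name.split():
        t = token.lower()
        if t in lowered:
            return True
        # "sp." written as "sp," or bare "sp" at the end of a name
        if t.rstrip(_TRAILING_PUNCT) in stripped and t != t.rstrip(_TRAILING_PUNCT):
            return True
    return False


def sanitize_lineage(
    lineage: Lineage,
    uncertainty_markers: Sequence[str] = DEFAULT_UNCERTAINTY_MARKERS,
) -> Lineage:
    """Truncate a lineage at the shallowest rank bearing an uncertainty marker.

    Matching is whole-token and case-insensitive ("sp." matches the token
    "sp." but never "spinosa").  Every rank from the first marker-bearing
    one downwards is cleared, so the output ends at the last trustable
    rank; e.g. species "Cladotanytarsus gr. mancus" is reduced to the
    genus "Cladotanytarsus".
    """
    for i, name in enumerate(lineage.names):
        if name is None:
            break
        if _name_has_marker(name, uncertainty_markers):
            return lineage.truncate(i)
    return lineage


def lca(lineages: Iterable[Lineage]) -> Lineage:
    """Lowest common ancestor: the deepest rank-prefix shared by all inputs.

    Comparison is exact, case-sensitive string equality (names are
    whitespace-normalized on construction).  Disagreement at the top rank
    yields an empty lineage; an empty input collection is an error
    (no hits to combine).
    """
    lins = list(lineages)
    if not lins:
        raise ValueError("lca of an empty lineage collection")
    first = lins[0]
    depth = min(l.depth for l in lins)
    agree = 0
    for i in range(depth):
        if all(l.names[i] == first.names[i] for l in lins[1:]):
            agree = i + 1
        else:
            break
    return first.truncate(agree)


# ---------------------------------------------------------------------------
# Lineage TSV interface: seq_id + one column per rank, empty cell = absent.
# ---------------------------------------------------------------------------

LINEAGE_COLUMNS = ("seq_id",) + RANKS


def read_lineage_tsv(path) -> dict[str, Lineage]:
    """Read a lineage table keyed by ``seq_id``; empty cells are absent ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(LINEAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lineage TSV missing columns: {sorted(missing)}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        names = tuple(row[r] or None for r in RANKS)
        out[row["seq_id"]] = Lineage(names, source_id=row["seq_id"])
    return out


def write_lineage_tsv(lineages: dict[str, Lineage], path) -> None:
    rows = [
        {"seq_id": sid, **{r: (lin[r] or "") for r in RANKS}}
        for sid, lin in lineages.items()
    ]
    pd.DataFrame(rows, columns=list(LINEAGE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
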