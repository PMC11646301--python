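"""FASTA/FASTQ/TSV readers and writers.

Thin wrappers over Biopython's SeqIO that (a) carry Phred scores as
integer arrays, (b) speak the ``;size=N`` FASTA-header abundance dialect
used for dereplicated/denoised sequence sets, and (c) raise errors naming
the offending record on malformed input.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import ESV, QualityRead

_SIZE_RE = re.compile(r";size=(\d+)\b")


def read_fastq(path, sample: str = "") -> list[QualityRead]:
    """Phred+33 FASTQ to QualityRead list; malformed records raise."""
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                QualityRead(
                    rec.id,
                    str(rec.seq).upper(),
                    np.asarray(
                        rec.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                    sample=sample,
                )
            )
    except ValueError as exc:
        context = f" after record {reads[-1].read_id}" if reads else ""
        raise ValueError(f"malformed FASTQ {path}{context}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> list[tuple[str, str, int]]:
    """FASTA to (id, sequence, size) triples; size defaults to 1.

    The ``;size=N`` header dialect is parsed off the id.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        m = _SIZE_RE.search(header)
        size = int(m.group(1)) if m else 1
        seq_id = _SIZE_RE.sub("", header)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {seq_id} in {path}")
        out.append((seq_id, seq, size))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs; ids may already carry ;size=N."""
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n{seq}\n")


def write_esv_fasta(esvs: Sequence[ESV], path) -> None:
    write_fasta(
        ((f"{e.esv_id};size={e.total_abundance}", e.sequence) for e in esvs), path
    )


def read_esv_fasta(path) -> list[ESV]:
    return [
        ESV(seq_id, seq, {"pooled": size}) for seq_id, seq, size in read_fasta(path)
    ]


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
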