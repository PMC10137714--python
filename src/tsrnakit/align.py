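"""Read collapsing, filtering, and placement onto tRNA references.

Small-RNA reads are collapsed to distinct sequences with per-sample counts,
filtered (length window, N content, optional 3' adapter trimming), then
placed gap-free onto every mature and precursor tRNA reference. All
optimal-mismatch placements are reported; a read mapping to k places gets
weight 1/k so that weighted counts are conserved.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .reference import TRNAGeneModel


@dataclass
class CollapsedRead:
    read_id: str
    sequence: str
    count_per_sample: Dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> float:
        return float(sum(self.count_per_sample.values()))


@dataclass(frozen=True)
class FragmentAlignment:
    """Gap-free placement of a read on one gene, in mature or precursor space."""

    read_id: str
    gene_id: str
    space: str  # "mature" | "precursor"
    start: int  # 1-based closed
    end: int
    mismatches: int
    weight: float


def _sniff_format(path) -> str:
    p = Path(path)
    name = p.name[:-3] if p.name.endswith(".gz") else p.name
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def _open_maybe_gz(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def collapse_reads(sample_files: Mapping[str, object],
                   fmt: Optional[str] = None) -> List[CollapsedRead]:
    """Collapse FASTQ/FASTA files (one per sample) into distinct sequences.

    ``sample_files`` maps sample id -> path. The total collapsed count per
    sample equals the number of input reads in that sample's file.
    """
    table: Dict[str, Dict[str, float]] = {}
    for sample, path in sample_files.items():
        file_fmt = fmt or _sniff_format(path)
        with _open_maybe_gz(path) as handle:
            for i, rec in enumerate(SeqIO.parse(handle, file_fmt)):
                seq = str(rec.seq).upper().replace("U", "T")
                if not seq or any(c not in "ACGTN" for c in seq):
                    raise ValueError(
                        f"{path}: unreadable record #{i + 1} ({rec.id!r})")
                counts = table.setdefault(seq, {})
                counts[sample] = counts.get(sample, 0) + 1
    return collapse_sequences_from_table(table)


def collapse_sequences(per_sample: Mapping[str, Iterable[str]]
                       ) -> List[CollapsedRead]:
    """Collapse in-memory per-sample sequence iterables (simulator path)."""
    table: Dict[str, Dict[str, float]] = {}
    for sample, seqs in per_sample.items():
        for seq in seqs:
            counts = table.setdefault(seq.upper().replace("U", "T"), {})
            counts[sample] = counts.get(sample, 0) + 1
    return collapse_sequences_from_table(table)


def collapse_sequences_from_table(table: Mapping[str, Mapping[str, float]]
                                  ) -> List[CollapsedRead]:
    reads = []
    for i, seq in enumerate(sorted(table), start=1):
        reads.append(CollapsedRead(
            read_id=f"r{i:06d}", sequence=seq,
            count_per_sample=dict(table[seq])))
    return reads


def _trim_adapter3(seq: str, adapter: str, min_overlap: int = 8) -> str:
    """Trim the leftmost 3' occurrence of an adapter prefix (>= min_overlap nt)."""
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if adapter.startswith(tail) or tail == adapter[:len(tail)]:
            return seq[:i]
    return seq


def filter_reads(reads: Sequence[CollapsedRead], min_len: int = 15,
                 max_len: int = 45, max_n: int = 0,
                 adapter3: Optional[str] = None
                 ) -> Tuple[List[CollapsedRead], Dict[str, int]]:
    """Adapter-trim and length/N filter; returns (kept reads, removal report)."""
    report = {"input": len(reads), "adapter_trimmed": 0, "too_short": 0,
              "too_long": 0, "too_many_N": 0, "kept": 0}
    kept: List[CollapsedRead] = []
    for read in reads:
        seq = read.sequence
        if adapter3:
            trimmed = _trim_adapter3(seq, adapter3.upper().replace("U", "T"))
            if trimmed != seq:
                report["adapter_trimmed"] += 1
                seq = trimmed
        if len(seq) < min_len:
            report["too_short"] += 1
            continue
        if len(seq) > max_len:
            report["too_long"] += 1
            continue
        if seq.count("N") > max_n:
            report["too_many_N"] += 1
            continue
        kept.append(CollapsedRead(read.read_id, seq, dict(read.count_per_sample)))
        report["kept"] += 1
    return kept, report


def _scan(read: str, ref: str, max_mismatch: int) -> List[Tuple[int, int]]:
    """All (1-based start, mismatches) placements of read in ref, gap-free."""
    n, m = len(ref), len(read)
    out = []
    if m > n:
        return out
    if max_mismatch == 0 and "N" not in read:
        pos = ref.find(read)
        while pos != -1:
            out.append((pos + 1, 0))
            pos = ref.find(read, pos + 1)
        return out
    for off in range(n - m + 1):
        mm = 0
        for a, b in zip(read, ref[off:off + m]):
            if a != b:  # N never matches
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append((off + 1, mm))
    return out


def align_to_trna(reads: Sequence[CollapsedRead],
                  models: Sequence[TRNAGeneModel],
                  max_mismatch: int = 0
                  ) -> Tuple[List[FragmentAlignment], List[str]]:
    """Place every read on every reference, mature and precursor space.

    Keeps all placements achieving the minimal mismatch count for that read
    (across genes and spaces); precursor placements lying fully inside the
    mature region are suppressed in favour of the identical mature-space
    placement. Returns (alignments, unaligned read ids).
    """
    alignments: List[FragmentAlignment] = []
    unaligned: List[str] = []
    for read in reads:
        hits: List[Tuple[str, str, int, int, int]] = []
        for model in models:
            for start, mm in _scan(read.sequence, model.mature_seq, max_mismatch):
                hits.append((model.gene_id, "mature", start,
                             start + len(read.sequence) - 1, mm))
            for start, mm in _scan(read.sequence, model.precursor_seq,
                                   max_mismatch):
                end = start + len(read.sequence) - 1
                if end <= model.mature_end:
                    continue  # duplicate of the mature-space placement
                hits.append((model.gene_id, "precursor", start, end, mm))
        if not hits:
            unaligned.append(read.read_id)
            continue
        best = min(h[4] for h in hits)
        optimal = [h for h in hits if h[4] == best]
        w = 1.0 / len(optimal)
        for gene_id, space, start, end, mm in optimal:
            alignments.append(FragmentAlignment(
                read_id=read.read_id, gene_id=gene_id, space=space,
                start=start, end=end, mismatches=mm, weight=w))
    return alignments, unaligned


def alignments_to_table(alignments: Sequence[FragmentAlignment]):
    import pandas as pd

    return pd.DataFrame(
        [(a.read_id, a.gene_id, a.space, a.start, a.end, a.mismatches, a.weight)
         for a in alignments],
        columns=["read_id", "gene_id", "space", "start", "end", "mismatches",
                 "weight"])
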