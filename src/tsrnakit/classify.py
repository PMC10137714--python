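"""Nine-type tsRNA classification, record merging/naming, and landscape summaries.

The nine categories follow the cleavage-position scheme used for tRNA-derived
small RNAs:

* ``tRF-5a/5b/5c`` — 5'-anchored fragments ending in the D-loop, between the
  D-loop and the anticodon stem, or in the anticodon stem respectively;
* ``tiRNA-5`` — 5' halves, 30-36 nt, cleaved in/after the anticodon loop;
* ``i-tRF`` — fragments internal to the mature tRNA (and the bucket for
  anchored fragments outside every defined length window);
* ``tiRNA-3`` — 3' halves cleaved in the anticodon loop;
* ``tRF-3a/3b`` — 3'-anchored CCA fragments, <=20 nt vs longer;
* ``tRF-1`` — RNase Z products starting immediately after the mature 3' end
  on the precursor (trailer-derived).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import CollapsedRead, FragmentAlignment
from .reference import TRNAGeneModel


class TsRNAType(str, Enum):
    TRF_5A = "tRF-5a"
    TRF_5B = "tRF-5b"
    TRF_5C = "tRF-5c"
    TRF_3A = "tRF-3a"
    TRF_3B = "tRF-3b"
    TRF_1 = "tRF-1"
    I_TRF = "i-tRF"
    TIRNA_5 = "tiRNA-5"
    TIRNA_3 = "tiRNA-3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


NINE_TYPES: Tuple[TsRNAType, ...] = tuple(TsRNAType)

#: 5' anchor tolerance: a fragment starting at position <= 3 counts as
#: 5'-anchored (2 nt of 5'-end raggedness; the 30-nt lower bound of the
#: half-length window is only reachable with this allowance when the
#: anticodon loop starts at position 32).
ANCHOR5_MAX_START = 3
#: 3' anchor tolerance: end >= mature_end - 1.
ANCHOR3_SLACK = 1
#: Half (tiRNA) length window, nt.
HALF_LEN = (30, 36)
#: tRF-1 must start within this many nt after the mature 3' end.
TRF1_START_SLACK = 2
#: 5' anticodon stem length (nt) — the tRF-5b/tRF-5c boundary sits at the
#: stem start, 5 nt before the anticodon loop.
AC_STEM_LEN = 5
#: tRF-3a/3b length boundary, nt.
TRF3_LEN_SPLIT = 20


def classify_fragment(alignment: FragmentAlignment, model: TRNAGeneModel,
                      anchor5_max_start: int = ANCHOR5_MAX_START,
                      anchor3_slack: int = ANCHOR3_SLACK,
                      half_len: Tuple[int, int] = HALF_LEN) -> TsRNAType:
    """Deterministically assign one of the nine tsRNA types.

    The 5'-anchor rule takes precedence over the 3'-anchor rule so that
    near-full-length fragments are judged by their 5' cleavage position.
    Anchored fragments whose length falls outside every defined window
    (e.g. 5'-anchored, ending past the anticodon-loop start but longer than
    36 nt) drop into the i-tRF bucket.
    """
    lm = model.landmarks
    start, end = alignment.start, alignment.end
    length = end - start + 1
    if alignment.space == "precursor":
        if not (1 <= start and end <= lm.mature_end + len(model.trailer_seq)):
            raise ValueError(
                f"alignment {start}-{end} outside precursor of {model.gene_id}")
        if start > lm.mature_end:
            return TsRNAType.TRF_1
        return TsRNAType.I_TRF  # spans the RNase Z site; no canonical class
    if not (1 <= start <= end <= lm.mature_end):
        raise ValueError(
            f"alignment {start}-{end} outside mature {model.gene_id}")
    ac_lo, ac_hi = lm.anticodon_loop
    if start <= anchor5_max_start:  # 5'-anchored; precedence over 3' anchor
        if end >= ac_lo:
            if half_len[0] <= length <= half_len[1]:
                return TsRNAType.TIRNA_5
            return TsRNAType.I_TRF
        if end <= lm.d_loop[1]:
            return TsRNAType.TRF_5A
        if end < ac_lo - AC_STEM_LEN:
            return TsRNAType.TRF_5B
        return TsRNAType.TRF_5C
    if end >= lm.mature_end - anchor3_slack:  # 3'-anchored
        if ac_lo <= start <= ac_hi:
            return TsRNAType.TIRNA_3
        if start > ac_hi:
            return TsRNAType.TRF_3A if length <= TRF3_LEN_SPLIT else TsRNAType.TRF_3B
        return TsRNAType.I_TRF  # starts 5' of the loop yet reaches the 3' end
    return TsRNAType.I_TRF


@dataclass
class TsRNARecord:
    name: str
    type: TsRNAType
    sequence: str
    parents: Tuple[str, ...]
    origin: str  # cytosolic | mitochondrial
    source_space: str  # mature | precursor
    counts: Dict[str, float] = field(default_factory=dict)
    amino_acid: str = ""
    anticodon: str = ""
    flags: Tuple[str, ...] = ()

    @property
    def total_count(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def length(self) -> int:
        return len(self.sequence)


def merge_and_name(reads: Sequence[CollapsedRead],
                   alignments: Sequence[FragmentAlignment],
                   models: Sequence[TRNAGeneModel]) -> List[TsRNARecord]:
    """Merge aligned reads into named tsRNA records.

    One record per distinct sequence; parents are all genes carrying an
    optimal placement. The majority-weight type wins (ties broken by
    lexicographically first label, flagged). Names follow
    ``tRF-<AA>-<Anticodon>-<serial>`` / ``tiRNA-<AA>-<Anticodon>-<serial>``
    with zero-padded serials assigned within each (prefix, AA, anticodon)
    family in descending total-count order, then lexicographic sequence order.
    """
    by_gene = {m.gene_id: m for m in models}
    by_read: Dict[str, List[FragmentAlignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    read_by_id = {r.read_id: r for r in reads}

    drafts = []
    for read_id, alns in by_read.items():
        read = read_by_id[read_id]
        type_w: Dict[TsRNAType, float] = defaultdict(float)
        space_w: Dict[str, float] = defaultdict(float)
        parents = []
        for aln in alns:
            model = by_gene[aln.gene_id]
            type_w[classify_fragment(aln, model)] += aln.weight
            space_w[aln.space] += aln.weight
            parents.append(aln.gene_id)
        parents = tuple(sorted(set(parents)))
        flags: List[str] = []
        wmax = max(type_w.values())
        top = sorted(t for t, w in type_w.items() if w >= wmax - 1e-12)
        if len(top) > 1:
            flags.append("ambiguous_type")
        ts_type = min(top, key=lambda t: t.value)
        smax = max(space_w.values())
        space = sorted(s for s, w in space_w.items() if w >= smax - 1e-12)[0]

        parent_models = [by_gene[g] for g in parents]
        aa_ac = {(m.amino_acid, m.anticodon) for m in parent_models}
        if len(aa_ac) > 1:
            flags.append("ambiguous_parent_family")
            first = by_gene[parents[0]]
            aa, ac = first.amino_acid, first.anticodon
        else:
            (aa, ac), = aa_ac
        origins = {m.origin for m in parent_models}
        if origins == {"mitochondrial"}:
            origin = "mitochondrial"
        else:
            if len(origins) > 1:
                flags.append("mixed_origin")
            origin = "cytosolic"
        drafts.append(TsRNARecord(
            name="", type=ts_type, sequence=read.sequence, parents=parents,
            origin=origin, source_space=space,
            counts=dict(read.count_per_sample), amino_acid=aa, anticodon=ac,
            flags=tuple(flags)))

    # serials within each naming family, by descending count then sequence
    families: Dict[Tuple[str, str, str], List[TsRNARecord]] = defaultdict(list)
    for rec in drafts:
        prefix = "tiRNA" if rec.type in (TsRNAType.TIRNA_5, TsRNAType.TIRNA_3) \
            else "tRF"
        families[(prefix, rec.amino_acid, rec.anticodon)].append(rec)
    out: List[TsRNARecord] = []
    for (prefix, aa, ac), members in sorted(families.items()):
        members.sort(key=lambda r: (-r.total_count, r.sequence))
        for i, rec in enumerate(members, start=1):
            rec.name = f"{prefix}-{aa}-{ac}-{i:03d}"
            out.append(rec)
    return out


def records_to_table(records: Sequence[TsRNARecord]) -> pd.DataFrame:
    samples = sorted({s for r in records for s in r.counts})
    rows = []
    for r in records:
        row = {
            "name": r.name, "type": r.type.value, "sequence": r.sequence,
            "length": r.length, "parents": ",".join(r.parents),
            "amino_acid": r.amino_acid, "anticodon": r.anticodon,
            "origin": r.origin, "source_space": r.source_space,
            "flags": ",".join(r.flags),
        }
        for s in samples:
            row[s] = r.counts.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def count_matrix_from_records(records: Sequence[TsRNARecord]) -> pd.DataFrame:
    """Feature x sample count matrix keyed by tsRNA name."""
    samples = sorted({s for r in records for s in r.counts})
    data = {r.name: [r.counts.get(s, 0.0) for s in samples] for r in records}
    return pd.DataFrame.from_dict(data, orient="index", columns=samples)


def _portions(series: pd.Series) -> pd.Series:
    total = series.sum()
    return series / total * 100.0 if total > 0 else series * 0.0


def summarize_landscape(records: Sequence[TsRNARecord]) -> Dict[str, pd.DataFrame]:
    """Landscape summary tables (percentages).

    Because published tsRNA surveys mix "percent of distinct tsRNAs" with
    "percent of reads", every composition table is emitted in both bases.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_table(records)
    df["total"] = [r.total_count for r in records]

    def both(key: str) -> pd.DataFrame:
        distinct = _portions(df.groupby(key).size().astype(float))
        reads = _portions(df.groupby(key)["total"].sum())
        return pd.DataFrame({"pct_distinct": distinct, "pct_reads": reads}
                            ).fillna(0.0)

    type_tbl = both("type").reindex([t.value for t in NINE_TYPES]).fillna(0.0)
    length_hist = (
        df.groupby("length").agg(n_distinct=("name", "size"),
                                 n_reads=("total", "sum"))
        .reindex(range(15, 46), fill_value=0.0))
    return {
        "type_composition": type_tbl,
        "length_histogram": length_hist,
        "origin_split": both("origin"),
        "space_split": both("source_space"),
        "per_amino_acid": both("amino_acid").sort_values(
            "pct_distinct", ascending=False),
        "per_parent_family": _per_family(df),
    }


def _per_family(df: pd.DataFrame) -> pd.DataFrame:
    fam = df.assign(family="tRNA-" + df["amino_acid"] + "-" + df["anticodon"])
    distinct = _portions(fam.groupby("family").size().astype(float))
    reads = _portions(fam.groupby("family")["total"].sum())
    return (pd.DataFrame({"pct_distinct": distinct, "pct_reads": reads})
            .fillna(0.0).sort_values("pct_distinct", ascending=False))
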