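"""tRNA gene models with cloverleaf landmark coordinates.

A :class:`TRNAGeneModel` carries the mature tRNA sequence (intron removed,
CCA-terminated), the 3' trailer of the precursor transcript, and the loop
landmarks the fragment classifier keys on. Landmarks are **inputs** (one row
per gene in a TSV sidecar) rather than being predicted from sequence;
structure prediction is out of scope for this package.

Coordinate convention: 1-based closed intervals on the mature sequence.
Precursor coordinates extend the mature axis by the trailer, i.e. trailer
position 1 sits at ``mature_end + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = Tuple[int, int]

#: The 22 parental amino-acid labels carried by tRNA genes: the 20 standard
#: residues plus selenocysteine (Sec) and initiator methionine (iMet).
AMINO_ACIDS_22 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Sec", "iMet",
)

ORIGINS = ("cytosolic", "mitochondrial")

LANDMARK_COLUMNS = [
    "gene_id", "d_loop_start", "d_loop_end", "ac_loop_start", "ac_loop_end",
    "anticodon_start", "anticodon_end", "t_loop_start", "t_loop_end",
    "trailer_seq",
]


class ValidationError(ValueError):
    """A gene model violated a structural invariant."""


@dataclass(frozen=True)
class LandmarkSet:
    """Cloverleaf landmarks on mature-tRNA coordinates (1-based, closed)."""

    d_loop: Interval
    anticodon_loop: Interval
    anticodon: Interval
    t_loop: Interval
    mature_end: int

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("d_loop", self.d_loop),
            ("anticodon_loop", self.anticodon_loop),
            ("anticodon", self.anticodon),
            ("t_loop", self.t_loop),
        ):
            if not (1 <= lo <= hi <= self.mature_end):
                raise ValidationError(
                    f"{name} interval {lo}-{hi} outside [1, {self.mature_end}]"
                )
        if not self.d_loop[1] < self.anticodon_loop[0]:
            raise ValidationError("D-loop must end before the anticodon loop")
        if not (self.anticodon_loop[0] <= self.anticodon[0]
                and self.anticodon[1] <= self.anticodon_loop[1]):
            raise ValidationError("anticodon must lie inside the anticodon loop")
        if self.anticodon[1] - self.anticodon[0] + 1 != 3:
            raise ValidationError("anticodon landmark must span 3 nt")
        if not self.anticodon_loop[1] < self.t_loop[0]:
            raise ValidationError("anticodon loop must end before the T-loop")


@dataclass
class TRNAGeneModel:
    """One tRNA gene: mature/precursor sequences plus landmarks.

    ``mature_seq`` always ends in CCA; when the genomic copy lacks it, the
    trinucleotide is appended (post-transcriptional CCA addition) and
    ``cca_appended`` records the fact.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    origin: str
    gene_seq: str
    mature_seq: str
    trailer_seq: str
    landmarks: LandmarkSet
    intron_span: Optional[Interval] = None
    cca_appended: bool = False

    @property
    def precursor_seq(self) -> str:
        """Mature axis extended by the 3' trailer."""
        return self.mature_seq + self.trailer_seq

    @property
    def mature_end(self) -> int:
        return self.landmarks.mature_end

    def validate(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"{self.gene_id}: origin {self.origin!r} not in {ORIGINS}")
        if self.amino_acid not in AMINO_ACIDS_22:
            raise ValidationError(
                f"{self.gene_id}: unknown amino-acid label {self.amino_acid!r}")
        if not self.mature_seq.endswith("CCA"):
            raise ValidationError(f"{self.gene_id}: mature sequence lacks 3' CCA")
        if self.landmarks.mature_end != len(self.mature_seq):
            raise ValidationError(
                f"{self.gene_id}: mature_end {self.landmarks.mature_end} != "
                f"len(mature_seq) {len(self.mature_seq)}")
        self.landmarks.validate()
        lo, hi = self.landmarks.anticodon
        observed = self.mature_seq[lo - 1:hi]
        if observed != self.anticodon.upper().replace("U", "T"):
            raise ValidationError(
                f"{self.gene_id}: anticodon landmark reads {observed}, "
                f"declared {self.anticodon}")


def build_mature(gene_seq: str, intron_span: Optional[Interval] = None
                 ) -> Tuple[str, bool]:
    """Splice out the intron (if any) and guarantee a 3' CCA.

    Returns ``(mature_seq, cca_appended)``.
    """
    seq = gene_seq.upper().replace("U", "T")
    if intron_span is not None:
        lo, hi = intron_span
        if not (1 < lo <= hi < len(seq)):
            raise ValueError(
                f"intron span {lo}-{hi} not strictly inside gene of length {len(seq)}")
        seq = seq[:lo - 1] + seq[hi:]
    if seq.endswith("CCA"):
        return seq, False
    return seq + "CCA", True


def _fasta_header(model: TRNAGeneModel) -> str:
    return f"{model.gene_id}|{model.amino_acid}|{model.anticodon}|{model.origin}"


def write_trna_references(models: Sequence[TRNAGeneModel], fasta_path, table_path
                          ) -> None:
    """Write mature sequences as FASTA plus the landmark TSV sidecar."""
    records = [
        SeqRecord(Seq(m.mature_seq), id=_fasta_header(m), description="")
        for m in models
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for m in models:
        lm = m.landmarks
        rows.append({
            "gene_id": m.gene_id,
            "d_loop_start": lm.d_loop[0], "d_loop_end": lm.d_loop[1],
            "ac_loop_start": lm.anticodon_loop[0],
            "ac_loop_end": lm.anticodon_loop[1],
            "anticodon_start": lm.anticodon[0], "anticodon_end": lm.anticodon[1],
            "t_loop_start": lm.t_loop[0], "t_loop_end": lm.t_loop[1],
            "trailer_seq": m.trailer_seq,
        })
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(
        table_path, sep="\t", index=False)


def load_trna_references(fasta_path, landmark_table_path
                         ) -> Tuple[list[TRNAGeneModel], list[str]]:
    """Load gene models from FASTA + landmark table.

    FASTA headers follow ``>gene_id|amino_acid|anticodon|origin``; the mature
    sequence in the FASTA is taken as-is except that a missing 3' CCA is
    appended (and flagged). Returns ``(models, problems)`` where *problems*
    lists validation failures for genes that were loadable but invalid —
    failing genes are reported, never silently dropped. A missing landmark
    row is a hard error.
    """
    table = pd.read_csv(landmark_table_path, sep="\t", dtype={"gene_id": str})
    table = table.set_index("gene_id", drop=False)
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate landmark rows for: {dupes}")
    models: list[TRNAGeneModel] = []
    problems: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"FASTA header {rec.id!r} not of form gene_id|aa|anticodon|origin")
        gene_id, aa, anticodon, origin = parts
        if gene_id not in table.index:
            raise ValueError(f"no landmark row for gene {gene_id!r}")
        row = table.loc[gene_id]
        mature, appended = build_mature(str(rec.seq))
        trailer = row["trailer_seq"]
        trailer = "" if pd.isna(trailer) else str(trailer).upper()
        landmarks = LandmarkSet(
            d_loop=(int(row["d_loop_start"]), int(row["d_loop_end"])),
            anticodon_loop=(int(row["ac_loop_start"]), int(row["ac_loop_end"])),
            anticodon=(int(row["anticodon_start"]), int(row["anticodon_end"])),
            t_loop=(int(row["t_loop_start"]), int(row["t_loop_end"])),
            mature_end=len(mature),
        )
        model = TRNAGeneModel(
            gene_id=gene_id, amino_acid=aa, anticodon=anticodon, origin=origin,
            gene_seq=str(rec.seq).upper().replace("U", "T"),
            mature_seq=mature, trailer_seq=trailer, landmarks=landmarks,
            cca_appended=appended,
        )
        try:
            model.validate()
        except ValidationError as exc:
            problems.append(str(exc))
        models.append(model)
    return models, problems


_CANONICAL_SEED = 76427  # fixed so canonical_template() is deterministic


def canonical_template() -> TRNAGeneModel:
    """Deterministic 76-nt mature tRNA model with textbook landmarks.

    Standard tRNA numbering: D-loop 14-21, anticodon loop 32-38 (anticodon
    34-36), T-loop 54-60, 3' CCA at 74-76. The 16-nt precursor trailer ends
    in TTTT (pol III terminator read-through), so the RNase Z product window
    starts at precursor position 77.
    """
    rng = np.random.default_rng(_CANONICAL_SEED)
    body = list(rng.choice(list("ACGT"), size=73))
    anticodon = "GCC"  # glycine isoacceptor
    body[33:36] = list(anticodon)
    if body[-3:] == list("CCA"):
        body[-1] = "G"  # keep the 73-nt body + appended-CCA frame
    gene_seq = "".join(body)  # no genomic CCA: exercises the append rule
    mature, appended = build_mature(gene_seq)
    trailer = "".join(rng.choice(list("ACGT"), size=12)) + "TTTT"
    landmarks = LandmarkSet(
        d_loop=(14, 21), anticodon_loop=(32, 38), anticodon=(34, 36),
        t_loop=(54, 60), mature_end=76,
    )
    model = TRNAGeneModel(
        gene_id="tRNA-Gly-GCC-1-1", amino_acid="Gly", anticodon=anticodon,
        origin="cytosolic", gene_seq=gene_seq, mature_seq=mature,
        trailer_seq=trailer, landmarks=landmarks, cca_appended=appended,
    )
    model.validate()
    return model
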