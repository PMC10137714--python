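"""Amino-acid usage of CDS regions vs the parental-tRNA spectrum of tsRNAs.

Compares two proportion vectors on a shared amino-acid alphabet: (a) the
fraction of tsRNAs per parental-tRNA amino acid and (b) the amino-acid
usage of the coding regions of a gene set (e.g. differentially expressed
mRNAs), then reports their Pearson correlation.

Alphabet harmonization: codon translation can yield neither selenocysteine
nor a distinct initiator methionine, so the default comparison alphabet is
the 20 standard residues — parental iMet folds into Met, Sec-parented
records are excluded and the remaining fractions renormalized (the
exclusion is reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .classify import TsRNARecord
from .network import correlate

AA_20 = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
         "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp",
         "Tyr", "Val")

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclass
class AAUsageVector:
    labels: Tuple[str, ...]
    proportions: np.ndarray  # sums to 1
    basis_n: float  # codons or tsRNAs underlying the vector
    notes: Tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.labels))


def aa_usage_from_cds(cds: Mapping[str, str],
                      gene_subset: Optional[Iterable[str]] = None
                      ) -> AAUsageVector:
    """Pooled amino-acid usage over the CDS set (standard genetic code).

    Each gene counts once (unweighted pooling); stop codons are excluded;
    CDS lengths not divisible by 3 are trimmed with a note. ``cds`` maps
    gene id -> DNA sequence (load FASTA via :func:`read_fasta_dict`).
    """
    genes = sorted(gene_subset) if gene_subset is not None else sorted(cds)
    if not genes:
        raise ValueError("empty gene subset")
    counts = {aa: 0 for aa in AA_20}
    notes = []
    n_codons = 0
    for gene in genes:
        if gene not in cds:
            raise KeyError(f"no CDS for gene {gene!r}")
        seq = cds[gene].upper().replace("U", "T")
        if len(seq) % 3:
            notes.append(f"{gene}: length {len(seq)} trimmed to codon multiple")
            seq = seq[:len(seq) - len(seq) % 3]
        protein = str(Seq(seq).translate())
        for aa1 in protein:
            if aa1 == "*":
                continue
            aa3 = _ONE_TO_THREE.get(aa1)
            if aa3 is None:
                notes.append(f"{gene}: ambiguous residue {aa1!r} skipped")
                continue
            counts[aa3] += 1
            n_codons += 1
    if n_codons == 0:
        raise ValueError("no coding codons in subset")
    props = np.array([counts[aa] / n_codons for aa in AA_20])
    return AAUsageVector(AA_20, props, n_codons, tuple(notes))


def tsrna_parental_aa(records: Sequence[TsRNARecord], basis: str = "distinct",
                      parent_aa: Optional[Mapping[str, str]] = None
                      ) -> AAUsageVector:
    """Proportion of tsRNAs per parental amino acid on the 20-AA alphabet.

    ``basis`` is "distinct" (each tsRNA counts once) or "reads"
    (count-weighted). Multi-parent records with conflicting amino acids
    split fractionally across their parents' labels (requires
    ``parent_aa``: gene id -> amino acid; otherwise the record's own label
    is used). iMet folds into Met; Sec mass is excluded and renormalized.
    """
    if basis not in ("distinct", "reads"):
        raise ValueError("basis must be 'distinct' or 'reads'")
    mass = {aa: 0.0 for aa in AA_20}
    excluded_sec = 0.0
    total = 0.0
    for rec in records:
        w = 1.0 if basis == "distinct" else rec.total_count
        if parent_aa is not None:
            labels = [parent_aa[p] for p in rec.parents]
        else:
            labels = [rec.amino_acid]
        share = w / len(labels)
        for aa in labels:
            aa = "Met" if aa == "iMet" else aa
            total += share
            if aa == "Sec":
                excluded_sec += share
            else:
                mass[aa] += share
    kept = total - excluded_sec
    if kept <= 0:
        raise ValueError("all tsRNA mass excluded (Sec-only input)")
    props = np.array([mass[aa] / kept for aa in AA_20])
    notes = ()
    if excluded_sec:
        notes = (f"excluded Sec mass: {excluded_sec:g} of {total:g}",)
    return AAUsageVector(AA_20, props, kept, notes)


def aa_correlation(v1: AAUsageVector, v2: AAUsageVector
                   ) -> Tuple[float, float]:
    """Pearson R (with two-sided p) between two usage vectors."""
    if v1.labels != v2.labels:
        raise ValueError("amino-acid alphabets differ")
    r, p, defined = correlate(v1.proportions, v2.proportions)
    if not defined:
        raise ValueError("constant usage vector: correlation undefined")
    return r, p


def read_fasta_dict(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
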