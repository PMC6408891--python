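"""Codon alignments: protein-guided back-translation and cleaning.

A :class:`CodonAlignment` holds gapped coding sequences of equal length
divisible by 3, with gaps in whole-codon units and no internal stop codons.
``back_translate`` threads unaligned CDS through a gapped protein alignment
(each residue becomes its codon, each gap a ``---``), so downstream codon
models see exactly the columns the protein aligner chose.

``clean_alignment`` mirrors the residue/sequence-overlap filtering used to
drop uninformative columns and sequences before model fitting: codon
columns with too few residues are removed, then sequences whose residues
rarely overlap the rest of the alignment are erased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .genetic_code import GAP_CODON, STOP_CODONS, translate_codon

__all__ = [
    "CodonAlignment",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "back_translate",
    "clean_alignment",
]


class AlignmentError(ValueError):
    """Inconsistent sequences or an alignment emptied by filtering."""


@dataclass
class CodonAlignment:
    """Aligned coding sequences keyed by gene id.

    ``column_map`` maps each codon column to the protein-alignment column it
    came from (identity when the alignment was not derived from a protein
    alignment).
    """

    ids: list[str]
    sequences: dict[str, str]
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("empty alignment")
        lengths = {len(self.sequences[i]) for i in self.ids}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (L,) = lengths
        if L % 3 != 0:
            raise AlignmentError(f"alignment length {L} not divisible by 3")
        if not self.column_map:
            self.column_map = list(range(L // 3))
        for gid in self.ids:
            seq = self.sequences[gid].upper()
            self.sequences[gid] = seq
            for c in range(0, L, 3):
                codon = seq[c : c + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise AlignmentError(
                        f"{gid}: partial-codon gap {codon!r} at codon {c // 3 + 1}"
                    )
                if codon in STOP_CODONS and c + 3 < len(seq.rstrip("-").rstrip()):
                    raise AlignmentError(
                        f"{gid}: internal stop codon {codon} at codon {c // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[self.ids[0]]) // 3

    def codon(self, gid: str, col: int) -> str:
        return self.sequences[gid][3 * col : 3 * col + 3]

    def ungapped(self, gid: str) -> str:
        return self.sequences[gid].replace("-", "")

    def subset(self, keep_ids=None, keep_cols=None) -> "CodonAlignment":
        ids = [i for i in self.ids if keep_ids is None or i in set(keep_ids)]
        cols = list(range(self.n_codons)) if keep_cols is None else list(keep_cols)
        if not ids or not cols:
            raise AlignmentError("filtering removed every sequence or column")
        seqs = {
            gid: "".join(self.codon(gid, c) for c in cols) for gid in ids
        }
        return CodonAlignment(ids, seqs, [self.column_map[c] for c in cols])


def read_fasta(path: str) -> dict[str, str]:
    """Ordered id -> sequence map from a FASTA file."""
    records = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_phylip(aln: CodonAlignment, path: str) -> None:
    """Sequential PHYLIP, for interoperability with codeml-style tooling."""
    L = aln.n_codons * 3
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {L}\n")
        for gid in aln.ids:
            fh.write(f"{gid}  {aln.sequences[gid]}\n")


def back_translate(
    protein_alignment: dict[str, str], cds: dict[str, str]
) -> CodonAlignment:
    """Convert a gapped protein alignment to the codon alignment of its
    coding sequences.

    Each amino acid is replaced by its source codon, each protein gap by
    ``---``; ungapping the output reproduces the input CDS exactly. A
    terminal stop codon on the CDS is tolerated and stripped. Mismatched
    lengths, internal stops and codon/residue disagreements raise per-gene
    errors naming the offending position.
    """
    missing = [g for g in protein_alignment if g not in cds]
    if missing:
        raise AlignmentError(f"no CDS for: {missing}")

    out: dict[str, str] = {}
    for gid, prot in protein_alignment.items():
        dna = cds[gid].upper().replace("U", "T")
        if len(dna) % 3 != 0:
            raise AlignmentError(f"{gid}: CDS length {len(dna)} not divisible by 3")
        if len(dna) >= 3 and dna[-3:] in STOP_CODONS:
            dna = dna[:-3]
        residues = prot.replace("-", "")
        if len(residues) * 3 != len(dna):
            raise AlignmentError(
                f"{gid}: protein length {len(residues)} x3 != CDS length {len(dna)}"
            )
        codons, k = [], 0
        for pos, aa in enumerate(prot.upper(), start=1):
            if aa == "-":
                codons.append(GAP_CODON)
                continue
            codon = dna[3 * k : 3 * k + 3]
            k += 1
            trans = translate_codon(codon)
            if trans == "*":
                raise AlignmentError(
                    f"{gid}: internal stop codon {codon} at codon {k}"
                )
            if aa not in ("X", trans) and trans != "X":
                raise AlignmentError(
                    f"{gid}: codon {codon} (= {trans}) does not encode {aa} at "
                    f"alignment column {pos}"
                )
            codons.append(codon)
        out[gid] = "".join(codons)
    return CodonAlignment(list(protein_alignment), out)


def clean_alignment(
    aln: CodonAlignment,
    gap_threshold: float = 0.25,
    res_overlap: float = 0.25,
    seq_overlap: float = 0.90,
) -> CodonAlignment:
    """Drop gap-dominated codon columns, then poorly overlapping sequences.

    Column pass: a codon column is kept when the fraction of sequences with
    a residue (non-gap codon) there is >= ``gap_threshold``.

    Sequence pass: a residue is *well overlapped* when at least
    ``res_overlap`` of the other sequences also hold a residue in its
    column; a sequence is kept when its well-overlapped residues cover at
    least ``seq_overlap`` of the alignment columns — so mostly-gap
    sequences, which cannot inform the model, are erased.

    Raises :class:`AlignmentError` if nothing survives.
    """
    n_seq = len(aln.ids)
    n_col = aln.n_codons
    present = [
        [aln.codon(gid, c) != GAP_CODON for c in range(n_col)] for gid in aln.ids
    ]

    keep_cols = [
        c
        for c in range(n_col)
        if sum(present[s][c] for s in range(n_seq)) / n_seq >= gap_threshold
    ]
    if not keep_cols:
        raise AlignmentError("column filtering removed every codon column")

    keep_ids = []
    for s, gid in enumerate(aln.ids):
        good = 0
        for c in keep_cols:
            if not present[s][c]:
                continue
            others = sum(present[t][c] for t in range(n_seq)) - 1
            if n_seq == 1 or others / (n_seq - 1) >= res_overlap:
                good += 1
        if good / len(keep_cols) >= seq_overlap:
            keep_ids.append(gid)
    if not keep_ids:
        raise AlignmentError("sequence filtering removed every sequence")
    return aln.subset(keep_ids=keep_ids, keep_cols=keep_cols)
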