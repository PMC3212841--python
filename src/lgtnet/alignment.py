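"""Alignment containers, FASTA I/O, block trimming and reverse translation.

Alignments are kept as plain per-strain strings plus a ``column_map`` that
records, for every current column, its coordinate in the original (untrimmed)
alignment — so positions inferred downstream (e.g. recombination breakpoints)
can always be reported in original coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class Alignment:
    """A multiple alignment keyed by strain identifier.

    ``column_map[i]`` is the 0-based coordinate of current column ``i`` in the
    original alignment; identity when no trimming has occurred.
    """

    sequences: dict
    column_map: np.ndarray = field(default=None)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.column_map is None:
            self.column_map = np.arange(self.length)
        else:
            self.column_map = np.asarray(self.column_map)
            if len(self.column_map) != self.length:
                raise ValueError("column_map length mismatch")

    @property
    def names(self) -> list:
        return list(self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        """(n_sequences, length) array of single-byte characters."""
        return np.array([list(s) for s in self.sequences.values()], dtype="U1")

    def take_columns(self, idx) -> "Alignment":
        idx = np.asarray(idx, dtype=int)
        seqs = {k: "".join(np.array(list(v), dtype="U1")[idx])
                for k, v in self.sequences.items()}
        return Alignment(seqs, column_map=self.column_map[idx])


# ``NucAlignment`` is the same container; the name documents intent at call
# sites that require nucleotide data.
NucAlignment = Alignment


def read_fasta(path) -> Alignment:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return Alignment(seqs)


def write_fasta(aln: Alignment, path) -> None:
    recs = [SeqRecord(Seq(s), id=k, description="")
            for k, s in aln.sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def trim_alignment_blocks(aln: Alignment,
                          min_conserved_frac: float = 0.5,
                          min_flank_frac: float = 0.5,
                          max_nonconserved_run: int = 50,
                          min_block_len: int = 5,
                          allow_all_gaps: bool = True) -> Alignment:
    """Remove ambiguously aligned regions, Gblocks-style.

    A column is *conserved* when its most frequent residue is shared by more
    than ``min_conserved_frac`` of the sequences (the count threshold is
    ``floor(n * frac) + 1``, i.e. the relaxed (n/2)+1 rule at the default).
    Runs of more than ``max_nonconserved_run`` contiguous non-conserved
    columns are removed; surviving blocks are trimmed back to flank-quality
    columns at both ends and dropped entirely when shorter than
    ``min_block_len``.  With ``allow_all_gaps=False`` any gapped column is
    rejected outright.

    Returns the concatenated retained blocks; the result's ``column_map``
    gives the original coordinate of each kept column.
    """
    if aln.length == 0:
        raise ValueError("empty alignment")
    n = aln.n_sequences
    mat = aln.matrix()
    cons_count = int(np.floor(n * min_conserved_frac)) + 1
    flank_count = int(np.floor(n * min_flank_frac)) + 1

    L = aln.length
    conserved = np.zeros(L, dtype=bool)
    flank = np.zeros(L, dtype=bool)
    rejected = np.zeros(L, dtype=bool)
    for j in range(L):
        col = mat[:, j]
        has_gap = np.any(col == GAP)
        if has_gap and not allow_all_gaps:
            rejected[j] = True
            continue
        vals, counts = np.unique(col[col != GAP], return_counts=True)
        top = counts.max() if counts.size else 0
        conserved[j] = top >= cons_count
        flank[j] = top >= flank_count

    # remove over-long non-conserved stretches
    j = 0
    while j < L:
        if conserved[j] or rejected[j]:
            j += 1
            continue
        k = j
        while k < L and not conserved[k] and not rejected[k]:
            k += 1
        if k - j > max_nonconserved_run:
            rejected[j:k] = True
        j = k

    keep = np.zeros(L, dtype=bool)
    j = 0
    while j < L:
        if rejected[j]:
            j += 1
            continue
        k = j
        while k < L and not rejected[k]:
            k += 1
        # trim block ends to flank-quality columns
        lo, hi = j, k - 1
        while lo <= hi and not flank[lo]:
            lo += 1
        while hi >= lo and not flank[hi]:
            hi -= 1
        if lo <= hi and (hi - lo + 1) >= min_block_len:
            keep[lo:hi + 1] = True
        j = k

    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("no alignment columns retained after block trimming")
        return Alignment({k: "" for k in aln.sequences},
                         column_map=np.array([], dtype=int))
    return aln.take_columns(idx)


def reverse_translate(protein_aln: Alignment, cds_sequences: dict) -> Alignment:
    """Map a protein alignment onto codons using each strain's CDS.

    Each CDS must translate (standard code; an optional trailing stop codon
    is allowed) to its ungapped aligned protein; mismatches raise with the
    sequence name and the offending amino-acid position.
    """
    out = {}
    for name, prot in protein_aln.sequences.items():
        if name not in cds_sequences:
            raise ValueError(f"no CDS provided for sequence {name!r}")
        cds = cds_sequences[name].upper().replace("U", "T")
        residues = prot.replace(GAP, "")
        if len(cds) == 3 * (len(residues) + 1) and \
                str(Seq(cds[-3:]).translate()) == "*":
            cds = cds[:-3]
        if len(cds) != 3 * len(residues):
            raise ValueError(
                f"{name}: CDS length {len(cds)} does not match "
                f"{len(residues)} aligned residues")
        translated = str(Seq(cds).translate())
        for i, (a, b) in enumerate(zip(translated, residues)):
            if a != b and b != "X":
                raise ValueError(
                    f"{name}: CDS translates to {a!r} but alignment has "
                    f"{b!r} at residue position {i + 1}")
        codons = [cds[3 * i:3 * i + 3] for i in range(len(residues))]
        it = iter(codons)
        out[name] = "".join("---" if aa == GAP else next(it) for aa in prot)
    pmap = protein_aln.column_map
    column_map = np.repeat(pmap * 3, 3) + np.tile([0, 1, 2], len(pmap))
    return Alignment(out, column_map=column_map)


def translate_alignment(nuc_aln: Alignment) -> Alignment:
    """Codon-wise translation; '---' becomes '-'. Inverse of reverse_translate."""
    if nuc_aln.length % 3:
        raise ValueError("alignment length not divisible by 3")
    out = {}
    for name, seq in nuc_aln.sequences.items():
        aas = []
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            aas.append(GAP if codon == "---" else str(Seq(codon).translate()))
        out[name] = "".join(aas)
    return Alignment(out, column_map=nuc_aln.column_map[::3] // 3)
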