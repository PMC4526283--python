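"""Locating starting kmers by six-frame peptide-kmer hashing.

Every overlapping peptide kmer of the aligned reference proteins is stored
in one hash shared by all target genes, keyed to the model column where the
window begins.  Reads are then translated in all six frames in a single
pass; an exact peptide hit anchors a read substring (re-oriented to the
coding strand) at known consecutive match columns, which is where assembly
starts.  Reference sets may be larger and looser than the HMM seed
alignments; multiple references per gene are welcome and never weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .io_formats import GAP_CHARS, MultipleAlignment, SequenceRecord
from .kmer_graph import ConfigurationError, reverse_complement, translate
from .profile_hmm import match_columns


@dataclass(frozen=True)
class StartingKmer:
    """A read-derived nucleotide kmer anchored to model match columns."""

    nt_kmer: str
    gene: str
    model_column_first: int
    model_column_last: int
    frame: int  # +1, +2, +3, -1, -2, -3
    read_id: str


class ReferenceKmerMap:
    """Hash from peptide kmer to the (gene, model column) pairs it starts."""

    def __init__(self, peptide_k: int):
        if peptide_k < 1:
            raise ConfigurationError("peptide_k must be >= 1")
        self.peptide_k = peptide_k
        self.entries: dict[str, set[tuple[str, int]]] = {}
        self.model_length: dict[str, int] = {}

    def add(self, peptide: str, gene: str, column: int) -> None:
        self.entries.setdefault(peptide, set()).add((gene, column))

    def get(self, peptide: str) -> Optional[set[tuple[str, int]]]:
        return self.entries.get(peptide)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.entries


def build_reference_kmer_map(
    refs: dict[str, MultipleAlignment],
    peptide_k: int,
    match_cols: Optional[dict[str, list[int]]] = None,
    expected_length: Optional[dict[str, int]] = None,
    symfrac: float = 0.5,
) -> ReferenceKmerMap:
    """Index every reference window of ``peptide_k`` consecutive residues.

    A window is indexed only when its residues are adjacent in the ungapped
    sequence and occupy consecutive match columns: windows spanning an
    insert column, or interrupted by a deletion, are skipped.  ``match_cols``
    may pin the match-column set per gene (0-based alignment columns);
    otherwise it is derived from the reference alignment with the same
    gap-fraction rule used for model building.
    """
    refmap = ReferenceKmerMap(peptide_k)
    for gene in sorted(refs):
        aln = refs[gene]
        mcols = (match_cols or {}).get(gene)
        if mcols is None:
            mcols = match_columns(aln, symfrac)
        L = len(mcols)
        if expected_length is not None and gene in expected_length:
            if L != expected_length[gene]:
                raise ConfigurationError(
                    f"gene {gene!r}: reference alignment implies {L} match "
                    f"columns but the model has {expected_length[gene]}"
                )
        col_to_j = {c: j + 1 for j, c in enumerate(mcols)}
        refmap.model_length[gene] = L
        for rec in aln.records:
            residues = rec.residues.upper()
            # (model column or None, residue) for each non-gap residue in order
            occupied = [
                (col_to_j.get(c), ch)
                for c, ch in enumerate(residues)
                if ch not in GAP_CHARS
            ]
            for i in range(len(occupied) - peptide_k + 1):
                window = occupied[i : i + peptide_k]
                first_j = window[0][0]
                if first_j is None:
                    continue
                if any(
                    j is None or j != first_j + offset
                    for offset, (j, _) in enumerate(window)
                ):
                    continue
                peptide = "".join(ch for _, ch in window)
                refmap.add(peptide, gene, first_j)
    return refmap


def find_starting_kmers(
    reads: Iterable[SequenceRecord],
    refmap: ReferenceKmerMap,
    nucleotide_k: int,
) -> set[StartingKmer]:
    """Scan reads in all six frames for exact peptide-kmer hits.

    The returned nucleotide kmers are re-oriented to the coding strand, so a
    read and its reverse complement yield identical starting kmers.  One
    :class:`StartingKmer` is emitted per (gene, model position) a peptide
    maps to; results are deduplicated on (kmer, gene, first column).  The
    pass is single regardless of how many genes share the map.
    """
    if nucleotide_k != 3 * refmap.peptide_k:
        raise ConfigurationError(
            f"nucleotide k {nucleotide_k} must be 3 x peptide k {refmap.peptide_k}"
        )
    pk = refmap.peptide_k
    found: dict[tuple[str, str, int], StartingKmer] = {}
    for read in reads:
        seq = read.residues.upper()
        for sense, oriented in ((1, seq), (-1, reverse_complement(seq))):
            for offset in range(3):
                protein = translate(oriented[offset:])
                for i in range(len(protein) - pk + 1):
                    peptide = protein[i : i + pk]
                    if "*" in peptide or "X" in peptide:
                        continue
                    hits = refmap.get(peptide)
                    if not hits:
                        continue
                    start = offset + 3 * i
                    nt = oriented[start : start + nucleotide_k]
                    if any(ch not in "ACGT" for ch in nt):
                        continue
                    for gene, column in hits:
                        key = (nt, gene, column)
                        if key not in found:
                            found[key] = StartingKmer(
                                nt_kmer=nt,
                                gene=gene,
                                model_column_first=column,
                                model_column_last=column + pk - 1,
                                frame=sense * (offset + 1),
                                read_id=read.id,
                            )
    return set(found.values())
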