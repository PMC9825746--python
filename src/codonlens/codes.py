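"""Genetic-code tables, codon indexing and six-frame translation.

A genetic code is a 64-entry table assigning each codon a meaning: one of
the 20 amino-acid letters, ``*`` for a translation stop, or ``?`` for an
uninferred codon.  Codons are indexed lexicographically with base order
A < C < G < T, so ``AAA`` is index 0 and ``TTT`` is index 63.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Data import CodonTable as _NCBICodonTable

from .errors import InvalidCodeError, InvalidCodonError, InvalidSequenceError

#: Canonical HMMER amino-acid alphabet order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Symbols a genetic-code table may contain.
CODE_SYMBOLS = frozenset(AA_ALPHABET) | {"*", "?"}

BASES = "ACGT"

#: All 64 codons in canonical (lexicographic) order.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=3)
)

_CODON_TO_INDEX = {c: i for i, c in enumerate(CODONS)}

#: IUPAC nucleotide codes accepted on input ('U' is normalised to 'T').
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


def codon_index(codon: str) -> int:
    """Return the canonical 0..63 index of a three-base DNA codon.

    Raises :class:`InvalidCodonError` for anything but three unambiguous
    A/C/G/T characters.
    """
    idx = _CODON_TO_INDEX.get(codon.upper())
    if idx is None:
        raise InvalidCodonError(
            f"not an unambiguous DNA codon: {codon!r}"
        )
    return idx


def codon_from_index(index: int) -> str:
    """Inverse of :func:`codon_index`."""
    if not 0 <= index <= 63:
        raise InvalidCodonError(f"codon index out of range: {index}")
    return CODONS[index]


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon meaning table in canonical codon order."""

    name: str
    table: str

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise InvalidCodeError(
                f"code {self.name!r}: table has {len(self.table)} entries, need 64"
            )
        bad = set(self.table) - CODE_SYMBOLS
        if bad:
            raise InvalidCodeError(
                f"code {self.name!r}: invalid symbols {sorted(bad)!r}"
            )

    def __getitem__(self, codon: str) -> str:
        return self.table[codon_index(codon)]

    def translate_codon(self, codon: str) -> str:
        """Meaning of ``codon``; 'X' if it contains a non-ACGT base."""
        idx = _CODON_TO_INDEX.get(codon)
        return "X" if idx is None else self.table[idx]

    def with_codon(self, codon: str, meaning: str) -> "GeneticCode":
        """A copy of this code with one codon's meaning replaced."""
        i = codon_index(codon)
        return GeneticCode(
            name=f"{self.name}[{codon}->{meaning}]",
            table=self.table[:i] + meaning + self.table[i + 1:],
        )

    def synonyms(self, amino_acid: str) -> list[str]:
        """All codons whose meaning is ``amino_acid`` under this code."""
        return [c for c, m in zip(CODONS, self.table) if m == amino_acid]


def ncbi_table(table_id: int) -> GeneticCode:
    """NCBI translation table ``table_id`` (1..33) as a :class:`GeneticCode`."""
    try:
        tbl = _NCBICodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise InvalidCodeError(f"no NCBI translation table {table_id}") from None
    meanings = []
    for codon in CODONS:
        if codon in tbl.stop_codons:
            meanings.append("*")
        else:
            meanings.append(tbl.forward_table[codon])
    return GeneticCode(name=f"ncbi{table_id}", table="".join(meanings))


def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI translation table 1)."""
    return ncbi_table(1)


def normalize_sequence(seq: str) -> str:
    """Uppercase, normalise RNA 'U' to 'T', and validate IUPAC characters."""
    if not seq:
        raise InvalidSequenceError("empty nucleotide sequence")
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        raise InvalidSequenceError(
            f"non-IUPAC nucleotide characters: {sorted(bad)!r}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support (input normalised)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of one strand of a source sequence.

    ``codon_coords[i]`` is the forward-strand coordinate (0-based) of the
    first base of residue ``i``'s codon, i.e. the lowest coordinate the
    codon occupies regardless of strand.
    """

    source_id: str
    strand: str
    frame: int
    protein: str
    codon_coords: tuple[int, ...] = field(repr=False)

    @property
    def target_id(self) -> str:
        """Identifier used for this frame in alignment output."""
        return f"{self.source_id}|{self.strand}|{self.frame}"


def parse_target_id(target_id: str) -> tuple[str, str, int]:
    """Split a frame identifier back into (source_id, strand, frame)."""
    source_id, strand, frame = target_id.rsplit("|", 2)
    return source_id, strand, int(frame)


def _translate_frame(seq: str, code: GeneticCode) -> str:
    n = len(seq) // 3
    return "".join(code.translate_codon(seq[3 * i: 3 * i + 3]) for i in range(n))


def six_frame_translate(
    seq: str, code: GeneticCode | None = None, source_id: str = ""
) -> list[FrameTranslation]:
    """Translate a nucleotide sequence in all six frames.

    Returns exactly six :class:`FrameTranslation` records: frames 0..2 on
    '+' then 0..2 on '-'.  Reverse-strand frames are read on the reverse
    complement.  Codons containing any non-ACGT character translate to
    'X'; trailing partial codons are dropped.
    """
    if code is None:
        code = standard_code()
    s = normalize_sequence(seq)
    L = len(s)
    rc = reverse_complement(s)
    out: list[FrameTranslation] = []
    for strand, strand_seq in (("+", s), ("-", rc)):
        for frame in range(3):
            sub = strand_seq[frame:]
            protein = _translate_frame(sub, code)
            if strand == "+":
                coords = tuple(frame + 3 * i for i in range(len(protein)))
            else:
                coords = tuple(L - (frame + 3 * i) - 3 for i in range(len(protein)))
            out.append(
                FrameTranslation(
                    source_id=source_id,
                    strand=strand,
                    frame=frame,
                    protein=protein,
                    codon_coords=coords,
                )
            )
    return out


@dataclass(frozen=True)
class CodonDifference:
    """One codon whose meaning differs between two code tables."""

    codon: str
    reference: str
    inferred: str
    category: str  # 'stop-to-sense' | 'sense-to-sense' | 'sense-to-stop' | 'uninferred'


def compare_codes(
    inferred: GeneticCode, reference: GeneticCode
) -> list[CodonDifference]:
    """Per-codon differences of ``inferred`` relative to ``reference``.

    A '?' in the inferred table is categorised ``uninferred`` and is never
    a reassignment call; reassignments are ``stop-to-sense`` (reference
    stop gains an amino-acid meaning) or ``sense-to-sense`` (a sense codon
    changes amino acid).
    """
    diffs = []
    for codon, ref, inf in zip(CODONS, reference.table, inferred.table):
        if ref == inf:
            continue
        if inf == "?":
            category = "uninferred"
        elif ref == "*":
            category = "stop-to-sense"
        elif inf == "*":
            category = "sense-to-stop"
        else:
            category = "sense-to-sense"
        diffs.append(CodonDifference(codon, ref, inf, category))
    return diffs


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, wrapped) FASTA file as (id, seq) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterator[tuple[str, str]] | list[tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    """Write (id, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
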