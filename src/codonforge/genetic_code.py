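"""Genetic-code tables and synonymous-family structure.

Every downstream statistic (RSCU, ENC, GC3s, CAI, ...) is defined over the
partition of sense codons into synonymous families. The partition is taken
from an NCBI translation table (Biopython's ``Bio.Data.CodonTable``); the
default is the standard code (table 1), under which the 61 sense codons
split into 18 multi-codon families plus the single-codon families Met and
Trp, leaving 59 "analyzable" sense codons.

Six-fold families (Leu, Ser, Arg under the standard code) are treated as
single k=6 families, never split 2+4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A translation table together with its synonymous-family partition.

    Attributes
    ----------
    table_id : int
        NCBI translation-table identifier (1 = standard, 4 = mold
        mitochondrial, ...).
    codon_to_aa : dict
        Maps each of the 64 DNA triplets to a one-letter amino acid, or to
        ``"*"`` for stop.
    families : dict
        Maps amino acid -> tuple of its synonymous codons (the family).
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)
    families: dict[str, tuple[str, ...]] = field(repr=False)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != "*")

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """Sense codons in families of size >= 2 (59 under the standard code)."""
        return tuple(
            c for c in self.sense_codons
            if len(self.families[self.codon_to_aa[c]]) >= 2
        )

    def degeneracy_class(self, aa: str) -> int:
        """Family size k of amino acid ``aa`` (1, 2, 3, 4 or 6)."""
        return len(self.families[aa])

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def translate(self, seq: str) -> str:
        """Translate an in-frame DNA string; stops render as '*'."""
        return "".join(
            self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
        )

    def class_counts(self) -> dict[int, int]:
        """Number of amino-acid families per degeneracy class k."""
        out: dict[int, int] = {}
        for codons in self.families.values():
            out[len(codons)] = out.get(len(codons), 0) + 1
        return out


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table: {table_id}") from exc
    codon_to_aa: dict[str, str] = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            codon_to_aa[codon] = "*"
        else:
            codon_to_aa[codon] = table.forward_table[codon]
    families: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        families={aa: tuple(cs) for aa, cs in families.items()},
    )


STANDARD_CODE = get_code(1)

# Kyte-Doolittle hydropathy, used for GRAVY.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_RESIDUES = frozenset("FYW")
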