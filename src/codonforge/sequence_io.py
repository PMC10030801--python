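"""Reading, validation and filtering of coding sequences.

Genes arrive either as one-record-per-gene FASTA or as CDS features of a
GenBank flat file (joined exons, strand-resolved). Validation enforces
in-frame length, tallies internal stop codons, and flags the terminal stop
so that it is excluded from every codon statistic. The <100-amino-acid
filter counts translated residues excluding the terminal stop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .genetic_code import GeneticCode, STANDARD_CODE

log = logging.getLogger(__name__)

#: The mitochondrial core protein-coding genes shared across most fungi.
CORE_PCG_NAMES = (
    "atp6", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "rps3",
)

# Common annotation synonyms, lower-cased.
GENE_SYNONYMS: dict[str, str] = {
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3",
    "nd4": "nad4", "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nad4l": "nad4l",
}


def canonical_gene_name(name: str) -> str:
    low = name.strip().lower()
    return GENE_SYNONYMS.get(low, low)


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame CDS with species and gene labels."""

    species: str
    gene: str
    seq: str
    has_terminal_stop: bool = False
    n_internal_stops: int = 0

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, self.n_codons * 3, 3)]


@dataclass
class GeneSet:
    """An ordered collection of genes from one species, plus the code in force."""

    species: str
    genes: list[CodingSequence] = field(default_factory=list)
    code: GeneticCode = STANDARD_CODE

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene_labels(self) -> list[str]:
        return [g.gene for g in self.genes]

    def get(self, gene: str) -> CodingSequence:
        for g in self.genes:
            if g.gene == gene:
                return g
        raise KeyError(gene)


def _normalize_seq(raw: str) -> str:
    return str(raw).upper().replace("U", "T")


def load_fasta(path: str | Path, species: str, code: GeneticCode = STANDARD_CODE) -> GeneSet:
    """Read a multi-record FASTA, one gene per record.

    Record ids are taken as gene labels; sequences are upper-cased with
    U -> T. Duplicate gene labels are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    genes: list[CodingSequence] = []
    for rec in records:
        label = rec.id
        if label in seen:
            raise ValueError(f"duplicate gene label in {path}: {label!r}")
        seen.add(label)
        genes.append(CodingSequence(species=species, gene=label, seq=_normalize_seq(rec.seq)))
    return GeneSet(species=species, genes=genes, code=code)


def write_fasta(gs: GeneSet, path: str | Path, width: int = 70) -> Path:
    """Write a GeneSet as multi-record FASTA (inverse of :func:`load_fasta`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in gs:
            fh.write(f">{g.gene}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")
    return path


def extract_core_pcgs(
    path: str | Path,
    gene_names: tuple[str, ...] = CORE_PCG_NAMES,
    species: str | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> GeneSet:
    """Extract named CDS features from a GenBank flat file.

    CDS locations are resolved through Biopython (``join()`` exons
    concatenated, ``complement()`` strands reverse-complemented), so every
    returned sequence is in coding orientation beginning at its start codon.
    Gene-name matching is case-insensitive with a synonym table. Requested
    genes missing from the annotation are reported with a warning, not an
    error.
    """
    path = Path(path)
    record = next(SeqIO.parse(str(path), "genbank"))
    if species is None:
        species = record.annotations.get("organism", record.id)
    wanted = {canonical_gene_name(n): n for n in gene_names}
    found: dict[str, CodingSequence] = {}
    n_cds = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        n_cds += 1
        names = feat.qualifiers.get("gene", []) + feat.qualifiers.get("product", [])
        canon = next((canonical_gene_name(n) for n in names if canonical_gene_name(n) in wanted), None)
        if canon is None or canon in found:
            continue
        seq = _normalize_seq(feat.location.extract(record.seq))
        found[canon] = CodingSequence(species=species, gene=wanted[canon], seq=seq)
    if n_cds == 0:
        raise ValueError(f"no CDS features in {path}")
    missing = [wanted[c] for c in wanted if c not in found]
    if missing:
        warnings.warn(f"genes not annotated in {path.name}: {', '.join(sorted(missing))}")
    genes = [found[canonical_gene_name(n)] for n in gene_names if canonical_gene_name(n) in found]
    return GeneSet(species=species, genes=genes, code=code)


def validate_cds(cs: CodingSequence, code: GeneticCode = STANDARD_CODE, strict: bool = False) -> CodingSequence:
    """Enforce in-frame length and account for stop codons.

    Lenient mode drops a trailing partial codon with a warning; strict mode
    raises. A terminal stop is flagged (and later excluded from all codon
    statistics); internal stops are counted, and raise in strict mode.
    """
    seq = _normalize_seq(cs.seq)
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{cs.gene}: non-ACGT characters {sorted(bad)}")
    if len(seq) % 3 != 0:
        if strict:
            raise ValueError(f"{cs.gene}: length {len(seq)} not a multiple of 3")
        warnings.warn(f"{cs.gene}: dropping trailing partial codon ({len(seq) % 3} nt)")
        seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    has_terminal_stop = bool(codons) and codons[-1] in code.stop_codons
    internal = sum(1 for c in codons[:-1] if c in code.stop_codons)
    if internal and strict:
        raise ValueError(f"{cs.gene}: {internal} internal stop codon(s)")
    return replace(
        cs, seq=seq, has_terminal_stop=has_terminal_stop, n_internal_stops=internal
    )


def validate_gene_set(gs: GeneSet, strict: bool = False) -> GeneSet:
    return GeneSet(
        species=gs.species,
        genes=[validate_cds(g, gs.code, strict=strict) for g in gs.genes],
        code=gs.code,
    )


def filter_min_length(gs: GeneSet, min_aa: int = 100) -> GeneSet:
    """Drop genes coding fewer than ``min_aa`` amino acids (terminal stop excluded)."""
    kept = []
    for g in gs.genes:
        n_aa = g.n_codons - (1 if g.has_terminal_stop else 0)
        if n_aa >= min_aa:
            kept.append(g)
        else:
            log.info("filtered %s/%s: %d aa < %d", gs.species, g.gene, n_aa, min_aa)
    if not kept:
        raise ValueError(f"empty gene set for {gs.species} after {min_aa}-aa filter")
    return GeneSet(species=gs.species, genes=kept, code=gs.code)
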