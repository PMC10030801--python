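"""Shared fixtures: toy sequences, a synthetic GenBank record, small gene sets.

The GenBank fixture is built programmatically with Biopython (synthetic
record, not a real accession) so the repository ships no binary or
downloaded data.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from codonforge.genetic_code import STANDARD_CODE
from codonforge.sequence_io import CodingSequence, GeneSet


def make_gene(codons: list[str], gene: str = "toy", species: str = "test", stop: bool = True) -> CodingSequence:
    """Build a validated CodingSequence from an explicit codon list."""
    seq = "".join(codons) + ("TAA" if stop else "")
    return CodingSequence(
        species=species, gene=gene, seq=seq, has_terminal_stop=stop
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def code():
    return STANDARD_CODE


def random_cds(rng: np.random.Generator, n_codons: int, species: str = "test", gene: str = "rand") -> CodingSequence:
    """Random stop-free CDS of n_codons sense codons plus terminal TAA."""
    sense = np.array(STANDARD_CODE.sense_codons, dtype=object)
    body = "".join(rng.choice(sense, size=n_codons).tolist())
    return CodingSequence(species=species, gene=gene, seq=body + "TAA", has_terminal_stop=True)


@pytest.fixture
def genbank_file(tmp_path):
    """Synthetic mitogenome-like GenBank flat file with three CDS features.

    atp6: forward strand; cob: reverse strand (complement); cox1: two exons
    joined. Every CDS translates without internal stops and begins with ATG.
    """
    rng = np.random.default_rng(7)
    sense = [c for c in STANDARD_CODE.sense_codons if c != "ATG"]

    def coding(n):
        return "ATG" + "".join(rng.choice(np.array(sense, dtype=object), size=n - 2).tolist()) + "TAA"

    atp6 = coding(40)          # 120 nt
    cob = coding(50)           # 150 nt
    cox1a, cox1b = coding(60)[:90], coding(60)[90:]  # split into 2 exons

    spacer = "".join(rng.choice(np.array(list("ACGT")), size=30).tolist())
    genome = (
        spacer
        + atp6
        + spacer
        + str(Seq(cob).reverse_complement())
        + spacer
        + cox1a
        + spacer
        + cox1b
        + spacer
    )
    rec = SeqRecord(Seq(genome), id="SYN0001", name="SYN0001",
                    description="synthetic test mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["organism"] = "Synthetica testii"

    p = len(spacer)
    rec.features.append(SeqFeature(
        FeatureLocation(p, p + len(atp6), strand=1), type="CDS",
        qualifiers={"gene": ["atp6"]}))
    p += len(atp6) + len(spacer)
    rec.features.append(SeqFeature(
        FeatureLocation(p, p + len(cob), strand=-1), type="CDS",
        qualifiers={"gene": ["COB"]}))
    p += len(cob) + len(spacer)
    loc = CompoundLocation([
        FeatureLocation(p, p + len(cox1a), strand=1),
        FeatureLocation(p + len(cox1a) + len(spacer),
                        p + len(cox1a) + len(spacer) + len(cox1b), strand=1),
    ])
    rec.features.append(SeqFeature(loc, type="CDS", qualifiers={"gene": ["cox1"]}))

    path = tmp_path / "synthetic_mitogenome.gb"
    SeqIO.write(rec, str(path), "genbank")
    return {"path": path, "atp6": atp6, "cob": cob, "cox1": cox1a + cox1b}


@pytest.fixture
def small_gene_set(rng):
    """Six random genes of 120-250 codons from one species."""
    genes = [random_cds(rng, int(n), gene=f"g{i}") for i, n in
             enumerate(rng.integers(120, 250, size=6))]
    return GeneSet(species="test", genes=genes)
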