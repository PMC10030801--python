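"""Codon counting and the composition / bias statistics built on counts.

Counts are tallied per gene (or pooled per species); stop codons — terminal
and, should they occur in-frame under the configured code, internal — are
tracked separately and never enter family statistics. From the counts we
derive base and positional GC content, the synonymous third-position
frequencies (A3s/T3s/G3s/C3s with base-specific denominators, and GC3s),
relative synonymous codon usage (RSCU), and Wright's effective number of
codons (ENC). GRAVY and AROMO are computed from the translated protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    AROMATIC_RESIDUES,
    KYTE_DOOLITTLE,
    GeneticCode,
    STANDARD_CODE,
)
from .sequence_io import CodingSequence, GeneSet


@dataclass
class CodonCountTable:
    """Counts of sense codons for one gene or a pooled gene set.

    ``counts`` holds sense codons only; stop-codon occurrences live in
    ``stop_counts`` and never contribute to family statistics.
    """

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    scope: str = "gene"

    @property
    def n_codons_total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def pooled_with(self, other: "CodonCountTable") -> "CodonCountTable":
        counts = dict(self.counts)
        for c, n in other.counts.items():
            counts[c] = counts.get(c, 0) + n
        stops = dict(self.stop_counts)
        for c, n in other.stop_counts.items():
            stops[c] = stops.get(c, 0) + n
        return CodonCountTable(counts=counts, stop_counts=stops, scope="pooled")


@dataclass(frozen=True)
class CompositionProfile:
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    GC: float
    GC1: float
    GC2: float
    GC3: float

    @property
    def GC12(self) -> float:
        return (self.GC1 + self.GC2) / 2.0


@dataclass(frozen=True)
class RSCUTable:
    """Per-codon RSCU over multi-codon families; Met/Trp excluded.

    Codons of amino acids never observed in the data carry RSCU 0.0 and are
    listed in ``unobserved_families``.
    """

    rscu: dict[str, float]
    family_sizes: dict[str, int]
    unobserved_families: frozenset[str] = frozenset()
    scope: str = "gene"


@dataclass(frozen=True)
class ENCRecord:
    enc: float | None
    class_homozygosity: dict[int, float]
    imputed_classes: frozenset[int] = frozenset()
    dropped_classes: frozenset[int] = frozenset()
    message: str = ""


def count_codons(cs: CodingSequence, code: GeneticCode = STANDARD_CODE, scope: str = "gene") -> CodonCountTable:
    """Tally in-frame triplets; stop codons are tallied apart from sense counts."""
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    for codon in cs.codons():
        if code.codon_to_aa[codon] == "*":
            stops[codon] = stops.get(codon, 0) + 1
        else:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts=counts, stop_counts=stops, scope=scope)


def pooled_counts(gs: GeneSet) -> CodonCountTable:
    """Pool codon counts over every gene of a species."""
    pooled = CodonCountTable(counts={}, stop_counts={}, scope="pooled")
    for g in gs:
        pooled = pooled.pooled_with(count_codons(g, gs.code))
    pooled.scope = "pooled"
    return pooled


def base_composition(cct: CodonCountTable) -> CompositionProfile:
    """Base percentages and positional GC over the sense codons of a table."""
    if cct.n_codons_total == 0:
        raise ValueError("empty codon count table")
    base_tot = {b: 0 for b in "ACGT"}
    pos_gc = [0, 0, 0]
    for codon, n in cct.counts.items():
        for i, b in enumerate(codon):
            base_tot[b] += n
            if b in "GC":
                pos_gc[i] += n
    n_nt = 3 * cct.n_codons_total
    n_cod = cct.n_codons_total
    pct = {b: 100.0 * base_tot[b] / n_nt for b in "ACGT"}
    return CompositionProfile(
        pct_A=pct["A"], pct_T=pct["T"], pct_G=pct["G"], pct_C=pct["C"],
        GC=pct["G"] + pct["C"],
        GC1=100.0 * pos_gc[0] / n_cod,
        GC2=100.0 * pos_gc[1] / n_cod,
        GC3=100.0 * pos_gc[2] / n_cod,
    )


def synonymous_third_position_stats(
    cct: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> dict[str, float | None]:
    """A3s/T3s/G3s/C3s and GC3s over synonymous-family codons.

    For base X, the denominator of X3s is restricted to codons whose family
    offers X at the third position — the base-specific convention, under
    which the four values may sum above 100%. GC3s uses the plain shared
    denominator (all synonymous-family codons). A base whose denominator is
    zero yields ``None`` rather than NaN.
    """
    syn = set(code.synonymous_codons)
    num = {b: 0 for b in "ACGT"}
    den = {b: 0 for b in "ACGT"}
    total = 0
    gc_end = 0
    for codon, n in cct.counts.items():
        if codon not in syn:
            continue
        total += n
        third_offers = {c[2] for c in code.family_of(codon)}
        for b in "ACGT":
            if b in third_offers:
                den[b] += n
        num[codon[2]] += n
        if codon[2] in "GC":
            gc_end += n
    out: dict[str, float | None] = {}
    for b in "ACGT":
        out[f"{b}3s"] = (num[b] / den[b]) if den[b] > 0 else None
    out["GC3s"] = (gc_end / total) if total > 0 else None
    return out


def rscu(cct: CodonCountTable, code: GeneticCode = STANDARD_CODE, scope: str | None = None) -> RSCUTable:
    """RSCU_ij = k * n_ij / sum_j n_ij within each multi-codon family."""
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    unobserved: set[str] = set()
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        sizes[aa] = k
        fam_n = sum(cct.get(c) for c in fam)
        if fam_n == 0:
            unobserved.add(aa)
            for c in fam:
                values[c] = 0.0
        else:
            for c in fam:
                values[c] = k * cct.get(c) / fam_n
    return RSCUTable(
        rscu=values,
        family_sizes=sizes,
        unobserved_families=frozenset(unobserved),
        scope=scope or cct.scope,
    )


def _family_homozygosity(counts: list[int]) -> float | None:
    """Wright's F = (n * sum p_i^2 - 1) / (n - 1); None when n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in counts)
    return (n * p2 - 1.0) / (n - 1.0)


def enc(cct: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> ENCRecord:
    """Wright's effective number of codons.

    Per-family homozygosity F is averaged within each degeneracy class k;
    the statistic sums N_k / F_k-bar over classes plus one codon per
    single-codon family (ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 under the
    standard code). Families with n < 2 or F = 0 are excluded from the
    class mean. A missing k=3 class is imputed as (F2+F4)/2; any other
    missing class is dropped and the result rescaled to the code's full
    range. Values are capped to [20, enc_max] (enc_max = 61 for the
    standard code).
    """
    class_counts = code.class_counts()
    n_single = class_counts.get(1, 0)
    enc_max = n_single + sum(k * nk for k, nk in class_counts.items() if k >= 2)

    fams_by_class: dict[int, list[float]] = {k: [] for k in class_counts if k >= 2}
    for aa, fam in code.families.items():
        k = len(fam)
        if k < 2:
            continue
        f = _family_homozygosity([cct.get(c) for c in fam])
        if f is not None and f > 0:
            fams_by_class[k].append(f)

    fbar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in fams_by_class.items() if v
    }
    imputed: set[int] = set()
    if 3 in class_counts and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
        imputed.add(3)

    present = [k for k in class_counts if k >= 2 and k in fbar]
    dropped = {k for k in class_counts if k >= 2 and k not in fbar}
    if not present:
        return ENCRecord(
            enc=None, class_homozygosity={}, message="no synonymous family with n >= 2"
        )
    value = n_single + sum(class_counts[k] / fbar[k] for k in present)
    if dropped:
        attainable = n_single + sum(k * class_counts[k] for k in present)
        value *= enc_max / attainable
    value = min(max(value, 20.0), float(enc_max))
    return ENCRecord(
        enc=value,
        class_homozygosity=fbar,
        imputed_classes=frozenset(imputed),
        dropped_classes=frozenset(dropped),
    )


def _residues(cs: CodingSequence, code: GeneticCode) -> str:
    aa = code.translate(cs.seq)
    return aa.replace("*", "")


def gravy(cs: CodingSequence, code: GeneticCode = STANDARD_CODE) -> float:
    """Mean Kyte-Doolittle hydropathy of the translated protein."""
    res = _residues(cs, code)
    if not res:
        raise ValueError(f"{cs.gene}: empty translation")
    return sum(KYTE_DOOLITTLE[a] for a in res) / len(res)


def aromo(cs: CodingSequence, code: GeneticCode = STANDARD_CODE) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp) in the translation."""
    res = _residues(cs, code)
    if not res:
        raise ValueError(f"{cs.gene}: empty translation")
    return sum(1 for a in res if a in AROMATIC_RESIDUES) / len(res)
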