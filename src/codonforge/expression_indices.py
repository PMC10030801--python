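"""Reference-set-dependent bias indices: CAI, CBI, FOP.

CAI weights (relative adaptiveness w = RSCU / RSCU_max per family) are
derived from a pooled reference count table — by default the species' own
pooled gene set, since no external highly-expressed reference exists for
fungal mitochondria. CBI is the Bennetzen–Hall excess of optimal-codon use
over random expectation; FOP is the plain optimal-codon fraction. Both
consume an optimal-codon set, normally the ΔRSCU-derived one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .codon_statistics import CodonCountTable, pooled_counts, rscu
from .genetic_code import GeneticCode, STANDARD_CODE
from .sequence_io import GeneSet

log = logging.getLogger(__name__)

#: Smoothing weight for codons absent from the reference set.
ZERO_COUNT_WEIGHT = 0.01


@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w per sense codon, max 1 within each family."""

    w: dict[str, float]
    source: str = "self-derived"
    unusable_families: frozenset[str] = frozenset()


@dataclass(frozen=True)
class OptimalCodonSet:
    codons: frozenset[str]
    provenance: str = "delta-rscu"

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class UsageIndexRecord:
    """Per-gene scalar indices, merged across modules into one row."""

    species: str
    gene: str
    n_codons: int = 0
    values: dict[str, float | None] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float | None:
        return self.values.get(key)


def cai_weights(
    reference: GeneSet | CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    smoothing: float = ZERO_COUNT_WEIGHT,
) -> ReferenceWeights:
    """w_ij = RSCU_ij / max_j RSCU_ij on the pooled reference counts.

    Codons unobserved in the reference get weight ``smoothing`` (default
    0.01); families entirely absent are flagged unusable and skipped by
    :func:`cai`.
    """
    cct = pooled_counts(reference) if isinstance(reference, GeneSet) else reference
    table = rscu(cct, code)
    w: dict[str, float] = {}
    unusable: set[str] = set()
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        if aa in table.unobserved_families:
            unusable.add(aa)
            continue
        rmax = max(table.rscu[c] for c in fam)
        for c in fam:
            wc = table.rscu[c] / rmax
            if wc == 0.0:
                wc = smoothing
                log.info("zero-count reference codon %s (%s): w = %g", c, aa, smoothing)
            w[c] = wc
    source = "self-derived" if isinstance(reference, GeneSet) else "count-table"
    return ReferenceWeights(w=w, source=source, unusable_families=frozenset(unusable))


def cai(cct: CodonCountTable, wts: ReferenceWeights, code: GeneticCode = STANDARD_CODE) -> float:
    """Geometric mean of w over counted codons (Met/Trp/stops excluded)."""
    log_sum = 0.0
    n = 0
    for codon, cnt in cct.counts.items():
        if codon not in wts.w:  # single-codon family or unusable family
            continue
        log_sum += cnt * math.log(wts.w[codon])
        n += cnt
    if n == 0:
        raise ValueError("no analyzable codons for CAI")
    return math.exp(log_sum / n)


def _optimal_families(opt: OptimalCodonSet, code: GeneticCode) -> dict[str, tuple[str, ...]]:
    fams: dict[str, tuple[str, ...]] = {}
    for c in opt.codons:
        aa = code.codon_to_aa[c]
        fams[aa] = code.families[aa]
    return fams


def cbi(cct: CodonCountTable, opt: OptimalCodonSet, code: GeneticCode = STANDARD_CODE) -> float:
    """Bennetzen–Hall codon bias index.

    CBI = (N_opt - N_ran) / (N_tot - N_ran) over families that contain at
    least one optimal codon, where N_ran is the optimal-codon count expected
    under uniform synonymous usage. 1 = only optimal codons; negative =
    optimal codons avoided.
    """
    if not opt.codons:
        raise ValueError("empty optimal codon set")
    n_opt = n_tot = n_ran = 0.0
    for aa, fam in _optimal_families(opt, code).items():
        k = len(fam)
        k_opt = sum(1 for c in fam if c in opt.codons)
        fam_n = sum(cct.get(c) for c in fam)
        n_tot += fam_n
        n_ran += fam_n * k_opt / k
        n_opt += sum(cct.get(c) for c in fam if c in opt.codons)
    if math.isclose(n_tot, n_ran):
        raise ValueError("degenerate CBI: N_tot equals N_ran")
    return (n_opt - n_ran) / (n_tot - n_ran)


def fop(cct: CodonCountTable, opt: OptimalCodonSet, code: GeneticCode = STANDARD_CODE) -> float:
    """Frequency of optimal codons: N_opt / N_tot over synonymous-family codons."""
    if not opt.codons:
        raise ValueError("empty optimal codon set")
    syn = set(code.synonymous_codons)
    n_tot = sum(n for c, n in cct.counts.items() if c in syn)
    if n_tot == 0:
        raise ValueError("no synonymous-family codons")
    n_opt = sum(n for c, n in cct.counts.items() if c in opt.codons)
    return n_opt / n_tot
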