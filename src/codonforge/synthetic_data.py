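"""Synthetic coding sequences with closed-form codon-usage ground truth.

Genes are generated i.i.d. per codon: amino acids are drawn from a
frequency vector, then a codon is drawn from per-amino-acid synonymous
weights. Two knobs reshape the weights without touching the encoded
protein:

* ``gc3_pressure`` mixes the third-position base distribution toward G/C
  within each family (0 = fully A/T-ending, 0.5 = symmetric, 1 = fully
  G/C-ending), emulating directional mutation pressure at silent sites;
* ``selection_strength`` multiplies the weight of each family's preferred
  codon by exp(strength), emulating translational selection that sharpens
  usage onto one codon per family and drives ENC down.

Because both act within families, the expected RSCU, GC3(s) and amino-acid
composition of every gene are available in closed form, giving every
downstream statistic a known truth to recover. Genes carry an ATG start
and a TAA stop (the AT-rich stop, fixed for determinism). No positional
autocorrelation is simulated.

The ``amanita_like`` preset emulates the composition regime of fungal
mitochondrial core genes: ~12 genes of 376-2004 bp, strongly AT-rich
(T ~ 41%, A ~ 32% pooled), GC3s ~ 11%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genetic_code import GeneticCode, STANDARD_CODE, get_code
from .sequence_io import CodingSequence, GeneSet

#: Third-position base weights of the amanita_like preset (AT-rich, A > T,
#: G > C at silent sites, matching the regime of fungal mitochondria).
AMANITA_THIRD_BASE = {"T": 0.42, "A": 0.47, "G": 0.065, "C": 0.045}

#: Amino-acid frequencies of the amanita_like preset. Calibrated once by
#: constrained least squares so that, combined with AMANITA_THIRD_BASE,
#: the pooled composition lands on T ~ 41%, A ~ 32%, GC3s ~ 0.11; frozen.
AMANITA_AA_FREQUENCIES: dict[str, float] = {}  # filled below by _calibrated()


@dataclass(frozen=True)
class SimSpec:
    """Generating parameters for one synthetic gene set."""

    n_genes: int = 12
    length_codons: int | tuple[int, int] = 300
    aa_frequencies: dict[str, float] | None = None  # None = uniform over 20
    codon_weights: dict[str, dict[str, float]] | None = None  # None = uniform
    third_base_weights: dict[str, float] | None = None
    gc3_pressure: float | None = None
    selection_strength: float = 0.0
    seed: int = 0
    species: str = "synthetic"
    table_id: int = 1

    @property
    def code(self) -> GeneticCode:
        return get_code(self.table_id)


@dataclass
class SimResult:
    gene_set: GeneSet
    spec: SimSpec
    truth: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_rscu: dict[str, float] = field(default_factory=dict)


def _aa_frequencies(spec: SimSpec) -> dict[str, float]:
    code = spec.code
    if spec.aa_frequencies is None:
        aas = sorted(code.families)
        return {a: 1.0 / len(aas) for a in aas}
    total = sum(spec.aa_frequencies.values())
    return {a: p / total for a, p in spec.aa_frequencies.items() if p > 0}


def effective_codon_weights(spec: SimSpec) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon probabilities after pressure and selection.

    Base weights (uniform unless given) are multiplied by the third-base
    distribution — either ``third_base_weights`` or the symmetric
    GC-vs-AT split implied by ``gc3_pressure`` — then the family's
    highest-weight codon (ties broken alphabetically) is boosted by
    exp(selection_strength), and the family renormalized.
    """
    code = spec.code
    if spec.third_base_weights is not None:
        b3 = dict(spec.third_base_weights)
    elif spec.gc3_pressure is not None:
        g = spec.gc3_pressure
        b3 = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
    else:
        b3 = {b: 0.25 for b in "ACGT"}
    out: dict[str, dict[str, float]] = {}
    for aa, fam in code.families.items():
        base = (
            dict(spec.codon_weights.get(aa, {c: 1.0 for c in fam}))
            if spec.codon_weights
            else {c: 1.0 for c in fam}
        )
        w = {c: base.get(c, 0.0) * b3[c[2]] for c in fam}
        if sum(w.values()) == 0:
            w = {c: 1.0 for c in fam}
        if spec.selection_strength > 0 and len(fam) > 1:
            preferred = max(sorted(w), key=lambda c: w[c])
            w[preferred] *= float(np.exp(spec.selection_strength))
        tot = sum(w.values())
        out[aa] = {c: v / tot for c, v in w.items()}
    return out


def expected_rscu(spec: SimSpec) -> dict[str, float]:
    """Closed-form expected RSCU: k * w_c within each multi-codon family."""
    weights = effective_codon_weights(spec)
    out: dict[str, float] = {}
    for aa, fam in spec.code.families.items():
        if len(fam) < 2:
            continue
        for c in fam:
            out[c] = len(fam) * weights[aa][c]
    return out


def expected_composition(spec: SimSpec) -> dict[str, float]:
    """Expected pooled base fractions, positional GC, and GC3s."""
    code = spec.code
    aa_freq = _aa_frequencies(spec)
    weights = effective_codon_weights(spec)
    codon_p: dict[str, float] = {}
    for aa, p in aa_freq.items():
        for c, w in weights[aa].items():
            codon_p[c] = codon_p.get(c, 0.0) + p * w
    base = {b: 0.0 for b in "ACGT"}
    pos_gc = [0.0, 0.0, 0.0]
    syn_total = syn_gc3 = 0.0
    syn = set(code.synonymous_codons)
    for c, p in codon_p.items():
        for i, b in enumerate(c):
            base[b] += p / 3.0
            if b in "GC":
                pos_gc[i] += p
        if c in syn:
            syn_total += p
            if c[2] in "GC":
                syn_gc3 += p
    return {
        "A": base["A"], "T": base["T"], "G": base["G"], "C": base["C"],
        "GC1": pos_gc[0], "GC2": pos_gc[1], "GC3": pos_gc[2],
        "GC3s": syn_gc3 / syn_total if syn_total else float("nan"),
    }


def _draw_length(spec: SimSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.length_codons, int):
        return spec.length_codons
    lo, hi = spec.length_codons
    return int(rng.integers(lo, hi + 1))


def _draw_gene(spec: SimSpec, n_codons: int, rng: np.random.Generator) -> str:
    aa_freq = _aa_frequencies(spec)
    weights = effective_codon_weights(spec)
    aas = sorted(aa_freq)
    p_aa = np.array([aa_freq[a] for a in aas])
    aa_idx = rng.choice(len(aas), size=n_codons, p=p_aa)
    codons = np.empty(n_codons, dtype=object)
    for i, aa in enumerate(aas):
        mask = aa_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        fam = sorted(weights[aa])
        p_c = np.array([weights[aa][c] for c in fam])
        codons[mask] = rng.choice(np.array(fam, dtype=object), size=k, p=p_c)
    return "ATG" + "".join(codons.tolist()) + "TAA"


def simulate_gene_set(spec: SimSpec) -> SimResult:
    """Generate ``n_genes`` i.i.d. genes under one SimSpec; seeded, reproducible."""
    aa_freq = _aa_frequencies(spec)
    if not aa_freq:
        raise ValueError("empty amino-acid alphabet")
    rng = np.random.default_rng(spec.seed)
    comp = expected_composition(spec)
    genes = []
    truth: dict[str, dict[str, float]] = {}
    for i in range(spec.n_genes):
        n = _draw_length(spec, rng)
        seq = _draw_gene(spec, n, rng)
        label = f"gene{i + 1:02d}"
        genes.append(
            CodingSequence(
                species=spec.species, gene=label, seq=seq, has_terminal_stop=True
            )
        )
        truth[label] = {
            "n_codons_body": float(n),
            "gc3_expected": comp["GC3"],
            "gc3s_expected": comp["GC3s"],
        }
    gs = GeneSet(species=spec.species, genes=genes, code=spec.code)
    return SimResult(gene_set=gs, spec=spec, truth=truth, expected_rscu=expected_rscu(spec))


def simulate_mutation_scenario(n_genes: int = 50, seed: int = 0, length_codons: int = 300) -> SimResult:
    """Genes under pure directional mutation pressure.

    Each gene draws its own GC pressure g ~ U(0.15, 0.75), applied to all
    three codon positions (codons are drawn from the 61-codon distribution
    proportional to the product of per-base probabilities, stops excluded),
    so GC12 and GC3 co-vary and the neutrality slope is ~1.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    code = STANDARD_CODE
    rng = np.random.default_rng(seed)
    sense = np.array(code.sense_codons, dtype=object)
    genes = []
    truth = {}
    for i in range(n_genes):
        g = float(rng.uniform(0.15, 0.75))
        pb = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
        q = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in sense])
        q /= q.sum()
        body = "".join(rng.choice(sense, size=length_codons, p=q).tolist())
        label = f"gene{i + 1:02d}"
        genes.append(
            CodingSequence(species="mutation-sim", gene=label, seq="ATG" + body + "TAA", has_terminal_stop=True)
        )
        truth[label] = {"gc_pressure": g}
    gs = GeneSet(species="mutation-sim", genes=genes, code=code)
    spec = SimSpec(n_genes=n_genes, length_codons=length_codons, seed=seed, species="mutation-sim")
    return SimResult(gene_set=gs, spec=spec, truth=truth)


def simulate_selection_scenario(
    n_genes: int = 50,
    seed: int = 0,
    length_codons: int = 300,
    selection_strength: float = 3.0,
) -> SimResult:
    """Genes under translational selection with varying silent-site GC.

    Amino-acid composition is held fixed (so GC12 is near-constant and the
    neutrality slope ~0) while per-gene gc3_pressure varies and selection
    sharpens usage onto one codon per family, pushing observed ENC below
    Wright's expected curve.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    genes = []
    truth = {}
    base = SimSpec(
        n_genes=1,
        length_codons=length_codons,
        selection_strength=selection_strength,
        species="selection-sim",
    )
    for i in range(n_genes):
        g3 = float(rng.uniform(0.1, 0.7))
        sub = replace(base, gc3_pressure=g3, seed=int(rng.integers(0, 2**31 - 1)))
        seq = _draw_gene(sub, length_codons, np.random.default_rng(sub.seed))
        label = f"gene{i + 1:02d}"
        genes.append(
            CodingSequence(species="selection-sim", gene=label, seq=seq, has_terminal_stop=True)
        )
        truth[label] = {"gc3_pressure": g3, "selection_strength": selection_strength}
    gs = GeneSet(species="selection-sim", genes=genes, code=STANDARD_CODE)
    return SimResult(gene_set=gs, spec=replace(base, n_genes=n_genes, seed=seed), truth=truth)


def amanita_like(seed: int = 0, n_genes: int = 12, species: str = "amanita-sim") -> SimSpec:
    """Preset emulating the fungal-mitochondrial composition regime."""
    return SimSpec(
        n_genes=n_genes,
        length_codons=(376 // 3, 2004 // 3),
        aa_frequencies=dict(AMANITA_AA_FREQUENCIES),
        third_base_weights=dict(AMANITA_THIRD_BASE),
        seed=seed,
        species=species,
    )


def simulate_amanita_study(n_species: int = 9, seed: int = 0) -> list[SimResult]:
    """Nine amanita-like species with mildly perturbed per-species weights.

    Per-species third-base weights are jittered (Dirichlet-like, small)
    around the preset so species differ enough for the RSCU clustering and
    cross-species comparisons to be non-degenerate.
    """
    rng = np.random.default_rng(seed)
    results = []
    for i in range(n_species):
        jitter = rng.normal(0.0, 0.12, size=4)
        b3 = {
            b: max(0.005, AMANITA_THIRD_BASE[b] * float(np.exp(jitter[j])))
            for j, b in enumerate("TAGC")
        }
        tot = sum(b3.values())
        b3 = {b: v / tot for b, v in b3.items()}
        spec = replace(
            amanita_like(seed=int(rng.integers(0, 2**31 - 1)), species=f"species{i + 1:02d}"),
            third_base_weights=b3,
        )
        results.append(simulate_gene_set(spec))
    return results


def write_fixture(sim: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + truth TSV + generating-spec file; byte-stable per seed."""
    from .sequence_io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = write_fasta(sim.gene_set, out / "genes.fasta")
    truth = out / "truth.tsv"
    fields = sorted({k for v in sim.truth.values() for k in v})
    with open(truth, "w") as fh:
        fh.write("gene\t" + "\t".join(fields) + "\n")
        for g in sim.gene_set.gene_labels():
            row = sim.truth.get(g, {})
            fh.write(g + "\t" + "\t".join(f"{row.get(f, float('nan')):.6g}" for f in fields) + "\n")
    specfile = out / "sim_spec.txt"
    with open(specfile, "w") as fh:
        s = sim.spec
        fh.write(f"n_genes={s.n_genes}\nlength_codons={s.length_codons}\n")
        fh.write(f"gc3_pressure={s.gc3_pressure}\nselection_strength={s.selection_strength}\n")
        fh.write(f"seed={s.seed}\nspecies={s.species}\ntable_id={s.table_id}\n")
        if s.third_base_weights:
            for b in "TAGC":
                fh.write(f"third_base_{b}={s.third_base_weights[b]:.6g}\n")
        if s.aa_frequencies:
            for a in sorted(s.aa_frequencies):
                fh.write(f"aa_{a}={s.aa_frequencies[a]:.6g}\n")
    return {"fasta": fasta, "truth": truth, "spec": specfile}


def _calibrated() -> dict[str, float]:
    # Frozen output of the one-time composition calibration (see docs).
    return {
        "A": 0.0318, "C": 0.0159, "D": 0.0239, "E": 0.0325, "F": 0.1146,
        "G": 0.0530, "H": 0.0080, "I": 0.0693, "K": 0.0610, "L": 0.1587,
        "M": 0.0269, "N": 0.0629, "P": 0.0265, "Q": 0.0219, "R": 0.0252,
        "S": 0.0904, "T": 0.0497, "V": 0.0650, "W": 0.0058, "Y": 0.0570,
    }


AMANITA_AA_FREQUENCIES.update(_calibrated())
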