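"""Correspondence analysis of per-gene RSCU and optimal-codon determination.

Per species: axis contributions of the CA on the genes x 59-codon RSCU
matrix, correlation of Axis 1 with usage indices, counts of high-frequency
(RSCU > 1), high-expression (ΔRSCU > 0.08) and optimal codons, and which
optimal codons recur across species.
"""

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

from codonforge.pipeline import AnalysisConfig, run_from_fasta

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "simulated"
inputs = {d.name: d / "genes.fasta" for d in sorted(SIM.iterdir()) if d.is_dir()}
if not inputs:
    raise SystemExit("run 01_simulate_study.py first")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_from_fasta(inputs, AnalysisConfig())

rows, shared = [], Counter()
for s in bundle.per_species:
    rep = s.optimal_report
    contrib = s.coa_result.contribution_pct
    ax1 = s.axis_corr.set_index("indicator")
    rows.append(dict(
        species=s.species,
        axis1_pct=contrib[0], axis2_pct=contrib[1],
        axis3_pct=contrib[2], axis4_pct=contrib[3],
        r_axis1_gc3s=ax1.loc["GC3s", "r"],
        n_high_frequency=len(rep.high_frequency),
        n_high_expression=len(rep.high_expression),
        n_optimal=len(rep.optimal),
    ))
    shared.update(rep.optimal)
df = pd.DataFrame(rows)
df.round(3).to_csv(ROOT / "coa_optimal_summary.tsv", sep="\t", index=False)
print(df.round(2).to_string(index=False))
print(f"\ntop-4 axes explain {df[[f'axis{i}_pct' for i in range(1, 5)]].sum(axis=1).mean():.1f}%"
      " of inertia on average")
print(f"optimal codons per species: {df.n_optimal.min()}-{df.n_optimal.max()}")
print("most shared optimal codons:",
      ", ".join(f"{c} ({n} species)" for c, n in shared.most_common(5)))
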