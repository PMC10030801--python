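"""Hierarchical clustering of species on pooled RSCU profiles.

Average-linkage (UPGMA) on Euclidean distances over the species x 59-codon
RSCU matrix; writes the Newick tree and prints cophenetic structure.
"""

import warnings
from pathlib import Path

from codonforge.pipeline import AnalysisConfig, run_from_fasta

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "simulated"
inputs = {d.name: d / "genes.fasta" for d in sorted(SIM.iterdir()) if d.is_dir()}
if not inputs:
    raise SystemExit("run 01_simulate_study.py first")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_from_fasta(inputs, AnalysisConfig())

tree = bundle.tree
(ROOT / "species_tree.nwk").write_text(tree.newick + "\n")
print("newick:", tree.newick)
d = tree.cophenetic_distances()
closest = d.where(d > 0).stack().idxmin()
print(f"\nclosest pair by codon usage: {closest[0]} / {closest[1]} "
      f"(cophenetic distance {d.loc[closest]:.3f})")
print(f"tree written to {ROOT / 'species_tree.nwk'}")
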