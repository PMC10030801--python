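"""Generate the synthetic nine-species study used by the downstream analyses.

Nine amanita-like species, 12 genes each (376-2004 bp, AT-rich, low GC3s),
with per-species jitter on silent-site base preferences. Writes one FASTA +
truth TSV per species under results/simulated/.
"""

import sys
from pathlib import Path

from codonforge.synthetic_data import simulate_amanita_study, write_fixture

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"

sims = simulate_amanita_study(n_species=9, seed=SEED)
for sim in sims:
    d = OUT / sim.gene_set.species
    write_fixture(sim, d)
    lengths = [g.length_nt for g in sim.gene_set]
    print(f"{sim.gene_set.species}: {len(sim.gene_set)} genes, "
          f"{min(lengths)}-{max(lengths)} nt")
print(f"\nwrote fixtures for {len(sims)} species under {OUT}")
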