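# aepks — accelerated evolution of modular PKS assembly lines

Modular polyketide synthases (PKSs) are enzymatic assembly lines: each
*extension module* (minimally KS–AT–ACP, optionally a KR/DH/ER
reductive loop) condenses one (alkyl)malonyl extender onto the growing
chain, adding two backbone carbons. Because the modules of one cluster
are highly similar tandem paralogs, integrating a temperature-sensitive
high-copy replicon plasmid into a PKS gene and then forcing its
resolution drives homologous recombination between *different*
modules, not just the perfect direct repeat created by integration.
The resolved genomes carry module deletions and duplications, and the
strains produce ring-contracted or ring-expanded analogues of the
parent polyketide — a laboratory-accelerated version of how these gene
clusters evolve naturally.

`aepks` is a toolkit for the computational side of that experiment,
aimed at people engineering or analysing modular PKS clusters:

* **data model + I/O** (`aepks.model`, `aepks.io`) — clusters as
  ordered genes and modules of typed, activity-flagged domains;
  lossless GenBank and JSON round-trips, FASTA writers.
* **synthetic data** (`aepks.synthetic`) — parent clusters with
  tunable inter-module identity (conserved KS/AT cores and pre-ACP
  linker, variable loops), integrated-plasmid states, and hybrid genes
  with known ground-truth crossovers.
* **recombination simulator** (`aepks.simulate`) — enumerates
  module-aligned homologous window pairs flanking the replicon,
  samples resolution events weighted by identity and length, and
  classifies outcomes (revertant / contraction / expansion /
  non-producer / complex).
* **junction detector** (`aepks.junctions`) — window-based sequence
  attribution of a translated hybrid gene against all native modules;
  junctions are reported as *regions* between non-sequential modules,
  validated by at least two discriminating residues, classified by
  domain context (within KS, within AT, pre-ACP linker) and checked
  for AT extender-unit compatibility; Plotcon-style conservation
  profiles.
* **virtual assembly line** (`aepks.assembly`) — backbone carbon
  counts (`starter + 2 × modules`), per-module α-substituent from the
  AT substrate and β-carbon state from the *active* reductive domains;
  `carbon_delta` gives the product change between parent and hybrid.
* **screening report** (`aepks.screen`) — phenotype tallies with the
  exact percentage conventions of plate screens, plus a small
  config-driven pipeline runner.

A thin CLI (`ae-pks simulate | detect-junctions | predict | run`)
wraps the library.

## Worked example

```python
from aepks import *

# A 14-extension-module, 3-gene parent cluster shaped like the
# rapamycin PKS: mean inter-module amino-acid identity 0.6, with
# KS/AT cores and the pre-ACP linker boosted by 0.2.
spec = SyntheticSpec(n_modules=14, identity_target=0.6, hotspot_boost=0.2,
                     seed=7, name="raplike")
cluster = generate_cluster(spec)

# Integrate a plasmid via a 2 kb homology segment in module 2, then
# simulate 1000 resolution events.
m2 = cluster.module_by_index(2)
s, _ = m2.nt_interval
state = generate_integrant(cluster, m2.gene_id, (s + 1000, s + 3000), seed=7)
summary = simulate_population(state, 1000, params=SimulationParams(), seed=7)
print(summary.counts)
print(tally_events(summary.events["event_class"]).percentages)

# Detect the junction in a six-module deletion hybrid and predict the
# product change.
hybrid = generate_hybrid(cluster, 3, 9, crossover_frac=0.5)
(j,) = detect_junctions(hybrid, cluster)
print(j.upstream_module, "->", j.downstream_module, j.ambiguity_interval,
      j.domain_context, j.at_compatible)
print(carbon_delta(cluster, hybrid))
```

prints

```
{'revertant': 155, 'contraction': 406, 'expansion': 439, 'non_producer': 0, 'complex': 0}
{'parent_producer': 15.5, 'new_analogue': 84.5, 'non_producer': 0.0}
3 -> 9 (3739, 3751) within_AT True
-12
```

Of 1000 resolutions, 155 recombined through the perfect repeat and
revert to the parent producer; the rest recombined between different
modules and encode new assembly lines (with every crossover
codon-aligned, none frameshift). The deletion hybrid joins module 3 to
module 9 — the crossover can only be localised to a 12-residue region
where the two modules are identical, here inside the AT-coding
sequence, joining two methylmalonyl-selecting ATs (`True` =
compatible). Losing six extension modules removes 12 backbone carbons
from the product.

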