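# Methods

## The model in one paragraph

A modular PKS cluster is an ordered list of genes, each encoding an
ordered list of extension modules; a module is a protein segment with
typed, activity-flagged domains (KS, AT, DH, ER, KR, ACP, plus a
CoA-ligase-like loading domain at index 0). Integration of a replicon
plasmid through a homology segment turns the genome into
`prefix + repeat + replicon + repeat + suffix`; resolution is a single
homologous crossover between a locus left of the replicon and a locus
right of it, which deletes the replicon and everything between the
crossover points. Because the modules are tandem paralogs, the
crossover can pair *different* modules: the two pair into one chimeric
module and the assembly line loses (or, through the abstract
sister-exchange channel, gains) `|i - j|` modules. Each extension
module contributes two backbone carbons, so the product change is
`2 × Δmodules`.

## Coordinates and I/O

All internal coordinates are 0-based half-open (amino acids within a
module, nucleotides within a gene); GenBank I/O converts to and from
the format's 1-based inclusive convention through Biopython. All genes
are normalised to the forward strand at parse time (reverse-strand CDS
and their sub-features are flipped), which keeps every downstream
position calculation strand-free. Domains are `misc_feature` records
with a controlled note (`domain:<KIND>;active:<bool>;substrate:<tag>`);
activity defaults to active so that inactive domains — which real
clusters carry and which must survive round-trips — are an explicit
annotation. Writers are deterministic (sorted JSON keys, fixed feature
order, 60-column FASTA).

## Synthetic clusters

The generator emulates the statistical structure of a real modular PKS
coding region, not any particular cluster:

* One template module is drawn uniformly over the 20 amino acids; each
  module is an independently substituted copy. Substitution
  probabilities are solved in closed form from the target pairwise
  identity (`q = (1-m)² + m²/19` for a flat replacement distribution)
  and applied with separate rates inside and outside the "hotspot"
  mask (KS + AT + pre-ACP linker), so hotspot columns sit at
  `identity_target + hotspot_boost` while the overall mean pairwise
  identity is recalibrated until within ±2 percentage points of
  `identity_target` (at most 25 rounds; an unreachable target raises
  an explicit infeasibility error, as does a target below the ~0.05
  floor of the flat model).
* Substitutions are identity-flat (no BLOSUM weighting): the junction
  rule is driven purely by identity, so similarity chemistry would add
  parameters without changing behaviour.
* Back-translation uses one fixed canonical codon per amino acid plus
  seeded synonymous substitutions at rate 0.1, so codon-level identity
  sits below amino-acid identity as in real paralogs.
* Default geometry: 14 extension modules of 1500 aa (KS 430, AT 300,
  DH 220, ER 200, KR 140, ACP 60, with the 80-aa stretch before ACP
  acting as the flexible linker), a 700-aa loading module, three genes
  — the shape of the rapamycin-like clusters these experiments use.
  AT substrates alternate malonyl/methylmalonyl by default and are
  fully controllable.
* Hybrids place crossovers at codon boundaries (the sequenced
  productive recombinants are in-frame; frameshifts are the
  simulator's non-producer channel, not the generator's business) and
  record ground truth (module pair, crossover position) in-object and
  as a sidecar TSV.

What the generator does **not** emulate: real domain-boundary
irregularities, inter-module linker length variation, codon-usage
bias, GC skew, or assembly/sequencing artefacts. Passing tests
therefore demonstrate correctness of the algorithms under the stated
homology structure, not performance on raw sequencing data.

## Recombination simulator

Candidate loci are ungapped module-aligned windows (default 100 nt,
stepped by one window) paired across the replicon; paralogous modules
are collinear, so gapped search would add cost without changing the
hotspot structure. A pair qualifies at nucleotide identity ≥
`min_identity` (default 0.8); the perfect repeat pair created by
integration is always included at identity 1.0. Sampling weight is
`(identity − min_identity + ε) · window_length` with ε = 0.01, and the
crossover is placed uniformly inside an exactly identical run of at
least `min_identical_run` = 20 nt — recombination cannot be localised
more finely than the identical stretch it happened in. These defaults
are declared configuration, not measured kinetics; no recombination
rates are fitted to screen statistics, which are strain- and
construct-specific.

Two structural choices:

* **Expansions.** A single-molecule deletion geometry cannot duplicate
  modules, yet duplications are observed. They are modelled abstractly
  as the same locus pairing with roles reversed on a sister copy
  (`allow_expansion`, default on), which reproduces expanded
  architectures without committing to an unproven physical mechanism.
* **Crossovers are codon-aligned by default** (`codon_aligned=True`).
  Module-aligned loci share reading-frame phase, so codon-aligned
  splices between stop-free genes provably cannot create internal
  stops; disabling the flag allows arbitrary in-run splice points,
  whose rare boundary-codon artefacts are then classified as
  non-producers.

Classification: byte-identity with the parent ⇒ revertant; any
frameshift or internal stop ⇒ non-producer; otherwise by
extension-module count versus the parent (contraction / expansion),
with equal-count-but-different-sequence labelled complex. For
reporting, revertants map to parent-compound producers, in-frame
rearrangements to new-analogue producers, and the rest to
non-producers. The closed-form outcome distribution (weight mass per
class over candidates that contain a long-enough identical run,
normalised) is exposed for direct comparison with Monte-Carlo runs;
rejection-resampling of run-less candidates makes the two exactly
consistent.

## Junction detection

Modules are aligned by pinning the KS, AT and ACP starts and
end-padding the variable segments; the conservation profile is the
sliding mean pairwise column identity over that alignment
(gap-vs-residue and gap-vs-gap count as mismatch).

Attribution slides a window (default 30 aa) over the hybrid
translation and scores it against every module at the homologous
module-aligned offset; each position is attributed to the argmax, with
exact ties marked ambiguous and absorbed into junction regions rather
than broken arbitrarily. This replaces a BLAST master/slave sweep with
a deterministic, dependency-free equivalent driven by the same
quantity (sequence identity); BLAST scores are approximated in
behaviour, not reproduced bit-exactly. Attribution requires
equal-length modules (a gap-free alignment); hybrids formed by
homologous crossovers between such modules stay in register by
construction.

A junction is emitted at each attribution transition `i → j` with
`j ∉ {i, i+1}` — a switch to the natively following module is
indistinguishable from parent sequence, which is how "non-sequential"
is made operational. The transition must be supported by at least two
downstream positions where the hybrid matches module j and differs
from module i; the reported region is the maximal stretch across the
transition where modules i and j agree, so two independent crossovers
inside one identical run yield identical regions. Attribution runs
shorter than the window are treated as boundary noise: windows
straddling module boundaries can flicker to a third module for a few
positions. The consequence, verified against a brute-force
chimera-scoring oracle, is that crossovers at least one window away
from module boundaries are recovered exactly (pair and region), while
crossovers closer to a boundary than one window are localised to
within a window but may be labelled with the adjacent full module —
the sub-window trace of the true module is below any sustainable
evidence threshold. Junctions are reported in coordinate order;
multiple junctions per gene are allowed. Domain context is the domain
containing the region midpoint (within_KS / within_AT /
pre_ACP_linker / other); AT compatibility compares the extender
substrates of the joined modules and is not-applicable outside
AT-coding sequence. Inter-junction distances, where needed, are
midpoint-to-midpoint, matching the region-valued way junctions are
reported.

## Assembly line

Backbone carbons = starter carbons + 2 per extension module; the
starter is a parameter (7 for the cyclohexane-derived starters of the
rapamycin examples) — starter biosynthesis and post-PKS tailoring are
out of scope. α-substituent: malonyl → H, methylmalonyl → CH₃.
β-state from *active* domains only: none → ketone, KR → hydroxyl,
KR+DH → enoyl, KR+DH+ER → methylene; an active DH or ER without an
active KR upstream cannot act and leaves a ketone. Modules missing a
mandatory KS/AT/ACP yield a non-viable prediction carrying the reason
rather than an exception. Cyclisation (including whether truncated
chains close at all), stereochemistry and NRPS extensions are
deliberately not modelled.

## Screening arithmetic

Percentages are computed exactly from integer counts and rounded half
up: one decimal place for populations above 100, nearest integer for
small control arms — the two conventions such screens print.

## Problem sizes

The test suite exercises the detector on 200 independent 14-module
clusters (identity 0.6, hotspot boost 0.2, seeds 1–200), the
detector–oracle equivalence on every single-crossover hybrid of a
5-module toy cluster (300-aa modules, crossovers on a 10-residue
grid), and the simulator against its closed form at 10⁴ events on a
6-module cluster — sizes chosen so the full suite runs in well under a
minute while every property is exercised at meaningful multiplicity.

## Known limitations

* Attribution assumes equal-length (gap-free aligned) modules; loop
  length polymorphism is handled by the aligner and profile but not by
  the detector.
* The simulator's weight function and window geometry are assumptions;
  absolute class fractions should not be compared to any particular
  screen, only structural behaviours (revertant-only below the
  identity floor, frame preservation, hotspot concentration).
* Chimeric-module domain complements are assigned by a midpoint rule
  (each domain slot comes from whichever parent contributes its
  majority); crossovers inside a domain do not model folding or
  activity of the fused domain.
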