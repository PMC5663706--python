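"""Core data model for modular polyketide synthase (PKS) gene clusters.

A modular PKS is an enzymatic assembly line: every round of polyketide
chain extension is carried out by a separate *module* of catalytic
domains encoded in order on one of a handful of giant genes. An
extension module minimally carries a ketosynthase (KS), an
acyltransferase (AT) selecting the extender unit (malonyl- or
methylmalonyl-CoA) and an acyl carrier protein (ACP); an optional
reductive loop (KR, DH, ER) sets the oxidation state of the new
beta-carbon. A loading module (CoA-ligase-like domain, index 0) may
precede the extensions. Domains can be present in the sequence yet
catalytically inactive; the model keeps them, flagged.

Internal coordinates are uniformly 0-based half-open, in amino acids
within a module (``aa_interval``) or nucleotides within a gene
(``nt_interval``). All genes are stored on the forward strand;
reverse-strand CDS are reverse-complemented at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import AmbiguousBaseError, FrameError, ValidationError

__all__ = [
    "DOMAIN_KINDS",
    "AT_SUBSTRATES",
    "DomainAnnotation",
    "ModuleDef",
    "Gene",
    "PKSCluster",
    "HybridRecord",
    "translate_gene",
    "find_internal_stops",
    "module_order",
]

DOMAIN_KINDS = ("CoL", "KS", "AT", "DH", "ER", "KR", "ACP")
AT_SUBSTRATES = ("malonyl", "methylmalonyl", "none")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DomainAnnotation:
    """One catalytic domain inside a module.

    ``aa_interval`` is 0-based half-open in the amino-acid coordinates
    of the parent module. ``at_substrate`` is meaningful only for AT
    domains (the extender unit the AT selects); every other kind must
    carry ``"none"``.
    """

    kind: str
    aa_interval: tuple[int, int]
    active: bool = True
    at_substrate: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        if self.at_substrate not in AT_SUBSTRATES:
            raise ValidationError(f"unknown AT substrate {self.at_substrate!r}")
        start, end = self.aa_interval
        if not (0 <= start < end):
            raise ValidationError(f"{self.kind}: bad aa_interval {self.aa_interval}")
        if (self.kind == "AT") != (self.at_substrate != "none"):
            raise ValidationError(
                f"{self.kind}: at_substrate must be set iff kind is AT "
                f"(got {self.at_substrate!r})"
            )


@dataclass
class ModuleDef:
    """One assembly-line module: its position, its protein sequence and
    an ordered, non-overlapping list of domain annotations.

    ``index`` is the 1-based position in the native assembly line;
    index 0 is the loading module. ``nt_interval`` locates the module
    inside its encoding gene (forward strand, 0-based half-open)."""

    index: int
    gene_id: str
    aa_seq: str
    nt_interval: tuple[int, int]
    domains: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.index < 0:
            raise ValidationError(f"module index {self.index} < 0")
        s, e = self.nt_interval
        if e - s != 3 * len(self.aa_seq):
            raise ValidationError(
                f"module {self.index}: nt_interval length {e - s} != 3*{len(self.aa_seq)}"
            )
        prev_end = -1
        for dom in self.domains:
            ds, de = dom.aa_interval
            if ds < prev_end:
                raise ValidationError(
                    f"module {self.index}: domain {dom.kind} at {dom.aa_interval} "
                    "overlaps or is out of order"
                )
            if de > len(self.aa_seq):
                raise ValidationError(
                    f"module {self.index}: domain {dom.kind} exceeds module length"
                )
            prev_end = de
        if self.is_extension:
            for kind in ("KS", "AT", "ACP"):
                if sum(1 for d in self.domains if d.kind == kind) != 1:
                    raise ValidationError(
                        f"extension module {self.index} must carry exactly one {kind}"
                    )

    @property
    def is_extension(self) -> bool:
        return self.index >= 1

    def domain(self, kind: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None

    @property
    def at_substrate(self) -> str:
        at = self.domain("AT")
        return at.at_substrate if at is not None else "none"

    def active_kinds(self) -> frozenset[str]:
        return frozenset(d.kind for d in self.domains if d.active)


@dataclass
class Gene:
    """A PKS-encoding gene, stored forward-strand. ``strand`` records
    the orientation the gene had in the source file."""

    gene_id: str
    nt_seq: str
    strand: str = "+"


@dataclass
class PKSCluster:
    """An ordered multi-gene PKS cluster with its modules in
    assembly-line order."""

    name: str
    genes: list[Gene]
    modules: list[ModuleDef]
    loading_present: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicate gene ids")
        indices = [m.index for m in self.modules]
        if len(set(indices)) != len(indices):
            raise ValidationError(f"duplicate module indices in {self.name}")
        if sorted(indices) != indices:
            raise ValidationError("modules not in assembly-line order")
        if self.loading_present != (0 in indices):
            raise ValidationError("loading_present inconsistent with module indices")
        by_gene: dict[str, list[ModuleDef]] = {}
        for m in self.modules:
            if m.gene_id not in gene_ids:
                raise ValidationError(f"module {m.index} references unknown gene {m.gene_id}")
            by_gene.setdefault(m.gene_id, []).append(m)
        for gid, mods in by_gene.items():
            gene = self.gene(gid)
            prev_end = 0
            for m in sorted(mods, key=lambda m: m.nt_interval[0]):
                s, e = m.nt_interval
                if s < prev_end or e > len(gene.nt_seq):
                    raise ValidationError(
                        f"module {m.index}: nt_interval {m.nt_interval} overlaps "
                        f"or exceeds gene {gid}"
                    )
                prev_end = e
        for gene in self.genes:
            stops = find_internal_stops(gene.nt_seq)
            if stops:
                raise FrameError(
                    f"gene {gene.gene_id} has internal stop codon(s) at codon(s) "
                    f"{stops[:5]}", gene=gene.gene_id, codons=stops,
                )

    # --- lookups -----------------------------------------------------

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def module_by_index(self, index: int) -> ModuleDef:
        for m in self.modules:
            if m.index == index:
                return m
        raise KeyError(index)

    @property
    def extension_modules(self) -> list[ModuleDef]:
        return [m for m in self.modules if m.is_extension]

    @property
    def n_extension_modules(self) -> int:
        return len(self.extension_modules)

    # --- genome coordinates ------------------------------------------
    # The cluster "genome" is the concatenation of its gene sequences in
    # order; gene offsets are cumulative.

    def gene_offset(self, gene_id: str) -> int:
        off = 0
        for g in self.genes:
            if g.gene_id == gene_id:
                return off
            off += len(g.nt_seq)
        raise KeyError(gene_id)

    def genome(self) -> str:
        return "".join(g.nt_seq for g in self.genes)

    def module_genome_interval(self, module: ModuleDef) -> tuple[int, int]:
        off = self.gene_offset(module.gene_id)
        s, e = module.nt_interval
        return off + s, off + e

    def module_aa_slice(self, module: ModuleDef) -> str:
        gene = self.gene(module.gene_id)
        s, e = module.nt_interval
        return translate_gene(gene.nt_seq[s:e])

    def copy(self) -> "PKSCluster":
        return PKSCluster(
            name=self.name,
            genes=[replace(g) for g in self.genes],
            modules=[
                replace(m, domains=list(m.domains)) for m in self.modules
            ],
            loading_present=self.loading_present,
        )


@dataclass
class HybridRecord:
    """A (possibly recombinant) PKS coding sequence with its translation.

    For synthetic hybrids, ``truth_junctions`` carries the ground-truth
    crossovers and ``modules``/``origins`` describe the realised
    architecture (origins like ``"3/10"`` mark chimeric modules)."""

    seq_id: str
    nt_seq: str
    aa_seq: str
    parent_cluster: PKSCluster | None = None
    truth_junctions: list | None = None
    modules: list[ModuleDef] | None = None
    origins: list[str] | None = None

    def __post_init__(self) -> None:
        if self.truth_junctions:
            for tj in self.truth_junctions:
                if not (0 <= tj.crossover_aa <= len(self.aa_seq)):
                    raise ValidationError(
                        f"truth junction at aa {tj.crossover_aa} outside sequence"
                    )


# --- translation ------------------------------------------------------


def find_internal_stops(nt_seq: str, frame: int = 0) -> list[int]:
    """0-based codon indices of stop codons before the final codon."""
    sub = nt_seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    n_codons = len(sub) // 3
    stops = [
        i for i in range(n_codons)
        if sub[3 * i: 3 * i + 3] in _STANDARD_TABLE.stop_codons
    ]
    return [i for i in stops if i < n_codons - 1]


def translate_gene(nt_seq: str, frame: int = 0, internal_stop: str = "raise") -> str:
    """Translate a coding sequence with the standard genetic code.

    The trailing partial codon is dropped and a terminal stop codon is
    stripped. Internal stops are never silently removed: with
    ``internal_stop="raise"`` (default) a :class:`FrameError` listing
    the offending codons is raised; with ``"keep"`` they appear as
    ``*`` in the output.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    bad = [i for i, b in enumerate(nt_seq) if b not in VALID_BASES]
    if bad:
        raise AmbiguousBaseError(bad)
    sub = nt_seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if len(sub) < 3:
        raise ValueError("sequence shorter than one codon")
    aa = str(Seq(sub).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        codons = [i for i, c in enumerate(aa) if c == "*"]
        if internal_stop == "raise":
            raise FrameError(
                f"internal stop codon(s) at codon(s) {codons}", codons=codons
            )
        if internal_stop != "keep":
            raise ValueError(f"internal_stop must be 'raise' or 'keep', got {internal_stop!r}")
    return aa


def module_order(cluster: PKSCluster) -> list[ModuleDef]:
    """Modules in canonical assembly-line order: loading module (index
    0) first if present, then extension modules by increasing index."""
    indices = [m.index for m in cluster.modules]
    if len(set(indices)) != len(indices):
        raise ValidationError("duplicate module indices")
    return sorted(cluster.modules, key=lambda m: m.index)
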