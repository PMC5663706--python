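"""Synthetic PKS clusters, plasmid integrants and hybrid genes with
known ground truth.

Real assembly-line PKS genes are tandem arrays of mutually homologous
extension modules whose amino-acid identity is elevated inside the KS
and AT coding regions and in the flexible linker just upstream of ACP,
and lower across the variable reductive loop. The generator emulates
exactly that structure: one template module is drawn at random, every
module is derived from it by seeded substitution, with separate
substitution pressure inside and outside the conserved "hotspot"
regions so that the realised mean pairwise identity matches a target
while hotspot columns stay more conserved. Amino-acid sequences are
back-translated with one canonical codon per residue plus seeded
synonymous jitter, so codon-level identity sits below amino-acid
identity, as in real paralogous modules.

Hybrids model a single homologous crossover between two non-adjacent
modules i and j at a homologous position: the product carries modules
``1..i-1``, one chimeric module (front of i, back of j), then
``j+1..n``, so the extension-module change is ``i - j`` (negative for
contractions, positive for the abstract sister-exchange expansions).
Crossovers sit at codon boundaries, as in the sequenced productive
recombinants; frameshifted outcomes are the simulator's business.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .errors import InfeasibleSpecError, ValidationError
from .model import (
    DomainAnnotation,
    Gene,
    HybridRecord,
    ModuleDef,
    PKSCluster,
)
from .simulate import IntegratedState

__all__ = [
    "SyntheticSpec",
    "TruthJunction",
    "generate_cluster",
    "generate_hybrid",
    "generate_integrant",
    "mean_pairwise_identity",
    "write_truth_tsv",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Canonical codon per amino acid (one fixed choice) and full synonym sets
# from the standard genetic code.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _SYNONYMS.setdefault(aa, []).append(codon)
_CANONICAL = {aa: codons[0] for aa, codons in _SYNONYMS.items()}

# Baseline extension-module layout at 1500 aa (kind, start, end); scaled
# proportionally for other module lengths. The stretch between KR end
# and ACP start is the pre-ACP linker.
_BASE_LAYOUT = [
    ("KS", 0, 430),
    ("AT", 450, 750),
    ("DH", 770, 990),
    ("ER", 1000, 1200),
    ("KR", 1210, 1350),
    ("ACP", 1430, 1490),
]
_BASE_LEN = 1500
_LOADING_LAYOUT = [("CoL", 0, 500), ("ACP", 600, 680)]
_LOADING_LEN = 700


def _scale_layout(layout, base_len: int, length: int) -> list[tuple[str, int, int]]:
    out = []
    for kind, s, e in layout:
        ss = int(round(s * length / base_len))
        ee = int(round(e * length / base_len))
        if ee <= ss:
            raise InfeasibleSpecError(f"module length {length} too short for layout")
        out.append((kind, ss, ee))
    for (_, _, e1), (_, s2, _) in zip(out, out[1:]):
        if s2 < e1:
            raise InfeasibleSpecError(f"scaled layout overlaps at length {length}")
    if out[-1][2] > length:
        raise InfeasibleSpecError("layout exceeds module length")
    return out


@dataclass(frozen=True)
class TruthJunction:
    """Ground-truth crossover of a synthetic hybrid: upstream module i,
    downstream module j, and the crossover position in hybrid amino-acid
    and nucleotide coordinates (codon-aligned, so nt = 3*aa)."""

    upstream_module: int
    downstream_module: int
    crossover_aa: int
    crossover_nt: int

    def __post_init__(self):
        if self.downstream_module in (self.upstream_module, self.upstream_module + 1):
            raise ValidationError("junction modules must be non-sequential")
        if self.crossover_nt != 3 * self.crossover_aa:
            raise ValidationError("crossover_nt must equal 3*crossover_aa")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cluster.

    ``identity_target`` is the mean pairwise amino-acid identity across
    extension modules; ``hotspot_boost`` is how much higher identity is
    inside KS, AT and the pre-ACP linker (non-hotspot columns are
    depressed so the overall mean still hits the target).
    """

    n_modules: int = 14
    module_aa_length: int = 1500
    domain_layout: list[tuple[str, int, int]] | None = None
    identity_target: float = 0.6
    hotspot_boost: float = 0.2
    seed: int = 0
    n_genes: int = 3
    loading_module: bool = True
    loading_aa_length: int = 700
    at_substrates: list[str] | None = None
    inactive_domains: dict[int, frozenset[str]] = field(default_factory=dict)
    codon_jitter: float = 0.1
    name: str = "synthetic"

    def __post_init__(self):
        if not (0 < self.identity_target <= 1):
            raise ValidationError("identity_target must be in (0, 1]")
        if self.hotspot_boost < 0 or self.identity_target + self.hotspot_boost > 1:
            raise ValidationError("identity_target + hotspot_boost must be <= 1")
        if self.n_modules < 1:
            raise ValidationError("need at least one extension module")
        if self.n_genes < 1 or self.n_genes > self.n_modules:
            raise ValidationError("n_genes must be in [1, n_modules]")

    @property
    def layout(self) -> list[tuple[str, int, int]]:
        if self.domain_layout is not None:
            return self.domain_layout
        return _scale_layout(_BASE_LAYOUT, _BASE_LEN, self.module_aa_length)

    def hotspot_mask(self) -> np.ndarray:
        """Boolean mask over module positions: KS + AT + pre-ACP linker."""
        mask = np.zeros(self.module_aa_length, dtype=bool)
        layout = self.layout
        for kind, s, e in layout:
            if kind in ("KS", "AT"):
                mask[s:e] = True
        acp_start = next(s for kind, s, _ in layout if kind == "ACP")
        pre_end = max(e for kind, _, e in layout if kind != "ACP")
        mask[pre_end:acp_start] = True
        return mask

    def substrate_of(self, index: int) -> str:
        if self.at_substrates is not None:
            return self.at_substrates[index - 1]
        return "methylmalonyl" if index % 2 == 0 else "malonyl"


# --- identity calibration --------------------------------------------


def _mutation_rate(q: float) -> float:
    """Per-position substitution probability so that two modules
    independently derived from one template share fraction q of
    positions: q = (1-m)^2 + m^2/19."""
    c = 20.0 / 19.0
    disc = 1.0 - c * (1.0 - q)
    if disc < 0:
        raise InfeasibleSpecError(
            f"pairwise identity {q:.3f} below the ~0.05 floor of the flat "
            "substitution model"
        )
    return float((1.0 - np.sqrt(disc)) / c)


def mean_pairwise_identity(seqs: list[str]) -> float:
    """Mean over all unordered pairs of the fraction of identical
    positions (sequences must share one length)."""
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    total, pairs = 0.0, 0
    for a in range(n):
        for b in range(a + 1, n):
            total += float(np.mean(arr[a] == arr[b]))
            pairs += 1
    return total / pairs


def _derive_modules(rng: np.random.Generator, template: np.ndarray,
                    hot: np.ndarray, q_hot: float, q_non: float,
                    n: int) -> np.ndarray:
    L = template.size
    m = np.where(hot, _mutation_rate(q_hot), _mutation_rate(q_non))
    mods = np.empty((n, L), dtype=np.int64)
    for k in range(n):
        mutate = rng.random(L) < m
        offsets = rng.integers(1, 20, size=L)
        mods[k] = np.where(mutate, (template + offsets) % 20, template)
    return mods


def _back_translate(aa: str, rng: np.random.Generator, jitter: float) -> str:
    codons = [_CANONICAL[a] for a in aa]
    if jitter > 0:
        hits = np.flatnonzero(rng.random(len(aa)) < jitter)
        for p in hits:
            syn = _SYNONYMS[aa[p]]
            codons[p] = syn[rng.integers(0, len(syn))]
    return "".join(codons)


def generate_cluster(spec: SyntheticSpec) -> PKSCluster:
    """Generate a multi-gene cluster of homologous extension modules
    (plus an optional loading module) matching ``spec``.

    Deterministic for a fixed seed. Raises :class:`InfeasibleSpecError`
    when the identity target cannot be realised. The realised mean
    pairwise identity is recalibrated until it is within 2 percentage
    points of ``identity_target``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.module_aa_length
    layout = spec.layout
    hot = spec.hotspot_mask()
    f_hot = float(hot.mean())

    t, b = spec.identity_target, spec.hotspot_boost
    q_hot = t + b
    q_non = (t - f_hot * q_hot) / (1.0 - f_hot) if f_hot < 1 else t
    if q_non <= 0:
        raise InfeasibleSpecError(
            "hotspot_boost too large: non-hotspot identity would be negative"
        )

    template = rng.integers(0, 20, size=L)
    aa_arr = None
    for _ in range(25):
        mods = _derive_modules(rng, template, hot, min(q_hot, 1.0), q_non, spec.n_modules)
        seqs = ["".join(AA_ALPHABET[i] for i in row) for row in mods]
        realized = mean_pairwise_identity(seqs) if spec.n_modules > 1 else t
        if abs(realized - t) <= 0.02:
            aa_arr = seqs
            break
        shift = t - realized
        q_hot = min(1.0, max(0.06, q_hot + shift))
        q_non = min(1.0, max(0.06, q_non + shift))
    if aa_arr is None:
        raise InfeasibleSpecError(
            f"could not calibrate identity to {t} +/- 0.02 for spec {spec}"
        )

    # Build module definitions, back-translate, assemble genes.
    def domains_for(index: int) -> list[DomainAnnotation]:
        inactive = spec.inactive_domains.get(index, frozenset())
        return [
            DomainAnnotation(
                kind=kind,
                aa_interval=(s, e),
                active=kind not in inactive,
                at_substrate=spec.substrate_of(index) if kind == "AT" else "none",
            )
            for kind, s, e in layout
        ]

    module_aas: list[tuple[int, str, list[DomainAnnotation]]] = []
    if spec.loading_module:
        load_layout = _scale_layout(_LOADING_LAYOUT, _LOADING_LEN, spec.loading_aa_length)
        load_aa = "".join(
            AA_ALPHABET[i] for i in rng.integers(0, 20, size=spec.loading_aa_length)
        )
        load_doms = [
            DomainAnnotation(kind=k, aa_interval=(s, e)) for k, s, e in load_layout
        ]
        module_aas.append((0, load_aa, load_doms))
    for k in range(spec.n_modules):
        idx = k + 1
        module_aas.append((idx, aa_arr[k], domains_for(idx)))

    # Near-even contiguous split of extension modules across genes; the
    # loading module rides on the first gene.
    base, rem = divmod(spec.n_modules, spec.n_genes)
    sizes = [base + (1 if g < rem else 0) for g in range(spec.n_genes)]
    gene_names = [f"{spec.name}{chr(ord('A') + g)}" for g in range(spec.n_genes)]

    genes: list[Gene] = []
    modules: list[ModuleDef] = []
    cursor = 0
    for g, size in enumerate(sizes):
        chunk = module_aas[cursor: cursor + size] if g > 0 else module_aas[: sizes[0] + (1 if spec.loading_module else 0)]
        if g == 0:
            cursor = len(chunk)
        else:
            cursor += size
        parts = []
        offset = 0
        for index, aa, doms in chunk:
            nt = _back_translate(aa, rng, spec.codon_jitter)
            modules.append(
                ModuleDef(
                    index=index,
                    gene_id=gene_names[g],
                    aa_seq=aa,
                    nt_interval=(offset, offset + len(nt)),
                    domains=doms,
                )
            )
            parts.append(nt)
            offset += len(nt)
        genes.append(Gene(gene_names[g], "".join(parts) + "TAA"))

    return PKSCluster(
        name=spec.name,
        genes=genes,
        modules=sorted(modules, key=lambda m: m.index),
        loading_present=spec.loading_module,
    )


# --- hybrids ----------------------------------------------------------


def _module_nt(cluster: PKSCluster, module: ModuleDef) -> str:
    gene = cluster.gene(module.gene_id)
    s, e = module.nt_interval
    return gene.nt_seq[s:e]


def generate_hybrid(
    cluster: PKSCluster,
    i: int,
    j: int,
    crossover_frac: float | None = None,
    seed: int = 0,
    seq_id: str | None = None,
) -> HybridRecord:
    """Single-crossover hybrid joining module ``i`` (upstream, kept up
    to the crossover) to module ``j`` (downstream, kept from the
    homologous point onward). ``j > i+1`` contracts the line (modules
    between them are lost, i and j merge into one chimera); ``j < i``
    expands it (tandem duplication of ``j..i``). ``j == i`` and
    ``j == i+1`` are rejected: the former is a revertant, the latter
    indistinguishable from the parent sequence. The net module change
    is ``i - j``.

    When ``crossover_frac`` is None a position is sampled from
    ``seed``; crossovers sit at codon boundaries so frame is preserved.
    """
    ext = cluster.extension_modules
    n = len(ext)
    if not (1 <= i <= n) or not (1 <= j <= n):
        raise ValidationError(f"module indices ({i}, {j}) out of range 1..{n}")
    if j in (i, i + 1):
        raise ValidationError(f"j={j} must not equal i or i+1 (i={i})")
    lengths = {len(m.aa_seq) for m in ext}
    if len(lengths) != 1:
        raise ValidationError("hybrid construction requires equal-length modules")
    L = lengths.pop()
    if crossover_frac is None:
        crossover_frac = float(np.random.default_rng(seed).uniform(0.05, 0.95))
    if not (0 < crossover_frac < 1):
        raise ValidationError("crossover_frac must be in (0, 1)")
    x = min(max(int(round(crossover_frac * L)), 1), L - 1)

    by_index = {m.index: m for m in ext}
    mi, mj = by_index[i], by_index[j]

    kept = [by_index[k] for k in range(1, i)]
    tail = [by_index[k] for k in range(j + 1, n + 1)]

    aa_parts = [m.aa_seq for m in kept]
    nt_parts = [_module_nt(cluster, m) for m in kept]
    chim_aa = mi.aa_seq[:x] + mj.aa_seq[x:]
    chim_nt = _module_nt(cluster, mi)[: 3 * x] + _module_nt(cluster, mj)[3 * x:]
    aa_parts.append(chim_aa)
    nt_parts.append(chim_nt)
    aa_parts += [m.aa_seq for m in tail]
    nt_parts += [_module_nt(cluster, m) for m in tail]

    # Chimeric domain complement: each domain slot comes from whichever
    # parent contributes the majority of it (midpoint rule).
    if [d.kind for d in mi.domains] != [d.kind for d in mj.domains]:
        raise ValidationError("modules i and j have different domain complements")
    chim_domains = []
    for di, dj in zip(mi.domains, mj.domains):
        src = di if (di.aa_interval[0] + di.aa_interval[1]) / 2 < x else dj
        chim_domains.append(src)

    modules: list[ModuleDef] = []
    origins: list[str] = []
    offset = 0
    source = kept + [None] + tail  # None marks the chimera slot
    for slot, (src, aa, nt) in enumerate(zip(source, aa_parts, nt_parts), start=1):
        doms = chim_domains if src is None else src.domains
        modules.append(
            ModuleDef(
                index=slot,
                gene_id="hybrid",
                aa_seq=aa,
                nt_interval=(offset, offset + len(nt)),
                domains=list(doms),
            )
        )
        origins.append(f"{i}/{j}" if src is None else str(src.index))
        offset += len(nt)

    crossover_aa = (i - 1) * L + x
    truth = TruthJunction(
        upstream_module=i,
        downstream_module=j,
        crossover_aa=crossover_aa,
        crossover_nt=3 * crossover_aa,
    )
    return HybridRecord(
        seq_id=seq_id or f"{cluster.name}_hybrid_{i}_{j}",
        nt_seq="".join(nt_parts),
        aa_seq="".join(aa_parts),
        parent_cluster=cluster,
        truth_junctions=[truth],
        modules=modules,
        origins=origins,
    )


# --- integrated-plasmid states ---------------------------------------


def generate_integrant(
    cluster: PKSCluster,
    gene_id: str,
    homology_interval: tuple[int, int],
    seed: int = 0,
    replicon_nt: int = 500,
    marker_nt: int = 300,
) -> IntegratedState:
    """Model single-crossover plasmid integration via a homology segment
    inside one gene: the resulting genome carries the homology segment
    as a direct repeat flanking the (placeholder) replicon + marker."""
    gene = cluster.gene(gene_id)
    s, e = homology_interval
    if not (0 <= s < e <= len(gene.nt_seq)):
        raise ValidationError(
            f"homology interval {homology_interval} not within gene {gene_id} "
            f"(len {len(gene.nt_seq)})"
        )
    rng = np.random.default_rng(seed)
    foreign = "".join(
        "ACGT"[b] for b in rng.integers(0, 4, size=replicon_nt + marker_nt)
    )
    genome = cluster.genome()
    off = cluster.gene_offset(gene_id)
    hs, he = off + s, off + e
    full = genome[:he] + foreign + genome[hs:]
    hlen = e - s
    return IntegratedState(
        parent=cluster,
        insertion_nt=he,
        repeat_copies=((hs, he), (he + len(foreign), he + len(foreign) + hlen)),
        replicon_interval=(he, he + len(foreign)),
        full_seq=full,
    )


def write_truth_tsv(hybrids: list[HybridRecord], path: str | Path) -> Path:
    """Sidecar TSV of ground-truth junctions: seq_id, i, j, crossover_nt,
    crossover_aa."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("seq_id\ti\tj\tcrossover_nt\tcrossover_aa\n")
        for h in hybrids:
            for tj in h.truth_junctions or []:
                fh.write(
                    f"{h.seq_id}\t{tj.upstream_module}\t{tj.downstream_module}\t"
                    f"{tj.crossover_nt}\t{tj.crossover_aa}\n"
                )
    return path
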