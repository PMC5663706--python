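"""Stochastic model of accelerated-evolution resolution events.

After single-crossover integration, the genome carries the plasmid
replicon flanked by a perfect direct repeat of the homology segment,
embedded in a tandem array of mutually homologous PKS modules. Under
replicon-induced stress the state resolves by homologous recombination
between a locus left of the replicon and a locus right of it; the
replicon and everything between the crossover points is lost.
Recombination through the perfect repeat restores the parent
(revertant); recombination between homologous stretches of two
*different* modules conflates them into a chimera, deleting the
intervening modules (contraction). Module duplications, which the
single-molecule deletion geometry cannot produce, are modelled
abstractly as the same pairing with the roles of the two loci reversed
on a sister copy (``allow_expansion``).

Candidate loci are ungapped module-aligned windows (modules are
collinear paralogs, so no gapped search is needed); a pair qualifies
when its nucleotide identity reaches ``min_identity``. A pair is
sampled with probability proportional to
``(identity - min_identity + epsilon) * window_length`` and the
crossover is placed uniformly inside an exactly identical run of at
least ``min_identical_run`` nucleotides — recombination cannot be
localised more finely than the identical stretch it happened in.
These weights are declared model assumptions, not measured biology.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AEPKSError, ValidationError
from .model import Gene, PKSCluster, find_internal_stops

__all__ = [
    "IntegratedState",
    "Candidate",
    "RecombinationEvent",
    "ResolvedGenome",
    "OutcomeSummary",
    "SimulationParams",
    "enumerate_homologous_pairs",
    "sample_resolution",
    "classify_outcome",
    "simulate_population",
    "outcome_distribution",
    "PHENOTYPE_OF_CLASS",
]

EVENT_CLASSES = ("revertant", "contraction", "expansion", "non_producer", "complex")

# Reporting map onto the three screening phenotypes.
PHENOTYPE_OF_CLASS = {
    "revertant": "parent_producer",
    "contraction": "new_analogue",
    "expansion": "new_analogue",
    "complex": "new_analogue",
    "non_producer": "non_producer",
}


@dataclass
class IntegratedState:
    """Genome state after single-crossover plasmid integration: the
    homology segment occurs as two identical direct repeats flanking
    the replicon."""

    parent: PKSCluster
    insertion_nt: int
    repeat_copies: tuple[tuple[int, int], tuple[int, int]]
    replicon_interval: tuple[int, int]
    full_seq: str

    def __post_init__(self):
        (l1, r1), (l2, r2) = self.repeat_copies
        if self.full_seq[l1:r1] != self.full_seq[l2:r2]:
            raise ValidationError("repeat copies are not identical substrings")
        if not (r1 <= self.replicon_interval[0] and self.replicon_interval[1] <= l2):
            raise ValidationError("replicon does not lie between the repeat copies")

    @property
    def insert_shift(self) -> int:
        """Offset between right-copy state coordinates and parent
        coordinates."""
        return len(self.full_seq) - len(self.parent.genome())

    @property
    def homology_parent_interval(self) -> tuple[int, int]:
        return self.repeat_copies[0]


@dataclass(frozen=True)
class Candidate:
    """One candidate crossover pairing: a window left of the replicon
    and a module-aligned window right of it, with their parent-genome
    coordinates and the modules they fall in. ``orientation`` is
    "forward" (deletion geometry) or "reversed" (abstract
    sister-exchange duplication)."""

    left_locus: tuple[int, int]
    right_locus: tuple[int, int]
    identity: float
    parent_left: int
    parent_right: int
    module_left: int
    module_right: int
    offset: int
    orientation: str = "forward"

    @property
    def length(self) -> int:
        return self.left_locus[1] - self.left_locus[0]


@dataclass
class ResolvedGenome:
    """Outcome of one resolution: the reconstituted gene set and the
    arithmetic extension-module count."""

    genes: list[Gene]
    genome: str
    n_extension: int


@dataclass
class RecombinationEvent:
    candidate: Candidate
    crossover_left: int
    crossover_right: int
    window_identity: float
    event_class: str
    result: ResolvedGenome


@dataclass
class OutcomeSummary:
    """Tally of a simulated resolution population."""

    n: int
    seed: int
    counts: dict[str, int]
    fractions: dict[str, float]
    phenotype_counts: dict[str, int]
    phenotype_fractions: dict[str, float]
    events: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if sum(self.counts.values()) != self.n:
            raise ValidationError("class counts do not sum to n")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("class fractions do not sum to 1")


@dataclass(frozen=True)
class SimulationParams:
    """Declared kinetic knobs of the resolution model (config, not
    biology): window and step in nt, identity floor, minimum exactly
    identical run around a crossover, and the epsilon of the sampling
    weight."""

    window_nt: int = 100
    step_nt: int = 100
    min_identity: float = 0.8
    min_identical_run: int = 20
    epsilon: float = 0.01
    allow_expansion: bool = True
    codon_aligned: bool = True

    def __post_init__(self):
        if self.window_nt < self.min_identical_run:
            raise ValidationError("window_nt must be >= min_identical_run")
        if not (0 < self.min_identity <= 1):
            raise ValidationError("min_identity must be in (0, 1]")


# --- candidate enumeration -------------------------------------------


def enumerate_homologous_pairs(
    state: IntegratedState,
    window_nt: int = 100,
    min_identity: float = 0.8,
    step_nt: int | None = None,
    allow_expansion: bool = True,
) -> list[Candidate]:
    """All module-aligned window pairs (left of the replicon x right of
    it) with ungapped nucleotide identity >= ``min_identity``, plus —
    always — the duplicated homology-segment pair at identity 1.0."""
    params_step = step_nt or window_nt
    parent = state.parent
    genome = parent.genome()
    garr = np.frombuffer(genome.encode(), dtype=np.uint8)
    hs, he = state.homology_parent_interval
    shift = state.insert_shift

    ext = parent.extension_modules
    intervals = {m.index: parent.module_genome_interval(m) for m in ext}
    nt_lens = {m.index: intervals[m.index][1] - intervals[m.index][0] for m in ext}

    candidates: list[Candidate] = []
    for a, b in itertools.product(ext, ext):
        la, lb = nt_lens[a.index], nt_lens[b.index]
        max_off = min(la, lb) - window_nt
        if max_off < 0:
            continue
        sa, sb = intervals[a.index][0], intervals[b.index][0]
        eq = garr[sa: sa + min(la, lb)] == garr[sb: sb + min(la, lb)]
        csum = np.concatenate(([0], np.cumsum(eq)))
        for o in range(0, max_off + 1, params_step):
            p1, p2 = sa + o, sb + o
            # left window must end before the replicon (i.e. inside the
            # state prefix parent[:he]); right window must start at or
            # after the homology start so it exists right of the replicon.
            if p1 + window_nt > he or p2 < hs:
                continue
            ident = float(csum[o + window_nt] - csum[o]) / window_nt
            if ident < min_identity:
                continue
            orientations = ["forward"]
            if allow_expansion and p1 != p2:
                orientations.append("reversed")
            for orient in orientations:
                candidates.append(
                    Candidate(
                        left_locus=(p1, p1 + window_nt),
                        right_locus=(p2 + shift, p2 + shift + window_nt),
                        identity=ident,
                        parent_left=p1,
                        parent_right=p2,
                        module_left=a.index,
                        module_right=b.index,
                        offset=o,
                        orientation=orient,
                    )
                )

    # The perfect direct repeat created by integration, as one
    # full-length candidate pair.
    candidates.append(
        Candidate(
            left_locus=(hs, he),
            right_locus=(hs + shift, he + shift),
            identity=1.0,
            parent_left=hs,
            parent_right=hs,
            module_left=-1,
            module_right=-1,
            offset=0,
            orientation="forward",
        )
    )
    return candidates


def candidate_weight(c: Candidate, params: SimulationParams) -> float:
    return (c.identity - params.min_identity + params.epsilon) * c.length


# --- resolution -------------------------------------------------------


def _identical_run_positions(eq: np.ndarray, min_run: int,
                             codon_positions: np.ndarray | None) -> np.ndarray:
    """Positions lying inside maximal identical runs of length >=
    min_run (optionally restricted to codon-boundary positions)."""
    if not eq.any():
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    keep = (ends - starts) >= min_run
    pos = np.concatenate(
        [np.arange(s, e) for s, e in zip(starts[keep], ends[keep])]
        or [np.empty(0, dtype=np.int64)]
    )
    if codon_positions is not None and pos.size:
        pos = pos[codon_positions[pos]]
    return pos


def _resolve(parent: PKSCluster, q_up: int, q_down: int) -> ResolvedGenome:
    """Build the resolved genome ``parent[:q_up] + parent[q_down:]`` and
    its gene set; for q_up > q_down this duplicates the span between."""
    genome = parent.genome()
    offsets = []
    pos = 0
    for g in parent.genes:
        offsets.append((pos, pos + len(g.nt_seq), g))
        pos += len(g.nt_seq)

    def gene_at(q: int):
        for s, e, g in offsets:
            if s <= q < e:
                return s, e, g
        return offsets[-1]

    su, _, gu = gene_at(q_up)
    sd, ed, gd = gene_at(q_down)
    iu = next(k for k, (s, _, _) in enumerate(offsets) if s == su)
    idn = next(k for k, (s, _, _) in enumerate(offsets) if s == sd)

    merged = Gene(
        gene_id=gu.gene_id if gu.gene_id == gd.gene_id else f"{gu.gene_id}-{gd.gene_id}",
        nt_seq=gu.nt_seq[: q_up - su] + gd.nt_seq[q_down - sd:],
    )
    genes = [g for _, _, g in offsets[:iu]] + [merged] + [g for _, _, g in offsets[idn + 1:]]
    # n_extension is provisional; callers overwrite it with the event
    # arithmetic before classification.
    return ResolvedGenome(
        genes=genes,
        genome=genome[:q_up] + genome[q_down:],
        n_extension=parent.n_extension_modules,
    )


def _event_arith_count(parent: PKSCluster, c: Candidate) -> int:
    """Extension-module count of the resolved line, from the module
    indices of the two crossover loci."""
    n = parent.n_extension_modules
    if c.parent_left == c.parent_right:
        return n
    if c.module_left < 0 or c.module_right < 0:
        return n
    if c.orientation == "forward":
        return n - (c.module_right - c.module_left)
    return n + (c.module_right - c.module_left)


def classify_outcome(
    parent: PKSCluster,
    result_genes: list[Gene],
    n_extension: int | None = None,
) -> str:
    """Classify a resolved gene set: ``non_producer`` on any frameshift,
    internal stop or empty assembly line; ``revertant`` if the genome is
    byte-identical to the parent; contraction/expansion by extension-
    module count; ``complex`` when the count matches the parent but the
    sequence does not (e.g. a balanced deletion + duplication)."""
    genome = "".join(g.nt_seq for g in result_genes)
    if genome == parent.genome():
        return "revertant"
    for g in result_genes:
        if len(g.nt_seq) % 3 != 0 or find_internal_stops(g.nt_seq):
            return "non_producer"
    if n_extension is None:
        # Infer from the length change at the mean module size.
        mod_nt = int(
            np.mean([3 * len(m.aa_seq) for m in parent.extension_modules])
        )
        n_extension = parent.n_extension_modules + round(
            (len(genome) - len(parent.genome())) / mod_nt
        )
    if n_extension < 1:
        return "non_producer"
    if n_extension < parent.n_extension_modules:
        return "contraction"
    if n_extension > parent.n_extension_modules:
        return "expansion"
    return "complex"


def sample_resolution(
    state: IntegratedState,
    candidates: list[Candidate],
    rng: np.random.Generator,
    params: SimulationParams = SimulationParams(),
    max_retries: int = 100,
) -> RecombinationEvent:
    """Sample one resolution event: pick a candidate pair by weight,
    place the crossover uniformly inside an exactly identical run, and
    reconstruct + classify the resolved genome."""
    if not candidates:
        raise AEPKSError("empty candidate list")
    parent = state.parent
    garr = np.frombuffer(parent.genome().encode(), dtype=np.uint8)
    weights = np.array([candidate_weight(c, params) for c in candidates])
    if (weights <= 0).any():
        raise ValidationError("non-positive candidate weight; check epsilon")
    probs = weights / weights.sum()

    for _ in range(max_retries):
        k = int(rng.choice(len(candidates), p=probs))
        c = candidates[k]
        pos = _draw_crossover(garr, c, rng, params)
        if pos is None:
            continue
        q_up, q_down = _splice_coords(c, pos)
        n_ext = _event_arith_count(parent, c)
        result = _resolve(parent, q_up, q_down)
        result.n_extension = n_ext
        cls = classify_outcome(parent, result.genes, n_extension=n_ext)
        return RecombinationEvent(
            candidate=c,
            crossover_left=q_up,
            crossover_right=q_down,
            window_identity=c.identity,
            event_class=cls,
            result=result,
        )
    raise AEPKSError(
        f"no candidate with an identical run >= {params.min_identical_run} nt "
        f"found in {max_retries} draws"
    )


def _draw_crossover(garr, c: Candidate, rng, params: SimulationParams):
    w = c.length
    eq = garr[c.parent_left: c.parent_left + w] == garr[c.parent_right: c.parent_right + w]
    codon_ok = None
    if params.codon_aligned:
        codon_ok = (np.arange(c.parent_left, c.parent_left + w) % 3) == 0
    pos = _identical_run_positions(eq, params.min_identical_run, codon_ok)
    if pos.size == 0:
        return None
    return int(pos[rng.integers(0, pos.size)])


def _splice_coords(c: Candidate, pos: int) -> tuple[int, int]:
    if c.orientation == "forward":
        return c.parent_left + pos, c.parent_right + pos
    return c.parent_right + pos, c.parent_left + pos


def candidate_is_eligible(garr, c: Candidate, params: SimulationParams) -> bool:
    w = c.length
    eq = garr[c.parent_left: c.parent_left + w] == garr[c.parent_right: c.parent_right + w]
    codon_ok = None
    if params.codon_aligned:
        codon_ok = (np.arange(c.parent_left, c.parent_left + w) % 3) == 0
    return _identical_run_positions(eq, params.min_identical_run, codon_ok).size > 0


def outcome_distribution(
    state: IntegratedState,
    candidates: list[Candidate],
    params: SimulationParams = SimulationParams(),
) -> dict[str, float]:
    """Closed-form event-class distribution: weight mass per class over
    eligible candidates (those containing an identical run long enough
    to host a crossover), normalised."""
    parent = state.parent
    garr = np.frombuffer(parent.genome().encode(), dtype=np.uint8)
    mass: Counter = Counter()
    for c in candidates:
        if not candidate_is_eligible(garr, c, params):
            continue
        pos_any = _draw_crossover(garr, c, np.random.default_rng(0), params)
        q_up, q_down = _splice_coords(c, pos_any)
        n_ext = _event_arith_count(parent, c)
        result = _resolve(parent, q_up, q_down)
        cls = classify_outcome(parent, result.genes, n_extension=n_ext)
        mass[cls] += candidate_weight(c, params)
    total = sum(mass.values())
    if total == 0:
        raise AEPKSError("no eligible candidates")
    return {cls: mass.get(cls, 0.0) / total for cls in EVENT_CLASSES}


def simulate_population(
    state: IntegratedState,
    n: int,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    candidates: list[Candidate] | None = None,
) -> OutcomeSummary:
    """Draw ``n`` independent resolution events, classify and tally
    them. Deterministic per seed; the per-event log is retained as a
    DataFrame on the summary."""
    if n < 1:
        raise ValidationError("population size must be >= 1")
    if candidates is None:
        candidates = enumerate_homologous_pairs(
            state,
            window_nt=params.window_nt,
            min_identity=params.min_identity,
            step_nt=params.step_nt,
            allow_expansion=params.allow_expansion,
        )
    rng = np.random.default_rng(seed)
    parent = state.parent
    garr = np.frombuffer(parent.genome().encode(), dtype=np.uint8)
    weights = np.array([candidate_weight(c, params) for c in candidates])
    probs = weights / weights.sum()

    # Result sequence and class depend only on the candidate (splices
    # anywhere inside an identical run yield the same string), so cache.
    cache: dict[int, tuple[str, int]] = {}
    rows = []
    counts: Counter = Counter()
    for _ in range(n):
        for _retry in range(100):
            k = int(rng.choice(len(candidates), p=probs))
            c = candidates[k]
            pos = _draw_crossover(garr, c, rng, params)
            if pos is not None:
                break
        else:
            raise AEPKSError("no eligible candidate found in 100 draws")
        if k in cache:
            cls, n_ext = cache[k]
        else:
            q_up, q_down = _splice_coords(c, pos)
            n_ext = _event_arith_count(parent, c)
            result = _resolve(parent, q_up, q_down)
            cls = classify_outcome(parent, result.genes, n_extension=n_ext)
            cache[k] = (cls, n_ext)
        q_up, q_down = _splice_coords(c, pos)
        counts[cls] += 1
        rows.append(
            {
                "left_start": c.left_locus[0],
                "left_end": c.left_locus[1],
                "right_start": c.right_locus[0],
                "right_end": c.right_locus[1],
                "module_left": c.module_left,
                "module_right": c.module_right,
                "orientation": c.orientation,
                "identity": c.identity,
                "crossover_left": q_up,
                "crossover_right": q_down,
                "event_class": cls,
                "n_extension": n_ext,
            }
        )

    count_dict = {cls: counts.get(cls, 0) for cls in EVENT_CLASSES}
    frac = {cls: v / n for cls, v in count_dict.items()}
    ph_counts: Counter = Counter()
    for cls, v in count_dict.items():
        ph_counts[PHENOTYPE_OF_CLASS[cls]] += v
    ph = {k: ph_counts.get(k, 0) for k in ("parent_producer", "new_analogue", "non_producer")}
    return OutcomeSummary(
        n=n,
        seed=seed,
        counts=count_dict,
        fractions=frac,
        phenotype_counts=ph,
        phenotype_fractions={k: v / n for k, v in ph.items()},
        events=pd.DataFrame(rows),
    )
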