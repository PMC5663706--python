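"""Recombination-junction detection in hybrid PKS genes.

A junction is the place in a translated hybrid gene where sequence
attribution switches from one native module to a *non-sequential* one:
the amino acids upstream are identical to module i, and downstream at
least two amino acids differ from module i while matching another
module j with j not in {i, i+1} (a switch to the natively following
module is indistinguishable from parent sequence). Because the two
modules are typically identical for a stretch around the crossover,
the junction is reported as a *region* — the maximal run across the
transition where modules i and j agree — rather than a point; the true
crossover can sit anywhere inside it.

Attribution is window-based: every hybrid position is scored by the
identity of its surrounding window against every module at the
homologous module-aligned offset, and attributed to the argmax (ties
are marked ambiguous and absorbed into the junction region). This is a
deterministic, dependency-free stand-in for a BLAST master/slave
sweep; both are driven purely by sequence identity.

Junction regions are classified by domain context (within KS, within
AT, in the flexible pre-ACP linker, or other) and, for junctions
inside AT-coding sequence, checked for extender-unit compatibility of
the joined modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import HybridRecord, ModuleDef, PKSCluster

__all__ = [
    "ModuleAlignment",
    "Attribution",
    "Junction",
    "SimilarityProfile",
    "align_modules",
    "attribute_positions",
    "detect_junctions",
    "classify_domain_context",
    "at_compatibility",
    "conservation_profile",
]

ANCHOR_KINDS = ("KS", "AT", "ACP")


@dataclass
class ModuleAlignment:
    """Anchor-based multiple alignment of a cluster's extension modules.

    Modules are aligned by pinning the starts of the shared KS, AT and
    ACP domains and end-padding the variable stretches between anchors
    with gaps. ``col_to_pos[m][c]`` maps alignment column c back to a
    module-local position (-1 at gaps)."""

    module_indices: list[int]
    rows: list[str]
    col_to_pos: list[np.ndarray]
    anchor_cols: dict[str, int]
    cluster: PKSCluster

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def has_gaps(self) -> bool:
        return any("-" in r for r in self.rows)

    def matrix(self) -> np.ndarray:
        return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows])


def align_modules(cluster: PKSCluster) -> ModuleAlignment:
    """Align extension modules by their KS/AT/ACP anchors, gap-padding
    the variable segments (notably the reductive loop between AT end
    and ACP start)."""
    modules = cluster.extension_modules
    if len(modules) < 2:
        raise ValidationError("alignment needs at least two extension modules")
    bounds: list[list[int]] = []
    for m in modules:
        anchors = {}
        for kind in ANCHOR_KINDS:
            d = m.domain(kind)
            if d is None:
                raise ValidationError(f"module {m.index} lacks {kind} anchor domain")
            anchors[kind] = d.aa_interval[0]
        b = [0, anchors["KS"], anchors["AT"], anchors["ACP"], len(m.aa_seq)]
        if b != sorted(b):
            raise ValidationError(f"module {m.index}: anchors out of order")
        bounds.append(b)

    n_seg = 4
    seg_lens = [max(b[s + 1] - b[s] for b in bounds) for s in range(n_seg)]
    rows, maps = [], []
    # anchor columns: cumulative sums of padded segment lengths
    anchor_cols = {
        "KS": seg_lens[0],
        "AT": seg_lens[0] + seg_lens[1],
        "ACP": seg_lens[0] + seg_lens[1] + seg_lens[2],
    }
    for m, b in zip(modules, bounds):
        row = []
        cmap = []
        for s in range(n_seg):
            seg = m.aa_seq[b[s]: b[s + 1]]
            row.append(seg + "-" * (seg_lens[s] - len(seg)))
            cmap.extend(range(b[s], b[s + 1]))
            cmap.extend([-1] * (seg_lens[s] - len(seg)))
        rows.append("".join(row))
        maps.append(np.array(cmap))
    return ModuleAlignment(
        module_indices=[m.index for m in modules],
        rows=rows,
        col_to_pos=maps,
        anchor_cols=anchor_cols,
        cluster=cluster,
    )


@dataclass
class Attribution:
    """Per-position best-module attribution of a hybrid sequence.
    ``best[p]`` is the position in ``module_indices`` of the winning
    module, or -1 where the windowed identity is tied (ambiguous)."""

    module_indices: list[int]
    best: np.ndarray
    window_counts: np.ndarray  # (n_modules, len) integer match counts
    match: np.ndarray          # (n_modules, len) per-position equality
    module_len: int
    window_aa: int


def attribute_positions(
    hybrid: HybridRecord,
    alignment: ModuleAlignment,
    window_aa: int = 30,
) -> Attribution:
    """Score every hybrid position against every module at the
    homologous module-aligned offset, using the identity of the
    surrounding ``window_aa`` residues; attribute to the argmax, ties
    marked ambiguous.

    Requires equal-length (gap-free) modules so that hybrid positions
    map onto module offsets by position modulo module length — which
    holds for any hybrid formed by homologous crossovers between
    equal-length modules.
    """
    if not hybrid.aa_seq:
        raise ValidationError("empty hybrid translation")
    if len(hybrid.aa_seq) < window_aa:
        raise ValidationError("hybrid shorter than attribution window")
    if alignment.has_gaps:
        raise ValidationError(
            "window attribution requires equal-length modules (gap-free alignment)"
        )
    mat = alignment.matrix()          # (n, L)
    L = mat.shape[1]
    harr = np.frombuffer(hybrid.aa_seq.encode(), dtype=np.uint8)
    cols = np.arange(harr.size) % L
    match = mat[:, cols] == harr[None, :]      # (n, P)

    half = window_aa // 2
    csum = np.concatenate(
        [np.zeros((mat.shape[0], 1), dtype=np.int64), np.cumsum(match, axis=1)], axis=1
    )
    P = harr.size
    lo = np.maximum(np.arange(P) - half, 0)
    hi = np.minimum(np.arange(P) + half + 1, P)
    counts = csum[:, hi] - csum[:, lo]         # (n, P)

    order = np.argsort(-counts, axis=0)
    top = order[0]
    top_val = counts[top, np.arange(P)]
    second_val = np.where(
        counts.shape[0] > 1, counts[order[1], np.arange(P)], -1
    )
    best = np.where(top_val > second_val, top, -1)
    return Attribution(
        module_indices=alignment.module_indices,
        best=best,
        window_counts=counts,
        match=match,
        module_len=L,
        window_aa=window_aa,
    )


@dataclass
class Junction:
    """A detected recombination junction between non-sequential modules.

    ``ambiguity_interval`` is the half-open amino-acid interval on the
    hybrid within which the crossover cannot be localised (modules i
    and j are identical across it); ``discriminating_positions`` are
    the downstream residues proving the switch (hybrid == module j !=
    module i)."""

    upstream_module: int
    downstream_module: int
    ambiguity_interval: tuple[int, int]
    discriminating_positions: list[int]
    nt_interval: tuple[int, int]
    domain_context: str = "other"
    at_compatible: bool | None = None

    def __post_init__(self):
        if self.downstream_module in (self.upstream_module, self.upstream_module + 1):
            raise ValidationError("junction modules must be non-sequential")
        if self.nt_interval != (3 * self.ambiguity_interval[0], 3 * self.ambiguity_interval[1]):
            raise ValidationError("nt_interval must be 3x the aa interval")

    @property
    def midpoint_aa(self) -> int:
        return (self.ambiguity_interval[0] + self.ambiguity_interval[1]) // 2

    def contains_crossover(self, aa_pos: int) -> bool:
        return self.ambiguity_interval[0] <= aa_pos < self.ambiguity_interval[1]


def detect_junctions(
    hybrid: HybridRecord,
    cluster: PKSCluster,
    window_aa: int = 30,
    min_discriminating: int = 2,
    min_run_aa: int | None = None,
    alignment: ModuleAlignment | None = None,
    attribution: Attribution | None = None,
) -> list[Junction]:
    """Detect recombination junctions in a hybrid gene.

    A junction is emitted at each attribution transition i -> j with j
    not in {i, i+1}, validated by at least ``min_discriminating``
    downstream positions where the hybrid matches module j and differs
    from module i. An empty list means no non-native junction was
    found (a revertant, or a crossover inside sequence too similar to
    localise — the undetectable case is reported as absence, never as
    a wrong module pair).

    Attribution runs shorter than ``min_run_aa`` (default: the window
    size) are treated as noise: windows straddling module boundaries
    can flicker to a third module for a handful of positions, and the
    upstream/downstream attribution must be sustained."""
    if min_run_aa is None:
        min_run_aa = window_aa
    if alignment is None:
        alignment = align_modules(cluster)
    if attribution is None:
        attribution = attribute_positions(hybrid, alignment, window_aa=window_aa)
    best = attribution.best
    L = attribution.module_len
    idx_of = attribution.module_indices
    mat = alignment.matrix()
    cols = np.arange(best.size) % L

    # Run-length encode the attribution; ambiguous stretches between
    # two runs of the same module are absorbed into that run.
    runs: list[tuple[int, int, int]] = []  # (module_row, start, end)
    for p, b in enumerate(best):
        if b < 0:
            continue
        if runs and runs[-1][0] == b:
            runs[-1] = (b, runs[-1][1], p + 1)
        else:
            runs.append((b, p, p + 1))
    # Drop sub-threshold runs, then re-merge neighbours that now carry
    # the same module.
    runs = [r for r in runs if r[2] - r[1] >= min_run_aa]
    merged: list[tuple[int, int, int]] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1] = (r[0], merged[-1][1], r[2])
        else:
            merged.append(r)
    runs = merged

    junctions: list[Junction] = []
    for (ri, si, ei), (rj, sj, ej) in zip(runs, runs[1:]):
        mi, mj = idx_of[ri], idx_of[rj]
        if mj == mi or mj == mi + 1:
            continue
        # Discriminating positions: hybrid == M_j != M_i (and the
        # reverse for the upstream side), at aligned offsets.
        differ = mat[ri, cols] != mat[rj, cols]
        disc_j = attribution.match[rj] & differ & ~attribution.match[ri]
        disc_i = attribution.match[ri] & differ & ~attribution.match[rj]
        dj_idx = np.flatnonzero(disc_j)
        di_idx = np.flatnonzero(disc_i)
        dj_after = dj_idx[dj_idx >= si]
        if dj_after.size < min_discriminating:
            continue
        v = int(dj_after[0])
        di_before = di_idx[di_idx < v]
        if di_before.size == 0:
            continue
        u = int(di_before[-1])
        n_disc = int(dj_after[dj_after < ej].size)
        if n_disc < min_discriminating:
            continue
        interval = (u + 1, v + 1)
        j = Junction(
            upstream_module=mi,
            downstream_module=mj,
            ambiguity_interval=interval,
            discriminating_positions=[int(p) for p in dj_after[:10]],
            nt_interval=(3 * interval[0], 3 * interval[1]),
        )
        j.domain_context = classify_domain_context(j, cluster, module_len=L)
        j.at_compatible = at_compatibility(j, cluster)
        junctions.append(j)
    return junctions


def classify_domain_context(
    junction: Junction, cluster: PKSCluster, module_len: int | None = None
) -> str:
    """Label a junction by where its region midpoint falls in the
    upstream module: inside KS, inside AT, in the flexible linker
    between the last pre-ACP domain and ACP, or other."""
    module = cluster.module_by_index(junction.upstream_module)
    if module_len is None:
        module_len = len(module.aa_seq)
    pos = junction.midpoint_aa % module_len
    if not (0 <= pos < len(module.aa_seq)):
        raise ValidationError("junction midpoint outside module coordinates")
    acp = module.domain("ACP")
    pre_acp_end = max(
        (d.aa_interval[1] for d in module.domains if d.kind != "ACP"), default=0
    )
    for d in module.domains:
        s, e = d.aa_interval
        if s <= pos < e:
            if d.kind == "KS":
                return "within_KS"
            if d.kind == "AT":
                return "within_AT"
            return "other"
    if acp is not None and pre_acp_end <= pos < acp.aa_interval[0]:
        return "pre_ACP_linker"
    return "other"


def at_compatibility(junction: Junction, cluster: PKSCluster) -> bool | None:
    """For junctions inside AT-coding sequence: do the joined modules
    select the same extender unit? None (not applicable) outside AT or
    when a substrate is unannotated."""
    if junction.domain_context != "within_AT":
        return None
    si = cluster.module_by_index(junction.upstream_module).at_substrate
    sj = cluster.module_by_index(junction.downstream_module).at_substrate
    if "none" in (si, sj):
        warnings.warn(
            f"AT substrate unannotated for junction {junction.upstream_module}/"
            f"{junction.downstream_module}; compatibility not applicable",
            stacklevel=2,
        )
        return None
    return si == sj


@dataclass
class SimilarityProfile:
    """Sliding-window mean pairwise identity across aligned modules
    (the Plotcon-style conservation profile). ``values[k]`` covers
    alignment columns [k, k+window)."""

    window_aa: int
    values: np.ndarray
    anchor_cols: dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(self.values.size), "identity": self.values}
        )


def conservation_profile(alignment: ModuleAlignment, window_aa: int = 10) -> SimilarityProfile:
    """Per-window mean pairwise identity over all module pairs.
    Gap-vs-residue (and gap-gap) comparisons count as mismatch."""
    La = alignment.length
    if window_aa > La:
        raise ValidationError("window larger than alignment")
    mat = alignment.matrix()
    gap = ord("-")
    n = mat.shape[0]
    col_sum = np.zeros(La)
    pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            eq = (mat[a] == mat[b]) & (mat[a] != gap) & (mat[b] != gap)
            col_sum += eq
            pairs += 1
    col_identity = col_sum / pairs
    kernel = np.ones(window_aa) / window_aa
    values = np.convolve(col_identity, kernel, mode="valid")
    return SimilarityProfile(
        window_aa=window_aa, values=values, anchor_cols=dict(alignment.anchor_cols)
    )


def junctions_to_dataframe(junctions: list[Junction], seq_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "seq_id": seq_id,
            "i": j.upstream_module,
            "j": j.downstream_module,
            "aa_start": j.ambiguity_interval[0],
            "aa_end": j.ambiguity_interval[1],
            "nt_start": j.nt_interval[0],
            "nt_end": j.nt_interval[1],
            "n_discriminating": len(j.discriminating_positions),
            "domain_context": j.domain_context,
            "at_compatible": "" if j.at_compatible is None else str(j.at_compatible).lower(),
        }
        for j in junctions
    ]
    cols = [
        "seq_id", "i", "j", "aa_start", "aa_end", "nt_start", "nt_end",
        "n_discriminating", "domain_context", "at_compatible",
    ]
    return pd.DataFrame(rows, columns=cols)
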