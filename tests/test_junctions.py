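"""Junction detection, attribution, conservation profiling."""

import numpy as np
import pytest

from aepks import (
    DomainAnnotation,
    Gene,
    HybridRecord,
    ModuleDef,
    PKSCluster,
    SyntheticSpec,
    align_modules,
    at_compatibility,
    attribute_positions,
    classify_domain_context,
    conservation_profile,
    detect_junctions,
    generate_cluster,
    generate_hybrid,
)
from aepks.errors import ValidationError
from aepks.junctions import Junction

from conftest import native_aa
from oracles import sliding_identity_oracle


class TestAlignModules:
    def test_identical_modules_align_without_gaps(self):
        cluster = generate_cluster(
            SyntheticSpec(n_modules=3, module_aa_length=300, identity_target=1.0,
                          hotspot_boost=0.0, seed=2)
        )
        aln = align_modules(cluster)
        assert not aln.has_gaps
        assert len(set(aln.rows)) == 1

    def test_gaps_confined_to_reductive_loop(self, small_cluster):
        # Modules differing only in loop content: one module lacks the
        # ER segment entirely, so gaps must sit between AT end and ACP.
        mods = list(small_cluster.extension_modules[:3])
        donor = small_cluster.extension_modules[3]
        s, e = donor.domain("ER").aa_interval
        cut = e - s
        aa = donor.aa_seq[:s] + donor.aa_seq[e:]
        domains = []
        for d in donor.domains:
            if d.kind == "ER":
                continue
            ds, de = d.aa_interval
            if ds >= e:
                ds, de = ds - cut, de - cut
            domains.append(DomainAnnotation(d.kind, (ds, de), d.active, d.at_substrate))
        short = ModuleDef(index=4, gene_id=donor.gene_id, aa_seq=aa,
                          nt_interval=(0, 3 * len(aa)), domains=domains)
        aln = align_modules(_wrap_modules(mods + [short]))
        assert aln.has_gaps
        at_end_col = aln.anchor_cols["AT"] + (
            donor.domain("AT").aa_interval[1] - donor.domain("AT").aa_interval[0]
        )
        acp_col = aln.anchor_cols["ACP"]
        gap_cols = {c for row in aln.rows for c, ch in enumerate(row) if ch == "-"}
        assert gap_cols and all(at_end_col <= c < acp_col for c in gap_cols)

    def test_anchor_columns_more_conserved_than_loop(self, small_cluster):
        aln = align_modules(small_cluster)
        prof = conservation_profile(aln, window_aa=10)
        ks, at, acp = (aln.anchor_cols[k] for k in ("KS", "AT", "ACP"))
        core = prof.values[ks: at]
        loop = prof.values[at + 120: acp - 30]
        assert core.mean() > loop.mean()

    def test_module_without_anchor_rejected(self):
        mods = [m2_stub(1), m2_stub(2)]
        # strip the AT after construction to bypass the type invariant
        mods[1].domains = [d for d in mods[1].domains if d.kind != "AT"]
        with pytest.raises(ValidationError, match="module 2"):
            align_modules(_wrap_modules(mods))


class TestAttribution:
    def test_native_gene_follows_native_order(self, small_cluster):
        aln = align_modules(small_cluster)
        hyb = HybridRecord("native", nt_seq="", aa_seq=native_aa(small_cluster))
        att = attribute_positions(hyb, aln)
        L = att.module_len
        # majority attribution per module slot must be the native module
        for slot in range(small_cluster.n_extension_modules):
            seg = att.best[slot * L + 50: (slot + 1) * L - 50]
            vals, counts = np.unique(seg[seg >= 0], return_counts=True)
            assert att.module_indices[vals[counts.argmax()]] == slot + 1

    def test_all_identical_modules_fully_ambiguous(self):
        cluster = generate_cluster(
            SyntheticSpec(n_modules=4, module_aa_length=300, identity_target=1.0,
                          hotspot_boost=0.0, seed=5)
        )
        aln = align_modules(cluster)
        hyb = HybridRecord("x", nt_seq="", aa_seq=native_aa(cluster))
        att = attribute_positions(hyb, aln)
        assert (att.best == -1).all()

    def test_hybrid_attribution_switches_at_truth(self, small_cluster):
        hybrid = generate_hybrid(small_cluster, 2, 5, crossover_frac=0.5)
        aln = align_modules(small_cluster)
        att = attribute_positions(hybrid, aln)
        x = hybrid.truth_junctions[0].crossover_aa
        before = att.best[x - 200: x - 50]
        after = att.best[x + 50: x + 200]
        assert att.module_indices[np.bincount(before[before >= 0]).argmax()] == 2
        assert att.module_indices[np.bincount(after[after >= 0]).argmax()] == 5

    def test_short_hybrid_rejected(self, small_cluster):
        aln = align_modules(small_cluster)
        with pytest.raises(ValidationError):
            attribute_positions(HybridRecord("s", nt_seq="", aa_seq="MKT"), aln)


class TestDetectJunctions:
    def test_native_gene_has_no_junctions(self, small_cluster):
        hyb = HybridRecord("native", nt_seq="", aa_seq=native_aa(small_cluster))
        assert detect_junctions(hyb, small_cluster) == []

    def test_deletion_hybrid_single_correct_junction(self, small_cluster, deletion_hybrid):
        js = detect_junctions(deletion_hybrid, small_cluster)
        assert len(js) == 1
        (j,) = js
        tj = deletion_hybrid.truth_junctions[0]
        assert (j.upstream_module, j.downstream_module) == (1, 4)
        assert j.contains_crossover(tj.crossover_aa)
        assert len(j.discriminating_positions) >= 2

    def test_expansion_hybrid_detected(self, small_cluster):
        hybrid = generate_hybrid(small_cluster, 4, 2, crossover_frac=0.35)
        js = detect_junctions(hybrid, small_cluster)
        assert [(j.upstream_module, j.downstream_module) for j in js] == [(4, 2)]
        assert js[0].contains_crossover(hybrid.truth_junctions[0].crossover_aa)

    def test_crossovers_in_same_identical_run_give_same_interval(self, rap_like_cluster):
        # Find two distinct crossover points inside one identical stretch
        # of modules 3 and 9 and confirm identical reported regions.
        m3 = rap_like_cluster.module_by_index(3).aa_seq
        m9 = rap_like_cluster.module_by_index(9).aa_seq
        eq = np.array([a == b for a, b in zip(m3, m9)])
        runs = _runs_of_true(eq)
        start, end = max(runs, key=lambda r: r[1] - r[0])
        assert end - start >= 3, "fixture lacks a shared identical run"
        L = len(m3)
        f1 = (start + 1) / L
        f2 = (end - 1) / L
        h1 = generate_hybrid(rap_like_cluster, 3, 9, crossover_frac=f1)
        h2 = generate_hybrid(rap_like_cluster, 3, 9, crossover_frac=f2)
        j1 = detect_junctions(h1, rap_like_cluster)[0]
        j2 = detect_junctions(h2, rap_like_cluster)[0]
        assert h1.truth_junctions[0].crossover_aa != h2.truth_junctions[0].crossover_aa
        assert j1.ambiguity_interval == j2.ambiguity_interval

    def test_ambiguity_shrinks_as_identity_decreases(self):
        widths = []
        for ident in (0.9, 0.7, 0.5):
            cluster = generate_cluster(
                SyntheticSpec(n_modules=5, module_aa_length=400,
                              identity_target=ident, hotspot_boost=0.0, seed=21)
            )
            spans = []
            for frac in (0.3, 0.5, 0.7):
                h = generate_hybrid(cluster, 1, 4, crossover_frac=frac)
                js = detect_junctions(h, cluster)
                if js:
                    s, e = js[0].ambiguity_interval
                    spans.append(e - s)
            widths.append(np.mean(spans))
        assert widths[0] >= widths[1] >= widths[2]

    def test_detection_invariant_to_synonymous_changes(self, small_cluster, deletion_hybrid):
        # detector operates on the translation: the nt sequence is unused
        other = HybridRecord(
            "syn", nt_seq="X", aa_seq=deletion_hybrid.aa_seq
        )
        j1 = detect_junctions(deletion_hybrid, small_cluster)
        j2 = detect_junctions(other, small_cluster)
        assert [(a.upstream_module, a.downstream_module, a.ambiguity_interval)
                for a in j1] == [(b.upstream_module, b.downstream_module, b.ambiguity_interval)
                                 for b in j2]


class TestDomainContext:
    def _junction_at(self, midpoint, cluster, i=1, j=3):
        return Junction(
            upstream_module=i, downstream_module=j,
            ambiguity_interval=(midpoint, midpoint + 2),
            discriminating_positions=[midpoint + 2, midpoint + 3],
            nt_interval=(3 * midpoint, 3 * (midpoint + 2)),
        )

    def test_contexts(self, small_cluster, small_spec):
        layout = dict((k, (s, e)) for k, s, e in small_spec.layout)
        ks_mid = sum(layout["KS"]) // 2
        at_mid = sum(layout["AT"]) // 2
        dh_mid = sum(layout["DH"]) // 2
        linker = (layout["KR"][1] + layout["ACP"][0]) // 2
        assert classify_domain_context(
            self._junction_at(ks_mid, small_cluster), small_cluster) == "within_KS"
        assert classify_domain_context(
            self._junction_at(at_mid, small_cluster), small_cluster) == "within_AT"
        assert classify_domain_context(
            self._junction_at(dh_mid, small_cluster), small_cluster) == "other"
        assert classify_domain_context(
            self._junction_at(linker, small_cluster), small_cluster) == "pre_ACP_linker"

    def test_at_compatibility_rules(self, small_cluster, small_spec):
        layout = dict((k, (s, e)) for k, s, e in small_spec.layout)
        at_mid = sum(layout["AT"]) // 2
        ks_mid = sum(layout["KS"]) // 2
        # default substrate pattern: odd -> malonyl, even -> methylmalonyl
        j_same = self._junction_at(at_mid, small_cluster, i=1, j=3)
        j_same.domain_context = "within_AT"
        assert at_compatibility(j_same, small_cluster) is True
        j_diff = self._junction_at(at_mid, small_cluster, i=1, j=4)
        j_diff.domain_context = "within_AT"
        assert at_compatibility(j_diff, small_cluster) is False
        j_ks = self._junction_at(ks_mid, small_cluster, i=1, j=3)
        j_ks.domain_context = "within_KS"
        assert at_compatibility(j_ks, small_cluster) is None


class TestConservationProfile:
    def test_identical_modules_profile_is_one(self):
        cluster = generate_cluster(
            SyntheticSpec(n_modules=3, module_aa_length=300, identity_target=1.0,
                          hotspot_boost=0.0, seed=6)
        )
        prof = conservation_profile(align_modules(cluster), window_aa=10)
        assert np.allclose(prof.values, 1.0)

    def test_hotspot_regions_exceed_background(self, small_cluster, small_spec):
        aln = align_modules(small_cluster)
        prof = conservation_profile(aln, window_aa=10)
        hot = small_spec.hotspot_mask()[: prof.values.size]
        assert prof.values[hot].mean() > prof.values[~hot].mean()

    def test_two_module_profile_equals_pairwise_sliding_identity(self):
        cluster = generate_cluster(
            SyntheticSpec(n_modules=2, module_aa_length=300, identity_target=0.6,
                          hotspot_boost=0.1, seed=8, n_genes=1)
        )
        m1, m2 = (m.aa_seq for m in cluster.extension_modules)
        prof = conservation_profile(align_modules(cluster), window_aa=10)
        oracle = sliding_identity_oracle(m1, m2, 10)
        assert np.allclose(prof.values, oracle)

    def test_window_larger_than_alignment_rejected(self, small_cluster):
        with pytest.raises(ValidationError):
            conservation_profile(align_modules(small_cluster), window_aa=10_000)


# --- helpers ----------------------------------------------------------


def _wrap_modules(modules):
    """Minimal cluster-like shim for alignment of hand-built modules."""
    class _Shim:
        extension_modules = [m for m in modules if m.index >= 1]
    return _Shim()


def m2_stub(index):
    return ModuleDef(
        index=index, gene_id="g", aa_seq="A" * 60, nt_interval=(0, 180),
        domains=[
            DomainAnnotation("KS", (0, 20)),
            DomainAnnotation("AT", (20, 40), at_substrate="malonyl"),
            DomainAnnotation("ACP", (50, 60)),
        ],
    )


def _runs_of_true(mask):
    runs, start = [], None
    for k, v in enumerate(mask):
        if v and start is None:
            start = k
        elif not v and start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs
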