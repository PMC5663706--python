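"""Resolution simulator: candidate enumeration, sampling, classification."""

import numpy as np
import pytest

from aepks import (
    Gene,
    SimulationParams,
    SyntheticSpec,
    classify_outcome,
    enumerate_homologous_pairs,
    generate_cluster,
    generate_integrant,
    outcome_distribution,
    sample_resolution,
    simulate_population,
)
from aepks.errors import ValidationError
from aepks.model import find_internal_stops
from aepks.simulate import candidate_weight

from oracles import sliding_identity_oracle

PARAMS = SimulationParams()


def make_state(identity, seed=5, n_modules=6, boost=0.0):
    cluster = generate_cluster(
        SyntheticSpec(
            n_modules=n_modules, module_aa_length=400, identity_target=identity,
            hotspot_boost=boost, seed=seed, n_genes=2,
        )
    )
    m2 = cluster.module_by_index(2)
    s, _ = m2.nt_interval
    state = generate_integrant(cluster, m2.gene_id, (s + 120, s + 720), seed=seed)
    return cluster, state


class TestEnumerate:
    def test_identical_modules_make_every_aligned_pair_qualify(self):
        # aa-identical modules; codon jitter keeps nt windows around 0.92
        cluster, state = make_state(identity=1.0)
        cands = enumerate_homologous_pairs(state, window_nt=100, min_identity=0.85)
        inter = [c for c in cands if c.module_left != c.module_right and c.module_left > 0]
        possible = enumerate_homologous_pairs(state, window_nt=100, min_identity=0.0)
        inter_possible = [
            c for c in possible if c.module_left != c.module_right and c.module_left > 0
        ]
        assert inter and len(inter) == len(inter_possible)

    def test_low_identity_only_repeat_pair_class_qualifies(self):
        cluster, state = make_state(identity=0.3)
        cands = enumerate_homologous_pairs(state, window_nt=100, min_identity=0.8)
        assert all(c.parent_left == c.parent_right for c in cands)

    def test_repeat_pair_always_present_at_identity_one(self):
        cluster, state = make_state(identity=0.3)
        cands = enumerate_homologous_pairs(state, window_nt=100, min_identity=0.999)
        perfect = [c for c in cands if c.identity == 1.0 and c.module_left == -1]
        assert len(perfect) == 1
        (l1, r1), _ = state.repeat_copies
        assert perfect[0].left_locus == (l1, r1)

    def test_window_identity_matches_sliding_oracle(self):
        cluster, state = make_state(identity=0.6, boost=0.2)
        genome = cluster.genome()
        cands = enumerate_homologous_pairs(state, window_nt=60, min_identity=0.0)
        rng = np.random.default_rng(0)
        for c in (cands[i] for i in rng.integers(0, len(cands), 25)):
            w1 = genome[c.parent_left: c.parent_left + 60]
            w2 = genome[c.parent_right: c.parent_right + 60]
            assert c.identity == pytest.approx(sliding_identity_oracle(w1, w2, 60)[0])

    def test_hotspot_boost_concentrates_candidates_in_ks_at(self):
        spec = SyntheticSpec(
            n_modules=6, module_aa_length=400, identity_target=0.6,
            hotspot_boost=0.25, seed=13, n_genes=2,
        )
        cluster = generate_cluster(spec)
        m2 = cluster.module_by_index(2)
        s, _ = m2.nt_interval
        state = generate_integrant(cluster, m2.gene_id, (s + 120, s + 720), seed=13)
        cands = [
            c for c in enumerate_homologous_pairs(state, 100, min_identity=0.75)
            if c.module_left > 0 and c.parent_left != c.parent_right
            and c.orientation == "forward"
        ]
        assert cands, "no inter-module candidates at this threshold"
        hot = spec.hotspot_mask()
        in_hot = sum(1 for c in cands if hot[min(c.offset // 3, hot.size - 1)])
        assert in_hot / len(cands) > hot.mean()


class TestSampleResolution:
    def test_only_repeat_candidate_forces_byte_identical_revertant(self):
        cluster, state = make_state(identity=0.3)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.95)
        repeat_only = [c for c in cands if c.module_left == -1]
        ev = sample_resolution(state, repeat_only, np.random.default_rng(1), PARAMS)
        assert ev.event_class == "revertant"
        assert ev.result.genome == cluster.genome()

    def test_contraction_module_arithmetic(self):
        cluster, state = make_state(identity=0.85, n_modules=6)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.8)
        pick = next(
            c for c in cands
            if c.orientation == "forward" and c.module_left == 2 and c.module_right == 5
        )
        ev = sample_resolution(state, [pick], np.random.default_rng(2), PARAMS)
        assert ev.event_class == "contraction"
        assert ev.result.n_extension == 6 - (5 - 2)

    def test_determinism_same_seed_same_event(self):
        cluster, state = make_state(identity=0.7)
        p75 = SimulationParams(min_identity=0.75)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.75)
        e1 = sample_resolution(state, cands, np.random.default_rng(42), p75)
        e2 = sample_resolution(state, cands, np.random.default_rng(42), p75)
        assert e1.candidate == e2.candidate
        assert (e1.crossover_left, e1.crossover_right) == (e2.crossover_left, e2.crossover_right)

    def test_resolution_removes_replicon_and_one_repeat_copy(self):
        cluster, state = make_state(identity=0.7)
        p75 = SimulationParams(min_identity=0.75)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.75)
        rng = np.random.default_rng(3)
        (l1, r1), _ = state.repeat_copies
        hom = state.full_seq[l1:r1]
        replicon = state.full_seq[slice(*state.replicon_interval)]
        for _ in range(10):
            ev = sample_resolution(state, cands, rng, p75)
            assert replicon not in ev.result.genome
            if ev.event_class == "revertant":
                assert ev.result.genome.count(hom) == 1

    def test_frame_preserved_on_codon_aligned_events(self):
        cluster, state = make_state(identity=0.8)
        p75 = SimulationParams(min_identity=0.75)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.75)
        rng = np.random.default_rng(4)
        for _ in range(25):
            ev = sample_resolution(state, cands, rng, p75)
            for g in ev.result.genes:
                assert len(g.nt_seq) % 3 == 0
                assert not find_internal_stops(g.nt_seq)


class TestClassify:
    def test_parent_is_revertant(self, small_cluster):
        assert classify_outcome(small_cluster, list(small_cluster.genes)) == "revertant"

    def test_internal_stop_is_non_producer(self, small_cluster):
        genes = [Gene(g.gene_id, g.nt_seq) for g in small_cluster.genes]
        nt = genes[0].nt_seq
        genes[0] = Gene(genes[0].gene_id, nt[:300] + "TAA" + nt[303:])
        assert classify_outcome(small_cluster, genes) == "non_producer"

    def test_frameshift_is_non_producer(self, small_cluster):
        genes = [Gene(g.gene_id, g.nt_seq) for g in small_cluster.genes]
        genes[0] = Gene(genes[0].gene_id, genes[0].nt_seq[1:])
        assert classify_outcome(small_cluster, genes) == "non_producer"

    def test_balanced_deletion_plus_duplication_is_complex(self, small_cluster):
        # same extension-module count as parent, different sequence
        genes = [Gene(g.gene_id, g.nt_seq) for g in small_cluster.genes]
        g0 = genes[0].nt_seq
        genes[0] = Gene(genes[0].gene_id, g0[:300] + "GCTGCA" + g0[306:])
        cls = classify_outcome(
            small_cluster, genes, n_extension=small_cluster.n_extension_modules
        )
        assert cls == "complex"


class TestPopulation:
    def test_forced_revertant_distribution(self):
        cluster, state = make_state(identity=0.3)
        summary = simulate_population(state, 200, seed=8)
        assert summary.counts["revertant"] == 200
        assert summary.phenotype_fractions["parent_producer"] == 1.0

    def test_fractions_sum_to_one_and_counts_to_n(self):
        cluster, state = make_state(identity=0.7, boost=0.15)
        summary = simulate_population(state, 500, seed=9)
        assert sum(summary.counts.values()) == 500
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert len(summary.events) == 500

    def test_same_seed_identical_summaries(self):
        cluster, state = make_state(identity=0.7, boost=0.15)
        s1 = simulate_population(state, 300, seed=10)
        s2 = simulate_population(state, 300, seed=10)
        assert s1.counts == s2.counts
        assert s1.events.equals(s2.events)

    def test_monte_carlo_matches_closed_form_weights(self):
        cluster, state = make_state(identity=0.7, boost=0.15)
        p75 = SimulationParams(min_identity=0.75)
        cands = enumerate_homologous_pairs(state, 100, min_identity=0.75)
        exact = outcome_distribution(state, cands, p75)
        n = 3000
        summary = simulate_population(state, n, params=p75, seed=12)
        for cls, p in exact.items():
            sigma = max(np.sqrt(p * (1 - p) / n), 1e-6)
            assert abs(summary.fractions[cls] - p) <= max(3 * sigma, 0.01), cls

    def test_zero_population_rejected(self):
        cluster, state = make_state(identity=0.5)
        with pytest.raises(ValidationError):
            simulate_population(state, 0)
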