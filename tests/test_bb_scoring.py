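import itertools

import numpy as np
import pytest

from bteval.bb_scoring import (EventScoringOptions,
                               aggregate_entity_scores, aggregate_event_scores,
                               category_similarity, entities_overlap,
                               heuristic_sentence_spans, pair_entities,
                               score_events, score_subtask1,
                               segment_similarity)
from bteval.fixtures import (ErrorSpec, FixtureProfile, generate_bb_document,
                             perturb_document)
from bteval.ontology import WangConfig, wang_similarity
from bteval.standoff import (AnnotatedDocument, Fragment, TextBoundEntity,
                             parse_standoff_document)


def ent(eid, *frags, etype="Habitat"):
    return TextBoundEntity(eid, etype, tuple(Fragment(s, e) for s, e in frags))


# --- independent oracle: exhaustive maximum over one-to-one matchings ----

def brute_force_best_total(refs, preds, sim):
    overlap_pairs = [(i, j) for i in range(len(refs)) for j in range(len(preds))
                     if entities_overlap(refs[i], preds[j])]
    best = 0.0
    for size in range(min(len(refs), len(preds)), -1, -1):
        for combo in itertools.combinations(overlap_pairs, size):
            if (len({i for i, _ in combo}) == size
                    and len({j for _, j in combo}) == size):
                best = max(best, sum(sim(refs[i], preds[j]) for i, j in combo))
    return best


class TestSegmentSimilarity:
    def test_identical_spans(self):
        assert segment_similarity(ent("a", (3, 9)), ent("b", (3, 9))) == 1.0

    def test_partial_overlap(self):
        assert segment_similarity(ent("a", (0, 10)), ent("b", (5, 15))) == pytest.approx(1 / 3)

    def test_discontinuous(self):
        a = ent("a", (0, 6), (17, 26))
        b = ent("b", (0, 6))
        assert segment_similarity(a, b) == pytest.approx(0.4)

    def test_disjoint(self):
        assert segment_similarity(ent("a", (0, 5)), ent("b", (10, 15))) == 0.0

    def test_symmetric(self, rng):
        for _ in range(30):
            s1, s2 = sorted(rng.integers(0, 40, size=2))
            t1, t2 = sorted(rng.integers(0, 40, size=2))
            a, b = ent("a", (s1, s2 + 1)), ent("b", (t1, t2 + 1))
            assert segment_similarity(a, b) == segment_similarity(b, a)


class TestCategorySimilarity:
    def test_equal_singletons(self, chain_ontology):
        assert category_similarity(chain_ontology, {"A"}, {"A"}) == 1.0

    def test_parent_prediction(self, chain_ontology):
        cfg = WangConfig(weights={"is_a": 0.8})
        got = category_similarity(chain_ontology, {"A"}, {"B"}, cfg)
        assert got == pytest.approx(3.24 / 4.24)

    def test_multilabel_mean_of_max(self, chain_ontology):
        cfg = WangConfig(weights={"is_a": 0.8})
        got = category_similarity(chain_ontology, {"A", "C"}, {"A"}, cfg)
        want = (1.0 + wang_similarity(chain_ontology, "C", "A", cfg)) / 2
        assert got == pytest.approx(want)

    def test_empty_prediction_scores_zero(self, chain_ontology):
        assert category_similarity(chain_ontology, {"A"}, set()) == 0.0

    def test_both_empty_scores_one(self, chain_ontology):
        assert category_similarity(chain_ontology, set(), set()) == 1.0

    def test_max_matching_aggregation(self, chain_ontology):
        got = category_similarity(chain_ontology, {"A", "B"}, {"A", "B"},
                                  aggregation="max-matching")
        assert got == 1.0


class TestPairEntities:
    def test_best_of_two_preds_wins(self):
        ref = [ent("r", (0, 10))]
        preds = [ent("p1", (0, 5)), ent("p2", (0, 9))]
        pairing = pair_entities(ref, preds, segment_similarity)
        assert [p.id for _, p, _ in pairing.pairs] == ["p2"]
        assert [p.id for p in pairing.unmatched_pred] == ["p1"]

    def test_crossed_overlaps_exhaustive(self):
        refs = [ent("r1", (0, 10)), ent("r2", (8, 20))]
        preds = [ent("p1", (5, 12)), ent("p2", (0, 9))]
        pairing = pair_entities(refs, preds, segment_similarity)
        assert pairing.total == pytest.approx(
            brute_force_best_total(refs, preds, segment_similarity), abs=1e-9)
        assert len(pairing.pairs) == 2

    def test_no_overlap_all_unmatched(self):
        refs = [ent("r1", (0, 5))]
        preds = [ent("p1", (10, 15)), ent("p2", (20, 22))]
        pairing = pair_entities(refs, preds, segment_similarity)
        assert not pairing.pairs
        assert len(pairing.unmatched_ref) == 1 and len(pairing.unmatched_pred) == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_optimality_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        def rand_ents(prefix, n):
            out = []
            for k in range(n):
                start = int(rng.integers(0, 30))
                out.append(ent(f"{prefix}{k}", (start, start + int(rng.integers(1, 10)))))
            return out
        refs = rand_ents("r", int(rng.integers(0, 6)))
        preds = rand_ents("p", int(rng.integers(0, 6)))
        pairing = pair_entities(refs, preds, segment_similarity)
        assert pairing.total == pytest.approx(
            brute_force_best_total(refs, preds, segment_similarity), abs=1e-6)


class TestScoreSubtask1:
    def test_perfect_prediction(self, bb_doc, tree_ontology):
        s = score_subtask1(bb_doc, bb_doc, tree_ontology)
        assert s.ser == 0.0 and s.recall == 1.0 and s.precision == 1.0 and s.f1 == 1.0

    def test_half_boundary_similarity(self, chain_ontology):
        text = "x" * 40
        ref = parse_standoff_document(text, "T1\tHabitat 0 10\nN1\tReference T1 Referent:A\n")
        pred = parse_standoff_document(text, "T1\tHabitat 0 5\nN1\tReference T1 Referent:A\n")
        s = score_subtask1(ref, pred, chain_ontology)
        assert s.recall == pytest.approx(0.5)
        assert s.ser == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_injected_deletions_insertions_recovered(self, seed, tree_ontology):
        profile = FixtureProfile(discontinuity_rate=0.0, events_per_doc=6,
                                 entities_per_doc=12)
        doc = generate_bb_document(profile, tree_ontology, seed=seed)
        pred, truth = perturb_document(doc, ErrorSpec(n_delete=2, n_insert=3, seed=seed))
        s = score_subtask1(doc, pred, tree_ontology)
        assert s.deletions == truth["deletions"] == 2
        assert s.insertions == truth["insertions"] == 3
        assert s.substitution_mass == 0.0
        assert s.ser == pytest.approx(5 / truth["n_reference"])

    def test_detection_mode_ignores_concepts(self, bb_doc, tree_ontology):
        # break every concept assignment; detection score must stay perfect
        concepts = sorted(tree_ontology.concepts)
        wrong = {eid: frozenset({concepts[0] if next(iter(c)) != concepts[0] else concepts[1]})
                 for eid, c in bb_doc.normalizations.items()}
        pred = replace_norms(bb_doc, wrong)
        detection = score_subtask1(bb_doc, pred, tree_ontology, mode="detection")
        official = score_subtask1(bb_doc, pred, tree_ontology, mode="official")
        assert detection.ser == 0.0
        assert official.ser > 0.0

    def test_categorization_mode_ignores_boundaries(self, chain_ontology):
        text = "x" * 40
        ref = parse_standoff_document(text, "T1\tHabitat 0 10\nN1\tReference T1 Referent:A\n")
        pred = parse_standoff_document(text, "T1\tHabitat 0 4\nN1\tReference T1 Referent:A\n")
        s = score_subtask1(ref, pred, chain_ontology, mode="categorization")
        assert s.ser == 0.0 and s.recall == 1.0

    def test_empty_reference_rejected(self, chain_ontology):
        empty = AnnotatedDocument("d", "some text")
        with pytest.raises(ValueError, match="SER undefined"):
            score_subtask1(empty, empty, chain_ontology)

    def test_bounds_on_random_fixtures(self, tree_ontology):
        for seed in range(5):
            doc = generate_bb_document(FixtureProfile(), tree_ontology, seed=seed)
            pred, _ = perturb_document(
                doc, ErrorSpec(n_delete=1, n_insert=1, n_substitute=1,
                               boundary_jitter=2, seed=seed), onto=tree_ontology)
            s = score_subtask1(doc, pred, tree_ontology)
            assert 0.0 <= s.recall <= 1.0 and 0.0 <= s.precision <= 1.0
            assert s.ser >= 0.0

    def test_micro_aggregation(self, tree_ontology):
        docs = [generate_bb_document(FixtureProfile(), tree_ontology, seed=s)
                for s in range(3)]
        scores = [score_subtask1(d, d, tree_ontology) for d in docs]
        agg = aggregate_entity_scores(scores)
        assert agg.ser == 0.0 and agg.n_reference == sum(s.n_reference for s in scores)


def replace_norms(doc, norms):
    return AnnotatedDocument(doc_id=doc.doc_id, text=doc.text,
                             entities=doc.entities, events=doc.events,
                             normalizations=norms, equivalences=doc.equivalences,
                             sentence_spans=doc.sentence_spans)


def strip_events(doc, keep_ids):
    return AnnotatedDocument(doc_id=doc.doc_id, text=doc.text,
                             entities=doc.entities,
                             events={k: v for k, v in doc.events.items() if k in keep_ids},
                             normalizations=doc.normalizations,
                             equivalences=frozenset(),
                             sentence_spans=doc.sentence_spans)


class TestScoreEvents:
    TEXT = "Bacillus one lives here. Bacillus one lives there. The gut of cows."

    def _docs(self, pred_bacterium="T1"):
        ref_ann = ("T1\tBacterium 0 12\tBacillus one\n"
                   "T2\tHabitat 19 23\there\n"
                   "T3\tBacterium 25 37\tBacillus one\n"
                   "T4\tHabitat 44 49\tthere\n"
                   "*\tEquiv T1 T3\n"
                   "E1\tLocalization Bacterium:T1 Localization:T2\n")
        pred_ann = ("T1\tBacterium 0 12\tBacillus one\n"
                    "T2\tHabitat 19 23\there\n"
                    "T3\tBacterium 25 37\tBacillus one\n"
                    f"E1\tLocalization Bacterium:{pred_bacterium} Localization:T2\n")
        ref = parse_standoff_document(self.TEXT, ref_ann, "d")
        pred = parse_standoff_document(self.TEXT, pred_ann, "d")
        return ref, pred

    def test_identical_prediction(self, bb_doc):
        s = score_events(bb_doc, bb_doc, subtask=2)
        assert s.recall == 1.0 and s.precision == 1.0 and s.f1 == 1.0

    def test_equivalence_member_counts_as_correct(self):
        ref, pred = self._docs(pred_bacterium="T3")
        s = score_events(ref, pred, subtask=2)
        assert s.recall == 1.0 and s.precision == 1.0

    def test_non_equivalent_bacterium_fails(self):
        ref, pred = self._docs()
        # remove the equivalence: prediction via T3 must now fail
        ref = AnnotatedDocument(doc_id=ref.doc_id, text=ref.text,
                                entities=ref.entities, events=ref.events,
                                normalizations=ref.normalizations,
                                equivalences=frozenset(),
                                sentence_spans=ref.sentence_spans)
        _, pred = self._docs(pred_bacterium="T3")
        assert score_events(ref, pred, subtask=2).recall == 0.0

    def test_partial_habitat_overlap_contributes_se(self):
        text = "Bug x lives in warm soil."
        ref = parse_standoff_document(
            text, "T1\tBacterium 0 5\tBug x\nT2\tHabitat 15 24\twarm soil\n"
                  "E1\tLocalization Bacterium:T1 Localization:T2\n")
        pred = parse_standoff_document(
            text, "T1\tBacterium 0 5\tBug x\nT2\tHabitat 20 24\tsoil\n"
                  "E1\tLocalization Bacterium:T1 Localization:T2\n")
        s = score_events(ref, pred, subtask=3)
        assert s.recall == pytest.approx(4 / 9)
        relaxed = score_events(ref, pred, subtask=3,
                               options=EventScoringOptions(relax_boundaries=True))
        assert relaxed.recall == 1.0

    def test_partof_both_arguments_graded(self):
        text = "The gut of cows is rich."
        ref = parse_standoff_document(
            text, "T1\tHabitat 4 7\tgut\nT2\tHabitat 11 15\tcows\n"
                  "E1\tPartOf Host:T2 Part:T1\n")
        pred = parse_standoff_document(
            text, "T1\tHabitat 4 7\tgut\nT2\tHabitat 11 14\tcow\n"
                  "E1\tPartOf Host:T2 Part:T1\n")
        s = score_events(ref, pred, subtask=3)
        assert s.recall == pytest.approx(0.75)  # 1 * 3/4
        assert s.per_type["PartOf"].n_reference == 1
        assert s.per_type["Localization"].n_reference == 0

    def test_intra_sentence_restriction(self, tree_ontology):
        profile = FixtureProfile(intra_sentence_rate=0.5, events_per_doc=8,
                                 partof_rate=0.0, discontinuity_rate=0.0)
        doc = generate_bb_document(profile, tree_ontology, seed=13)
        full = score_events(doc, doc, subtask=2)
        intra = score_events(doc, doc, subtask=2,
                             options=EventScoringOptions(intra_sentence=True))
        assert intra.n_reference < full.n_reference
        assert intra.recall == 1.0
        assert "intra-sentence" in intra.flags

    def test_intra_sentence_without_spans_uses_heuristic(self):
        ref, pred = self._docs()
        s = score_events(ref, pred, subtask=2,
                         options=EventScoringOptions(intra_sentence=True))
        assert "heuristic-sentence-splitter" in s.flags

    def test_uninvolved_entities_do_not_affect_scores(self, bb_doc):
        base = score_events(bb_doc, bb_doc, subtask=2)
        extra = dict(bb_doc.entities)
        extra["TX"] = TextBoundEntity("TX", "Habitat", (Fragment(0, 3),))
        fat = AnnotatedDocument(doc_id=bb_doc.doc_id, text=bb_doc.text,
                                entities=extra, events=bb_doc.events,
                                normalizations=bb_doc.normalizations,
                                equivalences=bb_doc.equivalences,
                                sentence_spans=bb_doc.sentence_spans)
        assert score_events(fat, fat, subtask=2) == base

    def test_relaxation_dominance(self, tree_ontology, rng):
        for seed in range(10):
            profile = FixtureProfile(events_per_doc=6, discontinuity_rate=0.0)
            doc = generate_bb_document(profile, tree_ontology, seed=seed)
            pred = jitter_habitats(doc, np.random.default_rng(seed))
            official = score_events(doc, pred, subtask=3)
            relaxed = score_events(doc, pred, subtask=3,
                                   options=EventScoringOptions(relax_boundaries=True))
            assert relaxed.f1 >= official.f1 - 1e-12

    def test_bad_subtask(self, bb_doc):
        with pytest.raises(ValueError):
            score_events(bb_doc, bb_doc, subtask=1)

    def test_aggregation(self, tree_ontology):
        docs = [generate_bb_document(FixtureProfile(), tree_ontology, seed=s)
                for s in range(3)]
        agg = aggregate_event_scores([score_events(d, d, subtask=2) for d in docs])
        assert agg.recall == 1.0 and agg.f1 == 1.0


def jitter_habitats(doc, rng):
    """Prediction with habitat boundaries shifted but events kept."""
    ents = {}
    for eid, e in doc.entities.items():
        if e.etype == "Habitat" and rng.random() < 0.7:
            f = e.fragments[-1]
            new_end = min(len(doc.text), f.end + int(rng.integers(1, 3)))
            frags = e.fragments[:-1] + (Fragment(f.start, new_end),)
            ents[eid] = TextBoundEntity(eid, e.etype, frags, doc.surface_of(frags))
        else:
            ents[eid] = e
    return AnnotatedDocument(doc_id=doc.doc_id, text=doc.text, entities=ents,
                             events=doc.events, normalizations=doc.normalizations,
                             equivalences=doc.equivalences,
                             sentence_spans=doc.sentence_spans)


class TestHeuristicSplitter:
    def test_splits_on_periods(self):
        spans = heuristic_sentence_spans("One here. Two there. Three.")
        assert len(spans) == 3
        assert spans[0] == Fragment(0, 9)
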