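"""Contextual pruning: N-CS windows, featurization, training, evaluation."""

import numpy as np
import pytest

from medkg.corpus import Document, Sentence, corpus_index
from medkg.errors import (
    ConfigurationError,
    FeatureError,
    ModelCompatibilityError,
    ProvenanceError,
    TrainingError,
)
from medkg.inference import FORWARD, MEANINGFUL, MEANINGLESS, ChainStep, InferenceChain
from medkg.kg import CAUSE, ConceptClass, Entity, Relation
from medkg.pruning import (
    PruningConfig,
    evaluate,
    extract_ncs,
    featurize_chain,
    fit_vocabulary,
    train,
)


def _relation(prov):
    s = Entity.from_name("cough", ConceptClass.SYMPTOM)
    d = Entity.from_name("flu", ConceptClass.DISEASE)
    return Relation(CAUSE, s, d, provenance=prov)


def _doc(doc_id, n_sentences):
    return Document(
        doc_id,
        [Sentence.from_surfaces(i, ["w", str(i)]) for i in range(n_sentences)],
    )


class TestExtractNcs:
    def test_interior_window(self):
        corpus = {"d": _doc("d", 20)}
        (w,) = extract_ncs(_relation([("d", 5)]), corpus, 3)
        assert w.sentence_indices == (2, 3, 4, 5, 6, 7, 8)

    def test_clipped_at_document_start(self):
        corpus = {"d": _doc("d", 20)}
        (w,) = extract_ncs(_relation([("d", 0)]), corpus, 3)
        assert w.sentence_indices == (0, 1, 2, 3)

    def test_clipped_at_document_end(self):
        corpus = {"d": _doc("d", 6)}
        (w,) = extract_ncs(_relation([("d", 5)]), corpus, 3)
        assert w.sentence_indices == (2, 3, 4, 5)

    def test_degenerate_n_zero(self):
        corpus = {"d": _doc("d", 10)}
        (w,) = extract_ncs(_relation([("d", 4)]), corpus, 0)
        assert w.sentence_indices == (4,)

    def test_window_size_bound(self, default_bundle, default_corpus):
        """Every window obeys |window| <= 2N+1 and stays inside the document."""
        n = 3
        for chain in default_bundle.chains[:30]:
            for step in chain.steps:
                for w in extract_ncs(step.relation, default_corpus, n):
                    assert len(w.sentence_indices) <= 2 * n + 1
                    doc = default_corpus[w.document_id]
                    assert all(0 <= i < len(doc.sentences) for i in w.sentence_indices)

    def test_out_of_range_provenance(self):
        corpus = {"d": _doc("d", 3)}
        with pytest.raises(ProvenanceError):
            extract_ncs(_relation([("d", 9)]), corpus, 3)

    def test_missing_provenance_is_feature_error(self):
        with pytest.raises(FeatureError):
            extract_ncs(_relation([]), {"d": _doc("d", 3)}, 3)


def _chain_fixture():
    """A single-relation chain over a tiny handmade corpus."""
    sentences = [
        Sentence.from_surfaces(0, ["lung", "lung", "cough"]),
        Sentence.from_surfaces(1, ["cough", "may", "cause", "flu"]),
        Sentence.from_surfaces(2, ["rest", "advised"]),
    ]
    doc = Document("doc", sentences)
    rel = Relation(
        CAUSE,
        Entity.from_name("cough", ConceptClass.SYMPTOM),
        Entity.from_name("flu", ConceptClass.DISEASE),
        provenance=[("doc", 1)],
    )
    chain = InferenceChain(
        steps=[ChainStep(rel, FORWARD)],
        entity_path=[rel.subject, rel.object],
        label=MEANINGFUL,
    )
    return chain, {"doc": doc}


class TestFeaturize:
    def test_direct_count_read_off(self):
        from medkg.pruning import Vocabulary

        chain, corpus = _chain_fixture()
        vocab = Vocabulary(["cough", "lung"])
        x = featurize_chain(chain, corpus, vocab, n=1)
        # N-CS block spans sentences 0..2: cough x2, lung x2
        assert list(x[:2]) == [2, 2]
        # entity-name block: cough + flu -> cough 1, lung 0
        assert list(x[2:]) == [1, 0]

    def test_dimensionality(self, default_bundle, default_corpus):
        chains = default_bundle.chains[:4]
        vocab = fit_vocabulary(chains, default_corpus, 3)
        x = featurize_chain(chains[0], default_corpus, vocab, 3)
        assert x.shape == (2 * 3 * len(vocab),)

    def test_pure_function(self, default_bundle, default_corpus):
        chains = default_bundle.chains[:2]
        vocab = fit_vocabulary(chains, default_corpus, 3)
        a = featurize_chain(chains[0], default_corpus, vocab, 3)
        b = featurize_chain(chains[0], default_corpus, vocab, 3)
        assert np.array_equal(a, b)

    def test_signal_in_middle_block_noise_free(self, clean_bundle):
        """With every signal planted and no noise, the middle relation's N-CS
        block co-mentions the precedent bodily part for meaningful chains and
        never for meaningless chains."""
        corpus = corpus_index(clean_bundle.documents)
        vocab = fit_vocabulary(clean_bundle.chains, corpus, 3)
        v = len(vocab)
        for chain in clean_bundle.chains[:40] + clean_bundle.chains[-40:]:
            x = featurize_chain(chain, corpus, vocab, 3)
            part = chain.entity_path[0].id
            col = vocab.index[part]
            middle_count = x[v : 2 * v][col]
            if chain.label == MEANINGFUL:
                assert middle_count >= 1
            else:
                assert middle_count == 0

    def test_vocabulary_deterministic_and_order_invariant(self, default_bundle, default_corpus):
        chains = default_bundle.chains[:10]
        a = fit_vocabulary(chains, default_corpus, 3)
        b = fit_vocabulary(list(reversed(chains)), default_corpus, 3)
        assert a.terms == b.terms

    def test_empty_training_set_rejected(self, default_corpus):
        with pytest.raises(ConfigurationError):
            fit_vocabulary([], default_corpus, 3)


class TestTraining:
    def test_separable_fixture_trains_to_perfect_accuracy(self, clean_bundle):
        corpus = corpus_index(clean_bundle.documents)
        model = train(clean_bundle.chains, corpus, PruningConfig(random_seed=0))
        pred = model.predict(clean_bundle.chains, corpus)
        truth = [c.label for c in clean_bundle.chains]
        assert pred == truth

    def test_label_flip_symmetry(self, small_bundle):
        """Flipping every training label flips every prediction."""
        corpus = corpus_index(small_bundle.documents)
        chains = small_bundle.chains
        model = train(chains, corpus, PruningConfig(random_seed=0))
        flipped = [
            InferenceChain(
                steps=c.steps,
                entity_path=c.entity_path,
                label=MEANINGLESS if c.label == MEANINGFUL else MEANINGFUL,
            )
            for c in chains
        ]
        flipped_model = train(flipped, corpus, PruningConfig(random_seed=0))
        a = model.predict(chains, corpus)
        b = flipped_model.predict(chains, corpus)
        flip = {MEANINGFUL: MEANINGLESS, MEANINGLESS: MEANINGFUL}
        assert b == [flip[l] for l in a]

    def test_same_seed_same_predictions(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        a = train(small_bundle.chains, corpus, PruningConfig(random_seed=5))
        b = train(small_bundle.chains, corpus, PruningConfig(random_seed=5))
        assert a.predict(small_bundle.chains, corpus) == b.predict(
            small_bundle.chains, corpus
        )

    def test_single_class_training_rejected(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        positives = [c for c in small_bundle.chains if c.label == MEANINGFUL]
        with pytest.raises(TrainingError):
            train(positives, corpus)

    def test_unlabeled_chains_rejected_at_training(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        chains = list(small_bundle.chains)
        chains[0] = InferenceChain(
            steps=chains[0].steps, entity_path=chains[0].entity_path
        )
        with pytest.raises(TrainingError):
            train(chains, corpus)

    def test_incompatible_chain_length_rejected(self, small_bundle, toy_graph):
        from medkg.inference import INVERSE

        corpus = corpus_index(small_bundle.documents)
        model = train(small_bundle.chains, corpus, PruningConfig(random_seed=0))
        rel = toy_graph.get_relation("LOCATED_IN", "inflammation", "lung")
        rel.provenance.append(("missing", 0))
        short = InferenceChain(
            steps=[ChainStep(rel, INVERSE)],
            entity_path=[toy_graph.entities["lung"], toy_graph.entities["inflammation"]],
        )
        with pytest.raises(ModelCompatibilityError):
            model.predict([short], corpus)


class TestEvaluate:
    def test_balanced_baseline_exactly_half(self, default_bundle, default_corpus):
        report = evaluate(default_bundle.chains, default_corpus, PruningConfig(random_seed=1))
        assert report.baseline_precision == 0.5

    def test_confusion_conservation(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        report = evaluate(small_bundle.chains, corpus, PruningConfig(random_seed=1))
        n = len(small_bundle.chains)
        total = sum(f["tp"] + f["fp"] + f["tn"] + f["fn"] for f in report.folds)
        assert total == n
        tp_fn = sum(f["tp"] + f["fn"] for f in report.folds)
        assert tp_fn == sum(1 for c in small_bundle.chains if c.label == MEANINGFUL)

    def test_perfect_classifier_fixture(self, clean_bundle):
        corpus = corpus_index(clean_bundle.documents)
        report = evaluate(clean_bundle.chains, corpus, PruningConfig(random_seed=2))
        for fold in report.folds:
            assert fold["fp"] == 0 and fold["fn"] == 0

    def test_presentation_order_invariance(self, small_bundle):
        """Precision/recall do not depend on the order chains are presented."""
        corpus = corpus_index(small_bundle.documents)
        chains = small_bundle.chains
        a = evaluate(chains, corpus, PruningConfig(random_seed=3))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(chains))
        shuffled = [chains[i] for i in perm]
        b = evaluate(shuffled, corpus, PruningConfig(random_seed=3))
        assert a.precision == pytest.approx(b.precision)
        assert a.recall == pytest.approx(b.recall)

    def test_too_few_chains_per_class(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        few = small_bundle.chains[:4] + small_bundle.chains[-4:]
        with pytest.raises(ConfigurationError):
            evaluate(few, corpus, PruningConfig(cv_folds=5))

    @pytest.mark.parametrize(
        "classifier", ["naive_bayes", "linear_svm", "decision_tree"]
    )
    def test_other_classifiers_run(self, small_bundle, classifier):
        corpus = corpus_index(small_bundle.documents)
        report = evaluate(
            small_bundle.chains, corpus,
            PruningConfig(classifier=classifier, random_seed=1),
        )
        assert 0.0 <= report.precision <= 1.0
        assert 0.0 <= report.recall <= 1.0


class TestPrune:
    def test_empty_input(self, small_bundle):
        corpus = corpus_index(small_bundle.documents)
        model = train(small_bundle.chains, corpus, PruningConfig(random_seed=0))
        assert model.prune([], corpus) == ([], [])

    def test_partition_property(self, default_bundle, default_corpus):
        model = train(default_bundle.chains, default_corpus, PruningConfig(random_seed=1))
        retained, discarded = model.prune(default_bundle.chains, default_corpus)
        assert len(retained) + len(discarded) == len(default_bundle.chains)
        ids = {id(c) for c in retained} | {id(c) for c in discarded}
        assert len(ids) == len(default_bundle.chains)

    def test_motif_chain_retained_and_junction_crossings_discarded(
        self, default_bundle, default_corpus
    ):
        """The lung chain survives pruning; the skin and mouth analogues do not."""
        model = train(default_bundle.chains, default_corpus, PruningConfig(random_seed=1))
        retained, discarded = model.prune(default_bundle.demo_chains, default_corpus)
        assert [c.entity_path[0].id for c in retained] == ["lung"]
        assert {c.entity_path[0].id for c in discarded} == {"skin", "mouth"}
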