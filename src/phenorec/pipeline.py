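"""End-to-end cross-validated annotation pipeline.

Wires the stages together: preprocess → featurize → k-fold CRF training →
decoding → dictionary/rule validation → pooled exact-span scoring.  The
per-fold dictionary is built from that fold's *training* annotations only,
so the held-out fold never leaks into the validation rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phenorec.brown import BrownClusters, train_brown_clusters
from phenorec.corpus import AnnotationRecord, Corpus, Ontology
from phenorec.crf import ChainCRF, CRFConfig, make_folds, predict, train
from phenorec.evaluate import Score, score
from phenorec.features import (
    DEFAULT_STOP_WORDS,
    FeatureConfig,
    LabeledSequence,
    decode_bio,
    encode_bio,
    sentence_features,
)
from phenorec.lexicon import Dictionary, WordLists, build_dictionary
from phenorec.preprocess import Sentence, preprocess_document
from phenorec.rules import RuleConfig, validate

__all__ = ["PipelineConfig", "FoldResult", "PipelineResult", "run_pipeline",
           "annotate_documents"]


@dataclass
class PipelineConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    crf: CRFConfig = field(default_factory=CRFConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)
    k_folds: int = 10
    seed: int = 42
    use_validation: bool = True
    generate_variations: bool = True
    brown_clusters: int = 16
    id_strict: bool = False


@dataclass
class FoldResult:
    fold: int
    predictions: list[AnnotationRecord]
    score: Score


@dataclass
class PipelineResult:
    folds: list[FoldResult]
    pooled: Score
    predictions: list[AnnotationRecord]

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "folds": [
                {"fold": f.fold, **f.score.as_dict(), "n_predictions": len(f.predictions)}
                for f in self.folds
            ],
        }


def _featurize(
    sentences: list[Sentence],
    annotations: list[AnnotationRecord],
    config: FeatureConfig,
    brown: BrownClusters | None,
) -> list[LabeledSequence]:
    out = []
    for sent in sentences:
        if not sent.tokens:
            continue
        seq = encode_bio(sent, [a for a in annotations if a.doc_id == sent.doc_id])
        seq.features = sentence_features(sent, config, DEFAULT_STOP_WORDS, brown)
        out.append(seq)
    return out


def annotate_documents(
    model: ChainCRF,
    corpus: Corpus,
    doc_ids: list[str],
    sentences_by_doc: dict[str, list[Sentence]],
    feature_config: FeatureConfig,
    brown: BrownClusters | None,
    dictionary: Dictionary,
    word_lists: WordLists,
    rule_config: RuleConfig,
    use_validation: bool = True,
) -> list[AnnotationRecord]:
    """CRF-label and (optionally) rule-validate a set of documents."""
    predictions: list[AnnotationRecord] = []
    for doc_id in doc_ids:
        doc = next(d for d in corpus.documents if d.doc_id == doc_id)
        sentences = [s for s in sentences_by_doc[doc_id] if s.tokens]
        seqs = [
            LabeledSequence(s, ["O"] * len(s.tokens),
                            sentence_features(s, feature_config, DEFAULT_STOP_WORDS, brown))
            for s in sentences
        ]
        labels = predict(model, seqs)
        spans: list[tuple[int, int, str]] = []
        for seq, labs in zip(seqs, labels):
            spans.extend(decode_bio(
                LabeledSequence(seq.sentence, labs, seq.features), doc.text))
        if use_validation:
            final, _audit = validate(spans, doc, sentences, dictionary,
                                     word_lists, rule_config)
            for cand in final:
                hpo_id = sorted(cand.hpo_ids)[0] if cand.hpo_ids else "HP_0000000"
                predictions.append(AnnotationRecord(
                    doc_id, cand.start, cand.end, hpo_id,
                    doc.text[cand.start : cand.end]))
        else:
            for s, e, surf in spans:
                ids = dictionary.lookup(surf)
                predictions.append(AnnotationRecord(
                    doc_id, s, e, sorted(ids)[0] if ids else "HP_0000000", surf))
    return predictions


def run_pipeline(
    corpus: Corpus,
    ontology: Ontology,
    word_lists: WordLists,
    config: PipelineConfig | None = None,
    max_folds: int | None = None,
) -> PipelineResult:
    """Document-level k-fold cross-validation of the full annotator.

    ``max_folds`` limits evaluation to the first n folds (the single-fold
    feature-ablation protocol); pooled metrics cover the evaluated folds.
    """
    config = config or PipelineConfig()
    sentences_by_doc = {
        doc.doc_id: preprocess_document(doc) for doc in corpus.documents
    }
    brown = None
    if config.features.other:
        token_lists = [
            [t.text for t in sent.tokens]
            for sents in sentences_by_doc.values() for sent in sents
        ]
        brown = train_brown_clusters(token_lists, num_clusters=config.brown_clusters)

    plan = make_folds(corpus.doc_ids, k=config.k_folds, seed=config.seed)
    folds: list[FoldResult] = []
    all_predictions: list[AnnotationRecord] = []
    n_eval = config.k_folds if max_folds is None else min(max_folds, config.k_folds)

    for fold in range(n_eval):
        train_ids, test_ids = plan.split(fold)
        train_set = set(train_ids)
        train_anns = [a for a in corpus.annotations if a.doc_id in train_set]
        dictionary = build_dictionary(
            ontology, train_anns, generate=config.generate_variations,
            word_lists=word_lists)

        train_seqs: list[LabeledSequence] = []
        for doc_id in train_ids:
            train_seqs.extend(_featurize(
                sentences_by_doc[doc_id],
                [a for a in train_anns if a.doc_id == doc_id],
                config.features, brown))
        model = train(train_seqs, config.crf)

        preds = annotate_documents(
            model, corpus, test_ids, sentences_by_doc, config.features, brown,
            dictionary, word_lists, config.rules, config.use_validation)
        gold = [a for a in corpus.annotations if a.doc_id in set(test_ids)]
        folds.append(FoldResult(fold, preds, score(preds, gold, config.id_strict)))
        all_predictions.extend(preds)

    eval_docs = {d for f in range(n_eval) for d in plan.fold_ids(f)}
    pooled_gold = [a for a in corpus.annotations if a.doc_id in eval_docs]
    pooled = score(all_predictions, pooled_gold, config.id_strict)
    return PipelineResult(folds, pooled, all_predictions)
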