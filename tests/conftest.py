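"""Shared fixtures: the annotated sample abstract, synthetic corpora, and
session-scoped trained models (reused so the suite trains each model once)."""

from __future__ import annotations

import pytest

from herbkg.model import EncoderConfig, TrainConfig, domain_finetune_mlm, train_classifier
from herbkg.pubtator import AnnotatedDocument, EntityMention, RelationAnnotation
from herbkg.simulate import GeneratorSpec, generate_corpus, make_separable_re_set

SAMPLE_TITLE = (
    "Cinnamaldehyde Inhibits Lymphocyte Proliferation and Modulates "
    "T-Cell Differentiation."
)
SAMPLE_ABSTRACT = (
    "Two kinds of cinnamaldehyde derivative, 2′-hydroxycinnamaldehyde (HCA) and "
    "2′-benzoxy-cinnamaldehyde (BCA), were studied for their immunomodulatory "
    "effects. These compounds were screened as anticancer drug candidates from stem "
    "bark of Cinnamomum cassia for their inhibitory effect on farnesyl protein "
    "transferase activity."
)


@pytest.fixture
def sample_doc() -> AnnotatedDocument:
    """The annotated cinnamaldehyde abstract with its published offsets."""
    pmid = "9848396"
    return AnnotatedDocument(
        pmid=pmid,
        title=SAMPLE_TITLE,
        abstract=SAMPLE_ABSTRACT,
        mentions=(
            EntityMention(pmid, 0, 14, "Cinnamaldehyde", "Chemical", "C012843"),
            EntityMention(pmid, 127, 151, "2′-hydroxycinnamaldehyde", "Chemical", "C117567"),
            EntityMention(pmid, 162, 187, "2′-benzoxy-cinnamaldehyde", "Chemical", "C117567"),
            EntityMention(pmid, 322, 339, "Cinnamomum cassia", "Herb", "119260"),
        ),
        relations=(
            RelationAnnotation(pmid, "HHC", "119260", "D013390"),
            RelationAnnotation(pmid, "HHC", "119260", "C117567"),
            RelationAnnotation(pmid, "CAD", "D013390", "C565232"),
            RelationAnnotation(pmid, "CAD", "C117567", "C565232"),
        ),
    )


@pytest.fixture(scope="session")
def gen_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=7, n_docs=30)


@pytest.fixture(scope="session")
def corpus(gen_spec):
    """30 generated documents plus their planted ground truth."""
    return generate_corpus(gen_spec)


@pytest.fixture(scope="session")
def separable_set(gen_spec):
    """60 cue-word-separable examples, 10 per label."""
    return make_separable_re_set(gen_spec, n_per_label=10)


@pytest.fixture(scope="session")
def tiny_enc() -> EncoderConfig:
    return EncoderConfig.tiny()


@pytest.fixture(scope="session")
def overfit_state(separable_set, tiny_enc):
    """Tiny classifier trained to convergence on the separable fixture set."""
    tc = TrainConfig(epochs=30, learning_rate=0.001, optimizer="adam", seed=0)
    return train_classifier(separable_set, tiny_enc, tc)


@pytest.fixture(scope="session")
def mlm_result(tiny_enc):
    """Masked-LM fine-tuning run on a 200-document synthetic corpus."""
    docs, _ = generate_corpus(GeneratorSpec(seed=11, n_docs=200))
    return domain_finetune_mlm(docs, tiny_enc, steps=500, seed=2)
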