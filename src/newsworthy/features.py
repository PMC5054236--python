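"""Prefixed n-gram featurization of citation records.

Citations are turned into sparse counts of unigrams and bigrams drawn from
three fields: title, abstract, and MeSH headings.  Field provenance is
encoded in the feature string itself — "TI-" marks a title term, "MH-" a
MeSH heading, and abstract terms carry no prefix.  Title terms are emitted
twice, once prefixed and once into the unprefixed stream, so a word such
as "study" can act both as a generic text feature and as a specifically
title-positioned one.  Bigrams never span field boundaries.

Filtering follows the usual bag-of-words hygiene for citation corpora:
stop words are removed before n-gram formation, features seen in fewer
than ``min_df`` documents are dropped, and if more than ``max_features``
survive only the most frequent are kept.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .corpus import Citation, LabeledCorpus

# The classic Glasgow IR English stop-word list (318 words), shipped
# verbatim so featurization is stable across library versions.
STOP_WORDS = frozenset((
    'a', 'about', 'above', 'across', 'after', 'afterwards', 'again', 'against', 'all', 'almost',
    'alone', 'along', 'already', 'also', 'although', 'always', 'am', 'among', 'amongst', 'amoungst',
    'amount', 'an', 'and', 'another', 'any', 'anyhow', 'anyone', 'anything', 'anyway', 'anywhere',
    'are', 'around', 'as', 'at', 'back', 'be', 'became', 'because', 'become', 'becomes', 'becoming',
    'been', 'before', 'beforehand', 'behind', 'being', 'below', 'beside', 'besides', 'between',
    'beyond', 'bill', 'both', 'bottom', 'but', 'by', 'call', 'can', 'cannot', 'cant', 'co', 'con',
    'could', 'couldnt', 'cry', 'de', 'describe', 'detail', 'do', 'done', 'down', 'due', 'during',
    'each', 'eg', 'eight', 'either', 'eleven', 'else', 'elsewhere', 'empty', 'enough', 'etc',
    'even', 'ever', 'every', 'everyone', 'everything', 'everywhere', 'except', 'few', 'fifteen',
    'fifty', 'fill', 'find', 'fire', 'first', 'five', 'for', 'former', 'formerly', 'forty', 'found',
    'four', 'from', 'front', 'full', 'further', 'get', 'give', 'go', 'had', 'has', 'hasnt', 'have',
    'he', 'hence', 'her', 'here', 'hereafter', 'hereby', 'herein', 'hereupon', 'hers', 'herself',
    'him', 'himself', 'his', 'how', 'however', 'hundred', 'i', 'ie', 'if', 'in', 'inc', 'indeed',
    'interest', 'into', 'is', 'it', 'its', 'itself', 'keep', 'last', 'latter', 'latterly', 'least',
    'less', 'ltd', 'made', 'many', 'may', 'me', 'meanwhile', 'might', 'mill', 'mine', 'more',
    'moreover', 'most', 'mostly', 'move', 'much', 'must', 'my', 'myself', 'name', 'namely',
    'neither', 'never', 'nevertheless', 'next', 'nine', 'no', 'nobody', 'none', 'noone', 'nor',
    'not', 'nothing', 'now', 'nowhere', 'of', 'off', 'often', 'on', 'once', 'one', 'only', 'onto',
    'or', 'other', 'others', 'otherwise', 'our', 'ours', 'ourselves', 'out', 'over', 'own', 'part',
    'per', 'perhaps', 'please', 'put', 'rather', 're', 'same', 'see', 'seem', 'seemed', 'seeming',
    'seems', 'serious', 'several', 'she', 'should', 'show', 'side', 'since', 'sincere', 'six',
    'sixty', 'so', 'some', 'somehow', 'someone', 'something', 'sometime', 'sometimes', 'somewhere',
    'still', 'such', 'system', 'take', 'ten', 'than', 'that', 'the', 'their', 'them', 'themselves',
    'then', 'thence', 'there', 'thereafter', 'thereby', 'therefore', 'therein', 'thereupon',
    'these', 'they', 'thick', 'thin', 'third', 'this', 'those', 'though', 'three', 'through',
    'throughout', 'thru', 'thus', 'to', 'together', 'too', 'top', 'toward', 'towards', 'twelve',
    'twenty', 'two', 'un', 'under', 'until', 'up', 'upon', 'us', 'very', 'via', 'was', 'we', 'well',
    'were', 'what', 'whatever', 'when', 'whence', 'whenever', 'where', 'whereafter', 'whereas',
    'whereby', 'wherein', 'whereupon', 'wherever', 'whether', 'which', 'while', 'whither', 'who',
    'whoever', 'whole', 'whom', 'whose', 'why', 'will', 'with', 'within', 'without', 'would', 'yet',
    'you', 'your', 'yours', 'yourself', 'yourselves',
))

TITLE_PREFIX = "TI-"
MESH_PREFIX = "MH-"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization settings.

    ``uni_and_bigram`` is the mode for the discriminative model; the
    supervised topic model uses ``unigram_only``.  ``min_df=2`` drops
    features seen in fewer than two articles; ``max_features`` caps the
    vocabulary at the most frequent features (50,000 by default).
    """

    ngram_mode: str = "uni_and_bigram"  # or "unigram_only"
    fields_used: tuple[str, ...] = ("title", "abstract", "mesh")
    min_df: int = 2
    max_features: int = 50_000
    emit_unprefixed_title: bool = True

    def __post_init__(self) -> None:
        if self.ngram_mode not in ("unigram_only", "uni_and_bigram"):
            raise ValueError(f"unknown ngram_mode {self.ngram_mode!r}")
        bad = set(self.fields_used) - {"title", "abstract", "mesh"}
        if bad:
            raise ValueError(f"unknown fields {bad}")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "ngram_mode": self.ngram_mode,
                "fields_used": sorted(self.fields_used),
                "min_df": self.min_df,
                "max_features": self.max_features,
                "emit_unprefixed_title": self.emit_unprefixed_title,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokenization.

    Punctuation is stripped; digits are retained, so "95% CI" tokenizes to
    ["95", "ci"].  MeSH headings are not tokenized by this function — they
    are normalized whole (see the MH- feature convention), which preserves
    qualifier strings such as "england/epidemiology".
    """
    if not text:
        return []
    return _TOKEN_RE.findall(text.lower())


def _mesh_feature(heading: str) -> str:
    """Normalize a MeSH heading to its feature form: lowercase, spaces -> hyphens."""
    return MESH_PREFIX + "-".join(heading.lower().split())


def _ngram_stream(tokens: list[str], bigrams: bool) -> Iterable[str]:
    yield from tokens
    if bigrams:
        for a, b in zip(tokens, tokens[1:]):
            yield f"{a} {b}"


def extract_features(citation: Citation, config: FeatureConfig) -> Counter:
    """Feature -> count mapping for a single citation.

    Stop words are removed before n-grams are formed, so a bigram may join
    words that were separated only by stop words in the original text.
    """
    bigrams = config.ngram_mode == "uni_and_bigram"
    counts: Counter = Counter()

    if "title" in config.fields_used:
        toks = [t for t in tokenize(citation.title) if t not in STOP_WORDS]
        counts.update(TITLE_PREFIX + t for t in toks)
        if config.emit_unprefixed_title:
            counts.update(toks)
        if bigrams:
            for a, b in zip(toks, toks[1:]):
                counts[f"{TITLE_PREFIX}{a} {TITLE_PREFIX}{b}"] += 1
                if config.emit_unprefixed_title:
                    counts[f"{a} {b}"] += 1

    if "abstract" in config.fields_used:
        toks = [t for t in tokenize(citation.abstract) if t not in STOP_WORDS]
        counts.update(_ngram_stream(toks, bigrams))

    if "mesh" in config.fields_used and citation.mesh_terms:
        heads = [_mesh_feature(h) for h in citation.mesh_terms]
        counts.update(heads)
        if bigrams:
            counts.update(f"{a} {b}" for a, b in zip(heads, heads[1:]))

    return counts


@dataclass
class Vocabulary:
    """Deterministic feature index with document frequencies."""

    features: list[str]
    document_frequency: dict[str, int]
    config_fingerprint: str
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {f: i for i, f in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: str) -> bool:
        return feature in self.index

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\tdocument_frequency\n")
            for f in self.features:
                fh.write(f"{f}\t{self.document_frequency[f]}\n")

    @classmethod
    def from_tsv(cls, path, config_fingerprint: str = "") -> "Vocabulary":
        feats, df = [], {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                f, d = line.rstrip("\n").split("\t")
                feats.append(f)
                df[f] = int(d)
        return cls(feats, df, config_fingerprint)


def build_vocabulary(corpus: LabeledCorpus, config: FeatureConfig) -> Vocabulary:
    """Build the feature index for a corpus.

    Features occurring in fewer than ``config.min_df`` documents are
    dropped; if more than ``config.max_features`` remain, the ones with the
    highest total corpus count are kept (ties broken lexicographically).
    The retained features are ordered lexicographically, so the index is a
    pure function of (corpus, config).
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    df: Counter = Counter()
    tf: Counter = Counter()
    for cit in corpus:
        counts = extract_features(cit, config)
        df.update(counts.keys())
        tf.update(counts)
    kept = [f for f, d in df.items() if d >= config.min_df]
    if not kept:
        raise ValueError("vocabulary is empty after min_df filtering")
    if len(kept) > config.max_features:
        # highest total frequency first; ties lexicographic
        kept.sort(key=lambda f: (-tf[f], f))
        kept = kept[: config.max_features]
    kept.sort()
    return Vocabulary(kept, {f: df[f] for f in kept}, config.fingerprint())


def vectorize(corpus: LabeledCorpus, vocab: Vocabulary, config: FeatureConfig) -> sp.csr_matrix:
    """Sparse document-by-feature count matrix.

    Rows follow corpus citation order, columns follow vocabulary order;
    out-of-vocabulary features are silently ignored.
    """
    if vocab.config_fingerprint and vocab.config_fingerprint != config.fingerprint():
        raise ValueError("vocabulary was built with an incompatible feature config")
    data, indices, indptr = [], [], [0]
    for cit in corpus:
        counts = extract_features(cit, config)
        cols = sorted(vocab.index[f] for f in counts if f in vocab.index)
        for j in cols:
            indices.append(j)
        # second pass to align values with sorted column order
        by_col = {vocab.index[f]: c for f, c in counts.items() if f in vocab.index}
        data.extend(by_col[j] for j in cols)
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(corpus), len(vocab)),
    )
    return X


def featurize_corpus(
    corpus: LabeledCorpus, config: FeatureConfig | None = None
) -> tuple[sp.csr_matrix, Vocabulary]:
    """Convenience: build the vocabulary and count matrix in one call."""
    config = config or FeatureConfig()
    vocab = build_vocabulary(corpus, config)
    return vectorize(corpus, vocab, config), vocab
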