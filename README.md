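# newsworthy

What makes a biomedical research article *newsworthy*? Only a sliver of the
literature ever attracts a press release from its journal or university, and
a smaller sliver still gets covered by the news media. `newsworthy` is a
toolkit for modeling that selection process from citation records alone:
given titles, abstracts, and MeSH headings, it asks how predictable press
attention is and which words and topics carry the signal.

The package provides the full analysis pipeline:

* **Corpus construction** — read labeled citation corpora from JSONL/CSV or
  PubMed MEDLINE exports, and build matched case–control corpora: for each
  positive article, up to *m* control articles are sampled from the same
  journal and issue (or year), isolating content effects from venue and
  timing.
* **Featurization** — bag-of-words counts of uni- and bigrams from titles,
  abstracts, and MeSH headings, with field-prefixed feature names
  (`TI-study`, `MH-great-britain`, plain abstract terms), a standard English
  stop list, a document-frequency ≥ 2 filter, and a 50,000-feature cap.
* **Discriminative model** — ℓ2-regularized logistic regression

      min_w,w₀  ½‖w‖² + λ Σᵢ log(1 + exp(−ỹᵢ(wᵀXᵢ + w₀)))

  (small λ = strong regularization, unpenalized intercept), evaluated by
  stratified five-fold cross-validated AUC with λ chosen by *nested* CV
  over a logarithmic grid (1e−5 … 1e2) inside each training split.
* **Robust feature ranking** — 1000 bootstrap refits give each coefficient
  a normal-approximation 95% CI (mean ± 1.96 SD); positively predictive
  features are ranked by descending CI *lower* bound, negative ones by
  ascending *upper* bound, plus KDE summaries of coefficient densities.
* **Supervised topic model (sLDA)** — K topics with a softmax label
  response on the document's empirical topic frequencies z̄
  (P(c | z̄) ∝ exp(η_cᵀ z̄)), fit by variational EM with a monotone evidence
  lower bound; reports each topic's coefficient, prevalence, and top words.
* **Synthetic corpora** — generators with planted logistic signals and
  planted topics, so every stage is testable against known ground truth
  without access to any proprietary corpus.

## Worked example

```python
import numpy as np
from collections import Counter
import newsworthy as nw

# a synthetic matched-PR corpus: 800 citations, 12.5% positive, with three
# planted words ("outbreak" in titles, "mortality" in abstracts, the
# "Pandemics" MeSH heading), each shifting the log-odds of a press release
corpus = nw.make_discriminative_corpus(nw.DiscriminativeSpec(seed=5))
X, vocab = nw.featurize_corpus(corpus)
y = corpus.labels()

cv = nw.cross_validate(X.astype(float), y, k=5, seed=7)
print(f"mean AUC {cv.mean_auc:.3f} (SD {cv.sd_auc:.3f})")

lam = Counter(cv.selected_lambdas).most_common(1)[0][0]
summary = nw.bootstrap_coefficients(X.astype(float), y, lam=lam, B=200,
                                    seed=9, feature_names=list(vocab.features))
for r in nw.rank_features(summary, "positive", top_n=5):
    print(f"{r['rank']:2d} {r['feature']:15s} mean={r['mean']:+.3f} "
          f"CI=[{r['ci_lower']:+.3f}, {r['ci_upper']:+.3f}]")
```

prints

```
mean AUC 0.860 (SD 0.019)
 1 mortality       mean=+0.300 CI=[+0.246, +0.354]
 2 TI-outbreak     mean=+0.235 CI=[+0.205, +0.266]
 3 outbreak        mean=+0.235 CI=[+0.205, +0.266]
 4 MH-pandemics    mean=+0.213 CI=[+0.184, +0.242]
 5 aw00000 aw00001 mean=+0.089 CI=[+0.035, +0.143]
```

The classifier discriminates well above chance (AUC 0.860 against the
construction's theoretical ceiling of ≈0.95), and the three planted
features top the ranking by CI lower bound — the bound rewards
coefficients that stay large across resamples, not ones that are large
once (the planted title word appears twice, as its `TI-` form and its
unprefixed copy). The background bigram in fifth place shows why the CI
ranking matters: its interval barely clears zero.

The same corpus feeds the topic model:

```python
from newsworthy.pipeline import _documents_for_slda
docs, words, kept = _documents_for_slda(corpus)
model, states, trace = nw.fit_slda(docs, y[kept], V=len(words), K=20, seed=0)
top = nw.topic_report(model, states)[0]
print(top["coefficient"], top["top_words"][:5])
```

Everything above is also available from the shell:

```
newsworthy simulate corpus.jsonl --seed 5
newsworthy run corpus.jsonl report/ --seed 7
```

which, at the default analysis scale (1000 bootstrap replicates, 20-topic
model), takes on the order of ten minutes and writes the full report bundle (CV result JSON, top-25 positive and
negative feature tables, coefficient-density TSVs, sLDA topic table, and a
manifest with every seed and a config hash for exact replay).

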