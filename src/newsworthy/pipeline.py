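"""End-to-end runs: featurize, cross-validate, bootstrap-rank, topic-model.

``run_pipeline`` ties the stages together and writes a report bundle:

  cv_result.json            nested-CV fold AUCs and selected lambdas
  features_positive.tsv     top-n positively predictive features (CI ranking)
  features_negative.tsv     top-n negatively predictive features
  densities.tsv             bootstrap coefficient densities, long format
  slda_topics.tsv           per-topic coefficient, prevalence, top words
  manifest.json             config hash, seeds, stage log, software version

All outputs are written atomically (temp file + rename) and are a pure
function of (corpus, config): rerunning with the same manifest reproduces
the numeric outputs byte-for-byte.  Timestamps live only in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bootstrap import bootstrap_coefficients, coefficient_density, rank_features
from .corpus import LabeledCorpus
from .features import FeatureConfig, build_vocabulary, vectorize
from .logreg import DEFAULT_LAMBDA_GRID, cross_validate
from .slda import fit_slda, topic_report

logger = logging.getLogger("newsworthy")

#: densities are only retained when the replicate matrix stays below this size
MAX_SAMPLE_CELLS = 20_000_000


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    task: str = "PR"
    feature_source: str = "article"
    ngram_mode: str = "uni_and_bigram"
    min_df: int = 2
    max_features: int = 50_000
    cv_folds: int = 5
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    bootstrap_B: int = 1000
    top_n: int = 25
    n_density_features: int = 4
    slda_enabled: bool = True
    slda_K: int = 20
    slda_alpha: float = 1.0
    slda_max_iter: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _ranked_tsv(rows: list[dict]) -> str:
    lines = ["rank\tfeature\tmean\tci_lower\tci_upper\trobust"]
    for r in rows:
        robust = int(r["ci_lower"] > 0 or r["ci_upper"] < 0)
        lines.append(
            f"{r['rank']}\t{r['feature']}\t{r['mean']:.10g}\t{r['ci_lower']:.10g}\t{r['ci_upper']:.10g}\t{robust}"
        )
    return "\n".join(lines) + "\n"


def _documents_for_slda(corpus: LabeledCorpus) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Unigram token-id documents for the topic model.

    Uses the unigram-only featurization over the same three fields; empty
    documents (no in-vocabulary tokens) are dropped, with their row indices
    returned so labels can be aligned.
    """
    cfg = FeatureConfig(ngram_mode="unigram_only")
    vocab = build_vocabulary(corpus, cfg)
    X = vectorize(corpus, vocab, cfg)
    docs, kept = [], []
    for i in range(X.shape[0]):
        row = X.getrow(i)
        if row.nnz == 0:
            continue
        docs.append(np.repeat(row.indices, row.data).astype(np.int64))
        kept.append(i)
    return docs, list(vocab.features), kept


def run_pipeline(config: RunConfig, corpus: LabeledCorpus, out_dir: str | Path) -> dict:
    """Run all stages and write the report bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    cv_seed, boot_seed, slda_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seeds": {"cv": cv_seed, "bootstrap": boot_seed, "slda": slda_seed},
        "version": __version__,
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "artifacts": {},
    }
    stage = "featurize"
    try:
        fcfg = FeatureConfig(ngram_mode=config.ngram_mode, min_df=config.min_df,
                             max_features=config.max_features)
        vocab = build_vocabulary(corpus, fcfg)
        X = vectorize(corpus, vocab, fcfg)
        y = corpus.labels()
        manifest["stages"][stage] = {"n_documents": X.shape[0], "n_features": X.shape[1]}
        logger.info("featurize: %d documents x %d features", *X.shape)

        stage = "cross_validate"
        cv = cross_validate(X, y, k=config.cv_folds, lambda_grid=config.lambda_grid, seed=cv_seed)
        _atomic_write(out / "cv_result.json", json.dumps(cv.to_dict(), indent=2, sort_keys=True) + "\n")
        manifest["artifacts"]["cv_result"] = "cv_result.json"
        manifest["stages"][stage] = {"mean_auc": cv.mean_auc, "sd_auc": cv.sd_auc}

        stage = "bootstrap"
        # fixed lambda for all replicates: the modal fold-selected value
        lam_counts = Counter(cv.selected_lambdas)
        lam = sorted(lam_counts, key=lambda l: (-lam_counts[l], l))[0]
        keep = X.shape[1] * config.bootstrap_B <= MAX_SAMPLE_CELLS
        summary = bootstrap_coefficients(
            X, y, lam=lam, B=config.bootstrap_B, seed=boot_seed,
            feature_names=list(vocab.features), keep_samples=keep,
        )
        pos = rank_features(summary, "positive", config.top_n)
        neg = rank_features(summary, "negative", config.top_n)
        _atomic_write(out / "features_positive.tsv", _ranked_tsv(pos))
        _atomic_write(out / "features_negative.tsv", _ranked_tsv(neg))
        manifest["artifacts"]["features_positive"] = "features_positive.tsv"
        manifest["artifacts"]["features_negative"] = "features_negative.tsv"
        manifest["stages"][stage] = {"lambda": lam, "B": config.bootstrap_B,
                                     "redraws": summary.n_redraws}

        stage = "densities"
        if keep:
            lines = ["feature\tcoefficient\tdensity"]
            sel = [r["feature"] for r in pos[: config.n_density_features]]
            sel += [r["feature"] for r in neg[: config.n_density_features]]
            for feat in sel:
                xs, ds = coefficient_density(summary, feat)
                lines.extend(f"{feat}\t{x:.10g}\t{d:.10g}" for x, d in zip(xs, ds))
            _atomic_write(out / "densities.tsv", "\n".join(lines) + "\n")
            manifest["artifacts"]["densities"] = "densities.tsv"
        else:
            manifest["artifacts"]["densities"] = {
                "skipped": "replicate matrix too large to retain samples"
            }

        stage = "slda"
        if config.slda_enabled:
            docs, words, kept = _documents_for_slda(corpus)
            model, states, trace = fit_slda(
                docs, y[kept], V=len(words), K=config.slda_K, alpha=config.slda_alpha,
                max_iter=config.slda_max_iter, seed=slda_seed, vocab_words=words,
            )
            report = topic_report(model, states)
            m = max(len(r["top_words"]) for r in report)
            lines = ["topic\tcoefficient\tprevalence\t" + "\t".join(f"word_{j+1}" for j in range(m))]
            for r in report:
                lines.append(
                    f"{r['topic']}\t{r['coefficient']:.10g}\t{r['prevalence']:.10g}\t"
                    + "\t".join(r["top_words"])
                )
            _atomic_write(out / "slda_topics.tsv", "\n".join(lines) + "\n")
            manifest["artifacts"]["slda_topics"] = "slda_topics.tsv"
            manifest["stages"][stage] = {
                "K": config.slda_K, "em_iterations": trace.n_iter,
                "elbo": trace.elbo[-1], "converged": trace.converged,
            }
        else:
            manifest["artifacts"]["slda_topics"] = {"skipped": "slda disabled in config"}
    except Exception as exc:
        manifest["failed_stage"] = stage
        _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
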