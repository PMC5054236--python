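"""Matched negative sampling.

Positives (articles that received a press release or news coverage) are
paired with control articles drawn from an unlabeled pool that share the
same publication venue and time — e.g. up to 10 articles from the same
journal and issue, or up to 20 from the same journal and year.  Matching
on venue/time keys isolates content predictors from journal prestige and
publication-date effects.

Positives are processed in corpus order, and a pool article claimed by an
earlier positive is removed from later eligible sets, so the combined
negative corpus is duplicate-free (global sampling without replacement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corpus import Citation, NEGATIVE, POSITIVE

logger = logging.getLogger("newsworthy")

MATCH_KEYS = ("journal", "issue", "year")


@dataclass(frozen=True)
class MatchSpec:
    """Which keys must agree and how many negatives to draw per positive."""

    match_keys: tuple[str, ...] = ("journal", "issue")
    max_per_positive: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.match_keys:
            raise ValueError("match_keys must be non-empty")
        bad = set(self.match_keys) - set(MATCH_KEYS)
        if bad:
            raise ValueError(f"unknown match keys {bad}; valid: {MATCH_KEYS}")
        if self.max_per_positive < 1:
            raise ValueError("max_per_positive must be >= 1")


def _key_of(cit: Citation, keys: tuple[str, ...]) -> tuple:
    """Exact-equality match key: strings are whitespace-trimmed and casefolded."""
    out = []
    for k in keys:
        v = getattr(cit, k)
        out.append(v.strip().casefold() if isinstance(v, str) else v)
    return tuple(out)


def sample_matched_negatives(
    positives: list[Citation],
    pool: list[Citation],
    spec: MatchSpec,
) -> tuple[list[Citation], dict[str, list[str]]]:
    """Sample matched negatives for each positive.

    Returns the sampled citations (relabeled negative, in the order drawn)
    and a provenance map ``positive id -> [sampled negative ids]``.
    Sampling is uniform without replacement within each eligible set, and
    without replacement globally across positives; a positive with an empty
    eligible set simply contributes no negatives (logged, not an error).
    Identical ``spec.seed`` yields identical output.
    """
    pos_ids = {p.id for p in positives}
    for c in pool:
        if c.label == POSITIVE:
            raise ValueError(f"pool citation {c.id!r} is labeled positive")
        if c.id in pos_ids:
            raise ValueError(f"pool citation {c.id!r} shares an id with a positive")

    # eligible pool indices per match key, in pool order (deterministic)
    by_key: dict[tuple, list[int]] = {}
    for i, c in enumerate(pool):
        by_key.setdefault(_key_of(c, spec.match_keys), []).append(i)

    rng = np.random.default_rng(spec.seed)
    taken: set[int] = set()
    negatives: list[Citation] = []
    provenance: dict[str, list[str]] = {}
    for p in positives:
        eligible = [i for i in by_key.get(_key_of(p, spec.match_keys), ()) if i not in taken]
        if not eligible:
            logger.warning("no eligible matched controls for positive %s", p.id)
            provenance[p.id] = []
            continue
        n_draw = min(spec.max_per_positive, len(eligible))
        chosen = rng.choice(len(eligible), size=n_draw, replace=False)
        drawn = [eligible[j] for j in sorted(chosen)]
        taken.update(drawn)
        provenance[p.id] = [pool[i].id for i in drawn]
        negatives.extend(pool[i].with_label(NEGATIVE) for i in drawn)
    return negatives, provenance
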