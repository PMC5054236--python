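"""Citation data model and corpus I/O.

A corpus is an ordered list of citation records — title, abstract, MeSH
headings, journal/issue/year match keys, and a newsworthiness label
(did the article get a press release / news coverage?).  Corpus order is
significant: it fixes the row order of every downstream matrix.

JSONL is the canonical interchange format; CSV and MEDLINE flat files
(the format PubMed exports) are supported as importers.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import Medline

logger = logging.getLogger("newsworthy")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
LABELS = (POSITIVE, NEGATIVE, UNLABELED)

#: separator used to pack MeSH heading lists into a single CSV cell
_MESH_SEP = "|"


@dataclass(frozen=True)
class Citation:
    """One scholarly article record.

    ``label`` is "positive" (received a press release / news coverage),
    "negative", or "unlabeled" (e.g. a pool article awaiting matched
    sampling).  ``issue`` is an opaque issue/volume identifier used only
    as a match key.
    """

    id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    journal: str = ""
    year: int | None = None
    issue: str = ""
    label: str = UNLABELED
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("citation id must be a non-empty string")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "mesh_terms", tuple(self.mesh_terms))

    def has_text(self) -> bool:
        """True if at least one of title/abstract/MeSH is non-empty."""
        return bool(self.title.strip() or self.abstract.strip() or self.mesh_terms)

    def with_label(self, label: str) -> "Citation":
        return replace(self, label=label)


@dataclass
class LabeledCorpus:
    """An ordered, stable collection of citations for one modeling task.

    ``task`` distinguishes press-release prediction ("PR") from news-coverage
    prediction ("NC"); ``feature_source`` selects whether features come from
    the journal article or from the corresponding press-release text, which
    is only meaningful for the NC task.
    """

    citations: list[Citation] = field(default_factory=list)
    task: Literal["PR", "NC"] = "PR"
    feature_source: Literal["article", "press_release"] = "article"

    def __post_init__(self) -> None:
        if self.feature_source == "press_release" and self.task != "NC":
            raise ValueError("feature_source='press_release' is only valid for task='NC'")
        ids = [c.id for c in self.citations]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate citation ids in corpus")

    def __len__(self) -> int:
        return len(self.citations)

    def __iter__(self):
        return iter(self.citations)

    def labels(self) -> np.ndarray:
        """0/1 label vector; raises if any citation is unlabeled."""
        out = np.empty(len(self.citations), dtype=np.int64)
        for i, c in enumerate(self.citations):
            if c.label == POSITIVE:
                out[i] = 1
            elif c.label == NEGATIVE:
                out[i] = 0
            else:
                raise ValueError(f"citation {c.id!r} is unlabeled; cannot form label vector")
        return out


def _citation_from_dict(d: dict) -> Citation:
    year = d.get("year")
    if year is not None and year != "":
        year = int(year)
    else:
        year = None
    mesh = d.get("mesh_terms") or ()
    if isinstance(mesh, str):
        mesh = tuple(t for t in mesh.split(_MESH_SEP) if t)
    return Citation(
        id=str(d["id"]),
        title=d.get("title", "") or "",
        abstract=d.get("abstract", "") or "",
        mesh_terms=tuple(mesh),
        journal=d.get("journal", "") or "",
        year=year,
        issue=str(d.get("issue", "") or ""),
        label=d.get("label", UNLABELED) or UNLABELED,
        source_tag=d.get("source_tag", "") or "",
    )


def _iter_jsonl(path: Path) -> Iterable[dict]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def _iter_csv(path: Path) -> Iterable[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV must have a header including an 'id' column")
        if "label" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV must have a 'label' column")
        yield from reader


def _iter_medline(path: Path, default_label: str) -> Iterable[dict]:
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID")
            if not pmid:
                continue
            dp = rec.get("DP", "")
            year = None
            tok = dp.split()[0] if dp else ""
            if tok[:4].isdigit():
                year = int(tok[:4])
            yield {
                "id": pmid,
                "title": rec.get("TI", ""),
                "abstract": rec.get("AB", ""),
                "mesh_terms": tuple(rec.get("MH", ())),
                "journal": rec.get("JT", ""),
                "year": year,
                "issue": rec.get("IP", "") or rec.get("VI", ""),
                "label": default_label,
            }


def read_corpus(
    path: str | Path,
    format: Literal["jsonl", "csv", "medline"] = "jsonl",
    task: Literal["PR", "NC"] = "PR",
    feature_source: Literal["article", "press_release"] = "article",
    default_label: str = UNLABELED,
) -> LabeledCorpus:
    """Read a labeled corpus from disk.

    Records that violate the citation invariants (no id, no text at all,
    bad label) are skipped with a logged count rather than aborting the
    whole import.  ``default_label`` is applied to MEDLINE records, which
    carry no label of their own.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        raw = _iter_jsonl(path)
    elif format == "csv":
        raw = _iter_csv(path)
    elif format == "medline":
        raw = _iter_medline(path, default_label)
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    citations: list[Citation] = []
    skipped = 0
    for d in raw:
        try:
            if "id" not in d or d["id"] in (None, ""):
                raise ValueError("missing id")
            if format != "medline" and "label" not in d:
                raise ValueError("missing label")
            cit = _citation_from_dict(d)
            if not cit.has_text():
                raise ValueError("no title/abstract/MeSH text")
        except (ValueError, KeyError) as exc:
            skipped += 1
            logger.warning("skipping record (%s)", exc)
            continue
        citations.append(cit)
    if skipped:
        logger.info("read_corpus: skipped %d unparseable record(s) from %s", skipped, path)
    if not citations:
        raise ValueError(f"{path}: no valid citation records")
    return LabeledCorpus(citations=citations, task=task, feature_source=feature_source)


def write_corpus(
    corpus: LabeledCorpus,
    path: str | Path,
    format: Literal["jsonl", "csv"] = "jsonl",
) -> None:
    """Write a corpus; ``read_corpus(write_corpus(c))`` reproduces all fields."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for c in corpus:
                d = asdict(c)
                d["mesh_terms"] = list(c.mesh_terms)
                fh.write(json.dumps(d, ensure_ascii=False) + "\n")
    elif format == "csv":
        fields = ["id", "title", "abstract", "mesh_terms", "journal", "year", "issue", "label", "source_tag"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for c in corpus:
                d = asdict(c)
                d["mesh_terms"] = _MESH_SEP.join(c.mesh_terms)
                d["year"] = "" if c.year is None else c.year
                writer.writerow(d)
    else:
        raise ValueError(f"unsupported write format {format!r}")


def corpus_summary(corpus: LabeledCorpus) -> dict:
    """Corpus-level descriptive statistics.

    Returns counts and percentages of positive/negative citations plus the
    mean/SD of title and abstract lengths in words, where "word" is defined
    by the same tokenizer used for featurization so that the statistics are
    consistent with the feature space.
    """
    from .features import tokenize

    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    n_pos = sum(1 for c in corpus if c.label == POSITIVE)
    n_neg = sum(1 for c in corpus if c.label == NEGATIVE)
    n_lab = n_pos + n_neg
    title_len = np.array([len(tokenize(c.title)) for c in corpus], dtype=float)
    abstract_len = np.array([len(tokenize(c.abstract)) for c in corpus], dtype=float)
    return {
        "n": len(corpus),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": 100.0 * n_pos / n_lab if n_lab else float("nan"),
        "pct_negative": 100.0 * n_neg / n_lab if n_lab else float("nan"),
        "title_length_mean": float(title_len.mean()),
        "title_length_sd": float(title_len.std()),
        "abstract_length_mean": float(abstract_len.mean()),
        "abstract_length_sd": float(abstract_len.std()),
    }
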