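"""Corpus readers/writers and preprocessing.

The corpus dialect is JSONL: one UTF-8 JSON object per line with fields

    message_id      str, unique within a file (required)
    participant_id  str or null
    text            str, the raw message (required)
    tokens          list[str] or null — filled by :func:`tokenize` if absent
    scores_raw      list[float] or null — raw trait scores
    scores_std      list[float] or null — standardized trait scores

Preprocessing mirrors common social-media hygiene for trait-language work:
drop messages shorter than five words or containing links, strip emoji codes
and hashtags, and (for long-form blog text) truncate to the shortest sentence
prefix reaching roughly thirty words.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger("traitlm")

# strip at token edges only, so contractions and in-word apostrophes survive
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)

LINK_PATTERN = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
HASHTAG_PATTERN = re.compile(r"#\w+")
EMOJI_CODE_PATTERN = re.compile(r":[a-z_]+:|&#\d+;", re.IGNORECASE)
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


class CorpusFormatError(ValueError):
    """A corpus line failed to parse in strict mode."""


@dataclass(frozen=True)
class CorpusRecord:
    """One message with optional author link and trait scores."""

    message_id: str
    text: str
    participant_id: str | None = None
    tokens: tuple[str, ...] | None = None
    scores_raw: tuple[float, ...] | None = None
    scores_std: tuple[float, ...] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "message_id": self.message_id,
                "participant_id": self.participant_id,
                "text": self.text,
                "tokens": list(self.tokens) if self.tokens is not None else None,
                "scores_raw": list(self.scores_raw) if self.scores_raw is not None else None,
                "scores_std": list(self.scores_std) if self.scores_std is not None else None,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusRecord":
        if "message_id" not in d or "text" not in d:
            raise CorpusFormatError("record missing required field message_id/text")
        return cls(
            message_id=str(d["message_id"]),
            text=str(d["text"]),
            participant_id=d.get("participant_id"),
            tokens=tuple(d["tokens"]) if d.get("tokens") is not None else None,
            scores_raw=tuple(float(x) for x in d["scores_raw"])
            if d.get("scores_raw") is not None
            else None,
            scores_std=tuple(float(x) for x in d["scores_std"])
            if d.get("scores_std") is not None
            else None,
        )


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase, whitespace-split, punctuation stripped at token edges."""
    out = []
    for raw in text.lower().split():
        tok = _EDGE_PUNCT.sub("", raw)
        if tok:
            out.append(tok)
    return tuple(out)


def read_corpus(path: str | Path, strict: bool = False) -> list[CorpusRecord]:
    """Read a JSONL corpus.

    In lenient mode malformed lines are skipped and counted in the log; in
    strict mode the first malformed line raises :class:`CorpusFormatError`
    with its line number.
    """
    path = Path(path)
    records: list[CorpusRecord] = []
    seen_ids: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                if not isinstance(d, dict):
                    raise CorpusFormatError("line is not a JSON object")
                rec = CorpusRecord.from_dict(d)
                if rec.message_id in seen_ids:
                    raise CorpusFormatError(f"duplicate message_id {rec.message_id!r}")
            except (json.JSONDecodeError, CorpusFormatError, ValueError, TypeError) as exc:
                if strict:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
                continue
            seen_ids.add(rec.message_id)
            records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
    if not records:
        logger.warning("%s: empty corpus", path)
    return records


def write_corpus(path: str | Path, records: Iterable[CorpusRecord]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json())
            fh.write("\n")


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation (. ! ?) followed by whitespace."""
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def truncate_blog(text: str, target_words: int = 30) -> str:
    """Keep the shortest sentence prefix whose word count first reaches
    ``target_words``; long-form posts are thereby cut to roughly 30 words."""
    sentences = split_sentences(text)
    kept: list[str] = []
    total = 0
    for sent in sentences:
        kept.append(sent)
        total += len(sent.split())
        if total >= target_words:
            break
    return " ".join(kept)


def preprocess(
    records: Iterable[CorpusRecord],
    min_words: int = 5,
    strip_patterns: Sequence[re.Pattern] = (HASHTAG_PATTERN, EMOJI_CODE_PATTERN),
    drop_patterns: Sequence[re.Pattern] = (LINK_PATTERN,),
    blog_mode: bool = False,
    blog_target_words: int = 30,
) -> list[CorpusRecord]:
    """Filter and normalize raw messages.

    Messages containing any ``drop_pattern`` (links by default) are removed
    outright; ``strip_patterns`` (hashtags, emoji codes) are deleted from the
    text; messages left with fewer than ``min_words`` tokens are removed.
    In ``blog_mode`` each surviving text is first truncated by sentence to
    roughly ``blog_target_words`` words.
    """
    out: list[CorpusRecord] = []
    n_links = n_short = 0
    for rec in records:
        text = rec.text
        if any(p.search(text) for p in drop_patterns):
            n_links += 1
            continue
        for p in strip_patterns:
            text = p.sub(" ", text)
        if blog_mode:
            text = truncate_blog(text, blog_target_words)
        tokens = tokenize(text)
        if len(tokens) < min_words:
            n_short += 1
            continue
        out.append(replace(rec, text=text, tokens=tokens))
    logger.info(
        "preprocess: kept %d, dropped %d with links, %d below %d words",
        len(out), n_links, n_short, min_words,
    )
    return out
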