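"""Text normalization: protected-token extraction, tokenization, POS tagging.

Mirrors the usual social-media preprocessing chain: user IDs, URLs and
email addresses are pulled out by regular expressions before tokenization
so they survive as single tokens, then the remaining text is split on
whitespace with punctuation and emoticons separated into their own tokens,
and finally each token receives a coarse part-of-speech tag from an exact
lexicon (the synthetic language has one, so a statistical tagger is
unnecessary).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .synthetic import NEGATIVE_EMOTICONS, POSITIVE_EMOTICONS, Post

__all__ = [
    "ProcessingError",
    "TokenizedPost",
    "extract_proper_nouns",
    "tokenize",
    "pos_tag",
    "tokenize_post",
    "tokenize_corpus",
    "EMOTICONS",
]

EMOTICONS: frozenset[str] = frozenset(POSITIVE_EMOTICONS) | frozenset(NEGATIVE_EMOTICONS)
_PUNCT_CHARS = set(string.punctuation)
# characters that split off as their own tokens; word-internal marks such as
# '_' or '-' stay inside tokens so vocabulary items survive tokenization
_SPLIT_CHARS = set("!?.,;:\"()[]{}<>")

# order matters: URLs may contain '@' and '@name' must not eat an email's
# domain part, so match URLs first, then emails, then user mentions.
_URL_RE = r"[A-Za-z][A-Za-z0-9+.-]*://[^\s]+"
_EMAIL_RE = r"[A-Za-z0-9._%+-]+@[A-Za-z0-9-]+(?:\.[A-Za-z0-9-]+)+"
_USER_RE = r"@[A-Za-z0-9_]+"
_PROTECTED_RE = re.compile(
    f"(?P<url>{_URL_RE})|(?P<email>{_EMAIL_RE})|(?P<user_id>{_USER_RE})"
)
_PLACEHOLDER_RE = re.compile(r"\x00(\d+)\x00")


class ProcessingError(ValueError):
    """Raised on malformed preprocessing input (e.g. orphan placeholder)."""


@dataclass
class TokenizedPost:
    """A post after tokenization and tagging; tags align with tokens."""

    post_id: str
    tokens: list[str]
    pos_tags: list[str]
    protected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.pos_tags):
            raise ProcessingError("tokens and pos_tags must have equal length")


def extract_proper_nouns(text: str) -> tuple[list[tuple[str, str]], str]:
    """Replace user IDs, URLs and emails with numbered placeholders.

    Returns ``(protected, masked_text)`` where ``protected[i]`` is the
    ``(token, kind)`` behind placeholder ``i``.  Masking is reversible and
    idempotent (placeholders use characters the patterns cannot match).
    """
    protected: list[tuple[str, str]] = []

    def _sub(match: re.Match) -> str:
        kind = match.lastgroup or "url"
        protected.append((match.group(0), kind))
        return f"\x00{len(protected) - 1}\x00"

    masked = _PROTECTED_RE.sub(_sub, text)
    return protected, masked


def restore_protected(masked: str, protected: Sequence[tuple[str, str]]) -> str:
    """Inverse of :func:`extract_proper_nouns`."""
    return _PLACEHOLDER_RE.sub(lambda m: protected[int(m.group(1))][0], masked)


def _split_token(token: str) -> list[str]:
    """Split punctuation runs into single-character tokens; emoticons stay whole."""
    if token in EMOTICONS:
        return [token]
    parts: list[str] = []
    buf = ""
    for ch in token:
        if ch in _SPLIT_CHARS:
            if buf:
                parts.append(buf)
                buf = ""
            parts.append(ch)
        else:
            buf += ch
    if buf:
        parts.append(buf)
    # re-merge any emoticon that the character split broke apart
    merged: list[str] = []
    i = 0
    while i < len(parts):
        matched = False
        for emo in sorted(EMOTICONS, key=len, reverse=True):
            k = len(emo)
            if "".join(parts[i : i + k]) == emo and all(len(p) == 1 for p in parts[i : i + k]):
                merged.append(emo)
                i += k
                matched = True
                break
        if not matched:
            merged.append(parts[i])
            i += 1
    return merged


def tokenize(masked: str, protected: Sequence[tuple[str, str]] = ()) -> list[str]:
    """Whitespace tokenization with punctuation/emoticon splitting.

    Placeholders produced by :func:`extract_proper_nouns` are restored as
    single, unsplit tokens; an out-of-range placeholder raises
    :class:`ProcessingError`.
    """
    tokens: list[str] = []
    for raw in masked.split():
        m = _PLACEHOLDER_RE.fullmatch(raw)
        if m is None and "\x00" in raw:
            m2 = _PLACEHOLDER_RE.search(raw)
            if m2 is None:
                raise ProcessingError(f"malformed placeholder in token {raw!r}")
            # placeholder glued to punctuation: split around it
            for piece in _PLACEHOLDER_RE.split(raw):
                if piece == "":
                    continue
                if piece.isdigit() and f"\x00{piece}\x00" in raw:
                    idx = int(piece)
                    if idx >= len(protected):
                        raise ProcessingError(f"orphan placeholder {idx}")
                    tokens.append(protected[idx][0])
                else:
                    tokens.extend(_split_token(piece))
            continue
        if m is not None:
            idx = int(m.group(1))
            if idx >= len(protected):
                raise ProcessingError(f"orphan placeholder {idx}")
            tokens.append(protected[idx][0])
        else:
            tokens.extend(_split_token(raw))
    return tokens


def pos_tag(
    tokens: Sequence[str],
    tag_lexicon: Mapping[str, str],
    protected_tokens: Iterable[str] = (),
) -> list[str]:
    """Coarse tags: lexicon entry, else EMO / PUNCT / PROPER / OTHER."""
    protected_set = set(protected_tokens)
    tags = []
    for tok in tokens:
        if tok in protected_set:
            tags.append("PROPER")
        elif tok in EMOTICONS:
            tags.append("EMO")
        elif tok and all(ch in _PUNCT_CHARS for ch in tok):
            tags.append("PUNCT")
        elif tok in tag_lexicon:
            tags.append(tag_lexicon[tok])
        else:
            tags.append("OTHER")
    return tags


def tokenize_post(post: Post, tag_lexicon: Mapping[str, str]) -> TokenizedPost:
    protected, masked = extract_proper_nouns(post.text)
    tokens = tokenize(masked, protected)
    tags = pos_tag(tokens, tag_lexicon, protected_tokens=(t for t, _ in protected))
    return TokenizedPost(post_id=post.id, tokens=tokens, pos_tags=tags, protected=protected)


def tokenize_corpus(posts: Iterable[Post], tag_lexicon: Mapping[str, str]) -> list[TokenizedPost]:
    return [tokenize_post(p, tag_lexicon) for p in posts]
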