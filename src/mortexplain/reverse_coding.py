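"""Reverse coding: render coded certificates as model-input sentences.

Reverse coding maps each ICD-style code on a certificate back to its
concept title and serialises the record as a single sentence,

    "<Sex>, <age> years: (<title>) due to (<title>) ... ; with (<title>)"

with the Part 1 lines flattened in line order and chained by " due to ",
and Part 2 contributing conditions appended as "; with (...)" clauses.

Tokenization is a lowercased word-and-punctuation split with explicit
character offsets and a word map (word index -> contiguous token range) so
token-level attributions can be aggregated back to words. Punctuation at
the edge of a whitespace chunk forms its own single-token word; interior
punctuation (hyphens, commas inside numbers) stays inside the word, which
is where multi-token words come from.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SentenceRecord",
    "Vocabulary",
    "render_sentence",
    "tokenize_text",
    "tokenize",
    "detokenize",
    "parse_titles",
    "write_sentences_tsv",
    "read_sentences_tsv",
]

PAD_ID = 0
UNK_ID = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


@dataclass(frozen=True)
class SentenceRecord:
    """A tokenized sentence with word alignment and its class label."""

    cert_id: str
    text: str
    tokens: tuple[str, ...]
    token_ids: tuple[int, ...]
    token_offsets: tuple[tuple[int, int], ...]
    word_map: tuple[tuple[int, int], ...]  # word -> [start, end) token range
    label: str
    label_index: int

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def words(self) -> list[str]:
        return [
            " ".join(self.tokens[a:b]) if b - a > 1 else self.tokens[a]
            for a, b in self.word_map
        ]


class Vocabulary:
    """Token vocabulary with reserved ids 0 = padding, 1 = unknown."""

    def __init__(self, tokens: Sequence[str]):
        self.id_to_token: list[str] = [PAD_TOKEN, UNK_TOKEN, *tokens]
        self.token_to_id: dict[str, int] = {
            t: i for i, t in enumerate(self.id_to_token)
        }
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    @classmethod
    def from_texts(cls, texts: Iterable[str]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for text in texts:
            for tok, _ in _scan_tokens(text):
                seen.setdefault(tok, None)
        return cls(sorted(seen))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.id_to_token, fh)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            toks = json.load(fh)
        if toks[:2] != [PAD_TOKEN, UNK_TOKEN]:
            raise ValueError("vocabulary file lacks reserved padding/unknown ids")
        return cls(toks[2:])


def render_sentence(cert, codebook) -> str:
    """Serialise a certificate as the single-sentence model input."""
    titles = []
    for code in (c for line in cert.part1_lines for c in line):
        titles.append(codebook.title(code))
    if not titles:
        raise ValueError(f"certificate {cert.cert_id} has an empty Part 1")
    sentence = f"{cert.sex.capitalize()}, {int(cert.age)} years: " + " due to ".join(
        f"({t})" for t in titles
    )
    for code in cert.part2:
        sentence += f"; with ({codebook.title(code)})"
    return sentence


_PAREN_RE = re.compile(r"\(([^()]*)\)")


def parse_titles(sentence: str) -> list[str]:
    """Recover the parenthesised condition titles from a rendered sentence."""
    return _PAREN_RE.findall(sentence)


def _scan_tokens(text: str) -> list[tuple[str, tuple[int, int]]]:
    return [
        (m.group(0).lower(), (m.start(), m.end())) for m in _TOKEN_RE.finditer(text)
    ]


def tokenize_text(text: str) -> tuple[list[str], list[tuple[int, int]], list[tuple[int, int]]]:
    """Tokenize; returns (tokens, character offsets, word map).

    Words are built per whitespace chunk: leading/trailing punctuation
    tokens are standalone words, the interior run is one word.
    """
    if not text or not text.strip():
        raise ValueError("empty text")
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    word_map: list[tuple[int, int]] = []
    for m in re.finditer(r"\S+", text):
        chunk_toks = _scan_tokens(m.group(0))
        base = len(tokens)
        for tok, (a, b) in chunk_toks:
            tokens.append(tok)
            offsets.append((m.start() + a, m.start() + b))
        # Split the chunk into words: edge punctuation alone, interior joined.
        is_word = [bool(re.search(r"\w", t)) for t in tokens[base:]]
        if any(is_word):
            first = is_word.index(True)
            last = len(is_word) - 1 - is_word[::-1].index(True)
            for j in range(first):
                word_map.append((base + j, base + j + 1))
            word_map.append((base + first, base + last + 1))
            for j in range(last + 1, len(is_word)):
                word_map.append((base + j, base + j + 1))
        else:
            for j in range(len(is_word)):
                word_map.append((base + j, base + j + 1))
    return tokens, offsets, word_map


def tokenize(
    cert_id: str,
    text: str,
    vocabulary: Vocabulary,
    label: str = "",
    label_index: int = -1,
) -> SentenceRecord:
    """Tokenize ``text`` into a :class:`SentenceRecord`.

    Out-of-vocabulary words map to the unknown token id; the word map
    covers every token exactly once.
    """
    tokens, offsets, word_map = tokenize_text(text)
    ids = tuple(vocabulary[t] for t in tokens)
    return SentenceRecord(
        cert_id=cert_id,
        text=text,
        tokens=tuple(tokens),
        token_ids=ids,
        token_offsets=tuple(offsets),
        word_map=tuple(word_map),
        label=label,
        label_index=label_index,
    )


def detokenize(tokens: Sequence[str]) -> str:
    """Whitespace-joined token string (round-trips through the tokenizer)."""
    return " ".join(tokens)


def write_sentences_tsv(path, records: Iterable[SentenceRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("cert_id\ttext\tlabel\n")
        for r in records:
            fh.write(f"{r.cert_id}\t{r.text}\t{r.label}\n")


def read_sentences_tsv(
    path, vocabulary: Vocabulary, label_indexer=None
) -> list[SentenceRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cert_id, text, label = line.rstrip("\n").split("\t")
            idx = label_indexer(label) if label_indexer else -1
            out.append(tokenize(cert_id, text, vocabulary, label, idx))
    return out
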