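"""Dictionary-based gene/protein named-entity recognition.

Every mention is normalized to a canonical symbol via an alias lexicon
(Entrez-style: official symbol, stable gene id, description, aliases).
Matching is deterministic:

* matches must start and end at a word boundary, where a boundary is the
  start/end of the sentence or any character that is neither alphanumeric
  nor a hyphen (so ``E-cadherin`` is one token);
* aliases of four or more characters match case-insensitively, shorter
  aliases case-sensitively (keeps ``MET`` from matching the verb "met");
* overlapping candidate matches are resolved leftmost-longest.

Ambiguous aliases (one surface string claimed by two genes after case
folding) are rejected when the lexicon is loaded: disambiguation is out of
scope, and a mention must map to exactly one symbol.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .corpus_io import Corpus

#: Aliases at least this long match case-insensitively.
CASE_INSENSITIVE_MIN_LEN = 4


class LexiconError(ValueError):
    """Lexicon failed validation; ``errors`` lists each problem with its line."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass(frozen=True)
class LexiconEntry:
    canonical_symbol: str
    gene_id: str
    description: str
    aliases: tuple[str, ...]  # includes the canonical symbol itself


@dataclass(frozen=True)
class MentionEvent:
    """One recognized gene occurrence, located by half-open char span."""

    pmid: str
    sentence_index: int
    canonical_symbol: str
    matched_text: str
    start: int
    end: int


@dataclass
class GeneLexicon:
    entries: list[LexiconEntry]
    # (alias, canonical, case_insensitive) triples for the scanner
    _patterns: list[tuple[str, str, bool]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._patterns = [
            (alias, e.canonical_symbol, len(alias) >= CASE_INSENSITIVE_MIN_LEN)
            for e in self.entries
            for alias in e.aliases
        ]

    @property
    def symbols(self) -> list[str]:
        return [e.canonical_symbol for e in self.entries]

    @property
    def patterns(self) -> list[tuple[str, str, bool]]:
        return list(self._patterns)

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(stream: TextIO | str) -> GeneLexicon:
    """Load a 4-column TSV lexicon: symbol, gene_id, description, aliases.

    Aliases are pipe-separated; the canonical symbol is implicitly its own
    alias.  Duplicate canonical symbols and aliases mapping to two different
    canonicals (after case folding) abort the load, with line numbers and
    the colliding canonicals named.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header is None or [h.strip().lower() for h in header[:4]] != [
        "symbol",
        "gene_id",
        "description",
        "aliases",
    ]:
        raise LexiconError(
            ["lexicon header must be: symbol, gene_id, description, aliases"]
        )
    entries: list[LexiconEntry] = []
    errors: list[str] = []
    claimed: dict[str, tuple[str, int]] = {}  # folded alias -> (canonical, line)
    seen_symbols: dict[str, int] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 4:
            errors.append(f"line {lineno}: expected 4 columns, got {len(row)}")
            continue
        symbol, gene_id, description, alias_field = (c.strip() for c in row[:4])
        if not symbol:
            errors.append(f"line {lineno}: empty symbol")
            continue
        if symbol in seen_symbols:
            errors.append(
                f"line {lineno}: duplicate canonical symbol {symbol!r}"
                f" (first at line {seen_symbols[symbol]})"
            )
            continue
        seen_symbols[symbol] = lineno
        aliases = [symbol] + [a.strip() for a in alias_field.split("|") if a.strip()]
        unique_aliases: list[str] = []
        local_seen: set[str] = set()
        for alias in aliases:
            folded = alias.lower()
            if folded in local_seen:
                continue  # repeated alias within one row is harmless
            local_seen.add(folded)
            if folded in claimed and claimed[folded][0] != symbol:
                other, other_line = claimed[folded]
                errors.append(
                    f"line {lineno}: ambiguous alias {alias!r} maps to both"
                    f" {other!r} (line {other_line}) and {symbol!r}"
                )
                continue
            claimed[folded] = (symbol, lineno)
            unique_aliases.append(alias)
        entries.append(
            LexiconEntry(
                canonical_symbol=symbol,
                gene_id=gene_id,
                description=description,
                aliases=tuple(unique_aliases),
            )
        )
    if errors:
        raise LexiconError(errors)
    return GeneLexicon(entries=entries)


def _is_boundary(text: str, index: int) -> bool:
    """True at the text edges or at a char that is not alphanumeric and not '-'."""
    if index < 0 or index >= len(text):
        return True
    ch = text[index]
    return not (ch.isalnum() or ch == "-")


def find_gene_mentions(
    sentence: str,
    lexicon: GeneLexicon,
    pmid: str = "",
    sentence_index: int = 0,
) -> list[MentionEvent]:
    """Scan one sentence for alias matches, leftmost-longest, normalized.

    Returned mentions never overlap and are ordered by start position.
    """
    lowered = sentence.lower()
    candidates: list[tuple[int, int, str]] = []
    for alias, canonical, case_insensitive in lexicon._patterns:
        haystack = lowered if case_insensitive else sentence
        needle = alias.lower() if case_insensitive else alias
        if not needle:
            continue
        pos = haystack.find(needle)
        while pos != -1:
            end = pos + len(needle)
            if _is_boundary(sentence, pos - 1) and _is_boundary(sentence, end):
                candidates.append((pos, end, canonical))
            pos = haystack.find(needle, pos + 1)
    # leftmost first, then longest; canonical as a final deterministic key
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    mentions: list[MentionEvent] = []
    cursor = 0
    for start, end, canonical in candidates:
        if start < cursor:
            continue
        mentions.append(
            MentionEvent(
                pmid=pmid,
                sentence_index=sentence_index,
                canonical_symbol=canonical,
                matched_text=sentence[start:end],
                start=start,
                end=end,
            )
        )
        cursor = end
    return mentions


def mine_corpus(corpus: Corpus, lexicon: GeneLexicon) -> list[MentionEvent]:
    """Run :func:`find_gene_mentions` over every sentence of every record."""
    events: list[MentionEvent] = []
    for record in corpus.records:
        for idx, sentence in enumerate(record.sentences):
            events.extend(
                find_gene_mentions(sentence, lexicon, pmid=record.pmid, sentence_index=idx)
            )
    return events


def mentions_to_tsv(mentions: Iterable[MentionEvent], stream: TextIO) -> None:
    stream.write("pmid\tsentence_index\tsymbol\ttext\tstart\tend\n")
    for m in mentions:
        stream.write(
            f"{m.pmid}\t{m.sentence_index}\t{m.canonical_symbol}\t"
            f"{m.matched_text}\t{m.start}\t{m.end}\n"
        )
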