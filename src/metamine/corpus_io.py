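"""Reading and writing abstract corpora in MEDLINE flat-file format.

A corpus is a set of PubMed-style records, each carrying a PMID, a title
(``TI``) and an abstract (``AB``).  Records are segmented into sentences at
parse time because the sentence is the unit of every downstream statistic:
gene frequencies and gene-phenotype co-occurrences are counted at most once
per sentence.

Field unfolding (continuation lines joined with a single space) is delegated
to :mod:`Bio.Medline`; block segmentation is done here so that malformed
blocks can be reported with their byte offset in the input.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import Medline

logger = logging.getLogger(__name__)

#: Strings that end with a period but do not terminate a sentence.
#: Editable: pass a custom tuple to :func:`split_sentences` / :func:`parse_medline`.
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "et al.",
    "Fig.",
    "Figs.",
    "e.g.",
    "i.e.",
    "vs.",
    "cf.",
    "ca.",
    "No.",
    "Ref.",
)


class MedlineParseError(ValueError):
    """A MEDLINE block could not be parsed.

    Carries the byte offset of the offending block in the input stream.
    """

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


@dataclass
class AbstractRecord:
    """One abstract: the title is kept as one extra sentence ahead of the
    abstract's own sentences, so that gene mentions in titles are mined too."""

    pmid: str
    title: str
    abstract: str
    sentences: list[str] = field(default_factory=list)


@dataclass
class Corpus:
    """An ordered collection of abstracts from one retrieval arm."""

    label: str
    records: list[AbstractRecord] = field(default_factory=list)

    @property
    def n_papers(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# Candidate boundary: terminal punctuation followed by whitespace and an
# uppercase letter or digit.
_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s+[A-Z0-9])")


def split_sentences(
    text: str, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
) -> list[str]:
    """Rule-based sentence segmentation.

    A boundary is a run of ``. ? !`` followed by whitespace and an uppercase
    letter or digit, unless the text up to the period ends with one of the
    abbreviations.  Produced sentences are stripped of surrounding whitespace
    and never empty; every non-whitespace character of the input is preserved.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()
        head = text[:end]
        if any(head.endswith(abbr) for abbr in abbreviations):
            continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _iter_blocks(text: str) -> Iterator[tuple[int, str]]:
    """Yield (byte_offset, block_text) for blank-line-separated blocks."""
    offset = 0
    block_lines: list[str] = []
    block_offset = 0
    for line in text.splitlines(keepends=True):
        if line.strip() == "":
            if block_lines:
                yield block_offset, "".join(block_lines)
                block_lines = []
        else:
            if not block_lines:
                block_offset = offset
            block_lines.append(line)
        offset += len(line.encode("utf-8"))
    if block_lines:
        yield block_offset, "".join(block_lines)


def parse_medline(
    stream: TextIO | str,
    label: str = "corpus",
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> Corpus:
    """Parse a MEDLINE flat file (tags PMID, TI, AB) into a :class:`Corpus`.

    Records missing an ``AB`` field get an empty abstract and a logged
    warning.  A block with no ``PMID`` tag, or a duplicated PMID, raises
    :class:`MedlineParseError` naming the byte offset of the block.
    """
    text = stream if isinstance(stream, str) else stream.read()
    corpus = Corpus(label=label)
    seen: set[str] = set()
    for byte_offset, block in _iter_blocks(text):
        if not re.search(r"^PMID", block, flags=re.MULTILINE):
            raise MedlineParseError("MEDLINE block has no PMID tag", byte_offset)
        rec = Medline.read(io.StringIO(block))
        pmid = rec.get("PMID", "")
        if not pmid:
            raise MedlineParseError("MEDLINE block has an empty PMID", byte_offset)
        if pmid in seen:
            raise MedlineParseError(f"duplicate PMID {pmid}", byte_offset)
        seen.add(pmid)
        title = str(rec.get("TI", "")).strip()
        abstract = str(rec.get("AB", "")).strip()
        if not abstract:
            logger.warning("record %s has no AB field; abstract left empty", pmid)
        sentences = ([title] if title else []) + split_sentences(
            abstract, abbreviations
        )
        corpus.records.append(
            AbstractRecord(pmid=pmid, title=title, abstract=abstract, sentences=sentences)
        )
    return corpus


def write_medline(corpus: Corpus, stream: TextIO) -> None:
    """Write a corpus back to MEDLINE flat-file form.

    Fields are emitted on single lines (no wrapping), which round-trips
    exactly through :func:`parse_medline`.
    """
    for rec in corpus.records:
        stream.write(f"PMID- {rec.pmid}\n")
        if rec.title:
            stream.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            stream.write(f"AB  - {rec.abstract}\n")
        stream.write("\n")


def corpus_to_medline(corpus: Corpus) -> str:
    buf = io.StringIO()
    write_medline(corpus, buf)
    return buf.getvalue()
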