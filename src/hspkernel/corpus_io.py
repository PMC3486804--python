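"""Corpus and dependency-parse readers/writers.

Two plain-text dialects are consumed:

* **Corpus XML** — ``<corpus><document id><sentence id text><entity .../>
  <pair .../></sentence></document></corpus>``.  Entities carry inclusive
  character offsets (``charOffset="3-11"``, both ends inside the mention, as
  drug-interaction corpora print them); offsets are converted to 0-based
  half-open form at this boundary and used half-open everywhere else.
* **Parse tables** — CoNLL-style blocks, one sentence per blank-line
  separated block, first line ``# <sentence id>``, then one tab-separated
  row per token: ``index  form  POS  head  relation`` with 1-based token
  indices and head 0 denoting the root.

``load_instances`` joins the two files into candidate instances: one per
``<pair>`` element, each carrying the sentence parse and every entity of
the sentence (needed for blinding non-candidate drug mentions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from lxml import etree

from .errors import (
    CorpusFormatError,
    DanglingReferenceError,
    OffsetMismatchError,
    ParseFormatError,
)

__all__ = [
    "EntityMention",
    "Token",
    "DependencyParse",
    "Sentence",
    "CandidateInstance",
    "BlindingPlan",
    "read_corpus",
    "write_corpus",
    "read_parses",
    "write_parses",
    "load_instances",
    "blind_entities",
]


@dataclass(frozen=True)
class EntityMention:
    entity_id: str
    char_start: int  # 0-based, half-open
    char_end: int
    text: str

    def __post_init__(self):
        if self.char_start >= self.char_end:
            raise CorpusFormatError(
                f"entity {self.entity_id}: empty span [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class Token:
    form: str
    pos: str
    char_start: int = -1
    char_end: int = -1


@dataclass(frozen=True)
class DependencyParse:
    """Tokens plus (head, dependent, relation) triples.

    Root attachments (head index 0 in the file) are not dependencies; the
    affected token indices are kept in ``root_indices``.  Non-tree parses
    (cycles, multiple heads) are recorded verbatim — the graph kernel
    operates on general directed graphs.
    """

    tokens: tuple[Token, ...]
    dependencies: tuple[tuple[int, int, str], ...]  # (head idx, dependent idx, relation), 0-based
    root_indices: tuple[int, ...] = ()

    def __post_init__(self):
        n = len(self.tokens)
        for (h, d, rel) in self.dependencies:
            if not (0 <= h < n and 0 <= d < n):
                raise ParseFormatError(f"dependency ({h}, {d}, {rel}) index out of range (n={n})")
            if h == d:
                raise ParseFormatError(f"dependency with head == dependent at token {h}")


@dataclass(frozen=True)
class Sentence:
    sentence_id: str
    document_id: str
    text: str
    entities: tuple[EntityMention, ...]
    pairs: tuple[tuple[str, str, bool], ...]  # (e1 id, e2 id, interaction)


@dataclass(frozen=True)
class CandidateInstance:
    """One labeled candidate drug pair in one sentence.

    ``e1`` precedes ``e2`` by character start.  ``entities`` lists every
    entity of the sentence, including the candidates.
    """

    sentence_id: str
    document_id: str
    text: str
    e1: EntityMention
    e2: EntityMention
    label: bool
    parse: DependencyParse
    entities: tuple[EntityMention, ...] = ()

    def __post_init__(self):
        if self.e1.entity_id == self.e2.entity_id:
            raise CorpusFormatError(
                f"sentence {self.sentence_id}: pair of entity {self.e1.entity_id} with itself"
            )
        if self.e1.char_start > self.e2.char_start:
            object.__setattr__(self, "e1", self.e2)
            object.__setattr__(self, "e2", self.e1)


# ---------------------------------------------------------------------------
# corpus XML


def read_corpus(source) -> list[Sentence]:
    """Parse corpus XML into sentences with entities and labeled pairs."""
    try:
        tree = etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CorpusFormatError(f"malformed corpus XML: {exc}") from exc
    sentences: list[Sentence] = []
    for doc in tree.getroot().iter("document"):
        doc_id = doc.get("id", "")
        for sent in doc.iter("sentence"):
            sid = sent.get("id", "")
            text = sent.get("text")
            if text is None:
                raise CorpusFormatError(f"sentence {sid}: missing text attribute")
            entities = []
            for ent in sent.iter("entity"):
                offset = ent.get("charOffset", "")
                try:
                    start_s, end_s = offset.split("-")
                    start, end = int(start_s), int(end_s) + 1  # inclusive -> half-open
                except ValueError as exc:
                    raise CorpusFormatError(
                        f"sentence {sid}: bad charOffset {offset!r}"
                    ) from exc
                ent_text = ent.get("text", "")
                if text[start:end] != ent_text:
                    raise OffsetMismatchError(
                        f"sentence {sid}: entity {ent.get('id')} text {ent_text!r} != "
                        f"sentence[{start}:{end}] = {text[start:end]!r}"
                    )
                entities.append(EntityMention(ent.get("id", ""), start, end, ent_text))
            by_id = {e.entity_id: e for e in entities}
            pairs = []
            for pair in sent.iter("pair"):
                e1, e2 = pair.get("e1"), pair.get("e2")
                for eid in (e1, e2):
                    if eid not in by_id:
                        raise DanglingReferenceError(
                            f"sentence {sid}: pair references unknown entity {eid!r}"
                        )
                interaction = pair.get("interaction", "false").lower() == "true"
                pairs.append((e1, e2, interaction))
            sentences.append(Sentence(sid, doc_id, text, tuple(entities), tuple(pairs)))
    return sentences


def write_corpus(sentences: Sequence[Sentence], path) -> None:
    root = etree.Element("corpus")
    docs: dict[str, etree._Element] = {}
    for s in sentences:
        doc = docs.get(s.document_id)
        if doc is None:
            doc = etree.SubElement(root, "document", id=s.document_id)
            docs[s.document_id] = doc
        sent = etree.SubElement(doc, "sentence", id=s.sentence_id, text=s.text)
        for e in s.entities:
            etree.SubElement(
                sent,
                "entity",
                id=e.entity_id,
                charOffset=f"{e.char_start}-{e.char_end - 1}",
                text=e.text,
                type="drug",
            )
        for i, (e1, e2, label) in enumerate(s.pairs):
            etree.SubElement(
                sent,
                "pair",
                id=f"{s.sentence_id}.p{i}",
                e1=e1,
                e2=e2,
                interaction="true" if label else "false",
            )
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# parse tables


def read_parses(source) -> dict[str, DependencyParse]:
    """Read all parse blocks; returns sentence id -> parse."""
    if hasattr(source, "read"):
        content = source.read()
    else:
        with open(source) as fh:
            content = fh.read()
    parses: dict[str, DependencyParse] = {}
    for block in content.split("\n\n"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        if not lines[0].startswith("#"):
            raise ParseFormatError(f"parse block missing '# <sentence id>' header: {lines[0]!r}")
        sid = lines[0][1:].strip()
        tokens: list[Token] = []
        deps: list[tuple[int, int, str]] = []
        roots: list[int] = []
        heads: list[tuple[int, int, str]] = []
        for expected, line in enumerate(lines[1:], start=1):
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseFormatError(f"sentence {sid}: expected 5 columns, got {len(cols)}: {line!r}")
            idx, form, pos, head_s, rel = cols
            if int(idx) != expected:
                raise ParseFormatError(
                    f"sentence {sid}: non-contiguous token index {idx} (expected {expected})"
                )
            tokens.append(Token(form=form, pos=pos))
            heads.append((expected, int(head_s), rel))
        n = len(tokens)
        for (dep_idx, head, rel) in heads:
            if head == 0:
                roots.append(dep_idx - 1)
            elif 1 <= head <= n:
                deps.append((head - 1, dep_idx - 1, rel))
            else:
                raise ParseFormatError(f"sentence {sid}: head {head} out of range (n={n})")
        parses[sid] = DependencyParse(tuple(tokens), tuple(deps), tuple(roots))
    return parses


def write_parses(parses: dict[str, DependencyParse], path) -> None:
    with open(path, "w") as fh:
        first = True
        for sid, parse in parses.items():
            if not first:
                fh.write("\n")
            first = False
            fh.write(f"# {sid}\n")
            head_of = {d: (h + 1, rel) for (h, d, rel) in parse.dependencies}
            for i, tok in enumerate(parse.tokens):
                head, rel = head_of.get(i, (0, "root"))
                fh.write(f"{i + 1}\t{tok.form}\t{tok.pos}\t{head}\t{rel}\n")


def align_tokens(text: str, parse: DependencyParse) -> DependencyParse:
    """Fill in character offsets by matching token forms left-to-right."""
    tokens = []
    cursor = 0
    for tok in parse.tokens:
        start = text.find(tok.form, cursor)
        if start < 0:
            raise ParseFormatError(f"token {tok.form!r} not found in sentence text after {cursor}")
        end = start + len(tok.form)
        tokens.append(replace(tok, char_start=start, char_end=end))
        cursor = end
    return replace(parse, tokens=tuple(tokens))


def load_instances(corpus_path, parses_path) -> list[CandidateInstance]:
    """Join corpus sentences with their parses into candidate instances."""
    sentences = read_corpus(corpus_path)
    parses = read_parses(parses_path)
    instances: list[CandidateInstance] = []
    for s in sentences:
        if s.sentence_id not in parses:
            raise ParseFormatError(f"no parse for sentence {s.sentence_id}")
        parse = align_tokens(s.text, parses[s.sentence_id])
        by_id = {e.entity_id: e for e in s.entities}
        for (e1_id, e2_id, label) in s.pairs:
            instances.append(
                CandidateInstance(
                    sentence_id=s.sentence_id,
                    document_id=s.document_id,
                    text=s.text,
                    e1=by_id[e1_id],
                    e2=by_id[e2_id],
                    label=label,
                    parse=parse,
                    entities=s.entities,
                )
            )
    return instances


# ---------------------------------------------------------------------------
# entity blinding


@dataclass(frozen=True)
class BlindingPlan:
    """Token-level relabeling for one candidate instance.

    ``groups`` lists, in sentence order, ``(kept token index, merged token
    indices, replacement label)`` for each blinded entity: the candidate
    pair becomes DRUG1/DRUG2, any other drug mention in the sentence becomes
    DRUG so the classifier cannot memorize drug names.  Multi-token mentions
    collapse onto the mention's dependency head (first token if the head is
    unresolvable); external dependencies re-attach to the kept token.
    ``warnings`` records entity spans that had to be aligned by maximal
    token overlap.
    """

    groups: tuple[tuple[int, frozenset[int], str], ...]
    warnings: tuple[str, ...] = ()


def _covered_tokens(entity: EntityMention, parse: DependencyParse) -> tuple[list[int], bool]:
    """Token indices overlapping the entity span; flag if boundaries cross."""
    covered = []
    crossed = False
    for i, tok in enumerate(parse.tokens):
        overlap = min(entity.char_end, tok.char_end) - max(entity.char_start, tok.char_start)
        if overlap > 0:
            covered.append(i)
            if overlap < tok.char_end - tok.char_start:
                crossed = True
    return covered, crossed


def _head_within(span: list[int], parse: DependencyParse) -> int:
    """Token of the span whose head lies outside it (the span's syntactic head)."""
    span_set = set(span)
    head_of = {d: h for (h, d, _rel) in parse.dependencies}
    external = [i for i in span if head_of.get(i, -1) not in span_set]
    if len(external) == 1:
        return external[0]
    return span[0]


def blind_entities(instance: CandidateInstance) -> BlindingPlan:
    """Plan the DRUG1/DRUG2/DRUG relabeling for one candidate instance."""
    parse = instance.parse
    if parse.tokens and parse.tokens[0].char_start < 0:
        parse = align_tokens(instance.text, parse)
    labeled: list[tuple[EntityMention, str]] = [
        (instance.e1, "DRUG1"),
        (instance.e2, "DRUG2"),
    ]
    candidate_ids = {instance.e1.entity_id, instance.e2.entity_id}
    for ent in instance.entities:
        if ent.entity_id not in candidate_ids:
            labeled.append((ent, "DRUG"))

    groups: list[tuple[int, frozenset[int], str]] = []
    warnings: list[str] = []
    taken: set[int] = set()
    for ent, label in labeled:
        covered, crossed = _covered_tokens(ent, parse)
        covered = [i for i in covered if i not in taken]
        if not covered:
            raise CorpusFormatError(
                f"sentence {instance.sentence_id}: entity {ent.entity_id} covers no tokens"
            )
        if crossed:
            warnings.append(
                f"entity {ent.entity_id} crosses token boundaries; aligned by maximal overlap"
            )
        kept = _head_within(covered, parse)
        groups.append((kept, frozenset(covered), label))
        taken.update(covered)
    groups.sort(key=lambda g: g[0])
    return BlindingPlan(groups=tuple(groups), warnings=tuple(warnings))
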