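"""Seeded generators: random labeled graphs and planted-signal toy corpora.

The toy corpus emulates a drug-interaction corpus at desk scale: sentences
are drawn from a template grammar of about a dozen frames, each with a
hand-written dependency parse, two drug entities and one labeled candidate
pair.  The planted signal is structural: positive frames place an
interaction trigger verb (``inhibits``, ``potentiates``, ...) on the
dependency path between the candidates; negative frames never do, though
some contain a trigger verb buried in a distractor clause off the path and
some carry a prunable leading clause.  A pipeline that reads the corpus,
blinds the entities, builds and prunes the graphs and classifies with the
HSP kernel must therefore recover the labels, and pruning measurably
simplifies the distractor frames.  No attempt is made to match a real
corpus's lexical distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import DependencyParse, EntityMention, Sentence, Token, write_corpus, write_parses
from .graph_model import Component, LabeledNode, NodeKind, SentenceGraph

__all__ = ["random_graph", "toy_corpus", "FRAMES"]


# ---------------------------------------------------------------------------
# random graphs (kernel test harness)


def random_graph(
    seed: int,
    n_nodes: int,
    edge_prob: float,
    alphabet_size: int = 5,
    two_components: bool = False,
    edge_weight: float = 1.0,
) -> SentenceGraph:
    """Random directed vertex-labeled graph, deterministic per seed.

    Token nodes only, labels drawn from ``L0 .. L{alphabet_size-1}``; edges
    drawn independently with probability ``edge_prob`` over all ordered node
    pairs without self-loops.  With ``two_components`` the nodes split into
    a dependency-like and a linear-like half (no cross edges).  Candidate
    markers are left empty: these graphs exercise the kernel, not pruning.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(n_nodes):
        if two_components and i >= n_nodes // 2:
            comp, idx = Component.LINEAR, i - n_nodes // 2
        else:
            comp, idx = Component.DEPENDENCY, i
        label = f"L{int(rng.integers(alphabet_size))}"
        nodes.append(LabeledNode(i, label, NodeKind.TOKEN, comp, token_index=idx))
    edges = set()
    for u in range(n_nodes):
        for v in range(n_nodes):
            if u == v or nodes[u].component != nodes[v].component:
                continue
            if rng.random() < edge_prob:
                edges.add((u, v))
    return SentenceGraph(nodes=tuple(nodes), edges=frozenset(edges), edge_weight=edge_weight)


# ---------------------------------------------------------------------------
# toy corpus


@dataclass(frozen=True)
class Frame:
    """One sentence template: tokens ``(form, pos, head, relation)`` with
    1-based heads (0 = root), slots written ``{D1}``/``{D2}``/``{TRIG}``/...
    ``positive`` is the gold label of the (D1, D2) candidate pair;
    ``distractor`` marks frames with a prunable leading clause."""

    name: str
    tokens: tuple[tuple[str, str, int, str], ...]
    positive: bool
    distractor: bool = False


def _f(name, positive, rows, distractor=False) -> Frame:
    return Frame(
        name=name,
        tokens=tuple((form, pos, head, rel) for (form, pos, head, rel) in rows),
        positive=positive,
        distractor=distractor,
    )


# Positive frames: the trigger verb lies on the dependency path D1 .. D2.
# Negative frames: no trigger on the path; f_neg_distractor buries the same
# trigger lexeme inside a relative clause two hops off the path, and the
# distractor frames prepend a clause the pruner must remove.
FRAMES: tuple[Frame, ...] = (
    _f("pos_active", True, [
        ("{D1}", "nn", 2, "nsubj"),
        ("{TRIG}", "vbz", 0, "root"),
        ("the", "dt", 4, "det"),
        ("{EFFECT}", "nn", 2, "dobj"),
        ("of", "in", 4, "prep"),
        ("{D2}", "nn", 5, "pobj"),
        (".", ".", 2, "punct"),
    ]),
    _f("pos_coadmin", True, [
        ("coadministration", "nn", 5, "nsubj"),
        ("of", "in", 1, "prep"),
        ("{D1}", "nn", 2, "pobj"),
        ("{ADV}", "rb", 5, "advmod"),
        ("{TRIG}", "vbz", 0, "root"),
        ("the", "dt", 8, "det"),
        ("plasma", "nn", 8, "nn"),
        ("{EFFECT}", "nn", 5, "dobj"),
        ("of", "in", 8, "prep"),
        ("{D2}", "nn", 9, "pobj"),
        (".", ".", 5, "punct"),
    ]),
    _f("pos_modal", True, [
        ("{D1}", "nn", 4, "nsubj"),
        ("may", "md", 4, "aux"),
        ("{ADV}", "rb", 4, "advmod"),
        ("{TRIG}", "vb", 0, "root"),
        ("the", "dt", 6, "det"),
        ("{EFFECT}", "nn", 4, "dobj"),
        ("of", "in", 6, "prep"),
        ("{D2}", "nn", 7, "pobj"),
        ("in", "in", 4, "prep"),
        ("some", "dt", 11, "det"),
        ("patients", "nns", 9, "pobj"),
        (".", ".", 4, "punct"),
    ]),
    _f("pos_passive", True, [
        ("the", "dt", 2, "det"),
        ("{EFFECT}", "nn", 6, "nsubjpass"),
        ("of", "in", 2, "prep"),
        ("{D1}", "nn", 3, "pobj"),
        ("is", "vbz", 6, "auxpass"),
        ("{TRIGVBN}", "vbn", 0, "root"),
        ("by", "in", 6, "prep"),
        ("{D2}", "nn", 7, "pobj"),
        (".", ".", 6, "punct"),
    ]),
    # leading clause mimics a report sentence that pruning must discard
    _f("pos_distractor", True, [
        ("however", "rb", 5, "advmod"),
        (",", ",", 5, "punct"),
        ("there", "ex", 5, "expl"),
        ("has", "vbz", 5, "aux"),
        ("been", "vbn", 0, "root"),
        ("one", "cd", 7, "num"),
        ("report", "nn", 5, "nsubj"),
        ("of", "in", 7, "prep"),
        ("{NOUN}", "nn", 8, "pobj"),
        (",", ",", 5, "punct"),
        ("and", "cc", 5, "cc"),
        ("{D1}", "nn", 13, "nsubj"),
        ("{TRIG}", "vbz", 5, "conj"),
        ("the", "dt", 15, "det"),
        ("{EFFECT}", "nn", 13, "dobj"),
        ("of", "in", 15, "prep"),
        ("{D2}", "nn", 16, "pobj"),
        (".", ".", 13, "punct"),
    ], distractor=True),
    _f("neg_conj", False, [
        ("{D1}", "nn", 5, "nsubjpass"),
        ("and", "cc", 1, "cc"),
        ("{D2}", "nn", 1, "conj"),
        ("were", "vbd", 5, "auxpass"),
        ("administered", "vbn", 0, "root"),
        ("to", "in", 5, "prep"),
        ("healthy", "jj", 8, "amod"),
        ("volunteers", "nns", 6, "pobj"),
        (".", ".", 5, "punct"),
    ]),
    _f("neg_received", False, [
        ("patients", "nns", 2, "nsubj"),
        ("received", "vbd", 0, "root"),
        ("{D1}", "nn", 2, "dobj"),
        ("and", "cc", 3, "cc"),
        ("{D2}", "nn", 3, "conj"),
        ("during", "in", 2, "prep"),
        ("the", "dt", 8, "det"),
        ("study", "nn", 6, "pobj"),
        (".", ".", 2, "punct"),
    ]),
    _f("neg_no_interaction", False, [
        ("no", "dt", 4, "det"),
        ("clinically", "rb", 3, "advmod"),
        ("significant", "jj", 4, "amod"),
        ("interaction", "nn", 10, "nsubjpass"),
        ("between", "in", 4, "prep"),
        ("{D1}", "nn", 5, "pobj"),
        ("and", "cc", 6, "cc"),
        ("{D2}", "nn", 6, "conj"),
        ("was", "vbd", 10, "auxpass"),
        ("observed", "vbn", 0, "root"),
        (".", ".", 10, "punct"),
    ]),
    _f("neg_detected", False, [
        ("{D1}", "nn", 3, "nsubjpass"),
        ("was", "vbd", 3, "auxpass"),
        ("detected", "vbn", 0, "root"),
        ("in", "in", 3, "prep"),
        ("plasma", "nn", 4, "pobj"),
        ("after", "in", 3, "prep"),
        ("{D2}", "nn", 8, "nn"),
        ("administration", "nn", 6, "pobj"),
        (".", ".", 3, "punct"),
    ]),
    # trigger lexeme present but inside a relative clause off the D1..D2
    # path: pruning removes it, an unpruned graph sees a misleading trigger
    _f("neg_offpath_trigger", False, [
        ("however", "rb", 10, "advmod"),
        (",", ",", 10, "punct"),
        ("a", "dt", 4, "det"),
        ("{NOUN}", "nn", 10, "nsubjpass"),
        ("that", "wdt", 6, "nsubj"),
        ("{TRIG}", "vbz", 4, "rcmod"),
        ("gastric", "jj", 8, "amod"),
        ("acidity", "nn", 6, "dobj"),
        ("was", "vbd", 10, "auxpass"),
        ("reported", "vbn", 0, "root"),
        (",", ",", 10, "punct"),
        ("and", "cc", 10, "cc"),
        ("{D1}", "nn", 15, "nsubjpass"),
        ("was", "vbd", 15, "auxpass"),
        ("given", "vbn", 10, "conj"),
        ("with", "in", 15, "prep"),
        ("{D2}", "nn", 16, "pobj"),
        (".", ".", 15, "punct"),
    ], distractor=True),
)

DRUG_NAMES = (
    "warfarin", "digoxin", "phenytoin", "cimetidine", "rifampin", "ketoconazole",
    "theophylline", "erythromycin", "amiodarone", "quinidine", "verapamil",
    "fluoxetine", "carbamazepine", "lithium", "propranolol", "methotrexate",
    "omeprazole", "simvastatin", "clarithromycin", "diazepam",
)
TRIGGERS = ("increases", "inhibits", "potentiates", "reduces", "enhances", "decreases")
TRIGGERS_VBN = ("increased", "inhibited", "potentiated", "reduced", "enhanced", "decreased")
EFFECTS = ("effect", "metabolism", "clearance", "absorption", "concentration")
ADVERBS = ("markedly", "significantly", "moderately")
NOUNS = ("bleeding", "dizziness", "nausea", "headache")


def _realize(frame: Frame, rng: np.random.Generator):
    """Fill one frame's slots; returns (text, forms, offsets, entity_spans, parse)."""
    d1, d2 = rng.choice(len(DRUG_NAMES), size=2, replace=False)
    slots = {
        "{D1}": DRUG_NAMES[d1],
        "{D2}": DRUG_NAMES[d2],
        "{TRIG}": TRIGGERS[int(rng.integers(len(TRIGGERS)))],
        "{TRIGVBN}": TRIGGERS_VBN[int(rng.integers(len(TRIGGERS_VBN)))],
        "{EFFECT}": EFFECTS[int(rng.integers(len(EFFECTS)))],
        "{ADV}": ADVERBS[int(rng.integers(len(ADVERBS)))],
        "{NOUN}": NOUNS[int(rng.integers(len(NOUNS)))],
    }
    forms = [slots.get(form, form) for (form, _pos, _h, _r) in frame.tokens]
    text = " ".join(forms)

    offsets = []
    cursor = 0
    for form in forms:
        offsets.append((cursor, cursor + len(form)))
        cursor += len(form) + 1

    entity_spans = []
    for i, (form, _pos, _h, _r) in enumerate(frame.tokens):
        if form in ("{D1}", "{D2}"):
            entity_spans.append((form, i))
    entity_spans.sort(key=lambda s: s[1])

    parse = DependencyParse(
        tokens=tuple(Token(form, pos) for form, (_, pos, _h, _r) in zip(forms, frame.tokens)),
        dependencies=tuple(
            (h - 1, i, rel) for i, (_f2, _p, h, rel) in enumerate(frame.tokens) if h > 0
        ),
        root_indices=tuple(i for i, (_f2, _p, h, _r) in enumerate(frame.tokens) if h == 0),
    )
    return text, forms, offsets, entity_spans, parse


def toy_corpus(
    seed: int,
    n_sentences: int,
    positive_rate: float = 0.3,
    out_dir: str | Path | None = None,
    sentences_per_document: int = 10,
) -> tuple[list[Sentence], dict[str, DependencyParse]]:
    """Generate a planted-signal corpus; optionally write it to disk.

    Each sentence holds two drug entities and one candidate pair whose label
    follows the frame's planted signal.  Frames are drawn positive with
    probability ``positive_rate``.  When ``out_dir`` is given, ``corpus.xml``
    and ``parses.conll`` are written in the dialects ``corpus_io`` reads;
    regeneration with the same seed is byte-identical.
    """
    if n_sentences < 1:
        raise ValueError("need at least one sentence")
    rng = np.random.default_rng(seed)
    pos_frames = [f for f in FRAMES if f.positive]
    neg_frames = [f for f in FRAMES if not f.positive]

    sentences: list[Sentence] = []
    parses: dict[str, DependencyParse] = {}
    for i in range(n_sentences):
        doc_id = f"d{i // sentences_per_document}"
        sid = f"{doc_id}.s{i}"
        if rng.random() < positive_rate:
            frame = pos_frames[int(rng.integers(len(pos_frames)))]
        else:
            frame = neg_frames[int(rng.integers(len(neg_frames)))]
        text, forms, offsets, entity_spans, parse = _realize(frame, rng)
        entities = []
        ent_ids = {}
        for j, (slot, tok_idx) in enumerate(entity_spans):
            start, end = offsets[tok_idx]
            eid = f"{sid}.e{j}"
            entities.append(EntityMention(eid, start, end, forms[tok_idx]))
            ent_ids[slot] = eid
        pairs = ((ent_ids["{D1}"], ent_ids["{D2}"], frame.positive),)
        sentences.append(
            Sentence(
                sentence_id=sid,
                document_id=doc_id,
                text=text,
                entities=tuple(entities),
                pairs=pairs,
            )
        )
        parses[sid] = parse

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus(sentences, out_dir / "corpus.xml")
        write_parses(parses, out_dir / "parses.conll")
    return sentences, parses


def frame_of_sentence_id(
    sentences: list[Sentence], parses: dict[str, DependencyParse]
) -> dict[str, str]:
    """Map sentence id -> generating frame name, recovered from the parse shape
    (the per-token relation sequence is unique to each frame)."""
    by_shape = {
        tuple(rel if h > 0 else "root" for (_f2, _p, h, rel) in f.tokens): f.name for f in FRAMES
    }
    out = {}
    for s in sentences:
        parse = parses[s.sentence_id]
        rels = ["root"] * len(parse.tokens)
        for (_h, d, rel) in parse.dependencies:
            rels[d] = rel
        name = by_shape.get(tuple(rels))
        if name is not None:
            out[s.sentence_id] = name
    return out
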