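"""Label encoding and hierarchical neighborhood hashing.

Every distinct node label (a token like ``"treated/vbn"`` or a dependency
relation like ``"nsubjpass"``) is assigned a unique D-bit code.  The
neighborhood hash update then mixes a node's own code with the codes of its
in- and out-neighbors using cyclic bit rotation and XOR:

    h_{k+1}(v) = rot(h_k(v), rot_center)
                 XOR_{u -> v} rot(h_k(u), rot_in)
                 XOR_{v -> u} rot(h_k(u), rot_out)

Distinct rotation offsets for the three roles make edge direction observable
in the hash.  Level k of the resulting hierarchy summarizes the labeled
neighborhood of radius k around each node: two nodes whose radius-k
neighborhoods are isomorphic with equal labels receive equal level-k values
(up to the negligible collision probability of the D-bit codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import VocabularyOverflowError
from .graph_model import KernelConfig, SentenceGraph

__all__ = ["rot", "LabelVocabulary", "HashLabeling", "encode", "nh_update", "hierarchical_labels"]


def rot(x: int, offset: int, D: int) -> int:
    """Cyclic left-rotation of the D-bit value ``x`` by ``offset`` positions.

    The ``offset`` leading bits wrap around to the right end.  ``rot`` is a
    bijection on D-bit values and ``rot`` applied D times is the identity.
    """
    if not 0 <= offset < D:
        raise ValueError(f"rotation offset {offset} outside [0, {D})")
    mask = (1 << D) - 1
    x &= mask
    return ((x << offset) | (x >> (D - offset))) & mask


@dataclass
class LabelVocabulary:
    """Persistent injective map from label strings to D-bit codes.

    Codes are assigned sequentially from 1 in first-seen order (0 is the
    reserved null, ``2**D - 1`` the reserved unknown-label code), which makes
    encodings reproducible across runs, unlike random code draws.  A frozen
    vocabulary (inference mode) maps unseen labels to the UNK code instead
    of growing.
    """

    D: int = 24
    frozen: bool = False
    _codes: dict[str, int] = field(default_factory=dict)

    @property
    def unk_code(self) -> int:
        return (1 << self.D) - 1

    def __len__(self) -> int:
        return len(self._codes)

    def __contains__(self, label: str) -> bool:
        return label in self._codes

    def code(self, label: str) -> int:
        """Code for ``label``, appending it when unfrozen."""
        c = self._codes.get(label)
        if c is not None:
            return c
        if self.frozen:
            return self.unk_code
        c = len(self._codes) + 1
        if c >= self.unk_code:
            raise VocabularyOverflowError(
                f"vocabulary exceeded capacity 2**{self.D} - 2 = {self.unk_code - 1}"
            )
        self._codes[label] = c
        return c

    def items(self):
        return self._codes.items()

    # -- persistence: two-column text, label <TAB> code ------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#D\t{self.D}\n")
            for label, code in self._codes.items():
                fh.write(f"{label}\t{code}\n")

    @classmethod
    def load(cls, path, frozen: bool = True) -> "LabelVocabulary":
        D = 24
        codes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, value = line.split("\t")
                if key == "#D":
                    D = int(value)
                else:
                    codes[key] = int(value)
        vocab = cls(D=D, frozen=frozen)
        vocab._codes = codes
        return vocab


@dataclass
class HashLabeling:
    """Hash values per node at every hierarchy level 0..R.

    ``levels[k][node_id]`` is the D-bit hash of the radius-k neighborhood;
    level 0 equals the raw vocabulary codes.
    """

    levels: list[dict[int, int]]

    @property
    def R(self) -> int:
        return len(self.levels) - 1

    def hex(self, level: int, node_id: int, D: int = 24) -> str:
        """Zero-padded hex rendering (e.g. ``"675D2A"`` for D=24)."""
        width = (D + 3) // 4
        return format(self.levels[level][node_id], f"0{width}X")


def encode(g: SentenceGraph, vocab: LabelVocabulary) -> dict[int, int]:
    """Level-0 labeling: each node mapped to the code of its label string."""
    return {n.node_id: vocab.code(n.label) for n in g.nodes}


def nh_update(g: SentenceGraph, labeling: Mapping[int, int], config: KernelConfig) -> dict[int, int]:
    """One neighborhood-hash iteration over all nodes."""
    D = config.D
    out: dict[int, int] = {}
    for n in g.nodes:
        h = rot(labeling[n.node_id], config.rot_center, D)
        for u in g.in_neighbors(n.node_id):
            h ^= rot(labeling[u], config.rot_in, D)
        for u in g.out_neighbors(n.node_id):
            h ^= rot(labeling[u], config.rot_out, D)
        out[n.node_id] = h
    return out


def hierarchical_labels(
    g: SentenceGraph, vocab: LabelVocabulary, config: KernelConfig
) -> HashLabeling:
    """Hash labels at levels 0..R, level k = k applications of the update."""
    levels = [encode(g, vocab)]
    for _ in range(config.R):
        levels.append(nh_update(g, levels[-1], config))
    return HashLabeling(levels=levels)
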