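"""CES-D-8 item definitions and network node identifiers.

The depression screener has eight items (D1..D8) answered on a four-point
frequency scale (1 = rarely or none of the time .. 4 = most or all of the
time). Two items are worded positively ("I was happy", "I enjoyed life") and
are reverse scored before any analysis. Network nodes are one family member's
response to one item; the member is encoded by a single-letter role: B (boy),
G (girl), F (father), M (mother), and nodes render as e.g. ``F_D7``.
"""

from __future__ import annotations

from dataclasses import dataclass

ITEM_CODES = tuple(f"D{i}" for i in range(1, 9))

#: item codes that are reverse scored (positively worded items)
REVERSE_ITEMS = frozenset({"D4", "D6"})

#: valid ordinal responses
RESPONSE_LEVELS = (1, 2, 3, 4)

ROLE_LETTERS = {
    ("child", "boy"): "B",
    ("child", "girl"): "G",
    ("parent", "father"): "F",
    ("parent", "mother"): "M",
}


@dataclass(frozen=True)
class SymptomItem:
    """One CES-D-8 item."""

    code: str
    label: str
    reverse_scored: bool


SYMPTOM_ITEMS = (
    SymptomItem("D1", "depressiveness", False),
    SymptomItem("D2", "effortfulness", False),
    SymptomItem("D3", "restlessness", False),
    SymptomItem("D4", "unhappiness", True),
    SymptomItem("D5", "loneliness", False),
    SymptomItem("D6", "unenjoyment", True),
    SymptomItem("D7", "sadness", False),
    SymptomItem("D8", "felt-life-could-not-go-on", False),
)

assert len(SYMPTOM_ITEMS) == 8
assert {it.code for it in SYMPTOM_ITEMS if it.reverse_scored} == set(REVERSE_ITEMS)


@dataclass(frozen=True, order=True)
class NodeId:
    """A network node: one family member's response to one item.

    ``role`` is one of B/G/F/M; ``item`` is D1..D8. The string form matches
    the edge notation used in published bridging-edge tables (``F_D7``).
    """

    role: str
    item: str

    def __post_init__(self) -> None:
        if self.role not in {"B", "G", "F", "M"}:
            raise ValueError(f"unknown role letter {self.role!r}")
        if self.item not in ITEM_CODES:
            raise ValueError(f"unknown item code {self.item!r}")

    @property
    def community(self) -> str:
        return "child" if self.role in {"B", "G"} else "parent"

    def __str__(self) -> str:
        return f"{self.role}_{self.item}"

    @classmethod
    def parse(cls, s: str) -> "NodeId":
        role, _, item = s.partition("_")
        return cls(role, item)


def node_ids(child_gender: str, parent_role: str) -> list[NodeId]:
    """The 16 node ids of one dyad-type network: 8 child then 8 parent."""
    c = ROLE_LETTERS[("child", child_gender)]
    p = ROLE_LETTERS[("parent", parent_role)]
    return [NodeId(c, it) for it in ITEM_CODES] + [NodeId(p, it) for it in ITEM_CODES]
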