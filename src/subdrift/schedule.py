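"""Dated substrain genealogies.

An inbred substrain history is a rooted tree whose internal nodes carry
calendar years (the dates at which colonies were physically separated) and
whose tips are the named substrains, all sampled in a common
``sampling_year``.  Branch lengths in *generations* follow from the node
dates and a constant breeding tempo ``generations_per_year``.

The default schedule encodes the NOD substrain colony history: a source
colony established in 1980, the Lt and BomTac lineages separated in 1984,
the ShiJcl and MrkTac lineages in 1986, and ShiLtDvs split from ShiLt in
1992; all five substrains are sampled in 2014 at four generations per year.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["ScheduleNode", "SeparationSchedule", "default_nod_schedule"]

NOD_SUBSTRAINS = ("BomTac", "MrkTac", "ShiJcl", "ShiLtDvs", "ShiLt")


@dataclass
class ScheduleNode:
    """A node of the dated genealogy.

    Internal nodes carry the calendar year of the split; tips carry the
    substrain name and no date (they are sampled at ``sampling_year``).
    """

    name: str | None = None
    date: float | None = None
    children: list["ScheduleNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_tip:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.tips())
        return out


class SeparationSchedule:
    """Dated genealogy of inbred substrains.

    Parameters
    ----------
    root:
        Root of the dated split tree. Internal node dates must strictly
        increase from root to tips.
    sampling_year:
        Calendar year at which every tip substrain is sampled; must be
        later than every split date.
    generations_per_year:
        Breeding tempo converting years to generations (default 4).
    """

    def __init__(
        self,
        root: ScheduleNode,
        sampling_year: float,
        generations_per_year: float = 4.0,
    ) -> None:
        self.root = root
        self.sampling_year = float(sampling_year)
        self.generations_per_year = float(generations_per_year)
        self.validate()

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be > 0")
        names = self.substrain_names
        if len(names) != len(set(names)):
            raise ValueError("duplicate substrain names in schedule")
        if len(names) < 2:
            raise ValueError("schedule must contain at least 2 substrains")

        def _walk(node: ScheduleNode, parent_date: float | None) -> None:
            if node.is_tip:
                if node.name is None:
                    raise ValueError("tip without a name")
                if parent_date is not None and parent_date >= self.sampling_year:
                    raise ValueError(
                        "sampling_year must postdate every split "
                        f"(split {parent_date} >= {self.sampling_year})"
                    )
                return
            if node.date is None:
                raise ValueError("internal node without a date")
            if parent_date is not None and node.date <= parent_date:
                raise ValueError(
                    f"node dates must strictly increase root→tips "
                    f"({node.date} <= {parent_date})"
                )
            for c in node.children:
                _walk(c, node.date)

        _walk(self.root, None)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def substrain_names(self) -> list[str]:
        return self.root.tips()

    def branches(self) -> Iterator[tuple[frozenset, float]]:
        """Yield ``(tip set below branch, branch length in generations)``.

        One entry per edge of the dated tree (the root itself has no branch
        above it).  Tip branches run from the parent split date to the
        sampling year.
        """

        def _walk(node: ScheduleNode) -> Iterator[tuple[frozenset, float]]:
            for child in node.children:
                end = self.sampling_year if child.is_tip else child.date
                years = end - node.date
                yield frozenset(child.tips()), years * self.generations_per_year
                if not child.is_tip:
                    yield from _walk(child)

        yield from _walk(self.root)

    def _mrca_date(self, a: str, b: str) -> float:
        node = self.root
        while True:
            nxt = None
            for c in node.children:
                tips = set(c.tips())
                if a in tips and b in tips:
                    nxt = c
                    break
            if nxt is None or nxt.is_tip:
                return node.date
            node = nxt

    def separation_years(self, a: str, b: str) -> float:
        """Years since substrains ``a`` and ``b`` were separated."""
        names = set(self.substrain_names)
        for x in (a, b):
            if x not in names:
                raise KeyError(f"unknown substrain {x!r}")
        if a == b:
            return 0.0
        return self.sampling_year - self._mrca_date(a, b)

    def path_generations(self, a: str, b: str) -> float:
        """Generations on the a<->b path (both lineages drift)."""
        return 2.0 * self.separation_years(a, b) * self.generations_per_year

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_json(cls, text: str) -> "SeparationSchedule":
        """Load from a JSON config.

        Expected shape::

            {"sampling_year": 2014, "generations_per_year": 4,
             "tree": {"date": 1980, "children": [
                 {"name": "A"}, {"date": 1984, "children": [...]}]}}
        """
        obj = json.loads(text)

        def _node(d: dict) -> ScheduleNode:
            return ScheduleNode(
                name=d.get("name"),
                date=d.get("date"),
                children=[_node(c) for c in d.get("children", [])],
            )

        return cls(
            _node(obj["tree"]),
            sampling_year=obj["sampling_year"],
            generations_per_year=obj.get("generations_per_year", 4.0),
        )

    def to_json(self) -> str:
        def _dict(node: ScheduleNode) -> dict:
            if node.is_tip:
                return {"name": node.name}
            return {"date": node.date, "children": [_dict(c) for c in node.children]}

        return json.dumps(
            {
                "sampling_year": self.sampling_year,
                "generations_per_year": self.generations_per_year,
                "tree": _dict(self.root),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_newick(
        cls,
        newick: str,
        root_date: float,
        sampling_year: float,
        generations_per_year: float = 4.0,
    ) -> "SeparationSchedule":
        """Parse a newick string whose branch lengths are in years.

        Node dates are ``root_date`` plus the cumulative branch length from
        the root; tip branch lengths beyond the last split are implied by
        the sampling year (tips are sampled at ``sampling_year``).
        """
        s = newick.strip().rstrip(";")
        pos = 0

        def _parse(date: float) -> ScheduleNode:
            nonlocal pos
            if s[pos] == "(":
                pos += 1
                children = [_parse_edge(date)]
                while s[pos] == ",":
                    pos += 1
                    children.append(_parse_edge(date))
                if s[pos] != ")":
                    raise ValueError(f"malformed newick at position {pos}: expected ')'")
                pos += 1
                _label()  # optional internal node label, ignored
                return ScheduleNode(date=date, children=children)
            name = _label()
            if not name:
                raise ValueError(f"malformed newick at position {pos}: expected a name")
            return ScheduleNode(name=name)

        def _label() -> str:
            nonlocal pos
            m = re.match(r"[^(),:;]*", s[pos:])
            pos += m.end()
            return m.group(0)

        def _length() -> float:
            nonlocal pos
            if pos < len(s) and s[pos] == ":":
                m = re.match(r":([0-9.eE+\-]+)", s[pos:])
                if m is None:
                    raise ValueError(f"malformed branch length at position {pos}")
                pos += m.end()
                return float(m.group(1))
            return 0.0

        def _parse_edge(parent_date: float) -> ScheduleNode:
            nonlocal pos
            if s[pos] == "(":
                start = pos
                node = _parse(parent_date)
                length = _length()
                # re-parse with the correct date now the length is known
                end = pos
                pos = start
                node = _parse(parent_date + length)
                pos = end
                return node
            name = _label()
            _length()
            return ScheduleNode(name=name)

        root = _parse(root_date)
        if pos != len(s):
            raise ValueError(f"trailing characters in newick at position {pos}")
        return cls(root, sampling_year, generations_per_year)


def default_nod_schedule(generations_per_year: float = 4.0) -> SeparationSchedule:
    """The default five-substrain NOD colony history (see module docstring)."""
    root = ScheduleNode(
        date=1980,
        children=[
            ScheduleNode(
                date=1984,
                children=[
                    ScheduleNode(
                        date=1992,
                        children=[ScheduleNode(name="ShiLt"), ScheduleNode(name="ShiLtDvs")],
                    ),
                    ScheduleNode(name="BomTac"),
                ],
            ),
            ScheduleNode(
                date=1986,
                children=[ScheduleNode(name="ShiJcl"), ScheduleNode(name="MrkTac")],
            ),
        ],
    )
    return SeparationSchedule(root, sampling_year=2014, generations_per_year=generations_per_year)
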