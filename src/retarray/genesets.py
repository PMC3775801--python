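"""Gene-set collections and the GMT interchange format."""

from __future__ import annotations

from pathlib import Path


class GeneSetCollection:
    """Named gene sets over a gene universe.

    Membership is stored as ``{name: frozenset(genes)}``; descriptions (the
    second GMT column) are kept for round-tripping.
    """

    def __init__(self, sets: dict, descriptions: dict | None = None):
        self._sets = {}
        self._desc = {}
        for name, members in sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[name] = members
            self._desc[name] = (descriptions or {}).get(name, "")

    def __len__(self):
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __contains__(self, name):
        return name in self._sets

    def __getitem__(self, name):
        return self._sets[name]

    def items(self):
        return self._sets.items()

    def description(self, name):
        return self._desc[name]

    @property
    def names(self):
        return list(self._sets)

    def universe(self) -> frozenset:
        """Union of all member genes."""
        out = set()
        for members in self._sets.values():
            out |= members
        return frozenset(out)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self._sets[n] for n in names},
            {n: self._desc[n] for n in names},
        )

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name in GMT: {name!r}")
            sets[name] = [g for g in fields[2:] if g]
            desc[name] = fields[1]
        return cls(sets, desc)

    def to_gmt(self, path) -> None:
        lines = []
        for name, members in self._sets.items():
            lines.append("\t".join([name, self._desc[name]] + sorted(members)))
        Path(path).write_text("\n".join(lines) + "\n")
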