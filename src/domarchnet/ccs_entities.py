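"""SCOP concise classification string (ccs) entities.

A protein architecture is written as a ``|``-joined, N-to-C ordered list of
SCOP fold-superfamily (FSF) identifiers, e.g. ``c.37.1|d.14.1``.  A trailing
``&`` marks a collapsed tandem repeat and makes the token a distinct unit:
``c.43.1&`` and ``c.43.1`` are different network nodes.

Entities are classified into three kinds:

* **domain** — a single FSF block;
* **supradomain** — a multi-block architecture that recurs as a contiguous
  proper sub-sequence of at least one other entity in the set;
* **multidomain** — any remaining multi-block architecture.

Matching of component parts inside larger architectures is order-sensitive
and contiguous; reversed or gapped occurrences never match, because domain
adjacency encodes the topology of the polypeptide chain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Block",
    "Architecture",
    "EntitySet",
    "CcsParseError",
    "parse_ccs",
    "classify_entities",
    "component_occurrences",
    "spliced_domains",
    "read_entity_tsv",
    "read_scop_descriptions",
]

# FSF-level sccs: class letter, fold number, superfamily number.
_FSF_RE = re.compile(r"^[a-l]\.\d+\.\d+$")


class CcsParseError(ValueError):
    """Raised for empty or malformed ccs labels."""


@dataclass(frozen=True)
class Block:
    """One FSF token of an architecture.

    ``repeat`` is True iff the token carried the ``&`` tandem-repeat marker;
    token identity is the pair ``(fsf_id, repeat)``.
    """

    fsf_id: str
    repeat: bool = False

    @property
    def token(self) -> str:
        return self.fsf_id + "&" if self.repeat else self.fsf_id

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


@dataclass(frozen=True)
class Architecture:
    """An ordered (N→C) sequence of blocks with its original label."""

    label: str
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise CcsParseError("architecture must have at least one block")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(b.token for b in self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __str__(self) -> str:
        return "|".join(self.tokens)


def parse_ccs(label: str, *, strict: bool = True) -> Architecture:
    """Parse a ccs label into an :class:`Architecture`.

    Parameters
    ----------
    label:
        ``|``-separated FSF tokens, optional trailing ``&`` per token.
    strict:
        When True (default), each token must match the FSF sccs pattern
        ``[a-l].fold.superfamily``; when False any non-empty token without
        ``|`` is accepted (useful for toy examples).

    Raises
    ------
    CcsParseError
        On an empty label or a malformed token (the message names it).
    """
    if not label:
        raise CcsParseError("empty ccs label")
    blocks: list[Block] = []
    for tok in label.split("|"):
        if not tok:
            raise CcsParseError(f"empty token in ccs label {label!r}")
        repeat = tok.endswith("&")
        core = tok[:-1] if repeat else tok
        if strict and not _FSF_RE.match(core):
            raise CcsParseError(
                f"malformed ccs token {tok!r}: expected class.fold.superfamily"
            )
        if not core:
            raise CcsParseError(f"malformed ccs token {tok!r}")
        blocks.append(Block(core, repeat))
    return Architecture(label, tuple(blocks))


@dataclass
class EntitySet:
    """A classified collection of architectures with unique labels."""

    entities: list[Architecture]
    kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entities]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in entity set")

    def __iter__(self) -> Iterator[Architecture]:
        return iter(self.entities)

    def __len__(self) -> int:
        return len(self.entities)

    def __getitem__(self, label: str) -> Architecture:
        return self._by_label[label]

    @property
    def _by_label(self) -> dict[str, Architecture]:
        return {e.label: e for e in self.entities}

    def labels(self) -> list[str]:
        return [e.label for e in self.entities]

    def of_kind(self, kind: str) -> list[Architecture]:
        return [e for e in self.entities if self.kind[e.label] == kind]

    def token_index(self) -> tuple[Mapping[tuple[str, ...], str], tuple[int, ...]]:
        """Cached map token-sequence → entity label, plus the sorted set of
        entity lengths; lets occurrence scans touch only candidate windows."""
        cached = getattr(self, "_token_index", None)
        if cached is None or cached[2] != len(self.entities):
            seqs = {e.tokens: e.label for e in self.entities}
            lengths = tuple(sorted({len(e.blocks) for e in self.entities}))
            cached = (seqs, lengths, len(self.entities))
            object.__setattr__(self, "_token_index", cached)
        return cached[0], cached[1]


def _is_proper_subsequence(needle: tuple[str, ...], hay: tuple[str, ...]) -> bool:
    n, h = len(needle), len(hay)
    if n >= h:
        return False
    return any(hay[i : i + n] == needle for i in range(h - n + 1))


def classify_entities(entities: Iterable[Architecture]) -> EntitySet:
    """Partition architectures into domains, supradomains and multidomains.

    Single-block entities are domains.  A multi-block entity is a supradomain
    when its token sequence occurs contiguously inside at least one *other*
    entity of the set, multidomain otherwise.  An architecture may exist both
    as a standalone protein and as a reused building block; classification
    picks supradomain whenever the sub-sequence condition holds.
    """
    ents = list(entities)
    eset = EntitySet(ents)  # validates uniqueness
    token_seqs = {e.label: e.tokens for e in ents}
    kind: dict[str, str] = {}
    for e in ents:
        if len(e.blocks) == 1:
            kind[e.label] = "domain"
            continue
        mine = token_seqs[e.label]
        if any(
            _is_proper_subsequence(mine, other)
            for lbl, other in token_seqs.items()
            if lbl != e.label
        ):
            kind[e.label] = "supradomain"
        else:
            kind[e.label] = "multidomain"
    eset.kind = kind
    return eset


def component_occurrences(
    container: Architecture, eset: EntitySet
) -> list[tuple[str, int, int]]:
    """Every occurrence of every other entity inside ``container``.

    Returns ``(component label, start, end)`` with 0-based half-open block
    positions.  Matching is exact token-wise (repeat markers distinguish),
    order-sensitive and contiguous; overlapping occurrences are all reported.
    The container itself never matches.
    """
    if len(container.blocks) < 2:
        raise ValueError("container must have at least 2 blocks")
    hay = container.tokens
    seqs, lengths = eset.token_index()
    out: list[tuple[str, int, int]] = []
    for n in lengths:
        if n > len(hay):
            break
        for i in range(len(hay) - n + 1):
            lbl = seqs.get(hay[i : i + n])
            if lbl is not None and lbl != container.label:
                out.append((lbl, i, i + n))
    out.sort(key=lambda t: (t[1], t[2], t[0]))
    return out


def spliced_domains(entities: Iterable[Architecture]) -> set[str]:
    """Union of block tokens over all architectures.

    Includes tokens that never occur as standalone entities; repeat-marked
    tokens stay distinct from their unmarked form.
    """
    toks: set[str] = set()
    for e in entities:
        toks.update(e.tokens)
    return toks


def read_entity_tsv(
    path, *, strict: bool = True
) -> tuple[list[Architecture], dict[str, float]]:
    """Read a two-column ``label<TAB>nd`` table.

    A header row is detected (and skipped) when the second field is not
    numeric; ``#`` comment lines and blank lines are ignored.
    """
    archs: list[Architecture] = []
    ages: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            label, nd_s = parts[0].strip(), parts[1].strip()
            try:
                nd = float(nd_s)
            except ValueError:
                if lineno == 1 or not archs:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-numeric age {nd_s!r}")
            archs.append(parse_ccs(label, strict=strict))
            ages[label] = nd
    return archs, ages


def read_scop_descriptions(path) -> dict[str, str]:
    """Parse a SCOP dir.des file (v1.75 dialect) into sccs → description.

    Columns: sunid, entry type, sccs, sid, description.  Only superfamily
    (``sf``) rows carry FSF-level sccs identifiers usable as node labels.
    """
    desc: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            _, etype, sccs, _, text = parts[:5]
            if etype == "sf":
                desc[sccs] = text
    return desc
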