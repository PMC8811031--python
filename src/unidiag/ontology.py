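"""Five-level ICD-9-CM ontology reconstruction.

The diagnosis coding system is organised as a tree:

    root (level 0)
      └── chapter (level 1)      e.g. 520–579, "Diseases of the digestive system"
            └── section (level 2)    e.g. 550–553, "Hernia of abdominal cavity"
                  └── category (level 3)     e.g. 550
                        └── subcategory (level 4)  e.g. 550.1
                              └── extension (level 5)   e.g. 550.12

The information content (IC) of a code is its level depth, so IC(root) = 0 and
IC(extension) = 5. E-codes (external causes, E800–E999) carry a four-character
category stem and at most one decimal digit, which sits at level 4; V-codes
behave like ordinary numeric codes with a two-digit stem.

Chapter and section ranges are shipped as a packaged table derived from the
standard ICD-9-CM tabular list (19 chapters: 17 disease chapters plus the V
and E supplementary classifications).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Union

EN_DASH = "–"
ROOT_CANONICAL = "ROOT"

_RANGE_KINDS = ("chapter", "section")
_CODE_RE = re.compile(r"([VE]?)(\d+)(\.(\d*))?\Z")
_STEM_RE = re.compile(r"([VE]?)(\d+)\Z")


@dataclass(frozen=True)
class ICD9Code:
    """A node of the reconstructed ontology.

    ``canonical`` is the dotted, zero-padded form ("038.9", "V58.61",
    "E950.0"), a range token for chapters/sections ("520–579"), or the root
    sentinel. ``level`` is the depth from the root (0–5).
    """

    raw: str
    canonical: str
    level: int
    kind: str  # root | chapter | section | category | subcategory | extension

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


ROOT = ICD9Code(raw=ROOT_CANONICAL, canonical=ROOT_CANONICAL, level=0, kind="root")


@dataclass(frozen=True)
class CodeRange:
    kind: str
    start: str  # padded stem, e.g. "001", "V01", "E800"
    end: str
    label: str

    @property
    def token(self) -> str:
        return f"{self.start}{EN_DASH}{self.end}"

    def contains_stem(self, stem: str) -> bool:
        cls_s, lo = _split_stem(self.start)
        cls, val = _split_stem(stem)
        if cls != cls_s:
            return False
        _, hi = _split_stem(self.end)
        return lo <= val <= hi


def _split_stem(stem: str) -> tuple[str, int]:
    m = _STEM_RE.match(stem)
    if m is None:
        raise ValueError(f"malformed ICD-9 category stem: {stem!r}")
    return m.group(1), int(m.group(2))


@lru_cache(maxsize=1)
def load_ranges() -> tuple[tuple[CodeRange, ...], tuple[CodeRange, ...]]:
    """Load the packaged chapter and section range tables."""
    text = (
        resources.files("unidiag").joinpath("data/icd9_ranges.tsv").read_text("utf-8")
    )
    chapters: list[CodeRange] = []
    sections: list[CodeRange] = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        kind, start, end, label = line.split("\t")
        rng = CodeRange(kind=kind, start=start, end=end, label=label)
        (chapters if kind == "chapter" else sections).append(rng)
    return tuple(chapters), tuple(sections)


def chapters() -> tuple[CodeRange, ...]:
    return load_ranges()[0]


def sections() -> tuple[CodeRange, ...]:
    return load_ranges()[1]


def _pad_stem(prefix: str, digits: str) -> str:
    width = {"": 3, "V": 2, "E": 3}[prefix]
    if len(digits) > width:
        raise ValueError(
            f"category part {prefix}{digits!s} exceeds {width} digits"
        )
    return prefix + digits.zfill(width)


def _range_for_token(a: str, b: str) -> CodeRange:
    for table in load_ranges():
        for rng in table:
            if rng.start == a and rng.end == b:
                return rng
    raise ValueError(f"range token {a}-{b} matches no packaged chapter or section")


def canonicalize(raw: Union[str, ICD9Code]) -> ICD9Code:
    """Normalise a source code string into a canonical ontology node.

    Accepts dotted ("038.9") and dotless MIMIC-style ("0389") codes, V- and
    E-codes, chapter/section range tokens with hyphen or en-dash, and the root
    sentinel. Leading zeros are restored ("38.9" → "038.9").
    """
    if isinstance(raw, ICD9Code):
        return raw
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError(f"empty or non-string ICD-9 code: {raw!r}")
    s = raw.strip().upper().replace(EN_DASH, "-")
    if s == ROOT_CANONICAL:
        return ROOT
    if "-" in s:
        parts = s.split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed range token: {raw!r}")
        try:
            a = _pad_stem(*_split_parts(parts[0]))
            b = _pad_stem(*_split_parts(parts[1]))
        except ValueError as exc:
            raise ValueError(f"malformed range token {raw!r}: {exc}") from exc
        rng = _range_for_token(a, b)
        return ICD9Code(
            raw=raw,
            canonical=rng.token,
            level=1 if rng.kind == "chapter" else 2,
            kind=rng.kind,
        )
    m = _CODE_RE.match(s)
    if m is None:
        raise ValueError(f"malformed ICD-9 code: {raw!r}")
    prefix, digits, dot, dec = m.group(1), m.group(2), m.group(3), m.group(4) or ""
    ncat = {"": 3, "V": 2, "E": 3}[prefix]
    max_dec = 1 if prefix == "E" else 2
    if dot is not None:
        if len(digits) > ncat:
            raise ValueError(f"malformed ICD-9 code (category too long): {raw!r}")
        cat = digits.zfill(ncat)
    elif len(digits) <= ncat:
        cat, dec = digits.zfill(ncat), ""
    elif len(digits) <= ncat + max_dec:
        cat, dec = digits[:ncat], digits[ncat:]
    else:
        raise ValueError(f"malformed ICD-9 code (too many digits): {raw!r}")
    if len(dec) > max_dec:
        raise ValueError(f"malformed ICD-9 code (too many decimals): {raw!r}")
    stem = prefix + cat
    if not dec:
        return ICD9Code(raw=raw, canonical=stem, level=3, kind="category")
    level = 3 + len(dec)
    kind = "subcategory" if level == 4 else "extension"
    return ICD9Code(raw=raw, canonical=f"{stem}.{dec}", level=level, kind=kind)


def _split_parts(part: str) -> tuple[str, str]:
    m = _STEM_RE.match(part.strip())
    if m is None:
        raise ValueError(f"malformed range endpoint: {part!r}")
    return m.group(1), m.group(2)


def _section_for(stem: str) -> CodeRange:
    for rng in sections():
        if rng.contains_stem(stem):
            return rng
    raise ValueError(f"no packaged ICD-9-CM section covers category {stem}")


def _chapter_for(stem: str) -> CodeRange:
    for rng in chapters():
        if rng.contains_stem(stem):
            return rng
    raise ValueError(f"category stem {stem} matches no ICD-9-CM chapter range")


def parent_of(code: ICD9Code) -> ICD9Code:
    """The unique parent node, one level up."""
    if code.kind == "root":
        raise ValueError("the root node has no parent")
    if code.kind == "chapter":
        return ROOT
    if code.kind == "section":
        rng = _chapter_for(code.canonical.split(EN_DASH)[0])
        return ICD9Code(raw=rng.token, canonical=rng.token, level=1, kind="chapter")
    if code.kind == "category":
        rng = _section_for(code.canonical)
        chap = _chapter_for(code.canonical)
        if (rng.start, rng.end) == (chap.start, chap.end):
            # chapter without internal sections (e.g. 280–289, 740–759):
            # the section level is skipped rather than duplicating the range
            return ICD9Code(
                raw=chap.token, canonical=chap.token, level=1, kind="chapter"
            )
        return ICD9Code(raw=rng.token, canonical=rng.token, level=2, kind="section")
    stem, dec = code.canonical.split(".")
    if len(dec) == 1:
        return ICD9Code(raw=stem, canonical=stem, level=3, kind="category")
    return ICD9Code(
        raw=f"{stem}.{dec[:-1]}",
        canonical=f"{stem}.{dec[:-1]}",
        level=4,
        kind="subcategory",
    )


class OntologyTree:
    """The reconstructed ontology: nodes plus a child→parent map.

    Only codes actually added (and their ancestors) are materialised; the
    "virtual" sibling padding of the full classification plays no role in
    similarity and is never created.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, ICD9Code] = {ROOT_CANONICAL: ROOT}
        self.parent: dict[str, str] = {}

    def __contains__(self, code: Union[str, ICD9Code]) -> bool:
        try:
            canonical = canonicalize(code).canonical
        except ValueError:
            return False
        return canonical in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def add(self, raw: Union[str, ICD9Code]) -> ICD9Code:
        """Insert a code and all of its ancestors; returns the canonical node."""
        code = canonicalize(raw)
        node = code
        while node.canonical not in self.nodes:
            self.nodes[node.canonical] = node
            if node.kind == "root":
                break
            parent = parent_of(node)
            self.parent[node.canonical] = parent.canonical
            node = parent
        return code

    def resolve(self, code: Union[str, ICD9Code]) -> str:
        canonical = canonicalize(code).canonical
        if canonical not in self.nodes:
            raise KeyError(f"code {canonical!r} is not in the ontology")
        return canonical

    def level(self, code: Union[str, ICD9Code]) -> int:
        return self.nodes[self.resolve(code)].level

    def information_content(self, code: Union[str, ICD9Code]) -> int:
        """IC of a code = its level depth from the root (0–5)."""
        return self.level(code)

    def path_to_root(self, code: Union[str, ICD9Code]) -> list[str]:
        """Canonical node chain from the code itself up to the root."""
        canonical = self.resolve(code)
        chain = [canonical]
        while chain[-1] != ROOT_CANONICAL:
            chain.append(self.parent[chain[-1]])
        return chain

    def lca(self, a: Union[str, ICD9Code], b: Union[str, ICD9Code]) -> ICD9Code:
        """Least common ancestor: deepest node on both root paths."""
        chain_a = self.path_to_root(a)
        on_b = set(self.path_to_root(b))
        for canonical in chain_a:  # chain ascends, first hit is deepest
            if canonical in on_b:
                return self.nodes[canonical]
        return ROOT  # unreachable: root is always shared

    def is_a(self, code: Union[str, ICD9Code], ancestor: Union[str, ICD9Code]) -> bool:
        """True when ``code`` equals ``ancestor`` or descends from it."""
        return canonicalize(ancestor).canonical in self.path_to_root(code)


def build_ontology(code_universe: Iterable[Union[str, ICD9Code]]) -> OntologyTree:
    """Build the tree containing every input code plus its ancestor closure.

    Codes whose category stem falls outside every packaged chapter/section
    range are rejected collectively, listing the offending raw strings.
    """
    tree = OntologyTree()
    bad: list[str] = []
    for raw in code_universe:
        try:
            tree.add(raw)
        except ValueError as exc:
            bad.append(f"{raw!r}: {exc}")
    if bad:
        raise ValueError("unplaceable ICD-9 codes: " + "; ".join(bad))
    return tree


def level(code: Union[str, ICD9Code], tree: OntologyTree) -> int:
    return tree.level(code)


def information_content(code: Union[str, ICD9Code], tree: OntologyTree) -> int:
    return tree.information_content(code)


def lca(a: Union[str, ICD9Code], b: Union[str, ICD9Code], tree: OntologyTree) -> ICD9Code:
    return tree.lca(a, b)
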