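"""Secondary-structure descriptor search.

A descriptor is an ordered 5'->3' list of structural elements — paired
helix arms and single-stranded stretches — that together define a
searchable secondary-structure motif, in the spirit of classic
descriptor-based tools such as RNABOB.  Helices are specified by an arm
length range, a mismatch budget and a pairing alphabet (Watson-Crick
with or without G.U wobble); single strands by an IUPAC pattern or a
variable-length run.  Nesting must be proper (no pseudoknots).

Descriptor grammar (one or more whitespace/newline separated tokens,
``#`` starts a comment)::

    h1(3:3,0)       helix arm, 3 bp exactly, 0 mismatches, wobble allowed
    h2(4:6,1,wc)    4-6 bp, 1 mismatch, strict Watson-Crick (no wobble)
    s1(NNRAU)       single strand, fixed-length IUPAC pattern
    s2(N{0:10})     single strand, 0-10 nt, any base
    h1'             closing (3') arm of helix h1

Matching is a backtracking search over all placements of the elements
as consecutive intervals of the target; a match may start and end
anywhere in the sequence.  Input sequences may be DNA or RNA (T and U
are interchangeable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal

from ._sequtils import IUPAC_RNA, to_rna

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class DescriptorParseError(ValueError):
    pass


@dataclass(frozen=True)
class HelixOpen:
    """5' arm of a helix."""

    name: str
    min_len: int
    max_len: int
    mismatch_budget: int
    allow_wobble: bool = True

    def token(self) -> str:
        wc = "" if self.allow_wobble else ",wc"
        return f"{self.name}({self.min_len}:{self.max_len},{self.mismatch_budget}{wc})"


@dataclass(frozen=True)
class HelixClose:
    """3' arm; pairs with the HelixOpen of the same name."""

    name: str

    def token(self) -> str:
        return f"{self.name}'"


@dataclass(frozen=True)
class SingleStrand:
    """Single-stranded element: fixed IUPAC pattern or variable-length run."""

    name: str
    pattern: str  # IUPAC over RNA codes; for variable elements a single code
    min_len: int
    max_len: int

    @property
    def fixed_length(self) -> bool:
        return self.min_len == self.max_len

    def token(self) -> str:
        if self.min_len == self.max_len and len(self.pattern) == self.min_len:
            return f"{self.name}({self.pattern})"
        return f"{self.name}({self.pattern}{{{self.min_len}:{self.max_len}}})"

    def matches_at(self, seq: str, pos: int, length: int) -> bool:
        if self.fixed_length and len(self.pattern) == length:
            pat = self.pattern
            for i in range(length):
                if seq[pos + i] not in IUPAC_RNA[pat[i]]:
                    return False
            return True
        allowed = IUPAC_RNA[self.pattern]
        return all(seq[pos + i] in allowed for i in range(length))


Element = HelixOpen | HelixClose | SingleStrand


@dataclass(frozen=True)
class Descriptor:
    elements: tuple[Element, ...]
    name: str = "descriptor"

    def element_names(self) -> list[str]:
        return [e.token() if isinstance(e, HelixClose) else e.name for e in self.elements]

    def helix(self, name: str) -> HelixOpen:
        for e in self.elements:
            if isinstance(e, HelixOpen) and e.name == name:
                return e
        raise KeyError(name)

    def single_strand(self, name: str) -> SingleStrand:
        for e in self.elements:
            if isinstance(e, SingleStrand) and e.name == name:
                return e
        raise KeyError(name)

    @property
    def min_span(self) -> int:
        span = 0
        for e in self.elements:
            if isinstance(e, HelixOpen):
                span += 2 * e.min_len
            elif isinstance(e, SingleStrand):
                span += e.min_len
        return span

    def serialize(self) -> str:
        return " ".join(e.token() for e in self.elements)


@dataclass(frozen=True)
class DescriptorMatch:
    """One placement of every descriptor element on a sequence.

    ``intervals`` maps element names (helix 3' arms under "<name>'") to
    0-based half-open intervals; ``substrings`` holds the corresponding
    sequence slices; ``n_mismatches`` the non-pairing positions per helix.
    """

    sequence: str
    intervals: dict[str, tuple[int, int]]
    substrings: dict[str, str]
    n_mismatches: dict[str, int]
    helix_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals.values())

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals.values())

    def sort_key(self) -> tuple:
        total_helix = sum(self.helix_lengths.values())
        flat = tuple(v for k in sorted(self.intervals) for v in self.intervals[k])
        return (self.start, -total_helix, flat)

    def helix_pairs(self, allow_mismatch: bool = False,
                    allow_wobble_lookup: dict[str, bool] | None = None
                    ) -> list[tuple[int, int]]:
        """Base-pair list implied by the matched helices.

        With ``allow_mismatch`` False (default) only positions that
        actually form an allowed pair are returned, so the list can be
        used directly as folding constraints.
        """
        pairs = []
        for name, length in self.helix_lengths.items():
            a5, _ = self.intervals[name]
            a3, _ = self.intervals[name + "'"]
            wob = True if allow_wobble_lookup is None else allow_wobble_lookup[name]
            for i in range(length):
                p, q = a5 + i, a3 + length - 1 - i
                if allow_mismatch or _paired(self.sequence[p], self.sequence[q], wob):
                    pairs.append((p, q))
        return pairs


def _paired(x: str, y: str, allow_wobble: bool) -> bool:
    if (x, y) in WC_PAIRS:
        return True
    return allow_wobble and (x, y) in WOBBLE_PAIRS


# -- parsing -------------------------------------------------------------

_HELIX_RE = re.compile(r"^(h[\w]*)\((\d+):(\d+),(\d+)(,wc)?\)$")
_CLOSE_RE = re.compile(r"^(h[\w]*)'$")
_SS_FIXED_RE = re.compile(r"^(s[\w]*)\(([A-Z]+)\)$")
_SS_VAR_RE = re.compile(r"^(s[\w]*)\(([A-Z])\{(\d+):(\d+)\}\)$")


def parse_descriptor(text: str, name: str = "descriptor") -> Descriptor:
    """Parse descriptor text; round-trips with :meth:`Descriptor.serialize`."""
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if tokens and tokens[0] == "name":
        if len(tokens) < 2:
            raise DescriptorParseError("'name' directive without a value")
        name = tokens[1]
        tokens = tokens[2:]
    if not tokens:
        raise DescriptorParseError("empty descriptor")

    elements: list[Element] = []
    stack: list[str] = []
    seen: set[str] = set()
    for i, tok in enumerate(tokens):
        if m := _CLOSE_RE.match(tok):
            hname = m.group(1)
            if not stack or stack[-1] != hname:
                raise DescriptorParseError(
                    f"token {i + 1} ({tok!r}): closing arm without matching open "
                    f"helix (open stack: {stack})"
                )
            stack.pop()
            elements.append(HelixClose(hname))
        elif m := _HELIX_RE.match(tok):
            hname, lo, hi, mm, wc = m.groups()
            if hname in seen:
                raise DescriptorParseError(f"token {i + 1}: duplicate element {hname!r}")
            lo, hi, mm = int(lo), int(hi), int(mm)
            if hi < lo:
                raise DescriptorParseError(f"token {i + 1} ({tok!r}): max < min length")
            seen.add(hname)
            stack.append(hname)
            elements.append(HelixOpen(hname, lo, hi, mm, allow_wobble=wc is None))
        elif m := _SS_VAR_RE.match(tok):
            sname, code, lo, hi = m.groups()
            _check_code(code, i, tok)
            if sname in seen:
                raise DescriptorParseError(f"token {i + 1}: duplicate element {sname!r}")
            if int(hi) < int(lo):
                raise DescriptorParseError(f"token {i + 1} ({tok!r}): max < min length")
            seen.add(sname)
            elements.append(SingleStrand(sname, code, int(lo), int(hi)))
        elif m := _SS_FIXED_RE.match(tok):
            sname, pat = m.groups()
            pat = to_rna(pat)
            for c in pat:
                _check_code(c, i, tok)
            if sname in seen:
                raise DescriptorParseError(f"token {i + 1}: duplicate element {sname!r}")
            seen.add(sname)
            elements.append(SingleStrand(sname, pat, len(pat), len(pat)))
        else:
            raise DescriptorParseError(f"token {i + 1}: cannot parse {tok!r}")
    if stack:
        raise DescriptorParseError(f"unclosed helices: {stack}")
    return Descriptor(tuple(elements), name=name)


def _check_code(c: str, i: int, tok: str) -> None:
    if to_rna(c) not in IUPAC_RNA:
        raise DescriptorParseError(f"token {i + 1} ({tok!r}): unknown IUPAC code {c!r}")


# -- matching ------------------------------------------------------------

def match_descriptor(
    seq: str, d: Descriptor, mode: Literal["first", "all"] = "first"
) -> list[DescriptorMatch]:
    """Find placements of descriptor ``d`` in ``seq``.

    ``mode="all"`` enumerates every distinct placement (unique interval
    assignment); ``mode="first"`` returns the single deterministic best
    placement under the (leftmost start, longest total helix length,
    smallest interval tuple) order.  A sequence shorter than the
    descriptor's minimum span yields an empty list.
    """
    rna = to_rna(seq)
    if any(c not in "ACGU" for c in rna):
        raise ValueError("sequence must be over {A,C,G,T/U}")
    n = len(rna)
    if n < d.min_span:
        return []

    results: list[DescriptorMatch] = []
    elements = d.elements

    def recurse(idx: int, pos: int, intervals: list[tuple[str, int, int]],
                arm5: dict[str, tuple[int, int]], mism: dict[str, int]) -> None:
        if idx == len(elements):
            iv = {name: (s, e) for name, s, e in intervals}
            subs = {name: rna[s:e] for name, (s, e) in iv.items()}
            hlens = {name: L for name, (_, L) in arm5.items()}
            results.append(
                DescriptorMatch(rna, iv, subs, dict(mism), hlens)
            )
            return
        el = elements[idx]
        if isinstance(el, SingleStrand):
            for L in range(el.min_len, el.max_len + 1):
                if pos + L > n:
                    break
                if el.matches_at(rna, pos, L):
                    intervals.append((el.name, pos, pos + L))
                    recurse(idx + 1, pos + L, intervals, arm5, mism)
                    intervals.pop()
        elif isinstance(el, HelixOpen):
            for L in range(el.min_len, el.max_len + 1):
                if pos + L > n:
                    break
                arm5[el.name] = (pos, L)
                intervals.append((el.name, pos, pos + L))
                recurse(idx + 1, pos + L, intervals, arm5, mism)
                intervals.pop()
                del arm5[el.name]
        else:  # HelixClose
            helix = d.helix(el.name)
            start5, L = arm5[el.name]
            if pos + L > n:
                return
            mm = 0
            for i in range(L):
                if not _paired(rna[start5 + i], rna[pos + L - 1 - i], helix.allow_wobble):
                    mm += 1
                    if mm > helix.mismatch_budget:
                        return
            intervals.append((el.name + "'", pos, pos + L))
            mism[el.name] = mm
            recurse(idx + 1, pos + L, intervals, arm5, mism)
            intervals.pop()
            del mism[el.name]

    for start in range(0, n - d.min_span + 1):
        recurse(0, start, [], {}, {})

    if mode == "all":
        return sorted(results, key=lambda m: m.sort_key())
    if not results:
        return []
    return [min(results, key=lambda m: m.sort_key())]


def extract_element(matches: list[DescriptorMatch], element_name: str) -> list[str]:
    """Matched substring of one element per match, in input order."""
    out = []
    for m in matches:
        if element_name not in m.substrings:
            raise KeyError(f"element {element_name!r} not in match")
        out.append(m.substrings[element_name])
    return out
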