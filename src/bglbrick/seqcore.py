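"""Double-stranded DNA model with restriction digestion and ligation.

The substrate of every cloning operation in this package is a
:class:`DnaSequence`: a linear or circular duplex represented by its top
strand.  Restriction enzymes are described by their recognition hexamer
and the two cut offsets into it (:class:`EnzymeSpec`); digestion produces
:class:`Fragment` objects whose ends carry explicit chemistry (blunt, or a
5'/3' single-stranded overhang), so that ligation compatibility — including
cross-enzyme joins such as BglII/BamHI or AvrII/SpeI — is decided by the
actual annealing rule rather than by enzyme identity.

Conventions
-----------
* Coordinates are 0-based, half-open, on the canonical top strand.
* An enzyme cuts the top strand before ``recognition[cut_top]`` and the
  bottom strand before (in top-strand coordinates) ``recognition[cut_bottom]``.
* Fragments of a digest tile the parent's top strand at the top-strand cut
  positions, so concatenating them in order reconstructs the parent exactly.
* Overhang sequences are read 5'->3' on the protruding strand.  Two ends
  anneal iff they have the same overhang kind and each overhang is the
  reverse complement of the other (for the palindromic enzymes bundled
  here every overhang is self-complementary, so this reduces to string
  equality).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Sequence

__all__ = [
    "AlphabetError",
    "TopologyError",
    "NoCutSiteError",
    "LigationIncompatibleError",
    "Feature",
    "DnaSequence",
    "EnzymeSpec",
    "End",
    "BLUNT",
    "Fragment",
    "SiteHit",
    "ENZYMES",
    "BGLBRICK_ENZYMES",
    "BOUNDARY_ENZYMES",
    "revcomp_str",
    "revcomp",
    "rotate",
    "circular_equal",
    "find_sites",
    "digest",
    "ends_compatible",
    "ligate",
    "circularize",
    "ligate_all",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class AlphabetError(ValueError):
    """A base outside {A, C, G, T} was supplied."""


class TopologyError(ValueError):
    """An operation received a sequence of the wrong topology."""


class NoCutSiteError(ValueError):
    """Digestion was requested but no recognition site is present."""


class LigationIncompatibleError(ValueError):
    """Two fragment ends cannot anneal; carries a structured report."""

    def __init__(self, end_a: "End", end_b: "End"):
        self.end_a = end_a
        self.end_b = end_b
        super().__init__(
            f"incompatible ends: {end_a.describe()} cannot join {end_b.describe()}"
        )

    @property
    def report(self) -> dict:
        return {"end_a": self.end_a.describe(), "end_b": self.end_b.describe()}


def _canonical(bases: str) -> str:
    up = bases.upper()
    for i, b in enumerate(up):
        if b not in _VALID:
            raise AlphabetError(f"non-ACGT character {b!r} at position {i}")
    return up


def revcomp_str(bases: str) -> str:
    """Reverse complement of a raw string (validated, canonicalized)."""
    return _canonical(bases).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotation on a sequence; 0-based half-open, may wrap the origin."""

    label: str
    start: int
    end: int
    strand: int = 1


@dataclass(frozen=True)
class DnaSequence:
    """A DNA duplex given by its top strand, linear or circular."""

    bases: str
    circular: bool = False
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if not self.bases:
            raise AlphabetError("empty sequence")
        object.__setattr__(self, "bases", _canonical(self.bases))
        object.__setattr__(self, "features", tuple(self.features))
        n = len(self.bases)
        for f in self.features:
            if not (0 <= f.start < n and 0 <= f.end <= n):
                raise ValueError(f"feature {f.label!r} outside [0, {n})")
            if not self.circular and f.end < f.start:
                raise ValueError(f"feature {f.label!r} wraps a linear sequence")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def topology(self) -> str:
        return "circular" if self.circular else "linear"

    def feature_seq(self, f: Feature) -> str:
        if f.end >= f.start:
            s = self.bases[f.start : f.end]
        else:  # wraps the circular origin
            s = self.bases[f.start :] + self.bases[: f.end]
        return s if f.strand >= 0 else revcomp_str(s)


def revcomp(seq: DnaSequence) -> DnaSequence:
    """Reverse complement; involution, preserves length and topology."""
    n = len(seq)
    feats = tuple(
        Feature(f.label, (n - f.end) % n if seq.circular else n - f.end,
                (n - f.start) % n if seq.circular else n - f.start, -f.strand)
        for f in seq.features
    )
    return DnaSequence(seq.bases.translate(_COMPLEMENT)[::-1], seq.circular, feats)


def rotate(seq: DnaSequence, k: int) -> DnaSequence:
    """Rotate a circular sequence so old position k becomes position 0."""
    if not seq.circular:
        raise TopologyError("rotate requires a circular sequence")
    n = len(seq)
    k %= n
    feats = tuple(
        Feature(f.label, (f.start - k) % n, (f.end - k) % n, f.strand)
        for f in seq.features
    )
    return DnaSequence(seq.bases[k:] + seq.bases[:k], True, feats)


def circular_equal(a: DnaSequence, b: DnaSequence) -> bool:
    """True iff b is a rotation of a or of revcomp(a).  Circular only."""
    if not (a.circular and b.circular):
        raise TopologyError("circular_equal requires two circular sequences")
    if len(a) != len(b):
        return False
    doubled = a.bases + a.bases
    return b.bases in doubled or revcomp_str(b.bases) in doubled


# ---------------------------------------------------------------------------
# Enzymes


@dataclass(frozen=True)
class EnzymeSpec:
    """A palindromic type IIP enzyme: 6-bp recognition plus cut offsets."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _canonical(self.recognition))
        if len(self.recognition) != 6:
            raise ValueError(f"{self.name}: recognition must be a hexamer")
        if not (0 <= self.cut_top <= 6 and 0 <= self.cut_bottom <= 6):
            raise ValueError(f"{self.name}: cut offsets must lie in [0, 6]")

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_kind(self) -> Literal["five_prime", "three_prime", "blunt"]:
        if self.cut_top < self.cut_bottom:
            return "five_prime"
        if self.cut_top > self.cut_bottom:
            return "three_prime"
        return "blunt"

    @property
    def overhang_seq(self) -> str:
        """Protruding strand produced by this enzyme, 5'->3' (top-strand text)."""
        lo, hi = sorted((self.cut_top, self.cut_bottom))
        return self.recognition[lo:hi]


def _load_enzymes() -> dict[str, EnzymeSpec]:
    table: dict[str, EnzymeSpec] = {}
    text = (resources.files("bglbrick.data") / "enzymes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rec, ct, cb = line.split("\t")
        table[name] = EnzymeSpec(name, rec, int(ct), int(cb))
    return table


#: The eight bundled enzymes of the pBb platform, keyed by name.
ENZYMES: dict[str, EnzymeSpec] = _load_enzymes()

#: The four assembly-standard enzymes (forbidden inside parts).
BGLBRICK_ENZYMES = tuple(ENZYMES[n] for n in ("EcoRI", "BglII", "BamHI", "XhoI"))

#: The three module-boundary enzymes of the pBb vector architecture.
BOUNDARY_ENZYMES = tuple(ENZYMES[n] for n in ("AatII", "AvrII", "SacI"))


# ---------------------------------------------------------------------------
# Site scanning


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence on the canonical top strand."""

    enzyme: str
    position: int  # 0-based start of the recognition hexamer
    wraps_origin: bool = False

    @property
    def end(self) -> int:
        return self.position + 6


def find_sites(
    seq: DnaSequence, enzymes: Iterable[EnzymeSpec] | EnzymeSpec
) -> list[SiteHit]:
    """Every recognition-site occurrence, sorted by position.

    Circular sequences are scanned across the origin; a site straddling
    index 0 is reported once, at its (wrapping) start position.  The
    bundled enzymes are palindromic, so top-strand hits are the complete
    answer.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    n = len(seq)
    text = seq.bases + (seq.bases[:5] if seq.circular else "")
    hits: list[SiteHit] = []
    for enz in enzymes:
        start = 0
        while True:
            p = text.find(enz.recognition, start)
            if p == -1 or p >= n:
                break
            hits.append(SiteHit(enz.name, p, wraps_origin=p + 6 > n))
            start = p + 1
    hits.sort(key=lambda h: (h.position, h.enzyme))
    return hits


# ---------------------------------------------------------------------------
# Fragments and digestion


@dataclass(frozen=True)
class End:
    """One terminus of a fragment.

    ``overhang`` is the protruding single strand read 5'->3'; empty for a
    blunt end.
    """

    kind: Literal["blunt", "five_prime", "three_prime"]
    overhang: str = ""

    def describe(self) -> str:
        if self.kind == "blunt":
            return "blunt"
        tick = "5'" if self.kind == "five_prime" else "3'"
        return f"{tick} overhang {self.overhang}"


BLUNT = End("blunt")


@dataclass(frozen=True)
class Fragment:
    """A digestion product: top-strand text plus typed ends.

    ``bases`` spans from this fragment's left top-strand cut to its right
    top-strand cut, so the fragments of a digest concatenate back to the
    parent top strand.
    """

    bases: str
    left_end: End = BLUNT
    right_end: End = BLUNT

    def __len__(self) -> int:
        return len(self.bases)


def flip(frag: Fragment) -> Fragment:
    """The same molecule read from the other strand."""
    return Fragment(revcomp_str(frag.bases), frag.right_end, frag.left_end)


def _junction_ends(enz: EnzymeSpec, overhang_top: str) -> tuple[End, End]:
    """(right end of left fragment, left end of right fragment) at a cut.

    ``overhang_top`` is the overhang region as written on the top strand.
    """
    if enz.overhang_kind == "blunt":
        return BLUNT, BLUNT
    if enz.overhang_kind == "five_prime":
        # top strand protrudes on the RIGHT fragment; bottom on the left
        return End("five_prime", revcomp_str(overhang_top)), End(
            "five_prime", overhang_top
        )
    # three_prime: top strand protrudes on the LEFT fragment
    return End("three_prime", overhang_top), End(
        "three_prime", revcomp_str(overhang_top)
    )


def digest(
    seq: DnaSequence, enzymes: Iterable[EnzymeSpec] | EnzymeSpec
) -> list[Fragment]:
    """Cut at every site of the given enzymes.

    A circular sequence with n cut positions yields n fragments (the first
    starting at the first cut); a linear one yields n+1 with blunt outer
    ends.  Raises :class:`NoCutSiteError` when no site is present.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    enzymes = list(enzymes)
    by_name = {e.name: e for e in enzymes}
    hits = find_sites(seq, enzymes)
    if not hits:
        raise NoCutSiteError(
            f"no site for {{{', '.join(sorted(by_name))}}} in {len(seq)} bp sequence"
        )
    n = len(seq)
    doubled = seq.bases + seq.bases
    # (top-strand cut position, junction end pair)
    cuts: list[tuple[int, End, End]] = []
    for h in hits:
        enz = by_name[h.enzyme]
        lo, hi = sorted((enz.cut_top, enz.cut_bottom))
        overhang_top = doubled[h.position + lo : h.position + hi]
        left_e, right_e = _junction_ends(enz, overhang_top)
        pos = h.position + enz.cut_top
        cuts.append((pos % n if seq.circular else pos, left_e, right_e))
    cuts.sort(key=lambda c: c[0])

    frags: list[Fragment] = []
    if seq.circular:
        for (pos_a, _, right_e_a), (pos_b, left_e_b, _) in zip(
            cuts, cuts[1:] + cuts[:1]
        ):
            if pos_b > pos_a:
                core = seq.bases[pos_a:pos_b]
            else:  # wraps the origin (also the single-cut case)
                core = seq.bases[pos_a:] + seq.bases[:pos_b]
            frags.append(Fragment(core, right_e_a, left_e_b))
    else:
        positions = [0] + [c[0] for c in cuts] + [n]
        left_ends = [BLUNT] + [c[2] for c in cuts]
        right_ends = [c[1] for c in cuts] + [BLUNT]
        for i in range(len(cuts) + 1):
            frags.append(
                Fragment(
                    seq.bases[positions[i] : positions[i + 1]],
                    left_ends[i],
                    right_ends[i],
                )
            )
    return frags


# ---------------------------------------------------------------------------
# Ligation


def ends_compatible(a: End, b: End) -> bool:
    """True iff the two ends can anneal and be sealed.

    Blunt joins blunt; cohesive ends join when the overhang kinds match and
    the protruding strands are mutual reverse complements (base pairing in
    antiparallel orientation).
    """
    if a.kind == "blunt" and b.kind == "blunt":
        return True
    return a.kind == b.kind and a.overhang == revcomp_str(b.overhang)


def ligate(a: Fragment, b: Fragment) -> Fragment:
    """Join a's right end to b's left end into one linear fragment.

    Raises :class:`LigationIncompatibleError` (with a structured report of
    both overhangs) when the chemistry does not match.
    """
    if not ends_compatible(a.right_end, b.left_end):
        raise LigationIncompatibleError(a.right_end, b.left_end)
    return Fragment(a.bases + b.bases, a.left_end, b.right_end)


def circularize(frag: Fragment) -> DnaSequence:
    """Seal a fragment's own two ends into a circular sequence."""
    if not ends_compatible(frag.right_end, frag.left_end):
        raise LigationIncompatibleError(frag.right_end, frag.left_end)
    return DnaSequence(frag.bases, circular=True)


def ligate_all(frags: Sequence[Fragment], circular: bool = True) -> DnaSequence:
    """Ligate fragments in the given order; optionally seal into a circle."""
    joined = frags[0]
    for nxt in frags[1:]:
        joined = ligate(joined, nxt)
    if circular:
        return circularize(joined)
    if not (joined.left_end.kind == "blunt" and joined.right_end.kind == "blunt"):
        # linear products keep their cohesive termini; expose as-is
        pass
    return DnaSequence(joined.bases, circular=False)
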