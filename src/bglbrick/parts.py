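"""The BglBrick assembly standard: parts, validation, idempotent composition.

A BglBrick part is an insert free of the four standard sites (EcoRI, BglII,
BamHI, XhoI), carried between a prefix holding EcoRI then BglII and a suffix
holding BamHI then XhoI.  Joining two parts cuts the upstream construct at
BamHI/XhoI and the downstream part at BglII/XhoI; the BamHI and BglII ends
share the 5' "GATC" overhang and fuse into the 6-bp scar GGATCT, which
neither parent enzyme recuts — so every composite is again a valid part and
assembly can iterate indefinitely.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import (
    BGLBRICK_ENZYMES,
    ENZYMES,
    DnaSequence,
    SiteHit,
    find_sites,
)

__all__ = [
    "SCAR",
    "SCAR_TRANSLATION",
    "FlankConfig",
    "DEFAULT_FLANKS",
    "PartValidationError",
    "ValidationReport",
    "BglBrickPart",
    "validate_part",
    "make_part",
    "assemble",
]

#: Junction left by a BamHI/BglII ligation (upstream BamHI half G +
#: downstream BglII half GATCT); cut by neither enzyme.
SCAR = "GGATCT"

#: In-frame translation of the scar under the standard genetic code.
#: Follows from the junction chemistry (GGA-TCT reads Gly-Ser in frame 0);
#: exposed for ORF fusions but not asserted for out-of-frame junctions.
SCAR_TRANSLATION = "GS"

_FORBIDDEN = {e.name: e.recognition for e in BGLBRICK_ENZYMES}


@dataclass(frozen=True)
class FlankConfig:
    """Prefix/suffix carried around every part.

    The defaults use a 3-bp "AAA" spacer between the paired enzyme sites,
    the geometry evidenced by the construction primer tails of the pBb
    vector set; exact alternative flanks (e.g. a registry-standard prefix)
    can be supplied instead.
    """

    prefix: str = "GAATTCAAAAGATCT"  # EcoRI aaa BglII
    suffix: str = "GGATCCAAACTCGAG"  # BamHI aaa XhoI

    def __post_init__(self) -> None:
        for text, first, second, label in (
            (self.prefix, "EcoRI", "BglII", "prefix"),
            (self.suffix, "BamHI", "XhoI", "suffix"),
        ):
            hits = find_sites(DnaSequence(text), BGLBRICK_ENZYMES)
            names = [h.enzyme for h in hits]
            if names != [first, second]:
                raise ValueError(
                    f"{label} must contain exactly one {first} then one "
                    f"{second} site; found {names}"
                )


DEFAULT_FLANKS = FlankConfig()


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a part check: all forbidden hits, split by region."""

    insert_hits: tuple[SiteHit, ...]
    flank_hits: tuple[SiteHit, ...]
    flank_structure_ok: bool

    @property
    def valid(self) -> bool:
        return not self.insert_hits and self.flank_structure_ok


class PartValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(f"part validation failed: {report}")


@dataclass(frozen=True)
class BglBrickPart:
    """prefix + insert + suffix; the unit of idempotent assembly."""

    insert: DnaSequence
    flanks: FlankConfig = DEFAULT_FLANKS

    def __post_init__(self) -> None:
        if self.insert.circular:
            raise ValueError("part insert must be linear")
        # check the assembled context, not just the insert: a site can also
        # arise across the flank/insert boundary (e.g. ...AGATCT + CGAG...
        # forms CTCGAG), and such a part would not survive assembly
        report = validate_part(
            DnaSequence(self.flanks.prefix + self.insert.bases + self.flanks.suffix),
            self.flanks,
        )
        if not report.valid:
            raise PartValidationError(report)

    @property
    def full_sequence(self) -> DnaSequence:
        return DnaSequence(
            self.flanks.prefix + self.insert.bases + self.flanks.suffix
        )


def validate_part(
    seq: DnaSequence, flanks: FlankConfig = DEFAULT_FLANKS
) -> ValidationReport:
    """Check a full part sequence (or bare insert) against the standard.

    Every hit of the four standard enzymes is reported.  When the sequence
    carries the given flanks, the expected four flank sites are separated
    from internal (insert-region) hits and the part is valid iff the insert
    region is clean; a bare insert is valid iff it has no hits at all (its
    flank structure is then vacuously absent and reported as such).
    """
    hits = find_sites(seq, BGLBRICK_ENZYMES)
    p, s = flanks.prefix, flanks.suffix
    has_flanks = (
        len(seq) >= len(p) + len(s)
        and seq.bases.startswith(p)
        and seq.bases.endswith(s)
    )
    if not has_flanks:
        return ValidationReport(tuple(hits), (), flank_structure_ok=not hits)
    lo, hi = len(p), len(seq) - len(s)
    flank_hits = tuple(h for h in hits if h.end <= lo or h.position >= hi)
    insert_hits = tuple(h for h in hits if lo < h.end and h.position < hi)
    structure_ok = [h.enzyme for h in flank_hits] == ["EcoRI", "BglII", "BamHI", "XhoI"]
    return ValidationReport(insert_hits, flank_hits, structure_ok)


def make_part(
    insert: DnaSequence, flanks: FlankConfig = DEFAULT_FLANKS
) -> BglBrickPart:
    """Wrap an insert in standard flanks, refusing internal forbidden sites."""
    return BglBrickPart(insert, flanks)


def assemble(upstream: BglBrickPart, downstream: BglBrickPart) -> BglBrickPart:
    """Compose two parts; the junction is the GGATCT scar.

    Models the standard reaction: the upstream construct opened at
    BamHI/XhoI receives the downstream part's BglII/XhoI fragment; the
    BamHI and BglII 5'-GATC ends seal into the scar, and the flanks of the
    result are inherited from the upstream part.  The composite insert is
    ``upstream.insert + GGATCT + downstream.insert`` and is itself a valid
    part.
    """
    joined = DnaSequence(
        upstream.insert.bases + SCAR + downstream.insert.bases
    )
    return BglBrickPart(joined, upstream.flanks)
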