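"""The pBb vector architecture: modules, nomenclature, combinatorial builds.

A pBb vector is a circle of three modules separated by unique boundary
sites — expression (AatII -> AvrII), replication origin (AvrII -> SacI),
antibiotic marker (SacI -> AatII) — so any module can be exchanged with a
single digest/ligate cycle while the other two remain untouched.  The
expression module carries repressor + promoter, then the BglBrick cassette
(5'-UTR + gene between the unique BglII and BamHI sites), then a
terminator.  Vector names follow the pBb grammar:

    pBb <origin letter> <promoter digit> <marker letter> - <payload label>

e.g. ``pBbE5a-RFP`` = ColE1 origin, PlacUV5 promoter, ampicillin marker,
carrying RFP.

The original parent-plasmid sequences are not bundled; module payloads
default to synthetic, deterministic, restriction-clean placeholder
sequences of realistic length (clearly labeled as such), and real payloads
read from GenBank drop into the same catalogs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Literal, Optional

import numpy as np

from . import synthdata
from .parts import SCAR, BglBrickPart
from .seqcore import (
    BGLBRICK_ENZYMES,
    ENZYMES,
    DnaSequence,
    Fragment,
    circular_equal,
    circularize,
    digest,
    find_sites,
    ligate,
    rotate,
)

__all__ = [
    "ORIGIN_CODES",
    "MARKER_CODES",
    "PromoterSystem",
    "default_promoter_catalog",
    "VectorName",
    "format_name",
    "parse_name",
    "parse_name_set",
    "VectorModule",
    "ModuleCatalog",
    "synthetic_catalog",
    "PbbVector",
    "assemble_vector",
    "build_library",
    "ar_ori_combinations",
    "swap_module",
    "insert_gene",
    "install_origin_avrii_spei",
]

#: Replication-origin letter codes (pSC101** is the site-removed, copy-up
#: derivative used as the canonical low-copy origin).
ORIGIN_CODES = {"E": "ColE1", "A": "p15A", "S": "pSC101**", "B": "pBBR1"}

#: Antibiotic-marker letter codes.
MARKER_CODES = {"a": "ampicillin", "c": "chloramphenicol", "k": "kanamycin"}

_SLOT_BOUNDARIES = {
    "expression": ("AatII", "AvrII"),
    "origin": ("AvrII", "SacI"),
    "marker": ("SacI", "AatII"),
}


@dataclass(frozen=True)
class PromoterSystem:
    name: str
    repressor: str
    inducer: str


def default_promoter_catalog() -> dict[int, PromoterSystem]:
    """Promoter digit -> inducible system.

    Codes 2, 3/4, 5 and 8 are fixed by the platform's published usage
    (Ptet, the two PprpB variants, PlacUV5, PBAD); the assignment of 1, 6,
    7 among the remaining IPTG systems (Ptrc, PLlacO-1, PT7) and the 3-vs-4
    order of the propionate variants are catalog defaults and may be
    overridden in configuration.
    """
    return {
        1: PromoterSystem("Ptrc", "LacIq", "IPTG"),
        2: PromoterSystem("Ptet", "TetR", "aTc"),
        3: PromoterSystem("PprpB(S)", "PrpR", "propionate"),
        4: PromoterSystem("PprpB(E)", "PrpR", "propionate"),
        5: PromoterSystem("PlacUV5", "LacIq", "IPTG"),
        6: PromoterSystem("PLlacO-1", "LacIq", "IPTG"),
        7: PromoterSystem("PT7", "LacIq", "IPTG"),
        8: PromoterSystem("PBAD", "AraC", "arabinose"),
    }


# ---------------------------------------------------------------------------
# Nomenclature


class NameError_(ValueError):
    """Malformed or unresolvable pBb vector name."""


@dataclass(frozen=True)
class VectorName:
    origin_code: str
    promoter_code: int
    marker_code: str
    payload_label: str

    def __post_init__(self) -> None:
        if self.origin_code not in ORIGIN_CODES:
            raise NameError_(f"unknown origin code {self.origin_code!r}")
        if self.promoter_code not in range(1, 9):
            raise NameError_(f"unknown promoter code {self.promoter_code!r}")
        if self.marker_code not in MARKER_CODES:
            raise NameError_(f"unknown marker code {self.marker_code!r}")


def format_name(name: VectorName) -> str:
    return (
        f"pBb{name.origin_code}{name.promoter_code}{name.marker_code}"
        f"-{name.payload_label}"
    )


_NAME_RE = re.compile(r"^pBb([A-Z])(\d)([a-z])-(.+)$")
_SET_RE = re.compile(r"^pBb\{([^}]+)\}(\d)([a-z])-(.+)$")


def parse_name(name: str) -> VectorName:
    """Parse a single pBb name; raises with the failing position."""
    m = _NAME_RE.match(name)
    if not m:
        for i, (c, pat) in enumerate(zip(name, "pBb")):
            if c != pat:
                raise NameError_(f"malformed name {name!r} at position {i}")
        raise NameError_(f"malformed name {name!r} (expected pBb<O><P><m>-<label>)")
    o, p, mk, label = m.groups()
    return VectorName(o, int(p), mk, label)


def parse_name_set(name: str) -> list[VectorName]:
    """Expand set notation like ``pBb{A, E, or S}3a-rfp``; single names pass."""
    m = _SET_RE.match(name)
    if not m:
        return [parse_name(name)]
    letters = re.findall(r"[A-Z]", m.group(1))
    return [
        VectorName(o, int(m.group(2)), m.group(3), m.group(4)) for o in letters
    ]


# ---------------------------------------------------------------------------
# Modules and catalogs


class ModulePayloadError(ValueError):
    """A module payload violates boundary- or standard-site uniqueness."""


@dataclass(frozen=True)
class VectorModule:
    """One of the three module slots, with its payload between boundaries."""

    kind: Literal["expression", "origin", "marker"]
    label: str
    payload: DnaSequence

    def __post_init__(self) -> None:
        if self.payload.circular:
            raise ModulePayloadError(f"{self.label}: payload must be linear")
        boundary = [ENZYMES[n] for n in ("AatII", "AvrII", "SacI")]
        hits = find_sites(self.payload, boundary + list(BGLBRICK_ENZYMES))
        if self.kind == "expression":
            names = sorted(h.enzyme for h in hits)
            if names != ["BamHI", "BglII", "EcoRI", "XhoI"]:
                raise ModulePayloadError(
                    f"{self.label}: expression payload must contain exactly the "
                    f"BglBrick cassette sites once each; found {names}"
                )
            order = [h.enzyme for h in sorted(hits, key=lambda h: h.position)]
            if order != ["EcoRI", "BglII", "BamHI", "XhoI"]:
                raise ModulePayloadError(
                    f"{self.label}: cassette sites out of order: {order}"
                )
        elif hits:
            raise ModulePayloadError(
                f"{self.label}: payload contains forbidden sites "
                f"{[(h.enzyme, h.position) for h in hits]}"
            )

    @property
    def boundaries(self) -> tuple[str, str]:
        return _SLOT_BOUNDARIES[self.kind]


def _expression_payload(
    promoter_region: str, utr_gene: str, terminator: str
) -> str:
    """repressor+promoter, BglBrick cassette with 'AAA' spacers, terminator."""
    return (
        promoter_region
        + "GAATTC" + "AAA" + "AGATCT"
        + utr_gene
        + "GGATCC" + "AAA" + "CTCGAG"
        + terminator
    )


@dataclass(frozen=True)
class ModuleCatalog:
    """Payloads for every origin, promoter system, and marker code."""

    origins: dict[str, VectorModule]
    expressions: dict[int, VectorModule]
    markers: dict[str, VectorModule]
    promoters: dict[int, PromoterSystem]
    gene_label: str = "rfp"


@lru_cache(maxsize=4)
def synthetic_catalog(seed: int = 2011, gene_label: str = "rfp") -> ModuleCatalog:
    """Deterministic placeholder catalogs (synthetic payload sequences).

    Payload lengths are realistic for the platform (origins ~1-2 kb,
    markers ~1 kb, expression modules ~1.7 kb); every payload is free of
    all eight bundled recognition sites outside the expression cassette.
    Real payloads imported from GenBank can replace any entry.
    """
    rng = np.random.default_rng(seed)
    promoters = default_promoter_catalog()
    origins = {}
    for code, name in ORIGIN_CODES.items():
        length = {"E": 900, "A": 1100, "S": 1600, "B": 1300}[code]
        origins[code] = VectorModule(
            "origin", f"{name} (synthetic placeholder)",
            DnaSequence(synthdata.random_clean_seq(length, rng)),
        )
    markers = {}
    for code, name in MARKER_CODES.items():
        markers[code] = VectorModule(
            "marker", f"{name} resistance (synthetic placeholder)",
            DnaSequence(synthdata.random_clean_seq(950, rng)),
        )
    expressions = {}
    for code, system in promoters.items():
        promoter_region = synthdata.random_clean_seq(900, rng)
        utr_gene = "TTTAAGAAGGAGATATACAT" + synthdata.random_clean_seq(680, rng)
        terminator = synthdata.random_clean_seq(130, rng)
        expressions[code] = VectorModule(
            "expression",
            f"{system.name}/{system.repressor} {gene_label} (synthetic placeholder)",
            DnaSequence(_expression_payload(promoter_region, utr_gene, terminator)),
        )
    return ModuleCatalog(origins, expressions, markers, promoters, gene_label)


# ---------------------------------------------------------------------------
# Vectors


@dataclass(frozen=True)
class PbbVector:
    """A circular pBb plasmid plus its parsed name."""

    seq: DnaSequence
    name: VectorName

    def __post_init__(self) -> None:
        if not self.seq.circular:
            raise ModulePayloadError("pBb vector must be circular")
        for enz_name in ("AatII", "AvrII", "SacI", "BglII", "BamHI"):
            hits = find_sites(self.seq, ENZYMES[enz_name])
            if len(hits) != 1:
                raise ModulePayloadError(
                    f"{format_name(self.name)}: expected exactly one "
                    f"{enz_name} site, found {len(hits)}"
                )

    def __str__(self) -> str:
        return format_name(self.name)

    def site_position(self, enzyme: str) -> int:
        return find_sites(self.seq, ENZYMES[enzyme])[0].position

    def module_span(self, kind: str) -> tuple[int, int]:
        """[start, end) of a module's payload (between boundary hexamers)."""
        a, b = _SLOT_BOUNDARIES[kind]
        return (self.site_position(a) + 6) % len(self.seq), self.site_position(b)

    def module_payload(self, kind: str) -> str:
        start, end = self.module_span(kind)
        doubled = self.seq.bases * 2
        if end < start:
            end += len(self.seq)
        return doubled[start:end]


def assemble_vector(
    expression: VectorModule,
    origin: VectorModule,
    marker: VectorModule,
    name: VectorName,
) -> PbbVector:
    """Compose the three modules around their boundary sites."""
    seq = DnaSequence(
        ENZYMES["AatII"].recognition + expression.payload.bases
        + ENZYMES["AvrII"].recognition + origin.payload.bases
        + ENZYMES["SacI"].recognition + marker.payload.bases,
        circular=True,
    )
    return PbbVector(seq, name)


def build_library(
    origins: Iterable[str] = "EASB",
    promoters: Iterable[int] = range(1, 9),
    markers: Iterable[str] = "ack",
    catalog: Optional[ModuleCatalog] = None,
) -> list[PbbVector]:
    """Every origin x promoter x marker combination, named per the grammar."""
    cat = catalog or synthetic_catalog()
    vectors = []
    for o in origins:
        for p in promoters:
            for m in markers:
                vectors.append(
                    assemble_vector(
                        cat.expressions[p], cat.origins[o], cat.markers[m],
                        VectorName(o, p, m, cat.gene_label),
                    )
                )
    return vectors


def ar_ori_combinations(
    origins: Iterable[str] = "EASB",
    markers: Iterable[str] = "ack",
) -> list[tuple[str, str]]:
    """The antibiotic-resistance x origin intermediates (12 by default)."""
    return [(o, m) for o in origins for m in markers]


# ---------------------------------------------------------------------------
# Module surgery (digest + ligate)


def _module_fragment(module: VectorModule) -> Fragment:
    """The ligatable fragment of a module, cut at both boundary enzymes."""
    enz_a, enz_b = (ENZYMES[n] for n in module.boundaries)
    lin = DnaSequence(
        enz_a.recognition + module.payload.bases + enz_b.recognition
    )
    frags = digest(lin, [enz_a, enz_b])
    assert len(frags) == 3
    return frags[1]


def swap_module(
    vector: PbbVector,
    new_module: VectorModule,
    code: str | int | None = None,
) -> PbbVector:
    """Exchange one module by digestion at its two boundary sites.

    The vector is digested with the slot's boundary enzymes (each site
    unique, giving two fragments); the backbone — recognized as the
    fragment still carrying the third boundary site — is ligated to the
    new module's fragment and recircularized.  The other two modules are
    untouched.  ``code`` (an origin/marker letter or promoter digit)
    updates the corresponding name component.
    """
    enz_a_name, enz_b_name = new_module.boundaries
    enz_a, enz_b = ENZYMES[enz_a_name], ENZYMES[enz_b_name]
    third = ({"AatII", "AvrII", "SacI"} - {enz_a_name, enz_b_name}).pop()
    frags = digest(vector.seq, [enz_a, enz_b])
    if len(frags) != 2:
        raise ModulePayloadError(
            f"expected 2 fragments from boundary digest, got {len(frags)}"
        )
    backbone = [
        f for f in frags
        if find_sites(DnaSequence(f.bases), ENZYMES[third])
    ]
    if len(backbone) != 1:
        raise ModulePayloadError("backbone fragment not uniquely identifiable")
    new_seq = circularize(ligate(backbone[0], _module_fragment(new_module)))
    name = vector.name
    if code is not None:
        field_name = {
            "origin": "origin_code",
            "expression": "promoter_code",
            "marker": "marker_code",
        }[new_module.kind]
        name = replace(name, **{field_name: code})
    return PbbVector(new_seq, name)


def insert_gene(
    vector: PbbVector, part: BglBrickPart, payload_label: str
) -> PbbVector:
    """Replace the BglII-BamHI cassette payload with a BglBrick insert.

    Models cutting the vector at its unique BglII and BamHI sites and
    ligating in the matching fragment of the part (both junctions are
    native GATC joins, so the sites are regenerated).
    """
    n = len(vector.seq)
    bgl = vector.site_position("BglII")
    bam = vector.site_position("BamHI")
    # rotate so the BglII recognition starts at 0 and the cassette is contiguous
    rot = rotate(vector.seq, bgl)
    bam_rot = (bam - bgl) % n
    new_bases = rot.bases[:6] + part.insert.bases + rot.bases[bam_rot:]
    return PbbVector(
        DnaSequence(new_bases, circular=True),
        replace(vector.name, payload_label=payload_label),
    )


def install_origin_avrii_spei(
    vector: PbbVector, origin_fragment: Fragment
) -> tuple[DnaSequence, dict]:
    """Install an AvrII/SpeI-cut origin product at the vector's AvrII site.

    Mirrors the broad-host-range origin construction: a PCR product with a
    5' AvrII tail and a 3' SpeI tail is digested with both enzymes and
    ligated into the backbone opened at its single AvrII site.  The two 5'
    CTAG overhangs are cross-compatible, so the AvrII/AvrII junction
    regenerates CCTAGG while the SpeI/AvrII junction yields a hybrid scar
    cut by neither enzyme.  Returns the new circle and a junction report.
    """
    backbone = digest(vector.seq, ENZYMES["AvrII"])
    assert len(backbone) == 1
    new_seq = circularize(ligate(origin_fragment, backbone[0]))
    avrii_after = find_sites(new_seq, ENZYMES["AvrII"])
    spei_after = find_sites(new_seq, ENZYMES["SpeI"])
    report = {
        "avrii_sites": len(avrii_after),
        "spei_sites": len(spei_after),
    }
    return new_seq, report
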