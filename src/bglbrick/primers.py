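"""Primer design and PCR simulation for vector construction.

Covers the three PCR idioms used to build the pBb vector set: tailed
amplification (non-annealing 5' additions introduce new restriction
sites), QuikChange-style mutagenic pairs (mutual reverse complements with
the point mutation near the center), and splice-overlap-extension (SOE)
fusion of two or more segments, optionally planting a mutation in the
overlap.  All simulation is exact sequence algebra: a primer anneals where
its 3' region matches the template exactly and uniquely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqcore import (
    BGLBRICK_ENZYMES,
    DnaSequence,
    find_sites,
    revcomp_str,
)

__all__ = [
    "Primer",
    "SpecificityError",
    "simulate_pcr",
    "design_mutagenic_pair",
    "simulate_mutagenesis",
    "SoeStep",
    "SoePlan",
    "design_soe_fusion",
    "simulate_soe",
    "tm",
]

MIN_ANNEAL = 15


class SpecificityError(ValueError):
    """A primer anneals at zero or multiple loci."""

    def __init__(self, message: str, loci: list[int]):
        self.loci = loci
        super().__init__(message)


@dataclass(frozen=True)
class Primer:
    """bases = tail + anneal, written 5'->3'."""

    name: str
    tail: str
    anneal: str

    def __post_init__(self) -> None:
        if len(self.anneal) < MIN_ANNEAL:
            raise ValueError(
                f"{self.name}: anneal region must be >= {MIN_ANNEAL} nt"
            )
        object.__setattr__(self, "tail", self.tail.upper())
        object.__setattr__(self, "anneal", self.anneal.upper())

    @property
    def bases(self) -> str:
        return self.tail + self.anneal

    @property
    def tm_anneal(self) -> float:
        return tm(self.anneal)


def _occurrences(text: str, pattern: str, length: int, circular: bool) -> list[int]:
    """Start positions (mod length for circular templates), each site once."""
    hay = text + (text[: len(pattern) - 1] if circular else "")
    loci = []
    start = 0
    while True:
        p = hay.find(pattern, start)
        if p == -1 or p >= length:
            break
        loci.append(p)
        start = p + 1
    return loci


def _unique_locus(template: DnaSequence, pattern: str, who: str) -> int:
    loci = _occurrences(template.bases, pattern, len(template), template.circular)
    if len(loci) != 1:
        raise SpecificityError(
            f"{who}: anneal region found at {len(loci)} loci {loci}", loci
        )
    return loci[0]


def simulate_pcr(template: DnaSequence, fwd: Primer, rev: Primer) -> DnaSequence:
    """Exact-match PCR: fwd.tail + template[fwd..rev] + revcomp(rev.tail).

    The forward anneal must occur exactly once on the top strand and the
    reverse anneal exactly once on the bottom strand; on a circular
    template the amplicon may span the origin.
    """
    f_start = _unique_locus(template, fwd.anneal, f"forward primer {fwd.name}")
    r_start = _unique_locus(
        template, revcomp_str(rev.anneal), f"reverse primer {rev.name}"
    )
    r_end = r_start + len(rev.anneal)
    n = len(template)
    if template.circular:
        span = (r_end - f_start) % n
        core = (template.bases * 2)[f_start : f_start + (span if span else n)]
    else:
        if r_end <= f_start:
            raise SpecificityError(
                "reverse locus lies upstream of forward locus on a linear template",
                [f_start, r_start],
            )
        core = template.bases[f_start:r_end]
    return DnaSequence(fwd.tail + core + revcomp_str(rev.tail))


def design_mutagenic_pair(
    template: DnaSequence,
    position: int,
    alt_base: str,
    arm_len: int | tuple[int, int] = 15,
    name: str = "QC",
) -> tuple[Primer, Primer]:
    """A QuikChange pair: template window with the mutation, plus its revcomp.

    ``arm_len`` is the number of flanking template bases on each side of
    the mutated position (a single int for symmetric arms or a
    (left, right) pair); each arm must be at least 10 nt.
    """
    left, right = (arm_len, arm_len) if isinstance(arm_len, int) else arm_len
    if left < 10 or right < 10:
        raise ValueError("each mutagenic arm must be >= 10 nt")
    n = len(template)
    if template.circular:
        doubled = template.bases * 2
        window = doubled[(position - left) % n :][: left + 1 + right]
    else:
        if position - left < 0 or position + right + 1 > n:
            raise ValueError("position too close to the template end for the arms")
        window = template.bases[position - left : position + right + 1]
    mutant = window[:left] + alt_base.upper() + window[left + 1 :]
    # the whole mutagenic oligo anneals (one mismatch); model tail as empty
    fwd = Primer(f"{name} F", "", mutant)
    rev = Primer(f"{name} R", "", revcomp_str(mutant))
    return fwd, rev


def simulate_mutagenesis(
    template: DnaSequence, pair: tuple[Primer, Primer]
) -> DnaSequence:
    """Whole-plasmid mutagenesis: write the forward oligo over its locus.

    The forward oligo must match the template everywhere except at exactly
    one position (the planted mutation).
    """
    fwd, rev = pair
    if revcomp_str(fwd.bases) != rev.bases:
        raise ValueError("mutagenic primers must be mutual reverse complements")
    oligo = fwd.bases
    n = len(template)
    hay = template.bases * 2 if template.circular else template.bases
    best: Optional[tuple[int, int]] = None  # (mismatches, start)
    limit = n if template.circular else n - len(oligo) + 1
    for start in range(max(limit, 0)):
        window = hay[start : start + len(oligo)]
        if len(window) < len(oligo):
            break
        mm = sum(1 for a, b in zip(window, oligo) if a != b)
        if best is None or mm < best[0]:
            best = (mm, start)
    if best is None or best[0] != 1:
        raise SpecificityError(
            f"mutagenic oligo {fwd.name} does not match the template with "
            f"exactly one mismatch (best: {best})",
            [],
        )
    start = best[1]
    if template.circular:
        rotated = template.bases[start:] + template.bases[:start]
        edited = oligo + rotated[len(oligo) :]
        # rotate back so coordinates are preserved
        back = (-start) % n
        edited = edited[back:] + edited[:back]
        return DnaSequence(edited, circular=True, features=template.features)
    edited = template.bases[:start] + oligo + template.bases[start + len(oligo) :]
    return DnaSequence(edited, features=template.features)


# ---------------------------------------------------------------------------
# SOE fusion


@dataclass(frozen=True)
class SoeStep:
    """One first-round PCR of an SOE plan."""

    template: DnaSequence
    forward: Primer
    reverse: Primer
    product: DnaSequence


@dataclass(frozen=True)
class SoePlan:
    steps: tuple[SoeStep, ...]
    outer_forward: Primer
    outer_reverse: Primer
    expected_product: DnaSequence
    warnings: tuple[str, ...] = ()


def design_soe_fusion(
    segments: Sequence[tuple[DnaSequence, tuple[int, int]]],
    junction_mutations: Optional[dict[int, tuple[int, str]]] = None,
    fwd_tail: str = "",
    rev_tail: str = "",
    overlap: int = 20,
    name: str = "SOE",
) -> SoePlan:
    """Plan an SOE fusion of template regions, in order.

    ``segments`` are (template, (start, end)) pairs; junction i joins
    segment i to segment i+1.  ``junction_mutations[i] = (offset, alt)``
    plants a substitution ``offset`` bases before junction i (i.e. within
    the tail of segment i), carried by both inner primers of that
    junction.  Outer tails are prepended/appended to the final product.
    Inner primer pairs at each junction are mutual reverse complements
    whose overlap (>= 15 nt) contains any planned mutation.
    """
    if not segments:
        raise ValueError("at least one segment required")
    junction_mutations = junction_mutations or {}
    # each inner primer spans `half` bases on each side of its junction
    half = max(overlap // 2, MIN_ANNEAL)

    texts = []
    for template, (start, end) in segments:
        if not (0 <= start < end <= len(template)):
            raise ValueError("segment region out of range")
        if end - start < 2 * half:
            raise ValueError(
                f"segments must be at least {2 * half} nt for a {half}-nt overlap arm"
            )
        texts.append(template.bases[start:end])
    # apply junction mutations to the fused reference
    fused = list(texts)
    for i, (offset, alt) in junction_mutations.items():
        if not (0 <= i < len(texts) - 1):
            raise ValueError(f"junction index {i} out of range")
        if not (1 <= offset <= half):
            raise ValueError(
                f"junction mutation offset must lie within the {half}-nt overlap arm"
            )
        seg = fused[i]
        pos = len(seg) - offset
        fused[i] = seg[:pos] + alt.upper() + seg[pos + 1 :]

    steps: list[SoeStep] = []
    warnings: list[str] = []
    n_seg = len(segments)
    for i, ((template, (start, end)), mutated) in enumerate(zip(segments, fused)):
        # overlap region spanning junction i-1 (head) and junction i (tail)
        head = fused[i - 1][-half:] if i > 0 else ""
        tail = fused[i + 1][:half] if i < n_seg - 1 else ""
        fwd_t = (fwd_tail if i == 0 else head).upper()
        rev_t = (rev_tail if i == n_seg - 1 else revcomp_str(tail)).upper()
        fwd = Primer(f"{name} F{i + 1}", fwd_t, mutated[:half])
        rev = Primer(f"{name} R{i + 1}", rev_t, revcomp_str(mutated[-half:]))
        product = DnaSequence(fwd.tail + mutated + revcomp_str(rev.tail))
        steps.append(SoeStep(template, fwd, rev, product))

    expected = DnaSequence(
        fwd_tail.upper() + "".join(fused) + revcomp_str(rev_tail)
    )
    for i in range(n_seg - 1):
        window = fused[i][-half:] + fused[i + 1][:half]
        if find_sites(DnaSequence(window), BGLBRICK_ENZYMES):
            warnings.append(
                f"junction {i}: overlap region contains a BglBrick site"
            )
    outer_f = steps[0].forward
    outer_r = steps[-1].reverse
    return SoePlan(tuple(steps), outer_f, outer_r, expected, tuple(warnings))


def simulate_soe(plan: SoePlan) -> DnaSequence:
    """Fuse the first-round products through their shared overlaps.

    Consecutive products must share an exact terminal overlap (>= 15 nt);
    the fusion concatenates them with the overlap counted once, then the
    outer primers define the final product (already carrying the tails).
    """
    fusion = plan.steps[0].product.bases
    for step in plan.steps[1:]:
        nxt = step.product.bases
        best = 0
        for k in range(min(len(fusion), len(nxt)), MIN_ANNEAL - 1, -1):
            if fusion.endswith(nxt[:k]):
                best = k
                break
        if best < MIN_ANNEAL:
            raise ValueError(
                f"products do not share a >= {MIN_ANNEAL} nt terminal overlap"
            )
        fusion = fusion + nxt[best:]
    return DnaSequence(fusion)


def tm(anneal: str) -> float:
    """Melting temperature of an annealing region, in degrees C.

    Wallace rule 2(A+T) + 4(G+C) for oligos shorter than 14 nt; the simple
    GC formula 64.9 + 41*(GC - 16.4)/N otherwise.  Deterministic by design;
    no salt or nearest-neighbor correction.
    """
    s = anneal.upper()
    if len(s) < 8:
        raise ValueError("anneal region must be >= 8 nt for a Tm estimate")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at != len(s):
        raise ValueError("non-ACGT character in anneal region")
    if len(s) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(s)
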