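"""Codon-aware removal of forbidden restriction sites (domestication).

Components destined for a BglBrick vector must not contain any of the four
standard sites internally.  This module plans single-nucleotide
substitutions that destroy such a site without creating a new one; inside
an annotated open reading frame only synonymous (translation-preserving)
edits are considered, ranked by the relative codon usage of the replacement
codon in E. coli K-12.  Outside ORFs every site-destroying single edit is
considered, ranked by distance from annotated functional features (the
effect of such an edit on e.g. promoter activity is not modeled and the
plan is flagged accordingly).

The package also bundles, as a verification fixture, the six QuikChange
primer pairs used to domesticate the original pBb vector components
(pSC101 origin, Cm and Km resistance modules, two propionate promoters and
the arabinose promoter); :func:`verify_qc_primers` re-derives each implied
wild-type/mutant pair and checks the design rules against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

from Bio.Seq import Seq

from .seqcore import (
    BGLBRICK_ENZYMES,
    ENZYMES,
    DnaSequence,
    EnzymeSpec,
    Feature,
    SiteHit,
    find_sites,
    revcomp_str,
)

__all__ = [
    "CodonUsageTable",
    "load_ecoli_usage",
    "MutationPlan",
    "UndomesticableError",
    "StalePlanError",
    "propose_removal",
    "apply_plan",
    "QC_PRIMERS",
    "verify_qc_primers",
]


class UndomesticableError(ValueError):
    """No single-base substitution can remove the site cleanly."""


class StalePlanError(ValueError):
    """A plan's reference base no longer matches the sequence."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon usage: per amino acid, codon -> fraction."""

    fractions: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        n_codons = sum(len(v) for v in self.fractions.values())
        if n_codons != 61:
            raise ValueError(f"expected 61 sense codons, got {n_codons}")
        for aa, codons in self.fractions.items():
            total = sum(codons.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions for {aa} sum to {total}, not 1")

    def score(self, codon: str) -> float:
        aa = str(Seq(codon).translate())
        if aa == "*":  # stop-codon swaps are allowed but carry no usage rank
            return 0.0
        return self.fractions[aa][codon]


def load_ecoli_usage() -> CodonUsageTable:
    """The bundled E. coli K-12 table, renormalized per amino acid."""
    raw: dict[str, dict[str, float]] = {}
    text = (
        resources.files("bglbrick.data") / "codon_usage_ecoli_k12.tsv"
    ).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, codon, frac = line.split("\t")
        raw.setdefault(aa, {})[codon] = float(frac)
    for aa, codons in raw.items():
        total = sum(codons.values())
        raw[aa] = {c: f / total for c, f in codons.items()}
    return CodonUsageTable(raw)


@dataclass(frozen=True)
class MutationPlan:
    """One single-base substitution that removes a forbidden site."""

    enzyme: str
    site_position: int
    position: int
    ref_base: str
    alt_base: str
    context: Literal["cds", "noncoding"]
    synonymous: bool
    usage_score: float  # relative frequency of the new codon (cds only)
    codon_before: str = ""
    codon_after: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base are identical")


def _forbidden_positions(seq_text: str, enzymes) -> set[tuple[str, int]]:
    hits = find_sites(DnaSequence(seq_text), enzymes)
    return {(h.enzyme, h.position) for h in hits}


def _edit(text: str, pos: int, alt: str) -> str:
    return text[:pos] + alt + text[pos + 1 :]


def propose_removal(
    seq: DnaSequence,
    hit: SiteHit,
    cds: Optional[Feature] = None,
    usage: Optional[CodonUsageTable] = None,
    enzymes=BGLBRICK_ENZYMES,
) -> list[MutationPlan]:
    """Rank every clean single-base edit that destroys ``hit``.

    In CDS mode (``cds`` gives the reading frame as a top-strand feature
    containing the site) candidates are all single-base substitutions
    within the codons overlapping the hexamer that are synonymous, destroy
    the site, and create no new site from ``enzymes``; they are ranked by
    the replacement codon's usage fraction, descending.  In noncoding mode
    candidates are the 18 single-base substitutions within the hexamer,
    filtered the same way and ranked by distance from annotated features
    (ties by position).

    Raises :class:`UndomesticableError` when no candidate qualifies.
    """
    if usage is None:
        usage = load_ecoli_usage()
    text = seq.bases
    before = _forbidden_positions(text, enzymes)
    if (hit.enzyme, hit.position) not in before:
        raise ValueError(
            f"{hit.enzyme} site at {hit.position} is not present in the sequence"
        )

    def clean(alt_text: str) -> bool:
        after = _forbidden_positions(alt_text, enzymes)
        return (hit.enzyme, hit.position) not in after and after <= before

    plans: list[MutationPlan] = []
    if cds is not None:
        if not (cds.start <= hit.position and hit.end <= cds.end):
            raise ValueError("site does not lie inside the annotated CDS")
        # codons (top-strand frame) overlapping the hexamer
        first = cds.start + ((hit.position - cds.start) // 3) * 3
        last = cds.start + ((hit.end - 1 - cds.start) // 3) * 3
        for codon_start in range(first, last + 1, 3):
            codon = text[codon_start : codon_start + 3]
            aa = str(Seq(codon).translate())
            for offset in range(3):
                pos = codon_start + offset
                ref = text[pos]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    new_codon = _edit(codon, offset, alt)
                    if str(Seq(new_codon).translate()) != aa:
                        continue
                    alt_text = _edit(text, pos, alt)
                    if not clean(alt_text):
                        continue
                    plans.append(
                        MutationPlan(
                            hit.enzyme, hit.position, pos, ref, alt,
                            "cds", True, usage.score(new_codon),
                            codon_before=codon, codon_after=new_codon,
                        )
                    )
        plans.sort(key=lambda p: (-p.usage_score, p.position, p.alt_base))
    else:
        feature_edges: list[int] = []
        for f in seq.features:
            feature_edges.extend((f.start, f.end))

        def feature_distance(pos: int) -> int:
            if not feature_edges:
                return 0
            return min(abs(pos - e) for e in feature_edges)

        for pos in range(hit.position, hit.end):
            ref = text[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                alt_text = _edit(text, pos, alt)
                if not clean(alt_text):
                    continue
                plans.append(
                    MutationPlan(
                        hit.enzyme, hit.position, pos, ref, alt,
                        "noncoding", False, 0.0,
                        note="regulatory context -- effect not modeled",
                    )
                )
        plans.sort(key=lambda p: (-feature_distance(p.position), p.position))
    if not plans:
        raise UndomesticableError(
            f"{hit.enzyme} site at {hit.position}: undomesticable by single substitution"
        )
    return plans


def apply_plan(seq: DnaSequence, plan: MutationPlan) -> DnaSequence:
    """Apply one substitution; length preserved, site count decreases."""
    if seq.bases[plan.position] != plan.ref_base:
        raise StalePlanError(
            f"expected {plan.ref_base} at {plan.position}, "
            f"found {seq.bases[plan.position]}"
        )
    return DnaSequence(
        _edit(seq.bases, plan.position, plan.alt_base), seq.circular, seq.features
    )


# ---------------------------------------------------------------------------
# Construction QC primer fixture

#: The six QuikChange primer pairs of the original pBb construction, as
#: printed: lowercase = template-matching, single capital = the introduced
#: point mutation.  Values: (forward, reverse, enzyme whose site is removed).
QC_PRIMERS: dict[str, tuple[str, str, str]] = {
    "pSC101QC": (
        "gaatttacagatacccagatcAcccgggaaaagg",
        "ccttttcccgggTgatctgggtatctgtaaattc",
        "BglII",
    ),
    "CmQC": (
        "ctttcattgccatacgAaattccggatgagcattc",
        "gaatgctcatccggaattTcgtatggcaatgaaag",
        "EcoRI",
    ),
    "KanQC": (
        "cctgtctcttgatcagatcAtgatcccctgc",
        "gcaggggatcaTgatctgatcaagagacagg",
        "BglII",
    ),
    "pProS": (
        "ggtcgccagatgatcAaattccaggctgatatccc",
        "gggatatcagcctggaattTgatcatctggcgacc",
        "EcoRI",
    ),
    "pProE": (
        "ccaggtgatcaaactcAaggctgatatcgcgaaac",
        "gtttcgcgatatcagcctTgagtttgatcacctgg",
        "XhoI",
    ),
    "pBAD": (
        "ccataagattagcggatTctacctgacgctttttatc",
        "gataaaaagcgtcaggtagAatccgctaatcttatgg",
        "BamHI",
    ),
}


@dataclass(frozen=True)
class QcCheck:
    name: str
    enzyme: str
    mutant_window: str
    wildtype_window: str
    mutation_position: int
    ref_base: str
    alt_base: str
    revcomp_ok: bool
    wildtype_has_site: bool
    mutant_site_free: bool

    @property
    def ok(self) -> bool:
        return self.revcomp_ok and self.wildtype_has_site and self.mutant_site_free


def verify_qc_primers(
    primers: dict[str, tuple[str, str, str]] | None = None,
) -> list[QcCheck]:
    """Re-derive and check each mutagenic primer pair.

    For each pair: (a) forward and reverse must be mutual reverse
    complements; (b) the capitalized base is the single mutant position —
    the wild-type base is recovered as the unique substitution there that
    restores the named recognition site; (c) the implied wild type must
    contain the named site and the mutant none.
    """
    if primers is None:
        primers = QC_PRIMERS
    checks: list[QcCheck] = []
    for name, (fwd, rev, enz_name) in primers.items():
        enz = ENZYMES[enz_name]
        revcomp_ok = revcomp_str(fwd) == rev.upper()
        caps = [i for i, c in enumerate(fwd) if c.isupper()]
        if len(caps) != 1:
            raise ValueError(f"{name}: expected exactly one capitalized base")
        pos = caps[0]
        mutant = fwd.upper()
        alt = mutant[pos]
        wt_candidates = [
            _edit(mutant, pos, b)
            for b in "ACGT"
            if b != alt and enz.recognition in _edit(mutant, pos, b)
        ]
        if len(wt_candidates) != 1:
            raise ValueError(
                f"{name}: wild-type base not uniquely recoverable "
                f"({len(wt_candidates)} candidates restore {enz_name})"
            )
        wildtype = wt_candidates[0]
        checks.append(
            QcCheck(
                name=name,
                enzyme=enz_name,
                mutant_window=mutant,
                wildtype_window=wildtype,
                mutation_position=pos,
                ref_base=wildtype[pos],
                alt_base=alt,
                revcomp_ok=revcomp_ok,
                wildtype_has_site=enz.recognition in wildtype,
                mutant_site_free=enz.recognition not in mutant,
            )
        )
    return checks
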