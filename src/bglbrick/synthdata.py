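"""Seeded synthetic-data generators with known ground truth.

Every input the toolkit consumes can be generated here: random
restriction-site-free DNA for parts and vector modules, microplate
time-series (logistic growth x Hill-activated expression, multiplicative
log-normal fluorescence noise), and qPCR runs (standard-curve dilution
series plus unknowns, additive Gaussian Ct noise).  All generators are
pure functions of (parameters, seed), and each dataset generator returns
its ground truth alongside the data so downstream recovery tests never
re-derive truth from the data itself.

Default study conditions mirror the pBb characterization design: plate
reads every 570 s for 20.5 h, triplicate wells, three control wells of the
reference vector per plate; qPCR standards as a four-fold, seven-point
dilution series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import ENZYMES, DnaSequence

__all__ = [
    "GrowthModel",
    "ExpressionModel",
    "QpcrModel",
    "gen_sequences",
    "random_clean_seq",
    "gen_plate",
    "gen_qpcr",
    "PLATE_COLUMNS",
    "QPCR_COLUMNS",
]

PLATE_COLUMNS = [
    "well", "time_s", "od600", "fluor", "channel",
    "vector", "strain", "medium", "inducer", "conc", "conc_unit",
]
QPCR_COLUMNS = ["sample", "target", "replicate", "ct", "role", "dilution"]

_ALL_RECOGNITIONS = tuple(e.recognition for e in ENZYMES.values())


# ---------------------------------------------------------------------------
# Sequences


def random_clean_seq(
    length: int,
    rng: np.random.Generator,
    forbidden: tuple[str, ...] = _ALL_RECOGNITIONS,
) -> str:
    """Uniform random ACGT string, optionally free of forbidden hexamers.

    Forbidden occurrences are repaired by resampling one base inside the
    first remaining occurrence until the string is clean; the repair loop
    is driven by the same generator, so output is deterministic per seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    bases = np.array(list("ACGT"))
    s = "".join(rng.choice(bases, size=length))
    if not forbidden:
        return s
    while True:
        hit = None
        for pat in forbidden:
            p = s.find(pat)
            if p != -1 and (hit is None or p < hit[0]):
                hit = (p, pat)
        if hit is None:
            return s
        p, pat = hit
        i = p + int(rng.integers(len(pat)))
        s = s[:i] + str(rng.choice(bases)) + s[i + 1 :]


def gen_sequences(
    lengths: list[int],
    forbidden_free: bool = True,
    seed: int = 0,
) -> list[DnaSequence]:
    """Random linear sequences; with ``forbidden_free`` no bundled-enzyme site."""
    rng = np.random.default_rng(seed)
    forbidden = _ALL_RECOGNITIONS if forbidden_free else ()
    return [DnaSequence(random_clean_seq(n, rng, forbidden)) for n in lengths]


# ---------------------------------------------------------------------------
# Plate-reader model


@dataclass(frozen=True)
class GrowthModel:
    """Logistic growth: OD(t) = K / (1 + ((K - OD0)/OD0) e^(-r t))."""

    od0: float = 0.05
    k_cap: float = 1.2
    rate: float = 6e-4  # 1/s  (~doubling scale of an hour at low density)

    def __post_init__(self) -> None:
        if min(self.od0, self.k_cap, self.rate) <= 0 or self.od0 >= self.k_cap:
            raise ValueError("require 0 < OD0 < K_cap and rate > 0")

    def od(self, t: np.ndarray | float) -> np.ndarray | float:
        a = (self.k_cap - self.od0) / self.od0
        return self.k_cap / (1.0 + a * np.exp(-self.rate * np.asarray(t, float)))


@dataclass(frozen=True)
class ExpressionModel:
    """Hill-activated specific fluorescence with crosstalk and CCR factors.

    Specific fluorescence at dose c and time t is
    ``hill(c) * min(1, t / t_rise)`` so the plateau equals the Hill value
    exactly from t_rise onward; raw fluorescence is SF x OD with
    multiplicative log-normal noise of parameter ``noise_sd``.
    Crosstalk coefficients are fractional changes per non-cognate inducer
    (+0.4 = 40% enhancement); ``glucose_factor`` multiplies SF when the
    medium carries 1% glucose (0.8 = the 20% repression regime).
    """

    basal: float = 200.0
    span: float = 4000.0
    k_half: float = 50.0   # inducer units (e.g. uM IPTG)
    hill_n: float = 2.0
    t_rise: float = 8 * 3600.0
    noise_sd: float = 0.05
    crosstalk: dict = field(default_factory=dict)  # inducer -> fractional change
    glucose_factor: float = 1.0

    def hill(self, conc: float) -> float:
        if conc < 0:
            raise ValueError("inducer concentration must be >= 0")
        if conc == 0:
            return self.basal
        cn = conc ** self.hill_n
        return self.basal + self.span * cn / (self.k_half ** self.hill_n + cn)

    def sf(self, conc: float, t: float, noncognate: tuple[str, ...] = (),
           glucose: bool = False) -> float:
        v = self.hill(conc) * min(1.0, t / self.t_rise)
        for ind in noncognate:
            v *= 1.0 + self.crosstalk.get(ind, 0.0)
        if glucose:
            v *= self.glucose_factor
        return v


def n_timepoints(duration_s: float, cadence_s: float) -> int:
    """Reads at t = 0, cadence, 2*cadence, ... <= duration (exact arithmetic)."""
    return int(duration_s // cadence_s) + 1


def gen_plate(
    growth: GrowthModel,
    expression: ExpressionModel,
    doses: list[float],
    seed: int,
    replicates: int = 3,
    cadence_s: float = 570.0,
    duration_s: float = 20.5 * 3600.0,
    vector: str = "pBbE5a-RFP",
    strain: str = "BLR(DE3)",
    medium: str = "LB",
    inducer: str = "IPTG",
    conc_unit: str = "uM",
    channel: str = "584/607",
    control_conc: float = 100.0,
    noncognate: tuple[str, ...] = (),
    glucose: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """A dose-response plate with three control wells; returns (data, truth).

    Control wells carry the reference vector at ``control_conc`` of its
    cognate inducer and are labeled ``control`` in the ``well`` column.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints(duration_s, cadence_s)) * cadence_s
    od = np.asarray(growth.od(t), float)
    rows = []

    def emit(well: str, conc: float, vec: str, non: tuple[str, ...]):
        sf = np.array([expression.sf(conc, ti, non, glucose) for ti in t])
        noise = (
            np.exp(rng.normal(0.0, expression.noise_sd, size=t.size))
            if expression.noise_sd > 0
            else np.ones(t.size)
        )
        fluor = sf * od * noise
        for ti, o, f in zip(t, od, fluor):
            rows.append(
                (well, float(ti), float(o), float(f), channel,
                 vec, strain, medium, inducer, float(conc), conc_unit)
            )

    for di, conc in enumerate(doses):
        for r in range(replicates):
            emit(f"dose{di}_rep{r}", conc, vector, noncognate)
    for r in range(3):
        emit(f"control_rep{r}", control_conc, vector, ())

    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    truth = {
        "hill": {
            "basal": expression.basal, "span": expression.span,
            "K": expression.k_half, "n": expression.hill_n,
        },
        "sf_plateau_by_dose": {c: expression.hill(c) for c in doses},
        "crosstalk": dict(expression.crosstalk),
        "glucose_factor": expression.glucose_factor,
        "control_conc": control_conc,
        "noise_sd": expression.noise_sd,
        "n_timepoints": int(t.size),
    }
    return df, truth


# ---------------------------------------------------------------------------
# qPCR model


@dataclass(frozen=True)
class QpcrModel:
    """Ct generator: Ct = intercept - log10(Q) / log10(1 + E) + noise.

    ``copy_number`` is the planted plasmids-per-chromosomal-equivalent of
    the unknown sample; the reference strain carries one marker-gene copy
    per chromosome by construction.  ``s16_multiplicity`` is the 16S rDNA
    copies per chromosome (7 rrn operons in E. coli).
    """

    efficiency_nptii: float = 0.95
    efficiency_16s: float = 0.93
    intercept_nptii: float = 22.0
    intercept_16s: float = 14.0
    ct_sd: float = 0.1
    copy_number: float = 60.0
    s16_multiplicity: float = 7.0

    def __post_init__(self) -> None:
        for e in (self.efficiency_nptii, self.efficiency_16s):
            if not (0.8 < e <= 1.0):
                raise ValueError("amplification efficiency must lie in (0.8, 1.0]")
        if self.copy_number <= 0:
            raise ValueError("copy number must be positive")

    def ct(self, target: str, q: float, noise: float = 0.0) -> float:
        if target == "nptII":
            e, b = self.efficiency_nptii, self.intercept_nptii
        elif target == "16S":
            e, b = self.efficiency_16s, self.intercept_16s
        else:
            raise ValueError(f"unknown target {target!r}")
        return b - math.log10(q) / math.log10(1.0 + e) + noise


def gen_qpcr(
    model: QpcrModel,
    seed: int,
    dilution_points: int = 7,
    dilution_factor: float = 4.0,
    standard_replicates: int = 2,
    unknown_replicates: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Standards, an unknown sample, and the reference strain; (data, truth).

    Standards span a ``dilution_factor``-fold series of
    ``dilution_points`` dilutions per target.  The unknown reflects the
    planted copy number through the Ct equation; the reference sample has
    one plasmid-marker copy per chromosome by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, model.ct_sd)) if model.ct_sd > 0 else 0.0

    for target in ("nptII", "16S"):
        for i in range(dilution_points):
            q = dilution_factor ** (-i)
            for r in range(standard_replicates):
                rows.append(
                    ("standard", target, r, model.ct(target, q, noise()),
                     "standard", q)
                )
    # unknowns: chromosome equivalents of sample and reference preparations,
    # in units of the standard stock (standards come from digested total DNA
    # of the same kind of preparation, so unknown Cts fall inside the
    # calibrated dilution range rather than being extrapolated)
    chrom_sample, chrom_ref = 1.0 / 120.0, 1.0 / 100.0
    quantities = {
        ("sample", "nptII"): model.copy_number * chrom_sample,
        ("sample", "16S"): model.s16_multiplicity * chrom_sample,
        ("reference", "nptII"): 1.0 * chrom_ref,
        ("reference", "16S"): model.s16_multiplicity * chrom_ref,
    }
    for (sample, target), q in quantities.items():
        role = "unknown" if sample == "sample" else "reference"
        for r in range(unknown_replicates):
            rows.append((sample, target, r, model.ct(target, q, noise()), role, np.nan))

    df = pd.DataFrame(rows, columns=QPCR_COLUMNS)
    truth = {
        "copy_number": model.copy_number,
        "efficiency": {
            "nptII": model.efficiency_nptii, "16S": model.efficiency_16s,
        },
        "expected_slope": {
            "nptII": -1.0 / math.log10(1.0 + model.efficiency_nptii),
            "16S": -1.0 / math.log10(1.0 + model.efficiency_16s),
        },
        "ct_sd": model.ct_sd,
    }
    return df, truth
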