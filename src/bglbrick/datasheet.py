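"""Quantitative vector characterization: the datasheet computations.

Given plate-reader kinetics and qPCR Ct tables this module computes the
panels of a vector datasheet: specific fluorescence (fluorescence / OD600)
time series, the 18-hour inducer dose response with control normalization,
a Hill fit summarizing it, inducer-crosstalk and catabolite-repression
percent changes, and plasmid copy number per chromosomal equivalent from
per-target qPCR standard curves.

Conventions: the dose-response summary uses the nearest measured timepoint
to the summary time (no interpolation); percent changes are
100 * (treated - baseline) / baseline, so a 0.8 ratio reads as -20%
(repression) and 1.4 as +40% (enhancement); Ct-to-quantity conversion
always goes through a fitted standard curve rather than a delta-delta-Ct
shortcut, and the reference strain maps to copy number 1 by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OD_FLOOR",
    "specific_fluorescence",
    "DoseResponseSummary",
    "dose_response",
    "HillFit",
    "fit_hill",
    "crosstalk_ratio",
    "repression_ratio",
    "StandardCurve",
    "fit_standard_curve",
    "CopyNumberResult",
    "copy_number",
    "copy_number_from_table",
    "render_datasheet",
]

#: Wells below this OD600 are masked rather than divided (ratio blow-up guard).
OD_FLOOR = 0.05


class UndefinedRatioError(ValueError):
    """Percent change against a non-positive baseline is undefined."""


def specific_fluorescence(
    df: pd.DataFrame,
    blank: float = 0.0,
    od_floor: float = OD_FLOOR,
) -> pd.DataFrame:
    """Add an ``sf`` column: (fluor - blank) / od600, masked below the floor.

    Rows with OD600 below ``od_floor`` get ``sf = NaN`` (masked, not
    divided).  Returns a copy; emits no warning unless every row is masked.
    """
    out = df.copy()
    od = out["od600"].to_numpy(float)
    fl = out["fluor"].to_numpy(float) - blank
    sf = np.where(od >= od_floor, fl / np.where(od > 0, od, np.nan), np.nan)
    out["sf"] = sf
    if np.all(~np.isfinite(sf)):
        import warnings

        warnings.warn("all timepoints below the OD floor; empty series")
    return out


@dataclass(frozen=True)
class DoseResponseSummary:
    """Per-dose mean/sd specific fluorescence at the summary timepoint."""

    summary_time_s: float
    actual_time_s: float
    doses: tuple[float, ...]
    mean_sf: tuple[float, ...]
    sd_sf: tuple[float, ...]
    n_replicates: tuple[int, ...]
    control_mean_sf: Optional[float]
    normalized: Optional[tuple[float, ...]]  # mean SF / mean control SF

    def as_dict(self) -> dict:
        return asdict(self)


def dose_response(
    df: pd.DataFrame,
    summary_time_s: float = 18 * 3600.0,
    control_mask: Optional[pd.Series] = None,
) -> DoseResponseSummary:
    """Summarize a plate at the measured timepoint nearest ``summary_time_s``.

    ``control_mask`` selects the control wells (e.g. the reference vector
    at its standard induction); when absent, normalization is skipped with
    a warning and absolute values are still reported.
    """
    if "sf" not in df.columns:
        df = specific_fluorescence(df)
    times = df["time_s"].unique()
    t_actual = float(times[np.argmin(np.abs(times - summary_time_s))])
    at_t = df[df["time_s"] == t_actual]

    if control_mask is not None:
        ctrl = at_t[control_mask.reindex(at_t.index, fill_value=False)]
        sample = at_t[~control_mask.reindex(at_t.index, fill_value=False)]
        control_mean = float(ctrl["sf"].mean()) if len(ctrl) else None
    else:
        import warnings

        warnings.warn("no control wells given; normalization skipped")
        sample, control_mean = at_t, None

    grouped = sample.groupby("conc")["sf"]
    doses = tuple(float(c) for c in grouped.mean().index)
    means = tuple(float(v) for v in grouped.mean())
    sds = tuple(float(v) if np.isfinite(v) else 0.0 for v in grouped.std(ddof=1))
    ns = tuple(int(v) for v in grouped.count())
    normalized = (
        tuple(m / control_mean for m in means) if control_mean else None
    )
    return DoseResponseSummary(
        summary_time_s, t_actual, doses, means, sds, ns, control_mean, normalized
    )


@dataclass(frozen=True)
class HillFit:
    basal: float
    span: float
    k_half: float
    hill_n: float
    residual_norm: float
    converged: bool

    def predict(self, conc: float) -> float:
        if conc == 0:
            return self.basal
        cn = conc ** self.hill_n
        return self.basal + self.span * cn / (self.k_half ** self.hill_n + cn)


def fit_hill(doses: Sequence[float], sf: Sequence[float]) -> HillFit:
    """Least squares for SF(c) = basal + span c^n / (K^n + c^n).

    Deterministic initialization: basal = min, span = max - min, K = the
    geometric median of the nonzero doses, n = 1.  Non-convergence is
    reported in the diagnostics, never raised.
    """
    c = np.asarray(doses, float)
    y = np.asarray(sf, float)
    if len(np.unique(c)) < 4 or 0.0 not in c:
        raise ValueError("need >= 4 distinct doses including 0")

    def model(conc, basal, span, k, n):
        conc = np.asarray(conc, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.where(conc > 0, conc, 1.0) ** n
            val = basal + span * cn / (k ** n + cn)
        return np.where(conc > 0, val, basal)

    nonzero = np.sort(c[c > 0])
    k0 = float(np.exp(np.median(np.log(nonzero))))
    p0 = [float(y.min()), float(y.max() - y.min()), k0, 1.0]
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, c, y, p0=p0, maxfev=20000,
                bounds=([0, 0, 1e-12, 0.05], [np.inf, np.inf, np.inf, 10.0]),
            )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = float(np.linalg.norm(y - model(c, *popt)))
    return HillFit(*(float(v) for v in popt), resid, converged)


def crosstalk_ratio(sf_cognate: float, sf_both: float) -> float:
    """Percent change when a non-cognate inducer is added.

    Positive = enhancement, negative = repression: 1.0 -> 1.4 gives +40%.
    """
    if sf_cognate <= 0:
        raise UndefinedRatioError("cognate-only specific fluorescence must be > 0")
    return 100.0 * (sf_both - sf_cognate) / sf_cognate


def repression_ratio(sf_no_glucose: float, sf_glucose: float) -> float:
    """Percent change caused by 1% glucose; 1.0 -> 0.8 gives -20%."""
    if sf_no_glucose <= 0:
        raise UndefinedRatioError("baseline specific fluorescence must be > 0")
    return 100.0 * (sf_glucose - sf_no_glucose) / sf_no_glucose


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class StandardCurve:
    """Ct = intercept + slope * log10(Q), from a dilution series."""

    slope: float
    intercept: float
    r_squared: float
    ct_min: float
    ct_max: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification gain minus one: 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def in_range(self, ct: float) -> bool:
        return self.ct_min <= ct <= self.ct_max


def fit_standard_curve(
    quantities: Sequence[float], cts: Sequence[float]
) -> StandardCurve:
    """OLS of Ct on log10(relative quantity); >= 3 positive-Q points."""
    q = np.asarray(quantities, float)
    ct = np.asarray(cts, float)
    if len(q) < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(q <= 0):
        raise ValueError("quantities must be strictly positive")
    res = stats.linregress(np.log10(q), ct)
    if res.slope >= 0:
        raise ValueError(
            "standard-curve slope is non-negative; dilution direction inverted?"
        )
    return StandardCurve(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(ct.min()), float(ct.max()),
    )


@dataclass(frozen=True)
class CopyNumberResult:
    """Plasmids per chromosomal equivalent, reference-calibrated."""

    copy_number: float
    q_nptii_sample: float
    q_16s_sample: float
    q_nptii_reference: float
    q_16s_reference: float
    warnings: tuple[str, ...] = ()


def copy_number(
    sample_ct_nptii: float,
    sample_ct_16s: float,
    reference_ct_nptii: float,
    reference_ct_16s: float,
    curve_nptii: StandardCurve,
    curve_16s: StandardCurve,
) -> CopyNumberResult:
    """(Q_nptII/Q_16S)_sample / (Q_nptII/Q_16S)_reference.

    The reference strain carries a single chromosomal marker copy, so it
    maps to exactly 1; Cts outside a curve's calibrated range attach an
    extrapolation warning rather than failing.
    """
    warnings = []
    for label, ct, curve in (
        ("sample nptII", sample_ct_nptii, curve_nptii),
        ("sample 16S", sample_ct_16s, curve_16s),
        ("reference nptII", reference_ct_nptii, curve_nptii),
        ("reference 16S", reference_ct_16s, curve_16s),
    ):
        if not curve.in_range(ct):
            warnings.append(f"{label}: Ct {ct:.2f} outside calibrated range")
    qs_n = curve_nptii.quantity(sample_ct_nptii)
    qs_16 = curve_16s.quantity(sample_ct_16s)
    qr_n = curve_nptii.quantity(reference_ct_nptii)
    qr_16 = curve_16s.quantity(reference_ct_16s)
    ratio = (qs_n / qs_16) / (qr_n / qr_16)
    return CopyNumberResult(ratio, qs_n, qs_16, qr_n, qr_16, tuple(warnings))


def copy_number_from_table(df: pd.DataFrame) -> CopyNumberResult:
    """Full qPCR pipeline on a Ct table.

    The table follows the qPCR schema (sample, target, replicate, ct,
    role, dilution): per-target curves are fitted from the ``standard``
    rows, unknown and reference Cts are averaged over replicates, and the
    ratio of ratios is calibrated against the reference strain.
    """
    curves = {}
    for target in ("nptII", "16S"):
        std = df[(df["role"] == "standard") & (df["target"] == target)]
        curves[target] = fit_standard_curve(std["dilution"], std["ct"])

    def mean_ct(role: str, target: str) -> float:
        rows = df[(df["role"] == role) & (df["target"] == target)]
        if rows.empty:
            raise ValueError(f"no Ct rows for role={role}, target={target}")
        return float(rows["ct"].mean())

    return copy_number(
        mean_ct("unknown", "nptII"),
        mean_ct("unknown", "16S"),
        mean_ct("reference", "nptII"),
        mean_ct("reference", "16S"),
        curves["nptII"],
        curves["16S"],
    )


# ---------------------------------------------------------------------------
# Report


def render_datasheet(
    vector_name: str,
    dose: Optional[DoseResponseSummary] = None,
    hill: Optional[HillFit] = None,
    media_panel: Optional[dict] = None,
    crosstalk_panel: Optional[dict] = None,
    repression_panel: Optional[dict] = None,
    copy: Optional[CopyNumberResult] = None,
    schema_version: str = "1.0",
) -> tuple[dict, str]:
    """Machine-readable (JSON-safe dict) and human-readable datasheet.

    Missing panels are rendered as "not measured".
    """
    doc = {
        "schema_version": schema_version,
        "vector": vector_name,
        "dose_response": dose.as_dict() if dose else None,
        "hill_fit": asdict(hill) if hill else None,
        "media_panel": media_panel,
        "crosstalk_panel": crosstalk_panel,
        "repression_panel": repression_panel,
        "copy_number": asdict(copy) if copy else None,
    }
    # guarantee JSON round-trip safety of every numeric field
    doc = json.loads(json.dumps(doc))

    lines = [f"Datasheet: {vector_name}", "=" * (11 + len(vector_name))]
    if dose:
        lines.append(
            f"Dose response at t = {dose.actual_time_s / 3600:.2f} h "
            f"({len(dose.doses)} doses)"
        )
        for c, m, s in zip(dose.doses, dose.mean_sf, dose.sd_sf):
            lines.append(f"  {c:>10.3g}  SF = {m:.1f} +/- {s:.1f}")
    else:
        lines.append("Dose response: not measured")
    if hill:
        lines.append(
            f"Hill fit: basal={hill.basal:.1f} span={hill.span:.1f} "
            f"K={hill.k_half:.3g} n={hill.hill_n:.2f}"
        )
    else:
        lines.append("Hill fit: not measured")
    for label, panel in (
        ("Media/strain panel", media_panel),
        ("Crosstalk panel", crosstalk_panel),
        ("Catabolite repression", repression_panel),
    ):
        if panel:
            lines.append(f"{label}:")
            for k, v in panel.items():
                lines.append(f"  {k}: {v:+.1f}%" if isinstance(v, float) else f"  {k}: {v}")
        else:
            lines.append(f"{label}: not measured")
    if copy:
        lines.append(f"Plasmid copy number: {copy.copy_number:.1f} per chromosome")
        for w in copy.warnings:
            lines.append(f"  warning: {w}")
    else:
        lines.append("Plasmid copy number: not measured")
    return doc, "\n".join(lines)
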