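"""MRM assay validation statistics and species authentication calls.

Consumes long-format peak-area tables as exported by chromatogram-
integration software (one row per measured transition/peptide per
injection) and computes the standard targeted-assay validation metrics:

* internal-standard (IS) recovery — percentage of a spiked short peptide
  standard (e.g. GWGG) recovered relative to reference injections,
  reflecting matrix effects;
* repeatability — intra-day precision, the mean over days of the
  within-day relative standard deviation (RSD, %);
* reproducibility — inter-day precision, the RSD of the day means;
* linearity — ordinary least squares of normalized area on dilution
  level, with R² as the squared Pearson correlation.

Areas are normalized to peak area per mg defatted flour before any
statistic is computed. Authentication calls combine the quantifier and
qualifier markers of a species panel: a sample is positive for a species
only when the quantifier signal clears its threshold AND at least one
qualifier is detected; a quantifier without qualifier support is
inconclusive, anything less is negative. Blank injections must come out
negative for every species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .marker_screen import MarkerCandidate

__all__ = [
    "RECORD_CLASSES",
    "PEAK_TABLE_COLUMNS",
    "PeakAreaRecord",
    "PrecisionEstimate",
    "LinearityFit",
    "ValidationReport",
    "AuthThresholds",
    "AuthenticationCall",
    "read_peak_table",
    "records_to_frame",
    "normalize_area",
    "rsd",
    "repeatability_reproducibility",
    "is_recovery",
    "linearity",
    "validation_report",
    "authenticate",
    "authenticate_table",
]

RECORD_CLASSES = ("sample", "blank", "is_spike", "is_reference")

#: Header of the long-format peak-area table.
PEAK_TABLE_COLUMNS = [
    "sample_id",
    "species_label",
    "peptide",
    "transition",
    "replicate",
    "day",
    "raw_area",
    "flour_mg",
    "dilution_level",
    "record_class",
]


@dataclass(frozen=True)
class PeakAreaRecord:
    """One measured (or simulated) chromatographic peak area."""

    sample_id: str
    species_label: str
    peptide: str
    replicate: int
    day: int
    raw_area: float
    flour_mg: float = 1.0
    transition: str | None = None
    dilution_level: float | None = None
    record_class: str = "sample"

    def __post_init__(self) -> None:
        if self.record_class not in RECORD_CLASSES:
            raise ValueError(f"unknown record_class {self.record_class!r}")
        if self.raw_area < 0:
            raise ValueError(f"raw_area must be >= 0, got {self.raw_area}")
        if self.record_class == "sample" and not self.flour_mg > 0:
            raise ValueError(f"sample record requires flour_mg > 0, got {self.flour_mg}")


def normalize_area(record: PeakAreaRecord) -> float:
    """Peak area per mg defatted flour: ``raw_area / flour_mg``."""
    if not record.flour_mg > 0:
        raise ValueError(f"flour_mg must be > 0 to normalize, got {record.flour_mg}")
    return record.raw_area / record.flour_mg


def records_to_frame(records: Iterable[PeakAreaRecord]) -> pd.DataFrame:
    """Long-format DataFrame with a ``normalized_area`` column appended."""
    rows = []
    for r in records:
        d = {
            "sample_id": r.sample_id,
            "species_label": r.species_label,
            "peptide": r.peptide,
            "transition": r.transition,
            "replicate": r.replicate,
            "day": r.day,
            "raw_area": r.raw_area,
            "flour_mg": r.flour_mg,
            "dilution_level": r.dilution_level,
            "record_class": r.record_class,
        }
        d["normalized_area"] = r.raw_area / r.flour_mg if r.flour_mg > 0 else r.raw_area
        rows.append(d)
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS + ["normalized_area"])


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited long-format peak-area table.

    The file must carry the standard header (see ``PEAK_TABLE_COLUMNS``);
    comma, tab, and semicolon delimiters are auto-detected. A
    ``normalized_area`` column (area per mg defatted flour) is appended.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak-area table missing columns {sorted(missing)}")
    if (df["raw_area"] < 0).any():
        raise ValueError(f"{path}: negative raw_area values present")
    bad_class = set(df["record_class"].unique()) - set(RECORD_CLASSES)
    if bad_class:
        raise ValueError(f"{path}: unknown record_class values {sorted(bad_class)}")
    sample = df["record_class"] == "sample"
    if (df.loc[sample, "flour_mg"] <= 0).any():
        raise ValueError(f"{path}: sample records require flour_mg > 0")
    df = df.copy()
    df["normalized_area"] = np.where(
        df["flour_mg"] > 0, df["raw_area"] / df["flour_mg"], df["raw_area"]
    )
    return df


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, %: 100 · s / mean (n−1 denominator)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"RSD requires >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class PrecisionEstimate:
    """Intra-/inter-day precision of one peptide's normalized areas.

    A metric that cannot be computed from the available grouping is
    ``None`` with its reason recorded, never an exception.
    """

    intra_day_rsd: float | None
    inter_day_rsd: float | None
    n_days: int
    n_values: int
    intra_reason: str | None = None
    inter_reason: str | None = None


def repeatability_reproducibility(
    records: Iterable[PeakAreaRecord] | pd.DataFrame,
) -> PrecisionEstimate:
    """Intra-day (repeatability) and inter-day (reproducibility) RSD.

    Input rows must belong to a single peptide. Repeatability is the mean
    over days of the within-day RSD of normalized areas; reproducibility
    is the RSD of the day means (day means, not a pooled RSD, so that a
    systematic day shift is not conflated with within-day scatter).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        return PrecisionEstimate(None, None, 0, 0, "no records", "no records")
    if df["peptide"].nunique() > 1:
        raise ValueError("precision metrics are computed per peptide; got several")

    by_day = df.groupby("day")["normalized_area"]
    day_means = by_day.mean()
    within = [g.values for _, g in by_day]

    intra = intra_reason = None
    per_day_rsds = [rsd(v) for v in within if len(v) >= 2 and v.mean() != 0]
    if per_day_rsds:
        intra = float(np.mean(per_day_rsds))
    else:
        intra_reason = "no day with >= 2 replicates (non-zero mean)"

    inter = inter_reason = None
    if len(day_means) >= 2 and day_means.mean() != 0:
        inter = rsd(day_means.values)
    else:
        inter_reason = "fewer than 2 days"

    return PrecisionEstimate(
        intra_day_rsd=intra,
        inter_day_rsd=inter,
        n_days=len(day_means),
        n_values=len(df),
        intra_reason=intra_reason,
        inter_reason=inter_reason,
    )


def is_recovery(
    spiked: Iterable[PeakAreaRecord] | Sequence[float],
    reference: Iterable[PeakAreaRecord] | Sequence[float],
) -> tuple[float, float]:
    """Internal-standard recovery, % (mean, sd).

    ``100 · mean(spiked areas) / mean(reference areas)``; the sd is
    propagated from the spiked replicates. Raw areas are used directly —
    the IS is spiked at a fixed amount, so flour normalization does not
    apply.
    """
    def areas(x):
        x = list(x)
        return [r.raw_area if isinstance(r, PeakAreaRecord) else float(r) for r in x]

    spiked_a = np.asarray(areas(spiked), dtype=float)
    ref_a = np.asarray(areas(reference), dtype=float)
    if spiked_a.size < 1 or ref_a.size < 1:
        raise ValueError("is_recovery requires >= 1 spiked and >= 1 reference record")
    ref_mean = ref_a.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; recovery undefined")
    mean_pct = float(100.0 * spiked_a.mean() / ref_mean)
    sd_pct = float(100.0 * spiked_a.std(ddof=1) / ref_mean) if spiked_a.size >= 2 else 0.0
    return mean_pct, sd_pct


@dataclass(frozen=True)
class LinearityFit:
    slope: float
    intercept: float
    r2: float
    n: int


def linearity(series: Sequence[tuple[float, float]]) -> LinearityFit:
    """Calibration-curve fit: OLS of normalized area on dilution level.

    Requires at least 3 distinct dilution levels. R² is the squared
    Pearson correlation; a perfectly flat response is reported as slope 0
    with R² 0 rather than an error.
    """
    pts = [(float(x), float(y)) for x, y in series]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise ValueError(f"linearity requires >= 3 distinct dilution levels, got {len(levels)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(y, y[0]):
        return LinearityFit(slope=0.0, intercept=float(y[0]), r2=0.0, n=len(pts))
    fit = stats.linregress(x, y)
    return LinearityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(pts),
    )


@dataclass(frozen=True)
class ValidationReport:
    """Per-peptide validation summary mirroring a targeted-assay report."""

    peptide: str
    is_recovery_pct: float | None
    is_recovery_sd: float | None
    repeatability_rsd_pct: float | None
    reproducibility_rsd_pct: float | None
    linearity_r2: float | None
    slope: float | None
    intercept: float | None
    n_values: int


def validation_report(
    df: pd.DataFrame, is_peptide: str = "GWGG"
) -> pd.DataFrame:
    """Full validation table from a long-format peak-area frame.

    Precision metrics are computed per peptide from ``sample`` records;
    linearity from rows carrying a dilution level; IS recovery from the
    ``is_spike`` vs ``is_reference`` records of ``is_peptide`` (reported
    on every peptide row, as a property of the run).
    """
    if "normalized_area" not in df.columns:
        df = df.assign(
            normalized_area=np.where(
                df["flour_mg"] > 0, df["raw_area"] / df["flour_mg"], df["raw_area"]
            )
        )
    rec_mean = rec_sd = None
    spiked = df[(df["record_class"] == "is_spike") & (df["peptide"] == is_peptide)]
    ref = df[(df["record_class"] == "is_reference") & (df["peptide"] == is_peptide)]
    if len(spiked) and len(ref):
        rec_mean, rec_sd = is_recovery(spiked["raw_area"].tolist(), ref["raw_area"].tolist())

    rows = []
    samples = df[df["record_class"] == "sample"]
    for peptide, group in samples.groupby("peptide"):
        if peptide == is_peptide:
            continue
        no_dil = group[group["dilution_level"].isna()] if group["dilution_level"].notna().any() else group
        prec = (
            repeatability_reproducibility(no_dil)
            if len(no_dil)
            else PrecisionEstimate(None, None, 0, 0, "no records", "no records")
        )
        lin = None
        dil = group.dropna(subset=["dilution_level"])
        if dil["dilution_level"].nunique() >= 3:
            lin = linearity(list(zip(dil["dilution_level"], dil["normalized_area"])))
        rows.append(
            ValidationReport(
                peptide=peptide,
                is_recovery_pct=rec_mean,
                is_recovery_sd=rec_sd,
                repeatability_rsd_pct=prec.intra_day_rsd,
                reproducibility_rsd_pct=prec.inter_day_rsd,
                linearity_r2=lin.r2 if lin else None,
                slope=lin.slope if lin else None,
                intercept=lin.intercept if lin else None,
                n_values=len(group),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class AuthThresholds:
    """Normalized-area floors for authentication calls.

    ``quantifier_min`` / ``qualifier_min`` are global defaults (area per
    mg defatted flour); per-species overrides take precedence. The
    optional qualifier/quantifier area-ratio consistency check (ratio
    within ``ratio_tolerance`` of a reference ratio) is off by default.
    """

    quantifier_min: float = 1000.0
    qualifier_min: float = 1000.0
    per_species_quantifier: Mapping[str, float] = field(default_factory=dict)
    per_species_qualifier: Mapping[str, float] = field(default_factory=dict)
    ratio_check: bool = False
    ratio_tolerance: float = 0.30
    reference_ratios: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def quantifier_floor(self, species: str) -> float:
        return self.per_species_quantifier.get(species, self.quantifier_min)

    def qualifier_floor(self, species: str) -> float:
        return self.per_species_qualifier.get(species, self.qualifier_min)


@dataclass(frozen=True)
class SpeciesEvidence:
    quantifier_area: float
    qualifiers_detected: int
    status: str  # positive | inconclusive | negative


@dataclass(frozen=True)
class AuthenticationCall:
    """Species authentication verdict for one sample."""

    sample_id: str
    species_called: frozenset[str]
    evidence: Mapping[str, SpeciesEvidence]


def _panel_roles(panel: Sequence[MarkerCandidate]) -> dict[str, dict[str, list[str]]]:
    roles: dict[str, dict[str, list[str]]] = {}
    for cand in panel:
        bucket = roles.setdefault(cand.species_tag, {"quantifier": [], "qualifier": []})
        if cand.role in ("quantifier", "qualifier"):
            bucket[cand.role].append(cand.sequence)
    return roles


def authenticate(
    records: Iterable[PeakAreaRecord] | pd.DataFrame,
    panel: Sequence[MarkerCandidate],
    thresholds: AuthThresholds = AuthThresholds(),
    species: Sequence[str] | None = None,
) -> AuthenticationCall:
    """Call species presence in one sample from its marker peak areas.

    A species is positive iff its quantifier normalized area clears the
    species threshold AND at least one qualifier is detected above the
    qualifier threshold; a cleared quantifier with zero qualifiers is
    inconclusive; otherwise negative. Multiple quantifier peptides (one
    per parent protein) are combined by their maximum normalized area.

    Raises
    ------
    ValueError
        If the panel lacks a quantifier for a species to be called, or the
        records span more than one sample.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sample_ids = df["sample_id"].unique() if len(df) else ["<empty>"]
    if len(sample_ids) > 1:
        raise ValueError(f"authenticate expects one sample, got {sorted(sample_ids)}")
    sample_id = str(sample_ids[0])

    roles = _panel_roles(panel)
    wanted = list(species) if species is not None else sorted(roles)
    by_pep = df.groupby("peptide")["normalized_area"].max() if len(df) else pd.Series(dtype=float)

    evidence: dict[str, SpeciesEvidence] = {}
    called: set[str] = set()
    for sp in wanted:
        sp_roles = roles.get(sp, {"quantifier": [], "qualifier": []})
        if not sp_roles["quantifier"]:
            raise ValueError(f"panel has no quantifier peptide for species {sp!r}")
        quant_area = max(
            (float(by_pep.get(p, 0.0)) for p in sp_roles["quantifier"]), default=0.0
        )
        n_qual = sum(
            1
            for p in sp_roles["qualifier"]
            if float(by_pep.get(p, 0.0)) >= thresholds.qualifier_floor(sp)
        )
        if quant_area >= thresholds.quantifier_floor(sp):
            status = "positive" if n_qual >= 1 else "inconclusive"
        else:
            status = "negative"
        if status == "positive" and thresholds.ratio_check:
            for p in sp_roles["qualifier"]:
                ref = thresholds.reference_ratios.get((sp, p))
                if ref and quant_area > 0:
                    ratio = float(by_pep.get(p, 0.0)) / quant_area
                    if abs(ratio - ref) > thresholds.ratio_tolerance * ref:
                        status = "inconclusive"
                        break
        if status == "positive":
            called.add(sp)
        evidence[sp] = SpeciesEvidence(quant_area, n_qual, status)
    return AuthenticationCall(sample_id, frozenset(called), evidence)


def authenticate_table(
    df: pd.DataFrame,
    panel: Sequence[MarkerCandidate],
    thresholds: AuthThresholds = AuthThresholds(),
    species: Sequence[str] | None = None,
) -> list[AuthenticationCall]:
    """Authenticate every sample in a long-format peak-area frame."""
    return [
        authenticate(group, panel, thresholds, species)
        for _, group in df.groupby("sample_id", sort=True)
    ]
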