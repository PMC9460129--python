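"""Firing-combination subarea features from amplitude spectra.

On a log-frequency vs dB chart, the region between a vibration spectrum
and the lowest mechanoreceptor threshold represents stimulus content
strong enough to make at least one receptor fire.  Cutting that region
horizontally at the remaining threshold curves partitions it into slabs,
each labelled by the combination of receptors firing there; the area of
each labelled piece is a feature ``D_i`` (dB x decades).  With the
published four-receptor model this yields exactly eight features:
D_SAI, D_SAISAII, D_SAISAIIFAI, D_FAII, D_SAIFAII, D_SAIIFAII,
D_SAISAIIFAII and D_ALL.

The earlier single-receptor reading -- accumulate the whole column into
the receptor holding the lowest threshold at that frequency -- is kept as
the reconstructed "A-method" baseline, and a one-way ANOVA screen keeps
only features that actually separate the physical samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import AmplitudeSpectrum, spectrum_to_db
from .thresholds import F_RANGE, ThresholdModel, band_structure, canonical_labels, default_model

__all__ = [
    "CANONICAL_LABELS",
    "FeatureVector",
    "SubareaFeatureExtractor",
    "extract_subarea_features",
    "extract_legacy_features",
    "screen_features",
    "feature_columns",
]

#: The eight firing-combination labels of the published model, in the
#: conventional reporting order.
CANONICAL_LABELS = (
    "SAI",
    "SAISAII",
    "SAISAIIFAI",
    "FAII",
    "SAIFAII",
    "SAIIFAII",
    "SAISAIIFAII",
    "ALL",
)


def feature_columns(labels=CANONICAL_LABELS) -> list[str]:
    return [f"D_{label}" for label in labels]


@dataclass
class FeatureVector:
    """Subarea features plus friction for one (sample, repetition)."""

    sample_id: str
    repetition: int
    D: dict[str, float] = field(default_factory=dict)
    mu_prime: float | None = None

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.D.items() if v < 0}
        if bad:
            raise ValueError(f"negative subarea features: {bad}")

    def to_series(self) -> pd.Series:
        row = {"sample_id": self.sample_id, "repetition": self.repetition}
        row.update({f"D_{k}": v for k, v in self.D.items()})
        if self.mu_prime is not None:
            row["mu_prime"] = self.mu_prime
        return pd.Series(row)


def _bin_widths_decades(freqs: np.ndarray, f_range: tuple[float, float]) -> np.ndarray:
    """Width of each bin in decades of frequency, edges clipped to f_range."""
    df = freqs[1] - freqs[0]
    lo = np.clip(freqs - df / 2.0, f_range[0], f_range[1])
    hi = np.clip(freqs + df / 2.0, f_range[0], f_range[1])
    with np.errstate(divide="ignore"):
        return np.log10(hi) - np.log10(lo)


def _bin_widths_linear(freqs: np.ndarray, f_range: tuple[float, float]) -> np.ndarray:
    df = freqs[1] - freqs[0]
    lo = np.clip(freqs - df / 2.0, f_range[0], f_range[1])
    hi = np.clip(freqs + df / 2.0, f_range[0], f_range[1])
    return hi - lo


def _check_coverage(freqs: np.ndarray, f_range: tuple[float, float]) -> None:
    if freqs[0] > f_range[0] or freqs[-1] < f_range[1]:
        missing = []
        if freqs[0] > f_range[0]:
            missing.append(f"[{f_range[0]}, {freqs[0]:g}) Hz")
        if freqs[-1] < f_range[1]:
            missing.append(f"({freqs[-1]:g}, {f_range[1]}] Hz")
        raise ValueError(
            "spectrum does not cover the threshold band: missing " + ", ".join(missing)
        )


def extract_subarea_features(
    freqs: np.ndarray,
    spec_db: np.ndarray,
    model: ThresholdModel | None = None,
    f_range: tuple[float, float] = F_RANGE,
    *,
    log_frequency: bool = True,
) -> dict[str, float]:
    """Integrate the spectrum-over-threshold region into per-combination areas.

    For every bin centred at ``f`` inside ``f_range``: the vertical column
    from the lowest defined threshold up to the spectrum level is cut by
    the band structure at ``f`` into slabs, and each slab contributes its
    height times the bin width (in decades by default) to the area of its
    firing combination.  Bins at or below the lowest threshold contribute
    nothing; the sum over combinations equals the total area between the
    spectrum and the lowest threshold.
    """
    model = model if model is not None else default_model()
    freqs = np.asarray(freqs, float)
    spec_db = np.asarray(spec_db, float)
    _check_coverage(freqs, f_range)
    widths = (
        _bin_widths_decades(freqs, f_range)
        if log_frequency
        else _bin_widths_linear(freqs, f_range)
    )
    labels = canonical_labels(model)
    D = {label: 0.0 for label in labels}
    inside = (freqs >= f_range[0]) & (freqs <= f_range[1]) & (widths > 0)
    for idx in np.nonzero(inside)[0]:
        f = float(freqs[idx])
        s = float(spec_db[idx])
        slabs = band_structure(model, f)
        if not slabs or s <= slabs[0].lower:
            continue
        w = widths[idx]
        for slab in slabs:
            top = min(s, slab.upper)
            height = top - slab.lower
            if height <= 0:
                continue
            D[slab.combo.label] += height * w
    return D


def extract_legacy_features(
    freqs: np.ndarray,
    spec_db: np.ndarray,
    model: ThresholdModel | None = None,
    f_range: tuple[float, float] = F_RANGE,
    *,
    log_frequency: bool = True,
) -> dict[str, float]:
    """Reconstructed prior-study baseline: pool area by lowest-threshold receptor.

    The frequency axis is split into bands according to which receptor
    holds the lowest threshold; within each band the whole area between
    spectrum and that lowest threshold is accumulated, and bands with the
    same receptor are pooled.  All four receptor keys are always present
    (a receptor that never holds the minimum, or never sees supra-threshold
    content, reports zero).  The total over receptors equals the total of
    the subarea features for the same spectrum.
    """
    model = model if model is not None else default_model()
    freqs = np.asarray(freqs, float)
    spec_db = np.asarray(spec_db, float)
    _check_coverage(freqs, f_range)
    widths = (
        _bin_widths_decades(freqs, f_range)
        if log_frequency
        else _bin_widths_linear(freqs, f_range)
    )
    out = {r: 0.0 for r in model.receptors}
    inside = (freqs >= f_range[0]) & (freqs <= f_range[1]) & (widths > 0)
    for idx in np.nonzero(inside)[0]:
        f = float(freqs[idx])
        s = float(spec_db[idx])
        slabs = band_structure(model, f)
        if not slabs or s <= slabs[0].lower:
            continue
        lowest = slabs[0]
        receptor = next(iter(lowest.combo.members))
        out[receptor] += (s - lowest.lower) * widths[idx]
    return out


class SubareaFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform amplitude spectra into firing-combination area features.

    Parameters
    ----------
    model : ThresholdModel, optional
        Piecewise threshold model; the packaged published model by default.
    method : {"subarea", "legacy"}
        "subarea" yields the eight combination features; "legacy" the
        reconstructed lowest-threshold-receptor baseline.
    f_range : (float, float)
        Frequency band integrated, Hz.
    db_ref, db_floor : float
        Reference amplitude (um) and clamp used to express spectra in dB.
    log_frequency : bool
        Integrate over decades of frequency (the thresholds are straight
        lines on that axis); False integrates over Hz.
    """

    def __init__(
        self,
        model: ThresholdModel | None = None,
        method: str = "subarea",
        f_range: tuple[float, float] = F_RANGE,
        db_ref: float = 1.0,
        db_floor: float = -120.0,
        log_frequency: bool = True,
    ):
        self.model = model
        self.method = method
        self.f_range = f_range
        self.db_ref = db_ref
        self.db_floor = db_floor
        self.log_frequency = log_frequency

    def fit(self, X=None, y=None) -> "SubareaFeatureExtractor":
        if self.method not in ("subarea", "legacy"):
            raise ValueError(f"unknown method {self.method!r}")
        self.model_ = self.model if self.model is not None else default_model()
        if self.method == "subarea":
            self.feature_labels_ = tuple(canonical_labels(self.model_))
        else:
            self.feature_labels_ = tuple(self.model_.receptors)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of AmplitudeSpectrum (or (freqs, db) pairs)."""
        if not hasattr(self, "model_"):
            self.fit()
        extract = (
            extract_subarea_features if self.method == "subarea" else extract_legacy_features
        )
        rows = []
        for item in X:
            if isinstance(item, AmplitudeSpectrum):
                freqs = item.frequencies
                db = spectrum_to_db(item, ref=self.db_ref, floor=self.db_floor)
                source = item.source_id
            else:
                freqs, db = item
                source = ""
            D = extract(
                freqs,
                db,
                self.model_,
                self.f_range,
                log_frequency=self.log_frequency,
            )
            row = {f"D_{k}": D[k] for k in self.feature_labels_}
            if source:
                sid, _, rep = source.partition(":")
                row["sample_id"] = sid
                row["repetition"] = int(rep) if rep else 1
            rows.append(row)
        return pd.DataFrame(rows)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_labels_"):
            self.fit()
        return np.asarray(feature_columns(self.feature_labels_), dtype=object)


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    feature_cols: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA across samples; keep features with p < alpha.

    Returns (selected feature columns, per-feature ANOVA table, per-feature
    Tukey HSD pairwise comparison frames).  Repetitions are the replicates;
    a feature constant across all rows is excluded with a warning.
    """
    if "sample_id" not in table.columns:
        raise ValueError("feature table needs a sample_id column")
    groups = table.groupby("sample_id")
    if groups.ngroups < 2:
        raise ValueError("ANOVA screening needs at least 2 samples")
    if (groups.size() < 2).any():
        raise ValueError("ANOVA screening needs >=2 repetitions per sample")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c.startswith("D_")]
    anova_rows = []
    tukey: dict[str, pd.DataFrame] = {}
    selected = []
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for col in feature_cols:
        values = [g[col].to_numpy() for _, g in groups]
        if np.ptp(table[col].to_numpy()) == 0:
            warnings.warn(f"feature {col} is constant across all rows; excluded")
            continue
        f_stat, p = stats.f_oneway(*values)
        anova_rows.append({"feature": col, "F": f_stat, "p": p, "selected": p < alpha})
        if p < alpha:
            selected.append(col)
        res = pairwise_tukeyhsd(table[col].to_numpy(), table["sample_id"].to_numpy(), alpha=alpha)
        tukey[col] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    anova = pd.DataFrame(anova_rows)
    return selected, anova, tukey
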