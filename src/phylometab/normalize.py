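"""Replicate-level normalization of metabolite intensity tables.

Turns raw positive intensities (one row per cultured replicate, one column
per metabolite) into the log-scale, dilution- and growth-corrected profiles
the divergence statistics consume. The pipeline order is fixed:

    feature filters -> kNN imputation -> PQN -> OD regression -> log + aggregate

PQN (probabilistic quotient normalization) removes per-sample multiplicative
dilution/biomass effects by dividing each sample by the median ratio of its
intensities to a reference spectrum (the per-metabolite median over
biological samples). The OD step then removes residual growth-linked trends
by regressing each metabolite's log intensity on the culture's optical
density at sampling and keeping the residual re-centred at the mean OD, so
each metabolite's mean level is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "SampleTable",
    "ProfileTable",
    "METADATA_COLUMNS",
    "filter_untargeted_features",
    "impute_knn",
    "pqn_normalize",
    "od_regress_out",
    "log_scale_and_aggregate",
    "growth_state",
    "fold_changes",
    "studentize",
    "normalize_pipeline",
]

#: Header contract for sample CSV files: metadata columns, then metabolites.
METADATA_COLUMNS = [
    "strain",
    "population",
    "species",
    "group",
    "od_inoc",
    "od_samp",
    "od_stat",
    "batch",
    "is_qc",
]


@dataclass
class SampleTable:
    """Replicate × metabolite intensities plus per-sample metadata.

    ``data`` holds positive intensities (NaN allowed, meaning not detected);
    ``meta`` carries, per sample, the strain/population/species labels, the
    wild/domesticated group label, the OD triplet (inoculation, sampling,
    stationary), the measurement batch, and a QC flag for pooled-extract
    samples. Both frames share the sample index.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same sample index")
        missing = [c for c in METADATA_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be positive where present")
        bio = self.meta.loc[~self.meta["is_qc"].astype(bool)]
        od = bio[["od_inoc", "od_samp", "od_stat"]].dropna()
        bad = od[(od["od_inoc"] > od["od_samp"]) | (od["od_samp"] > od["od_stat"])]
        if len(bad):
            raise ValueError(f"OD triplet out of order for samples: {list(bad.index)}")

    # -- convenience ---------------------------------------------------------------

    @property
    def is_qc(self) -> pd.Series:
        return self.meta["is_qc"].astype(bool)

    @property
    def bio(self) -> pd.DataFrame:
        """Intensity rows of biological (non-QC) samples."""
        return self.data.loc[~self.is_qc]

    @property
    def qc(self) -> pd.DataFrame:
        return self.data.loc[self.is_qc]

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def replace_data(self, data: pd.DataFrame) -> "SampleTable":
        return SampleTable(data=data, meta=self.meta.loc[data.index].copy())

    # -- CSV round trip ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta[METADATA_COLUMNS], self.data], axis=1)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleTable":
        raw = pd.read_csv(path, index_col="sample_id")
        raw.index.name = None
        meta = raw[METADATA_COLUMNS].copy()
        meta["is_qc"] = meta["is_qc"].astype(bool)
        data = raw.drop(columns=METADATA_COLUMNS).astype(float)
        return cls(data=data, meta=meta)


@dataclass
class ProfileTable:
    """Aggregated log-scale metabolite profiles (strain, population or species)."""

    levels: pd.DataFrame  # label × metabolite, natural-log scale
    aggregation: Literal["strain", "population", "species"] = "strain"

    def __post_init__(self) -> None:
        if self.levels.isna().any().any():
            raise ValueError("ProfileTable must be complete (impute first)")

    @property
    def labels(self) -> list[str]:
        return list(self.levels.index)

    def to_csv(self, path: str | Path) -> None:
        self.levels.to_csv(path, index_label=self.aggregation)


# ---------------------------------------------------------------------------------
# feature filtering (non-targeted channel)
# ---------------------------------------------------------------------------------


def _detected(frame: pd.DataFrame) -> pd.DataFrame:
    """Detection mask: present (non-missing) and strictly positive."""
    return frame.notna() & (frame > 0)


def filter_untargeted_features(
    table: SampleTable,
    qc_detect_min: float = 0.875,
    cv_max: float = 0.25,
    sample_detect_min: float = 0.90,
) -> tuple[SampleTable, pd.DataFrame]:
    """Apply the three QC-based feature filters of flow-injection metabolomics.

    A feature (putative metabolite) is retained iff it is

    1. detected in at least ``qc_detect_min`` of pooled-extract (QC) samples
       (inclusive threshold),
    2. has a coefficient of variation of its QC peak areas strictly below
       ``cv_max`` (computed as SD/mean on the linear scale), and
    3. is detected in at least ``sample_detect_min`` of biological samples.

    Returns the filtered table and a per-feature report with the measured
    rates and pass/fail flags.
    """
    for name, value in [("qc_detect_min", qc_detect_min), ("cv_max", cv_max),
                        ("sample_detect_min", sample_detect_min)]:
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    qc = table.qc
    if qc.empty:
        raise ValueError(
            "no QC samples present; pass a table with pooled-extract samples "
            "or disable the QC criteria explicitly"
        )
    bio = table.bio
    qc_rate = _detected(qc).mean(axis=0)
    bio_rate = _detected(bio).mean(axis=0)
    qc_cv = qc.std(axis=0, ddof=1) / qc.mean(axis=0)
    report = pd.DataFrame(
        {
            "qc_detection_rate": qc_rate,
            "qc_cv": qc_cv,
            "bio_detection_rate": bio_rate,
            "pass_qc_detection": qc_rate >= qc_detect_min,
            "pass_cv": qc_cv < cv_max,
            "pass_bio_detection": bio_rate >= sample_detect_min,
        }
    )
    report["retained"] = (
        report["pass_qc_detection"] & report["pass_cv"] & report["pass_bio_detection"]
    )
    kept = report.index[report["retained"]]
    return table.replace_data(table.data[kept]), report


# ---------------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------------


def impute_knn(table: SampleTable, k: int = 5) -> SampleTable:
    """Impute missing intensities by k-nearest-neighbour averaging.

    Neighbours are samples; distances are Euclidean over the log intensities
    of shared (mutually observed) features; each missing entry becomes the
    mean of its k nearest neighbours' values for that feature. Observed
    entries are never modified. Deterministic for fixed k.
    """
    data = table.data
    if data.notna().sum(axis=1).eq(0).any():
        empty = list(data.index[data.notna().sum(axis=1) == 0])
        raise ValueError(f"samples with all values missing cannot be imputed: {empty}")
    if not data.isna().any().any():
        return table.replace_data(data.copy())
    logged = np.log(data.to_numpy(dtype=float))
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(logged)
    out = pd.DataFrame(np.exp(filled), index=data.index, columns=data.columns)
    out[data.notna()] = data
    return table.replace_data(out)


# ---------------------------------------------------------------------------------
# PQN
# ---------------------------------------------------------------------------------


def pqn_normalize(table: SampleTable) -> tuple[SampleTable, pd.Series]:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-metabolite median over biological
    samples; each sample's quotient factor is the median over metabolites of
    (sample / reference), and the sample is divided by that factor. This
    removes multiplicative biomass/dilution differences between replicates.

    Returns the normalized table and the per-sample quotient factors.
    """
    data = table.data
    if data.isna().any().any():
        raise ValueError("PQN requires a complete table; impute first")
    reference = table.bio.median(axis=0)
    if (reference <= 0).any():
        bad = list(reference.index[reference <= 0])
        raise ValueError(f"non-positive reference median for metabolites: {bad}")
    quotients = data.div(reference, axis=1)
    factors = quotients.median(axis=1)
    normalized = data.div(factors, axis=0)
    return table.replace_data(normalized), factors.rename("pqn_factor")


# ---------------------------------------------------------------------------------
# OD regression
# ---------------------------------------------------------------------------------


def od_regress_out(
    table: SampleTable, scale: Literal["log", "linear"] = "log"
) -> SampleTable:
    """Remove growth-linked intensity trends by regression on OD at sampling.

    Per metabolite, ordinary least squares of intensity (log scale by
    default) on ``od_samp`` across biological samples; the output is the
    residual plus the fitted value at the mean OD, so each metabolite's mean
    level is preserved and a re-fit on the output has slope 0. QC samples
    (which have no OD reading) pass through unchanged.
    """
    data = table.data
    if data.isna().any().any():
        raise ValueError("OD regression requires a complete table; impute first")
    bio_mask = ~table.is_qc
    od = table.meta.loc[bio_mask, "od_samp"].to_numpy(dtype=float)
    if np.isnan(od).any():
        raise ValueError("od_samp missing for some biological samples")
    if np.ptp(od) == 0:
        warnings.warn("OD constant across samples; regression skipped", stacklevel=2)
        return table.replace_data(data.copy())
    values = data.loc[bio_mask].to_numpy(dtype=float)
    y = np.log(values) if scale == "log" else values
    od_c = od - od.mean()
    slope = od_c @ (y - y.mean(axis=0)) / (od_c @ od_c)
    corrected = y - np.outer(od_c, slope)
    out_bio = np.exp(corrected) if scale == "log" else corrected
    out = data.copy()
    out.loc[bio_mask] = out_bio
    return table.replace_data(out)


# ---------------------------------------------------------------------------------
# aggregation / derived quantities
# ---------------------------------------------------------------------------------


def log_scale_and_aggregate(
    table: SampleTable, level: Literal["strain", "population", "species"] = "strain"
) -> ProfileTable:
    """Natural-log the normalized intensities and average hierarchically.

    Replicates are averaged within strain first; strain profiles are then
    averaged within population (and populations within species) when a
    coarser level is requested, so every strain contributes equally to its
    population regardless of replicate count.
    """
    bio = table.bio
    if bio.isna().any().any():
        raise ValueError("aggregation requires a complete table; impute first")
    meta = table.meta.loc[bio.index]
    logged = np.log(bio)
    by_strain = logged.groupby(meta["strain"]).mean()
    if by_strain.index.hasnans or (by_strain.index == "").any():
        raise ValueError("every biological sample must carry a strain label")
    if level == "strain":
        return ProfileTable(levels=by_strain, aggregation="strain")
    strain_meta = meta.drop_duplicates("strain").set_index("strain")
    if level == "population":
        grouping = strain_meta.loc[by_strain.index, "population"]
        return ProfileTable(levels=by_strain.groupby(grouping).mean(),
                            aggregation="population")
    if level == "species":
        pop_levels = log_scale_and_aggregate(table, "population").levels
        pop_meta = strain_meta.drop_duplicates("population").set_index("population")
        grouping = pop_meta.loc[pop_levels.index, "species"]
        return ProfileTable(levels=pop_levels.groupby(grouping).mean(),
                            aggregation="species")
    raise ValueError(f"unknown aggregation level {level!r}")


def growth_state(od_inoc: float, od_samp: float, od_stat: float) -> float:
    """Fraction of the growth curve completed at sampling.

    Defined as (OD at sampling − OD at inoculation) / OD at stationary phase.
    """
    od_stat = np.asarray(od_stat, dtype=float)
    if np.any(od_stat <= 0):
        raise ValueError("stationary-phase OD must be positive")
    return (np.asarray(od_samp, dtype=float) - np.asarray(od_inoc, dtype=float)) / od_stat


def fold_changes(profiles: ProfileTable) -> pd.DataFrame:
    """Per-metabolite fold changes against the median label average.

    Profiles are exponentiated back to the linear scale; each label's value
    is divided by the median across labels, so the reference point is the
    typical label rather than any single one.
    """
    linear = np.exp(profiles.levels)
    med = linear.median(axis=0)
    if (med == 0).any():
        raise ValueError("zero median level; cannot form fold changes")
    return linear.div(med, axis=1)


def studentize(profiles: ProfileTable) -> pd.DataFrame:
    """Z-score each metabolite across labels (mean 0, sample SD 1)."""
    levels = profiles.levels
    if len(levels) < 2:
        raise ValueError("studentization needs at least two labels")
    sd = levels.std(axis=0, ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance metabolites cannot be studentized: {list(flat)}")
    return levels.sub(levels.mean(axis=0), axis=1).div(sd, axis=1)


# ---------------------------------------------------------------------------------
# pipeline wrapper
# ---------------------------------------------------------------------------------


def normalize_pipeline(
    table: SampleTable,
    channel: Literal["targeted", "untargeted"] = "targeted",
    level: Literal["strain", "population", "species"] = "strain",
    knn_k: int = 5,
    od_scale: Literal["log", "linear"] = "log",
) -> tuple[ProfileTable, dict]:
    """Run the full normalization chain and return aggregated profiles.

    Untargeted tables pass through the QC feature filters and kNN imputation
    first; targeted tables (complete by construction) skip straight to PQN.
    The report records which features were dropped and the PQN factors.
    """
    report: dict = {"channel": channel, "level": level}
    if channel == "untargeted":
        table, feature_report = filter_untargeted_features(table)
        report["feature_filter"] = feature_report
        table = impute_knn(table, k=knn_k)
    elif table.data.isna().any().any():
        raise ValueError("targeted channel must be complete")
    table, factors = pqn_normalize(table)
    report["pqn_factors"] = factors
    table = od_regress_out(table, scale=od_scale)
    profiles = log_scale_and_aggregate(table, level=level)
    return profiles, report
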