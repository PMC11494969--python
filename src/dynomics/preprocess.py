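"""Normalization, scaling, filtering, smoothing, and resampling of
longitudinal multi-omic abundance tables.

The pipeline mirrors the standard preparation of longitudinal microbiome
multi-omics: per-sample relative-abundance normalization within each omic
type, rescaling of gene and metabolite intensities onto the taxa scale (their
raw means are orders of magnitude smaller because there are many more of
them), removal of unannotated or near-constant metabolites, removal of
subjects with too few time points in any omic layer, and B-spline smoothing
with resampling onto a regular grid (default 7 days) to cope with irregular
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import DegenerateGroupError, DynomicsError
from .network import EntityRef, OMIC_TYPES, allowed_entity_types

#: Long-format columns of an omics table.
COLUMNS = ("subject", "time", "entity", "omic_type", "value", "has_compound_id")

#: Omic types that are normalized / counted as measurement layers.
MEASURED_TYPES = ("taxon", "gene", "metabolite")


@dataclass
class OmicsDataset:
    """Long-format longitudinal measurements: one row per (subject, time, entity).

    ``has_compound_id`` marks metabolites carrying a compound-database
    annotation (e.g., an HMDB identifier); it is True for every non-metabolite
    row.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns and c != "has_compound_id"]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if "has_compound_id" not in df.columns:
            df = df.assign(has_compound_id=True)
        df = df.loc[:, list(COLUMNS)].copy()
        df["subject"] = df["subject"].astype(str)
        df["entity"] = df["entity"].astype(str)
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        df["has_compound_id"] = df["has_compound_id"].astype(bool)
        bad_type = set(df["omic_type"].unique()) - set(OMIC_TYPES)
        if bad_type:
            raise ValueError(f"unknown omic types {sorted(bad_type)}")
        if not np.isfinite(df["value"]).all():
            raise ValueError("values must be finite")
        if (df["value"] < 0).any():
            raise ValueError("values must be non-negative")
        dup = df.duplicated(subset=["subject", "time", "entity"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (subject, time, entity) triple: "
                f"({first['subject']}, {first['time']}, {first['entity']})"
            )
        df = df.sort_values(["subject", "time", "omic_type", "entity"], kind="mergesort")
        self.frame = df.reset_index(drop=True)

    # -- convenience accessors ------------------------------------------------

    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    def entities(self) -> list[EntityRef]:
        pairs = self.frame[["entity", "omic_type"]].drop_duplicates()
        return sorted(EntityRef(n, t) for n, t in pairs.itertuples(index=False))

    def omic_types(self) -> list[str]:
        return sorted(self.frame["omic_type"].unique())

    def restrict_to_subset(self, subset_label: str) -> "OmicsDataset":
        """Keep only entities whose omic type belongs to the subset (clinical kept)."""
        keep = self.frame["omic_type"].isin(allowed_entity_types(subset_label))
        return OmicsDataset(self.frame.loc[keep])

    def subject_frame(self, subject: str) -> pd.DataFrame:
        return self.frame[self.frame["subject"] == subject]

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "OmicsDataset":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


def normalize_per_omic(ds: OmicsDataset) -> OmicsDataset:
    """Convert each omic type to relative abundances within every sample.

    Within every (subject, time point, omic type) group the values are divided
    by their sum, so each type separately adds up to 1 per sample.  Clinical
    variables are left untouched.  A group with no positive value is
    degenerate and raises.
    """
    df = ds.frame.copy()
    measured = df["omic_type"].isin(MEASURED_TYPES)
    grp = df.loc[measured].groupby(["subject", "time", "omic_type"], sort=False)["value"]
    sums = grp.transform("sum")
    if (sums <= 0).any():
        bad = df.loc[measured].loc[sums.index[sums <= 0][0]]
        raise DegenerateGroupError(
            f"all-zero group (subject={bad['subject']}, time={bad['time']}, "
            f"omic_type={bad['omic_type']})"
        )
    df.loc[measured, "value"] = df.loc[measured, "value"] / sums
    return OmicsDataset(df)


def scale_to_taxa_mean(ds: OmicsDataset) -> OmicsDataset:
    """Rescale gene and metabolite intensities onto the taxa scale.

    One global multiplier per omic type brings the overall gene mean and the
    overall metabolite mean to equal the overall taxa mean; taxa and clinical
    values are unchanged.
    """
    df = ds.frame.copy()
    taxa = df.loc[df["omic_type"] == "taxon", "value"]
    if taxa.empty:
        raise DynomicsError("dataset contains no taxon entities to scale against")
    target = taxa.mean()
    for omic in ("gene", "metabolite"):
        mask = df["omic_type"] == omic
        if not mask.any():
            continue
        mean = df.loc[mask, "value"].mean()
        if mean == 0:
            raise DynomicsError(f"cannot scale {omic}s: their mean is zero")
        df.loc[mask, "value"] *= target / mean
    return OmicsDataset(df)


def filter_metabolites(ds: OmicsDataset, variance_threshold: float = 1e-8) -> OmicsDataset:
    """Drop metabolites without a compound annotation or with near-zero variance.

    Variance is pooled over all originally sampled values of the entity
    (across subjects and time points).  Other omic types are untouched.
    """
    if variance_threshold < 0:
        raise ValueError("variance_threshold must be >= 0")
    df = ds.frame
    met = df[df["omic_type"] == "metabolite"]
    if met.empty:
        return OmicsDataset(df)
    drop: set[str] = set(met.loc[~met["has_compound_id"], "entity"])
    variances = met.groupby("entity")["value"].var(ddof=0)
    drop |= set(variances.index[variances < variance_threshold])
    keep = ~((df["omic_type"] == "metabolite") & df["entity"].isin(drop))
    return OmicsDataset(df.loc[keep])


def filter_subjects(ds: OmicsDataset, min_timepoints: int = 5) -> OmicsDataset:
    """Drop subjects with fewer than ``min_timepoints`` samples in any measured layer.

    A subject is removed if, for *any* measured omic type present in the
    dataset, it has fewer than the required number of distinct time points.
    """
    if min_timepoints < 1:
        raise ValueError("min_timepoints must be >= 1")
    df = ds.frame
    if df.empty:
        return OmicsDataset(df)
    present = [t for t in MEASURED_TYPES if (df["omic_type"] == t).any()]
    counts = (
        df[df["omic_type"].isin(present)]
        .groupby(["subject", "omic_type"])["time"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=present, fill_value=0)
    )
    ok = counts.ge(min_timepoints).all(axis=1)
    keep_subjects = set(ok.index[ok])
    return OmicsDataset(df[df["subject"].isin(keep_subjects)])


# Interpolating spline below this many points, penalized fit above.
_INTERPOLATE_MAX_POINTS = 8


def fit_series_spline(times: np.ndarray, values: np.ndarray):
    """Cubic spline fit of one series: interpolating when short, penalized (GCV) when long."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="mergesort")
    times, values = times[order], values[order]
    if len(times) < 4:
        raise DynomicsError(f"series has {len(times)} points; cubic smoothing needs at least 4")
    if len(times) <= _INTERPOLATE_MAX_POINTS:
        return CubicSpline(times, values)
    return make_smoothing_spline(times, values)  # lam chosen by GCV


def smooth_and_resample(ds: OmicsDataset, interval_days: float = 7.0) -> OmicsDataset:
    """Replace every (subject, entity) series by a cubic B-spline evaluated on a
    regular grid with the requested spacing.

    The grid spans the subject's observed time range (shared across the
    subject's entities so transition rows stay aligned); fitted values below
    zero are clipped to 0.  Series with fewer than four points raise, listing
    the offending series.
    """
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    df = ds.frame
    too_short: list[str] = []
    rows: list[pd.DataFrame] = []
    for subject, sub in df.groupby("subject", sort=True):
        t0, t1 = sub["time"].min(), sub["time"].max()
        n_steps = int(np.floor((t1 - t0) / interval_days + 1e-9))
        if n_steps > 1_000_000:
            raise DynomicsError(
                f"subject {subject!r}: resampling span {t1 - t0:g} days at "
                f"{interval_days:g}-day spacing would produce {n_steps + 1} points"
            )
        grid = t0 + interval_days * np.arange(n_steps + 1)
        for (entity, omic, has_id), series in sub.groupby(
            ["entity", "omic_type", "has_compound_id"], sort=True
        ):
            if series["time"].nunique() < 4:
                too_short.append(f"{subject}/{entity}")
                continue
            spline = fit_series_spline(series["time"].to_numpy(), series["value"].to_numpy())
            fitted = np.clip(spline(grid), 0.0, None)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "time": grid,
                        "entity": entity,
                        "omic_type": omic,
                        "value": fitted,
                        "has_compound_id": has_id,
                    }
                )
            )
    if too_short:
        raise DynomicsError(
            "series too short for cubic smoothing (need >= 4 time points): "
            + ", ".join(too_short)
        )
    if not rows:
        return OmicsDataset(df.iloc[0:0])
    return OmicsDataset(pd.concat(rows, ignore_index=True))


def preprocess(
    ds: OmicsDataset,
    min_timepoints: int = 5,
    variance_threshold: float = 1e-8,
    scale: bool = True,
) -> OmicsDataset:
    """Normalization, scaling, and filtering in the standard order.

    Smoothing/resampling is kept separate because temporal alignment sits
    between filtering and resampling in the full pipeline.
    """
    out = normalize_per_omic(ds)
    if scale and (out.frame["omic_type"] == "taxon").any():
        out = scale_to_taxa_mean(out)
    out = filter_metabolites(out, variance_threshold)
    out = filter_subjects(out, min_timepoints)
    return out
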