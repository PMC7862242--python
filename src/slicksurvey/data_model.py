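"""Survey data model: tows, counts, taxa and debris tables.

The unit of observation is a single surface neuston tow, labelled either
``slick`` (inside a surface convergence slick) or ``ambient`` (nearby open
water). Counts are standardized to densities by dividing by the volume of
water filtered by the net, so every comparison downstream is on individuals
per cubic metre (debris on mg per cubic metre).

All tables are plain :class:`pandas.DataFrame` objects read from / written to
headered CSV files; :class:`Survey` bundles the four tables and validates
cross-references between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HABITATS = ("slick", "ambient")
GEARS = ("ring_net_1m", "ik_trawl")
NATAL_HABITATS = ("coral_reef", "epipelagic", "deep_water", "other")
FUNCTIONAL_GROUPS = ("fish", "invertebrate_larva", "holozooplankton", "egg", "insect")
DEBRIS_CATEGORIES = ("plastic", "organic")

#: Required columns per table (CSV header names).
TOW_COLUMNS = ["tow_id", "habitat", "site", "volume_filtered_m3"]
TOW_OPTIONAL = [
    "pair_id", "date", "minutes_from_solar_noon", "year", "gear",
    "tow_length_m", "distance_to_shore_m", "sampling_order", "day",
]
COUNT_COLUMNS = ["tow_id", "taxon_id", "count"]
COUNT_OPTIONAL = ["life_stage", "total_length_mm"]
TAXON_COLUMNS = ["taxon_id", "family", "natal_habitat", "functional_group"]
TAXON_OPTIONAL = ["rank", "fishery_flag"]
DEBRIS_COLUMNS = ["tow_id", "category", "dry_weight_mg"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Table contents violate a survey invariant (e.g. non-positive volume)."""


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


@dataclass
class Survey:
    """The four cross-referenced survey tables.

    Attributes
    ----------
    tows : per-tow metadata (habitat, site, volume filtered, ...)
    counts : per-tow, per-taxon counts; fish rows may carry total_length_mm
    taxa : taxonomy / ecology annotations for every taxon_id
    debris : per-tow dry weights (mg) by category (plastic / organic)
    """

    tows: pd.DataFrame
    counts: pd.DataFrame
    taxa: pd.DataFrame
    debris: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.tows, TOW_COLUMNS, "tows")
        _require_columns(self.counts, COUNT_COLUMNS, "counts")
        _require_columns(self.taxa, TAXON_COLUMNS, "taxa")
        if len(self.debris):
            _require_columns(self.debris, DEBRIS_COLUMNS, "debris")

        bad_hab = set(self.tows["habitat"]) - set(HABITATS)
        if bad_hab:
            raise ValidationError(f"unknown habitat labels: {sorted(bad_hab)}")
        vol = pd.to_numeric(self.tows["volume_filtered_m3"], errors="coerce")
        nonpos = self.tows.loc[~(vol > 0), "tow_id"].tolist()
        if nonpos:
            raise ValidationError(
                f"non-positive volume_filtered_m3 for tows: {nonpos}"
            )
        if self.tows["tow_id"].duplicated().any():
            dup = self.tows.loc[self.tows["tow_id"].duplicated(), "tow_id"].tolist()
            raise ValidationError(f"duplicate tow_id values: {dup}")

        known_tows = set(self.tows["tow_id"])
        orphan = set(self.counts["tow_id"]) - known_tows
        if orphan:
            raise ValidationError(f"count rows reference unknown tows: {sorted(orphan)}")
        known_taxa = set(self.taxa["taxon_id"])
        orphan_tax = set(self.counts["taxon_id"]) - known_taxa
        if orphan_tax:
            raise ValidationError(
                f"count rows reference unknown taxa: {sorted(orphan_tax)}"
            )
        counts = pd.to_numeric(self.counts["count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise ValidationError("counts must be non-negative numbers")
        if len(self.debris):
            orphan_d = set(self.debris["tow_id"]) - known_tows
            if orphan_d:
                raise ValidationError(
                    f"debris rows reference unknown tows: {sorted(orphan_d)}"
                )
            if (pd.to_numeric(self.debris["dry_weight_mg"], errors="coerce") < 0).any():
                raise ValidationError("debris dry weights must be >= 0")
            bad_cat = set(self.debris["category"]) - set(DEBRIS_CATEGORIES)
            if bad_cat:
                raise ValidationError(f"unknown debris categories: {sorted(bad_cat)}")

    # -- convenience accessors -------------------------------------------
    @property
    def tow_ids(self) -> list[str]:
        return self.tows["tow_id"].tolist()

    @property
    def habitat(self) -> pd.Series:
        """Habitat label per tow, indexed by tow_id."""
        return self.tows.set_index("tow_id")["habitat"]

    @property
    def volumes(self) -> pd.Series:
        return self.tows.set_index("tow_id")["volume_filtered_m3"].astype(float)

    def n_tows(self, habitat: str | None = None) -> int:
        if habitat is None:
            return len(self.tows)
        return int((self.tows["habitat"] == habitat).sum())

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the four tables as CSV into ``out_dir``; return the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("tows", self.tows), ("counts", self.counts),
            ("taxa", self.taxa), ("debris", self.debris),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def load_survey(
    tow_path: str | Path,
    count_path: str | Path,
    taxon_path: str | Path,
    debris_path: str | Path | None = None,
) -> Survey:
    """Read the four survey CSVs and return a validated :class:`Survey`.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for contents that violate invariants
    (non-positive volumes, unknown tow or taxon ids, negative counts).
    """
    tows = pd.read_csv(tow_path)
    counts = pd.read_csv(count_path)
    taxa = pd.read_csv(taxon_path)
    if debris_path is not None:
        try:
            debris = pd.read_csv(debris_path)
        except pd.errors.EmptyDataError:
            debris = pd.DataFrame()
    else:
        debris = pd.DataFrame()
    return Survey(tows=tows, counts=counts, taxa=taxa, debris=debris)


@dataclass
class DensityMatrix:
    """Groups x tows matrix of densities (individuals m^-3, or mg m^-3).

    ``data`` has one row per taxon/group and one column per tow; ``habitat``
    is the slick/ambient label aligned to the columns.
    """

    data: pd.DataFrame
    habitat: pd.Series

    def __post_init__(self) -> None:
        self.habitat = self.habitat.reindex(self.data.columns)
        if self.habitat.isna().any():
            missing = self.habitat.index[self.habitat.isna()].tolist()
            raise ValidationError(f"no habitat label for tows: {missing}")
        if (self.data.values < 0).any():
            raise ValidationError("densities must be >= 0")

    @property
    def groups(self) -> list[str]:
        return self.data.index.tolist()

    def values_for(self, group: str, habitat: str) -> np.ndarray:
        """Density values of one group across all tows of one habitat."""
        cols = self.habitat.index[self.habitat == habitat]
        return self.data.loc[group, cols].to_numpy(dtype=float)

    def split(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(slick values, ambient values) for one group."""
        return self.values_for(group, "slick"), self.values_for(group, "ambient")

    def to_long(self) -> pd.DataFrame:
        """Tidy long format: (group, tow_id, habitat, density)."""
        long = (
            self.data.rename_axis("group")
            .reset_index()
            .melt(id_vars="group", var_name="tow_id", value_name="density")
        )
        long["habitat"] = long["tow_id"].map(self.habitat)
        return long[["group", "tow_id", "habitat", "density"]]


def compute_densities(
    survey: Survey, grouping: str = "taxon", subset: pd.DataFrame | None = None
) -> DensityMatrix:
    """Standardize counts to densities: count / volume filtered, per tow.

    ``grouping`` is one of ``taxon`` (raw taxon_id rows), ``family``,
    ``functional_group`` or ``natal_habitat``; counts of member taxa are
    summed per tow before dividing by the tow volume (equivalently after —
    the operation is linear). Tows with no counts for a group get density 0.

    ``subset`` optionally replaces ``survey.counts`` (e.g. counts restricted
    to a size class) while keeping all tows as columns.
    """
    counts = survey.counts if subset is None else subset
    if grouping == "taxon":
        key = counts["taxon_id"]
    else:
        if grouping not in survey.taxa.columns:
            raise SchemaError(f"grouping column {grouping!r} absent from taxa table")
        lookup = survey.taxa.set_index("taxon_id")[grouping]
        key = counts["taxon_id"].map(lookup)
    wide = (
        counts.assign(_group=key)
        .groupby(["_group", "tow_id"], sort=True)["count"]
        .sum()
        .unstack(fill_value=0)
        .reindex(columns=survey.tow_ids, fill_value=0)
    )
    wide.index.name = "group"
    dens = wide.div(survey.volumes.reindex(wide.columns), axis=1).astype(float)
    return DensityMatrix(data=dens, habitat=survey.habitat)


def debris_densities(survey: Survey, include_total: bool = True) -> DensityMatrix:
    """Debris dry weight standardized to mg m^-3 per tow and category.

    With ``include_total`` a ``debris_all`` row (plastic + organic) is added.
    """
    if not len(survey.debris):
        raise ValidationError("survey has no debris table")
    wide = (
        survey.debris.groupby(["category", "tow_id"])["dry_weight_mg"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=survey.tow_ids, fill_value=0.0)
    )
    dens = wide.div(survey.volumes.reindex(wide.columns), axis=1).astype(float)
    dens.index = [f"debris_{c}" for c in dens.index]
    if include_total:
        dens.loc["debris_all"] = dens.sum(axis=0)
    dens.index.name = "group"
    return DensityMatrix(data=dens, habitat=survey.habitat)


def filter_common(
    matrix: DensityMatrix, min_tows: int = 4
) -> tuple[DensityMatrix, list[str], list[str]]:
    """Drop groups present (density > 0) in fewer than ``min_tows`` tows.

    Returns (filtered matrix, retained ids, excluded ids). Presence means a
    strictly positive density in a tow; the default threshold of 4 tows is
    the rarity cutoff used for all between-habitat comparisons.
    """
    if min_tows < 1:
        raise ValueError("min_tows must be >= 1")
    presence = (matrix.data > 0).sum(axis=1)
    keep = presence[presence >= min_tows].index.tolist()
    drop = presence[presence < min_tows].index.tolist()
    return (
        DensityMatrix(data=matrix.data.loc[keep], habitat=matrix.habitat),
        keep,
        drop,
    )


def classify_slick_associated(ratio_table: pd.DataFrame) -> pd.Series:
    """Label each group from its slick:ambient ratio.

    ``slick_exclusive`` — never recorded in ambient tows (requires an
    ``ambient_occurrences`` or ``mean_ambient`` column equal to zero);
    ``slick_associated`` — point ratio >= 2 (or slick-exclusive);
    ``not_associated`` — otherwise.
    """
    ratios = ratio_table["point_ratio"] if "point_ratio" in ratio_table else ratio_table["ratio_mean"]
    if "ambient_occurrences" in ratio_table:
        exclusive = ratio_table["ambient_occurrences"] == 0
    elif "mean_ambient" in ratio_table:
        exclusive = ratio_table["mean_ambient"] == 0
    else:
        exclusive = pd.Series(False, index=ratio_table.index)
    labels = pd.Series("not_associated", index=ratio_table.index, dtype=object)
    labels[ratios >= 2] = "slick_associated"
    labels[exclusive] = "slick_exclusive"
    labels.name = "slick_association"
    return labels


def relative_abundance_in_slicks(matrix: DensityMatrix) -> pd.Series:
    """Mean-density-weighted share of each group found in slicks.

    d̄_slick / (d̄_slick + d̄_ambient) per group, in [0, 1]. Groups absent
    from every tow are undefined and returned as NaN with a warning.
    """
    cols_s = matrix.habitat.index[matrix.habitat == "slick"]
    cols_a = matrix.habitat.index[matrix.habitat == "ambient"]
    mean_s = matrix.data[cols_s].mean(axis=1)
    mean_a = matrix.data[cols_a].mean(axis=1)
    total = mean_s + mean_a
    absent = total == 0
    if absent.any():
        warnings.warn(
            f"groups absent everywhere, relative abundance undefined: "
            f"{total.index[absent].tolist()}"
        )
    with np.errstate(invalid="ignore"):
        share = mean_s / total
    share.name = "relative_abundance_slick"
    return share
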