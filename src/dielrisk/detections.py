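"""Camera-trap image processing: independent detections and deer groups.

Remote cameras fire bursts of images; all images of one species at one
site separated by no more than a fixed gap (default 15 minutes between
consecutive images) are collapsed into a single independent detection
stamped with the first image's time.  Deer detections are classified into
demographic groups: any detection containing at least one fawn is a
nursery group; otherwise the presence of an adult female (then an adult
male) decides the class, and deer detections with no classified
individuals are flagged as excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError, EmptySelectionError

TWO_PI = 2.0 * np.pi

SPECIES = ("deer", "black_bear", "bobcat", "coyote", "wolf", "human", "other")
CARNIVORES = ("black_bear", "bobcat", "coyote", "wolf")
GROUPS = ("nursery_group", "adult_female", "adult_male", "not_deer")

IMAGE_COLUMNS = ["site_id", "species", "datetime",
                 "n_adult_female", "n_adult_male", "n_fawn"]

__all__ = [
    "SPECIES",
    "CARNIVORES",
    "GROUPS",
    "read_images",
    "collapse_detections",
    "classify_deer_group",
    "time_of_day_rad",
    "to_circular_times",
]


def time_of_day_rad(timestamps: pd.Series) -> np.ndarray:
    """Map local clock timestamps to angles: 2*pi * seconds-since-midnight / 86400."""
    ts = pd.to_datetime(timestamps)
    seconds = (
        ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
        + ts.dt.microsecond / 1e6
    )
    return (TWO_PI * seconds / 86400.0).to_numpy(dtype=float)


def read_images(path) -> pd.DataFrame:
    """Read a raw image table (CSV) and validate it record by record."""
    df = pd.read_csv(path)
    missing = set(IMAGE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"image table missing columns: {sorted(missing)}")
    return validate_images(df)


def validate_images(images: pd.DataFrame) -> pd.DataFrame:
    """Validate species vocabulary, counts, and timestamps.

    Unparseable timestamps are reported with their row position so the
    offending camera record can be found in the source file.
    """
    images = images.copy()
    bad_species = set(images["species"]) - set(SPECIES)
    if bad_species:
        raise DataError(f"unknown species labels: {sorted(bad_species)}")
    parsed = pd.to_datetime(images["datetime"], errors="coerce", format="mixed")
    if parsed.isna().any():
        rows = images.index[parsed.isna()].tolist()[:5]
        raise DataError(f"unparseable datetime at rows {rows}")
    images["datetime"] = parsed
    counts = images[["n_adult_female", "n_adult_male", "n_fawn"]]
    if (counts.to_numpy() < 0).any():
        raise DataError("negative deer counts")
    return images


def classify_deer_group(n_adult_female: int, n_adult_male: int,
                        n_fawn: int) -> tuple[str, bool]:
    """Demographic class of a deer detection from its composition counts.

    Returns ``(group, excluded)``.  Fawn presence dominates: any fawn makes
    the detection a nursery group regardless of the adults present.  A deer
    detection with all-zero counts cannot be classified and is excluded
    (flag, not an error).
    """
    if n_fawn >= 1:
        return "nursery_group", False
    if n_adult_female >= 1:
        return "adult_female", False
    if n_adult_male >= 1:
        return "adult_male", False
    return "not_deer", True  # unclassifiable deer: excluded from group analyses


def collapse_detections(images: pd.DataFrame, gap_minutes: float = 15.0) -> pd.DataFrame:
    """Collapse an image table into independent detection events.

    Within each (site, species) stream sorted by time, a new event starts
    whenever the gap from the *previous image* exceeds ``gap_minutes``
    (a gap of exactly ``gap_minutes`` continues the event, and chained
    images can extend an event beyond ``gap_minutes`` total).  The event is
    stamped with its first image's timestamp; deer composition counts are
    the per-image maxima over the event, so a fawn in any image makes the
    event a nursery group.

    Returns a DataFrame with columns site_id, species, group, excluded,
    timestamp, time_of_day_rad, n_adult_female, n_adult_male, n_fawn,
    n_images.  Empty input yields an empty frame with the same columns.
    """
    out_cols = ["site_id", "species", "group", "excluded", "timestamp",
                "time_of_day_rad", "n_adult_female", "n_adult_male",
                "n_fawn", "n_images"]
    if len(images) == 0:
        return pd.DataFrame(columns=out_cols)
    images = validate_images(images)
    images = images.sort_values(["site_id", "species", "datetime"],
                                kind="mergesort").reset_index(drop=True)

    gap = pd.Timedelta(minutes=gap_minutes)
    stream_change = (
        (images["site_id"] != images["site_id"].shift())
        | (images["species"] != images["species"].shift())
    )
    time_gap = images["datetime"].diff() > gap
    event_id = (stream_change | time_gap).cumsum()

    agg = images.groupby(event_id).agg(
        site_id=("site_id", "first"),
        species=("species", "first"),
        timestamp=("datetime", "first"),
        n_adult_female=("n_adult_female", "max"),
        n_adult_male=("n_adult_male", "max"),
        n_fawn=("n_fawn", "max"),
        n_images=("datetime", "size"),
    )
    groups, excluded = [], []
    for _, row in agg.iterrows():
        if row["species"] == "deer":
            g, ex = classify_deer_group(
                row["n_adult_female"], row["n_adult_male"], row["n_fawn"]
            )
        else:
            g, ex = "not_deer", False
        groups.append(g)
        excluded.append(ex)
    agg["group"] = groups
    agg["excluded"] = excluded
    agg["time_of_day_rad"] = time_of_day_rad(agg["timestamp"])
    return agg.reset_index(drop=True)[out_cols]


def to_circular_times(events: pd.DataFrame, species: str | None = None,
                      group: str | None = None,
                      include_excluded: bool = False) -> np.ndarray:
    """Time-of-day angles of the events matching a species/group filter.

    Raises :class:`EmptySelectionError` when nothing matches, so a caller
    cannot silently fit a density to zero detections.
    """
    sel = events
    if species is not None:
        allowed = CARNIVORES if species == "carnivores" else (species,)
        sel = sel[sel["species"].isin(allowed)]
    if group is not None:
        sel = sel[sel["group"] == group]
    if not include_excluded and "excluded" in sel.columns:
        sel = sel[~sel["excluded"].astype(bool)]
    if len(sel) == 0:
        raise EmptySelectionError(
            f"no events match species={species!r}, group={group!r}"
        )
    if "time_of_day_rad" in sel.columns:
        return sel["time_of_day_rad"].to_numpy(dtype=float) % TWO_PI
    return time_of_day_rad(sel["timestamp"])
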