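"""Histological quantification of cardiac wounds.

Implements the section-level morphometry used to track regeneration after
cryoinjury:

* open-wall percentage: 100 x (largest open compact-myocardium length over a
  fish's sections) / (largest ventricle perimeter), maxima taken
  independently per fish;
* wound-area percentage: 100 x (largest wound area) / (largest ventricle
  area), likewise;
* AFOG wound composition: the wound photo is split into R/G/B channels, red
  (fibrin) and blue (collagen) areas are thresholded with one setting for the
  whole experiment, and orange (muscle/other) is the remainder, so the three
  percentages sum to exactly 100;
* myocardial proliferation index: 100 x PCNA+Mef2+ / Mef2+ nuclei, pooled
  over at least three sections per fish within the border zone (the
  cardiomyocytes closest to the wound);
* region cell counts: double-positive cells tallied inside versus away from
  the wound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASUREMENT_COLUMNS = (
    "fish",
    "section",
    "perimeter_um",
    "open_wall_um",
    "wound_area_um2",
    "ventricle_area_um2",
)

REGIONS = ("wound", "ventricle")


@dataclass(frozen=True)
class AFOGThresholds:
    """Channel thresholds on [0, 1]; one setting for all hearts of an
    experiment.  The defaults are arbitrary mid-range values and should be
    calibrated to the staining batch."""

    red: float = 0.6
    blue: float = 0.6

    def __post_init__(self) -> None:
        for v, name in ((self.red, "red"), (self.blue, "blue")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} threshold {v} outside [0, 1]")


def _validate_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table missing columns {sorted(missing)}")
    m = measurements
    num = m[list(MEASUREMENT_COLUMNS[2:])]
    if (num < 0).any().any():
        raise ValueError("negative measurement values")
    if (m["open_wall_um"] > m["perimeter_um"]).any():
        raise ValueError("open wall length exceeds ventricle perimeter")
    if (m["wound_area_um2"] > m["ventricle_area_um2"]).any():
        raise ValueError("wound area exceeds ventricle area")
    return m


def _per_fish_ratio(
    measurements: pd.DataFrame,
    num_col: str,
    den_col: str,
    matched_sections: bool,
) -> pd.Series:
    m = _validate_measurements(measurements)
    out = {}
    for fish, grp in m.groupby("fish", sort=True):
        if matched_sections:
            # ratio taken on the section with the largest denominator
            row = grp.loc[grp[den_col].idxmax()]
            num, den = row[num_col], row[den_col]
        else:
            num, den = grp[num_col].max(), grp[den_col].max()
        if den == 0:
            raise ZeroDivisionError(f"fish {fish!r}: zero {den_col}")
        out[fish] = 100.0 * num / den
    return pd.Series(out, name=f"{num_col}_pct")


def open_wall_percentage(
    measurements: pd.DataFrame, matched_sections: bool = False
) -> pd.Series:
    """Percentage of the myocardial wall still open, per fish.

    Default: the largest open-wall length and the largest perimeter are taken
    independently across the fish's sections (they may come from different
    sections).  ``matched_sections`` instead uses the single section with the
    largest perimeter.
    """
    return _per_fish_ratio(
        measurements, "open_wall_um", "perimeter_um", matched_sections
    ).rename("open_wall_pct")


def wound_area_percentage(
    measurements: pd.DataFrame, matched_sections: bool = False
) -> pd.Series:
    """Wound size as a percentage of ventricle size, per fish (largest wound
    area over largest ventricle area)."""
    return _per_fish_ratio(
        measurements, "wound_area_um2", "ventricle_area_um2", matched_sections
    ).rename("wound_area_pct")


def afog_composition(
    image: np.ndarray,
    mask: np.ndarray,
    thresholds: AFOGThresholds | None = None,
) -> dict[str, float]:
    """Red/blue/orange area percentages of the wound mask.

    A pixel is red (fibrin) when its red channel exceeds the red threshold,
    blue (collagen) likewise on the blue channel; a pixel exceeding both is
    assigned to the channel with the larger threshold excess (ties to red),
    so the classes are disjoint.  Orange is the remainder:
    orange% = 100 - red% - blue% holds exactly.  Pixels outside the mask
    never contribute.
    """
    thresholds = thresholds or AFOGThresholds()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected RGB image, got shape {image.shape}")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty wound mask")
    r_exc = image[:, :, 0][mask] - thresholds.red
    b_exc = image[:, :, 2][mask] - thresholds.blue
    red = (r_exc > 0) & ((b_exc <= 0) | (r_exc >= b_exc))
    blue = (b_exc > 0) & ~red
    red_pct = 100.0 * red.sum() / area
    blue_pct = 100.0 * blue.sum() / area
    # complement of the combined red+blue share, so the three percentages
    # sum to exactly 100.0 in floating point
    return {
        "red_pct": red_pct,
        "blue_pct": blue_pct,
        "orange_pct": 100.0 - (red_pct + blue_pct),
    }


def proliferation_index(
    nuclei: pd.DataFrame,
    fish: str,
    zone: str = "border",
    pooled: bool = True,
) -> float:
    """Percentage of Mef2+ nuclei that are also PCNA+ for one fish in one
    zone (default the border zone), pooled over the fish's sections.

    ``pooled`` False averages per-section percentages instead.  Fewer than
    three sections triggers a warning (the protocol asks for at least three);
    zero Mef2+ nuclei is an error.
    """
    required = {"fish", "section", "zone", "mef2", "pcna"}
    if not required <= set(nuclei.columns):
        raise ValueError(f"nuclei table missing columns {sorted(required - set(nuclei.columns))}")
    sel = nuclei[(nuclei["fish"] == fish) & (nuclei["zone"] == zone)]
    n_sections = sel["section"].nunique()
    if n_sections < 3:
        warnings.warn(
            f"fish {fish!r}: only {n_sections} section(s) in zone {zone!r}; "
            "the protocol asks for at least three",
            stacklevel=2,
        )
    mef2 = sel[sel["mef2"].astype(bool)]
    if len(mef2) == 0:
        raise ValueError(f"fish {fish!r}: no Mef2+ nuclei in zone {zone!r}")
    if pooled:
        return 100.0 * float(mef2["pcna"].astype(bool).mean())
    per_section = mef2.groupby("section")["pcna"].apply(lambda s: 100.0 * s.astype(bool).mean())
    return float(per_section.mean())


def count_region_cells(
    double_positive: np.ndarray,
    regions: np.ndarray,
    samples: np.ndarray | None = None,
    allowed_regions: tuple[str, ...] = REGIONS,
) -> pd.DataFrame:
    """Tally double-positive cells per region (in or away from the wound),
    optionally split by sample."""
    double_positive = np.asarray(double_positive, dtype=bool)
    regions = np.asarray(regions, dtype=object).astype(str)
    if regions.shape[0] != double_positive.shape[0]:
        raise ValueError("regions misaligned with cells")
    unknown = set(regions) - set(allowed_regions)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}")
    if samples is None:
        samples = np.full(len(regions), "all", dtype=object)
    samples = np.asarray(samples, dtype=object).astype(str)
    idx = pd.Index(allowed_regions, name="region")
    tab = pd.crosstab(
        pd.Series(regions[double_positive], name="region"),
        pd.Series(samples[double_positive], name="sample"),
    )
    cols = pd.unique(samples)
    return tab.reindex(index=idx, columns=cols, fill_value=0)
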