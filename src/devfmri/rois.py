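"""Region-of-interest definitions: name, network, hemisphere, MNI sphere.

ROIs are carried around as a pandas DataFrame ("roi table") with columns
``name, network, hemisphere, x, y, z, radius_mm, bilateral_partner``.
Networks are ``ToM`` (theory-of-mind regions: bilateral TPJ, precuneus,
medial-prefrontal subdivisions, right STS), ``Pain`` (the pain matrix:
bilateral MFG, insula, secondary sensory cortex, dACC), ``M1`` (bilateral
primary motor cortex, used as a nuisance timecourse for connectivity), and
``other``.

The default table ships nominal MNI centers for use with the synthetic
generator and the optional sphere-extraction reader; the M1 centers are the
standard primary-motor peaks [38, -24, 58] / [-38, -20, 58].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ROI_COLUMNS = [
    "name",
    "network",
    "hemisphere",
    "x",
    "y",
    "z",
    "radius_mm",
    "bilateral_partner",
]

NETWORKS = ("ToM", "Pain", "M1", "other")


@dataclass(frozen=True)
class RoiDef:
    """A single spherical ROI in MNI space."""

    name: str
    network: str
    hemisphere: str  # L, R, or M (midline)
    center: tuple[float, float, float]
    radius_mm: float
    bilateral_partner: str | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"ROI {self.name}: radius must be positive")
        if self.network not in NETWORKS:
            raise ValueError(f"ROI {self.name}: unknown network {self.network}")
        if self.hemisphere not in ("L", "R", "M"):
            raise ValueError(f"ROI {self.name}: hemisphere must be L, R or M")


_DEFAULT_ROIS = [
    # ToM network: 9 mm spheres
    RoiDef("RTPJ", "ToM", "R", (54.0, -54.0, 24.0), 9.0, "LTPJ"),
    RoiDef("LTPJ", "ToM", "L", (-50.0, -60.0, 21.0), 9.0, "RTPJ"),
    RoiDef("PC", "ToM", "M", (0.0, -58.0, 38.0), 9.0),
    RoiDef("DMPFC", "ToM", "M", (0.0, 54.0, 24.0), 9.0),
    RoiDef("MMPFC", "ToM", "M", (0.0, 52.0, 6.0), 9.0),
    RoiDef("VMPFC", "ToM", "M", (0.0, 52.0, -12.0), 9.0),
    RoiDef("RSTS", "ToM", "R", (54.0, -18.0, -12.0), 9.0),
    # Pain matrix: 9 mm spheres
    RoiDef("RMFG", "Pain", "R", (44.0, 6.0, 32.0), 9.0, "LMFG"),
    RoiDef("LMFG", "Pain", "L", (-44.0, 4.0, 32.0), 9.0, "RMFG"),
    RoiDef("RInsula", "Pain", "R", (38.0, 2.0, 2.0), 9.0, "LInsula"),
    RoiDef("LInsula", "Pain", "L", (-36.0, 2.0, 2.0), 9.0, "RInsula"),
    RoiDef("RS2", "Pain", "R", (58.0, -20.0, 16.0), 9.0, "LS2"),
    RoiDef("LS2", "Pain", "L", (-58.0, -22.0, 16.0), 9.0, "RS2"),
    RoiDef("dACC", "Pain", "M", (0.0, 16.0, 38.0), 9.0),
    # Bilateral primary motor cortex: 10 mm spheres
    RoiDef("RM1", "M1", "R", (38.0, -24.0, 58.0), 10.0, "LM1"),
    RoiDef("LM1", "M1", "L", (-38.0, -20.0, 58.0), 10.0, "RM1"),
]


def roi_table(rois: list[RoiDef] | None = None) -> pd.DataFrame:
    """Build (and validate) a roi-table DataFrame from RoiDef records."""
    rois = list(rois) if rois is not None else list(_DEFAULT_ROIS)
    rows = [
        {
            "name": r.name,
            "network": r.network,
            "hemisphere": r.hemisphere,
            "x": r.center[0],
            "y": r.center[1],
            "z": r.center[2],
            "radius_mm": r.radius_mm,
            "bilateral_partner": r.bilateral_partner,
        }
        for r in rois
    ]
    table = pd.DataFrame(rows, columns=ROI_COLUMNS)
    validate_roi_table(table)
    return table


def default_roi_table() -> pd.DataFrame:
    """The 7 ToM + 7 pain + 2 M1 default ROI table."""
    return roi_table(None)


def validate_roi_table(table: pd.DataFrame) -> None:
    missing = [c for c in ROI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"roi table missing columns: {missing}")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate ROI names: {dupes}")
    if (table["radius_mm"] <= 0).any():
        raise ValueError("all ROI radii must be positive")
    by_name = table.set_index("name")
    for name, partner in zip(table["name"], table["bilateral_partner"]):
        if partner is None or (isinstance(partner, float) and pd.isna(partner)):
            continue
        if partner not in by_name.index:
            raise ValueError(f"ROI {name}: partner {partner} not in table")
        if by_name.loc[partner, "bilateral_partner"] != name:
            raise ValueError(
                f"bilateral partnership {name}<->{partner} is not symmetric"
            )


def network_rois(table: pd.DataFrame, network: str) -> list[str]:
    """ROI names belonging to ``network``, in table order."""
    return table.loc[table["network"] == network, "name"].tolist()


def bilateral_pairs(table: pd.DataFrame) -> list[tuple[str, str]]:
    """Unordered bilateral pairs (each reported once, L/R order as found)."""
    seen: set[frozenset[str]] = set()
    pairs = []
    for name, partner in zip(table["name"], table["bilateral_partner"]):
        if partner is None or (isinstance(partner, float) and pd.isna(partner)):
            continue
        key = frozenset((name, partner))
        if key not in seen:
            seen.add(key)
            pairs.append((name, partner))
    return pairs
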