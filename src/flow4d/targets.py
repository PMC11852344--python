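"""Published group-level haemodynamic targets used to calibrate synthetic cohorts.

These are the group means ± SD reported for a postoperative obstructive-HCM
feasibility cohort (three subjects per arm): patients after isolated septal
myectomy, patients after myectomy with anterior mitral-valve leaflet extension
(AMVLE), and healthy controls.  The phantom generator treats each column as
the ground-truth distribution from which per-subject targets are drawn.

Kinetic-energy densities are stored in J/m³, numerically equal to the values
the clinical tables print (their "mJ/m³" label is the conventional clinical
scale; ½ρv² at the printed magnitudes is consistent with J/m³ ≡ mJ/L).
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

#: Group → metric → (mean, sd).  Units: wss Pa, vpeak m/s, ke J/m³,
#: av/mv forward flow ml/beat, strain %.
STUDY_GROUPS: dict[str, dict[str, tuple[float, float]]] = {
    "isolated_myectomy": {
        "ke_lvot": (314.2, 62.0),
        "vpeak_lvot": (1.63, 0.3),
        "ke_aorta": (480.8, 68.0),
        "wss_aorta": (0.73, 0.1),
        "mv_forward": (84.0, 19.0),
        "av_forward": (63.0, 6.0),
        "strain_lvot": (-10.4, 3.7),
    },
    "myectomy_amvle": {
        "ke_lvot": (350.2, 106.0),
        "vpeak_lvot": (1.53, 0.02),
        "ke_aorta": (359.9, 51.0),
        "wss_aorta": (0.59, 0.04),
        "mv_forward": (74.0, 12.0),
        "av_forward": (90.0, 9.0),
        "strain_lvot": (-12.8, 1.7),
    },
    "healthy_control": {
        "ke_lvot": (345.4, 33.0),
        "vpeak_lvot": (1.25, 0.0),
        "ke_aorta": (345.4, 33.0),
        "wss_aorta": (0.47, 0.01),
        "mv_forward": (83.0, 13.0),
        "av_forward": (86.0, 21.0),
        "strain_lvot": (-15.1, 2.5),
    },
}

#: Reference group for percent-difference columns in the cohort report.
REFERENCE_GROUP = "isolated_myectomy"

#: Tube radii (mm) per group and segment.  LVOT radii follow the reported
#: LVOT diameters (18.8 / 15.9 / 19.6 mm).  Patient ascending aortas use a
#: 25 mm diameter; healthy controls use 28 mm — both within the normal adult
#: range, and the wider healthy aorta is required for the joint WSS/KE
#: calibration to admit a power-law solution (low WSS at moderate KE implies
#: a wide, blunt-profiled vessel).
GROUP_RADII_MM: dict[str, dict[str, float]] = {
    "isolated_myectomy": {"aorta": 12.5, "lvot": 9.4, "av": 12.5, "mv": 15.0},
    "myectomy_amvle": {"aorta": 12.5, "lvot": 7.95, "av": 12.5, "mv": 15.0},
    "healthy_control": {"aorta": 14.0, "lvot": 9.8, "av": 14.0, "mv": 15.0},
}

_METRICS = ("ke_lvot", "vpeak_lvot", "ke_aorta", "wss_aorta",
            "mv_forward", "av_forward", "strain_lvot")


def targets_frame() -> pd.DataFrame:
    """The target table as a tidy DataFrame (one row per group)."""
    rows = []
    for group, metrics in STUDY_GROUPS.items():
        row: dict = {"group": group}
        for m in _METRICS:
            row[m], row[f"sd_{m}"] = metrics[m]
        for seg, r in GROUP_RADII_MM[group].items():
            row[f"radius_{seg}_mm"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def write_targets_csv(path) -> None:
    targets_frame().to_csv(path, index=False)


def load_targets_csv(path) -> dict[str, dict[str, tuple[float, float]]]:
    """Read a targets table written by :func:`write_targets_csv`.

    Returns the same mapping layout as :data:`STUDY_GROUPS`; radius columns,
    when present, are returned under the key ``"_radii"`` of each group.
    """
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValidationError("targets table needs a 'group' column")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        metrics: dict = {}
        for m in _METRICS:
            if m in df.columns:
                metrics[m] = (float(row[m]), float(row.get(f"sd_{m}", 0.0)))
        radii = {
            col[len("radius_"):-len("_mm")]: float(row[col])
            for col in df.columns
            if col.startswith("radius_") and col.endswith("_mm")
        }
        if radii:
            metrics["_radii"] = radii
        out[str(row["group"])] = metrics
    return out
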