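"""Packaged cohort tables.

Four CSVs transcribe the porcine study cohort: animal profiles (weight,
heart rate, cardiac output, peak flow, PA surface area), per-animal vessel
geometry (segment lengths/diameters and the bifurcation angle), per-animal
paired pre/post wall hemodynamics, and per-device hemodynamics including
the trans-device pressure drop.

``NON_OPTIMAL_DEVICES`` records which of the 20 devices were classified as
non-optimally placed.  The grouping is fully determined for 7 of the 8
devices; the eighth (a device in the main pulmonary artery of Case 7,
with the published record ambiguous about which of the two) is assigned to
the LPA-listed column ("PAPS I") — the unique assignment consistent with
both published group means, verified arithmetically before release.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .boundary import AnimalProfile

#: (case, device-column) pairs of the 8 non-optimally placed sensors.
NON_OPTIMAL_DEVICES = frozenset(
    {
        ("Case 01", "PAPS I"),
        ("Case 01", "PAPS II"),
        ("Case 03", "PAPS I"),
        ("Case 03", "PAPS II"),
        ("Case 05", "PAPS II"),
        ("Case 06", "PAPS II"),
        ("Case 09", "PAPS II"),
        ("Case 07", "PAPS I"),
    }
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("pahemo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_profile_table() -> pd.DataFrame:
    """Animal weights and hemodynamic baselines (plus PA surface area)."""
    return _read("cohort_profiles.csv")


def load_animal_profiles() -> list[AnimalProfile]:
    df = load_profile_table()
    return [
        AnimalProfile(
            case_id=r["case"],
            weight_kg=float(r["weight_kg"]),
            hr_bpm=float(r["hr_bpm"]),
            co_lpm=float(r["co_lpm"]),
            qmax_mls=float(r["qmax_mls"]),
        )
        for _, r in df.iterrows()
    ]


def load_geometry_table() -> pd.DataFrame:
    """Per-animal MPA/RPA/LPA lengths, diameters and bifurcation angle."""
    return _read("cohort_geometry.csv")


def load_pa_hemodynamics_table() -> pd.DataFrame:
    """Paired pre/post wall hemodynamics per animal (TAWSS, OSI, areas)."""
    return _read("cohort_pa_hemodynamics.csv")


def load_device_hemodynamics_table(with_grouping: bool = True) -> pd.DataFrame:
    """Per-device hemodynamics; optionally adds the placement grouping."""
    df = _read("cohort_device_hemodynamics.csv")
    if with_grouping:
        df["placement"] = [
            "non-optimal" if (c, d) in NON_OPTIMAL_DEVICES else "optimal"
            for c, d in zip(df["case"], df["device"])
        ]
    return df
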