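"""Bioactivity-guided dereplication of microfractionated extracts.

A crude extract is chromatographically split into time-sliced fractions
(e.g. 159 fractions of ~7 s) that are assayed individually, so growth
inhibition maps onto retention-time windows.  Features detected inside active
windows are then matched by exact mass against a reference compound table:
theoretical adduct m/z values are computed from molecular formulas using
monoisotopic atomic masses, and a feature matches when its signed relative
mass deviation is within the tolerance (default +/- 2 ppm, inclusive).
Features with no reference match are flagged as candidate novel compounds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FractionScheme",
    "FractionPlate",
    "CompoundRecord",
    "DereplicationHit",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ion_mz",
    "ppm_error",
    "percent_inhibition",
    "call_active",
    "activity_windows",
    "fraction_rt_window",
    "read_compound_db",
    "read_plate_csv",
    "dereplicate",
]

# Most-abundant-isotope atomic masses (u), CODATA/AME2020.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Se": 79.9165213,
}
ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # hydrogen atom minus electron

# adduct -> (number of protons added, charge)
_ADDUCTS: dict[str, tuple[int, int]] = {
    "[M+H]+": (1, 1),
    "[M+2H]2+": (2, 2),
    "[M+3H]3+": (3, 3),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse a molecular formula like ``C26H46N2O8`` into element counts."""
    if isinstance(formula, dict):
        comp = dict(formula)
    else:
        comp: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            comp[m.group(1)] = comp.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    unknown = set(comp) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise ValueError(f"unsupported element(s) {sorted(unknown)}")
    if any(n < 0 for n in comp.values()):
        raise ValueError("element counts must be >= 0")
    return comp


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of most-abundant-isotope masses."""
    comp = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.items())


def adduct_mz(formula: str | dict[str, int], adduct: str = "[M+H]+") -> float:
    """Theoretical m/z of a protonated adduct: (M + n * m_proton) / n.

    Full precision is returned; round to 4 decimals for display.
    """
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}")
    n_protons, charge = _ADDUCTS[adduct]
    m = monoisotopic_mass(formula)
    return (m + n_protons * PROTON_MASS) / charge


def ion_mz(ion_formula: str | dict[str, int], charge: int = 1) -> float:
    """m/z of a cation given directly by its ion formula (electrons removed).

    E.g. the [M+H]+ ion of C26H46N2O8 has ion formula C26H47N2O8 and
    m/z = (sum of atomic masses - charge * m_e) / charge.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(ion_formula) - charge * ELECTRON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class FractionScheme:
    """Microfractionation layout: n fractions of fixed duration plus a crude
    (unfractionated) control applied as the last index + 1."""

    n_fractions: int = 159
    fraction_seconds: float = 7.0
    start_offset_s: float = 30.0
    crude_control_index: int = 160

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.fraction_seconds <= 0:
            raise ValueError("fraction_seconds must be > 0")


def fraction_rt_window(idx: int, scheme: FractionScheme) -> tuple[float, float]:
    """Half-open RT window [start, end) of a 1-based fraction index."""
    if idx == scheme.crude_control_index:
        raise ValueError(f"fraction {idx} is the crude-extract control, not a chromatographic fraction")
    if not 1 <= idx <= scheme.n_fractions:
        raise ValueError(f"fraction index {idx} outside 1..{scheme.n_fractions}")
    start = scheme.start_offset_s + (idx - 1) * scheme.fraction_seconds
    return (start, start + scheme.fraction_seconds)


@dataclass(frozen=True)
class FractionPlate:
    """Microplate readouts: per-well (role, raw readout) plus well -> fraction."""

    wells: dict[str, tuple[str, float]]  # well -> (role, readout)
    layout: dict[str, int]  # sample well -> fraction index

    ROLES = ("sample", "medium-control", "positive-control", "growth-control")

    def __post_init__(self) -> None:
        for w, (role, r) in self.wells.items():
            if role not in self.ROLES:
                raise ValueError(f"well {w}: unknown role {role!r}")
            if r < 0:
                raise ValueError(f"well {w}: negative readout")

    def control_mean(self, role: str) -> float:
        vals = [r for (ro, r) in self.wells.values() if ro == role]
        if not vals:
            raise ValueError(f"plate has no {role} wells")
        return float(np.mean(vals))


def percent_inhibition(
    raw: float, medium_ctrl: float, growth_ctrl: float
) -> tuple[float, bool]:
    """Growth inhibition in percent, normalised between the plate controls.

        100 * (growth_ctrl - raw) / (growth_ctrl - medium_ctrl)

    0% = uninhibited growth, 100% = readout at the sterile-medium level.
    Values are clipped to [-10, 110] to tame outliers; the second return value
    flags whether clipping occurred (growth promotion or super-inhibition are
    reported, not silently discarded).
    """
    if growth_ctrl <= medium_ctrl:
        raise ValueError(
            f"assay failure: growth control ({growth_ctrl}) must exceed medium control ({medium_ctrl})"
        )
    pct = 100.0 * (growth_ctrl - raw) / (growth_ctrl - medium_ctrl)
    clipped = pct < -10.0 or pct > 110.0
    return float(np.clip(pct, -10.0, 110.0)), clipped


def call_active(plate: FractionPlate, threshold: float = 70.0) -> dict:
    """Call bioactive fractions: percent inhibition >= threshold (inclusive).

    Returns a dict with per-fraction inhibition, the set of active fraction
    indices, and contiguous activity windows as (first, last) index pairs.
    """
    medium = plate.control_mean("medium-control")
    growth = plate.control_mean("growth-control")
    inhibition: dict[int, float] = {}
    for well, (role, raw) in plate.wells.items():
        if role != "sample":
            continue
        if well not in plate.layout:
            raise ValueError(f"sample well {well} missing from plate layout")
        frac = plate.layout[well]
        pct, _ = percent_inhibition(raw, medium, growth)
        # replicate wells of one fraction: average
        if frac in inhibition:
            inhibition[frac] = (inhibition[frac] + pct) / 2.0
        else:
            inhibition[frac] = pct
    active = sorted(f for f, pct in inhibition.items() if pct >= threshold)
    return {
        "inhibition": inhibition,
        "active": active,
        "windows": activity_windows(active),
        "threshold": threshold,
    }


def activity_windows(active: list[int]) -> list[tuple[int, int]]:
    """Collapse sorted active fraction indices into contiguous (first, last) runs."""
    windows: list[tuple[int, int]] = []
    for f in sorted(active):
        if windows and f == windows[-1][1] + 1:
            windows[-1] = (windows[-1][0], f)
        else:
            windows.append((f, f))
    return windows


@dataclass(frozen=True)
class CompoundRecord:
    """Reference database entry: compound name, formula, searchable adducts."""

    name: str
    formula: str
    adducts: tuple[str, ...] = ("[M+H]+",)

    def __post_init__(self) -> None:
        parse_formula(self.formula)  # validate eagerly
        for a in self.adducts:
            if a not in _ADDUCTS:
                raise ValueError(f"unsupported adduct {a!r} on {self.name}")


@dataclass(frozen=True)
class DereplicationHit:
    compound: str
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm: float
    fractions: tuple[int, ...]


def read_compound_db(path) -> list[CompoundRecord]:
    """Read compound CSV ``name,formula[,adducts]`` (adducts ';'-separated)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        adducts = (
            tuple(a.strip() for a in str(row["adducts"]).split(";"))
            if "adducts" in df.columns and pd.notna(row.get("adducts"))
            else ("[M+H]+",)
        )
        records.append(CompoundRecord(name=str(row["name"]), formula=str(row["formula"]), adducts=adducts))
    return records


def read_plate_csv(path) -> FractionPlate:
    """Read plate CSV ``well,role,fraction,readout`` (fraction blank for controls)."""
    df = pd.read_csv(path)
    wells, layout = {}, {}
    for _, row in df.iterrows():
        well = str(row["well"])
        wells[well] = (str(row["role"]), float(row["readout"]))
        if str(row["role"]) == "sample" and pd.notna(row["fraction"]):
            layout[well] = int(row["fraction"])
    return FractionPlate(wells=wells, layout=layout)


def dereplicate(
    features: pd.DataFrame,
    active_fractions: list[int],
    db: list[CompoundRecord],
    scheme: FractionScheme | None = None,
    tol_ppm: float = 2.0,
) -> tuple[list[DereplicationHit], pd.DataFrame]:
    """Match features inside active RT windows against the reference table.

    ``features`` needs columns rt_s, mz (intensity optional).  A feature in an
    active fraction window matches a (compound, adduct) pair when
    ``|ppm_error| <= tol_ppm`` (inclusive).  Hits are sorted by absolute ppm
    error; unmatched active-window features are returned as candidates for
    novel chemistry.
    """
    if not db:
        raise ValueError("reference database is empty")
    scheme = scheme or FractionScheme()
    windows = [fraction_rt_window(f, scheme) for f in active_fractions]
    frac_of = dict(zip(active_fractions, windows))

    # theoretical m/z per (compound, adduct), computed once
    theo = [
        (rec.name, adduct, adduct_mz(rec.formula, adduct))
        for rec in db
        for adduct in rec.adducts
    ]

    hits: list[DereplicationHit] = []
    unknown_rows = []
    for _, row in features.iterrows():
        rt, mz = float(row["rt_s"]), float(row["mz"])
        supporting = tuple(
            f for f, (lo, hi) in frac_of.items() if lo <= rt < hi
        )
        if not supporting:
            continue
        matched = False
        for name, adduct, tmz in theo:
            err = ppm_error(mz, tmz)
            if abs(err) <= tol_ppm:
                hits.append(
                    DereplicationHit(
                        compound=name, adduct=adduct, theoretical_mz=tmz,
                        observed_mz=mz, ppm=err, fractions=supporting,
                    )
                )
                matched = True
        if not matched:
            unknown_rows.append({"rt_s": rt, "mz": mz, "fractions": supporting,
                                 "status": "unknown - candidate novel"})
    hits.sort(key=lambda h: abs(h.ppm))
    return hits, pd.DataFrame(unknown_rows)
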