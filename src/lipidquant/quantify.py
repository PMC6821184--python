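"""Quantitation: internal-standard normalization, protein scaling, class
summation, fold changes, PUFA flagging, plasmalogen classification and
stable-isotope-dilution enzyme-activity calculation.

Intensities become relative molar abundances by ratio to the class internal
standard (IS) spiked at a known amount, then scaling by measured protein:

    value = intensity / IS_intensity * IS_nmol / protein_mg    [nmol/mg]

Classes without an IS are only protein-scaled and keep a ``rel_per_mg``
unit tag; the two unit families must never be summed together, and class
totals are not comparable across classes (species respond differently to
their standard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import DEFAULT_STANDARDS, LipidDatabase

__all__ = [
    "AbundanceMatrix",
    "EnzymeAssayRecord",
    "default_is_map",
    "normalize",
    "class_totals",
    "fold_changes",
    "flag_pufa",
    "classify_sn1_linkage",
    "classify_hydrolysis_table",
    "enzyme_activity",
]

UNIT_MOLAR = "nmol_per_mg"
UNIT_RELATIVE = "rel_per_mg"

PLASMANYL = "plasmanyl"
PLASMENYL = "plasmenyl"
INDETERMINATE = "indeterminate"


def default_is_map() -> Dict[str, Tuple[str, float]]:
    """Class -> (standard species name, spiked nmol).

    Ether classes are normalized on their diacyl class standard (no
    ether-specific standards are spiked).
    """
    is_map: Dict[str, Tuple[str, float]] = {}
    for cls, ((n, d), nmol) in DEFAULT_STANDARDS.items():
        name = f"{cls} {n}:{d}"
        is_map[cls] = (name, nmol)
        ether = f"{cls}[O]"
        if ether not in is_map:
            is_map[ether] = (name, nmol)
    return is_map


@dataclass
class AbundanceMatrix:
    """Species-by-sample abundances with unit provenance.

    ``values`` rows are species names; ``units`` tags each species
    ``nmol_per_mg`` (IS-normalized) or ``rel_per_mg`` (protein-scaled
    only); ``species_class`` gives the display class per species. Internal
    standards are excluded from the values. ``invalid`` lists
    (class, sample) pairs whose IS intensity was zero or missing.
    """

    values: pd.DataFrame
    units: pd.Series
    species_class: pd.Series
    is_map: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    invalid: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be >= 0")


def _entry_lookup(db: LipidDatabase) -> pd.DataFrame:
    rows = []
    for e in db:
        rows.append(
            {
                "entry_key": e.key,
                "species": e.species.name,
                "class": e.species.display_class,
                "carbons": e.species.carbons,
                "double_bonds": e.species.double_bonds,
                "is_standard": e.is_standard,
            }
        )
    return pd.DataFrame(rows).set_index("entry_key")


def normalize(
    corrected: pd.DataFrame,
    db: LipidDatabase,
    sample_meta: pd.DataFrame,
    is_map: Optional[Mapping[str, Tuple[str, float]]] = None,
) -> AbundanceMatrix:
    """Internal-standard normalization and protein scaling.

    ``corrected`` is the isotope-corrected species (entry_key) x sample
    matrix; ``sample_meta`` must provide ``protein_mg`` per sample. For
    classes covered by ``is_map`` values come out in nmol per mg protein;
    other classes are scaled by protein only. Samples whose class IS
    intensity is zero/missing are flagged invalid (NaN), not guessed.
    """
    if is_map is None:
        is_map = default_is_map()
    missing = set(corrected.columns) - set(sample_meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    protein = sample_meta.loc[corrected.columns, "protein_mg"].astype(float)
    bad = protein[protein <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive protein_mg for sample(s): {list(bad.index)}"
        )

    lookup = _entry_lookup(db).loc[corrected.index]
    by_species = corrected.copy()
    by_species.index = lookup["species"].to_numpy()

    # IS intensities per class
    std_rows = lookup[lookup["is_standard"]]
    std_intensity: Dict[str, pd.Series] = {}
    for key, row in std_rows.iterrows():
        std_intensity[row["species"]] = corrected.loc[key]

    values = {}
    units = {}
    classes = {}
    invalid: List[Tuple[str, str]] = []
    flagged = set()
    for key, row in lookup.iterrows():
        if row["is_standard"]:
            continue
        cls = row["class"]
        x = corrected.loc[key].astype(float)
        if cls in is_map and is_map[cls][0] in std_intensity:
            std_name, nmol = is_map[cls]
            is_int = std_intensity[std_name].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                v = x / is_int * nmol / protein
            zero = ~(is_int > 0)
            v[zero] = np.nan
            for s in is_int.index[zero]:
                if (cls, s) not in flagged:
                    invalid.append((cls, s))
                    flagged.add((cls, s))
            units[row["species"]] = UNIT_MOLAR
        else:
            v = x / protein
            units[row["species"]] = UNIT_RELATIVE
        values[row["species"]] = v
        classes[row["species"]] = cls
    frame = pd.DataFrame(values).T
    frame.index.name = "species"
    return AbundanceMatrix(
        values=frame,
        units=pd.Series(units, name="unit"),
        species_class=pd.Series(classes, name="class"),
        is_map=dict(is_map),
        invalid=invalid,
    )


def class_totals(abundance: AbundanceMatrix) -> pd.DataFrame:
    """Per-class arithmetic sums of member species, per sample.

    Unit tags propagate; mixing unit tags within one class is an error.
    The result's ``attrs`` record that totals are only comparable within a
    class between sample groups, never across classes (species respond
    unequally to their standard).
    """
    out_rows = {}
    units = {}
    for cls, members in abundance.species_class.groupby(abundance.species_class):
        names = members.index
        tags = set(abundance.units.loc[names])
        if len(tags) > 1:
            raise ValueError(f"class {cls} mixes unit tags {sorted(tags)}")
        out_rows[cls] = abundance.values.loc[names].sum(axis=0, skipna=True)
        units[cls] = tags.pop()
    totals = pd.DataFrame(out_rows).T
    totals.index.name = "class"
    totals["unit"] = pd.Series(units)
    totals.attrs["cross_class_comparable"] = False
    totals.attrs["note"] = (
        "class totals assume equal response to the class internal standard; "
        "only within-class comparisons between sample groups are valid"
    )
    return totals


FOLD_OK = "ok"
FOLD_PATIENTS_ONLY = "detected_in_patients_only"
FOLD_UNDETECTED = "undetected"


def fold_changes(
    values: pd.DataFrame,
    condition: pd.Series,
    control_label: str = "control",
) -> pd.DataFrame:
    """Patient-mean over control-mean per row.

    A zero control mean with detectable patient signal yields the
    ``detected_in_patients_only`` sentinel (fold NaN), not infinity; both
    means zero yield ``undetected``.
    """
    cond = condition.loc[values.columns]
    ctrl = values.loc[:, cond == control_label]
    pat = values.loc[:, cond != control_label]
    if ctrl.shape[1] == 0 or pat.shape[1] == 0:
        raise ValueError("need at least one sample per condition")
    cm = ctrl.mean(axis=1, skipna=True)
    pm = pat.mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = pm / cm
    status = pd.Series(FOLD_OK, index=values.index)
    patients_only = (cm == 0) & (pm > 0)
    undetected = (cm == 0) & ~(pm > 0)
    status[patients_only] = FOLD_PATIENTS_ONLY
    status[undetected] = FOLD_UNDETECTED
    fold[patients_only | undetected] = np.nan
    return pd.DataFrame(
        {"control_mean": cm, "patient_mean": pm, "fold": fold, "status": status}
    )


def flag_pufa(carbons, double_bonds):
    """Polyunsaturated long-chain flag: total side-chain carbons >= 38 and
    double bonds >= 5 (e.g. PS 40:5)."""
    return (np.asarray(carbons) >= 38) & (np.asarray(double_bonds) >= 5)


def classify_sn1_linkage(
    untreated: float,
    treated: float,
    survival_threshold: float = 0.5,
    detection_floor: float = 0.0,
) -> str:
    """Classify an ether species from an acid-hydrolysis pair.

    Acid treatment hydrolyses the sn-1 vinyl ether of plasmenyl species but
    leaves plasmanyl (alkyl) species intact: a surviving fraction below the
    threshold marks plasmenyl, at/above marks plasmanyl. Species below the
    detection floor before treatment are indeterminate.
    """
    if untreated < 0 or treated < 0:
        raise ValueError("abundances must be >= 0")
    if untreated <= detection_floor or untreated == 0:
        return INDETERMINATE
    fraction = treated / untreated
    return PLASMENYL if fraction < survival_threshold else PLASMANYL


def classify_hydrolysis_table(
    pairs: pd.DataFrame,
    survival_threshold: float = 0.5,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Vectorized classification of a frame with ``untreated``/``treated``
    columns (indexed by species); adds ``fraction_remaining`` and
    ``linkage_call``."""
    calls = [
        classify_sn1_linkage(u, t, survival_threshold, detection_floor)
        for u, t in zip(pairs["untreated"], pairs["treated"])
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            pairs["untreated"] > 0, pairs["treated"] / pairs["untreated"], np.nan
        )
    out = pairs.copy()
    out["fraction_remaining"] = frac
    out["linkage_call"] = calls
    return out


@dataclass
class EnzymeAssayRecord:
    """A stable-isotope-dilution enzyme assay measurement.

    Product and internal-standard peak areas, the spiked IS amount (pmol),
    the calibration points (amount pmol, area ratio), the assayed protein
    (mg) and incubation time (h).
    """

    product_area: float
    is_area: float
    is_pmol: float = 87.0
    calibration: Tuple[Tuple[float, float], ...] = ()
    protein_mg: float = 0.040
    incubation_h: float = 1.0

    def __post_init__(self) -> None:
        if self.product_area < 0 or self.is_area < 0:
            raise ValueError("peak areas must be >= 0")
        if self.protein_mg <= 0:
            raise ValueError("protein_mg must be > 0")
        if self.incubation_h <= 0:
            raise ValueError("incubation_h must be > 0")


def _calibration_fit(
    calibration: Sequence[Tuple[float, float]],
    is_pmol: float,
    through_origin: bool = False,
) -> Tuple[float, float]:
    """OLS fit of (area ratio x IS pmol) against amount; returns (slope,
    intercept)."""
    if len(calibration) < 2:
        raise ValueError("calibration needs >= 2 points")
    amounts = np.array([a for a, _ in calibration], dtype=float)
    y = np.array([r for _, r in calibration], dtype=float) * is_pmol
    if through_origin:
        slope = float(amounts @ y / (amounts @ amounts))
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(amounts, y, 1)
    if slope == 0:
        raise ValueError("calibration slope is zero (non-invertible)")
    return float(slope), float(intercept)


def enzyme_activity(
    record: EnzymeAssayRecord,
    blank: Optional[EnzymeAssayRecord] = None,
    through_origin: bool = False,
) -> float:
    """Specific enzyme activity in pmol per hour per mg protein.

    The product amount is read off the calibration line through the
    isotope-dilution response (product area / IS area x IS pmol); an
    optional blank record's amount is subtracted; the amount is divided by
    protein mass and incubation time.
    """
    if record.is_area <= 0:
        raise ValueError("internal-standard peak area must be > 0")
    slope, intercept = _calibration_fit(
        record.calibration, record.is_pmol, through_origin
    )

    def _amount(r: EnzymeAssayRecord) -> float:
        y = r.product_area / r.is_area * r.is_pmol
        return (y - intercept) / slope

    amount = _amount(record)
    if blank is not None:
        amount -= _amount(blank)
    amount = max(amount, 0.0)
    return amount / (record.protein_mg * record.incubation_h)
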