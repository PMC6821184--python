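"""Lipid chemistry core.

Elemental formulas, monoisotopic masses, adduct ions, theoretical
isotopologue distributions and enumeration of an in-silico lipid database.

Species are identified at the sum-composition level, ``CLASS total
carbons:total double bonds`` (e.g. ``PC 34:1``), with ether species carrying
an ``[O]`` suffix (``PC[O] 34:1``). Formulas are derived from a per-class
rule table (backbone composition plus CH2 per side-chain carbon minus H2 per
double bond); ether species replace the sn-1 ester oxygen by an ether bond
(-O +2H versus the diacyl counterpart). Plasmenyl (vinyl-ether, plasmalogen)
species are represented on the alkyl rule with the vinyl-ether double bond
counted in ``double_bonds``, so ``P-36:2`` and ``O-36:3`` share one formula.

Element masses and natural isotope abundances are bundled as a versioned
data file so results are bit-reproducible across environments.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "ElementalFormula",
    "LipidSpecies",
    "AdductIon",
    "IsotopeDistribution",
    "DatabaseEntry",
    "LipidDatabase",
    "ADDUCTS",
    "element_table",
    "class_rules",
    "build_formula",
    "monoisotopic_mass",
    "mz_of",
    "isotope_distribution",
    "build_database",
    "default_database_config",
    "default_database",
]

_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S", "Na", "K")

ACYL = "acyl"
ALKYL = "alkyl"          # plasmanyl, 1-O-alkyl
ALKENYL = "alkenyl"      # plasmenyl, 1-O-alk-1'-enyl (plasmalogen)
UNKNOWN_ETHER = "unknown"
_ETHER_LINKAGES = (ALKYL, ALKENYL, UNKNOWN_ETHER)


# ---------------------------------------------------------------------------
# bundled constants
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def element_table() -> Dict[str, List[Tuple[int, float, float]]]:
    """Per-element isotope table: element -> [(shift, mass, abundance), ...].

    Entry 0 is the lightest isotope. Loaded once from the bundled
    ``data/elements.yaml``.
    """
    text = resources.files("lipidquant").joinpath("data/elements.yaml").read_text()
    raw = yaml.safe_load(text)
    table: Dict[str, List[Tuple[int, float, float]]] = {}
    for el, isotopes in raw["elements"].items():
        entries = sorted(
            ((iso["shift"], iso["mass"], iso["abundance"]) for iso in isotopes)
        )
        total = sum(ab for _, _, ab in entries)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"isotope abundances of {el} sum to {total}")
        table[el] = entries
    return table


@functools.lru_cache(maxsize=1)
def class_rules() -> Dict[str, dict]:
    """Lipid-class construction rules from the bundled ``class_rules.yaml``."""
    text = resources.files("lipidquant").joinpath("data/class_rules.yaml").read_text()
    return yaml.safe_load(text)["classes"]


# ---------------------------------------------------------------------------
# elemental formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Immutable elemental composition with element-wise arithmetic."""

    counts: Tuple[Tuple[str, int], ...] = ()

    @staticmethod
    def from_dict(counts: Mapping[str, int]) -> "ElementalFormula":
        items = []
        for el in _ELEMENT_ORDER:
            n = int(counts.get(el, 0))
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                items.append((el, n))
        unknown = set(counts) - set(_ELEMENT_ORDER)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        return ElementalFormula(tuple(items))

    @staticmethod
    def parse(text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C36H72NO8P``."""
        import re

        counts: Dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return ElementalFormula.from_dict(counts)

    def to_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula.from_dict(d)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({d[el]})"
                )
        return ElementalFormula.from_dict(d)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts
        ) or ""

    def __bool__(self) -> bool:
        return bool(self.counts)


# ---------------------------------------------------------------------------
# species and adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition resolution.

    Parameters
    ----------
    class_code : str
        Base class code (``PC``, ``TG`` ... ) without the ``[O]`` suffix.
    carbons : int
        Total side-chain carbon count.
    double_bonds : int
        Total side-chain double bonds. For plasmenyl species this includes
        the vinyl-ether double bond.
    sn1_linkage : str
        ``acyl`` for diacyl lipids, ``alkyl``/``alkenyl`` for ether lipids,
        ``unknown`` for an ether species of undetermined sub-type.
    """

    class_code: str
    carbons: int
    double_bonds: int
    sn1_linkage: str = ACYL

    def __post_init__(self) -> None:
        rules = class_rules()
        if self.class_code not in rules:
            raise ValueError(f"unregistered lipid class {self.class_code!r}")
        rule = rules[self.class_code]
        if self.carbons < rule["min_carbons"]:
            raise ValueError(
                f"{self.class_code}: carbons {self.carbons} below class "
                f"minimum {rule['min_carbons']}"
            )
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.sn1_linkage not in (ACYL,) + _ETHER_LINKAGES:
            raise ValueError(f"unknown sn1_linkage {self.sn1_linkage!r}")
        if self.is_ether and not rule.get("ether", False):
            raise ValueError(f"class {self.class_code} has no ether variant")

    @property
    def is_ether(self) -> bool:
        return self.sn1_linkage in _ETHER_LINKAGES

    @property
    def display_class(self) -> str:
        return f"{self.class_code}[O]" if self.is_ether else self.class_code

    @property
    def name(self) -> str:
        return f"{self.display_class} {self.carbons}:{self.double_bonds}"

    @staticmethod
    def from_name(name: str, sn1_linkage: Optional[str] = None) -> "LipidSpecies":
        """Inverse of :attr:`name`; ``PC[O] 34:1`` -> ether PC 34:1."""
        cls, _, nd = name.partition(" ")
        carbons, _, dbs = nd.partition(":")
        ether = cls.endswith("[O]")
        base = cls[:-3] if ether else cls
        if sn1_linkage is None:
            sn1_linkage = UNKNOWN_ETHER if ether else ACYL
        return LipidSpecies(base, int(carbons), int(dbs), sn1_linkage)


@dataclass(frozen=True)
class AdductIon:
    """An ionization adduct: label, polarity, mass delta (Da) and charge."""

    label: str
    polarity: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


PROTON_MASS = 1.00727646688

ADDUCTS: Dict[str, AdductIon] = {
    a.label: a
    for a in (
        AdductIon("[M+H]+", "positive", PROTON_MASS),
        AdductIon("[M+NH4]+", "positive", 18.03382555),
        AdductIon("[M+Na]+", "positive", 22.98922070),
        AdductIon("[M-H]-", "negative", -PROTON_MASS),
        AdductIon("[M+HCOO]-", "negative", 44.99820284),
    )
}


# ---------------------------------------------------------------------------
# formula construction and masses
# ---------------------------------------------------------------------------

def build_formula(species: LipidSpecies) -> ElementalFormula:
    """Derive the elemental formula of a species from its class rule.

    base + n*CH2 - d*H2, with ether species additionally -O +2H. The
    derivation is deterministic; identical species yield identical formulas.
    """
    rule = class_rules()[species.class_code]
    counts = dict(rule["base"])
    counts["C"] = counts.get("C", 0) + species.carbons
    counts["H"] = (
        counts.get("H", 0) + 2 * species.carbons - 2 * species.double_bonds
    )
    if species.is_ether:
        counts["O"] = counts.get("O", 0) - 1
        counts["H"] += 2
    if counts["H"] < 0:
        raise ValueError(
            f"{species.name}: double-bond count {species.double_bonds} "
            "exceeds what the carbon skeleton allows"
        )
    return ElementalFormula.from_dict(counts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count x lightest-isotope mass."""
    table = element_table()
    mass = 0.0
    for el, n in formula.counts:
        if el not in table:
            raise KeyError(f"element {el} missing from constants table")
        mass += n * table[el][0][1]
    return mass


def mz_of(formula: ElementalFormula, adduct: AdductIon) -> float:
    """m/z of a formula under an adduct: (M + delta) / charge."""
    return (monoisotopic_mass(formula) + adduct.mass_delta) / adduct.charge


# ---------------------------------------------------------------------------
# isotopologue distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated (centroided-by-nominal-shift) isotopologue distribution.

    ``abundances[k]`` is the probability that a molecule carries ``k`` extra
    nucleons; ``mass_shifts[k]`` is the abundance-weighted exact mass excess
    (Da) of that nominal bin relative to the monoisotopic peak.
    ``retained_fraction`` records the mass fraction kept after truncation at
    ``max_shift``.
    """

    shifts: Tuple[int, ...]
    mass_shifts: Tuple[float, ...]
    abundances: Tuple[float, ...]
    retained_fraction: float

    def fraction(self, k: int) -> float:
        return self.abundances[k] if k < len(self.abundances) else 0.0


def _single_element_distribution(
    isotopes: Sequence[Tuple[int, float, float]], n_atoms: int, max_shift: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact distribution of nominal shift for ``n_atoms`` of one element.

    Enumerates heavy-isotope count vectors with multinomial weights; returns
    (probability per shift 0..max_shift, mean exact mass excess per shift).
    """
    shifts = np.array([s for s, _, _ in isotopes])
    masses = np.array([m for _, m, _ in isotopes])
    abunds = np.array([a for _, _, a in isotopes])
    prob = np.zeros(max_shift + 1)
    mass_acc = np.zeros(max_shift + 1)
    heavy = [(s, m - masses[0], a) for s, m, a in isotopes if s > 0]
    if not heavy or n_atoms == 0:
        prob[0] = 1.0
        return prob, mass_acc

    log_a0 = math.log(abunds[0]) if abunds[0] > 0 else -math.inf
    maxima = [min(n_atoms, max_shift // s) for s, _, _ in heavy]
    for ks in itertools.product(*(range(m + 1) for m in maxima)):
        tot = sum(ks)
        shift = sum(k * s for k, (s, _, _) in zip(ks, heavy))
        if tot > n_atoms or shift > max_shift:
            continue
        # multinomial: n! / ((n-tot)! prod k!) * a0^(n-tot) * prod a^k
        logp = (
            math.lgamma(n_atoms + 1)
            - math.lgamma(n_atoms - tot + 1)
            + (n_atoms - tot) * log_a0
        )
        for k, (_, _, a) in zip(ks, heavy):
            logp += k * math.log(a) - math.lgamma(k + 1)
        p = math.exp(logp)
        dm = sum(k * d for k, (_, d, _) in zip(ks, heavy))
        prob[shift] += p
        mass_acc[shift] += p * dm
    mean_dm = np.divide(
        mass_acc, prob, out=np.zeros_like(mass_acc), where=prob > 0
    )
    return prob, mean_dm


def isotope_distribution(
    formula: ElementalFormula, max_shift: int = 3
) -> IsotopeDistribution:
    """Theoretical isotopologue distribution of a formula.

    Computed by element-wise convolution of exact per-element nominal-shift
    distributions (multinomial over heavy-isotope counts), truncated at
    ``max_shift``. Entry 0 is the monoisotopic peak with abundance equal to
    the product over elements of (lightest-isotope abundance)^count.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    table = element_table()
    prob = np.zeros(max_shift + 1)
    prob[0] = 1.0
    mass = np.zeros(max_shift + 1)
    for el, n in formula.counts:
        if el not in table:
            raise KeyError(f"element {el} missing from constants table")
        ep, em = _single_element_distribution(table[el], n, max_shift)
        new_prob = np.zeros(max_shift + 1)
        new_mass = np.zeros(max_shift + 1)
        for s1 in range(max_shift + 1):
            if prob[s1] == 0:
                continue
            for s2 in range(max_shift + 1 - s1):
                if ep[s2] == 0:
                    continue
                p = prob[s1] * ep[s2]
                new_prob[s1 + s2] += p
                new_mass[s1 + s2] += p * (mass[s1] + em[s2])
        prob = new_prob
        mass = np.divide(
            new_mass, new_prob, out=np.zeros_like(new_mass), where=new_prob > 0
        )
    retained = float(prob.sum())
    return IsotopeDistribution(
        shifts=tuple(range(max_shift + 1)),
        mass_shifts=tuple(float(m) for m in mass),
        abundances=tuple(float(p) for p in prob),
        retained_fraction=retained,
    )


# ---------------------------------------------------------------------------
# database enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatabaseEntry:
    """One (species, adduct) row of the lipid database."""

    species: LipidSpecies
    adduct: AdductIon
    formula: ElementalFormula
    theoretical_mz: float
    is_standard: bool = False
    standard_nmol: Optional[float] = None

    @property
    def key(self) -> str:
        return f"{self.species.name} {self.adduct.label}"


class LipidDatabase:
    """Sorted collection of database entries with TSV import/export."""

    def __init__(self, entries: Iterable[DatabaseEntry]):
        self.entries: List[DatabaseEntry] = sorted(
            entries, key=lambda e: e.theoretical_mz
        )
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate database definitions: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([e.theoretical_mz for e in self.entries])

    def standards(self) -> List[DatabaseEntry]:
        return [e for e in self.entries if e.is_standard]

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            rows.append(
                {
                    "class": e.species.display_class,
                    "carbons": e.species.carbons,
                    "double_bonds": e.species.double_bonds,
                    "sn1_linkage": e.species.sn1_linkage,
                    "formula": str(e.formula),
                    "adduct": e.adduct.label,
                    "charge": e.adduct.charge,
                    "theoretical_mz": e.theoretical_mz,
                    "is_standard": e.is_standard,
                    "standard_nmol": e.standard_nmol,
                }
            )
        return pd.DataFrame(rows)


# Internal-standard panel: one exogenous species per covered class, spiked at
# a fixed amount (nmol) per extraction. Short/saturated chains keep the
# standards outside the endogenous carbon ranges enumerated below.
DEFAULT_STANDARDS: Dict[str, Tuple[Tuple[int, int], float]] = {
    # class: ((carbons, double_bonds), nmol per extraction)
    "CL": ((56, 0), 0.1),
    "BMP": ((28, 0), 0.2),
    "PC": ((28, 0), 2.0),
    "PG": ((28, 0), 0.1),
    "PS": ((28, 0), 5.0),
    "PE": ((28, 0), 0.5),
    "PA": ((28, 0), 0.5),
    "SM": ((30, 1), 2.125),
    "LPG": ((14, 0), 0.02),
    "LPE": ((14, 0), 0.1),
    "LPC": ((14, 0), 0.5),
    "LPA": ((14, 0), 0.1),
    "PI": ((16, 0), 0.5),
    "DG": ((28, 0), 0.5),
    "TG": ((42, 0), 0.5),
}

# Default adduct per class: protonated/ammoniated species in positive mode
# for cholines and neutral lipids, deprotonated species in negative mode for
# acidic phospholipids.
DEFAULT_CLASS_ADDUCTS: Dict[str, str] = {
    "PC": "[M+H]+",
    "PC[O]": "[M+H]+",
    "LPC": "[M+H]+",
    "LPC[O]": "[M+H]+",
    "SM": "[M+H]+",
    "Cer": "[M+H]+",
    "DG": "[M+NH4]+",
    "DG[O]": "[M+NH4]+",
    "TG": "[M+NH4]+",
    "TG[O]": "[M+NH4]+",
    "CE": "[M+NH4]+",
    "PE": "[M-H]-",
    "PE[O]": "[M-H]-",
    "LPE": "[M-H]-",
    "LPE[O]": "[M-H]-",
    "PS": "[M-H]-",
    "PS[O]": "[M-H]-",
    "PI": "[M-H]-",
    "PG": "[M-H]-",
    "PA": "[M-H]-",
    # BMP is a structural isomer of PG; measuring it as the ammoniated ion in
    # positive mode keeps the two classes mass-distinguishable.
    "BMP": "[M+NH4]+",
    "CL": "[M-H]-",
    "LPG": "[M-H]-",
    "LPA": "[M-H]-",
}


def default_database_config() -> Dict[str, dict]:
    """Default enumeration config: per display class, carbon range,
    double-bond range and adduct label.

    Covers the internal-standard panel classes, their ether variants and
    the ether neutral lipids; carbon grids are even-numbered (two/three
    acyl chains of even-chain fatty acids).
    """
    diacyl = {"carbons": [32, 34, 36, 38], "double_bonds": [0, 1, 2, 3]}
    lyso = {"carbons": [16, 18, 20, 22], "double_bonds": [0, 1]}
    cfg: Dict[str, dict] = {}
    for cls in ("PC", "PE", "PS", "PI", "PG", "PA", "BMP", "SM"):
        cfg[cls] = dict(diacyl)
    cfg["PS"] = {"carbons": [36, 38, 40], "double_bonds": [1, 2, 5, 6]}
    for cls in ("LPC", "LPE", "LPG", "LPA"):
        cfg[cls] = dict(lyso)
    cfg["Cer"] = {"carbons": [34, 36, 38, 40], "double_bonds": [1, 2]}
    cfg["CL"] = {"carbons": [64, 68, 72], "double_bonds": [2, 4]}
    cfg["DG"] = {"carbons": [32, 34, 36], "double_bonds": [0, 1, 2]}
    cfg["TG"] = {"carbons": [48, 50, 52, 54], "double_bonds": [0, 1, 2, 3]}
    cfg["CE"] = {"carbons": [16, 18, 20], "double_bonds": [0, 1]}
    # ether variants
    cfg["PC[O]"] = {"carbons": [32, 34, 36, 38], "double_bonds": [1, 2, 3]}
    cfg["PE[O]"] = {"carbons": [32, 34, 36, 38], "double_bonds": [1, 2, 3]}
    cfg["PS[O]"] = {"carbons": [36, 38, 40], "double_bonds": [1, 2]}
    cfg["LPC[O]"] = {"carbons": [16, 18], "double_bonds": [0, 1]}
    cfg["LPE[O]"] = {"carbons": [16, 18], "double_bonds": [1, 2]}
    cfg["DG[O]"] = {"carbons": [32, 34, 36], "double_bonds": [1, 2]}
    cfg["TG[O]"] = {"carbons": [48, 50, 52], "double_bonds": [1, 2, 3]}
    for cls, sub in cfg.items():
        sub.setdefault("adduct", DEFAULT_CLASS_ADDUCTS[cls])
    return cfg


def _species_from_display(cls: str, carbons: int, dbs: int) -> LipidSpecies:
    ether = cls.endswith("[O]")
    base = cls[:-3] if ether else cls
    # ether sub-type assignment mirrors the hydrolysis findings: PE-ethers
    # are plasmenyl (plasmalogens), all other ether classes plasmanyl.
    if ether:
        linkage = ALKENYL if base in ("PE", "LPE") else ALKYL
    else:
        linkage = ACYL
    return LipidSpecies(base, carbons, dbs, linkage)


def build_database(
    class_config: Optional[Mapping[str, dict]] = None,
    standards: Optional[Mapping[str, Tuple[Tuple[int, int], float]]] = None,
) -> LipidDatabase:
    """Enumerate the lipid database from a per-class configuration.

    ``class_config`` maps a display class (``PC``, ``PC[O]`` ...) to carbon
    and double-bond grids plus an adduct label. Internal-standard species
    are appended per base class and flagged ``is_standard``. Entries are
    returned sorted by theoretical m/z. An empty config yields an empty
    database; duplicate (species, adduct) definitions raise.
    """
    if class_config is None and standards is None:
        class_config = default_database_config()
        standards = DEFAULT_STANDARDS
    class_config = class_config or {}
    standards = standards or {}

    entries: List[DatabaseEntry] = []
    for cls, sub in class_config.items():
        adduct = ADDUCTS[sub.get("adduct", DEFAULT_CLASS_ADDUCTS.get(cls, "[M+H]+"))]
        for n, d in itertools.product(sub["carbons"], sub["double_bonds"]):
            sp = _species_from_display(cls, n, d)
            f = build_formula(sp)
            entries.append(
                DatabaseEntry(sp, adduct, f, mz_of(f, adduct), is_standard=False)
            )
    for cls, ((n, d), nmol) in standards.items():
        adduct = ADDUCTS[DEFAULT_CLASS_ADDUCTS.get(cls, "[M+H]+")]
        sp = _species_from_display(cls, n, d)
        f = build_formula(sp)
        entries.append(
            DatabaseEntry(
                sp, adduct, f, mz_of(f, adduct),
                is_standard=True, standard_nmol=nmol,
            )
        )
    return LipidDatabase(entries)


def default_database() -> LipidDatabase:
    """The shipped default database (endogenous panel + standard panel)."""
    return build_database(default_database_config(), DEFAULT_STANDARDS)
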