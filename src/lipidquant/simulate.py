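"""Ground-truthed synthetic lipidomics studies.

Generates feature tables for control/patient fibroblast (or plasma)
lipidomes with the statistical structure the analysis pipeline assumes:
per-sample species amounts in nmol per mg protein with class-level fold
multipliers, internal standards spiked at fixed amounts, multiplicative
log-normal intensity noise, Gaussian ppm-scale mass error, isotopologue
peaks computed from elemental formulas, and resolution-limited merging of
unresolvable peaks into shared observed features (true overlap groups).

The default effect structure mirrors an ethanolamine-cytidylyltransferase
(ET) deficiency lipidome: ether-PC, ether-neutral and neutral lipids
accumulate (PC[O], LPC[O], DG, TG, DG[O], TG[O]), the CDP-ethanolamine
products and cholines fall (PC, LPC, PE, LPE, PE[O], LPE[O]), and
plasmanyl-PS[O] appears in patients while being absent from controls.
Everything is deterministic under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import FeatureTable, ResolutionModel
from .chem import (
    ALKENYL,
    DatabaseEntry,
    LipidDatabase,
    default_database,
    isotope_distribution,
)
from .quantify import EnzymeAssayRecord

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_BASELINES",
    "simulate_study",
    "simulate_hydrolysis_pairs",
    "simulate_enzyme_assay",
    "simulate_null_matrix",
]

# Patient-vs-control class fold multipliers. Synthetic defaults chosen to
# match the reported effect directions; the magnitudes are generator
# settings, not measured values.
DEFAULT_MULTIPLIERS: Dict[str, float] = {
    "PC[O]": 4.0,
    "LPC[O]": 4.0,
    "DG": 3.0,
    "TG": 3.0,
    "DG[O]": 4.0,
    "TG[O]": 4.0,
    "PC": 0.6,
    "LPC": 0.6,
    "PE": 0.5,
    "LPE": 0.5,
    "PE[O]": 0.5,
    "LPE[O]": 0.5,
}

# Class totals in nmol per mg protein, fibroblast-like scale.
DEFAULT_BASELINES: Dict[str, float] = {
    "PC": 40.0, "PE": 20.0, "PS": 8.0, "PI": 6.0, "PG": 1.5, "PA": 1.0,
    "BMP": 0.8, "CL": 4.0, "SM": 10.0, "Cer": 1.5,
    "LPC": 1.2, "LPE": 0.5, "LPG": 0.1, "LPA": 0.1,
    "DG": 1.5, "TG": 5.0, "CE": 2.0,
    "PC[O]": 2.5, "PE[O]": 4.0, "PS[O]": 0.3,
    "LPC[O]": 0.2, "LPE[O]": 0.2, "DG[O]": 0.3, "TG[O]": 0.4,
}


@dataclass(frozen=True)
class StudyConfig:
    """Synthetic study design and noise model.

    Defaults follow the study layout the pipeline targets: three control
    and two patient cell lines measured in quadruplicate, multiplicative
    log-normal intensity noise of 15% total CV — decomposed into a
    per-sample shared injection/extraction factor (12%, which internal
    standards cancel) and a per-species independent residual (9%) — 1 ppm
    (SD) mass error and a 280,000 resolving-power merge model.
    """

    n_control: int = 3
    n_patient: int = 2
    replicates: int = 4
    matrix: str = "fibroblast"
    cv: float = 0.09          # per-species independent intensity CV
    cv_shared: float = 0.12   # per-sample shared (injection/extraction) CV
    ppm_sd: float = 1.0
    response_factor: float = 1e6          # counts per nmol in the extract
    protein_mg_mean: float = 1.0
    protein_mg_sd: float = 0.1
    baseline_spread_sigma: float = 0.5    # log-SD of species weights in a class
    max_shift: int = 3
    resolution: ResolutionModel = field(default_factory=ResolutionModel)
    class_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    class_baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    patients_only_classes: Tuple[str, ...] = ("PS[O]",)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("class multipliers must be > 0")
        if self.cv < 0 or self.ppm_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """Per-sample truth record of a simulated study.

    ``amounts`` holds species-by-sample true amounts (nmol/mg protein,
    endogenous species only); ``multipliers`` the class fold map applied to
    patients; ``linkage`` the true sn-1 linkage per species; plus the noise
    parameters and seed that fully determine the realization.
    """

    amounts: pd.DataFrame
    multipliers: Dict[str, float]
    linkage: Dict[str, str]
    species_class: pd.Series
    standards_nmol: Dict[str, float]
    cv: float
    ppm_sd: float
    seed: int

    def class_sums(self) -> pd.DataFrame:
        """Exact class-by-sample sums of the species truths."""
        return self.amounts.groupby(self.species_class.loc[self.amounts.index]).sum()


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _sample_frame(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for kind, count in (("control", config.n_control), ("patient", config.n_patient)):
        for i in range(1, count + 1):
            for r in range(1, config.replicates + 1):
                protein = max(
                    rng.normal(config.protein_mg_mean, config.protein_mg_sd), 0.2
                )
                rows.append(
                    {
                        "sample_id": f"{kind}{i}_r{r}",
                        "group": f"{kind}{i}",
                        "condition": kind,
                        "replicate": r,
                        "protein_mg": protein,
                        "treatment": "none",
                        "matrix": config.matrix,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _species_baselines(
    entries: Sequence[DatabaseEntry],
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Distribute each class baseline over its member species with
    log-normal weights (fixed across samples)."""
    classes = pd.Series(
        [e.species.display_class for e in entries],
        index=[e.species.name for e in entries],
    )
    weights = pd.Series(
        np.exp(rng.normal(0.0, config.baseline_spread_sigma, len(entries))),
        index=classes.index,
    )
    baselines = pd.Series(0.0, index=classes.index)
    for cls, members in classes.groupby(classes):
        total = config.class_baselines.get(cls, 1.0)
        w = weights.loc[members.index]
        baselines.loc[members.index] = total * w / w.sum()
    return baselines


def _true_amounts(
    baselines: pd.Series,
    species_class: pd.Series,
    samples: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    mult = pd.Series(1.0, index=baselines.index)
    patient_mult = species_class.map(
        lambda c: config.class_multipliers.get(c, 1.0)
    )
    amounts = {}
    patients_only = species_class.isin(config.patients_only_classes)
    for sid, row in samples.iterrows():
        is_patient = row["condition"] == "patient"
        base = baselines * (patient_mult if is_patient else mult)
        if not is_patient:
            base = base.where(~patients_only, 0.0)
        noise = _lognormal_factors(rng, config.cv, len(base))
        amounts[sid] = base * noise
    out = pd.DataFrame(amounts)
    out.index.name = "species"
    return out


@dataclass
class _FeatureGeometry:
    """Deterministic peak-to-feature layout shared by paired tables."""

    feature_ids: List[str]
    feature_mz: np.ndarray
    feature_rt: np.ndarray
    feature_mode: List[str]
    members: List[List[Tuple[int, int]]]  # per feature: (entry index, shift)
    fractions: np.ndarray                 # entry x shift isotopologue fraction


def _build_geometry(
    db_entries: Sequence[DatabaseEntry],
    config: StudyConfig,
    rng: np.random.Generator,
    mean_total: np.ndarray,
) -> _FeatureGeometry:
    """Merge theoretical isotopologue peaks into observed features.

    Peaks of the same polarity closer than the resolution-merge threshold
    (single linkage over the sorted m/z axis) become one feature whose m/z
    is the intensity-weighted centroid distorted by a Gaussian ppm error.
    ``mean_total`` (per entry) supplies the centroid weights.
    """
    K = config.max_shift
    fracs = np.zeros((len(db_entries), K + 1))
    peak_rows = []  # (mode, mz, entry_idx, shift)
    class_rt = {}
    for i, e in enumerate(db_entries):
        dist = isotope_distribution(e.formula, K)
        cls = e.species.display_class
        rt0 = class_rt.setdefault(cls, 2.0 + 0.45 * len(class_rt))
        for k in range(K + 1):
            fracs[i, k] = dist.abundances[k]
            if dist.abundances[k] <= 0:
                continue
            mz = e.theoretical_mz + dist.mass_shifts[k] / e.adduct.charge
            peak_rows.append((e.adduct.polarity, mz, i, k, rt0))

    feature_ids: List[str] = []
    feature_mz: List[float] = []
    feature_rt: List[float] = []
    feature_mode: List[str] = []
    members: List[List[Tuple[int, int]]] = []
    for mode, prefix in (("positive", "P"), ("negative", "N")):
        peaks = sorted(p for p in peak_rows if p[0] == mode)
        clusters: List[List[tuple]] = []
        for p in peaks:
            if clusters and (
                p[1] - clusters[-1][-1][1]
                < config.resolution.merge_threshold(p[1])
            ):
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for ci, cluster in enumerate(clusters):
            w = np.array(
                [mean_total[i] * fracs[i, k] for _, _, i, k, _ in cluster]
            )
            if w.sum() <= 0:
                w = np.ones(len(cluster))
            mzs = np.array([p[1] for p in cluster])
            centroid = float(mzs @ w / w.sum())
            err = rng.normal(0.0, config.ppm_sd) * 1e-6
            feature_ids.append(f"{prefix}{ci + 1:05d}")
            feature_mz.append(centroid * (1.0 + err))
            feature_rt.append(float(np.mean([p[4] for p in cluster])))
            feature_mode.append(mode)
            members.append([(i, k) for _, _, i, k, _ in cluster])
    return _FeatureGeometry(
        feature_ids=feature_ids,
        feature_mz=np.asarray(feature_mz),
        feature_rt=np.asarray(feature_rt),
        feature_mode=feature_mode,
        members=members,
        fractions=fracs,
    )


def _total_intensities(
    db_entries: Sequence[DatabaseEntry],
    amounts: pd.DataFrame,
    samples: pd.DataFrame,
    config: StudyConfig,
    noise: np.ndarray,
) -> np.ndarray:
    """Entry x sample total ion intensity (all isotopologues)."""
    protein = samples["protein_mg"].to_numpy()
    out = np.zeros((len(db_entries), len(samples)))
    for i, e in enumerate(db_entries):
        if e.is_standard:
            moles = np.full(len(samples), e.standard_nmol)
        else:
            moles = amounts.loc[e.species.name].to_numpy() * protein
        out[i] = moles * config.response_factor * noise[i]
    return out


def _table_from_geometry(
    geometry: _FeatureGeometry,
    totals: np.ndarray,
    samples: pd.DataFrame,
) -> FeatureTable:
    n_samples = totals.shape[1]
    inten = np.zeros((len(geometry.feature_ids), n_samples))
    for fi, mem in enumerate(geometry.members):
        for i, k in mem:
            inten[fi] += totals[i] * geometry.fractions[i, k]
    features = pd.DataFrame(
        {
            "mz": geometry.feature_mz,
            "rt_min": geometry.feature_rt,
            "ion_mode": geometry.feature_mode,
        },
        index=pd.Index(geometry.feature_ids, name="feature_id"),
    )
    intensities = pd.DataFrame(
        inten, index=features.index, columns=list(samples.index)
    )
    keep = intensities.sum(axis=1) > 0
    return FeatureTable(
        features=features.loc[keep],
        intensities=intensities.loc[keep],
        samples=samples.copy(),
    )


def simulate_study(
    config: Optional[StudyConfig] = None,
    seed: int = 0,
    db: Optional[LipidDatabase] = None,
) -> Tuple[FeatureTable, GroundTruth]:
    """Simulate one control-vs-patient lipidomics study.

    Returns the observed feature table and the ground truth that produced
    it. Identical (config, seed, db) yield byte-identical outputs.
    """
    config = config or StudyConfig()
    if db is None:
        db = default_database()
    entries = list(db)
    if not any(not e.is_standard for e in entries):
        raise ValueError("species panel is empty")
    rng = np.random.default_rng(seed)

    samples = _sample_frame(config, rng)
    endo = [e for e in entries if not e.is_standard]
    baselines = _species_baselines(endo, config, rng)
    species_class = pd.Series(
        {e.species.name: e.species.display_class for e in endo}
    )
    amounts = _true_amounts(baselines, species_class, samples, config, rng)

    shared = _lognormal_factors(rng, config.cv_shared, len(samples))
    noise = shared[None, :] * _lognormal_factors(
        rng, config.cv, (len(entries), len(samples))
    )
    totals = _total_intensities(entries, amounts, samples, config, noise)
    geometry = _build_geometry(entries, config, rng, totals.mean(axis=1))
    table = _table_from_geometry(geometry, totals, samples)

    linkage = {e.species.name: e.species.sn1_linkage for e in endo}
    truth = GroundTruth(
        amounts=amounts,
        multipliers=dict(config.class_multipliers),
        linkage=linkage,
        species_class=species_class,
        standards_nmol={
            e.species.name: float(e.standard_nmol)
            for e in entries
            if e.is_standard
        },
        cv=config.cv,
        ppm_sd=config.ppm_sd,
        seed=seed,
    )
    return table, truth


def simulate_hydrolysis_pairs(
    config: Optional[StudyConfig] = None,
    efficiency: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    db: Optional[LipidDatabase] = None,
) -> Tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Paired acid-hydrolysis experiment: (treated, untreated, truth).

    The treated table shares the untreated table's samples, features and
    measurement-noise realization; plasmenyl (vinyl-ether) species survive
    with fraction ``1 - efficiency`` while plasmanyl and diacyl species are
    untouched, times an optional extra measurement noise of CV
    ``noise_cv`` on the treated aliquot. With ``efficiency=0`` and
    ``noise_cv=0`` the pair is identical.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    config = config or StudyConfig()
    if db is None:
        db = default_database()
    entries = list(db)
    rng = np.random.default_rng(seed)

    samples = _sample_frame(config, rng)
    endo = [e for e in entries if not e.is_standard]
    baselines = _species_baselines(endo, config, rng)
    species_class = pd.Series(
        {e.species.name: e.species.display_class for e in endo}
    )
    amounts = _true_amounts(baselines, species_class, samples, config, rng)
    shared = _lognormal_factors(rng, config.cv_shared, len(samples))
    noise = shared[None, :] * _lognormal_factors(
        rng, config.cv, (len(entries), len(samples))
    )
    totals = _total_intensities(entries, amounts, samples, config, noise)
    geometry = _build_geometry(entries, config, rng, totals.mean(axis=1))

    survival = np.array(
        [
            (1.0 - efficiency)
            if (not e.is_standard and e.species.sn1_linkage == ALKENYL)
            else 1.0
            for e in entries
        ]
    )
    extra = _lognormal_factors(rng, noise_cv, (len(entries), len(samples)))
    treated_totals = totals * survival[:, None] * extra

    untreated = _table_from_geometry(geometry, totals, samples)
    treated_samples = samples.copy()
    treated_samples["treatment"] = "HCl"
    treated = _table_from_geometry(geometry, treated_totals, treated_samples)

    truth = GroundTruth(
        amounts=amounts,
        multipliers=dict(config.class_multipliers),
        linkage={e.species.name: e.species.sn1_linkage for e in endo},
        species_class=species_class,
        standards_nmol={
            e.species.name: float(e.standard_nmol)
            for e in entries
            if e.is_standard
        },
        cv=config.cv,
        ppm_sd=config.ppm_sd,
        seed=seed,
    )
    return treated, untreated, truth


def simulate_enzyme_assay(
    true_activities: Sequence[float],
    seed: int = 0,
    noise_cv: float = 0.0,
    residual_cv: Optional[float] = None,
    protein_mg: float = 0.040,
    incubation_h: float = 1.0,
    is_pmol: float = 87.0,
    calibration_amounts: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0),
    response_factor: float = 1200.0,
    is_response_factor: float = 950.0,
) -> List[EnzymeAssayRecord]:
    """Simulate stable-isotope-dilution enzyme assays.

    Each activity (pmol/h/mg) produces ``activity * protein_mg *
    incubation_h`` pmol of product; product and internal-standard peak
    areas follow configurable linear response factors. ``noise_cv`` is the
    injection/extraction variability, which multiplies the product and IS
    areas of a record *jointly* — the variability the isotope-dilution
    ratio exists to cancel — while ``residual_cv`` (default a tenth of
    ``noise_cv``) is the small independent detector noise left on each
    area. Calibration points come from the same response model
    (noise-free), so a noise-free record round-trips exactly.
    """
    if any(a < 0 for a in true_activities):
        raise ValueError("activities must be >= 0")
    if residual_cv is None:
        residual_cv = noise_cv / 10.0
    rng = np.random.default_rng(seed)
    ratio_per_pmol = response_factor / is_response_factor / is_pmol
    calibration = tuple(
        (float(a), float(a * ratio_per_pmol)) for a in calibration_amounts
    )
    records = []
    for act in true_activities:
        product_pmol = act * protein_mg * incubation_h
        (e_shared,) = _lognormal_factors(rng, noise_cv, 1)
        e_prod, e_is = _lognormal_factors(rng, residual_cv, 2)
        records.append(
            EnzymeAssayRecord(
                product_area=product_pmol * response_factor * e_shared * e_prod,
                is_area=is_pmol * is_response_factor * e_shared * e_is,
                is_pmol=is_pmol,
                calibration=calibration,
                protein_mg=protein_mg,
                incubation_h=incubation_h,
            )
        )
    return records


def simulate_null_matrix(
    n_species: int = 2000,
    n_control: int = 3,
    n_patient: int = 2,
    replicates: int = 4,
    cv: float = 0.15,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Null-configuration abundance matrix (all class multipliers 1).

    Species amounts share one baseline model with pure multiplicative
    log-normal noise; returns (values species x samples, condition per
    sample). Used for statistical-calibration checks.
    """
    rng = np.random.default_rng(seed)
    cols = []
    cond = {}
    for kind, count in (("control", n_control), ("patient", n_patient)):
        for i in range(1, count + 1):
            for r in range(1, replicates + 1):
                sid = f"{kind}{i}_r{r}"
                cols.append(sid)
                cond[sid] = kind
    baselines = np.exp(rng.normal(0.0, 0.5, n_species))
    noise = _lognormal_factors(rng, cv, (n_species, len(cols)))
    values = pd.DataFrame(
        baselines[:, None] * noise,
        index=[f"species_{i:04d}" for i in range(n_species)],
        columns=cols,
    )
    return values, pd.Series(cond)
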