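"""Feature annotation and overlap-group assembly.

Observed MS features are matched to database entries (and their
isotopologue peaks) within a ppm mass tolerance; species whose isotopologue
peaks land on shared observed features — or whose theoretical peaks are
unresolvable at the instrument's resolving power — are collected into
overlap groups, each of which later forms one linear deconvolution system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    DatabaseEntry,
    IsotopeDistribution,
    LipidDatabase,
    isotope_distribution,
)

__all__ = [
    "FeatureTable",
    "ResolutionModel",
    "OverlapGroup",
    "ppm_error",
    "match_features",
    "build_overlap_groups",
]


@dataclass
class FeatureTable:
    """Feature-by-sample intensity matrix with feature and sample metadata.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns ``mz``, ``rt_min``, ``ion_mode``.
    intensities : pandas.DataFrame
        Rows aligned with ``features`` index, one column per sample.
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``group``, ``replicate``,
        ``protein_mg``, ``treatment``, ``matrix``.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.is_unique:
            raise ValueError("feature_ids must be unique")
        if (self.features["mz"] <= 0).any():
            raise ValueError("all feature m/z must be > 0")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be >= 0")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities indexes differ")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.intensities.columns)


@dataclass(frozen=True)
class ResolutionModel:
    """FWHM model of an FT-type analyzer.

    Resolving power is referenced at ``ref_mz`` and falls off as 1/sqrt(m/z),
    so the peak width grows as m/z^1.5:

        fwhm(mz) = mz^1.5 / (resolving_power * sqrt(ref_mz))

    Two theoretical peaks closer than ``merge_multiple`` FWHM are treated as
    unresolvable and merge into a single observed feature.
    """

    resolving_power: float = 280_000.0
    ref_mz: float = 200.0
    merge_multiple: float = 1.0

    def fwhm(self, mz: float) -> float:
        return mz ** 1.5 / (self.resolving_power * math.sqrt(self.ref_mz))

    def merge_threshold(self, mz: float) -> float:
        return self.merge_multiple * self.fwhm(mz)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million.

    (observed - theoretical) / theoretical * 1e6; the theoretical m/z is the
    reference denominator.
    """
    if np.any(np.asarray(theoretical_mz) <= 0):
        raise ValueError("theoretical m/z must be > 0")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def _distribution_cache(
    db: LipidDatabase, max_shift: int
) -> Dict[str, IsotopeDistribution]:
    cache: Dict[str, IsotopeDistribution] = {}
    for e in db:
        key = str(e.formula)
        if key not in cache:
            cache[key] = isotope_distribution(e.formula, max_shift)
    return cache


def _candidate_peaks(
    db: LipidDatabase, max_shift: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict[str, IsotopeDistribution]]:
    """Flat arrays (mz, entry index, shift) over all isotopologue peaks."""
    dists = _distribution_cache(db, max_shift)
    mzs: List[float] = []
    idxs: List[int] = []
    shifts: List[int] = []
    for i, e in enumerate(db):
        dist = dists[str(e.formula)]
        for k in range(max_shift + 1):
            if dist.abundances[k] <= 0:
                continue
            mzs.append(e.theoretical_mz + dist.mass_shifts[k] / e.adduct.charge)
            idxs.append(i)
            shifts.append(k)
    order = np.argsort(mzs)
    return (
        np.asarray(mzs)[order],
        np.asarray(idxs)[order],
        np.asarray(shifts)[order],
        dists,
    )


def match_features(
    table: FeatureTable,
    db: LipidDatabase,
    tolerance_ppm: float = 3.0,
    max_shift: int = 3,
    rt_windows: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> pd.DataFrame:
    """Match observed features to database isotopologue peaks within a ppm
    tolerance.

    Every candidate within tolerance (and of matching polarity) is recorded;
    per feature the accepted candidate is the one with minimum absolute ppm
    error, ties broken by lower double-bond count then lexical class order.
    Features with no candidate are absent from the output. ``rt_windows``
    (species name -> (lo, hi) minutes) optionally restricts candidates by
    retention time; matching is by m/z alone when it is None (the default).

    Returns a DataFrame with one row per (feature, candidate) pair.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    peak_mz, peak_idx, peak_shift, _ = _candidate_peaks(db, max_shift)
    entries = list(db)
    rows: List[dict] = []
    for fid, frow in table.features.iterrows():
        mz = float(frow["mz"])
        mode = frow["ion_mode"]
        half = mz * tolerance_ppm * 1e-6 * 1.0000001
        lo = np.searchsorted(peak_mz, mz - half, side="left")
        hi = np.searchsorted(peak_mz, mz + half, side="right")
        for j in range(lo, hi):
            e = entries[peak_idx[j]]
            if e.adduct.polarity != mode:
                continue
            if rt_windows is not None and e.species.name in rt_windows:
                lo_rt, hi_rt = rt_windows[e.species.name]
                if not (lo_rt <= float(frow.get("rt_min", np.nan)) <= hi_rt):
                    continue
            err = ppm_error(mz, peak_mz[j])
            if abs(err) > tolerance_ppm:
                continue
            rows.append(
                {
                    "feature_id": fid,
                    "species": e.species.name,
                    "class": e.species.display_class,
                    "carbons": e.species.carbons,
                    "double_bonds": e.species.double_bonds,
                    "sn1_linkage": e.species.sn1_linkage,
                    "adduct": e.adduct.label,
                    "entry_key": e.key,
                    "is_standard": e.is_standard,
                    "isotopologue_shift": int(peak_shift[j]),
                    "theoretical_mz": float(peak_mz[j]),
                    "ppm_error": float(err),
                }
            )
    ann = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "species", "class", "carbons", "double_bonds",
            "sn1_linkage", "adduct", "entry_key", "is_standard",
            "isotopologue_shift", "theoretical_mz", "ppm_error",
        ],
    )
    if ann.empty:
        ann["accepted"] = pd.Series(dtype=bool)
        return ann
    ann["abs_ppm"] = ann["ppm_error"].abs()
    ann = ann.sort_values(
        ["feature_id", "abs_ppm", "double_bonds", "class"], kind="mergesort"
    ).reset_index(drop=True)
    ann["accepted"] = ~ann.duplicated("feature_id", keep="first")
    return ann.drop(columns="abs_ppm")


@dataclass
class OverlapGroup:
    """A set of species whose isotopologue peaks share observed features.

    ``assignment`` maps (entry_key, isotopologue_shift) to the feature id
    the peak falls on; ``distributions`` holds each member's isotopologue
    distribution. A singleton group is a valid (1x1) system.
    """

    entry_keys: List[str]
    feature_ids: List[str]
    assignment: Dict[Tuple[str, int], str]
    distributions: Dict[str, IsotopeDistribution] = field(default_factory=dict)
    entries: Dict[str, DatabaseEntry] = field(default_factory=dict)


def build_overlap_groups(
    annotations: pd.DataFrame,
    db: LipidDatabase,
    resolution_model: Optional[ResolutionModel] = None,
    max_shift: int = 3,
    features: Optional[pd.DataFrame] = None,
) -> List[OverlapGroup]:
    """Partition annotated species and features into overlap groups.

    A species is a member when its monoisotopic (shift-0) peak is tied to
    an observed feature — either through a ppm-tolerance annotation, or
    (when a resolution model and the feature frame are supplied) because
    the peak lies within the resolution-merge envelope of a feature: an
    unresolved peak's centroid can sit beyond the ppm window of its
    members, so envelope matching is what lets merged clusters be
    deconvoluted. Each isotopologue peak is assigned to its best feature
    (smallest |ppm|, else nearest within the envelope). Two species join
    the same group when they share a feature or when any pair of their
    theoretical peaks is closer than the merge threshold. Connected
    components define the groups; groups are disjoint over both features
    and species.
    """
    if annotations.empty and features is None:
        return []
    dists = _distribution_cache(db, max_shift)
    entry_map = {e.key: e for e in db}

    # best feature per (entry, shift) from ppm-tolerance candidates
    assignment: Dict[Tuple[str, int], str] = {}
    if not annotations.empty:
        cand = annotations.copy()
        cand["abs_ppm"] = cand["ppm_error"].abs()
        cand = cand.sort_values("abs_ppm", kind="mergesort")
        best = cand.drop_duplicates(["entry_key", "isotopologue_shift"])
        assignment = {
            (r.entry_key, int(r.isotopologue_shift)): r.feature_id
            for r in best.itertuples()
        }

    # envelope matching for peaks without a ppm-tolerance candidate
    if resolution_model is not None and features is not None:
        by_mode: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for mode in ("positive", "negative"):
            sub = features[features["ion_mode"] == mode]
            order = np.argsort(sub["mz"].to_numpy())
            by_mode[mode] = (
                sub["mz"].to_numpy()[order],
                sub.index.to_numpy()[order],
            )
        for e in db:
            dist = dists[str(e.formula)]
            mz_arr, fid_arr = by_mode[e.adduct.polarity]
            if len(mz_arr) == 0:
                continue
            for k in range(max_shift + 1):
                if dist.abundances[k] <= 0 or (e.key, k) in assignment:
                    continue
                mz = e.theoretical_mz + dist.mass_shifts[k] / e.adduct.charge
                j = int(np.searchsorted(mz_arr, mz))
                best_j = None
                for jj in (j - 1, j):
                    if 0 <= jj < len(mz_arr):
                        if best_j is None or abs(mz_arr[jj] - mz) < abs(
                            mz_arr[best_j] - mz
                        ):
                            best_j = jj
                # a merged cluster's centroid can sit up to about one
                # threshold beyond an edge member (single-linkage chains),
                # so the assignment gate is twice the merge threshold
                if best_j is not None and abs(
                    mz_arr[best_j] - mz
                ) < 2.0 * resolution_model.merge_threshold(mz):
                    assignment[(e.key, k)] = fid_arr[best_j]

    # species present: monoisotopic peak tied to a feature
    present = sorted({key for (key, k) in assignment if k == 0})
    present_set = set(present)
    assignment = {
        (key, k): fid
        for (key, k), fid in assignment.items()
        if key in present_set
    }

    # union-find over species
    parent = {k: k for k in present}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_feature: Dict[str, List[str]] = {}
    for (key, _shift), fid in assignment.items():
        by_feature.setdefault(fid, []).append(key)
    for members in by_feature.values():
        for other in members[1:]:
            union(members[0], other)

    if resolution_model is not None:
        # link species whose theoretical peaks are unresolvable
        peaks: List[Tuple[float, str]] = []
        for key in present:
            e = entry_map[key]
            dist = dists[str(e.formula)]
            for k in range(max_shift + 1):
                if dist.abundances[k] > 0:
                    peaks.append(
                        (
                            e.theoretical_mz + dist.mass_shifts[k] / e.adduct.charge,
                            key,
                        )
                    )
        peaks.sort()
        for (mz1, k1), (mz2, k2) in zip(peaks, peaks[1:]):
            if k1 == k2:
                continue
            e1, e2 = entry_map[k1], entry_map[k2]
            if e1.adduct.polarity != e2.adduct.polarity:
                continue
            if mz2 - mz1 < resolution_model.merge_threshold(0.5 * (mz1 + mz2)):
                union(k1, k2)

    comps: Dict[str, List[str]] = {}
    for key in present:
        comps.setdefault(find(key), []).append(key)

    groups: List[OverlapGroup] = []
    for members in comps.values():
        members = sorted(members)
        fids = sorted(
            {assignment[(m, k)] for m in members for k in range(max_shift + 1)
             if (m, k) in assignment}
        )
        groups.append(
            OverlapGroup(
                entry_keys=members,
                feature_ids=fids,
                assignment={
                    (m, k): assignment[(m, k)]
                    for m in members
                    for k in range(max_shift + 1)
                    if (m, k) in assignment
                },
                distributions={
                    m: dists[str(entry_map[m].formula)] for m in members
                },
                entries={m: entry_map[m] for m in members},
            )
        )
    groups.sort(key=lambda g: g.entry_keys[0])
    return groups
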