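"""Natural-isotope-abundance correction.

Each overlap group defines one linear system per sample: the design matrix
maps species totals to observed feature intensities through their
isotopologue fractions, and a non-negative least-squares solve recovers the
deconvoluted per-species intensities. Strictly triangular systems (the
classic double-bond ladder, where the M+2 peak of an unsaturated species
contaminates the monoisotopic peak of its less-unsaturated neighbour) are
solved exactly; NNLS handles the general and noisy cases without producing
negative peel-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize

from .annotate import FeatureTable, OverlapGroup

__all__ = [
    "CorrectionSystem",
    "build_system",
    "solve_nnls",
    "deconvolute_group",
    "correct_feature_table",
]


@dataclass
class CorrectionSystem:
    """One overlap group's design: observed features x member species.

    ``design[f, s]`` is the isotopologue fraction of species ``s`` (of its
    total molecular population) whose peak falls on feature ``f``. Columns
    therefore sum to at most 1; truncation at the maximum shift drops the
    remainder, recorded per species in ``retained``.
    """

    feature_ids: List[str]
    entry_keys: List[str]
    design: np.ndarray
    retained: np.ndarray

    def __post_init__(self) -> None:
        if (self.design < 0).any() or (self.design > 1).any():
            raise ValueError("design entries must lie in [0, 1]")
        if (self.design.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("design column sums must be <= 1")
        if (self.design.sum(axis=0) <= 0).any():
            raise ValueError("design matrix has an all-zero column")


def build_system(group: OverlapGroup) -> CorrectionSystem:
    """Assemble the design matrix of an overlap group.

    Only isotopologue peaks that map to an observed feature enter the
    system; the retained mass fraction per species is the sum of mapped
    fractions (used for diagnostics, the NNLS scale is already the species
    total because design entries are fractions of the total).
    """
    fidx = {f: i for i, f in enumerate(group.feature_ids)}
    sidx = {k: j for j, k in enumerate(group.entry_keys)}
    A = np.zeros((len(fidx), len(sidx)))
    retained = np.zeros(len(sidx))
    for (key, shift), fid in group.assignment.items():
        frac = group.distributions[key].fraction(shift)
        A[fidx[fid], sidx[key]] += frac
        retained[sidx[key]] += frac
    return CorrectionSystem(
        feature_ids=list(group.feature_ids),
        entry_keys=list(group.entry_keys),
        design=A,
        retained=retained,
    )


def solve_nnls(design: np.ndarray, observed: np.ndarray) -> Tuple[np.ndarray, float]:
    """Non-negative least squares solve of one correction system.

    Returns (solution, residual 2-norm). Exact (residual 0) when the system
    is square, non-singular and consistent with non-negative truth.
    """
    if (np.asarray(observed) < 0).any():
        raise ValueError("observed intensities must be >= 0")
    x, rnorm = scipy.optimize.nnls(design, np.asarray(observed, dtype=float))
    return x, float(rnorm)


def deconvolute_group(
    group: OverlapGroup, intensities: Dict[str, float]
) -> pd.DataFrame:
    """Deconvolute one overlap group for one sample.

    ``intensities`` maps feature_id -> observed intensity. Returns a frame
    with the corrected total (monoisotopic-equivalent / M0-fraction)
    intensity per member species, the residual norm, the retained mass
    fraction, and a ``resolved`` flag that is False for every species of a
    rank-deficient system (reported, not silently zeroed).
    """
    system = build_system(group)
    y = np.array([float(intensities.get(f, 0.0)) for f in system.feature_ids])
    x, rnorm = solve_nnls(system.design, y)
    rank = np.linalg.matrix_rank(system.design)
    resolved = rank >= len(system.entry_keys)
    return pd.DataFrame(
        {
            "entry_key": system.entry_keys,
            "corrected_intensity": x if resolved else np.full_like(x, np.nan),
            "residual_norm": rnorm,
            "retained_fraction": system.retained,
            "resolved": resolved,
        }
    )


def correct_feature_table(
    table: FeatureTable,
    groups: Sequence[OverlapGroup],
    annotations: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply isotope correction to a whole feature table.

    Every group is solved per sample independently; missing features enter
    as zero intensity (the zero-fill policy, matching the "low/absent"
    semantics of species undetectable in a group of samples).

    Returns
    -------
    corrected : pandas.DataFrame
        Species (entry_key) x samples corrected total intensities.
    diagnostics : pandas.DataFrame
        Per (group, sample): residual norm, rank flag.
    unknowns : pandas.DataFrame
        Features with no annotation, passed through unchanged.
    """
    grouped_features = {f for g in groups for f in g.feature_ids}
    annotated = set(annotations["feature_id"]) if not annotations.empty else set()
    if not grouped_features <= set(table.features.index):
        raise ValueError("groups reference features absent from the table")

    sample_ids = table.sample_ids
    rows: Dict[str, np.ndarray] = {}
    diag_rows: List[dict] = []
    for gi, group in enumerate(groups):
        system = build_system(group)
        Y = table.intensities.reindex(system.feature_ids).fillna(0.0).to_numpy()
        rank = np.linalg.matrix_rank(system.design)
        resolved = rank >= len(system.entry_keys)
        X = np.empty((len(system.entry_keys), len(sample_ids)))
        for si in range(len(sample_ids)):
            x, rnorm = solve_nnls(system.design, Y[:, si])
            X[:, si] = x if resolved else np.nan
            diag_rows.append(
                {
                    "group": gi,
                    "sample_id": sample_ids[si],
                    "n_species": len(system.entry_keys),
                    "n_features": len(system.feature_ids),
                    "residual_norm": rnorm,
                    "resolved": resolved,
                }
            )
        for j, key in enumerate(system.entry_keys):
            rows[key] = X[j]
    corrected = pd.DataFrame.from_dict(
        rows, orient="index", columns=sample_ids
    ).sort_index()
    corrected.index.name = "entry_key"
    unknown_ids = [
        f for f in table.features.index
        if f not in grouped_features and f not in annotated
    ]
    unknowns = table.features.loc[unknown_ids].join(
        table.intensities.loc[unknown_ids]
    )
    return corrected, pd.DataFrame(diag_rows), unknowns
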