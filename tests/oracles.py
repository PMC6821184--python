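"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a deliberately different route from
the library code: atom-by-atom polynomial expansion for isotopologue
distributions, an exhaustive all-pairs scan for feature matching,
coordinate-wise grid refinement for non-negative least squares, classic
sequential peel-off subtraction for triangular systems, and a data-level
Monte-Carlo simulation for the Dunnett max-|t| null.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from lipidquant.chem import ElementalFormula, element_table


def brute_isotope_distribution(
    formula: ElementalFormula, max_shift: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Atom-by-atom polynomial expansion over all isotopologue combinations.

    Convolves the single-atom isotope pattern one atom at a time (no
    multinomial closed forms), tracking probability and probability-weighted
    exact mass per nominal shift. Returns (abundances, mean mass shifts).
    """
    table = element_table()
    prob = np.zeros(max_shift + 1)
    prob[0] = 1.0
    pmass = np.zeros(max_shift + 1)  # sum of p * mass-excess
    for el, n in formula.counts:
        isotopes = table[el]
        base_mass = isotopes[0][1]
        for _ in range(n):
            new_p = np.zeros(max_shift + 1)
            new_m = np.zeros(max_shift + 1)
            for shift, mass, ab in isotopes:
                dm = mass - base_mass
                for s0 in range(max_shift + 1 - shift):
                    new_p[s0 + shift] += prob[s0] * ab
                    new_m[s0 + shift] += (pmass[s0] + prob[s0] * dm) * ab
            prob, pmass = new_p, new_m
    mean = np.divide(pmass, prob, out=np.zeros_like(pmass), where=prob > 0)
    return prob, mean


def all_pairs_match(
    feature_mz: Sequence[float],
    feature_mode: Sequence[str],
    candidate_mz: Sequence[float],
    candidate_mode: Sequence[str],
    tolerance_ppm: float,
) -> Dict[int, List[int]]:
    """Exhaustive scan: feature index -> candidate indices within tolerance."""
    out: Dict[int, List[int]] = {}
    for i, (fm, fmode) in enumerate(zip(feature_mz, feature_mode)):
        hits = []
        for j, (cm, cmode) in enumerate(zip(candidate_mz, candidate_mode)):
            if fmode != cmode:
                continue
            if abs((fm - cm) / cm * 1e6) <= tolerance_ppm:
                hits.append(j)
        if hits:
            out[i] = hits
    return out


def grid_refine_nnls(
    A: np.ndarray, y: np.ndarray, n_rounds: int = 300, grid: int = 41
) -> np.ndarray:
    """Coordinate-wise shrinking-grid minimization of ||Ax - y|| over x >= 0.

    The objective is convex, so cyclic grid line searches with a slowly
    refining (and edge-expanding) step converge to the NNLS solution.
    """
    m, n = A.shape
    x = np.zeros(n)
    col_max = np.maximum(A.max(axis=0), 1e-12)
    steps = np.maximum(y.max() / col_max, 1.0)
    offsets = np.linspace(-1.0, 1.0, grid)

    def obj(v):
        r = A @ v - y
        return float(r @ r)

    for _ in range(n_rounds):
        for j in range(n):
            cand = np.clip(x[j] + steps[j] * offsets, 0.0, None)
            best_v, best_o = x[j], obj(x)
            trial = x.copy()
            for c in cand:
                trial[j] = c
                o = obj(trial)
                if o < best_o:
                    best_o, best_v = o, c
            at_edge = best_v in (cand[0], cand[-1]) and best_v != x[j]
            x[j] = best_v
            steps[j] *= 2.0 if at_edge else 0.9
    return x


def random_correction_system(
    rng: np.random.Generator, n_species: int
) -> tuple:
    """A random isotopologue-style design with a non-negative truth.

    Columns mimic truncated isotope patterns (a dominant monoisotopic
    fraction followed by decaying isotopologues) placed at random integer
    peak offsets, the structure real overlap groups have.
    """
    # distinct monoisotopic offsets: every species owns its M0 peak row
    offsets = np.sort(
        rng.choice(np.arange(n_species + 2), size=n_species, replace=False)
    )
    patterns = []
    for _ in range(n_species):
        m0 = rng.uniform(0.45, 0.95)
        tail = np.array([m0, 0.0, 0.0, 0.0])
        rest = 1.0 - m0
        for k in (1, 2, 3):
            frac = rest * rng.uniform(0.4, 0.8)
            tail[k] = frac
            rest -= frac
        patterns.append(tail)
    m = int(offsets.max()) + 4
    A = np.zeros((m, n_species))
    for j, (off, pat) in enumerate(zip(offsets, patterns)):
        A[off:off + 4, j] = pat
    keep = A.any(axis=1)
    A = A[keep]
    x_true = rng.uniform(0.0, 1000.0, n_species)
    return A, x_true


def peel_off_triangular(
    design: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Classic sequential subtraction for a strictly triangular system.

    Assumes columns ordered so that species j's monoisotopic peak is row j
    and only species i < j contaminate row j. Solves row by row,
    subtracting the predicted isotopologue contribution of already-solved
    species.
    """
    n = design.shape[1]
    x = np.zeros(n)
    for j in range(n):
        contamination = design[j, :j] @ x[:j]
        x[j] = (observed[j] - contamination) / design[j, j]
    return x


def dunnett_max_t_pvalue(
    t_obs: float,
    n_per_group: Sequence[int],
    n_control: int,
    n_draws: int = 1_000_000,
    seed: int = 12345,
) -> float:
    """Brute-force data-level Monte Carlo of the Dunnett max-|t| null.

    Simulates raw normal observations for every group, computes the pooled
    ANOVA error and every comparison-vs-control t statistic, and returns
    P(max_j |T_j| >= |t_obs|).
    """
    rng = np.random.default_rng(seed)
    ns = [n_control] + list(n_per_group)
    k = len(n_per_group)
    total = sum(ns)
    df = total - len(ns)
    max_abs = np.zeros(n_draws)
    # blockwise to bound memory
    block = 100_000
    out = []
    for start in range(0, n_draws, block):
        b = min(block, n_draws - start)
        sse = np.zeros(b)
        means = []
        for n_g in ns:
            data = rng.standard_normal((b, n_g))
            mu = data.mean(axis=1)
            sse += ((data - mu[:, None]) ** 2).sum(axis=1)
            means.append(mu)
        mse = sse / df
        m = np.zeros(b)
        for j in range(1, len(ns)):
            t = (means[j] - means[0]) / np.sqrt(
                mse * (1 / ns[j] + 1 / ns[0])
            )
            m = np.maximum(m, np.abs(t))
        out.append(m)
    max_abs = np.concatenate(out)
    return float(np.mean(max_abs >= abs(t_obs)))
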