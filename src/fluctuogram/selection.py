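"""Select putative communication residues and score them against references.

From the window series of residue-residue couplings ``k_IJ(t)`` the mean,
standard deviation and maximum over windows are tabulated per pair; three
criteria then pick residues:

* Criterion A (hubs): residue I is selected when at least ``N_cut``
  partners J with ``|I-J| > 3`` couple to it with mean ``k_IJ >= k_cut``.
* Criterion B (strong pairs): both residues of any pair with ``|I-J| > 3``
  and mean ``k_IJ >= K_B`` are selected.
* Criterion C (variable pairs): both residues of any pair with
  ``|I-J| > 3`` whose maximum coupling reaches ``K_C`` and whose
  normalized variation (coefficient of variation by default) reaches
  ``s_C`` are selected.

Selections are scored against a reference residue list with a +/-1
neighbour tolerance: the hit rate H is the fraction of selected residues
that land within the tolerance of a reference residue, the coverage C the
fraction of reference residues matched by a selection.  A Monte-Carlo
baseline draws the same number of residues uniformly without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluctgram import ResidueCouplingSeries

_VARIATION_MODES = ("cv_mean", "cv_max", "absolute")


@dataclass
class CouplingStatistics:
    """Mean / standard deviation / maximum of k_IJ over windows, per pair."""

    residues: np.ndarray    # sorted 1-based residue indices, length R
    mean: np.ndarray        # (R, R)
    sd: np.ndarray          # (R, R) population convention
    max: np.ndarray         # (R, R)

    @property
    def separation(self) -> np.ndarray:
        return np.abs(self.residues[:, None] - self.residues[None, :])


@dataclass
class CriteriaParams:
    """Cutoffs of the three selection criteria (kcal/mol/A^2 where dimensional)."""

    k_cut: float = 2.5
    n_cut: int = 10
    k_b: float = 11.0
    k_c: float = 8.0
    s_c: float = 0.8
    min_separation: int = 4       # pairs count only when |I-J| >= this (> 3)
    variation_mode: str = "cv_mean"

    def __post_init__(self) -> None:
        if min(self.k_cut, self.k_b, self.k_c, self.s_c) < 0 or self.n_cut < 0:
            raise ValueError("cutoffs must be non-negative")
        if self.variation_mode not in _VARIATION_MODES:
            raise ValueError(f"variation_mode must be one of {_VARIATION_MODES}")


@dataclass
class SelectionEvaluation:
    """Hit rate and coverage of a selection against a reference set."""

    selected: np.ndarray
    reference: np.ndarray
    tolerance: int
    n_selected: int
    n_hits: int
    hit_rate: float              # NaN when the selection is empty
    n_covered: int
    n_reference: int
    coverage: float


@dataclass
class BaselineStatistics:
    """Monte-Carlo statistics of uniformly random selections."""

    n_pick: int
    n_residues: int
    n_rounds: int
    seed: int
    mean_hits: float
    sd_hits: float
    mean_covered: float
    sd_covered: float
    mean_ratio: float            # covered reference residues / n_pick
    sd_ratio: float
    mean_hit_rate: float
    sd_hit_rate: float


def pair_statistics(series: ResidueCouplingSeries) -> CouplingStatistics:
    """Tabulate mean, population SD and maximum of k_IJ over windows."""
    if series.n_windows < 1:
        raise ValueError("need at least one window")
    return CouplingStatistics(
        residues=series.residues,
        mean=series.k_ij.mean(axis=0),
        sd=series.k_ij.std(axis=0),
        max=series.k_ij.max(axis=0),
    )


def _pair_mask(stats: CouplingStatistics, params: CriteriaParams) -> np.ndarray:
    """Off-diagonal pairs at or beyond the sequence-separation cutoff."""
    return stats.separation >= params.min_separation


def criterion_a(stats: CouplingStatistics, params: CriteriaParams) -> np.ndarray:
    """Residues with >= n_cut well-separated partners at mean k_IJ >= k_cut."""
    eligible = _pair_mask(stats, params) & (stats.mean >= params.k_cut)
    n_partners = eligible.sum(axis=1)
    return stats.residues[n_partners >= params.n_cut]


def criterion_b(stats: CouplingStatistics, params: CriteriaParams) -> np.ndarray:
    """Both members of every well-separated pair with mean k_IJ >= K_B."""
    strong = _pair_mask(stats, params) & (stats.mean >= params.k_b)
    return stats.residues[strong.any(axis=1)]


def criterion_c(stats: CouplingStatistics, params: CriteriaParams) -> np.ndarray:
    """Both members of well-separated pairs with high maximum AND high variation.

    The variation statistic is selected by ``params.variation_mode``:
    ``cv_mean`` = sd/mean (pairs with zero mean are excluded), ``cv_max`` =
    sd/max, ``absolute`` = sd itself.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.variation_mode == "cv_mean":
            variation = np.where(stats.mean > 0, stats.sd / stats.mean, -np.inf)
        elif params.variation_mode == "cv_max":
            variation = np.where(stats.max > 0, stats.sd / stats.max, -np.inf)
        else:
            variation = stats.sd
    qualify = (_pair_mask(stats, params)
               & (stats.max >= params.k_c)
               & (variation >= params.s_c))
    return stats.residues[qualify.any(axis=1)]


def combine_criteria(
    stats: CouplingStatistics,
    params: CriteriaParams,
) -> tuple[np.ndarray, dict[int, str]]:
    """Union of the A/B/C selections with per-residue provenance flags.

    Returns ``(residues, provenance)`` where provenance maps residue ->
    subset of "ABC" indicating which criteria selected it.
    """
    picks = {"A": criterion_a(stats, params),
             "B": criterion_b(stats, params),
             "C": criterion_c(stats, params)}
    provenance: dict[int, str] = {}
    for label, residues in picks.items():
        for r in residues:
            provenance[int(r)] = provenance.get(int(r), "") + label
    return np.array(sorted(provenance), dtype=int), provenance


def _within_tolerance(queries: np.ndarray, targets: np.ndarray,
                      tolerance: int) -> np.ndarray:
    """Boolean per query: lies within +/-tolerance of some target."""
    if len(targets) == 0:
        return np.zeros(len(queries), dtype=bool)
    diff = np.abs(queries[:, None] - targets[None, :])
    return (diff <= tolerance).any(axis=1)


def evaluate_selection(
    selected: np.ndarray,
    reference: np.ndarray,
    tolerance: int = 1,
) -> SelectionEvaluation:
    """Hit rate H and coverage C of a selection, with +/-tolerance matching."""
    selected = np.unique(np.asarray(selected, dtype=int))
    reference = np.unique(np.asarray(reference, dtype=int))
    hits = _within_tolerance(selected, reference, tolerance)
    covered = _within_tolerance(reference, selected, tolerance)
    n_sel, n_ref = len(selected), len(reference)
    return SelectionEvaluation(
        selected=selected,
        reference=reference,
        tolerance=tolerance,
        n_selected=n_sel,
        n_hits=int(hits.sum()),
        hit_rate=float(hits.sum() / n_sel) if n_sel else float("nan"),
        n_covered=int(covered.sum()),
        n_reference=n_ref,
        coverage=float(covered.sum() / n_ref) if n_ref else float("nan"),
    )


def random_baseline(
    n_pick: int,
    n_residues: int,
    reference: np.ndarray,
    tolerance: int = 1,
    n_rounds: int = 10000,
    seed: int = 0,
) -> BaselineStatistics:
    """Monte-Carlo baseline of uniformly random residue picks.

    Each round draws ``n_pick`` residues from ``1..n_residues`` without
    replacement and scores hits (picked residues within +/-tolerance of a
    reference residue), covered reference residues, the covered/n_pick
    ratio and the hit rate.  Deterministic for a fixed seed.
    """
    if n_pick > n_residues:
        raise ValueError("cannot pick more residues than exist")
    reference = np.unique(np.asarray(reference, dtype=int))
    rng = np.random.default_rng(seed)
    # n_rounds random permutations, first n_pick entries each (1-based)
    picks = np.argsort(rng.random((n_rounds, n_residues)), axis=1)[:, :n_pick] + 1

    # hit indicator over the residue axis: within +/-tol of a reference residue
    near_ref = np.zeros(n_residues + 2 * tolerance + 2, dtype=bool)
    for r in reference:
        near_ref[max(r - tolerance, 1): r + tolerance + 1] = True
    hits = near_ref[picks].sum(axis=1)

    # coverage: per round, was any pick within +/-tol of each reference residue
    picked = np.zeros((n_rounds, n_residues + 2 * tolerance + 2), dtype=bool)
    np.put_along_axis(picked, picks + tolerance, True, axis=1)
    covered = np.zeros(n_rounds, dtype=int)
    for r in reference:
        window = picked[:, r: r + 2 * tolerance + 1]
        covered += window.any(axis=1)

    ratio = covered / n_pick
    hit_rate = hits / n_pick
    return BaselineStatistics(
        n_pick=n_pick, n_residues=n_residues, n_rounds=n_rounds, seed=seed,
        mean_hits=float(hits.mean()), sd_hits=float(hits.std()),
        mean_covered=float(covered.mean()), sd_covered=float(covered.std()),
        mean_ratio=float(ratio.mean()), sd_ratio=float(ratio.std()),
        mean_hit_rate=float(hit_rate.mean()), sd_hit_rate=float(hit_rate.std()),
    )
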