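"""Per-site conservation screen of cavity residues.

For each cavity site (given in reference coordinates), the screen compares
the pairwise Grantham distances among a small foreground set of receptors
(e.g. the odor-responsive ones) against the pairwise distances within the
full receptor background at the same alignment column.  A site is called
relatively conserved in the foreground when its foreground mean pairwise
distance is significantly lower than the background's.

Three tests are offered.  The two-sample tests (Mann-Whitney, Welch t)
treat the C(n,2) pairwise distances of each group as observations; because
pairs share sequences these are not independent, so a subset-permutation
test — re-drawing foreground-sized subsets from the background and comparing
mean pairwise distances — is also provided and is the statistically safer
choice.  The Mann-Whitney default mirrors common practice.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignmentSet, SitePanel, build_position_map
from .grantham import AMINO_ACIDS, canonical_matrix

__all__ = [
    "ScreenConfig",
    "SiteResult",
    "site_pairwise_distances",
    "mean_pairwise_distance",
    "permutation_null",
    "screen_sites",
    "results_frame",
]

_TESTS = ("mann_whitney", "t_test", "permutation")
_ALTERNATIVES = ("less", "two-sided")


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings.

    ``alternative='less'`` is the one-sided convention: foreground more
    conserved (smaller distances) than background.  ``min_ungapped`` is the
    minimum number of usable (non-gap, non-X) foreground residues a site
    needs for a test; sites below it are reported with the p-value marked
    unavailable rather than dropped.  ``multiple_testing='bh'`` applies
    Benjamini-Hochberg across panel sites before flagging.
    """

    test: str = "mann_whitney"
    alternative: str = "less"
    alpha: float = 0.05
    permutations: int = 999
    seed: int = 0
    min_ungapped: int = 2
    include_foreground_in_background: bool = True
    multiple_testing: str = "none"

    def __post_init__(self) -> None:
        if self.test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}, got {self.test!r}")
        if self.alternative not in _ALTERNATIVES:
            raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test == "permutation" and self.permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.min_ungapped < 2:
            raise ValueError("min_ungapped must be >= 2")
        if self.multiple_testing not in ("none", "bh"):
            raise ValueError("multiple_testing must be 'none' or 'bh'")


@dataclass
class SiteResult:
    """Per-site screen output (positions and columns are 1-based)."""

    position: int
    column: int
    ref_residue: str
    label: str
    fg_mean: float
    bg_mean: float
    n_fg: int
    n_bg: int
    n_fg_pairs: int
    n_bg_pairs: int
    statistic: float
    p_value: float
    q_value: float
    conserved: bool
    note: str = ""


@functools.lru_cache(maxsize=1)
def _default_matrix_arrays():
    mat = canonical_matrix()
    lookup = {aa: i for i, aa in enumerate(mat.index)}
    return mat.to_numpy(dtype=float), lookup


def _matrix_arrays(matrix: pd.DataFrame | None):
    if matrix is None:
        return _default_matrix_arrays()
    lookup = {aa: i for i, aa in enumerate(matrix.index)}
    return matrix.to_numpy(dtype=float), lookup


def _residue_indices(residues, lookup) -> np.ndarray:
    try:
        return np.array([lookup[r] for r in residues], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown residue code {e.args[0]!r} in column residues") from None


def site_pairwise_distances(residues, matrix: pd.DataFrame | None = None) -> np.ndarray:
    """All C(n,2) pairwise Grantham distances over usable column residues.

    ``residues`` is a sequence of one-letter codes with gaps/'X' already
    removed (a ``collections.Counter`` is also accepted).  Returns an empty
    array when fewer than two residues are given.
    """
    if hasattr(residues, "elements"):  # Counter / multiset
        residues = list(residues.elements())
    else:
        residues = list(residues)
    if len(residues) < 2:
        return np.empty(0)
    D, lookup = _matrix_arrays(matrix)
    idx = _residue_indices(residues, lookup)
    sq = D[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sq[iu]


def mean_pairwise_distance(residues, matrix: pd.DataFrame | None = None) -> float:
    """Mean of the pairwise distances; NaN when fewer than two residues."""
    d = site_pairwise_distances(residues, matrix)
    return float(d.mean()) if d.size else math.nan


def _usable(chars: np.ndarray) -> np.ndarray:
    """Drop gaps and ambiguous residues from a column slice."""
    return chars[(chars != "-") & (chars != "X")]


def _subset_mean_pairwise(idx_matrix: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Mean pairwise distance for each row of residue-index subsets."""
    k = idx_matrix.shape[1]
    sq = D[idx_matrix[:, :, None], idx_matrix[:, None, :]]
    return sq.sum(axis=(1, 2)) / (k * (k - 1))


def permutation_null(
    aln: AlignmentSet,
    column: int,
    foreground_ids,
    background_ids=None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    matrix: pd.DataFrame | None = None,
    alternative: str = "less",
) -> tuple[float, float]:
    """Subset-permutation p-value for the observed foreground mean distance.

    Draws ``n_perm`` foreground-sized subsets (without replacement) from the
    usable background residues at ``column`` and compares their mean pairwise
    distances with the observed foreground mean.  Lower-tail p-value is
    ``(1 + #{permuted <= observed}) / (1 + n_perm)``.

    Returns ``(p_value, observed_mean)``; p is NaN when the foreground has
    fewer than two usable residues or the background cannot supply a
    foreground-sized subset.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    D, lookup = _matrix_arrays(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fg = _usable(aln.column(column)[aln.row_indices(list(foreground_ids))])
    bg_ids = list(background_ids) if background_ids is not None else list(aln.ids)
    bg = _usable(aln.column(column)[aln.row_indices(bg_ids)])
    k = len(fg)
    if k < 2 or len(bg) < k:
        return math.nan, mean_pairwise_distance(fg, matrix)
    fg_idx = _residue_indices(fg, lookup)
    bg_idx = _residue_indices(bg, lookup)
    observed = float(D[np.ix_(fg_idx, fg_idx)].sum() / (k * (k - 1)))
    # vectorized subsets: argsort of uniforms gives random permutations
    order = np.argsort(rng.random((n_perm, len(bg_idx))), axis=1)[:, :k]
    perm_means = _subset_mean_pairwise(bg_idx[order], D)
    p_low = (1 + np.sum(perm_means <= observed + 1e-12)) / (1 + n_perm)
    if alternative == "less":
        p = p_low
    else:
        p_high = (1 + np.sum(perm_means >= observed - 1e-12)) / (1 + n_perm)
        p = min(1.0, 2 * min(p_low, p_high))
    return float(p), observed


def _two_sample_test(fg: np.ndarray, bg: np.ndarray, test: str, alternative: str):
    if test == "mann_whitney":
        res = stats.mannwhitneyu(fg, bg, alternative=alternative, method="auto")
    else:
        res = stats.ttest_ind(fg, bg, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, NaN-aware."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def screen_sites(
    aln: AlignmentSet,
    panel: SitePanel,
    reference_id: str,
    foreground_ids,
    background_ids=None,
    config: ScreenConfig | None = None,
    matrix: pd.DataFrame | None = None,
) -> list[SiteResult]:
    """Run the conservation screen over every panel site.

    One :class:`SiteResult` per site, in panel order; sites with fewer than
    ``config.min_ungapped`` usable foreground residues are reported with the
    p-value unavailable, never dropped.  Results are invariant to receptor
    relabeling and record order.
    """
    config = config or ScreenConfig()
    fg_ids = list(foreground_ids)
    if len(fg_ids) < 2:
        raise ValueError(f"need at least 2 foreground receptors, got {len(fg_ids)}")
    posmap = build_position_map(aln, reference_id)
    bg_ids = list(background_ids) if background_ids is not None else list(aln.ids)
    if not config.include_foreground_in_background:
        bg_ids = [i for i in bg_ids if i not in set(fg_ids)]
    aln.row_indices(fg_ids)  # validate up front
    aln.row_indices(bg_ids)
    D, lookup = _matrix_arrays(matrix)
    rng = np.random.default_rng(config.seed)

    results: list[SiteResult] = []
    for site in panel:
        column = posmap.column_of(site.position)
        ref_res = posmap.residue_at(site.position)
        fg = _usable(aln.column(column)[aln.row_indices(fg_ids)])
        bg = _usable(aln.column(column)[aln.row_indices(bg_ids)])
        fg_d = site_pairwise_distances(fg, matrix)
        bg_d = site_pairwise_distances(bg, matrix)
        fg_mean = float(fg_d.mean()) if fg_d.size else math.nan
        bg_mean = float(bg_d.mean()) if bg_d.size else math.nan
        stat = p = math.nan
        note = ""
        if len(fg) < config.min_ungapped:
            note = "insufficient foreground residues"
        elif len(bg) < 2:
            note = "insufficient background residues"
        elif config.test == "permutation":
            p, _ = permutation_null(
                aln, column, fg_ids, bg_ids, config.permutations, rng, matrix,
                alternative=config.alternative,
            )
            if math.isnan(p):
                note = "background smaller than foreground"
        elif fg_d.size and bg_d.size:
            if np.ptp(np.concatenate([fg_d, bg_d])) == 0:
                # monomorphic data: no evidence either way
                stat, p = math.nan, 1.0
            else:
                stat, p = _two_sample_test(fg_d, bg_d, config.test, config.alternative)
        results.append(
            SiteResult(
                position=site.position,
                column=column,
                ref_residue=ref_res,
                label=site.label,
                fg_mean=fg_mean,
                bg_mean=bg_mean,
                n_fg=int(len(fg)),
                n_bg=int(len(bg)),
                n_fg_pairs=int(fg_d.size),
                n_bg_pairs=int(bg_d.size),
                statistic=stat,
                p_value=p,
                q_value=math.nan,
                conserved=False,
                note=note,
            )
        )

    pvals = np.array([r.p_value for r in results], dtype=float)
    qvals = _bh_adjust(pvals) if config.multiple_testing == "bh" else pvals.copy()
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        r.conserved = bool(
            not math.isnan(q)
            and q <= config.alpha
            and not math.isnan(r.fg_mean)
            and not math.isnan(r.bg_mean)
            and r.fg_mean < r.bg_mean
        )
    return results


def results_frame(results: list[SiteResult]) -> pd.DataFrame:
    """Screen results as a tidy DataFrame (one row per panel site)."""
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "column": r.column,
                "ref_residue": r.ref_residue,
                "label": r.label,
                "fg_mean": r.fg_mean,
                "bg_mean": r.bg_mean,
                "n_fg": r.n_fg,
                "n_bg": r.n_bg,
                "n_fg_pairs": r.n_fg_pairs,
                "n_bg_pairs": r.n_bg_pairs,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "conserved": r.conserved,
                "note": r.note,
            }
            for r in results
        ]
    )
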