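"""Seeded synthetic inputs for every pipeline stage.

Three generators mirror the statistical structure the pipeline assumes:

* :func:`gen_family` — a receptor family alignment with a small foreground
  subset that is physicochemically conserved at planted sites.  Conservation
  is modeled directly as a Grantham-radius residue pool around an anchor
  residue, so the planted effect size is exactly the quantity the screen
  measures (a substitution-process simulator would be indirect and is out of
  scope).
* :func:`gen_counts` — a two-group negative-binomial count table with planted
  down- (and up-) regulated genes, with receptor class labels so the
  candidate filter can be exercised end to end.
* :func:`gen_plate` — dual-luciferase plates with concentration-dependent
  responders and multiplicative (lognormal) noise on both luminescence
  channels.

Every generator is deterministic under a fixed seed, and returns a truth
record that fully determines the expected qualitative outcome downstream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentSet
from .grantham import AMINO_ACIDS, canonical_matrix

__all__ = [
    "FamilySpec",
    "PlantedSite",
    "FamilyTruth",
    "CountSpec",
    "CountTruth",
    "PlateSpec",
    "PlateTruth",
    "conserved_pool",
    "gen_family",
    "gen_counts",
    "gen_plate",
]


# ---------------------------------------------------------------------------
# receptor family


@dataclass(frozen=True)
class FamilySpec:
    """Synthetic receptor-family parameters.

    Defaults emulate the study geometry: a foreground of 5 responsive
    receptors against a 200-receptor annotated background (a desk-scale
    stand-in for a full repertoire of several hundred to >1000), sequence
    length 310 (typical OR length), three planted conserved sites at Grantham
    radius 50.  ``dirichlet_alpha`` < inf perturbs the per-column background
    residue distribution away from uniform (smaller = spikier columns);
    ``None`` keeps it uniform.
    """

    n_background: int = 200
    n_foreground: int = 5
    length: int = 310
    planted_sites: tuple[int, ...] = (40, 150, 250)
    anchors: tuple[str, ...] | None = None
    radius: float = 50.0
    gap_rate: float = 0.02
    dirichlet_alpha: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foreground < 2:
            raise ValueError("need at least 2 foreground receptors")
        if self.n_background < 2:
            raise ValueError("need at least 2 background receptors")
        if not 0 <= self.gap_rate < 0.5:
            raise ValueError("gap_rate must be in [0, 0.5)")
        if self.radius < 0:
            raise ValueError("conservation radius must be >= 0 (pool would be empty)")
        if any(not 1 <= p <= self.length for p in self.planted_sites):
            raise ValueError("planted sites must lie within the sequence length")
        if len(set(self.planted_sites)) != len(self.planted_sites):
            raise ValueError("planted sites must be unique")
        if self.anchors is not None and len(self.anchors) != len(self.planted_sites):
            raise ValueError("one anchor per planted site required")
        if self.dirichlet_alpha is not None and self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass(frozen=True)
class PlantedSite:
    position: int
    anchor: str
    radius: float
    pool: tuple[str, ...]


@dataclass(frozen=True)
class FamilyTruth:
    reference_id: str
    foreground_ids: tuple[str, ...]
    background_ids: tuple[str, ...]
    planted: tuple[PlantedSite, ...]
    seed: int


def conserved_pool(anchor: str, radius: float) -> tuple[str, ...]:
    """Residues within Grantham radius ``radius`` of ``anchor`` (canonical table)."""
    mat = canonical_matrix()
    if anchor not in mat.index:
        raise ValueError(f"unknown anchor residue {anchor!r}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return tuple(a for a in AMINO_ACIDS if mat.loc[anchor, a] <= radius)


def gen_family(spec: FamilySpec) -> tuple[AlignmentSet, FamilyTruth]:
    """Generate an aligned receptor family with planted conserved foreground sites.

    The first background record (the designated reference) carries no gaps,
    so reference residue positions coincide with alignment columns.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    L = spec.length
    n_bg, n_fg = spec.n_background, spec.n_foreground

    if spec.dirichlet_alpha is None:
        col_probs = np.full((L, 20), 1 / 20)
    else:
        col_probs = rng.dirichlet(np.full(20, spec.dirichlet_alpha), size=L)

    # cumulative-probability sampling, one column at a time (vectorized rows)
    def draw(n_rows: int) -> np.ndarray:
        u = rng.random((n_rows, L))
        cum = np.cumsum(col_probs, axis=1)  # (L, 20)
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        return aas[idx]

    bg = draw(n_bg)
    fg = draw(n_fg)

    anchors = spec.anchors
    if anchors is None:
        anchors = tuple(rng.choice(aas, size=len(spec.planted_sites)))
    planted = []
    for pos, anchor in zip(spec.planted_sites, anchors):
        pool = conserved_pool(str(anchor), spec.radius)
        fg[:, pos - 1] = rng.choice(np.array(pool), size=n_fg)
        planted.append(PlantedSite(pos, str(anchor), spec.radius, pool))

    # deletion-style gaps everywhere except the reference record (row 0)
    if spec.gap_rate > 0:
        gaps_bg = rng.random((n_bg, L)) < spec.gap_rate
        gaps_bg[0] = False
        bg[gaps_bg] = "-"
        gaps_fg = rng.random((n_fg, L)) < spec.gap_rate
        fg[gaps_fg] = "-"

    bg_ids = ["REF"] + [f"BG{i:04d}" for i in range(1, n_bg)]
    fg_ids = [f"FG{i:02d}" for i in range(1, n_fg + 1)]
    aln = AlignmentSet(
        bg_ids + fg_ids,
        ["".join(row) for row in bg] + ["".join(row) for row in fg],
    )
    truth = FamilyTruth(
        reference_id="REF",
        foreground_ids=tuple(fg_ids),
        background_ids=tuple(bg_ids),
        planted=tuple(planted),
        seed=spec.seed,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# count tables


@dataclass(frozen=True)
class CountSpec:
    """Two-group RNA-seq-like count-table parameters.

    Defaults emulate the study's two-group olfactory-epithelium design
    (2 animals x left/right per group -> 4 samples per group) at desk scale:
    2000 genes of which 120 are receptor (OR) genes and 150 receptor-like,
    with 15 OR, 49 OR-like and 76 other genes planted 4-fold down and 60
    genes planted 4-fold up.  ``dispersion`` is the negative-binomial
    dispersion (variance = m + dispersion * m^2); 0.05 corresponds to a
    biological coefficient of variation of ~22%, typical for genetically
    similar animals.  ``dispersion = 0`` gives Poisson counts.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    fold_change: float = 4.0
    n_or: int = 120
    n_or_like: int = 150
    n_planted_or: int = 15
    n_planted_or_like: int = 49
    n_planted_other: int = 76
    n_planted_up: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.n_or + self.n_or_like > self.n_genes:
            raise ValueError("more receptor genes than genes")
        if self.n_planted_or > self.n_or or self.n_planted_or_like > self.n_or_like:
            raise ValueError("more planted receptor genes than receptor genes")
        n_other = self.n_genes - self.n_or - self.n_or_like
        if self.n_planted_other + self.n_planted_up > n_other:
            raise ValueError("more planted non-receptor genes than available")


@dataclass(frozen=True)
class CountTruth:
    annotation: dict
    planted_down_or: tuple[str, ...]
    planted_down_or_like: tuple[str, ...]
    planted_down_other: tuple[str, ...]
    planted_up: tuple[str, ...]
    fold_change: float
    groups: dict
    seed: int

    @property
    def planted_down(self) -> tuple[str, ...]:
        return self.planted_down_or + self.planted_down_or_like + self.planted_down_other


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def gen_counts(spec: CountSpec) -> tuple[pd.DataFrame, CountTruth]:
    """Generate a gene x sample count matrix with planted DE receptor genes."""
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:05d}" for i in range(1, spec.n_genes + 1)])
    classes = np.array(["other"] * spec.n_genes, dtype=object)
    classes[: spec.n_or] = "OR"
    classes[spec.n_or : spec.n_or + spec.n_or_like] = "OR-like"

    or_idx = np.where(classes == "OR")[0]
    orlike_idx = np.where(classes == "OR-like")[0]
    other_idx = np.where(classes == "other")[0]
    down_or = rng.choice(or_idx, spec.n_planted_or, replace=False)
    down_orlike = rng.choice(orlike_idx, spec.n_planted_or_like, replace=False)
    other_pick = rng.choice(
        other_idx, spec.n_planted_other + spec.n_planted_up, replace=False
    )
    down_other = other_pick[: spec.n_planted_other]
    up_other = other_pick[spec.n_planted_other :]

    ctrl_mean = np.full(spec.n_genes, spec.baseline_mean)
    trt_mean = ctrl_mean.copy()
    down_all = np.concatenate([down_or, down_orlike, down_other])
    trt_mean[down_all] /= spec.fold_change
    trt_mean[up_other] *= spec.fold_change

    n = spec.n_per_group
    ctrl = _nb_draw(rng, np.repeat(ctrl_mean[:, None], n, axis=1), spec.dispersion)
    trt = _nb_draw(rng, np.repeat(trt_mean[:, None], n, axis=1), spec.dispersion)
    samples = [f"ctrl_{i}" for i in range(1, n + 1)] + [f"trt_{i}" for i in range(1, n + 1)]
    counts = pd.DataFrame(np.hstack([ctrl, trt]), index=genes, columns=samples)
    counts.index.name = "gene_id"

    truth = CountTruth(
        annotation=dict(zip(genes, classes)),
        planted_down_or=tuple(genes[np.sort(down_or)]),
        planted_down_or_like=tuple(genes[np.sort(down_orlike)]),
        planted_down_other=tuple(genes[np.sort(down_other)]),
        planted_up=tuple(genes[np.sort(up_other)]),
        fold_change=spec.fold_change,
        groups={s: ("control" if s.startswith("ctrl") else "treatment") for s in samples},
        seed=spec.seed,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# reporter plates


@dataclass(frozen=True)
class PlateSpec:
    """Dual-luciferase plate parameters.

    ``constructs`` maps a construct label to its true fold activation at each
    odor concentration (missing concentrations and concentration 0 mean fold
    1.0, i.e. non-responding).  Noise on both luminescence channels is
    multiplicative lognormal with the stated coefficients of variation.
    Replicate count defaults to 6 wells per (construct, concentration).
    """

    constructs: dict
    concentrations: tuple[float, ...] = (0.0, 100.0, 200.0)
    n_replicates: int = 6
    cv_firefly: float = 0.1
    cv_renilla: float = 0.1
    firefly_baseline: float = 1000.0
    renilla_baseline: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.constructs:
            raise ValueError("at least one construct required")
        for name, profile in self.constructs.items():
            for conc, fold in profile.items():
                if fold <= 0:
                    raise ValueError(f"fold activation must be > 0 ({name!r} at {conc})")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cv_firefly < 0 or self.cv_renilla < 0:
            raise ValueError("CVs must be >= 0")
        if self.firefly_baseline <= 0 or self.renilla_baseline <= 0:
            raise ValueError("baselines must be positive")


@dataclass(frozen=True)
class PlateTruth:
    responders: dict
    seed: int


def _lognoise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2, sigma, size)


def gen_plate(spec: PlateSpec) -> tuple[pd.DataFrame, PlateTruth]:
    """Generate well-level dual-luciferase readings."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name in spec.constructs:
        profile = spec.constructs[name]
        for conc in spec.concentrations:
            fold = 1.0 if conc == 0 else float(profile.get(conc, 1.0))
            ff = spec.firefly_baseline * fold * _lognoise(rng, spec.cv_firefly, spec.n_replicates)
            rn = spec.renilla_baseline * _lognoise(rng, spec.cv_renilla, spec.n_replicates)
            for rep in range(1, spec.n_replicates + 1):
                rows.append((name, conc, rep, ff[rep - 1], rn[rep - 1]))
    plate = pd.DataFrame(
        rows, columns=["construct", "concentration_uM", "replicate", "firefly", "renilla"]
    )
    responders = {
        name: {c: f for c, f in profile.items() if c != 0 and f != 1.0}
        for name, profile in spec.constructs.items()
    }
    return plate, PlateTruth(responders=responders, seed=spec.seed)
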