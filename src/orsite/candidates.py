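"""Candidate receptor-gene filtering from differential-expression results.

Odor exposure transcriptionally down-regulates the responding receptor genes
in the olfactory epithelium, so candidate odor-responsive receptors are the
olfactory-receptor genes among the down-regulated DEGs.  The standard route
is: a DE results table from edgeR/DESeq2 (this module does not re-implement
them) -> cutoff filter -> intersection with an OR annotation list.

For synthetic end-to-end runs, :func:`simple_de_test` provides a plain
two-group Welch test on log2 CPM values; it is a pipeline stand-in, not a
negative-binomial DE method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEGSets",
    "CandidateSet",
    "read_de_table",
    "validate_de_table",
    "filter_degs",
    "intersect_candidates",
    "simple_de_test",
]

GENE_CLASSES = ("OR", "OR-like", "other")


@dataclass(frozen=True)
class DEGSets:
    """Down- and up-regulated gene-id sets with the cutoffs that made them."""

    down: frozenset
    up: frozenset
    lfc_cutoff: float
    p_cutoff: float

    @property
    def both(self) -> frozenset:
        return self.down | self.up


@dataclass(frozen=True)
class CandidateSet:
    """Down-regulated DEGs partitioned by receptor annotation class."""

    down: frozenset
    or_genes: frozenset
    or_like_genes: frozenset
    other_genes: frozenset
    lfc_cutoff: float = 1.0
    p_cutoff: float = 0.05

    def counts(self) -> dict[str, int]:
        return {
            "down": len(self.down),
            "OR": len(self.or_genes),
            "OR-like": len(self.or_like_genes),
            "other": len(self.other_genes),
        }


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a DE results table (gene_id, log2fc, p_value) and return it.

    p_value may be NaN (test unavailable, e.g. an all-zero gene); such rows
    never enter a DEG set.  Non-finite log2fc or p outside [0, 1] raises with
    the offending gene named.
    """
    required = {"gene_id", "log2fc", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in DE table")
    bad_lfc = ~np.isfinite(table["log2fc"].to_numpy(dtype=float))
    if bad_lfc.any():
        raise ValueError(f"non-finite log2fc for gene {table.loc[bad_lfc, 'gene_id'].iloc[0]!r}")
    p = table["p_value"].to_numpy(dtype=float)
    bad_p = ~np.isnan(p) & ((p < 0) | (p > 1))
    if bad_p.any():
        raise ValueError(f"p-value outside [0, 1] for gene {table.loc[bad_p, 'gene_id'].iloc[0]!r}")
    return table


def read_de_table(path) -> pd.DataFrame:
    """Read a DE results TSV with header columns gene_id, log2fc, p_value."""
    table = pd.read_csv(path, sep="\t")
    return validate_de_table(table)


def filter_degs(
    table: pd.DataFrame,
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    direction: str = "down",
) -> DEGSets:
    """Apply the DEG cutoffs: |log2fc| >= lfc_cutoff (inclusive) and p < p_cutoff (strict).

    ``direction`` selects which sets are populated ('down', 'up' or 'both');
    the untouched direction is returned empty.  Idempotent and row-order
    invariant.
    """
    if direction not in ("down", "up", "both"):
        raise ValueError(f"direction must be down, up or both, got {direction!r}")
    if lfc_cutoff < 0:
        raise ValueError("lfc_cutoff must be non-negative")
    validate_de_table(table)
    lfc = table["log2fc"].to_numpy(dtype=float)
    p = table["p_value"].to_numpy(dtype=float)
    sig = ~np.isnan(p) & (p < p_cutoff)
    genes = table["gene_id"].to_numpy()
    down = frozenset(genes[sig & (lfc <= -lfc_cutoff)]) if direction in ("down", "both") else frozenset()
    up = frozenset(genes[sig & (lfc >= lfc_cutoff)]) if direction in ("up", "both") else frozenset()
    return DEGSets(down=down, up=up, lfc_cutoff=lfc_cutoff, p_cutoff=p_cutoff)


def intersect_candidates(
    down_set,
    annotation,
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> CandidateSet:
    """Partition the down-regulated set by receptor class.

    ``annotation`` maps gene_id -> class ('OR', 'OR-like' or 'other'); genes
    absent from the annotation are treated as 'other' with a logged warning.
    """
    down = frozenset(down_set)
    ors, orlike, other = set(), set(), set()
    unannotated = []
    for g in down:
        cls = annotation.get(g)
        if cls is None:
            unannotated.append(g)
            cls = "other"
        elif cls not in GENE_CLASSES:
            raise ValueError(f"gene {g!r} has unknown class {cls!r}")
        {"OR": ors, "OR-like": orlike, "other": other}[cls].add(g)
    if unannotated:
        logger.warning("%d down-regulated genes missing from annotation, treated as 'other'",
                       len(unannotated))
    return CandidateSet(
        down=down,
        or_genes=frozenset(ors),
        or_like_genes=frozenset(orlike),
        other_genes=frozenset(other),
        lfc_cutoff=lfc_cutoff,
        p_cutoff=p_cutoff,
    )


def read_annotation(path) -> dict[str, str]:
    """Read a 2-column TSV (gene_id, class) into an annotation mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "class"], comment="#")
    if df.iloc[0, 0] == "gene_id":  # header tolerated
        df = df.iloc[1:]
    bad = set(df["class"]) - set(GENE_CLASSES)
    if bad:
        raise ValueError(f"unknown gene classes in annotation: {sorted(bad)}")
    return dict(zip(df["gene_id"], df["class"]))


def simple_de_test(
    counts: pd.DataFrame,
    groups,
    treatment: str,
    control: str,
) -> pd.DataFrame:
    """Two-group DE stand-in on a gene x sample count matrix.

    Counts are normalized to counts-per-million with pseudocount 0.5; the
    reported log2 fold change is log2 of the ratio of group mean CPMs
    (treatment over control) and the p-value is a two-sided Welch t-test on
    log2 CPM.  Genes with zero counts in every sample get log2fc 0 and an
    unavailable (NaN) p-value.

    ``groups`` maps sample (column) name -> group label, or is a sequence of
    labels aligned with the columns.
    """
    if isinstance(groups, dict):
        labels = np.array([groups[c] for c in counts.columns])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != counts.shape[1]:
            raise ValueError("groups length does not match number of samples")
    for lab in (treatment, control):
        if (labels == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any() or not np.isfinite(mat).all():
        raise ValueError("counts must be finite and non-negative")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    cpm = (mat + 0.5) / libsize[None, :] * 1e6
    logcpm = np.log2(cpm)
    t_cols = labels == treatment
    c_cols = labels == control
    mean_t = cpm[:, t_cols].mean(axis=1)
    mean_c = cpm[:, c_cols].mean(axis=1)
    log2fc = np.log2(mean_t / mean_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(logcpm[:, t_cols], logcpm[:, c_cols],
                              axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    all_zero = (mat == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = np.nan
    # constant identical groups: difference exactly 0 with no variance
    const = np.nan_to_num(np.ptp(logcpm, axis=1)) == 0
    p[const & ~all_zero] = 1.0
    log2fc[const] = 0.0
    return pd.DataFrame({"gene_id": counts.index, "log2fc": log2fc, "p_value": p}).reset_index(
        drop=True
    )
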