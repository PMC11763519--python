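"""Dual-luciferase reporter analysis.

In the dual-luciferase system, firefly luciferase reports receptor pathway
activation and co-transfected renilla luciferase normalizes for cell number
and transfection efficiency; the per-well response is the firefly/renilla
ratio.  Receptor activation is assessed by comparing stimulated wells against
the same construct's no-odor (0 uM) wells; mutant constructs are assessed
against the wild type after expressing every group relative to the mean of a
control group (e.g. receptor-free transfection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseSummary",
    "RelativeResponse",
    "read_plate",
    "validate_plate",
    "normalize_wells",
    "response_test",
    "summarize_responses",
    "relative_response",
    "significance_tier",
]

PLATE_COLUMNS = ["construct", "concentration_uM", "replicate", "firefly", "renilla"]
_TESTS = ("t_test", "mann_whitney")


def significance_tier(p: float) -> str:
    """'**' for p<0.01, '*' for p<0.05, 'ns' otherwise (NaN -> 'na')."""
    if p is None or math.isnan(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ResponseSummary:
    """Normalized response of one (construct, concentration) vs its 0 uM wells."""

    construct: str
    concentration_uM: float
    n: int
    mean: float
    sem: float
    reference_n: int
    reference_mean: float
    statistic: float
    p_value: float

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


@dataclass(frozen=True)
class RelativeResponse:
    """Mutant vs wild-type response, both relative to the control-group mean."""

    mutant: str
    wildtype: str
    control: str
    concentration_uM: float
    mutant_n: int
    mutant_mean: float
    mutant_sem: float
    wildtype_n: int
    wildtype_mean: float
    wildtype_sem: float
    statistic: float
    p_value: float

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    for col in ("firefly", "renilla", "concentration_uM"):
        v = plate[col].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in column {col!r}")
    dup = plate.duplicated(subset=["construct", "concentration_uM", "replicate"])
    if dup.any():
        row = plate[dup].iloc[0]
        raise ValueError(
            f"duplicate replicate index {row['replicate']} for "
            f"({row['construct']}, {row['concentration_uM']} uM)"
        )
    return plate


def read_plate(path) -> pd.DataFrame:
    """Read a plate TSV with columns construct, concentration_uM, replicate, firefly, renilla."""
    return validate_plate(pd.read_csv(path, sep="\t"))


def normalize_wells(plate: pd.DataFrame) -> pd.DataFrame:
    """Add the per-well normalized response (firefly / renilla).

    Wells with renilla <= 0 cannot be normalized: they are flagged, logged
    and excluded from the returned table.  If no well survives, raises.
    The response is invariant to rescaling firefly and renilla by a common
    factor.
    """
    plate = validate_plate(plate)
    invalid = plate["renilla"].to_numpy(dtype=float) <= 0
    if invalid.any():
        logger.warning("excluding %d wells with renilla <= 0", int(invalid.sum()))
    kept = plate.loc[~invalid].copy()
    if kept.empty:
        raise ValueError("all wells invalid (renilla <= 0)")
    kept["response"] = kept["firefly"] / kept["renilla"]
    return kept


def _pick_test(x: np.ndarray, y: np.ndarray, test: str, alternative: str = "two-sided"):
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}, got {test!r}")
    if len(x) < 2 or len(y) < 2:
        return math.nan, math.nan
    if np.ptp(np.concatenate([x, y])) == 0:
        return math.nan, 1.0
    if test == "t_test":
        res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan


def _group_responses(norm: pd.DataFrame, construct: str, conc: float) -> np.ndarray:
    sel = (norm["construct"] == construct) & (norm["concentration_uM"] == conc)
    return norm.loc[sel, "response"].to_numpy(dtype=float)


def response_test(
    norm: pd.DataFrame,
    construct: str,
    concentration_uM: float,
    reference_concentration_uM: float = 0.0,
    test: str = "t_test",
) -> ResponseSummary:
    """Compare a construct's stimulated wells against its no-odor wells.

    Requires at least one stimulated and one reference well; with fewer than
    two replicates in either group the p-value is unavailable but means are
    still reported.
    """
    stim = _group_responses(norm, construct, concentration_uM)
    ref = _group_responses(norm, construct, reference_concentration_uM)
    if stim.size == 0:
        raise ValueError(
            f"no wells for {construct!r} at {concentration_uM} uM"
        )
    if ref.size == 0:
        raise ValueError(
            f"no reference ({reference_concentration_uM} uM) wells for {construct!r}"
        )
    stat, p = _pick_test(stim, ref, test)
    return ResponseSummary(
        construct=construct,
        concentration_uM=float(concentration_uM),
        n=int(stim.size),
        mean=float(stim.mean()),
        sem=_sem(stim),
        reference_n=int(ref.size),
        reference_mean=float(ref.mean()),
        statistic=stat,
        p_value=p,
    )


def summarize_responses(norm: pd.DataFrame, test: str = "t_test") -> pd.DataFrame:
    """Response test for every (construct, concentration > 0) pair on the plate."""
    rows = []
    for (construct, conc), _ in norm.groupby(["construct", "concentration_uM"], sort=True):
        if conc == 0:
            continue
        s = response_test(norm, construct, conc, test=test)
        rows.append(
            {
                "construct": s.construct,
                "concentration_uM": s.concentration_uM,
                "n": s.n,
                "mean_response": s.mean,
                "sem": s.sem,
                "reference_mean": s.reference_mean,
                "statistic": s.statistic,
                "p_value": s.p_value,
                "tier": s.tier,
            }
        )
    return pd.DataFrame(rows)


def relative_response(
    norm: pd.DataFrame,
    mutant: str,
    wildtype: str,
    control: str,
    concentration_uM: float,
    test: str = "t_test",
) -> RelativeResponse:
    """Mutant vs wild-type responses, each relative to the control-group mean.

    All three groups must have at least two wells at ``concentration_uM``
    (the control group is typically a receptor-free transfection measured on
    the same plate).  The control group's own relative response is 1 by
    construction.
    """
    groups = {}
    for name in (mutant, wildtype, control):
        x = _group_responses(norm, name, concentration_uM)
        if x.size < 2:
            raise ValueError(
                f"group {name!r} has {x.size} wells at {concentration_uM} uM, need >= 2"
            )
        groups[name] = x
    control_mean = float(groups[control].mean())
    if control_mean <= 0:
        raise ValueError(f"control group mean response is {control_mean}, must be positive")
    mt = groups[mutant] / control_mean
    wt = groups[wildtype] / control_mean
    stat, p = _pick_test(mt, wt, test)
    return RelativeResponse(
        mutant=mutant,
        wildtype=wildtype,
        control=control,
        concentration_uM=float(concentration_uM),
        mutant_n=int(mt.size),
        mutant_mean=float(mt.mean()),
        mutant_sem=_sem(mt),
        wildtype_n=int(wt.size),
        wildtype_mean=float(wt.mean()),
        wildtype_sem=_sem(wt),
        statistic=stat,
        p_value=p,
    )
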