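"""Bait-anchored Pearson co-expression sets and multi-bait intersections.

A *bait* is a known pathway gene; genes whose expression profiles correlate
with the bait above a threshold are pathway-membership candidates.  With
several baits, membership requires passing the threshold against every bait
(set intersection), which is the stringent variant used when a handful of
pathway genes is already known.

Correlations are computed on log2(FPKM + 1) by default; the log transform
stabilizes the several-orders-of-magnitude dynamic range of tissue expression
profiles.  Raw-FPKM correlation is available via ``transform="raw"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (constant vector or length < 3)."""


@dataclass
class CoexpressionResult:
    """Per-gene correlations against one or more baits plus threshold members.

    r_values : genes x baits DataFrame of Pearson r (NaN where undefined).
    members : genes passing the threshold against *every* bait; baits are
        always members (self-correlation defined as 1).
    mode : "ge" (r >= threshold) or "gt" (r > threshold).
    """

    bait_ids: list[str]
    r_values: pd.DataFrame
    threshold: float
    mode: str
    members: set[str]
    excluded: set[str] = field(default_factory=set)  # constant-profile genes

    def to_tsv(self, path: str | Path) -> None:
        out = self.r_values.copy()
        out.columns = [f"r_{b}" for b in self.bait_ids]
        out["member"] = [g in self.members for g in out.index]
        out.to_csv(path, sep="\t", index_label="gene_id")


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation of two equal-length vectors.

    Raises UndefinedCorrelationError for length < 3 or a constant vector,
    rather than silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _profiles(expr, transform: str) -> pd.DataFrame:
    if transform == "log2":
        return expr.log2()
    if transform == "raw":
        return expr.fpkm
    raise ValueError(f"unknown transform {transform!r}")


def _passes(r: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    if mode == "ge":
        return r >= threshold
    if mode == "gt":
        return r > threshold
    raise ValueError(f"mode must be 'ge' or 'gt', got {mode!r}")


def _r_against_bait(profiles: pd.DataFrame, bait: str) -> pd.Series:
    """Vectorized Pearson r of every gene row against the bait row.

    Constant rows (including a constant bait) yield NaN.
    """
    x = profiles.to_numpy(dtype=float)
    b = profiles.loc[bait].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    x_ss = (xc**2).sum(axis=1)
    b_ss = (bc**2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ bc) / np.sqrt(x_ss * b_ss)
    r[x_ss == 0] = np.nan
    if b_ss == 0:
        r[:] = np.nan
    r = np.clip(r, -1.0, 1.0)
    out = pd.Series(r, index=profiles.index)
    out.loc[bait] = 1.0  # self-correlation defined as exactly 1
    return out


def bait_set(
    expr,
    bait: str,
    threshold: float,
    mode: str = "ge",
    transform: str = "log2",
) -> CoexpressionResult:
    """Genes co-expressed with a single bait at the given r threshold."""
    return multi_bait_set(expr, [bait], threshold, mode=mode, transform=transform)


def multi_bait_set(
    expr,
    baits: list[str],
    threshold: float,
    mode: str = "ge",
    transform: str = "log2",
) -> CoexpressionResult:
    """Genes passing the r threshold against *every* bait (intersection).

    Each bait is a member of its own single-bait set (self r = 1), but with
    several mutually uncorrelated baits a bait can fail the intersection.
    Genes with a constant profile have undefined correlation; they are
    excluded and reported in ``excluded``.
    """
    if not baits:
        raise ValueError("at least one bait is required")
    missing = [b for b in baits if b not in expr.gene_ids]
    if missing:
        raise KeyError(f"bait gene(s) not in expression matrix: {missing}")
    if len(expr.sample_ids) < 3:
        raise ValueError("need at least 3 samples for co-expression analysis")

    profiles = _profiles(expr, transform)
    r_values = pd.DataFrame({b: _r_against_bait(profiles, b) for b in baits})

    excluded = set(r_values.index[r_values.isna().any(axis=1)]) - set(baits)
    if excluded:
        logger.warning(
            "%d gene(s) with constant profiles excluded from co-expression", len(excluded)
        )

    pass_all = np.ones(len(r_values), dtype=bool)
    for b in baits:
        r = r_values[b].to_numpy()
        ok = np.zeros_like(pass_all)
        defined = ~np.isnan(r)
        ok[defined] = _passes(r[defined], threshold, mode)
        pass_all &= ok
    # A bait's self-correlation is 1, so each bait is a member of its own set;
    # with several weakly correlated baits a bait can fail the intersection.
    members = set(r_values.index[pass_all])

    return CoexpressionResult(
        bait_ids=list(baits),
        r_values=r_values,
        threshold=threshold,
        mode=mode,
        members=members,
        excluded=excluded,
    )
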