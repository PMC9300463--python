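"""Three-criteria candidate selection and producer/non-producer comparison.

A candidate for the next pathway step must (1) be highly expressed in the
pathway tissue (root mean FPKM above a threshold), (2) be co-expressed with
the known upstream bait gene(s), and (3) belong to a protein family whose
chemistry fits the hypothesized step.  Criterion (3) is represented by a
family annotation table (P450, ABH, MDR, BAHD, OMT, other) plus a
full-length flag -- family classification itself comes from external
annotation tools and is an input here.

The comparative view joins producer candidates to their reciprocal-best-hit
orthologues in a non-producer relative; a shared early pathway shows up as
high-identity RBH partners for every early-step candidate, while genes absent
from the non-producer are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coexpression import multi_bait_set
from .expression import ExpressionMatrix, filter_expressed, tissue_mean

logger = logging.getLogger(__name__)

FAMILIES = ("P450", "ABH", "MDR", "BAHD", "OMT", "other")


@dataclass
class GeneAnnotation:
    """Family and completeness annotation for one gene model."""

    gene_id: str
    family: str
    full_length: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r} for {self.gene_id}; expected one of {FAMILIES}"
            )


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a 3-column TSV: gene_id, family, full_length."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(r.gene_id, r.family, bool(r.full_length))
        for r in df.itertuples(index=False)
    ]


def select_candidates(
    expr: ExpressionMatrix,
    annotations: list[GeneAnnotation],
    baits: list[str],
    family: str = "all",
    tissue: str = "root",
    min_fpkm: float = 20.0,
    r_threshold: float = 0.95,
    mode: str = "ge",
    transform: str = "log2",
) -> pd.DataFrame:
    """Ranked table of family members passing the expression and co-expression screens.

    Rows are full-length genes of the requested family (or any family with
    ``family="all"``) whose mean FPKM in ``tissue`` is >= ``min_fpkm`` and
    whose Pearson r passes ``r_threshold`` against every bait.  Sorted by the
    minimum r over baits (descending), ties broken by tissue mean FPKM
    (descending), then gene id.
    """
    if family != "all" and family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    fam_genes = [
        a.gene_id
        for a in annotations
        if a.full_length and (family == "all" or a.family == family)
    ]
    fam_genes = [g for g in fam_genes if g in expr.gene_ids]
    family_of = {a.gene_id: a.family for a in annotations}
    if not fam_genes:
        logger.warning("no full-length genes of family %r in the expression matrix", family)

    expressed = filter_expressed(expr, tissue, min_fpkm)
    coex = multi_bait_set(expr, baits, r_threshold, mode=mode, transform=transform)
    means = tissue_mean(expr, tissue)

    rows = []
    for g in fam_genes:
        if g not in expressed or g not in coex.members:
            continue
        r_per_bait = coex.r_values.loc[g]
        rows.append(
            {
                "gene_id": g,
                "family": family_of[g],
                f"{tissue}_mean_fpkm": float(means[g]),
                **{f"r_{b}": float(r_per_bait[b]) for b in baits},
                "min_r": float(r_per_bait.min()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "family", f"{tissue}_mean_fpkm"]
        + [f"r_{b}" for b in baits]
        + ["min_r"],
    )
    return table.sort_values(
        ["min_r", f"{tissue}_mean_fpkm", "gene_id"],
        ascending=[False, False, True],
        ignore_index=True,
    )


def comparative_presence(
    producer_candidates: pd.DataFrame, ortholog_pairs
) -> pd.DataFrame:
    """Join candidates to their RBH orthologues in the non-producer proteome.

    Candidates without an RBH partner are flagged absent -- in a shared-early /
    divergent-late pathway architecture those are the producer-specific steps.
    """
    by_producer = {p.id_a: p for p in ortholog_pairs if p.rbh}
    rows = []
    for g in producer_candidates.get("gene_id", pd.Series(dtype=str)):
        pair = by_producer.get(g)
        rows.append(
            {
                "gene_id": g,
                "ortholog": pair.id_b if pair else None,
                "percent_identity": pair.percent_identity if pair else float("nan"),
                "absent_in_nonproducer": pair is None,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "ortholog", "percent_identity", "absent_in_nonproducer"]
    )
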