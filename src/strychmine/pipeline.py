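"""End-to-end discovery runs: quantify -> co-express -> select -> compare.

One YAML/dict configuration drives the whole chain so that every threshold
and every gene-set cardinality is auditable from the run summary.  Reruns
with an identical configuration produce identical outputs; the summary is
stamped with a hash of the configuration and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import align, candidates, expression, kinetics, phylo
from .coexpression import multi_bait_set

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and bait choices for a discovery run.

    Thresholds default to the screen settings of root-alkaloid candidate
    mining: tissue mean FPKM >= 20, single-bait r >= 0.95, multi-bait
    intersection r > 0.6, family-wide screen r > 0.7.
    """

    counts: str
    design: str
    out_dir: str
    baits: list[str] = field(default_factory=list)
    annotations: str | None = None
    proteome_a: str | None = None
    proteome_b: str | None = None
    kinetics_data: str | None = None
    tissue: str = "root"
    min_fpkm: float = 20.0
    r_single: float = 0.95
    r_multi: float = 0.6
    r_family: float = 0.7
    family: str = "all"
    transform: str = "log2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baits:
            raise ValueError("at least one bait gene id is required")
        for name, thr in (("min_fpkm", self.min_fpkm),):
            if thr < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, thr in (
            ("r_single", self.r_single),
            ("r_multi", self.r_multi),
            ("r_family", self.r_family),
        ):
            if not -1.0 <= thr <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_discovery(config: PipelineConfig) -> dict:
    """Run the discovery chain and return (and write) a JSON-able summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}

    def stage(name: str, **info) -> None:
        summary["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    counts = expression.CountsMatrix.from_tsv(config.counts, config.design)
    expr = expression.compute_fpkm(counts)
    expr.to_tsv(out / "fpkm.tsv")
    stage("fpkm", n_genes=int(expr.fpkm.shape[0]), n_samples=int(expr.fpkm.shape[1]))

    expressed = expression.filter_expressed(expr, config.tissue, config.min_fpkm)
    stage(
        "expression_filter",
        tissue=config.tissue,
        min_fpkm=config.min_fpkm,
        n_expressed=len(expressed),
    )

    mode_single = "ge"
    coex = multi_bait_set(
        expr, config.baits, config.r_single if len(config.baits) == 1 else config.r_multi,
        mode=mode_single if len(config.baits) == 1 else "gt",
        transform=config.transform,
    )
    coex.to_tsv(out / "coexpression.tsv")
    stage(
        "coexpression",
        baits=config.baits,
        threshold=coex.threshold,
        mode=coex.mode,
        n_members=len(coex.members),
        n_excluded_constant=len(coex.excluded),
    )

    if config.annotations:
        annos = candidates.read_annotations(config.annotations)
        table = candidates.select_candidates(
            expr,
            annos,
            config.baits,
            family=config.family,
            tissue=config.tissue,
            min_fpkm=config.min_fpkm,
            r_threshold=config.r_single if len(config.baits) == 1 else config.r_multi,
            mode="ge" if len(config.baits) == 1 else "gt",
            transform=config.transform,
        )
        table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        per_family = table["family"].value_counts().to_dict() if len(table) else {}
        stage("candidates", n_candidates=int(len(table)), per_family=per_family)
    else:
        table = None
        stage("candidates", skipped="no annotation table supplied")

    if config.proteome_a and config.proteome_b:
        prot_a = align.read_fasta(config.proteome_a)
        prot_b = align.read_fasta(config.proteome_b)
        pairs = align.reciprocal_best_hits(prot_a, prot_b)
        with open(out / "orthologs.tsv", "w") as fh:
            fh.write("id_a\tid_b\tscore\tpct_identity\trbh\n")
            for p in pairs:
                fh.write(
                    f"{p.id_a}\t{p.id_b}\t{p.score:g}\t{p.percent_identity:.2f}\t{p.rbh}\n"
                )
        stage(
            "orthologs",
            n_a=len(prot_a),
            n_b=len(prot_b),
            n_rbh=len(pairs),
            rbh_coverage=len(pairs) / len(prot_a),
        )
        if table is not None and len(table):
            comp = candidates.comparative_presence(table, pairs)
            comp.to_csv(out / "comparative.tsv", sep="\t", index=False)
            stage(
                "comparative",
                n_candidates=int(len(comp)),
                n_absent=int(comp["absent_in_nonproducer"].sum()),
            )

    if config.kinetics_data:
        res = kinetics.MichaelisMenten.from_tsv(config.kinetics_data).fit()
        (out / "kinetics_fit.json").write_text(json.dumps(res.to_dict(), indent=2))
        stage("kinetics", **res.to_dict())

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
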