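"""Synthetic transcriptomes, proteomes and kinetics data with planted ground truth.

The generator emulates the statistical regime that bait-anchored co-expression
discovery assumes: a replicated multi-tissue bulk RNA-seq count matrix in which
a small pathway module is (i) preferentially expressed in one tissue (roots for
root-synthesized alkaloids) and (ii) tightly intercorrelated across samples,
embedded in a background of mutually uncorrelated genes.  Because the module is
planted, every downstream stage (FPKM filtering, co-expression thresholds,
orthologue mapping, clade tests, kinetics fits) can be scored against known
truth.

Counts follow a negative binomial with Var = mu + mu^2/dispersion, the standard
overdispersion model for bulk RNA-seq.  Module co-expression is induced by a
shared latent log-mean profile (the tissue design) plus independent per-gene
Gaussian jitter; the jitter variance is solved so that the *expected* pairwise
Pearson correlation of log2 FPKM within the module equals the requested value,
after accounting for the counting noise the NB adds on the log scale.  The
calibration is in expectation: any single draw scatters around the target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

LN2_SQ = math.log(2.0) ** 2


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-module transcriptome simulation.

    Parameters
    ----------
    n_genes : total number of genes (background + module).
    n_tissues : number of tissues; labels default to root/stem/leaf and are
        extended as tissue4, tissue5, ... beyond three.
    n_replicates_per_tissue : biological replicates per tissue (two, matching
        the two-sample-set design typical of non-model plant transcriptomes).
    pathway_size : number of planted pathway genes (includes the bait).
    pathway_tissue : tissue in which the module is enriched.
    module_correlation : target expected pairwise Pearson r of log2(FPKM+1)
        between module genes, in [0, 1].
    fold_root_enrichment : mean fold-change of module genes in pathway_tissue
        relative to the other tissues (>= 1).
    nb_dispersion : negative-binomial size parameter; Var = mu + mu^2/disp.
        20 corresponds to a squared biological CV of 0.05, typical of good
        bulk replicates.
    baseline_mean : expected count of a typical gene at reference depth.
    gene_length_range : (lo, hi) transcript lengths in bp, drawn uniformly.
    library_size_range : (lo, hi) target per-sample read totals; None scales
        0.8-1.2x around n_genes * baseline_mean.
    seed : master seed; all randomness derives from it.
    """

    n_genes: int = 1000
    n_tissues: int = 3
    n_replicates_per_tissue: int = 2
    pathway_size: int = 10
    pathway_tissue: str = "root"
    module_correlation: float = 0.97
    fold_root_enrichment: float = 20.0
    nb_dispersion: float = 20.0
    baseline_mean: float = 200.0
    gene_length_range: tuple[int, int] = (500, 3000)
    library_size_range: tuple[float, float] | None = None
    seed: int = 0

    _DEFAULT_TISSUES = ("root", "stem", "leaf")

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tissues < 1 or self.n_replicates_per_tissue < 1:
            raise ConfigurationError("gene, tissue and replicate counts must be >= 1")
        if self.pathway_size < 1:
            raise ConfigurationError("pathway_size must be >= 1")
        if self.pathway_size >= self.n_genes:
            raise ConfigurationError(
                f"pathway_size ({self.pathway_size}) must be < n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.module_correlation <= 1.0:
            raise ConfigurationError("module_correlation must lie in [0, 1]")
        if self.fold_root_enrichment < 1.0:
            raise ConfigurationError("fold_root_enrichment must be >= 1")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigurationError("nb_dispersion and baseline_mean must be > 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("gene_length_range must be a positive interval")
        if self.pathway_tissue not in self.tissues:
            raise ConfigurationError(
                f"pathway_tissue {self.pathway_tissue!r} not among tissues {self.tissues}"
            )

    @property
    def tissues(self) -> tuple[str, ...]:
        base = list(self._DEFAULT_TISSUES[: self.n_tissues])
        base += [f"tissue{i + 1}" for i in range(len(base), self.n_tissues)]
        return tuple(base)

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.n_replicates_per_tissue


@dataclass
class SyntheticDataset:
    """A simulated count matrix with its planted ground truth."""

    counts: pd.DataFrame           # genes x samples, non-negative ints
    gene_lengths: pd.Series        # bp per gene
    design: pd.Series              # sample -> tissue
    truth_module: set[str]         # planted pathway gene ids
    bait_id: str                   # a module gene used as co-expression bait
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write counts/design TSVs and the truth JSON; return written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "design": outdir / "design.tsv",
            "truth": outdir / "truth.json",
        }
        counts = self.counts.copy()
        counts.insert(0, "length", self.gene_lengths)
        counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        self.design.rename("tissue").to_csv(
            paths["design"], sep="\t", index_label="sample"
        )
        paths["truth"].write_text(
            json.dumps(
                {"truth_module": sorted(self.truth_module), "bait_id": self.bait_id},
                indent=2,
            )
        )
        return paths


@dataclass
class SyntheticProteome:
    """Parent protein sequences and mutated children at controlled identity."""

    parent_sequences: dict[str, str]
    child_sequences: dict[str, str]
    target_identity: float
    realized_identity: dict[str, float] = field(default_factory=dict)


@dataclass
class KineticsDataset:
    """Initial-rate data: substrate concentrations (uM), velocities (uM/min)."""

    substrate_conc: np.ndarray
    velocity: np.ndarray
    enzyme_conc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "S_uM": self.substrate_conc,
                "v_uM_per_min": self.velocity,
                "E_uM": self.enzyme_conc,
            }
        )


def _split_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    # independent streams: counts, proteins, kinetics
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in children)


def _jitter_sd(config: SimulationConfig) -> float:
    """Solve the per-gene log2 jitter SD from the target module correlation.

    On the log2 scale a module gene is (gene offset) + d_s + e_gs + nb_gs where
    d_s is the shared tissue profile, e the Gaussian jitter and nb the NB
    counting noise (delta method: var(log2 count) ~ (1/mu + 1/disp)/ln(2)^2).
    Expected pairwise Pearson r across samples is var(d)/(var(d) + var_indep),
    so var_indep = var(d) * (1 - r)/r, and the jitter absorbs whatever the NB
    noise does not already contribute (floored at zero).
    """
    r = config.module_correlation
    if r == 0.0:
        if config.fold_root_enrichment > 1.0:
            raise ConfigurationError(
                "module_correlation = 0 is unattainable while the module shares "
                "a tissue-enrichment profile (fold_root_enrichment > 1)"
            )
        return 0.0
    log_fold = math.log2(config.fold_root_enrichment)
    n = config.n_samples
    n_path = config.n_replicates_per_tissue
    d = np.zeros(n)
    d[:n_path] = log_fold
    var_d = float(np.var(d))
    if var_d == 0.0:
        return 0.0
    var_indep = var_d * (1.0 - r) / r
    # typical NB log-noise for a module gene, averaged over samples
    mu_path = config.baseline_mean * config.fold_root_enrichment
    mu_other = config.baseline_mean
    v_nb = (
        n_path * (1.0 / mu_path + 1.0 / config.nb_dispersion)
        + (n - n_path) * (1.0 / mu_other + 1.0 / config.nb_dispersion)
    ) / n / LN2_SQ
    return math.sqrt(max(0.0, var_indep - v_nb))


def simulate_transcriptome(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a replicated multi-tissue count matrix with a planted module.

    Background genes get independent per-gene latent means (log-normal around
    ``baseline_mean``) and tissue-independent NB counts.  The first
    ``pathway_size`` genes form the module: they share the tissue-enrichment
    profile, perturbed per gene and sample by calibrated Gaussian jitter.
    Deterministic given ``config.seed``.
    """
    rng, _, _ = _split_rngs(config.seed)
    n_genes, n_samples = config.n_genes, config.n_samples

    module_ids = [f"module{i:02d}" for i in range(config.pathway_size)]
    gene_ids = module_ids + [f"g{i:05d}" for i in range(config.pathway_size, n_genes)]

    samples, tissues = [], []
    for t in config.tissues:
        for r in range(config.n_replicates_per_tissue):
            samples.append(f"{t}_rep{r + 1}")
            tissues.append(t)
    design = pd.Series(tissues, index=pd.Index(samples, name="sample"), name="tissue")

    lo, hi = config.gene_length_range
    gene_lengths = rng.integers(lo, hi + 1, size=n_genes)

    # per-gene latent base expression (counts at reference depth)
    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # per-sample depth factors
    if config.library_size_range is None:
        depth = rng.uniform(0.8, 1.2, size=n_samples)
    else:
        l_lo, l_hi = config.library_size_range
        target = rng.uniform(l_lo, l_hi, size=n_samples)
        depth = target / (config.n_genes * config.baseline_mean)

    mu = np.outer(base, depth)

    is_path_tissue = np.array([t == config.pathway_tissue for t in tissues])
    sd = _jitter_sd(config)
    m = config.pathway_size
    jitter = rng.normal(0.0, sd, size=(m, n_samples))
    fold = np.where(is_path_tissue, config.fold_root_enrichment, 1.0)
    mu[:m, :] = mu[:m, :] * fold[None, :] * np.exp2(jitter)

    # NB draw via gamma-Poisson mixture: shape = dispersion, scale = mu/dispersion
    disp = config.nb_dispersion
    lam = rng.gamma(shape=disp, scale=mu / disp)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    lengths = pd.Series(gene_lengths, index=counts_df.index, name="length")
    return SyntheticDataset(
        counts=counts_df,
        gene_lengths=lengths,
        design=design,
        truth_module=set(module_ids),
        bait_id=module_ids[0],
        config=config,
    )


def mutate_orthologue(parent: str, target_identity: float, seed: int) -> str:
    """Substitute residues so the child has exactly round((1-t)*len) changes.

    No indels are introduced, so the realized identity is exact to within the
    rounding granularity 1/len and independent of any aligner's gap choices.
    Substitutions replace each chosen position with a uniformly drawn one of
    the 19 alternative residues.  Deterministic given ``seed``.
    """
    if not parent:
        raise ValueError("parent sequence must be non-empty")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must lie in (0, 1]")
    n_sub = round((1.0 - target_identity) * len(parent))
    if n_sub == 0:
        return parent
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(parent), size=n_sub, replace=False)
    child = list(parent)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(child[pos], "")
        child[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(child)


def random_protein(length: int, seed: int) -> str:
    """A uniform random protein sequence over the 20 canonical residues."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_proteome_pair(
    n_proteins: int,
    length: int,
    target_identity: float,
    seed: int,
    prefix_a: str = "A",
    prefix_b: str = "B",
) -> SyntheticProteome:
    """Two proteomes where B[i] is A[i] mutated to the target identity."""
    _, rng, _ = _split_rngs(seed)
    parents, children, realized = {}, {}, {}
    for i in range(n_proteins):
        pid_a, pid_b = f"{prefix_a}{i:03d}", f"{prefix_b}{i:03d}"
        parent = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        child = mutate_orthologue(parent, target_identity, seed=int(rng.integers(2**31)))
        parents[pid_a] = parent
        children[pid_b] = child
        same = sum(a == b for a, b in zip(parent, child))
        realized[pid_a] = same / length
    return SyntheticProteome(
        parent_sequences=parents,
        child_sequences=children,
        target_identity=target_identity,
        realized_identity=realized,
    )


def simulate_kinetics(
    kcat: float,
    km: float,
    enzyme_conc: float,
    substrate_concs,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> KineticsDataset:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise.

    v_i = kcat * E0 * S_i / (Km + S_i) * (1 + eps_i), eps_i ~ N(0, noise_cv).
    """
    if kcat <= 0 or km <= 0 or enzyme_conc <= 0:
        raise ValueError("kcat, km and enzyme_conc must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    s = np.asarray(substrate_concs, dtype=float)
    if s.size == 0 or np.any(s <= 0):
        raise ValueError("substrate_concs must be non-empty and positive")
    _, _, rng = _split_rngs(seed)
    v = kcat * enzyme_conc * s / (km + s)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=s.size))
    return KineticsDataset(substrate_conc=s, velocity=v, enzyme_conc=enzyme_conc)
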