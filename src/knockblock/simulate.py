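"""Synthetic genotypes, sparse phenotypes, and end-to-end FDR experiments.

Genotypes are block-correlated hard calls under Hardy-Weinberg
equilibrium: within each LD block a latent Gaussian with equicorrelated or
AR(1) structure is thresholded at the allele-frequency quantile for each
of two independent haplotypes, and the haplotypes are summed to dosages in
{0, 1, 2}.  Variants sit on a uniform physical grid so megabase windows
are meaningful.  Phenotypes follow a sparse linear model

    y = X beta + N(0, noise_var I),    noise_var = 3 by default,

with ``k = 10`` causal variants drawn uniformly and effects
``beta ~ N(0, effect_sd^2)`` (``effect_sd = sqrt(0.5)`` by default); the
phenotype is then standardized.

:func:`run_fdr_experiment` wires the whole pipeline — QC, standardization,
LD blocks, correlation estimation, grouping, maximum-entropy knockoff
optimization, ghost sampling, and the kappa/tau filter — and reports the
realized false discovery proportion and power per repetition.  A selected
group counts as a true discovery iff it contains at least one causal
variant.

The module also writes binary PLINK and VCF fixtures encoding the same
dosage matrix, used by the I/O round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, impute_and_standardize, qc_filter
from .ghost_inference import (
    group_stats,
    knockoff_filter,
    marginal_z,
    sample_knockoff_z,
)
from .grouping import build_groups
from .knockoff_optim import assemble_D, solve_maxent
from .ld_blocks import BlockBoundaries, estimate_sigma, split_blocks

__all__ = [
    "BlockSpec",
    "SimulationConfig",
    "ExperimentResult",
    "simulate_genotypes",
    "simulate_phenotype",
    "run_fdr_experiment",
    "write_fixtures",
]

POSITION_SPACING = 5_000  # bp between adjacent simulated variants


@dataclass
class BlockSpec:
    """Correlation structure of one simulated LD block."""

    size: int
    rho: float = 0.4
    kind: str = "equi"  # "equi" or "ar1"

    def __post_init__(self) -> None:
        if self.kind not in ("equi", "ar1"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic FDR/power experiments.

    Defaults are three equicorrelated blocks of 200 variants (rho = 0.4)
    over n = 1000 samples, k = 10 causal effects with sd sqrt(0.5), noise
    variance 3, m = 5 knockoffs, and target FDR 0.10 over 200 repetitions.
    """

    n: int = 1000
    blocks: list[BlockSpec] = field(
        default_factory=lambda: [BlockSpec(size=200, rho=0.4) for _ in range(3)]
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    k: int = 10
    effect_sd: float = float(np.sqrt(0.5))
    noise_var: float = 3.0
    m: int = 5
    q: float = 0.10
    cutoff: float = 0.5
    key_c: float = 0.5
    reps: int = 200
    seed: int = 0
    use_true_blocks: bool = True
    chrom: str = "1"

    @property
    def p(self) -> int:
        return sum(b.size for b in self.blocks)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.k > self.p:
            raise ValueError(f"k = {self.k} exceeds p = {self.p}")


@dataclass
class ExperimentResult:
    """Per-repetition selections and aggregate FDR/power with MC errors."""

    per_rep: pd.DataFrame
    mean_fdr: float
    mean_power: float
    se_fdr: float
    se_power: float
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genotype and phenotype generation
# ---------------------------------------------------------------------------

def _latent_block(
    n: int, spec: BlockSpec, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype's latent Gaussian draw for a block (n x size)."""
    if spec.kind == "equi":
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, spec.size))
        return np.sqrt(spec.rho) * shared + np.sqrt(1.0 - spec.rho) * noise
    # AR(1): L_j = rho * L_{j-1} + sqrt(1 - rho^2) * eps_j
    L = np.empty((n, spec.size))
    L[:, 0] = rng.standard_normal(n)
    innov = rng.standard_normal((n, spec.size - 1)) * np.sqrt(1.0 - spec.rho**2)
    for j in range(1, spec.size):
        L[:, j] = spec.rho * L[:, j - 1] + innov[:, j - 1]
    return L


def simulate_genotypes(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> GenotypeMatrix:
    """Block-correlated HWE hard-call genotypes.

    Each variant's allele frequency is drawn uniformly from
    ``config.maf_range``; two independent haplotypes are generated by
    thresholding the block's latent Gaussian at the frequency quantile and
    summed, so marginal genotype frequencies follow p^2, 2pq, q^2.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    n, p = config.n, config.p
    mafs = rng.uniform(*config.maf_range, size=p)
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n, p))
    for _hap in range(2):
        col = 0
        for spec in config.blocks:
            L = _latent_block(n, spec, rng)
            dosage[:, col : col + spec.size] += (
                L < thresholds[col : col + spec.size]
            ).astype(np.float64)
            col += spec.size
    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": (np.arange(p, dtype=np.int64) + 1) * POSITION_SPACING,
            "id": [f"snp{j + 1}" for j in range(p)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"sample{i + 1}" for i in range(n)]
    return GenotypeMatrix(values=dosage, samples=samples, variants=variants)


def simulate_phenotype(
    X: np.ndarray,
    k: int = 10,
    effect_sd: float = float(np.sqrt(0.5)),
    noise_var: float = 3.0,
    seed: int | np.random.Generator | None = None,
    standardize: bool = True,
    return_effects: bool = False,
) -> tuple[np.ndarray, ...]:
    """Sparse linear phenotype on a standardized genotype matrix.

    Draws ``k`` causal columns uniformly without replacement and effects
    ``beta ~ N(0, effect_sd^2)``; ``y = X beta + N(0, noise_var I)`` is
    standardized before being returned (disable with ``standardize=False``).
    Returns ``(y, causal_indices)``, plus ``beta`` when ``return_effects``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n, p = X.shape
    if k > p:
        raise ValueError(f"k = {k} exceeds p = {p}")
    causal = np.sort(rng.choice(p, size=k, replace=False))
    beta = rng.normal(0.0, effect_sd, size=k)
    y = X[:, causal] @ beta + rng.normal(0.0, np.sqrt(noise_var), size=n)
    if standardize:
        y = y - y.mean()
        sd = y.std()
        if sd > 0:
            y = y / sd
    if return_effects:
        return y, causal, beta
    return y, causal


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

def _true_boundaries_after_qc(
    config: SimulationConfig, kept: np.ndarray
) -> BlockBoundaries:
    """Map the generating block structure through the QC column subset."""
    edges = np.cumsum([0] + [b.size for b in config.blocks])
    labels = np.searchsorted(edges, kept, side="right") - 1
    blocks, chroms = [], []
    start = 0
    for lab in range(len(config.blocks)):
        size = int(np.sum(labels == lab))
        if size:
            blocks.append((start, start + size))
            chroms.append(config.chrom)
            start += size
    return BlockBoundaries(blocks=blocks, chroms=chroms)


def run_single_rep(
    config: SimulationConfig, rep_seed: np.random.SeedSequence
) -> dict:
    """One repetition of the full pipeline; returns FDP/power summaries."""
    rng_geno, rng_pheno, rng_ghost = (
        np.random.default_rng(s) for s in rep_seed.spawn(3)
    )
    G = simulate_genotypes(config, seed=rng_geno)
    Gq = qc_filter(G)
    # simulated variant ids are unique, so recover original column positions
    kept = pd.Index(G.variants["id"]).get_indexer(Gq.variants["id"]).astype(np.int64)
    X = impute_and_standardize(Gq)
    y, causal = simulate_phenotype(
        X, k=config.k, effect_sd=config.effect_sd,
        noise_var=config.noise_var, seed=rng_pheno,
    )

    if config.use_true_blocks:
        boundaries = _true_boundaries_after_qc(config, kept)
    else:
        boundaries = split_blocks(X, Gq.variants)

    z_all = marginal_z(X, y)
    T_parts, member_parts = [], []
    causal_set = set(causal.tolist())
    group_offset = 0
    group_has_causal: list[bool] = []
    for start, stop in boundaries:
        Xb = X[:, start:stop]
        sigma = estimate_sigma(Xb)
        groups = build_groups(sigma, cutoff=config.cutoff, c=config.key_c)
        S, _ = solve_maxent(
            sigma[np.ix_(groups.keys, groups.keys)],
            groups.key_groups,
            m=config.m,
        )
        D = assemble_D(sigma, groups.keys, S, m=config.m)
        zb = z_all[start:stop]
        z_knock = sample_knockoff_z(zb, sigma, D, m=config.m, seed=rng_ghost)
        T_parts.append(group_stats(zb, z_knock, groups.membership))
        for g in range(1, groups.n_groups + 1):
            members = np.flatnonzero(groups.membership == g) + start
            group_has_causal.append(bool(causal_set & set(members.tolist())))
        member_parts.append(groups.membership + group_offset)
        group_offset += groups.n_groups

    T = np.vstack(T_parts)
    result = knockoff_filter(T, q=config.q, m=config.m)
    truth = np.asarray(group_has_causal)
    n_sel = int(result.selected.sum())
    n_true = int((result.selected & truth).sum())
    n_false = n_sel - n_true
    n_causal_groups = int(truth.sum())
    return {
        "n_selected": n_sel,
        "n_false": n_false,
        "fdp": n_false / max(1, n_sel),
        "power": n_true / max(1, n_causal_groups),
    }


def run_fdr_experiment(config: SimulationConfig) -> ExperimentResult:
    """Run ``config.reps`` independent repetitions and aggregate FDR/power.

    Each repetition gets an independent child stream of the master seed,
    so results are reproducible end to end and per repetition.
    """
    master = np.random.SeedSequence(config.seed)
    rows = []
    for rep, rep_seed in enumerate(master.spawn(config.reps)):
        summary = run_single_rep(config, rep_seed)
        summary["rep"] = rep
        rows.append(summary)
    per_rep = pd.DataFrame(rows)
    fdp = per_rep["fdp"].to_numpy()
    power = per_rep["power"].to_numpy()
    reps = len(per_rep)
    return ExperimentResult(
        per_rep=per_rep,
        mean_fdr=float(fdp.mean()),
        mean_power=float(power.mean()),
        se_fdr=float(fdp.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        se_power=float(power.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture writers (binary PLINK + VCF)
# ---------------------------------------------------------------------------

# dosage -> 2-bit PLINK code: 0 -> 00 (hom A1), 1 -> 10 (het), 2 -> 11 (hom A2),
# missing -> 01
_DOSAGE_TO_PLINK_CODE = {0.0: 0b00, 1.0: 0b10, 2.0: 0b11}


def write_fixtures(G: GenotypeMatrix, out_dir: str | Path, name: str = "fixture") -> dict:
    """Write ``name.bed/.bim/.fam`` and ``name.vcf`` encoding the same dosages.

    Returns a dict with the PLINK prefix and the VCF path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / name
    n, p = G.values.shape

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in G.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in G.variants.itertuples():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.ref}\t{v.alt}\n")

    bytes_per_variant = (n + 3) // 4
    body = bytearray()
    for j in range(p):
        col = G.values[:, j]
        codes = np.full(bytes_per_variant * 4, 0b00, dtype=np.uint8)
        for i in range(n):
            x = col[i]
            codes[i] = 0b01 if np.isnan(x) else _DOSAGE_TO_PLINK_CODE[x]
        packed = (
            codes[0::4]
            | (codes[1::4] << 2)
            | (codes[2::4] << 4)
            | (codes[3::4] << 6)
        )
        body.extend(packed.tobytes())
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(bytes(body))

    vcf_path = out_dir / f"{name}.vcf"
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, v in enumerate(G.variants.itertuples()):
            gts = "\t".join(
                "./." if np.isnan(x) else gt_map[x] for x in G.values[:, j]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )
    return {"plink_prefix": prefix, "vcf": vcf_path}
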