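"""Synthetic multi-study case-control genotype cohorts.

The generator emulates the statistical structure the pipeline assumes:

* genotypes in Hardy-Weinberg proportions by construction — two haplotypes
  per individual are paired independently, each drawn from a first-order
  Markov chain over loci so adjacent SNPs within a block have allele
  correlation rho (hence dosage correlation rho and r^2 = rho^2 at distance
  one, decaying geometrically);
* every SNP in a block shares the block's allele frequency (drawn once from
  the configured range), which keeps the Markov copy mechanism
  marginal-preserving;
* uniform genotype missingness;
* optional two-subpopulation stratification: per-SNP allele-frequency
  divergence of +/- delta plus a subpopulation-specific disease offset, the
  classic confounding scenario PCA adjustment is meant to fix;
* case-control status from an additive logistic model with planted
  per-allele odds ratios and categorical covariate effects; the intercept is
  tuned by bisection so the expected case fraction matches the requested
  design, and cases/controls are then sampled retrospectively to exact
  quotas per study.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import (
    CASE,
    CONTROL,
    GeneModel,
    GenotypeDataset,
    PathwayModel,
    SampleMeta,
    SnpMeta,
)
from . import io as pio


@dataclass
class BlockConfig:
    """One LD block: n_snps at a shared MAF with adjacent correlation rho."""

    n_snps: int
    maf_range: tuple[float, float] = (0.1, 0.4)
    rho: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


@dataclass
class EffectSnp:
    """A planted causal SNP: per-allele odds ratio at (block, index)."""

    block: int
    index: int
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"odds ratio must be > 0, got {self.odds_ratio}")


@dataclass
class StratificationConfig:
    """Two hidden subpopulations with divergent MAFs and a disease offset."""

    maf_divergence: float = 0.15
    disease_log_odds: float = 0.0
    fraction: float = 0.5


@dataclass
class SimulationConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_studies: int = 1
    study_fractions: tuple[float, ...] | None = None
    blocks: list[BlockConfig] = field(
        default_factory=lambda: [BlockConfig(n_snps=10)]
    )
    effect_snps: list[EffectSnp] = field(default_factory=list)
    missing_rate: float = 0.0
    stratification: StratificationConfig | None = None
    sex_log_odds: float = 0.0
    age_strata: tuple[str, ...] = ("40-49", "50-59", "60-69")
    age_log_odds: tuple[float, ...] | None = None
    snp_spacing_bp: int = 1_000
    block_gap_bp: int = 50_000
    pool_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_fractions is None:
            self.study_fractions = tuple([1.0 / self.n_studies] * self.n_studies)
        if abs(sum(self.study_fractions) - 1.0) > 1e-9:
            raise ValueError("study fractions must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.age_log_odds is None:
            self.age_log_odds = tuple([0.0] * len(self.age_strata))
        if len(self.age_log_odds) != len(self.age_strata):
            raise ValueError("age_log_odds must align with age_strata")
        n_blocks = len(self.blocks)
        for e in self.effect_snps:
            if not 0 <= e.block < n_blocks:
                raise ValueError(f"effect SNP references missing block {e.block}")
            if not 0 <= e.index < self.blocks[e.block].n_snps:
                raise ValueError(f"effect SNP index {e.index} outside block")

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def snp_global_index(self, block: int, index: int) -> int:
        return sum(b.n_snps for b in self.blocks[:block]) + index


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated cohort."""

    effect_snp_ids: list[str]
    betas: dict[str, float]
    alpha: float
    subpopulation: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def snp_metadata(config: SimulationConfig) -> list[SnpMeta]:
    """Deterministic SNP coordinates: blocks laid head-to-tail on chr 1."""
    snps = []
    pos = 100_000
    for bi, block in enumerate(config.blocks):
        for j in range(block.n_snps):
            snps.append(SnpMeta(f"rs{bi}_{j}", "1", pos, "A", "G"))
            pos += config.snp_spacing_bp
        pos += config.block_gap_bp
    return snps


def block_gene_models(config: SimulationConfig) -> tuple[list[GeneModel], PathwayModel]:
    """One synthetic gene per LD block spanning exactly its SNPs, plus the
    pathway collecting them. Lets every simulated SNP map to one gene under
    any non-negative flank."""
    snps = snp_metadata(config)
    genes = []
    k = 0
    for bi, block in enumerate(config.blocks):
        first, last = snps[k], snps[k + block.n_snps - 1]
        genes.append(
            GeneModel(f"GENE{bi}", "1", "+", first.position, last.position)
        )
        k += block.n_snps
    pathway = PathwayModel("synthetic_pathway", tuple(g.gene_name for g in genes))
    return genes, pathway


def simulate_genotypes(
    config: SimulationConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    subpop: np.ndarray | None = None,
) -> np.ndarray:
    """Dosage matrix for n individuals (default the cohort size).

    ``subpop`` (0/1 per individual) selects the subpopulation-specific
    allele frequencies when stratification is configured. Missingness is NOT
    applied here — it is added once, after case-control sampling.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.n_total
    freqs = block_allele_frequencies(config)
    if config.stratification is not None and subpop is None:
        subpop = (rng.random(n) < config.stratification.fraction).astype(int)
    cols = []
    for bi, block in enumerate(config.blocks):
        f = freqs[bi]
        if config.stratification is not None:
            # divergence direction fixed per SNP by the block seed stream
            sign = np.where(rng.random(block.n_snps) < 0.5, 1.0, -1.0)
            f2 = np.clip(f + sign * config.stratification.maf_divergence, 0.01, 0.99)
            fmat = np.where(subpop[:, None] == 1, f2[None, :], f)
        else:
            fmat = np.broadcast_to(f, (n, block.n_snps))
        h1 = _markov_haplotypes(fmat, block.rho, rng)
        h2 = _markov_haplotypes(fmat, block.rho, rng)
        cols.append((h1 + h2).astype(float))
    return np.hstack(cols)


def block_allele_frequencies(config: SimulationConfig) -> list[np.ndarray]:
    """Per-block shared MAF, drawn once per block from its range (seeded
    independently of the genotype stream so metadata is reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out = []
    for block in config.blocks:
        lo, hi = block.maf_range
        maf = float(lo if lo == hi else rng.uniform(lo, hi))
        out.append(np.full(block.n_snps, maf))
    return out


def _markov_haplotypes(
    fmat: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order copy-mechanism chain: locus i+1 copies locus i w.p. rho,
    else draws fresh at its own frequency. With equal frequencies along the
    block this preserves marginals and gives corr rho^|i-j|."""
    n, m = fmat.shape
    h = np.empty((n, m), dtype=np.int8)
    h[:, 0] = rng.random(n) < fmat[:, 0]
    for j in range(1, m):
        copy = rng.random(n) < rho
        fresh = rng.random(n) < fmat[:, j]
        h[:, j] = np.where(copy, h[:, j - 1], fresh)
    return h


# ---------------------------------------------------------------------------
# Phenotype and retrospective sampling
# ---------------------------------------------------------------------------

def tune_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for alpha with mean(expit(alpha + eta)) = target."""
    if not 0.0 < target < 1.0:
        raise ValueError("target case fraction must be in (0, 1)")
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(_expit(mid + eta)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, SimulatedTruth]:
    """Full retrospective case-control cohort with planted effects.

    A virtual population ``pool_factor`` times the cohort size is generated;
    disease status is drawn from the additive logistic model; cases and
    controls are then sampled to the exact per-study quotas. The pool grows
    (up to 4 doublings) if a quota cannot be met; beyond that the requested
    design is declared unattainable.
    """
    rng = np.random.default_rng(config.seed)
    snps = snp_metadata(config)
    betas = np.zeros(config.n_snps)
    for e in config.effect_snps:
        betas[config.snp_global_index(e.block, e.index)] = np.log(e.odds_ratio)
    target = config.n_cases / config.n_total

    pool_n = int(np.ceil(config.pool_factor * config.n_total))
    for _attempt in range(5):
        subpop = None
        if config.stratification is not None:
            subpop = (rng.random(pool_n) < config.stratification.fraction).astype(int)
        G = simulate_genotypes(config, n=pool_n, rng=rng, subpop=subpop)

        sex = np.where(rng.random(pool_n) < 0.5, "female", "male")
        age = rng.choice(np.array(config.age_strata, dtype=object), size=pool_n)
        age_lo = dict(zip(config.age_strata, config.age_log_odds))
        eta = G @ betas
        eta += np.where(sex == "female", config.sex_log_odds, 0.0)
        eta += np.array([age_lo[a] for a in age])
        if subpop is not None:
            eta += subpop * config.stratification.disease_log_odds

        alpha = tune_intercept(eta, target)
        disease = rng.random(pool_n) < _expit(alpha + eta)
        study = rng.choice(
            np.arange(config.n_studies), size=pool_n, p=config.study_fractions
        )

        sel = _sample_quotas(disease, study, config, rng)
        if sel is not None:
            break
        pool_n *= 2
    else:
        raise ValueError(
            "requested case/control quotas unattainable from the simulated "
            "population; check odds ratios and offsets"
        )

    G = G[sel]
    if config.missing_rate > 0:
        mask = rng.random(G.shape) < config.missing_rate
        G[mask] = np.nan

    samples = [
        SampleMeta(
            sample_id=f"s{i:06d}",
            status=CASE if disease[j] else CONTROL,
            study=f"study{study[j] + 1}",
            sex=str(sex[j]),
            age_stratum=str(age[j]),
        )
        for i, j in enumerate(sel)
    ]
    dataset = GenotypeDataset(G, samples, snps)
    effect_ids = [
        snps[config.snp_global_index(e.block, e.index)].snp_id
        for e in config.effect_snps
    ]
    truth = SimulatedTruth(
        effect_snp_ids=effect_ids,
        betas={sid: float(np.log(e.odds_ratio))
               for sid, e in zip(effect_ids, config.effect_snps)},
        alpha=float(alpha),
        subpopulation=subpop[sel] if subpop is not None else None,
    )
    return dataset, truth


def _sample_quotas(disease, study, config, rng) -> np.ndarray | None:
    """Indices meeting exact per-study case/control quotas, or None."""
    quotas_cases = _split_quota(config.n_cases, config.study_fractions)
    quotas_controls = _split_quota(config.n_controls, config.study_fractions)
    chosen = []
    for s in range(config.n_studies):
        for want, is_case in ((quotas_cases[s], True), (quotas_controls[s], False)):
            idx = np.flatnonzero((study == s) & (disease == is_case))
            if len(idx) < want:
                return None
            chosen.append(rng.choice(idx, size=want, replace=False))
    return np.sort(np.concatenate(chosen))


def _split_quota(total: int, fractions) -> list[int]:
    """Largest-remainder split of a quota across studies."""
    raw = [total * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = total - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder
    for i in order[:short]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# Canonical test fixtures
# ---------------------------------------------------------------------------

def qc_violation_dataset() -> tuple[GenotypeDataset, dict]:
    """Hand-built 30-sample, 20-SNP dataset where one SNP fails each filter.

    SNPs: snp_lowcall is called in 21/29 retained samples (< 90%); snp_mono
    is monomorphic (MAF 0); snp_raremaf has one minor allele (MAF < 5%);
    snp_hwe has every control heterozygous (gross HWE violation); snp_ok and
    15 filler SNPs in exact Hardy-Weinberg proportions pass everything. One
    sample (s29) misses 4 of 20 calls (completion 0.80 < 94%); samples
    carrying a single missing call stay at 19/20 = 0.95 and are retained.
    """
    n = 30
    n_cases = 10
    nan = np.nan
    # exact HWE at frequency 0.5: dosage pattern [0,1,1,2] from two
    # deterministic haplotypes, period 4 over cases and controls alike
    hwe_ok = np.array([(i % 2) + ((i // 2) % 2) for i in range(n + 2)], dtype=float)
    ok = hwe_ok[:n].copy()
    lowcall = hwe_ok[1:n + 1].copy()
    lowcall[2:10] = nan  # 8 of the retained 29 samples uncalled
    mono = np.zeros(n)
    raremaf = np.zeros(n)
    raremaf[0] = 1.0  # single minor allele
    hwe = np.zeros(n)
    hwe[n_cases:] = 1.0  # every control heterozygous
    fillers = [np.roll(hwe_ok[:n], k).copy() for k in range(15)]
    X = np.column_stack([ok, lowcall, mono, raremaf, hwe] + fillers)
    # bad sample: 4 of 20 calls missing -> completion 0.80
    X[-1, :4] = nan
    samples = [
        SampleMeta(f"s{i:02d}", CASE if i < n_cases else CONTROL)
        for i in range(n)
    ]
    snps = [
        SnpMeta("snp_ok", "1", 1000, "A", "G"),
        SnpMeta("snp_lowcall", "1", 2000, "A", "G"),
        SnpMeta("snp_mono", "1", 3000, "A", "G"),
        SnpMeta("snp_raremaf", "1", 4000, "A", "G"),
        SnpMeta("snp_hwe", "1", 5000, "A", "G"),
    ] + [SnpMeta(f"snp_fill{k}", "1", 6000 + 1000 * k, "A", "G")
         for k in range(15)]
    manifest = {
        "removed_snps": {
            "snp_lowcall": "call_rate",
            "snp_mono": "maf",
            "snp_raremaf": "maf",
            "snp_hwe": "hwe",
        },
        "removed_samples": ["s29"],
        "retained_snps": ["snp_ok"] + [f"snp_fill{k}" for k in range(15)],
        "n_removed_snps": 4,
    }
    return GenotypeDataset(X, samples, snps), manifest


def exhaustive_permutation_dataset(seed: int = 42) -> GenotypeDataset:
    """8 samples (4 cases), 3 genes x 2 SNPs: C(8,4) = 70 relabelings, small
    enough for exact enumeration of the permutation null."""
    cfg = SimulationConfig(
        n_cases=4, n_controls=4,
        blocks=[BlockConfig(2, (0.3, 0.3)) for _ in range(3)],
        seed=seed, pool_factor=8.0,
    )
    dataset, _ = simulate_cohort(cfg)
    # guarantee polymorphism in the tiny sample
    for j in range(dataset.n_snps):
        col = dataset.dosages[:, j]
        if np.ptp(col) == 0:
            col[j % 8] = 1.0 if col[0] != 1.0 else 2.0
    return dataset


def overlap_window_genes() -> tuple[list[GeneModel], list[SnpMeta]]:
    """Two plus-strand genes whose flanked windows overlap, plus probe SNPs:
    one inside each gene, one in the shared overlap, one outside both, one
    on another chromosome at an in-range coordinate."""
    genes = [
        GeneModel("GENE_L", "2", "+", 100_000, 120_000),   # window 80k-130k
        GeneModel("GENE_R", "2", "+", 145_000, 160_000),   # window 125k-170k
    ]
    snps = [
        SnpMeta("in_left", "2", 110_000, "A", "G"),
        SnpMeta("in_overlap", "2", 127_000, "A", "G"),
        SnpMeta("in_right", "2", 150_000, "A", "G"),
        SnpMeta("outside", "2", 200_000, "A", "G"),
        SnpMeta("wrong_chrom", "3", 127_000, "A", "G"),
    ]
    return genes, snps


def make_fixture_suite(out_dir, seed: int = 2024) -> dict:
    """Write the canonical plain-text fixtures used by tests and examples.

    Deterministic given the seed: regenerating produces byte-identical
    files. Returns the manifest (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed}

    qc_ds, qc_manifest = qc_violation_dataset()
    pio.write_text_genotypes(qc_ds, out / "qc_violation.geno.tsv",
                             out / "qc_violation.snps.tsv")
    manifest["qc_violation"] = qc_manifest

    ex = exhaustive_permutation_dataset(seed=seed)
    pio.write_plink(ex, out / "exhaustive8")
    manifest["exhaustive8"] = {"n_relabelings": 70, "n_snps": ex.n_snps}

    genes, snps = overlap_window_genes()
    pio.write_gene_table(genes, out / "overlap_genes.tsv")
    manifest["overlap_genes"] = {"n_genes": len(genes)}

    null_cfg = SimulationConfig(
        n_cases=100, n_controls=100,
        blocks=[BlockConfig(5, (0.2, 0.4), rho=0.3) for _ in range(4)],
        seed=seed,
    )
    null_ds, _ = simulate_cohort(null_cfg)
    pio.write_plink(null_ds, out / "null_cohort")
    gm, pw = block_gene_models(null_cfg)
    pio.write_gene_table(gm, out / "null_cohort.genes.tsv")
    pio.write_gmt([pw], out / "null_cohort.gmt")

    planted_cfg = SimulationConfig(
        n_cases=150, n_controls=150,
        blocks=[BlockConfig(5, (0.2, 0.4), rho=0.3) for _ in range(4)],
        effect_snps=[EffectSnp(0, 2, 2.0)],
        seed=seed + 1,
    )
    planted_ds, truth = simulate_cohort(planted_cfg)
    pio.write_plink(planted_ds, out / "planted_cohort")
    manifest["planted_cohort"] = {
        "effect_snp_ids": truth.effect_snp_ids,
        "betas": truth.betas,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
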