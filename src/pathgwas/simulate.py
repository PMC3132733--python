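"""Synthetic case-control cohorts with known truth.

Generates everything the pipeline consumes — genotypes, covariates, disease
status, SNP→gene annotation and gene sets — under a fully specified model,
so every downstream stage can be tested against planted ground truth:

* genotypes: independent biallelic SNPs, per-subject dosage ~ Binomial(2, MAF)
  (Hardy-Weinberg proportions), missing calls dropped in at a fixed rate;
* covariates: age ~ Normal(age_mean, age_sd), sex ~ Bernoulli(sex_balance)
  coded 0 = female / 1 = male;
* disease: status ~ Bernoulli(expit(baseline + Σ β_s·dosage_s
  + β_age·age + β_sex·sex)), i.e. an additive per-minor-allele logistic
  risk model with optional covariate effects;
* annotation: disjoint SNP blocks per gene, gene sets drawn without
  replacement, with one designated set holding the planted effects.

No linkage disequilibrium or population structure is simulated: the
association and enrichment statistics never model LD, and the phenotype
permutation preserves whatever genotype correlation exists by construction.
Identical configuration + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import GenotypeMatrix, InvalidConfigError

__all__ = [
    "SimulationConfig",
    "AnnotationTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "simulate_cohort",
    "plant_effects",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generating model parameters.

    ``effect_map`` gives the per-minor-allele log-odds for each causal SNP
    (absent SNPs carry no effect).  ``age_effect`` / ``sex_effect`` are
    log-odds per year and per the male indicator; both default to zero so
    the baseline cohort has no confounding.
    """

    n_subjects: int = 700
    snp_mafs: Sequence[float] = field(default_factory=lambda: (0.3,))
    missing_rate: float = 0.0
    effect_map: Mapping[str, float] = field(default_factory=dict)
    baseline_log_odds: float = 0.0
    age_mean: float = 67.0
    age_sd: float = 6.5
    sex_balance: float = 0.5
    age_effect: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        mafs = np.asarray(self.snp_mafs, dtype=float)
        if mafs.size == 0 or np.any(mafs <= 0.0) or np.any(mafs > 0.5):
            raise InvalidConfigError("every MAF must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.sex_balance < 1.0:
            raise InvalidConfigError("sex_balance must lie in (0, 1)")
        if self.age_sd < 0:
            raise InvalidConfigError("age_sd must be non-negative")

    def snp_ids(self) -> np.ndarray:
        width = max(6, len(str(len(list(self.snp_mafs)))))
        return np.array(
            [f"rs{j + 1:0{width}d}" for j in range(len(list(self.snp_mafs)))], dtype=object
        )


@dataclass(frozen=True)
class AnnotationTruth:
    """SNP→gene map plus gene sets, with the enriched ("truth") set named."""

    snp_gene_map: Mapping[str, str]
    gene_sets: Mapping[str, tuple[str, ...]]
    enriched_set_name: str

    def enriched_genes(self) -> tuple[str, ...]:
        return self.gene_sets[self.enriched_set_name]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a subjects × SNPs dosage matrix under HWE with missingness."""
    rng = np.random.default_rng(config.seed)
    mafs = np.asarray(config.snp_mafs, dtype=float)
    n, s = config.n_subjects, mafs.size
    dosages = rng.binomial(2, mafs[None, :], size=(n, s)).astype(float)
    if config.missing_rate > 0:
        dosages[rng.random((n, s)) < config.missing_rate] = np.nan
    snp_ids = config.snp_ids()
    snps = pd.DataFrame(
        {
            "chrom": np.ones(s, dtype=int),
            "pos": np.arange(1, s + 1) * 1000,
            "minor_allele": ["A"] * s,
            "major_allele": ["G"] * s,
            "maf_true": mafs,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    subject_ids = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids, subject_ids=subject_ids, snps=snps)


def _risk_dosage(genotypes: GenotypeMatrix, snp_id: str, maf: float) -> np.ndarray:
    """Dosage vector for the risk model; missing calls take expectation 2·MAF."""
    col = genotypes.dosages[:, genotypes._index_of(snp_id)].copy()
    col[np.isnan(col)] = 2.0 * maf
    return col


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Covariate/status table for a simulated genotype matrix.

    Returns a DataFrame indexed by subject id with columns ``age`` (years),
    ``sex`` (0 female / 1 male) and ``status`` (0 control / 1 case).  The
    linear predictor imputes expected dosage 2·MAF for a missing genotype at
    a causal SNP (risk computation only; association drops missing subjects
    per SNP instead).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = genotypes.n_subjects
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = (rng.random(n) < config.sex_balance).astype(int)
    eta = np.full(n, config.baseline_log_odds, dtype=float)
    if config.effect_map:
        snp_set = set(genotypes.snp_ids.tolist())
        maf_lookup = dict(zip(simulate_snp_ids(config), np.asarray(config.snp_mafs, float)))
        for snp_id, beta in config.effect_map.items():
            if snp_id not in snp_set:
                raise KeyError(f"effect SNP {snp_id!r} absent from genotype matrix")
            maf = maf_lookup.get(snp_id)
            if maf is None:
                c = genotypes.counts(snp_id)
                maf = (2 * c.n_minor_hom + c.n_het) / (2 * max(c.n_typed, 1))
            eta += beta * _risk_dosage(genotypes, snp_id, maf)
    eta += config.age_effect * age + config.sex_effect * sex
    status = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {"age": age, "sex": sex, "status": status},
        index=pd.Index(genotypes.subject_ids, name="subject_id"),
    )


def simulate_snp_ids(config: SimulationConfig) -> np.ndarray:
    """SNP ids the generator assigns, in column order."""
    return config.snp_ids()


def simulate_annotation(
    n_genes: int,
    snps_per_gene: int,
    set_sizes: Sequence[int],
    enriched_set_index: int = 0,
    seed: int = 0,
    snp_ids: Sequence[str] | None = None,
) -> AnnotationTruth:
    """Assign disjoint SNP blocks to genes and sample gene sets.

    Gene ``Gk`` owns SNPs ``[k·snps_per_gene, (k+1)·snps_per_gene)``.  Each
    set is a without-replacement sample of genes; the set at
    ``enriched_set_index`` is designated to hold planted effects.
    """
    if n_genes < 1 or snps_per_gene < 1:
        raise InvalidConfigError("n_genes and snps_per_gene must be >= 1")
    if not set_sizes:
        raise InvalidConfigError("at least one gene set is required")
    if any(s < 1 or s > n_genes for s in set_sizes):
        raise InvalidConfigError("every set size must lie in [1, n_genes]")
    if not 0 <= enriched_set_index < len(set_sizes):
        raise InvalidConfigError("enriched_set_index out of range")
    rng = np.random.default_rng(seed)
    genes = [f"G{k + 1:05d}" for k in range(n_genes)]
    n_snps = n_genes * snps_per_gene
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:06d}" for j in range(n_snps)]
    elif len(snp_ids) < n_snps:
        raise InvalidConfigError(f"need {n_snps} SNP ids, got {len(snp_ids)}")
    snp_gene_map = {
        snp_ids[k * snps_per_gene + j]: genes[k]
        for k in range(n_genes)
        for j in range(snps_per_gene)
    }
    gene_sets = {
        f"SET{i + 1}": tuple(sorted(rng.choice(genes, size=size, replace=False)))
        for i, size in enumerate(set_sizes)
    }
    return AnnotationTruth(
        snp_gene_map=snp_gene_map,
        gene_sets=gene_sets,
        enriched_set_name=f"SET{enriched_set_index + 1}",
    )


def plant_effects(
    truth: AnnotationTruth,
    n_causal_genes: int,
    effect: float,
    seed: int = 0,
) -> dict[str, float]:
    """Pick one SNP in each of ``n_causal_genes`` enriched-set genes and give it ``effect``."""
    rng = np.random.default_rng(seed)
    enriched = list(truth.enriched_genes())
    if n_causal_genes > len(enriched):
        raise InvalidConfigError("more causal genes requested than the enriched set holds")
    causal_genes = rng.choice(enriched, size=n_causal_genes, replace=False)
    by_gene: dict[str, list[str]] = {}
    for snp, gene in truth.snp_gene_map.items():
        by_gene.setdefault(gene, []).append(snp)
    effect_map: dict[str, float] = {}
    for gene in causal_genes:
        snps = sorted(by_gene[gene])
        effect_map[snps[rng.integers(len(snps))]] = effect
    return effect_map


def simulate_cohort(
    config: SimulationConfig,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes and phenotypes together.

    Without quotas this is ``simulate_genotypes`` + ``simulate_phenotypes``
    and case/control counts arise stochastically from the risk model.  With
    ``n_cases``/``n_controls`` given, subjects are rejection-sampled in
    batches until both quotas fill (fixed designs such as 350/350), then
    re-labelled ``S000001…`` in sampling order.
    """
    if (n_cases is None) != (n_controls is None):
        raise InvalidConfigError("give both n_cases and n_controls, or neither")
    if n_cases is None:
        geno = simulate_genotypes(config)
        pheno = simulate_phenotypes(geno, config)
        return geno, pheno

    if n_cases < 1 or n_controls < 1:
        raise InvalidConfigError("case/control quotas must be >= 1")
    need_cases, need_controls = n_cases, n_controls
    batches_g: list[np.ndarray] = []
    batches_p: list[pd.DataFrame] = []
    batch_seed = config.seed
    template: GenotypeMatrix | None = None
    guard = 0
    while need_cases > 0 or need_controls > 0:
        guard += 1
        if guard > 1000:
            raise RuntimeError(
                "rejection sampling did not fill the case/control quotas; "
                "the risk model is too one-sided"
            )
        cfg = SimulationConfig(
            **{**_config_dict(config), "seed": batch_seed, "n_subjects": max(config.n_subjects, 64)}
        )
        geno = simulate_genotypes(cfg)
        pheno = simulate_phenotypes(geno, cfg)
        template = geno
        is_case = pheno["status"].to_numpy() == 1
        take_case = np.flatnonzero(is_case)[:need_cases]
        take_ctrl = np.flatnonzero(~is_case)[:need_controls]
        take = np.sort(np.concatenate([take_case, take_ctrl]))
        if take.size:
            batches_g.append(geno.dosages[take])
            batches_p.append(pheno.iloc[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
        batch_seed += 100003  # distinct stream per batch
    dosages = np.vstack(batches_g)
    pheno = pd.concat(batches_p, axis=0)
    subject_ids = np.array([f"S{i + 1:06d}" for i in range(len(pheno))], dtype=object)
    pheno = pheno.set_axis(pd.Index(subject_ids, name="subject_id"), axis=0)
    assert template is not None
    geno = GenotypeMatrix(
        dosages=dosages,
        snp_ids=template.snp_ids.copy(),
        subject_ids=subject_ids,
        snps=template.snps.copy() if template.snps is not None else None,
    )
    return geno, pheno


def _config_dict(config: SimulationConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "snp_mafs": tuple(config.snp_mafs),
        "missing_rate": config.missing_rate,
        "effect_map": dict(config.effect_map),
        "baseline_log_odds": config.baseline_log_odds,
        "age_mean": config.age_mean,
        "age_sd": config.age_sd,
        "sex_balance": config.sex_balance,
        "age_effect": config.age_effect,
        "sex_effect": config.sex_effect,
        "seed": config.seed,
    }
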