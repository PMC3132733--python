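"""Gene-level statistics and weighted KS running-sum pathway enrichment.

The pathway test proceeds in the order the pipeline runs:

1. **Gene statistic** — each gene is represented by its best SNP: the
   smallest single-SNP association p-value among the gene's QC-surviving,
   un-flagged SNPs.  The ranking statistic is r = −log10(p_min) (a
   chi-square(1)-quantile alternative is available).  Genes with no
   surviving SNP are omitted from the list entirely.
2. **Ranking** — genes sorted by r, largest first; ties break on gene id
   ascending so the list is deterministic.
3. **Enrichment score** — walking down the ranked list L of N genes, a
   running sum gains |r_j|^p / N_R at members of the tested set S (N_R is
   the sum of |r|^p over members, p the weight exponent, default 1) and
   loses 1/(N − N_S) at non-members.  The hit increments sum to 1 and the
   miss decrements sum to 1, so the walk ends at zero; the enrichment score
   ES is the maximum positive deviation reached, and the leading edge is
   the members of S ranked at or before the first position attaining ES.
4. **Permutation null** — case/control labels are shuffled across subjects
   (genotypes and covariates stay attached to their subjects) and steps
   1–3 are fully recomputed per permutation, including the per-SNP
   association scan.  The nominal p-value is the fraction of permuted ES
   at or above the observed ES; NES = observed ES divided by the mean of
   the positive permuted ES.

Only top-of-list enrichment is scored: the maximum *positive* deviation is
used, so depletion of a set from the top of the list never masquerades as
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import association_scan, scan_pvalues, _as_covariate_array
from .containers import GenotypeMatrix, UntestableSetError

__all__ = [
    "GeneStatistic",
    "GeneSet",
    "RunningSumProfile",
    "EnrichmentScore",
    "EnrichmentResult",
    "gene_statistics",
    "rank_genes",
    "enrichment_score",
    "permutation_test",
    "run_pathway_analysis",
]

_P_FLOOR = 1e-300  # keeps -log10(p) finite if a p-value underflows


@dataclass(frozen=True)
class GeneStatistic:
    gene_id: str
    best_snp_id: str
    p_min: float
    r: float


@dataclass(frozen=True)
class GeneSet:
    """A named pathway; ``effective_size`` counts members present in a gene list."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))

    def effective_size(self, gene_ids: Sequence[str]) -> int:
        present = set(gene_ids)
        return sum(1 for g in self.members if g in present)


@dataclass(frozen=True)
class RunningSumProfile:
    """Cumulative running-sum value after each gene of the ranked list."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    weight_p: float


@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    profile: RunningSumProfile
    leading_edge: tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed score plus its phenotype-permutation null summary."""

    set_name: str
    n_s: int
    es: float
    profile: RunningSumProfile
    leading_edge: tuple[str, ...]
    perm_es: np.ndarray
    nominal_p: float
    nes: float
    k_permutations: int
    seed: int


def gene_statistics(
    results: pd.DataFrame,
    snp_gene_map: Mapping[str, str],
    stat: str = "neglog10",
) -> pd.DataFrame:
    """Collapse per-SNP association results to one statistic per gene.

    Each gene's statistic comes from the SNP achieving the smallest p-value
    among its mapped, un-flagged SNPs (ties break on the lexicographically
    smaller SNP id).  Genes whose SNPs were all discarded or flagged are
    omitted.  ``stat`` selects the ranking transform: ``"neglog10"``
    (default, r = −log10 p) or ``"chi2"`` (r = chi-square(1) quantile of p).
    """
    if stat not in ("neglog10", "chi2"):
        raise ValueError("stat must be 'neglog10' or 'chi2'")
    if results.empty:
        return pd.DataFrame(columns=["gene_id", "best_snp_id", "p_min", "r"])
    df = results.loc[~results["flagged"], ["snp_id", "p"]].copy()
    df["gene_id"] = df["snp_id"].map(dict(snp_gene_map))
    df = df.dropna(subset=["gene_id", "p"])
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "best_snp_id", "p_min", "r"])
    # stable min-p per gene with lexicographic SNP-id tie-break
    df = df.sort_values(["gene_id", "p", "snp_id"], kind="mergesort")
    best = df.groupby("gene_id", sort=True).first().reset_index()
    best = best.rename(columns={"snp_id": "best_snp_id", "p": "p_min"})
    best["r"] = _rank_stat(best["p_min"].to_numpy(), stat)
    return best[["gene_id", "best_snp_id", "p_min", "r"]]


def _rank_stat(p: np.ndarray, stat: str) -> np.ndarray:
    p = np.clip(p, _P_FLOOR, 1.0)
    if stat == "chi2":
        from scipy.stats import chi2

        return chi2.isf(p, df=1)
    return -np.log10(p)


def rank_genes(stats: pd.DataFrame) -> pd.DataFrame:
    """Order genes by statistic r descending, gene id ascending on ties."""
    if stats.empty:
        return stats.copy()
    if stats["gene_id"].duplicated().any():
        dupes = stats.loc[stats["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in statistics: {dupes[:5]}")
    out = stats.sort_values(["r", "gene_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def _es_core(
    r: np.ndarray, hit: np.ndarray, weight_p: float
) -> tuple[float, np.ndarray, int]:
    """(es, running sum, first peak position) for a ranked hit indicator."""
    n = r.size
    n_s = int(hit.sum())
    w = np.abs(r) ** weight_p
    n_r = w[hit].sum()
    inc = np.empty(n)
    if n_r > 0:
        inc[hit] = w[hit] / n_r
    else:  # all member statistics are exactly zero; fall back to equal weights
        inc[hit] = 1.0 / n_s
    inc[~hit] = -1.0 / (n - n_s)
    cum = np.cumsum(inc)
    peak = int(np.argmax(cum))
    es = float(max(cum[peak], 0.0))
    return es, cum, peak


def enrichment_score(
    ranked: pd.DataFrame,
    gene_set: GeneSet,
    weight_p: float = 1.0,
) -> EnrichmentScore:
    """Weighted KS running-sum score of a gene set against a ranked list.

    ``ranked`` is a ``rank_genes`` output (columns ``gene_id``, ``r``).
    Raises :class:`UntestableSetError` if no member of the set appears in
    the list, and ``ValueError`` if the set swallows the whole list (the
    miss decrement would be undefined).
    """
    if weight_p < 0:
        raise ValueError("weight_p must be non-negative")
    gene_ids = ranked["gene_id"].to_numpy(dtype=object)
    r = ranked["r"].to_numpy(dtype=float)
    hit = np.isin(gene_ids, np.array(list(gene_set.members), dtype=object))
    n_s = int(hit.sum())
    if n_s == 0:
        raise UntestableSetError(
            f"gene set {gene_set.name!r} shares no genes with the ranked list"
        )
    if n_s == len(gene_ids):
        raise ValueError(
            f"gene set {gene_set.name!r} covers the entire ranked list; "
            "the running sum has no misses to balance"
        )
    es, cum, peak = _es_core(r, hit, weight_p)
    leading = tuple(gene_ids[: peak + 1][hit[: peak + 1]])
    profile = RunningSumProfile(gene_ids=tuple(gene_ids), values=cum, weight_p=weight_p)
    return EnrichmentScore(es=es, profile=profile, leading_edge=leading)


# ---------------------------------------------------------------------------
# phenotype-permutation null
# ---------------------------------------------------------------------------

def _prepare_perm_inputs(genotypes, results, snp_gene_map):
    """Index structures reused across permutations.

    SNPs flagged in the *observed* scan for data-dependent-only reasons
    (monomorphic / too few typed subjects) stay excluded throughout, since
    dosages do not change under label permutation.  Separation is refit per
    permutation by the validity mask of the batch solver.
    """
    mapped_series = results["snp_id"].map(dict(snp_gene_map))
    mapped = mapped_series.to_numpy(dtype=object)
    usable = mapped_series.notna().to_numpy() & ~(
        (results["flag_reason"] == "monomorphic")
        | (results["flag_reason"] == "insufficient_subjects")
    ).to_numpy()
    snp_idx = np.flatnonzero(usable)
    genes_sorted = np.array(sorted(set(mapped[snp_idx].tolist())), dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    gene_of_snp = np.array([gene_pos[g] for g in mapped[snp_idx]], dtype=int)
    dosage_block = genotypes.dosages.T[snp_idx]
    return snp_idx, dosage_block, genes_sorted, gene_of_snp


def _gene_r_from_pvalues(p, ok, gene_of_snp, n_genes, stat):
    pmin = np.full(n_genes, np.inf)
    valid = ok & np.isfinite(p)
    np.minimum.at(pmin, gene_of_snp[valid], p[valid])
    present = np.isfinite(pmin)
    r = np.zeros(n_genes)
    r[present] = _rank_stat(pmin[present], stat)
    return r, present


def _ranked_order(r, present):
    idx = np.flatnonzero(present)
    # sort by r descending, then gene index (== id order) ascending
    order = idx[np.lexsort((idx, -r[idx]))]
    return order


def _permutation_scores(
    genotypes: GenotypeMatrix,
    status: np.ndarray,
    covariates,
    snp_gene_map: Mapping[str, str],
    gene_sets: Sequence[GeneSet],
    k_permutations: int,
    seed: int,
    weight_p: float,
    stat: str = "neglog10",
):
    """Observed results per set plus a shared (K × n_sets) permuted-ES matrix."""
    if k_permutations < 1:
        raise ValueError("k_permutations must be >= 1")
    if not gene_sets:
        raise ValueError("at least one gene set is required")
    status = np.asarray(status, dtype=int)
    cov = _as_covariate_array(covariates, subject_ids=genotypes.subject_ids)

    observed = association_scan(genotypes, status, covariates)
    stats_df = gene_statistics(observed, snp_gene_map, stat=stat)
    ranked = rank_genes(stats_df)
    obs_scores = [enrichment_score(ranked, s, weight_p) for s in gene_sets]

    snp_idx, dosage_block, genes_sorted, gene_of_snp = _prepare_perm_inputs(
        genotypes, observed, snp_gene_map
    )
    n_genes = genes_sorted.size
    member_masks = [
        np.isin(genes_sorted, np.array(list(s.members), dtype=object)) for s in gene_sets
    ]

    rng = np.random.default_rng(seed)
    perm_es = np.empty((k_permutations, len(gene_sets)))
    for k in range(k_permutations):
        y = rng.permutation(status)
        p, ok = scan_pvalues(dosage_block, y, cov)
        r, present = _gene_r_from_pvalues(p, ok, gene_of_snp, n_genes, stat)
        order = _ranked_order(r, present)
        r_ranked = r[order]
        for m, mask in enumerate(member_masks):
            hit = mask[order]
            if not hit.any() or hit.all():
                perm_es[k, m] = np.nan
                continue
            perm_es[k, m], _, _ = _es_core(r_ranked, hit, weight_p)
    return observed, ranked, obs_scores, perm_es


def _summarise(score: EnrichmentScore, perm: np.ndarray, name, n_s, k, seed) -> EnrichmentResult:
    perm = perm[np.isfinite(perm)]
    nominal_p = float((perm >= score.es).sum() / len(perm)) if len(perm) else float("nan")
    positive = perm[perm > 0]
    nes = float(score.es / positive.mean()) if positive.size else float("nan")
    return EnrichmentResult(
        set_name=name,
        n_s=n_s,
        es=score.es,
        profile=score.profile,
        leading_edge=score.leading_edge,
        perm_es=perm,
        nominal_p=nominal_p,
        nes=nes,
        k_permutations=k,
        seed=seed,
    )


def permutation_test(
    genotypes: GenotypeMatrix,
    status: np.ndarray,
    covariates,
    snp_gene_map: Mapping[str, str],
    gene_set: GeneSet,
    k_permutations: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    stat: str = "neglog10",
    mode: str = "phenotype",
) -> EnrichmentResult:
    """Significance of one gene set's enrichment by permutation.

    ``mode="phenotype"`` (canonical): case/control labels are shuffled and
    the whole pipeline — association scan, gene statistics, ranking, score —
    is recomputed per permutation.  ``mode="gene"`` is a fast, *approximate*
    alternative that keeps the observed ranking and scores random same-size
    gene sets instead; it ignores LD-induced correlation between gene
    statistics and is not the reference procedure.
    """
    if mode == "gene":
        return _gene_label_permutation(
            genotypes, status, covariates, snp_gene_map, gene_set,
            k_permutations, seed, weight_p, stat,
        )
    if mode != "phenotype":
        raise ValueError("mode must be 'phenotype' or 'gene'")
    _, ranked, obs_scores, perm_es = _permutation_scores(
        genotypes, status, covariates, snp_gene_map, [gene_set],
        k_permutations, seed, weight_p, stat,
    )
    n_s = gene_set.effective_size(ranked["gene_id"])
    return _summarise(obs_scores[0], perm_es[:, 0], gene_set.name, n_s, k_permutations, seed)


def _gene_label_permutation(
    genotypes, status, covariates, snp_gene_map, gene_set,
    k_permutations, seed, weight_p, stat,
) -> EnrichmentResult:
    observed = association_scan(genotypes, status, covariates)
    ranked = rank_genes(gene_statistics(observed, snp_gene_map, stat=stat))
    score = enrichment_score(ranked, gene_set, weight_p)
    gene_ids = ranked["gene_id"].to_numpy(dtype=object)
    r = ranked["r"].to_numpy(dtype=float)
    n_s = gene_set.effective_size(gene_ids)
    rng = np.random.default_rng(seed)
    perm = np.empty(k_permutations)
    for k in range(k_permutations):
        hit = np.zeros(gene_ids.size, dtype=bool)
        hit[rng.choice(gene_ids.size, size=n_s, replace=False)] = True
        perm[k], _, _ = _es_core(r, hit, weight_p)
    return _summarise(score, perm, gene_set.name, n_s, k_permutations, seed)


def run_pathway_analysis(
    genotypes: GenotypeMatrix,
    status: np.ndarray,
    covariates,
    snp_gene_map: Mapping[str, str],
    gene_sets: Sequence[GeneSet],
    k_permutations: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    stat: str = "neglog10",
    benjamini_hochberg: bool = False,
) -> tuple[pd.DataFrame, list[EnrichmentResult]]:
    """Score several gene sets against one shared permutation stream.

    Every permutation's re-ranked gene list is scored against every set, so
    a single-set call is identical to :func:`permutation_test` and the cost
    of additional sets is marginal.  Returns (summary table, per-set
    results); ``benjamini_hochberg`` adds a ``p_bh`` column (off by default —
    the canonical analysis tests a single pathway).
    """
    if not gene_sets:
        raise ValueError("at least one gene set is required")
    names = [s.name for s in gene_sets]
    if len(set(names)) != len(names):
        raise ValueError("gene set names must be unique")
    _, ranked, obs_scores, perm_es = _permutation_scores(
        genotypes, status, covariates, snp_gene_map, gene_sets,
        k_permutations, seed, weight_p, stat,
    )
    results = [
        _summarise(
            obs_scores[m],
            perm_es[:, m],
            gene_sets[m].name,
            gene_sets[m].effective_size(ranked["gene_id"]),
            k_permutations,
            seed,
        )
        for m in range(len(gene_sets))
    ]
    table = pd.DataFrame(
        {
            "set": [res.set_name for res in results],
            "n_s": [res.n_s for res in results],
            "es": [res.es for res in results],
            "nes": [res.nes for res in results],
            "nominal_p": [res.nominal_p for res in results],
            "leading_edge": [",".join(res.leading_edge) for res in results],
            "k": k_permutations,
            "seed": seed,
        }
    )
    if benjamini_hochberg:
        from statsmodels.stats.multitest import multipletests

        table["p_bh"] = multipletests(table["nominal_p"], method="fdr_bh")[1]
    return table, results
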