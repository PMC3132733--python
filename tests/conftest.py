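"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the most literal route
available — exact rational enumeration for the Hardy-Weinberg test, a
step-by-step running-sum loop for the enrichment score, the 2×2
cross-product ratio for the binary-predictor odds ratio — so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pathgwas.containers import GenotypeMatrix


def make_matrix(dosages, snp_ids=None, subject_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain (subjects x SNPs) array of 0/1/2/nan."""
    dosages = np.asarray(dosages, dtype=float)
    n, s = dosages.shape
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(s)]
    if subject_ids is None:
        subject_ids = [f"sub{i + 1}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "chrom": 1,
            "pos": np.arange(1, s + 1) * 100,
            "minor_allele": ["A"] * s,
            "major_allele": ["G"] * s,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(snp_ids, dtype=object),
        subject_ids=np.array(subject_ids, dtype=object),
        snps=snps,
    )


def hwe_exact_oracle(n_minor_hom: int, n_het: int, n_major_hom: int) -> Fraction:
    """Exact-rational HWE conditional p-value by full enumeration."""
    n = n_minor_hom + n_het + n_major_hom
    na = 2 * n_minor_hom + n_het
    if na > n:
        na = 2 * n - na
    if na == 0:
        return Fraction(1)
    weights: dict[int, Fraction] = {}
    for h in range(na % 2, na + 1, 2):
        n_aa = (na - h) // 2
        n_AA = n - n_aa - h
        if n_AA < 0:
            continue
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(n_AA) * math.factorial(h) * math.factorial(n_aa),
        )
    total = sum(weights.values())
    p_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= p_obs), total)


def es_oracle(gene_ids, rs, members, weight_p=1.0):
    """Literal running-sum loop; recomputes the hit normaliser at every step."""
    members = set(members)
    in_set = [g in members for g in gene_ids]
    n = len(gene_ids)
    n_s = sum(in_set)
    cum = 0.0
    values = []
    for i in range(n):
        if in_set[i]:
            n_r = sum(
                abs(rs[j]) ** weight_p for j in range(n) if in_set[j]
            )  # recomputed each step on purpose
            cum += abs(rs[i]) ** weight_p / n_r
        else:
            cum -= 1.0 / (n - n_s)
        values.append(cum)
    return max(0.0, max(values)), values


def random_ranked_instance(rng, n_max=50):
    """Random (ranked gene list, member subset) instance for ES checks."""
    n = int(rng.integers(2, n_max + 1))
    r = np.sort(rng.exponential(1.0, size=n))[::-1]
    genes = [f"g{j}" for j in range(n)]
    n_s = int(rng.integers(1, n))
    members = list(rng.choice(genes, size=n_s, replace=False))
    ranked = pd.DataFrame({"gene_id": genes, "r": r})
    return ranked, members


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
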