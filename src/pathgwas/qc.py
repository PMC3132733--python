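"""Per-SNP quality control: call rate, Hardy-Weinberg exact test, MAF.

A SNP survives QC iff its call rate, HWE exact p-value and minor allele
frequency are all at or above the configured floors (boundary values pass;
only strictly worse SNPs are discarded).  Defaults mirror standard GWAS
practice: call rate ≥ 0.90, HWE p ≥ 1e-7, MAF ≥ 0.01, all computed on
non-missing genotypes in the total sample (cases + controls).

The HWE test is the exact conditional test: given the number of typed
subjects and the minor-allele count, the p-value sums the probabilities of
every heterozygote count whose conditional probability does not exceed that
of the observed count.  The exact test stays valid at the low genotype
counts where the chi-square approximation breaks down, which is where an
extreme floor like 1e-7 operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeCounts, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "call_rate",
    "minor_allele_frequency",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Inclusive-pass floors for the three SNP filters."""

    min_call_rate: float = 0.90
    hwe_p_floor: float = 1e-7
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_p_floor", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Filter tallies plus a per-SNP table of metrics, flags and reasons.

    A SNP failing several filters is counted once per filter but only once
    in the exclusion total: ``n_input - n_pass`` equals the number of SNPs
    failing at least one filter.
    """

    n_input: int
    n_fail_call_rate: int
    n_fail_hwe: int
    n_fail_maf: int
    n_pass: int
    per_snp: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QC: {self.n_input} SNPs in, {self.n_pass} pass "
            f"(fail call-rate {self.n_fail_call_rate}, HWE {self.n_fail_hwe}, "
            f"MAF {self.n_fail_maf})"
        )


def call_rate(counts: GenotypeCounts) -> float:
    """Fraction of subjects with a non-missing genotype."""
    if counts.total == 0:
        raise ValueError("call rate undefined for zero subjects")
    return counts.n_typed / counts.total


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the rarer allele among non-missing genotypes.

    If the nominal minor allele turns out to be the commoner one the
    complement frequency is returned; :func:`apply_qc` records such swaps
    and recodes the dosage matrix.
    """
    maf, _ = _maf_and_swap(counts)
    return maf


def _maf_and_swap(counts: GenotypeCounts) -> tuple[float, bool]:
    if counts.n_typed == 0:
        raise ValueError("MAF undefined when all genotypes are missing")
    freq = (2 * counts.n_minor_hom + counts.n_het) / (2 * counts.n_typed)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the typed-subject count ``n`` and minor-allele count
    ``n_a``; the p-value is the total probability of heterozygote counts no
    more probable than the observed one.  Monomorphic SNPs admit a single
    outcome, so p = 1.
    """
    if counts.n_typed == 0:
        raise ValueError("HWE test undefined when all genotypes are missing")
    n = counts.n_typed
    n_a = 2 * counts.n_minor_hom + counts.n_het
    if n_a > n:  # condition on the rarer allele; the distribution is symmetric
        n_a = 2 * n - n_a
        het_obs = counts.n_het
    else:
        het_obs = counts.n_het
    if n_a == 0:
        return 1.0
    # heterozygote count shares the parity of the minor-allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    n_aa = (n_a - hets) // 2
    n_AA = n - n_aa - hets
    # log P(het = h | n, n_a) up to the common normalising constant
    logp = hets * np.log(2.0) - (
        gammaln(n_aa + 1) + gammaln(hets + 1) + gammaln(n_AA + 1)
    )
    logp -= logp.max()
    p_all = np.exp(logp)
    p_all /= p_all.sum()
    p_obs = p_all[np.flatnonzero(hets == het_obs)[0]]
    # tolerance keeps exact ties (symmetric configurations) together despite
    # floating-point round-off
    return float(min(1.0, p_all[p_all <= p_obs * (1.0 + 1e-9)].sum()))


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    *,
    status: np.ndarray | None = None,
    hwe_controls_only: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter a genotype matrix and return (surviving matrix, report).

    The three filters are evaluated independently on the input matrix, so
    their application order cannot matter.  SNPs whose nominal minor allele
    is the commoner one in this sample are recoded (dosage flipped, allele
    labels swapped) in the surviving matrix, fixing the minor allele once
    for all downstream use.

    ``hwe_controls_only`` restricts the HWE test to control subjects
    (requires ``status``; 0 = control); the default tests the total sample.
    """
    n_input = genotypes.n_snps
    if n_input == 0:
        empty = pd.DataFrame(
            columns=["call_rate", "maf", "hwe_p", "flipped", "pass", "fail_reasons"]
        )
        return genotypes.subset_snps(np.zeros(0, dtype=int)), QcReport(0, 0, 0, 0, 0, empty)
    if hwe_controls_only and status is None:
        raise ValueError("hwe_controls_only requires status labels")

    cr = np.empty(n_input)
    maf = np.empty(n_input)
    hwe = np.empty(n_input)
    flipped = np.zeros(n_input, dtype=bool)
    controls = None
    if hwe_controls_only:
        controls = np.asarray(status) == 0
    for j in range(n_input):
        c = genotypes.counts(j)
        cr[j] = call_rate(c)
        if c.n_typed == 0:
            maf[j] = np.nan
            hwe[j] = np.nan
            continue
        maf[j], flipped[j] = _maf_and_swap(c)
        if hwe_controls_only:
            col = genotypes.dosages[controls, j]
            cc = GenotypeCounts(
                n_minor_hom=int((col == 2.0).sum()),
                n_het=int((col == 1.0).sum()),
                n_major_hom=int((col == 0.0).sum()),
                n_missing=int(np.isnan(col).sum()),
            )
            hwe[j] = hwe_exact_test(cc) if cc.n_typed else np.nan
        else:
            hwe[j] = hwe_exact_test(c)

    with np.errstate(invalid="ignore"):
        fail_cr = cr < thresholds.min_call_rate
        fail_maf = ~(maf >= thresholds.min_maf)  # nan MAF (all-missing) fails
        fail_hwe = ~(hwe >= thresholds.hwe_p_floor)
    ok = ~(fail_cr | fail_maf | fail_hwe)

    reasons = [
        ";".join(
            r
            for r, f in (("call_rate", fail_cr[j]), ("hwe", fail_hwe[j]), ("maf", fail_maf[j]))
            if f
        )
        for j in range(n_input)
    ]
    per_snp = pd.DataFrame(
        {
            "call_rate": cr,
            "maf": maf,
            "hwe_p": hwe,
            "flipped": flipped,
            "pass": ok,
            "fail_reasons": reasons,
        },
        index=pd.Index(genotypes.snp_ids, name="snp_id"),
    )
    report = QcReport(
        n_input=n_input,
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_pass=int(ok.sum()),
        per_snp=per_snp,
    )
    filtered = genotypes.subset_snps(ok)
    if flipped[ok].any():
        filtered.flip_snps(flipped[ok])
    return filtered, report
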