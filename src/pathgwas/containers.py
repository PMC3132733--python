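"""Shared in-memory containers and exceptions for the pathway-GWAS pipeline.

The central object is :class:`GenotypeMatrix`: a subjects × SNPs matrix of
minor-allele dosages (0/1/2, ``nan`` for a missing call) plus per-SNP
metadata (chromosome, position, allele labels).  Dosage coding is
strand-agnostic: every consumer sees counts of the minor allele as defined
in the total sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenotypeCounts",
    "InvalidConfigError",
    "MonomorphicError",
    "UntestableSetError",
    "PedParseError",
]


class InvalidConfigError(ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class MonomorphicError(ValueError):
    """A SNP has constant dosage among non-missing subjects."""


class UntestableSetError(ValueError):
    """A gene set shares no members with the ranked gene list."""


class PedParseError(ValueError):
    """Malformed PLINK text PED/MAP input; message names the offending line."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one biallelic SNP.

    ``n_minor_hom`` + ``n_het`` + ``n_major_hom`` + ``n_missing`` equals the
    number of subjects.
    """

    n_minor_hom: int
    n_het: int
    n_major_hom: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_minor_hom", "n_het", "n_major_hom", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_minor_hom + self.n_het + self.n_major_hom + self.n_missing

    @property
    def n_typed(self) -> int:
        """Subjects with a non-missing genotype."""
        return self.n_minor_hom + self.n_het + self.n_major_hom


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs minor-allele dosage matrix.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_subjects, n_snps)`` holding 0.0/1.0/2.0
        minor-allele counts, ``nan`` where the call is missing.
    snp_ids, subject_ids
        Unique identifiers along each axis.
    snps
        Optional per-SNP metadata indexed by SNP id with columns
        ``chrom``, ``pos``, ``minor_allele``, ``major_allele``.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    subject_ids: np.ndarray
    snps: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        if self.dosages.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or nan")
        if self.snps is not None and not self.snps.index.equals(pd.Index(self.snp_ids)):
            raise ValueError("snps metadata index must equal snp_ids")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def counts(self, snp: int | str) -> GenotypeCounts:
        """Genotype class counts for one SNP (by column index or id)."""
        j = snp if isinstance(snp, (int, np.integer)) else self._index_of(snp)
        col = self.dosages[:, j]
        n_missing = int(np.isnan(col).sum())
        return GenotypeCounts(
            n_minor_hom=int((col == 2.0).sum()),
            n_het=int((col == 1.0).sum()),
            n_major_hom=int((col == 0.0).sum()),
            n_missing=n_missing,
        )

    def _index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(hits[0])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNPs selected by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        meta = self.snps.iloc[keep].copy() if self.snps is not None else None
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            snp_ids=self.snp_ids[keep].copy(),
            subject_ids=self.subject_ids.copy(),
            snps=meta,
        )

    def flip_snps(self, flip: np.ndarray) -> None:
        """Swap minor/major coding (dosage -> 2 - dosage) for the masked SNPs, in place."""
        flip = np.asarray(flip, dtype=bool)
        self.dosages[:, flip] = 2.0 - self.dosages[:, flip]
        if self.snps is not None and {"minor_allele", "major_allele"} <= set(self.snps.columns):
            cols = self.snps.columns.get_indexer(["minor_allele", "major_allele"])
            block = self.snps.iloc[flip, cols].to_numpy()
            self.snps.iloc[flip, cols] = block[:, ::-1]
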