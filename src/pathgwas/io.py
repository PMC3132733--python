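"""Readers/writers for the pipeline's file formats, plus run configuration.

Formats handled (all plain text):

* PLINK text PED/MAP — genotypes.  MAP: ``chrom  snp_id  cM  pos``;
  PED: ``FID IID PAT MAT SEX PHENO`` followed by two allele columns per
  SNP.  Missing allele is ``"0"``; phenotype 1 = control, 2 = case, any
  other value = missing status.  On read, alleles are recoded to
  minor-allele dosage using sample-wide allele frequencies (ties break to
  the alphabetically smaller allele as minor).
* covariate TSV — ``FID IID AGE SEX`` (sex 0 = female / 1 = male).
* SNP→gene TSV — two columns ``SNP  GENE`` (many-to-one).
* GMT — one gene set per line: ``name <TAB> description <TAB> member…``.
* report TSVs — per-SNP, per-gene and per-set tables plus a run log.

Coordinates are 1-based as in the PLINK text dialect; no strand handling is
needed because dosage coding is strand-agnostic after minor-allele
recoding.  Every write-then-read round trip is lossless for the fields the
pipeline consumes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, PedParseError
from .enrichment import EnrichmentResult, GeneSet
from .qc import QcReport, QcThresholds

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "read_ped_map",
    "write_ped_map",
    "read_covariates",
    "write_covariates",
    "read_snp_gene_map",
    "write_snp_gene_map",
    "read_gmt",
    "write_gmt",
    "write_reports",
    "format_permutation_p",
]

logger = logging.getLogger("pathgwas")

_MISSING_ALLELE = "0"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed and a tag."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative end-to-end run configuration (YAML-loadable)."""

    ped: str
    map: str
    covariates: str
    snp_gene_map: str
    gene_sets: str
    out_dir: str = "pathgwas_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    weight_p: float = 1.0
    k_permutations: int = 1000
    seed: int = 0
    lambda_adjust: bool = True
    stat: str = "neglog10"

    def __post_init__(self) -> None:
        if self.k_permutations < 1:
            raise ValueError("k_permutations must be >= 1")
        if self.weight_p < 0:
            raise ValueError("weight_p must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc_raw = raw.pop("qc", {})
        return cls(qc=QcThresholds(**qc_raw), **raw)

    def to_yaml(self) -> str:
        d = {
            "ped": self.ped,
            "map": self.map,
            "covariates": self.covariates,
            "snp_gene_map": self.snp_gene_map,
            "gene_sets": self.gene_sets,
            "out_dir": self.out_dir,
            "qc": {
                "min_call_rate": self.qc.min_call_rate,
                "hwe_p_floor": self.qc.hwe_p_floor,
                "min_maf": self.qc.min_maf,
            },
            "weight_p": self.weight_p,
            "k_permutations": self.k_permutations,
            "seed": self.seed,
            "lambda_adjust": self.lambda_adjust,
            "stat": self.stat,
        }
        return yaml.safe_dump(d, sort_keys=False)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path):
    """Read PLINK text genotypes.

    Returns ``(GenotypeMatrix, status, covariates)`` where ``status`` is a
    0/1/nan array (control/case/missing) and ``covariates`` a DataFrame
    with the PED sex column (1 = male, 2 = female → recoded 1/0; 0 →
    missing), indexed by subject id (IID).
    """
    map_rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PedParseError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    snp_ids = [r[1] for r in map_rows]
    if len(set(snp_ids)) != len(snp_ids):
        raise PedParseError(f"{map_path}: duplicate SNP ids")
    n_snps = len(snp_ids)

    subject_ids: list[str] = []
    seen: set[str] = set()
    sexes: list[float] = []
    statuses: list[float] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PedParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                f"(6 + 2x{n_snps} SNPs), got {len(parts)}"
            )
        iid = parts[1]
        if iid in seen:
            raise PedParseError(f"{ped_path}:{lineno}: duplicate subject id {iid!r}")
        seen.add(iid)
        subject_ids.append(iid)
        sexes.append({"1": 1.0, "2": 0.0}.get(parts[4], np.nan))
        statuses.append({"1": 0.0, "2": 1.0}.get(parts[5], np.nan))
        allele_rows.append(parts[6:])

    n = len(subject_ids)
    dosages = np.full((n, n_snps), np.nan)
    minor_alleles: list[str] = []
    major_alleles: list[str] = []
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_snps, 2) if n else np.empty(
        (0, n_snps, 2), dtype=object
    )
    for j, snp_id in enumerate(snp_ids):
        col = alleles[:, j, :]
        observed = sorted({a for pair in col for a in pair if a != _MISSING_ALLELE})
        if len(observed) > 2:
            raise PedParseError(
                f"{ped_path}: SNP {snp_id!r} (MAP line {j + 1}) has >2 alleles: {observed}"
            )
        if not observed:
            minor_alleles.append("?")
            major_alleles.append("?")
            continue
        counts = {a: 0 for a in observed}
        for pair in col:
            for a in pair:
                if a != _MISSING_ALLELE:
                    counts[a] += 1
        if len(observed) == 1:
            major, minor = observed[0], observed[0]
        else:
            a, b = observed  # alphabetical; stable tie-break
            minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
        minor_alleles.append(minor)
        major_alleles.append(major)
        for i in range(n):
            a1, a2 = col[i]
            if a1 == _MISSING_ALLELE or a2 == _MISSING_ALLELE:
                continue
            dosages[i, j] = (a1 == minor) + (a2 == minor)

    snps = pd.DataFrame(
        {
            "chrom": [r[0] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "minor_allele": minor_alleles,
            "major_allele": major_alleles,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    geno = GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(snp_ids, dtype=object),
        subject_ids=np.array(subject_ids, dtype=object),
        snps=snps,
    )
    covariates = pd.DataFrame(
        {"sex": sexes}, index=pd.Index(subject_ids, name="subject_id")
    )
    return geno, np.array(statuses), covariates


def write_ped_map(
    genotypes: GenotypeMatrix,
    status: np.ndarray,
    ped_path: str | Path,
    map_path: str | Path,
    sex: np.ndarray | None = None,
) -> None:
    """Write PLINK text PED/MAP (phenotype 1 = control, 2 = case)."""
    snps = genotypes.snps
    with open(map_path, "w") as fh:
        for j, snp_id in enumerate(genotypes.snp_ids):
            chrom = snps["chrom"].iloc[j] if snps is not None else 1
            pos = snps["pos"].iloc[j] if snps is not None else (j + 1) * 1000
            fh.write(f"{chrom}\t{snp_id}\t0\t{pos}\n")
    minor = (
        snps["minor_allele"].to_numpy() if snps is not None else np.repeat("A", genotypes.n_snps)
    )
    major = (
        snps["major_allele"].to_numpy() if snps is not None else np.repeat("G", genotypes.n_snps)
    )
    status = np.asarray(status, dtype=float)
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(genotypes.subject_ids):
            sx = "0"
            if sex is not None and np.isfinite(float(sex[i])):
                sx = "1" if int(sex[i]) == 1 else "2"
            ph = "0"
            if np.isfinite(status[i]):
                ph = "2" if int(status[i]) == 1 else "1"
            fields = [str(iid), str(iid), "0", "0", sx, ph]
            row = genotypes.dosages[i]
            for j in range(genotypes.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += [_MISSING_ALLELE, _MISSING_ALLELE]
                elif d == 0:
                    fields += [major[j], major[j]]
                elif d == 1:
                    fields += [minor[j], major[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# covariates, SNP->gene map, GMT
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate TSV (FID IID AGE SEX) -> DataFrame(age, sex) indexed by IID."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    required = {"FID", "IID", "AGE", "SEX"}
    if not required <= set(df.columns):
        raise ValueError(f"covariate file must have columns {sorted(required)}")
    if df["IID"].duplicated().any():
        raise ValueError("duplicate subject ids in covariate file")
    return pd.DataFrame(
        {"age": df["AGE"].to_numpy(float), "sex": df["SEX"].to_numpy(float)},
        index=pd.Index(df["IID"].to_numpy(object), name="subject_id"),
    )


def write_covariates(pheno: pd.DataFrame, path: str | Path) -> None:
    """Write the covariate TSV from a phenotype table with age/sex columns."""
    out = pd.DataFrame(
        {
            "FID": pheno.index,
            "IID": pheno.index,
            "AGE": pheno["age"].to_numpy(),
            "SEX": pheno["sex"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_snp_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"SNP", "GENE"} <= set(df.columns):
        raise ValueError("SNP->gene map must have columns SNP and GENE")
    if df["SNP"].duplicated().any():
        raise ValueError("SNP->gene map assigns some SNP to several genes")
    return dict(zip(df["SNP"], df["GENE"]))


def write_snp_gene_map(snp_gene_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"SNP": list(snp_gene_map.keys()), "GENE": list(snp_gene_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members…).

    Duplicate members within a set are dropped with a warning; a blank set
    name or a memberless line is an error.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 member")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if not name.strip():
            raise ValueError(f"{path}:{lineno}: blank gene set name")
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            logger.warning(
                "%s:%d: gene set %r lists %d duplicate member(s); de-duplicated",
                path, lineno, name, len(members) - len(unique),
            )
        sets.append(GeneSet(name=name, members=tuple(unique)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.name, description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def format_permutation_p(p: float, k: int) -> str:
    """A permutation p of exactly 0 prints as the resolution bound '<1/K'."""
    if p == 0.0:
        return f"<{1.0 / k:g}"
    return f"{p:.4g}"


def _sig4(x: float) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.4g}"


def write_reports(
    out_dir: str | Path,
    *,
    config: PipelineConfig,
    qc_report: QcReport,
    snp_results: pd.DataFrame,
    adjusted_p: np.ndarray | None,
    lambda_gc: float | None,
    gene_stats: pd.DataFrame,
    set_results: Sequence[EnrichmentResult],
    gene_sets: Sequence[GeneSet],
    snp_meta: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the per-SNP, per-gene and per-set TSVs plus a run log.

    The per-SNP table mirrors the usual top-association layout: identifiers
    and position, raw and λ-adjusted p, minor allele, MAF, OR with its 95%
    CI.  The per-gene table flags set membership and leading-edge status
    for the first configured gene set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    snp_tab = snp_results.copy()
    if snp_meta is not None:
        cols = [c for c in ("chrom", "pos", "minor_allele", "role") if c in snp_meta.columns]
        snp_tab = snp_tab.merge(
            snp_meta[cols], left_on="snp_id", right_index=True, how="left"
        )
        lead = ["snp_id", *cols]
        snp_tab = snp_tab[lead + [c for c in snp_tab.columns if c not in lead]]
    snp_tab["p_lambda_adjusted"] = adjusted_p if adjusted_p is not None else np.nan
    for col in ("odds_ratio", "ci_low", "ci_high"):
        snp_tab[col] = snp_tab[col].map(_sig4)
    paths["per_snp"] = out / "per_snp.tsv"
    snp_tab.to_csv(paths["per_snp"], sep="\t", index=False, float_format="%.6g")

    leading = set(set_results[0].leading_edge) if set_results else set()
    in_set = set(gene_sets[0].members) if gene_sets else set()
    gene_tab = gene_stats.copy()
    gene_tab["in_set"] = gene_tab["gene_id"].isin(in_set)
    gene_tab["leading_edge"] = gene_tab["gene_id"].isin(leading)
    paths["per_gene"] = out / "per_gene.tsv"
    gene_tab.to_csv(paths["per_gene"], sep="\t", index=False, float_format="%.6g")

    rows = []
    for res in set_results:
        rows.append(
            {
                "set": res.set_name,
                "n_s": res.n_s,
                "es": f"{res.es:.6g}",
                "nes": f"{res.nes:.6g}",
                "nominal_p": format_permutation_p(res.nominal_p, res.k_permutations),
                "k": res.k_permutations,
                "seed": res.seed,
                "leading_edge": ",".join(res.leading_edge),
            }
        )
    paths["per_set"] = out / "per_set.tsv"
    pd.DataFrame(rows).to_csv(paths["per_set"], sep="\t", index=False)

    paths["log"] = out / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write("# pathgwas run log\n## configuration\n")
        fh.write(config.to_yaml())
        fh.write("## qc\n")
        fh.write(
            f"n_input\t{qc_report.n_input}\nn_pass\t{qc_report.n_pass}\n"
            f"n_fail_call_rate\t{qc_report.n_fail_call_rate}\n"
            f"n_fail_hwe\t{qc_report.n_fail_hwe}\n"
            f"n_fail_maf\t{qc_report.n_fail_maf}\n"
        )
        if lambda_gc is not None:
            fh.write(f"## genomic control\nlambda_gc\t{lambda_gc:.6g}\n")
    return paths
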