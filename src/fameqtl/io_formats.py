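"""File formats, domain containers, run configuration and logging.

Every on-disk format the pipeline touches is read and written here: VCF
genotypes (via cyvcf2), 6-column PED/FAM pedigrees, BED3 interval tracks,
TSV expression/annotation/covariate tables, the TSV eQTL output table and
the YAML run configuration.  All coordinate conventions are normalised at
the boundary: genotype and annotation positions are 1-based, BED intervals
stay 0-based half-open inside :class:`IntervalSet`.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fameqtl")


def get_logger() -> logging.Logger:
    """Package logger; line-oriented, stderr by default."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def log_stage(name: str):
    """Log entry, exit and wall time of a pipeline stage."""
    log = get_logger()
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    yield
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def norm_chrom(c: str) -> str:
    """Chromosome names compare equal after stripping an optional 'chr' prefix."""
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Family-structured individuals with parent links.

    ``table`` has columns family, individual, father, mother, sex; founders
    carry ``None`` for both parents.  Individuals are kept family-major and,
    within a family, parents-before-offspring, so downstream covariance
    matrices are literally block diagonal.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        self.table = t.where(pd.notnull(t), None)  # NaN parents -> None
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if t["individual"].duplicated().any():
            dup = t.loc[t["individual"].duplicated(), "individual"].tolist()
            raise ValueError(f"duplicate individual ids: {dup}")
        ids = set(t["individual"])
        for _, row in t.iterrows():
            f, m = row["father"], row["mother"]
            if (f is None) != (m is None):
                raise ValueError(
                    f"individual {row['individual']}: exactly one parent known; "
                    "either both parents must be in the file or both coded 0"
                )
            if f is not None and (f not in ids or m not in ids):
                raise ValueError(
                    f"individual {row['individual']}: parent(s) {f!r}/{m!r} "
                    "not present in pedigree"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {
            r["individual"]: (r["father"], r["mother"])
            for _, r in self.table.iterrows()
        }
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(i: str, stack: list[str]) -> None:
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                raise ValueError(f"pedigree cycle involving {' -> '.join(stack + [i])}")
            state[i] = 0
            f, m = parent[i]
            for p in (f, m):
                if p is not None:
                    visit(p, stack + [i])
            state[i] = 1

        for i in parent:
            visit(i, [])

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual"].tolist()

    @property
    def family_ids(self) -> list[str]:
        return self.table["family"].tolist()

    def founders(self) -> list[str]:
        t = self.table
        return t.loc[t["father"].isnull(), "individual"].tolist()

    def families(self) -> dict[str, list[str]]:
        """Family id -> member ids, preserving row order."""
        out: dict[str, list[str]] = {}
        for fam, iid in zip(self.table["family"], self.table["individual"]):
            out.setdefault(fam, []).append(iid)
        return out

    def sorted_parents_first(self) -> "Pedigree":
        """Reorder so parents precede offspring within each family."""
        order: list[int] = []
        idx_of = {iid: k for k, iid in enumerate(self.table["individual"])}
        placed: set[str] = set()
        for fam, members in self.families().items():
            remaining = list(members)
            while remaining:
                progressed = False
                for iid in list(remaining):
                    row = self.table.iloc[idx_of[iid]]
                    f, m = row["father"], row["mother"]
                    if (f is None or f in placed) and (m is None or m in placed):
                        order.append(idx_of[iid])
                        placed.add(iid)
                        remaining.remove(iid)
                        progressed = True
                if not progressed:  # pragma: no cover - cycles caught earlier
                    raise ValueError(f"cannot topologically order family {fam}")
        return Pedigree(self.table.iloc[order].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """SNP dosages (count of alt allele) for a set of samples.

    ``dosage`` is samples x snps, values in {0,1,2} with NaN for missing.
    ``snps`` has columns id, chrom, pos (1-based bp), ref, alt.  ``maf`` is
    the per-SNP minor allele frequency over non-missing dosages.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage shape does not match sample_ids x snps")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive")
        computed = compute_maf(self.dosage)
        if self.maf is None:
            self.maf = computed
        elif not np.allclose(np.nan_to_num(self.maf), np.nan_to_num(computed),
                             atol=1e-12):
            raise ValueError("stored maf inconsistent with dosages")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from genotypes: {missing}")
        rows = [pos[s] for s in ids]
        return GenotypeMatrix(list(ids), self.snps.copy(), self.dosage[rows])

    def imputed_dosage(self) -> np.ndarray:
        """Mean-impute missing dosages per SNP (logged)."""
        d = self.dosage.copy()
        miss = np.isnan(d)
        n_miss = int(miss.sum())
        if n_miss:
            col_mean = np.nanmean(d, axis=0)
            d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
            get_logger().info("mean-imputed %d missing dosage cells", n_miss)
        return d


def compute_maf(dosage: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP from non-missing dosages, in [0, 0.5]."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class ExpressionMatrix:
    """probes x samples real matrix of expression values."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match probes x samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids not unique")
        if np.isnan(self.values).all(axis=1).any():
            raise ValueError("expression contains an entirely-missing probe row")

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from expression: {missing}")
        cols = [pos[s] for s in ids]
        return ExpressionMatrix(self.probe_ids, list(ids), self.values[:, cols])


@dataclass
class ProbeAnnotation:
    """Transcript coordinates per probe: probe_id, gene_symbol, chrom, tx_start, tx_end."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if (t["tx_start"] > t["tx_end"]).any():
            bad = t.loc[t["tx_start"] > t["tx_end"], "probe_id"].tolist()
            raise ValueError(f"tx_start > tx_end for probes: {bad}")
        self.table = t

    def for_probe(self, probe_id: str) -> pd.Series:
        hit = self.table[self.table["probe_id"] == probe_id]
        if hit.empty:
            raise KeyError(f"no annotation for probe {probe_id}")
        return hit.iloc[0]


@dataclass
class CovariateTable:
    """Per-sample covariates: age, sex, smoking, and expression PCs once filled."""

    table: pd.DataFrame  # index: sample_id; columns age, sex, smoking[, pc1, pc2]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in covariates")

    def design_matrix(self, sample_ids: Sequence[str],
                      columns: Sequence[str] = ("age", "sex", "smoking", "pc1", "pc2"),
                      ) -> np.ndarray:
        """Intercept-first fixed-effect design for the given samples."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from covariates: {missing}")
        sub = self.table.loc[list(sample_ids), list(columns)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing covariate values in columns {bad}")
        return np.column_stack([np.ones(len(sub)), sub.to_numpy(float)])


@dataclass
class IntervalSet:
    """BED-convention intervals: 0-based inclusive start, exclusive end."""

    table: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if (t["start"] >= t["end"]).any():
            raise ValueError("interval with start >= end")
        t["chrom"] = t["chrom"].map(norm_chrom)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, maf_min: float = 0.05) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into dosages of the alt allele.

    Multi-allelic records are dropped (count logged); records with minor
    allele frequency below ``maf_min`` are excluded.  Missing genotypes
    become NaN and are excluded from the MAF denominator.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", norm_chrom(var.CHROM),
                     var.POS, var.REF, var.ALT[0]))
        dosages.append(gt)
    vcf.close()
    if n_multi:
        get_logger().info("read_vcf: excluded %d multi-allelic records", n_multi)
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dos = np.array(dosages, dtype=float).T if dosages else np.empty((len(samples), 0))
    maf = compute_maf(dos) if dos.size else np.empty(0)
    keep = np.where(np.nan_to_num(maf) >= maf_min)[0] if len(snps) else np.empty(0, int)
    n_dropped = len(snps) - len(keep)
    if n_dropped:
        get_logger().info("read_vcf: excluded %d SNPs with MAF < %g", n_dropped, maf_min)
    return GenotypeMatrix(samples, snps.iloc[keep].reset_index(drop=True),
                          dos[:, keep])


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED/FAM file (family, individual, father, mother, sex, [pheno])."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 5:
                raise ValueError(f"PED line with fewer than 5 columns: {line!r}")
            fam, iid, father, mother, sex = f[:5]
            rows.append({
                "family": fam,
                "individual": iid,
                "father": None if father == "0" else father,
                "mother": None if mother == "0" else mother,
                "sex": int(sex),
            })
    return Pedigree(pd.DataFrame(rows))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in ped.table.iterrows():
            fh.write(f"{r['family']}\t{r['individual']}\t{r['father'] or 0}\t"
                     f"{r['mother'] or 0}\t{r['sex']}\t-9\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file, preserving 0-based half-open coordinates."""
    t = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                    usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return IntervalSet(t)


def read_expression(path: str | Path, annotation_path: str | Path,
                    ) -> tuple[ExpressionMatrix, ProbeAnnotation]:
    """Read an expression TSV (probes as rows, samples as columns) plus its
    probe annotation TSV (probe_id, gene_symbol, chrom, tx_start, tx_end)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    expr = ExpressionMatrix(df.index.astype(str).tolist(),
                            df.columns.astype(str).tolist(),
                            df.to_numpy(float))
    ann = pd.read_csv(annotation_path, sep="\t",
                      dtype={"probe_id": str, "gene_symbol": str, "chrom": str})
    ann["chrom"] = ann["chrom"].map(norm_chrom)
    annotated = set(ann["probe_id"])
    missing = [p for p in expr.probe_ids if p not in annotated]
    if missing:
        get_logger().info("read_expression: %d probes lack annotation", len(missing))
    return expr, ProbeAnnotation(ann)


def read_covariates(path: str | Path) -> CovariateTable:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return CovariateTable(t)


def check_sample_alignment(expr: ExpressionMatrix, covar: CovariateTable,
                           genotypes: GenotypeMatrix) -> list[str]:
    """Samples usable for analysis: the expression samples, which must all be
    present in both covariates and genotypes (offenders listed otherwise)."""
    geno = set(genotypes.sample_ids)
    cov = set(covar.table.index)
    bad = [s for s in expr.sample_ids if s not in geno or s not in cov]
    if bad:
        raise ValueError(f"expression samples missing from genotypes or covariates: {bad}")
    return list(expr.sample_ids)


# ---------------------------------------------------------------------------
# eQTL table output
# ---------------------------------------------------------------------------

EQTL_COLUMNS = ["probe", "gene", "snp", "chrom", "pos", "beta_snp",
                "raw_p", "adjusted_p", "empirical_p", "fdr_significant"]


def write_eqtl_table(records: Iterable, path: str | Path) -> None:
    """Write EqtlRecords as a tab-delimited table with a fixed column order."""
    rows = [{
        "probe": r.probe_id, "gene": r.gene_symbol, "snp": r.snp_id,
        "chrom": r.chromosome, "pos": r.position, "beta_snp": r.beta_s,
        "raw_p": r.raw_p, "adjusted_p": r.adjusted_p,
        "empirical_p": r.empirical_p, "fdr_significant": int(r.fdr_significant),
    } for r in records]
    pd.DataFrame(rows, columns=EQTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str,
                                              "snp": str, "chrom": str})


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Structured run configuration for the cis scan.

    Sections mirror the YAML file: inputs (paths), model, permutation,
    enrichment, output, seed.
    """

    inputs: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    # model defaults
    @property
    def window_bp(self) -> int:
        return int(self.model.get("window_bp", 1_000_000))

    @property
    def maf_min(self) -> float:
        return float(self.model.get("maf_min", 0.05))

    @property
    def cis_anchor(self) -> str:
        # "transcript": window from tx start AND end; "tss": from tx start only
        return str(self.model.get("cis_anchor", "transcript"))

    @property
    def h2_bin_edges(self) -> list[float]:
        return list(self.permutation.get("bin_edges",
                                         [0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 1.0]))

    @property
    def n_perm(self) -> int:
        return int(self.permutation.get("n_perm", 3))

    @property
    def fdr_q(self) -> float:
        return float(self.output.get("fdr_q", 0.05))


def load_config(path: str | Path) -> ScanConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ScanConfig(
        inputs=raw.get("inputs", {}), model=raw.get("model", {}),
        permutation=raw.get("permutation", {}),
        enrichment=raw.get("enrichment", {}),
        output=raw.get("output", {}), seed=int(raw.get("seed", 0)),
    )
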