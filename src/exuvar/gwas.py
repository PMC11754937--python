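"""Mixed-model genome-wide association for accession-mean metabolite traits.

Genotypes of inbred accessions are binary (0/1) per biallelic SNP.
Preprocessing removes SNPs carried by fewer than a minimum number of
accessions (MAF as an accession count), recodes residual heterozygous
calls to the SNP's major allele, and masks per-trait outliers.

Population structure is handled EMMAX/P3D style: a kinship matrix K of
identity-by-state similarities (proportion of shared alleles) enters a
mixed model y = mu + u + e with u ~ N(0, sg2 * K), e ~ N(0, se2 * I).
The variance-component ratio delta = se2/sg2 is REML-estimated once per
trait on the null model via the eigendecomposition of K; every SNP is then
tested by generalized least squares with the covariance fixed, using an
F statistic with (1, n-2) reference degrees of freedom.

Significant SNPs (-log10 p >= 7.5 by default) are annotated with the
containing gene, or with the two nearest flanking genes when intergenic,
from a GFF3 file.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "GwasResult",
    "AnnotationHit",
    "read_genotypes",
    "write_genotypes_tsv",
    "preprocess",
    "ibs_kinship",
    "allele_difference_distance",
    "mlm_null_fit",
    "mlm_scan",
    "call_significant",
    "annotate_flanking",
]

MISSING = -9  # sentinel for missing calls
HET = 2  # sentinel for heterozygous calls pre-recoding


@dataclasses.dataclass
class GenotypeMatrix:
    """Accessions x SNPs calls with SNP map (chromosome, 1-based position).

    ``calls`` uses 0/1 for the two alleles, ``HET`` (2) for heterozygous
    and ``MISSING`` (-9) for no-calls; after :func:`preprocess` only 0/1
    remain. ``snps`` is a DataFrame with columns chrom, pos (and
    optionally ref/alt), one row per SNP column.
    """

    accessions: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.accessions = [str(a) for a in self.accessions]
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.accessions), len(self.snps)):
            raise ValueError("calls shape does not match accessions x snps")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def minor_allele_counts(self) -> np.ndarray:
        """Minor-allele accession count per SNP over binary, non-missing calls."""
        valid = (self.calls == 0) | (self.calls == 1)
        ones = np.where(valid & (self.calls == 1), 1, 0).sum(axis=0)
        n_valid = valid.sum(axis=0)
        return np.minimum(ones, n_valid - ones)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.accessions,
            self.snps.loc[np.asarray(mask)].reset_index(drop=True),
            self.calls[:, np.asarray(mask)],
            self.n_skipped_records,
        )


@dataclasses.dataclass
class KinshipMatrix:
    """Accession x accession IBS similarity; entries in [0, 1], diagonal 1."""

    labels: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        n = len(self.labels)
        if self.k.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(self.k, self.k.T, atol=1e-12):
            raise ValueError("kinship not symmetric")
        if not np.allclose(np.diag(self.k), 1.0, atol=1e-12):
            raise ValueError("kinship diagonal must be 1")
        if self.k.min() < -1e-12 or self.k.max() > 1 + 1e-12:
            raise ValueError("kinship entries outside [0, 1]")


@dataclasses.dataclass
class GwasResult:
    """Per-SNP association statistics for one trait."""

    trait_id: str
    table: pd.DataFrame  # chrom, pos, effect, se, p, neglog10p, maf_count
    sigma2_g: float
    sigma2_e: float
    delta: float
    n_used: int


@dataclasses.dataclass
class AnnotationHit:
    chrom: str
    pos: int
    relation: str  # genic | intergenic
    loci: list[dict]
    one_sided: bool = False


def read_genotypes(path, accessions: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (via cyvcf2) or a 0/1 TSV matrix.

    VCF: biallelic SNP records only (others skipped and counted); inbred
    lines are expected, so 0/0 -> 0, 1/1 -> 1, 0/1 -> HET, ./. -> MISSING.
    TSV: first two columns chrom, pos; remaining columns one per
    accession with values 0/1, ``het`` or empty/NA for missing.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        gm = _read_vcf(path)
    else:
        gm = _read_tsv(path)
    if accessions is not None:
        extra = set(gm.accessions) ^ set(map(str, accessions))
        if extra:
            raise ValueError(
                f"genotype samples do not match accession metadata: {sorted(extra)}"
            )
    return gm


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, cols = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gts = var.gt_types  # 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gts == 0] = 0
        col[gts == 3] = 1
        col[gts == 1] = HET
        cols.append(col)
        rows.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snps, calls, n_skipped_records=skipped)


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["pos"] = df["pos"].astype(int)
    snp_cols = ["chrom", "pos"]
    acc = [c for c in df.columns if c not in snp_cols]
    raw = df[acc].to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for val, code in (("0", 0), ("1", 1), ("het", HET)):
        calls[raw == val] = code
    return GenotypeMatrix(acc, df[snp_cols], calls.T)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    """Write the 0/1 TSV dialect read back by :func:`read_genotypes`."""
    out = g.snps[["chrom", "pos"]].copy()
    rev = {0: "0", 1: "1", HET: "het", MISSING: ""}
    for i, a in enumerate(g.accessions):
        out[a] = [rev[int(v)] for v in g.calls[i]]
    out.to_csv(path, sep="\t", index=False)


def detect_trait_outliers(trait: pd.Series, n_sd: float = 4.0) -> pd.Series:
    """Boolean mask of trait values beyond ``n_sd`` SDs of the mean."""
    v = trait.to_numpy(dtype=float)
    mu, sd = np.nanmean(v), np.nanstd(v)
    if sd == 0:
        return pd.Series(False, index=trait.index)
    return pd.Series(np.abs(v - mu) > n_sd * sd, index=trait.index)


def preprocess(
    g: GenotypeMatrix,
    traits: pd.DataFrame | None = None,
    maf_min_accessions: int = 5,
    outlier_sd: float = 4.0,
    max_missing_frac: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame | None]:
    """MAF filter, heterozygote recoding, and per-trait outlier masking.

    SNPs with a minor-allele accession count below ``maf_min_accessions``
    (counted over binary calls) are dropped, as are SNPs missing in more
    than ``max_missing_frac`` of accessions and SNPs monomorphic after
    het recoding. Heterozygous calls are rescored to the SNP's major
    allele. Trait outliers (beyond ``outlier_sd`` SDs) are set to NaN so
    the affected accession is excluded from that trait's scan only.
    """
    calls = g.calls.copy()
    n_acc = calls.shape[0]
    # het -> major allele, per SNP
    is01 = (calls == 0) | (calls == 1)
    ones = np.where(is01 & (calls == 1), 1, 0).sum(axis=0)
    zeros = np.where(is01 & (calls == 0), 1, 0).sum(axis=0)
    major = (ones > zeros).astype(np.int8)
    het_mask = calls == HET
    calls[het_mask] = np.broadcast_to(major, calls.shape)[het_mask]

    g2 = GenotypeMatrix(g.accessions, g.snps, calls, g.n_skipped_records)
    mac = g2.minor_allele_counts()
    missing_frac = (calls == MISSING).sum(axis=0) / n_acc
    keep = (mac >= maf_min_accessions) & (missing_frac <= max_missing_frac) & (mac > 0)
    n_mono = int(((mac == 0)).sum())
    if n_mono:
        warnings.warn(f"{n_mono} SNP(s) monomorphic after het recoding removed")
    g2 = g2.subset_snps(keep)

    if traits is not None:
        traits = traits.copy().astype(float)
        for col in traits.columns:
            out = detect_trait_outliers(traits[col], n_sd=outlier_sd)
            traits.loc[out, col] = np.nan
    return g2, traits


def ibs_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: proportion of shared alleles per pair.

    k(i, j) = #SNPs with identical binary calls / #SNPs non-missing in
    both accessions (pairwise-complete).
    """
    calls = g.calls.astype(float)
    calls[~((g.calls == 0) | (g.calls == 1))] = np.nan
    valid = ~np.isnan(calls)
    x = np.nan_to_num(calls)
    n_both = valid.astype(float) @ valid.T.astype(float)
    if (n_both == 0).any():
        i, j = np.argwhere(n_both == 0)[0]
        raise ValueError(
            f"no overlapping SNPs for pair ({g.accessions[i]}, {g.accessions[j]})"
        )
    # disagreements over both-valid sites: x_i(1-x_j) + (1-x_i)x_j
    v = valid.astype(float)
    xv = x * v
    n_diff = xv @ (v - xv).T + (v - xv) @ xv.T
    k = 1.0 - n_diff / n_both
    k = (k + k.T) / 2
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(list(g.accessions), k)


def allele_difference_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS kinship, after excluding singleton SNPs (minor count 1)."""
    mac = g.minor_allele_counts()
    g2 = g.subset_snps(mac >= 2)
    k = ibs_kinship(g2)
    d = 1.0 - k.k
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(k.labels, d, kind="allele_difference")


def _bend_kinship(k: np.ndarray, floor: float = 1e-8):
    """Eigendecompose K, clipping negative eigenvalues at ``floor``."""
    vals, vecs = np.linalg.eigh((k + k.T) / 2)
    if vals.min() < -0.05:
        raise ValueError("kinship far from PSD; refusing to bend")
    return np.maximum(vals, floor), vecs


def mlm_null_fit(y: np.ndarray, kin: KinshipMatrix):
    """REML fit of y = mu + u + e with u ~ N(0, sg2 K), e ~ N(0, se2 I).

    Returns (sigma2_g, sigma2_e, rotation) where rotation is (eigvals U
    of K, eigvecs) reused by the P3D scan. The profile REML is 1-D over
    log(delta) with delta = se2/sg2: rotating by U' diagonalizes the
    covariance to sg2 * (lambda_i + delta).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values in null fit")
    if np.std(y) == 0:
        raise ValueError("constant trait: variance components unidentifiable")
    lam, u = _bend_kinship(kin.k)
    ystar = u.T @ y
    xstar = u.T @ np.ones_like(y)
    n = len(y)

    def criterion(logdelta: float) -> float:
        w = 1.0 / (lam + np.exp(logdelta))
        xwx = np.sum(xstar * xstar * w)
        xwy = np.sum(xstar * ystar * w)
        ypy = np.sum(ystar * ystar * w) - xwy * xwy / xwx
        ypy = max(ypy, 1e-300)
        return (
            -np.sum(np.log(w)) + np.log(xwx) + (n - 1) * np.log(ypy)
        )

    from scipy.optimize import minimize_scalar

    grid = np.linspace(-12.0, 12.0, 49)
    best = min(grid, key=criterion)
    lo, hi = max(best - 1.0, -12.0), min(best + 1.0, 12.0)
    res = minimize_scalar(criterion, bounds=(lo, hi), method="bounded")
    logdelta = float(res.x) if res.fun <= criterion(best) else float(best)
    delta = float(np.exp(logdelta))
    w = 1.0 / (lam + delta)
    xwx = np.sum(xstar * xstar * w)
    xwy = np.sum(xstar * ystar * w)
    ypy = float(np.sum(ystar * ystar * w) - xwy * xwy / xwx)
    sigma2_g = ypy / (n - 1)
    sigma2_e = delta * sigma2_g
    return sigma2_g, sigma2_e, (lam, u)


def mlm_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    kin: KinshipMatrix,
    trait_id: str = "",
) -> GwasResult:
    """P3D/EMMAX scan: per-SNP GLS with variance components from the null.

    Accessions with a missing (NaN) trait value are excluded; the null
    model is refit on the retained subset. Each SNP is tested by an F
    statistic with (1, n-2) reference degrees of freedom. SNPs constant
    on the retained accessions get p = 1.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    yk = y[keep]
    idx = np.flatnonzero(keep)
    kk = KinshipMatrix(
        [kin.labels[i] for i in idx], _resub(kin.k, idx)
    )
    sigma2_g, sigma2_e, (lam, u) = mlm_null_fit(yk, kk)
    delta = sigma2_e / sigma2_g
    w = 1.0 / (lam + delta)
    n = len(yk)

    ystar = u.T @ yk
    ones_star = u.T @ np.ones(n)
    snp_calls = g.calls[idx].astype(float)
    snp_calls[~((g.calls[idx] == 0) | (g.calls[idx] == 1))] = np.nan
    # missing genotype -> mean impute within retained set for the test
    col_mean = np.nanmean(snp_calls, axis=0)
    nanmask = np.isnan(snp_calls)
    snp_calls[nanmask] = np.broadcast_to(col_mean, snp_calls.shape)[nanmask]
    gstar = u.T @ snp_calls

    # weighted regression of ystar on [ones_star, gstar_j] per SNP
    a11 = np.sum(ones_star * ones_star * w)
    a1y = np.sum(ones_star * ystar * w)
    a1g = gstar.T @ (ones_star * w)  # (m,)
    agg = np.einsum("ij,ij->j", gstar, gstar * w[:, None])
    agy = gstar.T @ (ystar * w)
    det = a11 * agg - a1g**2
    const = det <= 1e-12 * np.maximum(a11 * agg, 1e-300)
    det_safe = np.where(const, 1.0, det)
    beta = (a11 * agy - a1g * a1y) / det_safe
    yy = np.sum(ystar * ystar * w)
    # RSS = y'Wy - [a1y, agy] @ beta_full where beta_full solves the 2x2 system
    beta0 = (agg * a1y - a1g * agy) / det_safe
    rss = yy - (beta0 * a1y + beta * agy)
    rss = np.maximum(rss, 1e-300)
    df = n - 2
    se = np.sqrt((a11 / det_safe) * rss / df)
    fstat = (beta / se) ** 2
    p = stats.f.sf(fstat, 1, df)
    p = np.where(const, 1.0, p)
    beta = np.where(const, 0.0, beta)
    se = np.where(const, np.nan, se)

    table = g.snps[["chrom", "pos"]].copy()
    table["effect"] = beta
    table["se"] = se
    table["p"] = p
    table["neglog10p"] = -np.log10(np.maximum(p, 1e-300))
    table["maf_count"] = g.minor_allele_counts()
    table["constant_flag"] = const
    return GwasResult(
        trait_id=trait_id, table=table, sigma2_g=sigma2_g, sigma2_e=sigma2_e,
        delta=delta, n_used=n,
    )


def _resub(k: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return k[np.ix_(idx, idx)]


def call_significant(res: GwasResult, threshold_neglog10p: float = 7.5) -> pd.DataFrame:
    """SNPs at or above the -log10(p) significance threshold."""
    t = res.table
    return t.loc[t["neglog10p"] >= threshold_neglog10p].copy()


def _read_genes_gff3(gff_path) -> pd.DataFrame:
    """Gene features from a GFF3 file via gffutils (in-memory sqlite)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            dict(
                gene_id=gene.id, chrom=str(gene.seqid), start=int(gene.start),
                end=int(gene.end), strand=gene.strand,
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def annotate_flanking(hits: pd.DataFrame, gff_path) -> list[AnnotationHit]:
    """Assign each significant SNP a gene, or its two nearest flanking genes.

    A SNP inside a gene interval ([start, end], 1-based inclusive) is
    genic; otherwise the nearest gene upstream and nearest downstream on
    the same chromosome are reported (one-sided at chromosome ends). SNPs
    on chromosomes absent from the GFF are returned unannotated, flagged.
    """
    genes = _read_genes_gff3(gff_path)
    out: list[AnnotationHit] = []
    for _, snp in hits.iterrows():
        chrom, pos = str(snp["chrom"]), int(snp["pos"])
        sub = genes.loc[genes["chrom"] == chrom]
        if sub.empty:
            out.append(AnnotationHit(chrom, pos, "unannotated", [], one_sided=True))
            continue
        inside = sub.loc[(sub["start"] <= pos) & (pos <= sub["end"])]
        if len(inside):
            out.append(
                AnnotationHit(chrom, pos, "genic", inside.to_dict("records"))
            )
            continue
        up = sub.loc[sub["end"] < pos]
        down = sub.loc[sub["start"] > pos]
        loci = []
        if len(up):
            loci.append(up.loc[up["end"].idxmax()].to_dict())
        if len(down):
            loci.append(down.loc[down["start"].idxmin()].to_dict())
        out.append(
            AnnotationHit(chrom, pos, "intergenic", loci, one_sided=len(loci) < 2)
        )
    return out
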