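"""Synthetic study-shaped data with known ground truth.

Generates every input the pipeline consumes, mimicking the study design:
105 inbred accessions in 4 admixed genetic clusters, 3-5 replicate
root-exudate samples each, untargeted LC-MS feature tables with controlled
per-feature broad-sense heritability, structured genotypes, and correlated
geographic/environmental/life-history covariates.

Model choices
-------------
* Genotypes: Balding-Nichols drift. Ancestral allele frequencies are
  uniform on (0.1, 0.9); cluster frequencies are Beta-distributed around
  them with differentiation F_st; accession membership proportions come
  from a Dirichlet concentrated on a "home" cluster (drawn with the
  study's uneven cluster sizes); inbred 0/1 calls are Bernoulli draws
  from the membership-weighted frequency.
* Features: per feature, accession effects ~ N(0, V_B) and replicate
  residuals ~ N(0, V_E) on a latent log scale with V_B + V_E = 1 and
  V_B = target H2. Optional spiked SNP effects are added to the accession
  effects, sized as a fraction of the accession-mean trait variance. The
  latent value is mapped to a positive peak area by exponentiation
  (log-normal areas, heavy-tailed like LC-MS data) and random detection
  dropout is applied.
* Covariates: cluster centroids on an Iberia-like lon/lat box; 7
  environmental and 7 life-history columns are linear in coordinates and
  memberships plus noise, with one designed highly correlated pair
  (|r| >= 0.7) to exercise the variable screen.

Every function takes a :class:`SimulationConfig`; one global seed drives
deterministic per-component substreams.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .gwas import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_feature_table",
    "simulate_covariates",
    "simulate_gene_models",
    "simulate_replicate_values",
    "write_vcf",
    "write_gff3",
]

NPC_PATHWAYS = [
    "Alkaloids",
    "Amino acids and Peptides",
    "Carbohydrates",
    "Fatty acids",
    "Shikimates and Phenylpropanoids",
    "Terpenoids",
    "Polyketides",
]


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the real design."""

    n_accessions: int = 105
    replicates: int = 4  # 3-5 per accession in the study
    n_features: int = 100  # per ionization mode
    h2: float | np.ndarray = 0.3  # scalar or per-feature true H2
    n_snps: int = 1000
    n_clusters: int = 4
    fst: float = 0.15
    admixture_home: float = 6.0  # Dirichlet weight of the home cluster
    admixture_other: float = 0.8  # Dirichlet weight of the others
    cluster_weights: tuple = (75, 10, 13, 7)  # study cluster sizes
    spiked: tuple = ()  # (snp_index, feature_index, variance_fraction)
    dropout: float = 0.02  # per-entry (replicate-level) detection failure
    presence_beta: tuple | None = (0.35, 0.35)  # accession-presence Beta; None = ubiquitous
    noise_frac: float = 0.30  # fraction of sporadic one-off noise features
    log_area_scale: float = 0.3  # latent-to-log-area scale (keeps exp near-linear)
    seed: int = 0

    def h2_vector(self) -> np.ndarray:
        h = np.broadcast_to(np.asarray(self.h2, dtype=float), (self.n_features,))
        if (h < 0).any() or (h > 1).any():
            raise ValueError("true H2 must lie in [0, 1]")
        return h.copy()


def _component_rng(cfg: SimulationConfig, name: str) -> np.random.Generator:
    salt = {"genotypes": 1, "features": 2, "covariates": 3, "genes": 4}[name]
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Structured inbred genotypes plus the membership table.

    Returns (GenotypeMatrix, membership DataFrame accession x cluster).
    """
    rng = _component_rng(cfg, "genotypes")
    if not (0.0 <= cfg.fst < 1.0):
        raise ValueError("F_st must lie in [0, 1)")
    n, k, m = cfg.n_accessions, cfg.n_clusters, cfg.n_snps
    acc = [f"acc{i + 1:03d}" for i in range(n)]
    anc = rng.uniform(0.1, 0.9, size=m)
    if cfg.fst > 0:
        a = anc * (1 - cfg.fst) / cfg.fst
        b = (1 - anc) * (1 - cfg.fst) / cfg.fst
        freqs = rng.beta(a, b, size=(k, m))
    else:
        freqs = np.tile(anc, (k, 1))

    w = np.asarray(cfg.cluster_weights, dtype=float)[:k]
    home = rng.choice(k, size=n, p=w / w.sum())
    alpha = np.full((n, k), cfg.admixture_other)
    alpha[np.arange(n), home] = cfg.admixture_home
    membership = np.vstack([rng.dirichlet(a_) for a_ in alpha])
    acc_freq = membership @ freqs
    calls = (rng.random((n, m)) < acc_freq).astype(np.int8)

    chroms = np.repeat([str(c + 1) for c in range(5)], int(np.ceil(m / 5)))[:m]
    pos = np.concatenate(
        [
            np.sort(
                rng.choice(np.arange(1, 30_000_000), size=(chroms == c).sum(), replace=False)
            )
            for c in [str(c + 1) for c in range(5)]
        ]
    )
    snps = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "T"})
    g = GenotypeMatrix(acc, snps, calls)
    mem = pd.DataFrame(
        membership, index=acc, columns=[f"C{j + 1}" for j in range(k)]
    )
    mem.index.name = "accession_id"
    return g, mem


def simulate_replicate_values(
    cfg: SimulationConfig, genotypes: GenotypeMatrix | None = None
):
    """Latent replicate-level values per feature, before the area mapping.

    Returns (values array (n_samples, n_features), accession labels,
    truth DataFrame with true_h2 and any spiked-SNP betas).
    """
    rng = _component_rng(cfg, "features")
    n, r, f = cfg.n_accessions, cfg.replicates, cfg.n_features
    h2 = cfg.h2_vector()
    v_b, v_e = h2, 1.0 - h2
    acc_eff = rng.normal(0.0, 1.0, size=(n, f)) * np.sqrt(v_b)
    spiked_beta = np.zeros(f)
    for snp_i, feat_i, frac in cfg.spiked:
        if not (0 <= feat_i < f):
            raise ValueError(f"spiked feature index {feat_i} out of range")
        if genotypes is None:
            raise ValueError("spiked effects require genotypes")
        gvec = genotypes.calls[:, snp_i].astype(float)
        vg = gvec.var()
        if vg == 0:
            raise ValueError(f"spiked SNP {snp_i} is monomorphic")
        # fraction of the accession-mean trait variance explained
        base = v_b[feat_i] + v_e[feat_i] / r
        beta = np.sqrt(frac / (1.0 - frac) * base / vg)
        acc_eff[:, feat_i] += beta * (gvec - gvec.mean())
        spiked_beta[feat_i] = beta
    resid = rng.normal(0.0, 1.0, size=(n * r, f)) * np.sqrt(v_e)
    values = np.repeat(acc_eff, r, axis=0) + resid
    labels = np.repeat([f"acc{i + 1:03d}" for i in range(n)], r)
    truth = pd.DataFrame(
        {
            "feature_id": [f"F{j + 1:04d}" for j in range(f)],
            "true_h2": h2,
            "spiked_beta": spiked_beta,
        }
    ).set_index("feature_id")
    return values, labels, truth


def simulate_feature_table(
    cfg: SimulationConfig, genotypes: GenotypeMatrix | None = None,
    mode: str = "negative",
) -> tuple[FeatureTable, pd.DataFrame]:
    """Replicate-structured LC-MS peak-area table with known heritability.

    Latent values are exponentiated into log-normal peak areas around a
    per-feature baseline. Three kinds of missingness emulate real tables:
    accession-level structural absence (per-feature presence probability
    drawn from ``presence_beta``, driving the prevalence filter), a
    ``noise_frac`` fraction of sporadic one-off noise features (detected
    in scattered single replicates, driving the replicate filter), and
    replicate-level random ``dropout``. Returns (FeatureTable,
    ground-truth sidecar DataFrame).
    """
    values, labels, truth = simulate_replicate_values(cfg, genotypes)
    f, n, r = cfg.n_features, cfg.n_accessions, cfg.replicates
    base_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20]))
    mu = base_rng.normal(np.log(1e5), 0.5, size=f)
    areas = np.exp(mu + cfg.log_area_scale * values)

    kind = np.full(f, "signal", dtype=object)
    presence_q = np.ones(f)
    if cfg.presence_beta is not None:
        presence_q = base_rng.beta(*cfg.presence_beta, size=f)
        acc_present = base_rng.random((n, f)) < presence_q
        areas *= np.repeat(acc_present, r, axis=0)
    n_noise = int(round(cfg.noise_frac * f))
    if n_noise:
        noise_idx = base_rng.choice(f, size=n_noise, replace=False)
        kind[noise_idx] = "noise"
        # sporadic single-replicate blips, too rare for >= 2-replicate support
        sporadic = base_rng.random((n * r, n_noise)) < 0.04
        areas[:, noise_idx] = np.where(
            sporadic, np.exp(mu[noise_idx] + base_rng.normal(0, 0.3, (n * r, n_noise))), 0.0
        )
    if cfg.dropout > 0:
        drop = base_rng.random(areas.shape) < cfg.dropout
        areas = np.where(drop, 0.0, areas)
    truth = truth.assign(kind=kind, presence_q=presence_q)
    n, r = cfg.n_accessions, cfg.replicates
    sample_ids = [
        f"acc{i + 1:03d}_r{j + 1}" for i in range(n) for j in range(r)
    ]
    feature_ids = list(truth.index)
    peak = pd.DataFrame(areas, index=sample_ids, columns=feature_ids)
    sample_meta = pd.DataFrame(
        {
            "accession_id": labels,
            "replicate": [j + 1 for _ in range(n) for j in range(r)],
            "mode": mode,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    pathway_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 21]))
    feature_meta = pd.DataFrame(
        {
            "mode": mode,
            "npc_pathway": pathway_rng.choice(NPC_PATHWAYS, size=f),
            "class_probability": pathway_rng.uniform(0.3, 1.0, size=f),
            "tanimoto": pathway_rng.uniform(0.1, 0.9, size=f),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    # a small unassigned fraction, as in real CANOPUS output
    unassigned = pathway_rng.random(f) < 0.04
    feature_meta.loc[unassigned, "npc_pathway"] = np.nan
    table = FeatureTable(peak_area=peak, sample_meta=sample_meta, feature_meta=feature_meta)
    truth = truth.assign(seed=cfg.seed, fst=cfg.fst)
    return table, truth


def simulate_covariates(
    cfg: SimulationConfig, membership: pd.DataFrame
) -> pd.DataFrame:
    """Dataset S1-shaped accession metadata table.

    Columns: longitude, latitude, altitude, cluster memberships, 7
    environmental variables, 7 life-history traits. Environmental and
    life-history columns are linear in coordinates/memberships plus
    noise; ``annual_mean_temperature`` and ``temperature_seasonality``
    are built as a highly correlated pair (|r| >= 0.7) so the
    uncorrelated-variable screen always has something to drop.
    """
    rng = _component_rng(cfg, "covariates")
    k = membership.shape[1]
    # Iberia-like centroid box: lon in [-9, 3], lat in [36, 43]
    centroids = np.column_stack(
        [rng.uniform(-9, 3, size=k), rng.uniform(36, 43, size=k)]
    )
    coords = membership.to_numpy() @ centroids
    coords = coords + rng.normal(0, 0.4, size=coords.shape)
    lon, lat = coords[:, 0], coords[:, 1]
    m = membership.to_numpy()
    noise = lambda s: rng.normal(0, s, size=len(lon))  # noqa: E731

    temp = 28 - 0.45 * lat + 0.1 * lon + noise(0.4)
    env = pd.DataFrame(
        {
            "annual_mean_temperature": temp,
            "isothermality": 40 + 0.8 * lon + 2.0 * m[:, 0] + noise(1.0),
            # designed twin of temperature: |r| >= 0.7 by construction
            "temperature_seasonality": 2.0 * temp + 5 + noise(0.25),
            "annual_precipitation": 1500 - 25 * temp + 40 * m[:, min(2, k - 1)] + noise(40),
            "precipitation_seasonality": 30 + 1.5 * lat - 2.0 * m[:, min(1, k - 1)] + noise(2),
            "humanized_habitat": np.clip(0.3 + 0.02 * lon + 0.1 * m[:, 0] + noise(0.1), 0, 1),
            "topsoil_ph": 6.5 + 0.08 * lon + 0.5 * m[:, min(3, k - 1)] + noise(0.3),
        },
        index=membership.index,
    )
    life = pd.DataFrame(
        {
            "seed_weight": 20 + 1.5 * m[:, 0] - 0.2 * lat + noise(0.6),
            "dsds50": 30 + 8 * m[:, min(2, k - 1)] + 0.5 * lon + noise(3),
            "germination": np.clip(0.8 - 0.05 * m[:, min(1, k - 1)] + noise(0.06), 0, 1),
            "recruitment": np.clip(0.5 + 0.1 * m[:, 0] + noise(0.08), 0, 1),
            "survival": np.clip(0.6 + 0.02 * lat - 1.0 + noise(0.07), 0, 1),
            "flowering_time": 60 - 1.2 * temp + 5 * m[:, min(2, k - 1)] + noise(2.5),
            "fecundity": 300 + 20 * m[:, 0] - 4 * np.abs(lon) + noise(15),
        },
        index=membership.index,
    )
    meta = pd.concat(
        [
            pd.DataFrame(
                {
                    "longitude": lon,
                    "latitude": lat,
                    "altitude": np.abs(rng.normal(600, 300, size=len(lon))),
                },
                index=membership.index,
            ),
            membership,
            env,
            life,
        ],
        axis=1,
    )
    meta.index.name = "accession_id"
    return meta


def simulate_gene_models(
    cfg: SimulationConfig, genes_per_chrom: int = 40, gene_len: int = 3000,
    spacing: int = 8000,
) -> pd.DataFrame:
    """Regularly spaced gene models on the 5 simulated chromosomes."""
    rows = []
    for c in range(5):
        chrom = str(c + 1)
        start = 1000
        for i in range(genes_per_chrom):
            rows.append(
                dict(
                    gene_id=f"AT{chrom}G{(i + 1) * 100:05d}", chrom=chrom,
                    start=start, end=start + gene_len - 1,
                    strand="+" if i % 2 == 0 else "-",
                )
            )
            start += gene_len + spacing
    return pd.DataFrame(rows)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write inbred 0/1 calls as a minimal plain-text VCF."""
    code = {0: "0/0", 1: "1/1", 2: "0/1", -9: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accessions) + "\n"
        )
        ref = g.snps["ref"] if "ref" in g.snps else pd.Series("A", index=g.snps.index)
        alt = g.snps["alt"] if "alt" in g.snps else pd.Series("T", index=g.snps.index)
        for j, (_, snp) in enumerate(g.snps.iterrows()):
            gts = "\t".join(code[int(v)] for v in g.calls[:, j])
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t.\t{ref.iloc[j]}\t{alt.iloc[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (1-based inclusive intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\texuvar\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def write_feature_table_tsv(t: FeatureTable, path, annotation_path=None) -> None:
    """Write the sample-rows TSV dialect read by ``read_feature_table``."""
    out = pd.concat([t.sample_meta, t.peak_area], axis=1)
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, sep="\t", index=False)
    if annotation_path is not None:
        t.feature_meta.reset_index().rename(
            columns={"index": "feature_id"}
        ).to_csv(annotation_path, sep="\t", index=False)


def write_truth_sidecar(truth: pd.DataFrame, path) -> None:
    truth.reset_index().to_csv(path, sep="\t", index=False)


def write_manifest(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)
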