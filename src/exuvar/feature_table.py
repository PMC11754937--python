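"""LC-MS feature-table ingestion, normalization, and QC filtering.

The raw input is a samples x features table of absolute peak areas from an
untargeted LC-MS run, with each sample belonging to one accession (inbred
line) and one ionization mode. Downstream analyses work on *relative*
abundances: each feature's area divided by the total area of its sample
within the same ionization mode, so every sample contributes a composition
summing to one. Two QC filters follow:

1. a replicate-support filter that drops features never detected in at
   least two replicates of any single accession (an irreproducibility
   screen), and
2. a prevalence filter that drops features detected in fewer than 10% or
   more than 90% of accessions (too rare to analyse, or ubiquitous and
   uninformative).

Negative and positive ionization modes are filtered independently; feature
ids are unique within a mode.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "AbundanceTable",
    "FilterReport",
    "read_feature_table",
    "read_feature_annotations",
    "to_relative_abundance",
    "filter_single_replicate",
    "filter_prevalence",
    "accession_means",
    "filter_pipeline",
]

SAMPLE_META_COLS = ("sample_id", "accession_id", "replicate", "mode")
VALID_MODES = ("negative", "positive")


@dataclasses.dataclass
class FeatureTable:
    """Samples x features peak areas plus sample and feature metadata.

    ``peak_area`` is a DataFrame indexed by sample_id with feature ids as
    columns; zero means "not detected". ``sample_meta`` is indexed by
    sample_id with columns accession_id, replicate, mode. ``feature_meta``
    is indexed by feature_id and may carry mode, molecular_mass,
    npc_pathway/superclass/class, class_probability, tanimoto.
    """

    peak_area: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.peak_area.index.duplicated().any():
            dups = self.peak_area.index[self.peak_area.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        neg = self.peak_area.lt(0)
        if neg.any().any():
            col = neg.any(axis=0).idxmax()
            row = neg[col].idxmax()
            raise ValueError(
                f"negative peak area at sample {row!r}, feature {col!r}"
            )
        missing = set(self.peak_area.index) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_modes = set(self.sample_meta["mode"]) - set(VALID_MODES)
        if bad_modes:
            raise ValueError(f"unknown ionization modes: {sorted(bad_modes)}")
        # replicate index unique within accession x mode
        dup = self.sample_meta.duplicated(
            subset=["accession_id", "replicate", "mode"], keep=False
        )
        if dup.any():
            raise ValueError(
                "replicate index not unique within accession x mode: "
                f"{sorted(self.sample_meta.index[dup])}"
            )

    @property
    def modes(self) -> list[str]:
        return sorted(self.sample_meta["mode"].unique())

    def feature_mode(self) -> pd.Series:
        """Mode of each feature, from feature_meta or inferred (single-mode)."""
        if "mode" in self.feature_meta.columns:
            return self.feature_meta["mode"].reindex(self.peak_area.columns)
        if len(self.modes) > 1:
            raise ValueError(
                "multi-mode table requires a 'mode' column in feature_meta"
            )
        return pd.Series(self.modes[0], index=self.peak_area.columns)


@dataclasses.dataclass
class AbundanceTable:
    """Relative abundances (unit-sum per sample within mode) + pseudocount.

    ``rel_abundance`` already includes the pseudocount; ``detected`` records
    the pre-pseudocount detection mask (raw area > 0), which the filters
    and prevalence computations use.
    """

    rel_abundance: pd.DataFrame
    detected: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    pseudocount: float = 1e-10

    @property
    def accessions(self) -> list[str]:
        return sorted(self.sample_meta["accession_id"].unique())

    def subset_features(self, keep: Sequence[str]) -> "AbundanceTable":
        keep = list(keep)
        return AbundanceTable(
            rel_abundance=self.rel_abundance[keep],
            detected=self.detected[keep],
            sample_meta=self.sample_meta,
            feature_meta=self.feature_meta.reindex(keep),
            pseudocount=self.pseudocount,
        )


@dataclasses.dataclass
class FilterReport:
    """Per-mode accounting of the two QC filters.

    Invariant: n_input = n_removed_single_replicate + n_removed_prevalence
    + n_retained, per mode.
    """

    per_mode: pd.DataFrame  # index mode; columns n_input, n_removed_*, n_retained
    removal_reason: pd.Series  # feature_id -> {single_replicate, prevalence, retained}

    def __post_init__(self) -> None:
        pm = self.per_mode
        total = (
            pm["n_removed_single_replicate"]
            + pm["n_removed_prevalence"]
            + pm["n_retained"]
        )
        if not (total == pm["n_input"]).all():
            raise AssertionError("filter accounting does not conserve features")

    def summary_lines(self) -> list[str]:
        lines = []
        for mode, row in self.per_mode.iterrows():
            n = row["n_input"]
            lines.append(
                f"[{mode}] input {n} features: "
                f"{row['n_removed_single_replicate']} "
                f"({100 * row['n_removed_single_replicate'] / max(n, 1):.0f}%) removed by replicate filter, "
                f"{row['n_removed_prevalence']} "
                f"({100 * row['n_removed_prevalence'] / max(n, 1):.0f}%) removed by prevalence filter, "
                f"{row['n_retained']} retained"
            )
        return lines


def read_feature_table(
    path, fmt: str | None = None, annotation_path=None
) -> FeatureTable:
    """Read a TSV/CSV feature table.

    Layout: one row per sample; metadata columns ``sample_id, accession_id,
    replicate, mode``; every remaining column is a feature. Blank cells are
    read as 0 (not detected). An optional annotation sidecar TSV keyed by
    ``feature_id`` supplies feature metadata.
    """
    if fmt is None:
        fmt = "csv" if str(path).endswith(".csv") else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "accession_id": str})
    missing = [c for c in SAMPLE_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required metadata columns: {missing}")
    df = df.set_index("sample_id")
    sample_meta = df[["accession_id", "replicate", "mode"]].copy()
    areas = df.drop(columns=["accession_id", "replicate", "mode"])
    areas = areas.apply(pd.to_numeric).fillna(0.0).astype(float)
    if annotation_path is not None:
        feature_meta = read_feature_annotations(annotation_path)
        feature_meta = feature_meta.reindex(areas.columns)
    else:
        feature_meta = pd.DataFrame(index=areas.columns.copy())
        feature_meta.index.name = "feature_id"
    return FeatureTable(peak_area=areas, sample_meta=sample_meta, feature_meta=feature_meta)


def read_feature_annotations(path) -> pd.DataFrame:
    """Read the feature annotation sidecar (TSV keyed by feature_id)."""
    meta = pd.read_csv(path, sep="\t").set_index("feature_id")
    return meta


def to_relative_abundance(t: FeatureTable, pseudocount: float = 1e-10) -> AbundanceTable:
    """Convert absolute areas to relative abundances within sample x mode.

    Each value becomes area / (total area of that sample over the features
    of the sample's ionization mode); a small pseudocount (default 1e-10)
    is then added to every entry so no value is exactly zero.
    """
    fmode = t.feature_mode()
    # entries of a sample outside a feature's mode are undefined, not zero
    rel = pd.DataFrame(
        np.nan, index=t.peak_area.index, columns=t.peak_area.columns, dtype=float
    )
    for mode in t.modes:
        feats = fmode.index[fmode == mode]
        samples = t.sample_meta.index[t.sample_meta["mode"] == mode]
        block = t.peak_area.loc[samples, feats]
        totals = block.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(
                f"sample(s) with no detected feature in mode {mode}: "
                f"{sorted(zero.index)}"
            )
        rel.loc[samples, feats] = block.div(totals, axis=0)
    detected = t.peak_area.gt(0)
    return AbundanceTable(
        rel_abundance=rel + pseudocount,
        detected=detected,
        sample_meta=t.sample_meta,
        feature_meta=t.feature_meta,
        pseudocount=pseudocount,
    )


def _detections_by_accession(a: AbundanceTable) -> pd.DataFrame:
    """Accession x feature counts of replicates with a detection."""
    return a.detected.groupby(a.sample_meta["accession_id"]).sum()


def filter_single_replicate(
    a: AbundanceTable, rule: str = "per_accession"
) -> tuple[AbundanceTable, list[str]]:
    """Drop features without reproducible within-accession support.

    ``rule='per_accession'`` (default): a feature is removed iff *no*
    accession has it detected in >= 2 of its replicates — detections seen
    only once per accession are treated as irreproducible noise.
    ``rule='overall'``: removed iff detected in exactly one replicate
    across the whole table.
    """
    counts = _detections_by_accession(a)
    if rule == "per_accession":
        supported = (counts >= 2).any(axis=0)
        removed = [f for f in a.rel_abundance.columns if not supported.get(f, False)]
    elif rule == "overall":
        total = a.detected.sum(axis=0)
        removed = [f for f in a.rel_abundance.columns if total[f] <= 1]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    keep = [f for f in a.rel_abundance.columns if f not in set(removed)]
    return a.subset_features(keep), removed


def filter_prevalence(
    a: AbundanceTable, lo: float = 0.10, hi: float = 0.90
) -> tuple[AbundanceTable, list[str]]:
    """Drop features detected in < lo or > hi of accessions (strict).

    Presence in an accession = detected (raw area > 0) in at least one of
    its replicates; the denominator is the number of accessions.
    """
    if lo >= hi:
        raise ValueError(f"prevalence bounds must satisfy lo < hi, got {lo} >= {hi}")
    counts = _detections_by_accession(a)
    n_acc = counts.shape[0]
    if n_acc < 2:
        raise ValueError("prevalence filter needs >= 2 accessions")
    frac = (counts > 0).sum(axis=0) / n_acc
    removed = [
        f for f in a.rel_abundance.columns if frac[f] < lo or frac[f] > hi
    ]
    keep = [f for f in a.rel_abundance.columns if f not in set(removed)]
    return a.subset_features(keep), removed


def filter_pipeline(
    t: FeatureTable,
    pseudocount: float = 1e-10,
    lo: float = 0.10,
    hi: float = 0.90,
    replicate_rule: str = "per_accession",
) -> tuple[AbundanceTable, FilterReport]:
    """Normalize then filter, per ionization mode, with full accounting.

    Modes are processed independently (replicate filter, then prevalence
    filter) and the surviving features concatenated.
    """
    a = to_relative_abundance(t, pseudocount=pseudocount)
    fmode = t.feature_mode()
    reasons: dict[str, str] = {}
    rows = {}
    kept_frames: list[AbundanceTable] = []
    for mode in t.modes:
        feats = list(fmode.index[fmode == mode])
        samples = t.sample_meta.index[t.sample_meta["mode"] == mode]
        sub = AbundanceTable(
            rel_abundance=a.rel_abundance.loc[samples, feats],
            detected=a.detected.loc[samples, feats],
            sample_meta=a.sample_meta.loc[samples],
            feature_meta=a.feature_meta.reindex(feats),
            pseudocount=pseudocount,
        )
        sub1, rm_single = filter_single_replicate(sub, rule=replicate_rule)
        sub2, rm_prev = filter_prevalence(sub1, lo=lo, hi=hi)
        for f in rm_single:
            reasons[f] = "single_replicate"
        for f in rm_prev:
            reasons[f] = "prevalence"
        for f in sub2.rel_abundance.columns:
            reasons[f] = "retained"
        rows[mode] = {
            "n_input": len(feats),
            "n_removed_single_replicate": len(rm_single),
            "n_removed_prevalence": len(rm_prev),
            "n_retained": sub2.rel_abundance.shape[1],
        }
        kept_frames.append(sub2)
    report = FilterReport(
        per_mode=pd.DataFrame.from_dict(rows, orient="index"),
        removal_reason=pd.Series(reasons, name="reason"),
    )
    keep_ids = [f for sub in kept_frames for f in sub.rel_abundance.columns]
    filtered = AbundanceTable(
        rel_abundance=pd.concat(
            [s.rel_abundance for s in kept_frames], axis=1
        ).reindex(index=a.rel_abundance.index)[keep_ids],
        detected=pd.concat([s.detected for s in kept_frames], axis=1).reindex(
            index=a.detected.index
        )[keep_ids],
        sample_meta=a.sample_meta,
        feature_meta=a.feature_meta.reindex(keep_ids),
        pseudocount=pseudocount,
    )
    return filtered, report


def accession_means(a: AbundanceTable) -> pd.DataFrame:
    """Accession x feature arithmetic means over replicates.

    These per-accession trait means are the phenotypes used by the
    distance and GWAS stages.
    """
    means = a.rel_abundance.groupby(a.sample_meta["accession_id"]).mean()
    # NaN arises for a feature whose mode has no samples of an accession
    return means
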