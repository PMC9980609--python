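"""Sorted-fraction feature tables: contamination removal and rarefaction.

A FACS-Seq experiment sequences six kinds of samples: the unsorted initial
community, the sorted initial community, the whole incubated community, the
EdU-positive and EdU-negative sorted cells, and the sorter's sheath fluid.
Sequences present in the sorted communities *and* in the sheath fluid but
absent from the unsorted initial community can only have entered during
sorting, and are removed as contamination. Retention accounting tracks the
fraction of each sample's reads kept. Samples are then rarefied (subsampled
without replacement) to a common depth for diversity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FRACTIONS",
    "SORTED_FRACTIONS",
    "FeatureTable",
    "FilterReport",
    "flag_contaminants",
    "apply_filter",
    "rarefy",
]

FRACTIONS = ("initial_unsorted", "initial_sorted", "whole", "edu_pos", "edu_neg", "sheath")
#: Fractions that passed through the cell sorter (used by the contamination rule).
SORTED_FRACTIONS = ("initial_sorted", "whole", "edu_pos", "edu_neg")

META_COLUMNS = ("fraction", "experiment", "treatment", "replicate")


@dataclass
class FeatureTable:
    """Sample x feature count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, samples as rows (index = sample ids),
        features as columns.
    meta : pandas.DataFrame
        Indexed like ``counts``; columns ``fraction`` (one of `FRACTIONS`),
        ``experiment``, ``treatment``, ``replicate``. At most one sheath
        sample per experiment.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same sample index")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        bad = set(self.meta["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")
        sheath = self.meta[self.meta["fraction"] == "sheath"]
        dup = sheath["experiment"].value_counts()
        if (dup > 1).any():
            raise ValueError(
                f"more than one sheath sample in experiment(s): "
                f"{sorted(dup[dup > 1].index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, experiment: str, fraction: str | tuple[str, ...]) -> pd.DataFrame:
        fr = (fraction,) if isinstance(fraction, str) else fraction
        mask = (self.meta["experiment"] == experiment) & self.meta["fraction"].isin(fr)
        return self.counts.loc[mask[mask].index]

    def subset(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[sample_ids].copy(), self.meta.loc[sample_ids].copy())


@dataclass
class FilterReport:
    """Read-retention accounting for a contamination-filtering pass."""

    flagged_features: set[str]
    reads_removed_per_sample: pd.Series
    retained_fraction_per_sample: pd.Series
    mean_retained: float = field(init=False)
    sd_retained: float = field(init=False)

    def __post_init__(self) -> None:
        r = self.retained_fraction_per_sample
        self.mean_retained = float(r.mean())
        self.sd_retained = float(r.std(ddof=1)) if len(r) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reads_removed": self.reads_removed_per_sample,
                "retained_fraction": self.retained_fraction_per_sample,
            }
        )


def flag_contaminants(tbl: FeatureTable, min_count: int = 1) -> set[str]:
    """Features present in sheath fluid and >=1 sorted sample but absent from
    every unsorted initial sample, evaluated per experiment.

    "Present" means count >= ``min_count``. A feature flagged in any
    experiment is returned; the rule requires each experiment to carry both a
    sheath and an initial_unsorted sample.
    """
    flagged: set[str] = set()
    for exp in sorted(set(tbl.meta["experiment"])):
        sheath = tbl.samples_in(exp, "sheath")
        initial = tbl.samples_in(exp, "initial_unsorted")
        if sheath.empty:
            raise ValueError(f"experiment {exp!r} has no sheath sample")
        if initial.empty:
            raise ValueError(f"experiment {exp!r} has no initial_unsorted sample")
        sorted_ = tbl.samples_in(exp, SORTED_FRACTIONS)
        in_sheath = (sheath >= min_count).any(axis=0)
        in_sorted = (sorted_ >= min_count).any(axis=0) if not sorted_.empty else pd.Series(False, index=tbl.counts.columns)
        in_initial = (initial >= min_count).any(axis=0)
        hits = in_sheath & in_sorted & ~in_initial
        flagged.update(hits[hits].index)
    return flagged


def apply_filter(tbl: FeatureTable, flagged: set[str]) -> tuple[FeatureTable, FilterReport]:
    """Drop flagged feature columns; report per-sample read retention."""
    unknown = flagged - set(tbl.feature_ids)
    if unknown:
        raise ValueError(f"flagged ids not in table: {sorted(unknown)}")
    keep = [f for f in tbl.feature_ids if f not in flagged]
    totals = tbl.counts.sum(axis=1)
    removed = tbl.counts[[f for f in tbl.feature_ids if f in flagged]].sum(axis=1)
    retained = (totals - removed) / totals.where(totals > 0, other=np.nan)
    retained = retained.fillna(1.0)  # empty samples retain everything vacuously
    out = FeatureTable(tbl.counts[keep].copy(), tbl.meta.copy())
    report = FilterReport(
        flagged_features=set(flagged),
        reads_removed_per_sample=removed,
        retained_fraction_per_sample=retained,
    )
    return out, report


def rarefy(tbl: FeatureTable, depth: int, seed: int) -> tuple[FeatureTable, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped and returned in the
    second element. Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    dropped: list[str] = []
    for sid in tbl.sample_ids:
        row = tbl.counts.loc[sid].to_numpy(np.int64)
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        kept_rows[sid] = rng.multivariate_hypergeometric(row, depth)
    if not kept_rows:
        raise ValueError(f"all samples are below the rarefaction depth {depth}")
    counts = pd.DataFrame.from_dict(kept_rows, orient="index", columns=tbl.counts.columns)
    counts = counts.loc[[s for s in tbl.sample_ids if s in kept_rows]]
    return FeatureTable(counts, tbl.meta.loc[counts.index].copy()), dropped
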