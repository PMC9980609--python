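"""File dialects: event CSV, OD CSV, feature-table TSV + metadata TSV,
newick trees and KO-pair TSV.

Event CSV header: ``sample_id,edu_present,replicate,fitc,apc,fsc,ssc``.
OD CSV header: ``sample_id,replicate,time_h,od600``.
Feature tables are TSV with samples as rows and features as columns, paired
with a metadata TSV ``sample_id,fraction,experiment,treatment,replicate``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .filtering import FeatureTable
from .gating import EVENT_COLUMNS, FlowEventTable
from .growth import GrowthCurve

__all__ = [
    "read_event_tables",
    "write_event_tables",
    "read_growth_curves",
    "write_growth_curves",
    "read_feature_table",
    "write_feature_table",
    "read_tree",
    "write_distance_matrix",
]


def read_event_tables(path) -> list[FlowEventTable]:
    """Read an event CSV into one FlowEventTable per (sample_id, replicate)."""
    df = pd.read_csv(path)
    required = ["sample_id", "edu_present", "replicate"] + list(EVENT_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV missing columns: {missing}")
    tables = []
    for (sid, edu, rep), sub in df.groupby(
        ["sample_id", "edu_present", "replicate"], sort=True
    ):
        tables.append(
            FlowEventTable(
                sub[list(EVENT_COLUMNS)].reset_index(drop=True),
                sample_id=str(sid),
                edu_present=bool(edu),
                replicate=str(rep),
            )
        )
    return tables


def write_event_tables(tables, path) -> None:
    frames = []
    for t in tables:
        df = t.events[list(EVENT_COLUMNS)].copy()
        df.insert(0, "replicate", t.replicate)
        df.insert(0, "edu_present", t.edu_present)
        df.insert(0, "sample_id", t.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_growth_curves(path) -> dict:
    """OD CSV -> {(sample_id, replicate): GrowthCurve}."""
    df = pd.read_csv(path)
    required = ["sample_id", "replicate", "time_h", "od600"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"OD CSV missing columns: {missing}")
    out = {}
    for (sid, rep), sub in df.groupby(["sample_id", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        out[(str(sid), str(rep))] = GrowthCurve(
            times=sub["time_h"].to_numpy(float), od=sub["od600"].to_numpy(float)
        )
    return out


def write_growth_curves(curves: dict, path) -> None:
    frames = []
    for (sid, rep), curve in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "replicate": rep,
                    "time_h": curve.times,
                    "od600": curve.od,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_feature_table(counts_path, meta_path) -> FeatureTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
    missing = set(counts.index) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    return FeatureTable(counts.astype(np.int64), meta.loc[counts.index])


def write_feature_table(tbl: FeatureTable, counts_path, meta_path) -> None:
    tbl.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    tbl.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    # convert_underscores=False: feature ids legitimately contain underscores
    return TreeNode.read(str(Path(path)), convert_underscores=False)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )
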