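"""Cross-study consensus: directionality consistency check, ratio
averaging, and multi-source overlap selection.

Merging is always within one patient group (naive or ERT); the two
groups are never merged with each other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fabrymeta.errors import ConfigError
from fabrymeta.harmonize import direction_of

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = ("cluster_id", "group", "mean_ratio", "direction",
                     "n_studies", "fluids", "tag")
REMOVED_COLUMNS = ("cluster_id", "group", "n_up", "n_down", "studies")


def consistency_merge(
    features: pd.DataFrame,
    group: str,
    studies: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge thresholded per-study features of one group into consensus
    features, removing clusters reported with contradictory regulation.

    A cluster whose supporting studies all agree in direction yields one
    consensus feature whose mean_ratio is the arithmetic mean of the
    supporting ratios; a cluster observed with both directions is
    excluded and reported in the removed table. Consensus clusters and
    removed clusters partition the distinct input clusters.

    Outputs are sorted by cluster_id so repeated runs are byte-identical.
    """
    if group not in ("naive", "ERT"):
        raise ConfigError(f"group must be 'naive' or 'ERT', got {group!r}")
    meta = studies.set_index("study_id")
    in_group = features["study_id"].map(meta["group"]) == group
    feats = features[in_group]

    consensus_rows, removed_rows = [], []
    for cluster_id, grp in feats.groupby("cluster_id", sort=True):
        dirs = grp["direction"].to_numpy()
        if len(set(dirs)) > 1:
            removed_rows.append((
                cluster_id, group,
                int((dirs == "up").sum()), int((dirs == "down").sum()),
                ",".join(sorted(grp["study_id"]))))
            continue
        mean_ratio = float(np.mean(grp["ratio"].to_numpy(dtype=float)))
        fluids = sorted(set(grp["study_id"].map(meta["fluid"])))
        consensus_rows.append((
            cluster_id, group, mean_ratio, direction_of(mean_ratio),
            len(grp), ",".join(fluids), grp["tag"].iloc[0]))
    consensus = pd.DataFrame(consensus_rows, columns=list(CONSENSUS_COLUMNS))
    removed = pd.DataFrame(removed_rows, columns=list(REMOVED_COLUMNS))
    logger.info("consistency merge (%s): %d consensus features, %d "
                "contradictory clusters removed", group,
                len(consensus), len(removed))
    return consensus, removed


def find_overlaps(
    features: pd.DataFrame,
    studies: pd.DataFrame,
    min_sources: int = 2,
    granularity: str = "fluid",
) -> pd.DataFrame:
    """Select clusters whose evidence spans at least ``min_sources``
    distinct units at the chosen granularity.

    ``granularity="fluid"`` counts distinct fluid sources (urine/blood);
    ``granularity="study"`` counts distinct studies. Output is sorted by
    descending support, then cluster_id, with columns cluster_id,
    n_sources, sources.
    """
    if min_sources < 1:
        raise ConfigError("min_sources must be >= 1")
    if granularity not in ("fluid", "study"):
        raise ConfigError("granularity must be 'fluid' or 'study'")
    if features.empty:
        return pd.DataFrame(columns=["cluster_id", "n_sources", "sources"])
    meta = studies.set_index("study_id")
    if granularity == "fluid":
        unit = features["study_id"].map(meta["fluid"])
    else:
        unit = features["study_id"]
    df = pd.DataFrame({"cluster_id": features["cluster_id"], "unit": unit})
    agg = df.groupby("cluster_id")["unit"].agg(
        n_sources="nunique", sources=lambda u: ",".join(sorted(set(u))))
    agg = agg[agg["n_sources"] >= min_sources].reset_index()
    agg = agg.sort_values(["n_sources", "cluster_id"],
                          ascending=[False, True]).reset_index(drop=True)
    logger.info("overlap selection (granularity=%s, min_sources=%d): "
                "%d clusters", granularity, min_sources, len(agg))
    return agg
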