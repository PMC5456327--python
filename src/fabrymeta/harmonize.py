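"""Identifier harmonization and significance thresholding.

Raw published identifiers are mapped onto non-redundant molecular
clusters, redundant entries within one study are collapsed by averaging
their case/control ratios, and platform-specific plus global fold-change
and p-value thresholds are applied.

Direction convention: a ratio above 1 is up-regulation, below 1 is
down-regulation, and the fold-change magnitude of a ratio r is
max(r, 1/r), so a halving (r = 0.5) has the same magnitude as a doubling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fabrymeta.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("cluster_id", "study_id", "ratio", "p_value",
                   "direction", "tag")


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance thresholds for retaining a differential feature.

    Fold-change thresholds apply to the magnitude max(r, 1/r); the
    effective threshold for a feature is the larger of its platform
    threshold and the global threshold.
    """

    fc_transcriptomics: float = 2.0
    fc_prot_metab: float = 1.3
    fc_global: float = 1.4
    p_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fc_transcriptomics", "fc_prot_metab", "fc_global"):
            if getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be > 1")
        if not 0.0 < self.p_max < 1.0:
            raise ConfigError("p_max must lie in (0, 1)")

    def platform_threshold(self, platform: str) -> float:
        if platform == "transcriptomics":
            return self.fc_transcriptomics
        if platform in ("proteomics", "peptidomics", "metabolomics"):
            return self.fc_prot_metab
        raise ValidationError(f"unknown platform {platform!r}")


def direction_of(ratio: float | np.ndarray) -> np.ndarray | str:
    """Regulation direction of a case/control ratio: up iff ratio > 1."""
    if np.isscalar(ratio):
        return "up" if ratio > 1.0 else "down"
    return np.where(np.asarray(ratio) > 1.0, "up", "down")


def fc_magnitude(ratio):
    """Fold-change magnitude max(r, 1/r) of a positive ratio."""
    r = np.asarray(ratio, dtype=float)
    out = np.maximum(r, 1.0 / r)
    return float(out) if out.ndim == 0 else out


def map_identifiers(
    measurements: pd.DataFrame,
    alias_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach cluster_id and functionality tag to each measurement.

    Returns ``(mapped, unmapped)``; unmapped rows keep their raw_id and
    study_id for the audit log. ``len(mapped) + len(unmapped)`` always
    equals the input row count.
    """
    merged = measurements.merge(
        alias_map[["raw_id", "cluster_id", "tag"]], on="raw_id", how="left")
    hit = merged["cluster_id"].notna()
    mapped = merged[hit].reset_index(drop=True)
    unmapped = merged.loc[~hit, list(measurements.columns)].reset_index(drop=True)
    logger.info("identifier mapping: %d mapped, %d unmapped of %d "
                "measurements", len(mapped), len(unmapped), len(merged))
    return mapped, unmapped


def collapse_within_study(
    mapped: pd.DataFrame,
    p_policy: str = "min",
    ratio_policy: str = "arithmetic",
    return_dropped: bool = False,
):
    """Collapse redundant entries of one cluster within one study.

    The merged ratio is the arithmetic mean of the group's ratios (a
    geometric-mean option exists for sensitivity analysis); the merged
    p-value is the group minimum by default, or a Fisher combination.
    Groups whose members disagree in direction are dropped with a warning
    — the cross-study consistency check removes such contradictions
    between studies, and within-study conflicts are treated the same way.

    Idempotent: applying it to its own output is the identity.
    """
    if p_policy not in ("min", "fisher"):
        raise ConfigError("p_policy must be 'min' or 'fisher'")
    if ratio_policy not in ("arithmetic", "geometric"):
        raise ConfigError("ratio_policy must be 'arithmetic' or 'geometric'")
    if mapped["cluster_id"].isna().any():
        raise ValidationError("all records must carry a cluster_id")

    rows = []
    dropped_rows = []
    for (cluster_id, study_id), grp in mapped.groupby(
            ["cluster_id", "study_id"], sort=True):
        ratios = grp["ratio"].to_numpy(dtype=float)
        dirs = set(np.atleast_1d(direction_of(ratios)))
        if len(dirs) > 1:
            dropped_rows.append((cluster_id, study_id, len(grp)))
            logger.warning(
                "dropping cluster %s in study %s: %d entries with "
                "conflicting directions (ratios %s)",
                cluster_id, study_id, len(grp), np.round(ratios, 3).tolist())
            continue
        if ratio_policy == "arithmetic":
            ratio = float(np.mean(ratios))
        else:
            ratio = float(np.exp(np.mean(np.log(ratios))))
        pvals = grp["p_value"].to_numpy(dtype=float)
        if p_policy == "min" or len(pvals) == 1:
            p = float(np.min(pvals))
        else:
            p = float(stats.combine_pvalues(pvals, method="fisher").pvalue)
        rows.append((cluster_id, study_id, ratio, p,
                     direction_of(ratio), grp["tag"].iloc[0]))
    out = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    dropped = pd.DataFrame(dropped_rows,
                           columns=["cluster_id", "study_id", "n_entries"])
    logger.info("within-study collapsing: %d records -> %d features "
                "(%d conflicting groups dropped)",
                len(mapped), len(out), len(dropped))
    if return_dropped:
        return out, dropped
    return out


def apply_thresholds(
    features: pd.DataFrame,
    studies: pd.DataFrame,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Keep features with p < p_max and fold-change magnitude at or above
    both the platform threshold and the global threshold.

    Monotone in every threshold: raising any of them never admits a
    feature that was previously excluded. Symmetric in direction: a ratio
    r passes iff 1/r does.
    """
    config = config or ThresholdConfig()
    platform = features["study_id"].map(
        studies.set_index("study_id")["platform"])
    if platform.isna().any():
        missing = sorted(features.loc[platform.isna(), "study_id"].unique())
        raise ValidationError(f"study_id(s) with unknown platform: {missing}")
    thr = np.maximum(
        platform.map(config.platform_threshold).to_numpy(dtype=float),
        config.fc_global)
    magnitude = fc_magnitude(features["ratio"].to_numpy(dtype=float))
    keep = (features["p_value"].to_numpy(dtype=float) < config.p_max) & \
        (magnitude >= thr)
    out = features[keep].reset_index(drop=True)
    logger.info("thresholding: %d of %d features retained "
                "(fc_transcriptomics=%g, fc_prot_metab=%g, fc_global=%g, "
                "p_max=%g)", len(out), len(features),
                config.fc_transcriptomics, config.fc_prot_metab,
                config.fc_global, config.p_max)
    return out
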