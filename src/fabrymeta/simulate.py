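"""Synthetic multi-study measurement tables with planted ground truth.

The generator emulates published end-result tables of differential
expression studies: per-study molecule lists with case/control ratios
and p-values, redundant identifier aliases, platform-dependent
fold-change scales, a controlled fraction of cross-study direction
contradictions, and gene-set collections with planted enriched terms.

Because published tables only contain molecules that passed each
study's own significance criteria, planted signal ratios are drawn from
a log-normal distribution truncated at the platform's effective
reporting threshold, and planted p-values are below 0.05. Null
molecules have near-unity ratios and uniform p-values.

The default study design mirrors the meta-analysis dataspace: 11 human
studies (7 naive, 4 under enzyme replacement therapy) across urine and
blood, spanning transcriptomics, proteomics, peptidomics and
metabolomics platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fabrymeta.errors import ConfigError
from fabrymeta.harmonize import ThresholdConfig, direction_of
from fabrymeta.io_formats import FUNCTIONALITY_TAGS, GeneSet

#: (study_id, platform, fluid, group, n_case, n_control)
DEFAULT_STUDY_DESIGN = (
    ("Exp25666440", "proteomics", "urine", "naive", 11, 12),
    ("Exp17301227", "proteomics", "blood", "ERT", None, None),
    ("Exp18339188a", "transcriptomics", "blood", "ERT", None, None),
    ("Exp18339188b", "transcriptomics", "blood", "naive", None, None),
    ("Exp20954982", "peptidomics", "urine", "naive", 20, 10),
    ("Exp23385635", "peptidomics", "blood", "naive", 8, 6),
    ("Exp23464927", "proteomics", "urine", "ERT", None, None),
    ("Exp25619383", "proteomics", "blood", "naive", 32, 14),
    ("Exp21698285", "peptidomics", "urine", "naive", 35, 89),
    ("Exp26490183", "transcriptomics", "blood", "ERT", None, None),
    ("Exp25582508", "metabolomics", "urine", "naive", 16, 16),
)

#: Log-scale (natural log) location/scale of signal fold-change
#: magnitudes per platform: transcriptomics signals typically exceed
#: FC 2, the mass-spectrometry platforms FC 1.3-1.4.
DEFAULT_SIGNAL_LOG_PARAMS = {
    "transcriptomics": (math.log(2.8), 0.25),
    "proteomics": (math.log(1.9), 0.20),
    "peptidomics": (math.log(1.9), 0.20),
    "metabolomics": (math.log(1.8), 0.20),
}

_TAG_WEIGHTS = {
    "MET": 0.14, "CS": 0.14, "ENZ": 0.12, "TP": 0.08, "SIG": 0.08,
    "INH": 0.05, "UK": 0.08, "RCP": 0.05, "DIS": 0.02, "TF": 0.05,
    "MOD": 0.04, "TM": 0.05, "IGG": 0.04, "CHA": 0.02, "SCA": 0.02,
    "MHC": 0.01, "CNL": 0.01,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic-study generator.

    Signal clusters are planted in >= 2 studies of one group with a
    consistent direction; contradiction clusters are generated the same
    way and then flipped in exactly one randomly chosen supporting
    study. The proportion of up-regulated signals differs by group (the
    untreated group skews strongly upward).
    """

    studies: tuple = DEFAULT_STUDY_DESIGN
    n_signal_clusters: int = 60
    n_null_clusters: int = 140
    contradiction_fraction: float = 0.1
    supports_range: tuple[int, int] = (2, 4)
    n_frequent_clusters: int = 16
    frequent_supports_range: tuple[int, int] = (6, 9)
    frequent_up_probability: float = 0.7
    signal_log_params: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_LOG_PARAMS))
    null_log_sigma: float = 0.12
    signal_p_range: tuple[float, float] = (1e-6, 0.04)
    alias_range: tuple[int, int] = (1, 3)
    duplicate_fraction: float = 0.15
    null_studies_range: tuple[int, int] = (1, 3)
    up_probability: dict = field(
        default_factory=lambda: {"naive": 0.8, "ERT": 0.45})
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    # gene-set collection settings
    universe_terms: int = 40
    n_planted_terms: int = 5
    term_size_range: tuple[int, int] = (10, 25)
    planted_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.contradiction_fraction < 1.0:
            raise ConfigError("contradiction_fraction must lie in [0, 1)")
        if self.n_signal_clusters < 0 or self.n_null_clusters < 0:
            raise ConfigError("cluster counts must be nonnegative")
        if self.supports_range[0] < 2:
            raise ConfigError("planted features need >= 2 supporting studies")
        if self.n_frequent_clusters > self.n_signal_clusters:
            raise ConfigError("n_frequent_clusters cannot exceed "
                              "n_signal_clusters")
        if self.alias_range[0] < 1:
            raise ConfigError("every cluster needs >= 1 alias")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigError("planted_fraction must lie in [0, 1]")

    @property
    def n_contradiction_clusters(self) -> int:
        return int(round(self.contradiction_fraction * self.n_signal_clusters))


@dataclass
class SyntheticTruth:
    """Planted structure of one synthetic run.

    consensus_features maps cluster_id -> (direction, mean planted
    ratio); contradictory_clusters are disjoint from it by construction.
    enriched_terms is filled by :func:`generate_gene_sets`.
    """

    consensus_features: dict
    contradictory_clusters: set
    enriched_terms: set
    alias_groups: dict
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.consensus_features) & self.contradictory_clusters
        if overlap:
            raise ConfigError(
                f"contradictory clusters overlap consensus truth: {overlap}")
        if any(len(a) < 1 for a in self.alias_groups.values()):
            raise ConfigError("every alias group needs >= 1 alias")


def _draw_signal_magnitude(rng, platform: str, cfg: GeneratorConfig) -> float:
    """Log-normal fold-change magnitude, truncated at the effective
    reporting threshold (platform-specific and global)."""
    mu, sigma = cfg.signal_log_params[platform]
    floor = max(cfg.thresholds.platform_threshold(platform),
                cfg.thresholds.fc_global)
    for _ in range(1000):
        mag = float(np.exp(rng.normal(mu, sigma)))
        if mag >= floor:
            return mag
    return floor * 1.05  # unreachable for sane parameters


def _draw_signal_p(rng, cfg: GeneratorConfig) -> float:
    lo, hi = cfg.signal_p_range
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def generate_studies(
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate measurement, study and alias tables with planted truth.

    Identical (config, seed) pairs produce identical tables. Every
    planted consensus feature appears in at least two studies of one
    group with a consistent direction; every planted contradiction
    appears in at least two studies with opposing directions.
    """
    cfg = config or GeneratorConfig()
    master = np.random.SeedSequence(seed)
    rng_struct, rng_signal, rng_null, rng_dup = (
        np.random.default_rng(s) for s in master.spawn(4))

    studies = pd.DataFrame(
        list(cfg.studies),
        columns=["study_id", "platform", "fluid", "group",
                 "n_case", "n_control"])
    studies["n_case"] = pd.array(studies["n_case"], dtype="Int64")
    studies["n_control"] = pd.array(studies["n_control"], dtype="Int64")
    studies["ratio_convention"] = "ratio"
    by_group = {g: grp["study_id"].tolist()
                for g, grp in studies.groupby("group")}
    platform_of = studies.set_index("study_id")["platform"].to_dict()

    n_contra = cfg.n_contradiction_clusters
    n_total = cfg.n_signal_clusters + n_contra + cfg.n_null_clusters
    ids = [f"C{i:04d}" for i in range(1, n_total + 1)]
    order = rng_struct.permutation(n_total)
    signal_ids = [ids[i] for i in order[:cfg.n_signal_clusters]]
    contra_ids = [ids[i] for i in
                  order[cfg.n_signal_clusters:cfg.n_signal_clusters + n_contra]]
    null_ids = [ids[i] for i in order[cfg.n_signal_clusters + n_contra:]]

    tag_names = list(_TAG_WEIGHTS)
    tag_probs = np.array([_TAG_WEIGHTS[t] for t in tag_names])
    tag_probs = tag_probs / tag_probs.sum()
    tags = {cid: str(rng_struct.choice(tag_names, p=tag_probs))
            for cid in ids}
    assert set(tags.values()) <= set(FUNCTIONALITY_TAGS)

    alias_groups = {}
    for cid in ids:
        n_alias = int(rng_struct.integers(cfg.alias_range[0],
                                          cfg.alias_range[1] + 1))
        alias_groups[cid] = [f"{cid}_id{j}" for j in range(1, n_alias + 1)]

    groups = sorted(by_group)
    group_weights = np.array([len(by_group[g]) for g in groups], dtype=float)
    group_weights /= group_weights.sum()

    def plant_cluster(cid: str, rng) -> list[tuple[str, str, float, float]]:
        group = str(rng.choice(groups, p=group_weights))
        pool = by_group[group]
        k_max = min(cfg.supports_range[1], len(pool))
        k = int(rng.integers(cfg.supports_range[0], k_max + 1))
        supports = sorted(rng.choice(pool, size=k, replace=False))
        up = rng.random() < cfg.up_probability[group]
        records = []
        for sid in supports:
            mag = _draw_signal_magnitude(rng, platform_of[sid], cfg)
            ratio = mag if up else 1.0 / mag
            records.append((sid, cid, ratio, _draw_signal_p(rng, cfg)))
        return records

    def plant_frequent(cid: str, rng) -> list[tuple[str, str, float, float]]:
        # a frequently reported molecule: consistent direction across many
        # studies of both groups and both fluids
        k_max = min(cfg.frequent_supports_range[1], len(all_study_ids))
        k = int(rng.integers(cfg.frequent_supports_range[0], k_max + 1))
        supports = sorted(rng.choice(all_study_ids, size=k, replace=False))
        up = rng.random() < cfg.frequent_up_probability
        records = []
        for sid in supports:
            mag = _draw_signal_magnitude(rng, platform_of[sid], cfg)
            ratio = mag if up else 1.0 / mag
            records.append((sid, cid, ratio, _draw_signal_p(rng, cfg)))
        return records

    all_study_ids = studies["study_id"].tolist()
    signal_ids = sorted(signal_ids)
    frequent_ids = set(signal_ids[:cfg.n_frequent_clusters])
    rows: list[tuple[str, str, float, float]] = []
    consensus_truth = {}
    for cid in signal_ids:
        if cid in frequent_ids:
            recs = plant_frequent(cid, rng_signal)
        else:
            recs = plant_cluster(cid, rng_signal)
        rows.extend(recs)
        ratios = [r[2] for r in recs]
        consensus_truth[cid] = (direction_of(float(np.mean(ratios))),
                                float(np.mean(ratios)))

    for cid in sorted(contra_ids):
        recs = plant_cluster(cid, rng_signal)
        flip = int(rng_signal.integers(len(recs)))
        sid, c, ratio, p = recs[flip]
        recs[flip] = (sid, c, 1.0 / ratio, p)
        rows.extend(recs)

    for cid in sorted(null_ids):
        k = int(rng_null.integers(cfg.null_studies_range[0],
                                  cfg.null_studies_range[1] + 1))
        for sid in sorted(rng_null.choice(all_study_ids, size=k,
                                          replace=False)):
            ratio = float(np.exp(rng_null.normal(0.0, cfg.null_log_sigma)))
            rows.append((sid, cid, ratio, float(rng_null.uniform(0.0, 1.0))))

    # emit measurements under a randomly chosen alias; occasionally emit a
    # within-study duplicate under a second alias with a same-direction
    # jittered ratio (redundant entries are expected in curated tables)
    out_rows = []
    for sid, cid, ratio, p in rows:
        aliases = alias_groups[cid]
        alias = aliases[int(rng_dup.integers(len(aliases)))]
        out_rows.append((sid, alias, ratio, p))
        planted = cid in consensus_truth or cid in set(contra_ids)
        if (planted and len(aliases) >= 2
                and rng_dup.random() < cfg.duplicate_fraction):
            other = [a for a in aliases if a != alias]
            alias2 = other[int(rng_dup.integers(len(other)))]
            ratio2 = float(np.exp(np.log(ratio) * rng_dup.uniform(0.85, 1.15)))
            p2 = min(float(p * rng_dup.uniform(0.5, 2.0)),
                     cfg.signal_p_range[1])
            out_rows.append((sid, alias2, ratio2, p2))

    measurements = pd.DataFrame(
        out_rows, columns=["study_id", "raw_id", "ratio", "p_value"])
    alias_df = pd.DataFrame(
        [(alias, cid, tags[cid])
         for cid in ids for alias in alias_groups[cid]],
        columns=["raw_id", "cluster_id", "tag"])

    truth = SyntheticTruth(
        consensus_features=consensus_truth,
        contradictory_clusters=set(contra_ids),
        enriched_terms=set(),
        alias_groups=alias_groups,
        seed=seed,
    )
    return measurements, studies, alias_df, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[GeneSet]:
    """Gene-set collection over the synthetic universe.

    Planted enriched terms draw ``planted_fraction`` of their members
    from the true signal clusters; every other term samples uniformly
    from the whole universe. Planted term names are recorded in
    ``truth.enriched_terms``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    universe = sorted(truth.alias_groups)
    lo, hi = cfg.term_size_range
    if hi > len(universe):
        raise ConfigError(f"term size {hi} exceeds universe size "
                          f"{len(universe)}")
    signals = sorted(truth.consensus_features)
    names = [f"T{i:03d}" for i in range(1, cfg.universe_terms + 1)]
    planted = set(str(x) for x in rng.choice(
        names, size=min(cfg.n_planted_terms, len(names)), replace=False))

    sets = []
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        if name in planted and signals:
            n_sig = min(int(round(cfg.planted_fraction * size)), len(signals))
            core = list(rng.choice(signals, size=n_sig, replace=False))
            rest_pool = sorted(set(universe) - set(core))
            rest = list(rng.choice(rest_pool, size=size - n_sig,
                                   replace=False))
            members = sorted(core + rest)
            description = "planted"
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
            description = "background"
        sets.append(GeneSet(name, description, tuple(members)))
    truth.enriched_terms.update(planted)
    return sets


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist the planted structure as a TSV for test assertions."""
    rows = []
    for cid, (direction, mean_ratio) in sorted(
            truth.consensus_features.items()):
        rows.append(("consensus", cid, direction, f"{mean_ratio:.6g}", ""))
    for cid in sorted(truth.contradictory_clusters):
        rows.append(("contradiction", cid, "", "", ""))
    for term in sorted(truth.enriched_terms):
        rows.append(("enriched_term", term, "", "", ""))
    for cid, aliases in sorted(truth.alias_groups.items()):
        rows.append(("alias_group", cid, "", "", ",".join(aliases)))
    rows.append(("seed", str(truth.seed), "", "", ""))
    pd.DataFrame(rows, columns=["kind", "key", "direction", "mean_ratio",
                                "aliases"]).to_csv(path, sep="\t",
                                                   index=False)


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    consensus = {r.key: (r.direction, float(r.mean_ratio))
                 for r in df[df["kind"] == "consensus"].itertuples()}
    contradictions = set(df.loc[df["kind"] == "contradiction", "key"])
    enriched = set(df.loc[df["kind"] == "enriched_term", "key"])
    aliases = {r.key: r.aliases.split(",")
               for r in df[df["kind"] == "alias_group"].itertuples()}
    seed = int(df.loc[df["kind"] == "seed", "key"].iloc[0])
    return SyntheticTruth(consensus, contradictions, enriched, aliases, seed)
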