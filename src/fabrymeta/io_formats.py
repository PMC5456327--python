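"""Readers and writers for every external format the pipeline touches.

All tabular files are UTF-8, tab-separated, with a mandatory header row.
Unknown extra columns are ignored with a logged warning; every rejection
is counted and logged so the filtering funnel stays auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from fabrymeta.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of per-cluster functionality tags (CluSO-style).
FUNCTIONALITY_TAGS = (
    "MET", "CS", "ENZ", "TP", "SIG", "INH", "UK", "RCP", "DIS",
    "TF", "MOD", "TM", "IGG", "CHA", "SCA", "MHC", "CNL",
)

PLATFORMS = ("transcriptomics", "proteomics", "peptidomics", "metabolomics")
FLUIDS = ("urine", "blood")
GROUPS = ("naive", "ERT")
REGULATOR_KINDS = ("miRNA", "TF")

MEASUREMENT_COLUMNS = ("study_id", "raw_id", "ratio", "p_value")
STUDY_COLUMNS = ("study_id", "platform", "fluid", "group")
ALIAS_COLUMNS = ("raw_id", "cluster_id", "tag")
EDGE_COLUMNS = ("regulator", "target", "network_id", "kind")


@dataclass(frozen=True)
class GeneSet:
    """A named term (GO/pathway/disease) with member cluster ids.

    Members are stored deduplicated, in first-seen order.
    """

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            seen: set[str] = set()
            unique = tuple(m for m in self.members
                           if not (m in seen or seen.add(m)))
            object.__setattr__(self, "members", unique)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class RegulatoryEdge:
    """Regulator (miRNA or TF) -> target cluster with source-network label."""

    regulator: str
    target: str
    network_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in REGULATOR_KINDS:
            raise FormatError(
                f"unknown regulator kind {self.kind!r}; "
                f"expected one of {REGULATOR_KINDS}"
            )


def _read_tsv(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA", "N/A"], encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file {path} is missing required "
                          f"column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s file %s: ignoring extra column(s) %s",
                       what, path, extra)
    return df


def read_studies(path: str | Path) -> pd.DataFrame:
    """Read study metadata: study_id, platform, fluid, group, and optional
    n_case / n_control / ratio_convention columns."""
    optional = ["n_case", "n_control", "ratio_convention"]
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA", "N/A"], encoding="utf-8")
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"study file {path} is missing required "
                          f"column(s): {', '.join(missing)}")
    extra = [c for c in df.columns
             if c not in STUDY_COLUMNS and c not in optional]
    if extra:
        logger.warning("study file %s: ignoring extra column(s) %s", path, extra)

    if df["study_id"].duplicated().any():
        dups = sorted(df.loc[df["study_id"].duplicated(), "study_id"])
        raise ValidationError(f"duplicate study_id(s): {dups}")
    for col, vocab in (("platform", PLATFORMS), ("fluid", FLUIDS),
                       ("group", GROUPS)):
        bad = sorted(set(df[col].dropna()) - set(vocab))
        if bad:
            raise FormatError(f"study file {path}: unknown {col} value(s) "
                              f"{bad}; expected one of {vocab}")
    for col in ("n_case", "n_control"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
            if (df[col].dropna() < 0).any():
                raise ValidationError(f"{col} must be nonnegative")
        else:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "ratio_convention" not in df.columns:
        df["ratio_convention"] = "ratio"
    else:
        df["ratio_convention"] = df["ratio_convention"].fillna("ratio")
        bad = sorted(set(df["ratio_convention"]) - {"ratio", "signed_fc"})
        if bad:
            raise FormatError(f"unknown ratio_convention value(s) {bad}")
    keep = list(STUDY_COLUMNS) + ["n_case", "n_control", "ratio_convention"]
    return df[keep].reset_index(drop=True)


def _signed_fc_to_ratio(values: pd.Series) -> pd.Series:
    """Convert signed fold-changes to case/control ratios.

    A signed fold-change of -2 means halved (ratio 0.5); +2 means doubled.
    Magnitudes below 1 have no defined meaning under this convention.
    """
    v = values.astype(float)
    out = v.where(v >= 1.0, -1.0 / v)
    out[(v > -1.0) & (v < 1.0)] = np.nan
    return out


def read_measurements(
    path: str | Path,
    study_table: str | Path,
    errors: str = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read per-study molecule measurements joined against study metadata.

    Parameters
    ----------
    path
        Measurement TSV with columns study_id, raw_id, ratio, p_value.
    study_table
        Study TSV (see :func:`read_studies`).
    errors
        ``"raise"`` (default) raises :class:`ValidationError` naming the
        offending 1-based data row numbers; ``"collect"`` instead returns
        only the valid rows and logs the rejected count.

    Returns
    -------
    (measurements, studies)
        Measurements carry study_id, raw_id, ratio (float > 0), p_value.
        Row order of the input file is preserved.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    studies = read_studies(study_table)
    df = _read_tsv(path, MEASUREMENT_COLUMNS, "measurement")
    df = df[list(MEASUREMENT_COLUMNS)].copy()
    df["row"] = np.arange(1, len(df) + 1)

    known = set(studies["study_id"])
    dangling = sorted(set(df["study_id"]) - known)
    if dangling:
        raise ValidationError(
            f"measurement file references unknown study_id(s): {dangling}")

    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")

    # per-study signed fold-change convention (mixed literature conventions)
    conv = studies.set_index("study_id")["ratio_convention"]
    signed = df["study_id"].map(conv) == "signed_fc"
    if signed.any():
        df.loc[signed, "ratio"] = _signed_fc_to_ratio(df.loc[signed, "ratio"])

    bad = (
        df["ratio"].isna() | (df["ratio"] <= 0)
        | df["p_value"].isna() | (df["p_value"] < 0) | (df["p_value"] > 1)
    )
    if bad.any():
        rows = df.loc[bad, "row"].tolist()
        if errors == "raise":
            raise ValidationError(
                f"invalid measurement row(s) {rows}: require ratio > 0 and "
                f"p_value in [0, 1]")
        logger.warning("rejected %d invalid measurement row(s): %s",
                       len(rows), rows)
        df = df[~bad]
    logger.info("read %d measurements from %d studies", len(df), len(studies))
    return df.drop(columns=["row"]).reset_index(drop=True), studies


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df[list(MEASUREMENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_studies(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_alias_map(path: str | Path) -> pd.DataFrame:
    """Read the raw-identifier -> non-redundant cluster alias map.

    Enforces: each raw_id maps to at most one cluster_id; each cluster_id
    carries exactly one functionality tag drawn from the closed vocabulary.
    """
    df = _read_tsv(path, ALIAS_COLUMNS, "alias")
    df = df[list(ALIAS_COLUMNS)].drop_duplicates().reset_index(drop=True)
    amb = df.groupby("raw_id")["cluster_id"].nunique()
    amb = sorted(amb[amb > 1].index)
    if amb:
        raise ValidationError(f"raw_id(s) mapping to multiple clusters: {amb}")
    multi = df.groupby("cluster_id")["tag"].nunique()
    multi = sorted(multi[multi > 1].index)
    if multi:
        raise ValidationError(f"cluster_id(s) with conflicting tags: {multi}")
    bad = sorted(set(df["tag"]) - set(FUNCTIONALITY_TAGS))
    if bad:
        raise FormatError(f"unknown functionality tag(s) {bad}; expected "
                          f"one of {FUNCTIONALITY_TAGS}")
    return df


def write_alias_map(df: pd.DataFrame, path: str | Path) -> None:
    df[list(ALIAS_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in the standard GMT dialect.

    Each line: name TAB description TAB member TAB member ...
    Duplicate members within a line are dropped; a line with fewer than
    three fields is a format error naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    f"need name, description and at least one member")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, description, tuple(members)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_edges(path: str | Path) -> list[RegulatoryEdge]:
    """Read regulator -> target edges; deduplicated on
    (regulator, target, network_id). A regulator must keep one kind."""
    df = _read_tsv(path, EDGE_COLUMNS, "edge")
    bad = sorted(set(df["kind"]) - set(REGULATOR_KINDS))
    if bad:
        raise FormatError(f"unknown regulator kind(s) {bad}; expected one "
                          f"of {REGULATOR_KINDS}")
    kinds = df.groupby("regulator")["kind"].nunique()
    mixed = sorted(kinds[kinds > 1].index)
    if mixed:
        raise FormatError(f"regulator(s) with inconsistent kind: {mixed}")
    df = df.drop_duplicates(subset=["regulator", "target", "network_id"])
    return [RegulatoryEdge(r.regulator, r.target, r.network_id, r.kind)
            for r in df.itertuples(index=False)]


def write_edges(edges: Iterable[RegulatoryEdge], path: str | Path) -> None:
    rows = [(e.regulator, e.target, e.network_id, e.kind) for e in edges]
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write a simple interaction file: source TAB relation TAB target."""
    with open(path, "w", encoding="utf-8") as fh:
        for source, relation, target in edges:
            fh.write(f"{source}\t{relation}\t{target}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config file {path} must hold a mapping")
    return cfg
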