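"""Count-table ingestion, inclusion filters, and run configuration.

Species-code conventions (a concrete stand-in for scheme-specific
codes): a dot suffix marks a subspecies (``"SP001.1"`` aggregates into
``"SP001"``), a lowercase ``"x"`` anywhere in the code marks a hybrid
(dropped), and a code ending in ``"sp."`` is a genus-only record
(dropped). Inclusion rules: a site must be surveyed in at least three
distinct years, and a site is removed entirely if any species detected
there has no recordings in the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import NoAnalyzableSitesError, ParameterError
from .synthlib import COUNT_COLUMNS

REQUIRED_COUNT_COLUMNS = ["site_id", "year", "species_code", "count"]


def read_count_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read and clean a counts CSV.

    Subspecies rows are summed into their species-level code; hybrid and
    genus-only rows are dropped. Returns the table and a report of how
    many rows each rule touched.

    Raises
    ------
    ParameterError
        On missing columns or malformed counts (the offending CSV row
        numbers are named).
    """
    df = pd.read_csv(path, dtype={"species_code": str, "site_id": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"counts file {path} lacks required columns: {missing}")
    counts_num = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts_num.isna() | (counts_num != counts_num.round())]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ParameterError(f"non-integer counts at CSV row(s) {rows}")
    df["count"] = counts_num.astype(int)
    if (df["count"] < 1).any():
        rows = [int(i) + 2 for i in df.index[df["count"] < 1][:10]]
        raise ParameterError(f"counts must be >= 1; offending CSV row(s) {rows}")

    report = {"hybrid_rows_dropped": 0, "genus_rows_dropped": 0, "subspecies_rows_merged": 0}
    code = df["species_code"].astype(str)
    hybrids = code.str.contains("x", regex=False)
    genus_only = code.str.endswith("sp.")
    report["hybrid_rows_dropped"] = int(hybrids.sum())
    report["genus_rows_dropped"] = int((genus_only & ~hybrids).sum())
    df = df[~(hybrids | genus_only)].copy()

    has_dot = df["species_code"].str.contains(".", regex=False)
    report["subspecies_rows_merged"] = int(has_dot.sum())
    df["species_code"] = df["species_code"].str.split(".").str[0]

    group_cols = ["site_id", "year", "species_code"]
    other = [c for c in df.columns if c not in group_cols + ["count"]]
    agg = {"count": "sum", **{c: "first" for c in other}}
    df = df.groupby(group_cols, as_index=False).agg(agg)
    ordered = [c for c in COUNT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    return df[ordered], report


def apply_inclusion_filters(
    records: pd.DataFrame,
    library_species: set[str],
    min_surveys: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop sites that fail the survey or recording-coverage rules.

    A site is excluded when it was surveyed in fewer than
    ``min_surveys`` distinct years, or when any species detected there
    is absent from the recording library. The two rules are evaluated
    on the input independently (order cannot matter); a site failing
    both is reported under the survey rule.
    """
    years_per_site = records.groupby("site_id")["year"].nunique()
    few = set(years_per_site.index[years_per_site < min_surveys])
    covered = records["species_code"].isin(library_species)
    missing_sites = set(records.loc[~covered, "site_id"].unique())
    n_sites = records["site_id"].nunique()
    drop = few | missing_sites
    out = records[~records["site_id"].isin(drop)].reset_index(drop=True)
    report = {
        "sites_input": int(n_sites),
        "sites_dropped_min_surveys": len(few),
        "sites_dropped_missing_species": len(missing_sites - few),
        "sites_output": int(out["site_id"].nunique()),
    }
    if out.empty:
        raise NoAnalyzableSitesError("all sites were excluded by the inclusion filters")
    return out, report


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-backed)."""

    counts_path: str = "counts.csv"
    manifest_path: str = "library/manifest.csv"
    audio_dir: str = ""
    out_dir: str = "out"
    master_seed: int = 0
    canvas_s: float = 300.0
    n_iter: int = 5
    gain: str = "uniform"
    max_files: int = 50
    min_duration_s: float = 30.0
    min_surveys: int = 3
    year_mode: str = "continuous"
    n_boot: int = 1000
    log_level: str = "INFO"
    index: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
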