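"""Readers, writers and validated containers for panel-qPCR and annotation data.

The entry point of the expression pipeline is a matrix of quantification
cycles (Cq): one row per miRNA assay, one column per sample.  Cells where the
reaction never crossed the fluorescence threshold carry an explicit
*undetected* state (stored as NaN in the float matrix); numeric substitution
(e.g. a Cq of 41) happens only inside operations that explicitly opt in.

Genomic annotation of the assayed miRNAs is a BED-like table (0-based
half-open coordinates) with a cytogenetic band label and an optional locus
cluster id, used by the enrichment test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: strings accepted as the undetected state in delimited Cq tables
UNDETECTED_TOKENS = {"", "na", "nan", "undetermined", "undetected"}

CASE = "case"
CONTROL = "control"


class PanelValidationError(ValueError):
    """Raised when an input table violates the panel data model."""


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class CqPanel:
    """A miRNA x sample matrix of quantification cycles with group metadata.

    ``cq`` is a float DataFrame (rows: miRNA ids, columns: sample ids);
    NaN encodes the undetected state.  ``groups`` maps each sample to
    ``"case"`` or ``"control"`` (or ``""`` when unassigned); ``passages`` is
    free-text per-sample metadata.
    """

    cq: pd.DataFrame
    groups: pd.Series
    passages: pd.Series

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.groups is None:
            self.groups = pd.Series("", index=self.cq.columns, dtype=object)
        if self.passages is None:
            self.passages = pd.Series("", index=self.cq.columns, dtype=object)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def mirna_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask, True where a Cq value was recorded."""
        return self.cq.notna()

    @property
    def case_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.cq.index
        cols = self.cq.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise PanelValidationError(f"duplicate miRNA id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise PanelValidationError(f"duplicate sample id: {dup!r}")
        vals = self.cq.to_numpy(float)
        det = ~np.isnan(vals)
        bad = det & ~((vals > 0) & (vals <= 45) & np.isfinite(vals))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"Cq out of range (0, 45] for miRNA {idx[i]!r}, sample "
                f"{cols[j]!r}: {vals[i, j]!r}"
            )
        if not self.groups.index.equals(cols):
            self.groups = self.groups.reindex(cols, fill_value="")
        if not self.passages.index.equals(cols):
            self.passages = self.passages.reindex(cols, fill_value="")
        unknown = set(self.groups.unique()) - {CASE, CONTROL, ""}
        if unknown:
            raise PanelValidationError(f"unknown group label(s): {sorted(unknown)}")

    def require_groups(self) -> None:
        """Group statistics need at least one case and one control sample."""
        if not self.case_ids or not self.control_ids:
            raise PanelValidationError(
                "at least one case and one control sample are required "
                f"(got {len(self.case_ids)} case, {len(self.control_ids)} control)"
            )

    def subset(self, mirna_ids: Iterable[str]) -> "CqPanel":
        ids = list(mirna_ids)
        missing = set(ids) - set(self.cq.index)
        if missing:
            raise KeyError(f"miRNA ids not in panel: {sorted(missing)}")
        return CqPanel(self.cq.loc[ids].copy(), self.groups.copy(), self.passages.copy())


@dataclass
class MirnaAnnotation:
    """BED-like genomic annotation of miRNA assays.

    Columns: chrom, start, end (0-based half-open), mirna_id, band,
    cluster_id (None when the miRNA belongs to no locus cluster).  Cluster
    assignment is a partition: a miRNA appears at most once, hence in at most
    one cluster.
    """

    table: pd.DataFrame

    COLUMNS = ["chrom", "start", "end", "mirna_id", "band", "cluster_id"]

    def __post_init__(self) -> None:
        t = self.table
        missing = set(self.COLUMNS) - set(t.columns)
        if missing:
            raise PanelValidationError(f"annotation missing column(s): {sorted(missing)}")
        t = t[self.COLUMNS].copy()
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        if (t["start"] >= t["end"]).any():
            row = t[t["start"] >= t["end"]].iloc[0]
            raise PanelValidationError(
                f"start >= end for {row['mirna_id']!r} ({row['start']} >= {row['end']})"
            )
        if t["mirna_id"].duplicated().any():
            dup = t.loc[t["mirna_id"].duplicated(), "mirna_id"].iloc[0]
            raise PanelValidationError(f"duplicated mirna_id in annotation: {dup!r}")
        t["cluster_id"] = t["cluster_id"].where(
            ~t["cluster_id"].isin([".", "", None]) & t["cluster_id"].notna(), None
        )
        self.table = t.reset_index(drop=True)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table["mirna_id"])

    def cluster_members(self, cluster_id: str) -> set[str]:
        t = self.table
        return set(t.loc[t["cluster_id"] == cluster_id, "mirna_id"])


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

def _parse_cq_cell(raw: object, mirna: str, sample: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.lower() in UNDETECTED_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise PanelValidationError(
            f"non-numeric Cq cell for miRNA {mirna!r}, sample {sample!r}: {s!r}"
        ) from None


def read_cq_table(
    path: str | Path,
    dialect: str = "wide",
    groups: Mapping[str, str] | pd.Series | str | Path | None = None,
) -> CqPanel:
    """Read a Cq table in wide (miRNA rows x sample columns) or long
    (mirna, sample, cq triples) dialect.

    Undetected cells may be encoded as empty, "NA" or "Undetermined".
    ``groups`` is an optional sample -> group mapping, or a path to a
    delimited file with columns ``sample_id``, ``group`` and optionally
    ``passage``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"dialect must be 'wide' or 'long', got {dialect!r}")
    sep = _delimiter_for(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    if dialect == "wide":
        samples = [str(c) for c in header[1:]]  # pandas mangles duplicates
        _check_unique(samples, "sample")
        mirnas = raw.iloc[:, 0].astype(str).tolist()
        _check_unique(mirnas, "miRNA")
        data = np.empty((len(mirnas), len(samples)))
        for j, s in enumerate(samples):
            col = raw.iloc[:, j + 1]
            for i, m in enumerate(mirnas):
                data[i, j] = _parse_cq_cell(col.iloc[i], m, s)
        cq = pd.DataFrame(data, index=mirnas, columns=samples)
    else:
        need = {"mirna", "sample", "cq"}
        cols = {c.lower(): c for c in raw.columns}
        if not need <= set(cols):
            raise PanelValidationError(
                f"long dialect needs columns {sorted(need)}, got {list(raw.columns)}"
            )
        mirnas = list(dict.fromkeys(raw[cols["mirna"]]))
        samples = list(dict.fromkeys(raw[cols["sample"]]))
        seen: set[tuple[str, str]] = set()
        cq = pd.DataFrame(np.nan, index=mirnas, columns=samples)
        for _, row in raw.iterrows():
            key = (row[cols["mirna"]], row[cols["sample"]])
            if key in seen:
                raise PanelValidationError(f"duplicate (miRNA, sample) pair: {key}")
            seen.add(key)
            cq.loc[key[0], key[1]] = _parse_cq_cell(row[cols["cq"]], *key)

    group_s, passage_s = _load_groups(groups, list(cq.columns))
    return CqPanel(cq, group_s, passage_s)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise PanelValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def _load_groups(groups, samples: list[str]) -> tuple[pd.Series, pd.Series]:
    passages = pd.Series("", index=samples, dtype=object)
    if groups is None:
        return pd.Series("", index=samples, dtype=object), passages
    if isinstance(groups, (str, Path)):
        p = Path(groups)
        t = pd.read_csv(p, sep=_delimiter_for(p), dtype=str, keep_default_na=False)
        cols = {c.lower(): c for c in t.columns}
        if "sample_id" not in cols or "group" not in cols:
            raise PanelValidationError(
                "groups file needs columns sample_id and group"
            )
        mapping = dict(zip(t[cols["sample_id"]], t[cols["group"]]))
        if "passage" in cols:
            passages.update(pd.Series(dict(zip(t[cols["sample_id"]], t[cols["passage"]]))))
        groups = mapping
    s = pd.Series(groups).reindex(samples, fill_value="")
    return s.astype(object), passages


def write_cq_table(panel: CqPanel, path: str | Path, dialect: str = "wide") -> None:
    """Write a panel back to disk; undetected cells become "NA"."""
    path = Path(path)
    sep = _delimiter_for(path)
    if dialect == "wide":
        out = panel.cq.copy()
        out.index.name = "mirna"
        out.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")
    elif dialect == "long":
        long = panel.cq.stack(future_stack=True).reset_index()
        long.columns = ["mirna", "sample", "cq"]
        long.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.10g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_groups(panel: CqPanel, path: str | Path) -> None:
    path = Path(path)
    t = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "group": panel.groups.values,
            "passage": panel.passages.values,
        }
    )
    t.to_csv(path, sep=_delimiter_for(path), index=False)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> MirnaAnnotation:
    """Read a BED-like annotation: chrom, start, end, mirna_id, band, cluster_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    t = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        header=None,
        names=MirnaAnnotation.COLUMNS,
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    return MirnaAnnotation(t)


def write_annotation(ann: MirnaAnnotation, path: str | Path) -> None:
    path = Path(path)
    t = ann.table.copy()
    t["cluster_id"] = t["cluster_id"].fillna(".").replace({None: "."})
    t.to_csv(path, sep=_delimiter_for(path), index=False, header=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(results: Mapping[str, object], outdir: str | Path) -> Path:
    """Write a machine-readable report directory.

    DataFrame-valued entries become TSV files at full precision; everything
    else (parameter blocks, scalars, lists, nested dicts) is serialized into
    ``report.json``.  Returns the path of the JSON report.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise PanelValidationError(f"cannot create output directory {outdir}: {exc}")
    summary: dict[str, object] = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            fp = outdir / f"{key}.tsv"
            value.to_csv(fp, sep="\t", float_format="%.17g", na_rep="NA")
            summary[key] = {"file": fp.name, "rows": int(value.shape[0])}
        elif isinstance(value, pd.Series):
            fp = outdir / f"{key}.tsv"
            value.to_frame(key).to_csv(fp, sep="\t", float_format="%.17g", na_rep="NA")
            summary[key] = {"file": fp.name, "rows": int(value.shape[0])}
        else:
            summary[key] = _jsonable(value)
    report = outdir / "report.json"
    with open(report, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def read_report(outdir: str | Path) -> dict:
    outdir = Path(outdir)
    with open(outdir / "report.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    out: dict[str, object] = {}
    for key, value in summary.items():
        if isinstance(value, dict) and set(value) == {"file", "rows"}:
            out[key] = pd.read_csv(
                outdir / value["file"], sep="\t", index_col=0,
                float_precision="round_trip",
            )
        else:
            out[key] = value
    return out


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
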