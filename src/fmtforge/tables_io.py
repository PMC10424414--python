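"""Feature-table, taxonomy and metadata I/O plus the shared domain types.

All other modules build on the containers defined here: :class:`FeatureTable`
(a samples x taxa relative-abundance matrix with QIIME-style taxonomy column
labels), :class:`SampleMetadata` rows, and :class:`CohortBundle` (paired
donor / recipient tables for one or more FMT cohorts).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_INDEX = {name: i for i, name in enumerate(RANK_NAMES)}

#: tolerance used to decide whether rows of a table are already closed to 1
RELATIVE_ROW_SUM_TOL = 1e-6


class TaxonomyError(ValueError):
    """Raised for unparseable or out-of-order taxonomy strings."""


@dataclasses.dataclass(frozen=True)
class TaxonomyString:
    """A semicolon-delimited ranked lineage, kingdom -> species.

    Missing trailing ranks are allowed; ranks always appear in canonical
    order. Unprefixed labels are accepted and assigned ranks positionally
    (different 16S pipelines emit both dialects).
    """

    labels: tuple[str, ...]  # one label per rank present, prefixes stripped

    @classmethod
    def parse(cls, text: str) -> "TaxonomyString":
        parts = [p.strip() for p in text.split(";")]
        # drop trailing empty fields ("k__A;p__B;;;")
        while parts and parts[-1] == "":
            parts.pop()
        if not parts:
            raise TaxonomyError(f"empty taxonomy string: {text!r}")
        if len(parts) > len(RANK_PREFIXES):
            raise TaxonomyError(f"more than {len(RANK_PREFIXES)} ranks: {text!r}")
        labels = []
        for i, part in enumerate(parts):
            if part[:3] in ("k__", "p__", "c__", "o__", "f__", "g__", "s__"):
                if part[:3] != RANK_PREFIXES[i]:
                    raise TaxonomyError(
                        f"rank prefix {part[:3]!r} out of order at position {i} in {text!r}"
                    )
                labels.append(part[3:])
            else:
                labels.append(part)  # unprefixed: positional rank
        return cls(tuple(labels))

    @property
    def depth(self) -> int:
        return len(self.labels)

    def at_rank(self, rank: str) -> "TaxonomyString":
        """Truncate the lineage at `rank` (inclusive)."""
        k = RANK_INDEX[rank] + 1
        if k > self.depth:
            raise TaxonomyError(f"lineage {self} has no {rank} rank")
        return TaxonomyString(self.labels[:k])

    def filled(self) -> "TaxonomyString":
        """Return a full 7-rank lineage, padding missing or empty tail ranks.

        A blank label inherits "<parent-label>__unclassified" so every leaf
        has a complete root-to-leaf path (needed by the image builder).
        """
        labels = list(self.labels)
        while len(labels) < len(RANK_PREFIXES):
            labels.append("")
        out: list[str] = []
        for lab in labels:
            if lab:
                out.append(lab)
            else:
                parent = out[-1] if out else "root"
                base = parent.split("__unclassified")[0]
                out.append(f"{base}__unclassified")
        return TaxonomyString(tuple(out))

    def __str__(self) -> str:
        return ";".join(p + l for p, l in zip(RANK_PREFIXES, self.labels))

    def __lt__(self, other: "TaxonomyString") -> bool:
        return self.labels < other.labels


@dataclasses.dataclass
class FeatureTable:
    """Samples x taxa abundance matrix.

    `space_tag` records the numeric space: raw counts, relative (each row on
    the simplex) or log-normalized model space.
    """

    sample_ids: list[str]
    taxa: list[TaxonomyString]
    values: np.ndarray  # (n_samples, n_taxa), float
    space_tag: str  # counts | relative | log_normalized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        dup = _duplicates(str(t) for t in self.taxa)
        if dup:
            raise ValueError(f"duplicate taxa: {sorted(dup)}")
        if self.space_tag in ("counts", "relative") and (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxa[bad[1]]}"
            )
        if self.space_tag == "relative":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                worst = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"relative table row {self.sample_ids[worst]!r} sums to {sums[worst]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=[str(t) for t in self.taxa]
        )

    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return FeatureTable(list(ids), list(self.taxa), self.values[idx], self.space_tag)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.sample_ids), list(self.taxa), self.values.copy(), self.space_tag
        )


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample annotations; recipients carry pairing info, donors do not."""

    sample_id: str
    subject_id: str
    role: str  # donor | recipient
    donor_id: str | None = None
    cohort_id: str = "cohort0"
    days_post_fmt: int | None = None  # 0 = pre-FMT baseline, >0 = post-FMT
    age: float | None = None
    sex: str | None = None
    weight: float | None = None
    outcome: int | None = None  # binary clinical success, if known

    def __post_init__(self) -> None:
        if self.role == "recipient":
            if self.donor_id is None or self.days_post_fmt is None:
                raise ValueError(
                    f"recipient {self.sample_id!r} needs donor_id and days_post_fmt"
                )
        elif self.role == "donor":
            if self.donor_id is not None or self.days_post_fmt is not None:
                raise ValueError(
                    f"donor {self.sample_id!r} must not carry donor_id/days_post_fmt"
                )
        else:
            raise ValueError(f"unknown role {self.role!r}")


@dataclasses.dataclass
class CohortBundle:
    """Donor table + recipient table + pairing map + metadata for a study.

    `pairing` maps each recipient sample id to (donor sample id,
    days_post_fmt, cohort_id). Donors and recipients share one taxon axis
    (enforced here by union alignment with zero-padding).
    """

    donors: FeatureTable
    recipients: FeatureTable
    metadata: dict[str, SampleMetadata]
    pairing: dict[str, tuple[str, int, str]]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        donor_ids = set(self.donors.sample_ids)
        recip_ids = set(self.recipients.sample_ids)
        for rid, (did, _, _) in self.pairing.items():
            if rid not in recip_ids:
                raise ValueError(f"pairing key {rid!r} not a recipient sample")
            if did not in donor_ids:
                raise ValueError(f"pairing donor {did!r} not a donor sample")
        if [str(t) for t in self.donors.taxa] != [str(t) for t in self.recipients.taxa]:
            self.donors, self.recipients = align_union([self.donors, self.recipients])

    @property
    def cohort_ids(self) -> list[str]:
        return sorted({c for (_, _, c) in self.pairing.values()})

    def subject_of(self, recipient_sample: str) -> str:
        return self.metadata[recipient_sample].subject_id


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path: str | Path, dialect: str = "tsv_samples_by_taxa") -> FeatureTable:
    """Read a feature table from TSV (either orientation) or BIOM-JSON.

    The numeric space is auto-detected from row sums: rows summing to 1
    (within ``RELATIVE_ROW_SUM_TOL``) are tagged relative, otherwise counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    if dialect not in ("tsv_samples_by_taxa", "tsv_taxa_by_samples"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dialect == "tsv_taxa_by_samples":
        df = df.T
    return feature_table_from_frame(df)


def feature_table_from_frame(df: pd.DataFrame) -> FeatureTable:
    """Build a validated FeatureTable from a samples x taxa DataFrame."""
    dup = _duplicates(map(str, df.index))
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)}")
    bad: list[str] = []
    taxa: list[TaxonomyString] = []
    for col in df.columns:
        try:
            taxa.append(TaxonomyString.parse(str(col)))
        except TaxonomyError:
            bad.append(str(col))
    if bad:
        raise TaxonomyError(f"unparseable taxonomy labels: {bad}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundance values in table")
    sums = values.sum(axis=1)
    relative = bool(np.all(np.abs(sums - 1.0) <= RELATIVE_ROW_SUM_TOL))
    if relative:
        values = values / sums[:, None]  # exact re-closure
    return FeatureTable(
        [str(s) for s in df.index], taxa, values, "relative" if relative else "counts"
    )


def _read_biom_json(path: Path) -> FeatureTable:
    # minimal BIOM v1.0 support: dense or sparse OTU tables, taxa in rows
    doc = json.loads(path.read_text())
    n_rows, n_cols = doc["shape"]
    data = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            data[int(r), int(c)] = v
    else:
        data = np.asarray(doc["data"], dtype=float)
    taxa_labels = []
    for row in doc["rows"]:
        md = row.get("metadata") or {}
        tax = md.get("taxonomy")
        taxa_labels.append(";".join(tax) if tax else row["id"])
    sample_ids = [c["id"] for c in doc["columns"]]
    df = pd.DataFrame(data.T, index=sample_ids, columns=taxa_labels)
    return feature_table_from_frame(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, sep="\t")
    return path


METADATA_COLUMNS = [
    "sample_id", "subject_id", "role", "donor_id", "cohort_id",
    "days_post_fmt", "age", "sex", "weight", "outcome",
]


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        kwargs = {}
        for col in METADATA_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col]
        if "days_post_fmt" in kwargs:
            kwargs["days_post_fmt"] = int(kwargs["days_post_fmt"])
        if "outcome" in kwargs:
            kwargs["outcome"] = int(kwargs["outcome"])
        if "donor_id" in kwargs:
            kwargs["donor_id"] = str(kwargs["donor_id"])
        md = SampleMetadata(**kwargs)
        if md.sample_id in out:
            raise ValueError(f"duplicate metadata row for sample {md.sample_id!r}")
        out[md.sample_id] = md
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [dataclasses.asdict(m) for m in metadata.values()]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def align_union(tables: Sequence[FeatureTable]) -> list[FeatureTable]:
    """Zero-pad every table onto the union taxon axis (lexicographic order).

    Padded columns are all-zero, so relative rows keep their row sums; the
    operation is idempotent and insensitive to the order of the inputs.
    """
    if not tables:
        raise ValueError("need at least one table")
    tags = {t.space_tag for t in tables}
    if len(tags) > 1:
        raise ValueError(f"conflicting space_tags: {sorted(tags)}")
    union = sorted({str(t) for tab in tables for t in tab.taxa})
    taxa = [TaxonomyString.parse(t) for t in union]
    out = []
    for tab in tables:
        pos = {str(t): j for j, t in enumerate(tab.taxa)}
        values = np.zeros((tab.n_samples, len(union)))
        for j, name in enumerate(union):
            if name in pos:
                values[:, j] = tab.values[:, pos[name]]
        out.append(FeatureTable(list(tab.sample_ids), list(taxa), values, tab.space_tag))
    return out


def write_results(obj, path: str | Path, format: str = "json") -> Path:
    """Serialize a result object: JSON for records, TSV for DataFrames."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        if isinstance(obj, FeatureTable):
            obj = obj.to_frame()
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, TaxonomyString):
        return str(obj)
    return obj
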