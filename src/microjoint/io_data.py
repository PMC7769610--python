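"""Reading, validation and assembly of joint microbiome/event datasets.

The pipeline starts at a taxa-by-samples count table (the output of an
amplicon or shotgun profiling workflow), per-sample metadata giving the
subject, collection time and covariates, and a per-subject event table
with right-censored event times.  The central assembled object is a
:class:`JointDataset`: one focal taxon's count series aligned with each
subject's event record, with longitudinal observations collected after a
subject's event time removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._formula import Formula

__all__ = [
    "TaxonCountTable", "SampleMetadata", "EventRecord", "TaxonSeries",
    "JointDataset", "read_count_table", "write_count_table",
    "read_sample_metadata", "read_event_table", "collapse_taxa",
    "extract_taxon_series", "assemble_joint_dataset",
]

logger = logging.getLogger("microjoint")

#: recognised taxonomic ranks, outermost first
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: greengenes-style rank prefixes, stripped on parsing ("g__Prevotella")
_RANK_PREFIXES = tuple(f"{r[0]}__" for r in RANKS)


@dataclass
class TaxonCountTable:
    """Taxa x samples matrix of sequence read counts.

    Library sizes C_ij are the *column sums* — the total reads in a
    sample across all taxa — and are what the longitudinal submodel uses
    as its offset.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match taxon/sample ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = np.argwhere((self.counts < 0)
                          | (self.counts != np.floor(self.counts)))
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"count for taxon {self.taxon_ids[i]!r}, sample "
                f"{self.sample_ids[j]!r} is {self.counts[i, j]!r}: counts "
                "must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if np.any(self.library_sizes <= 0):
            empty = [s for s, c in zip(self.sample_ids, self.library_sizes)
                     if c <= 0]
            raise ValueError(f"samples with zero total reads: {empty}")

    @property
    def library_sizes(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids,
                            columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject, collection time, fixed covariates."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "time")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata is missing columns {missing}")
        f = self.frame.copy()
        f["sample_id"] = f["sample_id"].astype(str)
        f["subject_id"] = f["subject_id"].astype(str)
        f["time"] = f["time"].astype(float)
        if f["sample_id"].duplicated().any():
            raise ValueError("metadata sample_id values must be unique")
        if not np.all(np.isfinite(f["time"])) or (f["time"] < 0).any():
            raise ValueError("sample times must be finite and >= 0")
        self.frame = f.reset_index(drop=True)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.REQUIRED]


@dataclass
class EventRecord:
    """One subject's (possibly censored) event outcome."""

    subject_id: str
    event_time: float
    status: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.event_time) and self.event_time > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: event_time must be finite > 0")
        if self.status not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: status must be 0 or 1")


@dataclass
class TaxonSeries:
    """One taxon's longitudinal counts with designs, sorted by (subject, time).

    ``frame`` columns: ``subject_id``, ``sample_id``, ``time``, ``y``
    (focal-taxon reads), ``C`` (library size) plus covariates; the fixed
    and random design matrices are built from ``formula`` and kept
    aligned with the rows.
    """

    frame: pd.DataFrame
    formula: Formula
    design_fixed: np.ndarray = field(default=None, repr=False)
    design_random: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if isinstance(self.formula, str):
            self.formula = Formula.parse(self.formula)
        order = np.lexsort((f["time"].to_numpy(), f["subject_id"].to_numpy()))
        if not np.array_equal(order, np.arange(len(f))):
            f = f.iloc[order]
        dup = f.duplicated(subset=["subject_id", "time"])
        if dup.any():
            logger.warning("%d replicate samples at identical (subject, time); "
                           "kept in input order", int(dup.sum()))
        self.frame = f.reset_index(drop=True)
        y = self.frame["y"].to_numpy()
        C = self.frame["C"].to_numpy()
        if np.any(C <= 0):
            raise ValueError("library sizes must be > 0")
        if np.any(y < 0) or np.any(y > C):
            raise ValueError("counts must satisfy 0 <= y <= C (library size)")
        if self.design_fixed is None or self.design_random is None:
            X, Z = self.formula.build_design(self.frame)
            self.design_fixed, self.design_random = X, Z
        else:
            self.design_fixed = np.asarray(self.design_fixed, dtype=float)
            self.design_random = np.asarray(self.design_random, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=np.int64)

    @property
    def C(self) -> np.ndarray:
        return self.frame["C"].to_numpy(dtype=np.int64)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def subject_covariates(self, subject_id: str) -> dict:
        """Time-independent covariate values for one subject."""
        sub = self.frame[self.frame["subject_id"] == subject_id]
        if sub.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        out = {}
        for name in self.formula.covariate_names:
            vals = sub[name].to_numpy(dtype=float)
            if not np.all(vals == vals[0]):
                raise ValueError(
                    f"covariate {name!r} varies within subject "
                    f"{subject_id!r}; hazard evaluation requires "
                    "time-independent covariates")
            out[name] = float(vals[0])
        return out


@dataclass
class JointDataset:
    """Aligned longitudinal series and event records."""

    series: TaxonSeries
    events: list[EventRecord]

    def __post_init__(self) -> None:
        by_subj = {e.subject_id: e for e in self.events}
        if len(by_subj) != len(self.events):
            raise ValueError("duplicate subject ids in event records")
        series_subjects = set(self.series.subjects())
        missing = sorted(series_subjects - set(by_subj))
        if missing:
            raise ValueError(f"subjects missing an event record: {missing}")
        extra = sorted(set(by_subj) - series_subjects)
        if extra:
            raise ValueError(f"event records without longitudinal data: {extra}")
        t = self.series.time
        T = np.array([by_subj[s].event_time for s in self.series.subject_ids])
        if np.any(t > T + 1e-12):
            raise ValueError(
                "longitudinal observations after a subject's event time; "
                "use assemble_joint_dataset to trim them")

    def events_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": e.subject_id, "event_time": e.event_time,
                 "status": e.status, **e.covariates} for e in self.events]
        return pd.DataFrame(rows)

    @property
    def n_subjects(self) -> int:
        return len(self.events)


def read_count_table(path, format: str = "tsv") -> TaxonCountTable:
    """Read a taxa-by-samples count TSV (plain or BIOM-style dense TSV).

    The first column is the taxon id; an optional ``taxonomy`` column
    (semicolon-ranked lineage) is split off into the table's taxonomy map.
    BIOM-style tables may start with ``#``-prefixed comment lines and an
    ``#OTU ID`` header.
    """
    if format not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown count-table format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # drop BIOM comment lines such as "# Constructed from biom file"
    lines = [ln for ln in lines
             if ln.strip() and not (ln.startswith("#") and not
                                    ln.lower().startswith("#otu"))]
    if not lines:
        raise ValueError(f"no taxa parsed from {path}")
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    taxonomy = None
    tax_cols = [c for c in df.columns if c.lower() in ("taxonomy", "lineage")]
    if tax_cols:
        taxonomy = {str(t): [p.strip() for p in str(v).split(";")]
                    for t, v in df[tax_cols[0]].items()}
        df = df.drop(columns=tax_cols)
    if df.empty or not len(df.columns):
        raise ValueError(f"no taxa parsed from {path}")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c])
                          for c in df.columns]]
        raise ValueError(f"non-numeric counts in columns {list(bad)}")
    return TaxonCountTable(taxon_ids=[str(t) for t in df.index],
                           sample_ids=[str(c) for c in df.columns],
                           counts=counts, taxonomy=taxonomy)


def write_count_table(table: TaxonCountTable, path) -> None:
    """Write a count table as TSV (taxonomy, if present, as a last column)."""
    df = table.to_frame()
    if table.taxonomy is not None:
        df["taxonomy"] = [";".join(table.taxonomy.get(t, []))
                          for t in table.taxon_ids]
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_sample_metadata(path) -> SampleMetadata:
    """Read per-sample metadata CSV (``sample_id``, ``subject_id``, ``time`` + covariates)."""
    return SampleMetadata(pd.read_csv(path))


def read_event_table(path) -> list[EventRecord]:
    """Read a per-subject event CSV (``subject_id``, ``event_time``, ``status`` + covariates)."""
    df = pd.read_csv(path)
    required = ("subject_id", "event_time", "status")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    covars = [c for c in df.columns if c not in required]
    return [EventRecord(subject_id=str(r.subject_id),
                        event_time=float(r.event_time),
                        status=int(r.status),
                        covariates={c: float(getattr(r, c)) for c in covars})
            for r in df.itertuples(index=False)]


def _rank_label(lineage: list[str], rank_index: int) -> str:
    if rank_index < len(lineage):
        label = lineage[rank_index].strip()
        for pref in _RANK_PREFIXES:
            if label.startswith(pref):
                label = label[len(pref):]
        if label:
            return label
    return "unclassified"


def collapse_taxa(table: TaxonCountTable, rank: str) -> TaxonCountTable:
    """Sum counts over all taxa sharing a rank label (e.g. genus).

    Library sizes are unchanged by construction.  Taxa whose lineage does
    not resolve at ``rank`` are pooled under ``"unclassified"`` with a
    logged warning.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.taxonomy is None:
        raise ValueError("count table has no taxonomy; cannot collapse")
    idx = RANKS.index(rank)
    labels = []
    n_unclassified = 0
    for t in table.taxon_ids:
        lab = _rank_label(table.taxonomy.get(t, []), idx)
        if lab == "unclassified":
            n_unclassified += 1
        labels.append(lab)
    if n_unclassified:
        logger.warning("%d taxa lacked a %s label; grouped as 'unclassified'",
                       n_unclassified, rank)
    order = list(dict.fromkeys(labels))
    counts = np.zeros((len(order), len(table.sample_ids)), dtype=np.int64)
    for lab, row in zip(labels, table.counts):
        counts[order.index(lab)] += row
    return TaxonCountTable(taxon_ids=order, sample_ids=list(table.sample_ids),
                           counts=counts, taxonomy=None)


def extract_taxon_series(table: TaxonCountTable, taxon_id: str,
                         metadata: SampleMetadata,
                         formula: str | Formula) -> TaxonSeries:
    """Pull one taxon's counts into a modelling-ready series.

    ``y`` is the focal taxon's row; the library size ``C`` is the column
    sum of the *full* table, not the focal taxon.
    """
    if taxon_id not in table.taxon_ids:
        raise KeyError(f"taxon {taxon_id!r} not present in the count table")
    meta = metadata.frame.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    row = table.counts[table.taxon_ids.index(taxon_id)]
    frame = pd.DataFrame({
        "sample_id": table.sample_ids,
        "subject_id": meta.loc[table.sample_ids, "subject_id"].to_numpy(),
        "time": meta.loc[table.sample_ids, "time"].to_numpy(dtype=float),
        "y": row,
        "C": table.library_sizes,
    })
    for c in metadata.covariate_columns:
        frame[c] = meta.loc[table.sample_ids, c].to_numpy()
    return TaxonSeries(frame=frame, formula=formula)


def assemble_joint_dataset(series: TaxonSeries, events: list[EventRecord],
                           empty_subjects: str = "error") -> JointDataset:
    """Align a taxon series with event records.

    Longitudinal rows observed after a subject's event time are removed
    (the abundance path is only usable while the subject is event-free).
    ``empty_subjects`` controls what happens to subjects whose rows are
    all removed: ``"error"`` (default) or ``"drop"`` (remove the subject
    from both tables, logging the count — used by the simulator).
    """
    if empty_subjects not in ("error", "drop"):
        raise ValueError("empty_subjects must be 'error' or 'drop'")
    by_subj = {e.subject_id: e for e in events}
    series_subjects = set(series.subjects())
    missing = sorted(series_subjects - set(by_subj))
    if missing:
        raise ValueError(f"subjects missing an event record: {missing}")
    extra = sorted(set(by_subj) - series_subjects)
    if extra:
        raise ValueError(f"event records without longitudinal data: {extra}")

    T = np.array([by_subj[s].event_time for s in series.subject_ids])
    keep = series.time <= T
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("removed %d longitudinal observations after event times",
                    n_dropped)
    frame = series.frame[keep]
    kept_subjects = set(frame["subject_id"])
    lost = sorted(series_subjects - kept_subjects)
    if lost:
        if empty_subjects == "error":
            raise ValueError(
                f"subjects with no longitudinal data before their event "
                f"time: {lost} (model unidentifiable for these subjects)")
        logger.info("dropped %d subjects with no pre-event observations", len(lost))
    events_kept = [e for e in events if e.subject_id in kept_subjects]
    trimmed = TaxonSeries(frame=frame.reset_index(drop=True),
                          formula=series.formula)
    return JointDataset(series=trimmed, events=events_kept)
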