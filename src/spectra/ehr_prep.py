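"""EHR preparation: collapse raw diagnosis codes into primary diagnosis
clusters and build the person x diagnosis lifetime indicator matrix.

Raw EHR extracts carry one row per diagnosis event (person, raw code, date);
many raw codes denote essentially the same condition, so a cluster map sends
each raw code to a primary diagnosis label.  Lifetime operationalization: a
person scores 1 on a diagnosis iff at least one event ever maps to it; dates
are ignored.  The cohort filter keeps persons with at least one diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ClusterMap", "BinaryDiagnosisMatrix", "collapse_codes", "filter_cohort"]

EVENT_COLUMNS = ["person_id", "raw_code", "event_date"]


@dataclass(frozen=True)
class ClusterMap:
    """Mapping raw_code -> (diagnosis label, 0-based diagnosis index)."""

    raw_to_label: dict[str, str]
    labels: list[str]

    def __post_init__(self) -> None:
        index = {lab: i for i, lab in enumerate(self.labels)}
        if len(index) != len(self.labels):
            raise ValueError("duplicate diagnosis labels in cluster map")
        for code, lab in self.raw_to_label.items():
            if lab not in index:
                raise ValueError(f"code {code!r} maps to unknown label {lab!r}")

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterMap":
        """Build from a two-column frame (raw_code, diagnosis_label).

        Label index order follows first appearance.  Duplicate raw codes are
        an error (a code must map to exactly one cluster).
        """
        codes = df["raw_code"].astype(str)
        if codes.duplicated().any():
            dups = sorted(codes[codes.duplicated()].unique())
            raise ValueError(f"duplicate raw_code entries in cluster map: {dups}")
        labels = list(pd.unique(df["diagnosis_label"].astype(str)))
        return cls(raw_to_label=dict(zip(codes, df["diagnosis_label"].astype(str))),
                   labels=labels)

    @classmethod
    def read_tsv(cls, path) -> "ClusterMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_code": list(self.raw_to_label),
             "diagnosis_label": list(self.raw_to_label.values())}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class BinaryDiagnosisMatrix:
    """Persons x diagnoses 0/1 lifetime indicators."""

    person_ids: np.ndarray
    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.person_ids = np.asarray(self.person_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.person_ids), len(self.labels)):
            raise ValueError("matrix shape does not match ids/labels")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def prevalence(self) -> pd.Series:
        return pd.Series(self.values.mean(axis=0) if self.n_persons else
                         np.full(len(self.labels), np.nan),
                         index=self.labels, name="prevalence")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "person_id", self.person_ids)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BinaryDiagnosisMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = [c for c in df.columns if c != "person_id"]
        return cls(person_ids=df["person_id"].astype(str).to_numpy(),
                   labels=labels, values=df[labels].to_numpy())

    def subset_persons(self, index: np.ndarray) -> "BinaryDiagnosisMatrix":
        return BinaryDiagnosisMatrix(
            person_ids=self.person_ids[index], labels=list(self.labels),
            values=self.values[index], meta=dict(self.meta),
        )

    def subset_diagnoses(self, labels: list[str]) -> "BinaryDiagnosisMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return BinaryDiagnosisMatrix(
            person_ids=self.person_ids, labels=list(labels),
            values=self.values[:, idx], meta=dict(self.meta),
        )


def collapse_codes(events: pd.DataFrame, cmap: ClusterMap) -> BinaryDiagnosisMatrix:
    """Collapse raw-coded events into the person x diagnosis 0/1 matrix.

    A person gets 1 for a diagnosis iff at least one of their events maps to
    it (lifetime, date-agnostic).  Unmapped codes are counted and reported in
    ``meta['unmapped']``, never silently dropped.  Persons are ordered by
    sorted person id; columns follow the cluster map's index order.
    """
    if events.empty:
        return BinaryDiagnosisMatrix(
            person_ids=np.array([], dtype=str), labels=list(cmap.labels),
            values=np.zeros((0, len(cmap.labels)), dtype=np.int8),
            meta={"unmapped": {}, "n_events": 0},
        )
    codes = events["raw_code"].astype(str)
    mapped_label = codes.map(cmap.raw_to_label)
    unmapped_mask = mapped_label.isna()
    unmapped = codes[unmapped_mask].value_counts().to_dict()
    if unmapped:
        logger.warning("%d events with %d unmapped codes: %s",
                       int(unmapped_mask.sum()), len(unmapped),
                       sorted(unmapped)[:10])
    if unmapped_mask.all():
        raise ValueError("cluster map covers none of the event codes")

    persons = np.array(sorted(events["person_id"].astype(str).unique()))
    pidx = {p: i for i, p in enumerate(persons)}
    lidx = cmap.label_index
    rows = events["person_id"].astype(str).map(pidx).to_numpy()[~unmapped_mask.to_numpy()]
    cols = mapped_label[~unmapped_mask].map(lidx).to_numpy(dtype=int)
    values = np.zeros((len(persons), len(cmap.labels)), dtype=np.int8)
    values[rows, cols] = 1
    return BinaryDiagnosisMatrix(
        person_ids=persons, labels=list(cmap.labels), values=values,
        meta={"unmapped": unmapped, "n_events": int(len(events))},
    )


def filter_cohort(m: BinaryDiagnosisMatrix) -> BinaryDiagnosisMatrix:
    """Keep persons with at least one recorded diagnosis; preserve order."""
    keep = m.values.sum(axis=1) >= 1
    removed = int((~keep).sum())
    if removed:
        logger.info("cohort filter removed %d persons with no diagnosis", removed)
    out = m.subset_persons(np.flatnonzero(keep))
    out.meta["removed_no_diagnosis"] = removed
    return out
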