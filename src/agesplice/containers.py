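"""Core in-memory containers shared across the pipeline.

Matrices follow the SUPPA convention: rows are features (splicing events,
genes, transcripts), columns are samples, and ``-1`` marks cells where the
feature could not be quantified because the gene is not expressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Sentinel for unquantifiable PSI / ratio cells.
SENTINEL = -1.0

#: Event identifiers look like ``GENE;SE:chr1:100-200:300-400:+``.
EVENT_ID_RE = re.compile(
    r"^(?P<gene>[^;]+);(?P<event_type>[A-Z0-9]+):(?P<chrom>[^:]+):"
    r"(?P<coords>\d+-\d+(?::\d+-\d+)*):(?P<strand>[+-])$"
)

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


def parse_event_id(event_id: str) -> Optional[dict[str, str]]:
    """Split a SUPPA-style event ID into gene/type/coordinates/strand.

    Returns ``None`` for identifiers that do not follow the convention;
    such IDs are kept opaque.
    """
    m = EVENT_ID_RE.match(event_id)
    return m.groupdict() if m else None


@dataclass
class Cohort:
    """Donors of one tissue: one sample per donor.

    ``table`` is indexed by sample ID with columns ``donor_id``, ``age``
    (years), ``gender`` (0/1) and optionally ``disease`` (0/1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"donor_id", "age", "gender"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if self.table["donor_id"].duplicated().any():
            raise ValueError("duplicate donor_id in cohort")
        if not self.table["gender"].isin([0, 1]).all():
            raise ValueError("gender must be coded 0/1")
        if "disease" in self.table.columns:
            d = self.table["disease"].dropna()
            if not d.isin([0, 1]).all():
                raise ValueError("disease must be coded 0/1 when present")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def ages(self) -> pd.Series:
        return self.table["age"]

    @property
    def genders(self) -> pd.Series:
        return self.table["gender"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PsiMatrix:
    """Events x samples PSI values in [0, 1] with ``-1`` sentinels."""

    values: pd.DataFrame
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        ok = ((v >= 0.0) & (v <= 1.0)) | (v == SENTINEL)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"PSI value {v[i, j]!r} out of [0,1] and != -1 at event "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate event IDs: {dups[:5]}")
        if self.annotations is None:
            parsed = {
                eid: p for eid in self.values.index
                if (p := parse_event_id(eid)) is not None
            }
            if parsed:
                self.annotations = pd.DataFrame.from_dict(parsed, orient="index")
                self.annotations = self.annotations.reindex(self.values.index)

    @property
    def event_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def event_to_gene(self) -> pd.Series:
        """Map event IDs to gene names where the ID is parseable, else to itself."""
        if self.annotations is None or "gene" not in self.annotations:
            return pd.Series(self.values.index, index=self.values.index)
        genes = self.annotations["gene"]
        return genes.fillna(pd.Series(self.values.index, index=self.values.index))


@dataclass
class GroundTruth:
    """What the generator planted, for benchmarking downstream stages."""

    events: Optional[pd.DataFrame] = None          # is_age_assoc, beta_age, trend_class, gene
    factor_loadings: Optional[np.ndarray] = None   # events x factors
    factors: Optional[np.ndarray] = None           # factors x samples
    genes: Optional[pd.DataFrame] = None           # is_age_assoc, beta_age, is_switch
    transcripts: Optional[pd.DataFrame] = None     # gene, age_trend
    driver: Optional[dict] = None                  # motif_id, region, trend_class, sf_gene, sf_slope
    disease_coefs: Optional[dict] = None

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for name in self.__dataclass_fields__:
            a, b = getattr(self, name), getattr(other, name)
            setattr(out, name, b if b is not None else a)
        return out
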