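"""Readers and writers for every interchange format.

Matrices travel as tab-delimited text (SUPPA dialect for PSI: ``-1`` marks
unquantifiable cells), phenotypes as a TSV keyed by sample ID, cassette-exon
region sequences as FASTA with ``eventID|regionName`` headers, motif tables
as TSV, and models / ground truth / manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SimulationConfig
from .containers import SENTINEL, Cohort, GroundTruth, PsiMatrix
from .motifs import MotifRecord
from .regions import EventRegions

PathLike = Union[str, Path]

_FLOAT_FMT = "%.10g"


class PsiParseError(ValueError):
    """A PSI table cell failed validation."""


def write_psi_table(psi: PsiMatrix, path: PathLike) -> None:
    psi.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                      index_label="event_id")


def read_psi_table(path: PathLike) -> PsiMatrix:
    """Read a SUPPA-style PSI TSV, validating every cell to [0,1] or -1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise PsiParseError(f"duplicate event IDs in {path}: {dups[:5]}")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise PsiParseError(f"non-numeric PSI cell in {path}: {exc}") from exc
    ok = ((values >= 0.0) & (values <= 1.0)) | (values == SENTINEL)
    ok &= np.isfinite(values)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise PsiParseError(
            f"PSI value {values[i, j]!r} outside [0,1] and != -1 at "
            f"event {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    return PsiMatrix(pd.DataFrame(values, index=df.index, columns=df.columns))


def write_expression_table(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotype_table(cohort: Cohort, path: PathLike) -> None:
    cohort.table.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                        index_label="sample_id")


def read_phenotype_table(path: PathLike) -> Cohort:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    return Cohort(table)


def write_regions_fasta(regions: Mapping[str, EventRegions], path: PathLike) -> None:
    records = []
    for event_id in regions:
        ev = regions[event_id]
        for region, seq in ev.sequences.items():
            records.append(
                SeqRecord(Seq(seq), id=f"{event_id}|{region}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_regions_fasta(path: PathLike) -> dict[str, EventRegions]:
    raw: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"region FASTA header {rec.id!r} lacks the 'eventID|regionName' form"
            )
        event_id, region = rec.id.rsplit("|", 1)
        raw.setdefault(event_id, {})[region] = str(rec.seq).upper()
    return {eid: EventRegions(eid, seqs) for eid, seqs in raw.items()}


def write_motif_table(motifs: list[MotifRecord], path: PathLike) -> None:
    pd.DataFrame(
        [(m.motif_id, m.sf_gene, m.consensus) for m in motifs],
        columns=["motif_id", "sf_gene", "consensus"],
    ).to_csv(path, sep="\t", index=False)


def read_motif_table(path: PathLike) -> list[MotifRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"motif_id", "sf_gene", "consensus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"motif table missing columns {sorted(missing)}")
    return [
        MotifRecord(str(r.motif_id), str(r.sf_gene), str(r.consensus))
        for r in df.itertuples()
    ]


def write_results_table(results: pd.DataFrame, path: PathLike) -> None:
    results.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                   index_label=results.index.name or "feature_id")


def read_results_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload: dict = {}
    if truth.events is not None:
        payload["events"] = truth.events.reset_index().to_dict(orient="list")
    if truth.genes is not None:
        payload["genes"] = truth.genes.reset_index().to_dict(orient="list")
    if truth.driver is not None:
        payload["driver"] = truth.driver
    if truth.disease_coefs is not None:
        payload["disease_coefs"] = truth.disease_coefs
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)


def write_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def read_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_newick(newick: str, path: PathLike) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def load_yaml_config(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must hold a mapping")
    return data


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    kwargs = dict(data)
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    if "planted_driver" in kwargs and kwargs["planted_driver"] is not None:
        kwargs["planted_driver"] = tuple(kwargs["planted_driver"])
    if "motif_set" in kwargs:
        kwargs["motif_set"] = tuple(
            MotifRecord(*m) if not isinstance(m, MotifRecord) else m
            for m in kwargs["motif_set"]
        )
    if "region_lengths" in kwargs and kwargs["region_lengths"] is not None:
        kwargs["region_lengths"] = dict(kwargs["region_lengths"])
    return SimulationConfig(**kwargs)
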