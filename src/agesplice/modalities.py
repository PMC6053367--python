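"""Gene, transcript and transcript-ratio age scans, and modality comparison.

The three expression-level scans reuse the splicing detection machinery: the
response is the (log2-transformed) gene or transcript expression, or the
within-gene transcript ratio TR = T_x / sum_x T_x, and the hidden-factor
covariates are re-estimated from the matching matrix (gene-derived factors
for the gene scan, transcript-derived factors for the transcript and ratio
scans).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .association import scan_features
from .containers import SENTINEL

MODALITIES = ("psi", "gene", "transcript", "ratio")


def compute_transcript_ratios(
    transcript_matrix: pd.DataFrame, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Within-gene transcript ratios; zero-total gene-sample cells -> sentinel."""
    tx2gene = pd.Series(tx2gene)
    unmapped = transcript_matrix.index.difference(tx2gene.index)
    if len(unmapped):
        raise ValueError(
            f"transcripts without a gene mapping: {list(unmapped)[:5]}"
        )
    genes = tx2gene.loc[transcript_matrix.index]
    totals = transcript_matrix.groupby(genes.to_numpy(), sort=False).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = transcript_matrix / totals
    ratios = ratios.where(totals > 0, SENTINEL)
    return ratios


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) variance-stabilization for TPM-like expression."""
    return np.log2(matrix + 1.0)


def run_modality_scan(
    modality: str,
    phenotypes: pd.DataFrame,
    psi: Optional[pd.DataFrame] = None,
    gene_expr: Optional[pd.DataFrame] = None,
    tx_expr: Optional[pd.DataFrame] = None,
    tx2gene: Optional[Mapping[str, str]] = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """Run the age-association scan for one modality.

    ``psi`` passes the PSI matrix through unchanged; ``gene`` and
    ``transcript`` fit log2(x+1) expression; ``ratio`` fits within-gene
    transcript ratios with transcript-derived confounders.
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
    if modality == "psi":
        if psi is None:
            raise ValueError("psi matrix required for modality 'psi'")
        return scan_features(psi, phenotypes, **scan_kwargs)
    if modality == "gene":
        if gene_expr is None:
            raise ValueError("gene matrix required for modality 'gene'")
        return scan_features(log2_transform(gene_expr), phenotypes, **scan_kwargs)
    if tx_expr is None:
        raise ValueError(f"transcript matrix required for modality {modality!r}")
    log_tx = log2_transform(tx_expr)
    if modality == "transcript":
        return scan_features(log_tx, phenotypes, **scan_kwargs)
    if tx2gene is None:
        raise ValueError("tx2gene mapping required for modality 'ratio'")
    ratios = compute_transcript_ratios(tx_expr, tx2gene)
    return scan_features(ratios, phenotypes, factor_matrix=log_tx, **scan_kwargs)


@dataclass
class ModalityOverlap:
    """Gene-set overlap structure across the four detection modalities."""

    gene_sets: dict[str, frozenset]
    intersections: dict[tuple[str, ...], int]
    unique_genes: dict[str, frozenset]

    def membership_table(self) -> pd.DataFrame:
        genes = sorted(set().union(*self.gene_sets.values())) if self.gene_sets else []
        return pd.DataFrame(
            {m: [g in s for g in genes] for m, s in self.gene_sets.items()},
            index=pd.Index(genes, name="gene"),
        )


def significant_genes(
    results: pd.DataFrame, feature_to_gene: Optional[Mapping[str, str]] = None
) -> frozenset:
    """Genes with at least one significant feature in a scan result table."""
    sig = results.index[results["significant"]]
    if feature_to_gene is None:
        return frozenset(sig)
    m = pd.Series(feature_to_gene)
    return frozenset(m.reindex(sig).dropna())


def modality_overlap(
    gene_sets: Mapping[str, frozenset | set],
) -> ModalityOverlap:
    """All pairwise and higher-order intersection counts plus per-modality uniques."""
    sets = {name: frozenset(s) for name, s in gene_sets.items()}
    names = list(sets)
    intersections: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = frozenset.intersection(*(sets[c] for c in combo))
            intersections[combo] = len(inter)
    unique = {}
    for name in names:
        others = [sets[o] for o in names if o != name]
        unique[name] = sets[name] - frozenset().union(*others) if others else sets[name]
    return ModalityOverlap(sets, intersections, unique)
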