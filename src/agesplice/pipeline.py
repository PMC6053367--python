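"""End-to-end orchestration: from inputs (or the synthetic generator) to
result tables, with a reproducibility manifest.

Every stage is seeded from the pipeline seed, so two runs with the same
configuration produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .config import SimulationConfig
from .containers import Cohort, PsiMatrix
from .crosstissue import tissue_similarity
from .disease import nested_llr_test
from .drivers import classify_trend, count_matrix, identify_drivers, motif_enrichment_scan
from .modalities import modality_overlap, run_modality_scan, significant_genes
from .prediction import build_age_model, cv_age_prediction, mds_reduce, select_robust_events
from .simulate import simulate_dataset

logger = logging.getLogger("agesplice")


@dataclass
class PipelineConfig:
    """Thresholds, sizes and inputs of a full pipeline run.

    Either ``simulation`` (synthetic mode; ``n_tissues`` datasets are
    generated with per-tissue seeds) or ``psi_path`` + ``phenotype_path``
    must be provided.
    """

    # detection thresholds (tissue-level scan)
    fdr: float = 0.05
    perm_threshold: float = 0.05
    n_perm: int = 1000
    n_factors: int = 20
    min_samples: int = 50
    driver_fdr: float = 0.1
    stable_p_floor: float = 0.5
    # prediction / disease settings
    age_components: int = 30
    disease_components: int = 100
    cv_repeats: int = 100
    cv_folds: int = 10
    robust_runs: int = 10
    robust_min_detections: int = 8
    # modality toggles
    run_modalities: bool = True
    run_similarity: bool = True
    run_prediction: bool = True
    run_drivers: bool = True
    run_disease: bool = True
    # inputs
    simulation: Optional[SimulationConfig] = None
    n_tissues: int = 2
    psi_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    gene_path: Optional[str] = None
    transcript_path: Optional[str] = None
    regions_path: Optional[str] = None
    motif_path: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        for name in ("fdr", "perm_threshold", "driver_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                errs.append(f"{name} must be in (0, 1]")
        if self.min_samples < 2:
            errs.append("min_samples must be >= 2")
        if self.n_perm < 1:
            errs.append("n_perm must be >= 1")
        if self.simulation is None and (self.psi_path is None or self.phenotype_path is None):
            errs.append("either a simulation config or psi_path + phenotype_path is required")
        for name in ("psi_path", "phenotype_path", "gene_path",
                     "transcript_path", "regions_path", "motif_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errs.append(f"{name} does not exist: {p}")
        if errs:
            raise ValueError("invalid PipelineConfig: " + "; ".join(errs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["motif_set"] = [list(m) for m in
                                ((x.motif_id, x.sf_gene, x.consensus)
                                 for x in self.simulation.motif_set)]
            d["simulation"] = sim
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    scan_results: dict[str, pd.DataFrame] = field(default_factory=dict)


def _scan_kwargs(config: PipelineConfig, n_samples: int) -> dict:
    return {
        "n_factors": min(config.n_factors, max(1, n_samples - 2)),
        "n_perm": config.n_perm,
        "min_samples": config.min_samples,
        "fdr_threshold": config.fdr,
        "perm_threshold": config.perm_threshold,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every configured stage, writing result files and a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages_completed": stages,
        "thresholds_applied": {
            "fdr": config.fdr,
            "perm_threshold": config.perm_threshold,
            "n_perm": config.n_perm,
            "n_factors": config.n_factors,
            "min_samples": config.min_samples,
            "driver_fdr": config.driver_fdr,
        },
    }

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- inputs -----------------------------------------------------------
    tissues: dict[str, dict] = {}
    if config.simulation is not None:
        stage = "simulate"
        try:
            input_dir = out / "inputs"
            input_dir.mkdir(exist_ok=True)
            for t in range(config.n_tissues):
                sim = dataclasses.replace(
                    config.simulation,
                    seed=int(np.random.SeedSequence(
                        [config.seed, config.simulation.seed, t]
                    ).generate_state(1)[0] % (2**31 - 1)),
                )
                ds = simulate_dataset(sim)
                name = f"tissue{t + 1}"
                tissues[name] = {
                    "psi": ds.psi, "cohort": ds.cohort, "gene": ds.gene_expr,
                    "tx": ds.tx_expr, "tx2gene": ds.tx2gene,
                    "regions": ds.regions, "sf": ds.sf_expr, "truth": ds.truth,
                }
                io.write_psi_table(ds.psi, input_dir / f"{name}_psi.tsv")
                io.write_phenotype_table(ds.cohort, input_dir / f"{name}_phenotypes.tsv")
                if t == 0:
                    io.write_expression_table(ds.gene_expr, input_dir / f"{name}_gene_tpm.tsv")
                    io.write_expression_table(ds.tx_expr, input_dir / f"{name}_transcript_tpm.tsv")
                    io.write_regions_fasta(ds.regions, input_dir / f"{name}_regions.fa")
                    io.write_expression_table(ds.sf_expr, input_dir / f"{name}_sf_tpm.tsv")
                    io.write_ground_truth(ds.truth, input_dir / f"{name}_truth.json")
            motifs = list(config.simulation.motif_set)
            stages.append(stage)
        except Exception as exc:  # pragma: no cover - defensive
            _fail(stage, exc)
    else:
        stage = "load_inputs"
        try:
            psi = io.read_psi_table(config.psi_path)
            cohort = io.read_phenotype_table(config.phenotype_path)
            entry: dict = {"psi": psi, "cohort": cohort, "truth": None}
            entry["gene"] = (io.read_expression_table(config.gene_path)
                             if config.gene_path else None)
            entry["tx"] = (io.read_expression_table(config.transcript_path)
                           if config.transcript_path else None)
            entry["tx2gene"] = None
            entry["regions"] = (io.read_regions_fasta(config.regions_path)
                                if config.regions_path else None)
            entry["sf"] = None
            tissues["tissue1"] = entry
            motifs = io.read_motif_table(config.motif_path) if config.motif_path else []
            stages.append(stage)
        except Exception as exc:
            _fail(stage, exc)

    first = tissues["tissue1"]
    pheno1: Cohort = first["cohort"]
    n_samples = len(pheno1)
    scan_kwargs = _scan_kwargs(config, n_samples)

    # ---- per-tissue splicing scan ----------------------------------------
    scan_results: dict[str, pd.DataFrame] = {}
    try:
        for name, entry in tissues.items():
            res = run_modality_scan(
                "psi", entry["cohort"].table, psi=entry["psi"].values,
                seed=config.seed, **scan_kwargs,
            )
            scan_results[name] = res
            io.write_results_table(res, out / f"{name}_psi_scan.tsv")
        stages.append("scan")
    except Exception as exc:
        _fail("scan", exc)

    res1 = scan_results["tissue1"]
    psi1: PsiMatrix = first["psi"]
    event_to_gene = psi1.event_to_gene()

    # ---- modality scans + overlap ----------------------------------------
    if config.run_modalities and first.get("gene") is not None and first.get("tx") is not None:
        try:
            tx2gene = first["tx2gene"]
            if tx2gene is None:
                tx2gene = pd.Series(
                    [t.rsplit(".", 1)[0] for t in first["tx"].index],
                    index=first["tx"].index,
                )
            sets = {"splicing": significant_genes(res1, event_to_gene)}
            for modality, mapper in (
                ("gene", None),
                ("transcript", tx2gene),
                ("ratio", tx2gene),
            ):
                res = run_modality_scan(
                    modality, pheno1.table, gene_expr=first["gene"],
                    tx_expr=first["tx"], tx2gene=tx2gene,
                    seed=config.seed, **scan_kwargs,
                )
                io.write_results_table(res, out / f"tissue1_{modality}_scan.tsv")
                sets[modality] = significant_genes(res, mapper)
            overlap = modality_overlap(sets)
            overlap.membership_table().to_csv(out / "modality_overlap.tsv", sep="\t")
            stages.append("modality_scans")
        except Exception as exc:
            _fail("modality_scans", exc)

    # ---- cross-tissue similarity ----------------------------------------
    if config.run_similarity and len(tissues) >= 2:
        try:
            gene_sets = {
                name: significant_genes(scan_results[name],
                                        tissues[name]["psi"].event_to_gene())
                for name in tissues
            }
            sim = tissue_similarity(gene_sets)
            sim.matrix.to_csv(out / "tissue_jaccard.tsv", sep="\t",
                              float_format="%.10g")
            io.write_newick(sim.newick, out / "tissue_tree.nwk")
            stages.append("similarity")
        except Exception as exc:
            _fail("similarity", exc)

    # ---- age prediction ---------------------------------------------------
    if config.run_prediction:
        try:
            k = min(config.age_components, n_samples - 1)
            feats = mds_reduce(psi1.values, k)
            cv = cv_age_prediction(
                feats, pheno1.ages, n_repeats=config.cv_repeats,
                n_folds=config.cv_folds, seed=config.seed,
            )
            io.write_json({"spearman_accuracy": cv.accuracy,
                           "n_components": k,
                           "predictions": cv.predictions.round(6).to_dict()},
                          out / "age_prediction.json")
            robust = select_robust_events(
                psi1.values, pheno1.table, n_runs=config.robust_runs,
                min_detections=config.robust_min_detections,
                seed=config.seed, **scan_kwargs,
            )
            io.write_json({"robust_events": robust}, out / "robust_events.json")
            model_events = robust if robust else list(psi1.values.index)
            model = build_age_model(psi1.values.loc[model_events], pheno1.ages,
                                    n_components=min(k, len(model_events),
                                                     n_samples - 1),
                                    seed=config.seed)
            io.write_json(model.to_dict(), out / "age_model.json")
            stages.append("prediction")
        except Exception as exc:
            _fail("prediction", exc)

    # ---- driver detection -------------------------------------------------
    if config.run_drivers and first.get("regions") and motifs:
        try:
            trend = classify_trend(res1, stable_p_floor=config.stable_p_floor)
            classed = {e: first["regions"][e] for e in trend.index
                       if e in first["regions"]}
            counts = count_matrix(classed, motifs)
            enr = motif_enrichment_scan(counts, trend, motifs, fdr=config.driver_fdr)
            enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            calls_rows = []
            if first.get("sf") is not None:
                calls, untestable = identify_drivers(
                    enr, first["sf"], pheno1.table,
                    enrichment_fdr=config.driver_fdr,
                    min_samples=config.min_samples,
                )
                for c in calls:
                    calls_rows.append({
                        "sf_gene": c.sf_gene,
                        "sf_beta_age": c.sf_beta_age,
                        "sf_p_age": c.sf_p_age,
                        "mechanism": c.mechanism,
                        "motifs": ",".join(c.motif_ids),
                    })
                pd.DataFrame(
                    calls_rows,
                    columns=["sf_gene", "sf_beta_age", "sf_p_age",
                             "mechanism", "motifs"],
                ).to_csv(out / "driver_calls.tsv", sep="\t", index=False,
                         float_format="%.10g")
            stages.append("drivers")
        except Exception as exc:
            _fail("drivers", exc)

    # ---- disease contribution --------------------------------------------
    if config.run_disease and "disease" in pheno1.table.columns \
            and first.get("gene") is not None:
        try:
            labels = pheno1.table["disease"]
            if labels.nunique() == 2:
                sig_events = res1.index[res1["significant"]]
                psi_src = psi1.values.loc[sig_events] if len(sig_events) else psi1.values
                # keep n/df healthy at synthetic scale
                k = min(config.disease_components, max(1, n_samples // 10))
                ge_feats = mds_reduce(np.log2(first["gene"] + 1.0), k)
                psi_feats = mds_reduce(psi_src, min(k, max(1, len(psi_src) - 1)))
                llr = nested_llr_test(labels, pheno1.ages, pheno1.genders,
                                      ge_feats, psi_feats)
                io.write_json(
                    {
                        "llf_null": llr.llf_null, "llf_alt": llr.llf_alt,
                        "llr": llr.llr, "df": llr.df, "p_value": llr.p_value,
                        "family": llr.family, "n": llr.n,
                        "separation": llr.separation, "note": llr.note,
                        "n_significant_events": int(len(sig_events)),
                    },
                    out / "disease_llr.json",
                )
                stages.append("disease_llr")
        except Exception as exc:
            _fail("disease_llr", exc)

    io.write_json(manifest, out / "manifest.json")
    return PipelineResult(outdir=out, manifest=manifest, scan_results=scan_results)
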