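"""End-to-end pipeline: simulate -> qc -> de -> build-db -> score -> report.

One master seed drives every stage; each stage derives an independent
substream from the master seed and its stage name, so runs are
bit-identical under a fixed configuration and adding a stage never
perturbs another's draws. A JSON run manifest records parameters, derived
seeds, input/output checksums and wall-clock per stage — enough to re-run
the analysis identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import expression, qc, scoring, synthetic
from .io_formats import (
    read_cell_annotation,
    read_counts,
    read_gene_annotation,
    read_ppi,
    read_reference_pairs,
    write_table,
)
from .lr_database import build_database, read_database, write_database

__all__ = ["RunConfig", "run_pipeline", "analyze_dataset", "derive_seed"]

__version__ = "0.1.0"


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage-specific 31-bit seed derived from the master seed and name."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Structured configuration for one pipeline run.

    Stage parameters default to the published analysis settings: QC gates
    500 genes / 750 UMIs / 15% mito / novelty 0.4, DE gates min.pct 0.25
    and avg_log2FC 0.6 with BH adjustment, 1,000 bootstrap iterations and
    one-sided Bonferroni-corrected alpha 0.01.
    """

    outdir: str = "vascomm_run"
    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    qc_thresholds: dict[str, float] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.de = {
            "min_pct": 0.25,
            "logfc_threshold": 0.6,
            "only_pos": False,
            "adjust": "bh",
            "subtypes": ["cEC", "astrocyte"],
            **self.de,
        }
        self.scoring = {
            "iterations": 1000,
            "alpha": 0.01,
            "sender": "cEC",
            "comparisons": None,  # None -> cEC vs every other subtype per region
            "fixed_cutoff": None,
            **self.scoring,
        }
        self.validate()

    def validate(self) -> None:
        if not (0 < self.scoring["alpha"] < 1):
            raise ValueError("scoring.alpha must be in (0, 1)")
        if self.scoring["iterations"] < 1:
            raise ValueError("scoring.iterations must be >= 1")
        if not (0 <= self.de["min_pct"] <= 1):
            raise ValueError("de.min_pct must be in [0, 1]")
        if self.de["adjust"] not in ("bh", "bonferroni"):
            raise ValueError("de.adjust must be 'bh' or 'bonferroni'")
        qc.QCThresholds(**self.qc_thresholds)  # raises on negatives

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def analyze_dataset(
    dataset: "synthetic.SyntheticDataset",
    seed: int = 0,
    thresholds: qc.QCThresholds | None = None,
    de_subtypes: tuple[str, ...] = ("cEC", "astrocyte"),
    de_params: dict[str, Any] | None = None,
    alpha: float = 0.01,
    n_iterations: int = 1000,
    sender: str = "cEC",
    comparisons: list[dict[str, str]] | None = None,
) -> pd.DataFrame:
    """In-memory QC -> DE -> database -> scoring on one dataset.

    The same stage sequence as :func:`run_pipeline` without the on-disk
    round trip; returns the combined per-pair result table with the
    ME-pericyte nonspecific exclusion applied. Used wherever many
    replicate datasets are analyzed (calibration and power studies).
    """
    thresholds = thresholds or qc.QCThresholds()
    de_params = {
        "min_pct": 0.25,
        "logfc_threshold": 0.6,
        "only_pos": False,
        "adjust": "bh",
        **(de_params or {}),
    }
    counts, cells_all, gene_annot = dataset.counts, dataset.cells, dataset.genes
    metrics = qc.compute_qc_metrics(counts, gene_annot)
    kept, _ = qc.filter_cells(metrics, cells_all, thresholds)
    kept_idx = [counts.barcode_index()[b] for b in kept]
    filtered = type(counts)(counts.values[:, kept_idx], counts.gene_ids, kept)
    cells = cells_all.set_index("barcode").loc[kept].reset_index()
    norm = expression.normalize(filtered)

    regions = sorted(cells["region"].unique())
    de_tables = []
    if len(regions) >= 2:
        for subtype in de_subtypes:
            group_a = cells.loc[
                (cells["region"] == regions[1]) & (cells["subtype"] == subtype),
                "barcode",
            ].tolist()
            group_b = cells.loc[
                (cells["region"] == regions[0]) & (cells["subtype"] == subtype),
                "barcode",
            ].tolist()
            if group_a and group_b:
                table = expression.wilcoxon_de(norm, group_a, group_b, **de_params)
                de_tables.append(table[table["p_adjusted"] < 0.05])
    database = build_database(
        dataset.reference_pairs, de_tables, gene_annot, dataset.ppi
    )

    if comparisons is None:
        comparisons = []
        for region in regions:
            here = sorted(cells.loc[cells["region"] == region, "subtype"].unique())
            if sender not in here:
                continue
            comparisons += [
                {"region": region, "sender": sender, "receiver": r}
                for r in here
                if r != sender
            ]
    results = []
    for comp in comparisons:
        spec = scoring.ComparisonSpec(
            comp["region"], comp["sender"], comp["region"], comp["receiver"]
        )
        comp_seed = derive_seed(
            seed, f"score:{comp['region']}:{comp['sender']}->{comp['receiver']}"
        )
        results.append(
            scoring.score_pairs(
                norm, cells, database, spec,
                alpha=alpha, n_iterations=n_iterations, seed=comp_seed,
            )
        )
    if not results:
        raise ValueError(
            "no sender/receiver comparison could be formed from the "
            "QC-passing cells"
        )
    combined = pd.concat(results, ignore_index=True)
    me_mask = combined["region"] == "ME"
    if me_mask.any() and (combined.loc[me_mask, "receiver"] == "pericyte").any():
        me_results = combined[me_mask]
        all_subtypes = set(me_results["receiver"].unique())
        sig_map: dict[tuple[str, str], set[str]] = {}
        for row in me_results.itertuples(index=False):
            if row.significant:
                sig_map.setdefault((row.ligand, row.receptor), set()).add(row.receiver)
        peri_mask = me_mask & (combined["receiver"] == "pericyte")
        updated = scoring.exclude_nonspecific(combined[peri_mask], sig_map, all_subtypes)
        combined.loc[peri_mask, "excluded_nonspecific"] = updated[
            "excluded_nonspecific"
        ].to_numpy()
        combined.loc[peri_mask, "significant"] = updated["significant"].to_numpy()
    return combined


def run_pipeline(config: RunConfig, use_null_data: bool = False) -> dict[str, Any]:
    """Run every stage and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "qc": dict(config.qc_thresholds),
            "de": dict(config.de),
            "scoring": {k: v for k, v in config.scoring.items() if k != "comparisons"},
        },
        "stages": [],
    }

    def record(stage: str, started: float, outputs: dict[str, Path], **extra: Any) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "wall_clock_s": round(time.perf_counter() - started, 3),
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in outputs.items() if p.is_file()},
                **extra,
            }
        )

    # ---- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    sim_kwargs = dict(config.simulation)
    sim_seed = sim_kwargs.pop("seed", derive_seed(config.seed, "simulate"))
    if sim_kwargs:
        sim_config = synthetic.SimulationConfig(seed=sim_seed, **sim_kwargs)
    else:
        sim_config = synthetic.default_config(seed=sim_seed)
    dataset = (
        synthetic.generate_null_dataset(sim_config)
        if use_null_data
        else synthetic.generate_dataset(sim_config)
    )
    data_dir = outdir / "data"
    paths = synthetic.write_dataset(dataset, data_dir)
    record("simulate", t0, paths, seed=sim_seed)

    # ---- qc -------------------------------------------------------------
    t0 = time.perf_counter()
    counts = read_counts(paths["matrix"], paths["genes"], paths["barcodes"])
    cells = read_cell_annotation(paths["cells"], counts.barcodes)
    gene_annot = read_gene_annotation(paths["genes_annot"])
    thresholds = qc.QCThresholds(**config.qc_thresholds)
    metrics = qc.compute_qc_metrics(counts, gene_annot)
    kept, report = qc.filter_cells(metrics, cells, thresholds)
    qc_out = {"qc_report": outdir / "qc_report.tsv", "kept": outdir / "kept.tsv"}
    write_table(report.merge(metrics, on="barcode"), qc_out["qc_report"])
    pd.DataFrame({"barcode": kept}).to_csv(qc_out["kept"], sep="\t", index=False)
    record("qc", t0, qc_out, n_kept=len(kept), n_total=counts.n_cells)

    kept_idx = [counts.barcode_index()[b] for b in kept]
    filtered = type(counts)(
        counts.values[:, kept_idx], counts.gene_ids, kept
    )
    cells_kept = cells.set_index("barcode").loc[kept].reset_index()
    norm = expression.normalize(filtered)

    # ---- de -------------------------------------------------------------
    t0 = time.perf_counter()
    de_out: dict[str, Path] = {}
    de_tables = []
    regions = sorted(cells_kept["region"].unique())
    for subtype in config.de["subtypes"]:
        if len(regions) < 2:
            break
        group_a = cells_kept.loc[
            (cells_kept["region"] == regions[1]) & (cells_kept["subtype"] == subtype),
            "barcode",
        ].tolist()
        group_b = cells_kept.loc[
            (cells_kept["region"] == regions[0]) & (cells_kept["subtype"] == subtype),
            "barcode",
        ].tolist()
        if not group_a or not group_b:
            continue
        table = expression.wilcoxon_de(
            norm,
            group_a,
            group_b,
            min_pct=config.de["min_pct"],
            logfc_threshold=config.de["logfc_threshold"],
            only_pos=config.de["only_pos"],
            adjust=config.de["adjust"],
            label_a=f"{regions[1]}:{subtype}",
            label_b=f"{regions[0]}:{subtype}",
        )
        path = outdir / f"de_{subtype}.tsv"
        write_table(table, path)
        de_out[f"de_{subtype}"] = path
        de_tables.append(table)
    record("de", t0, de_out, n_de_genes=int(sum(len(t) for t in de_tables)))

    # ---- build-db -------------------------------------------------------
    t0 = time.perf_counter()
    reference = read_reference_pairs(paths["reference_pairs"])
    ppi = read_ppi(paths["ppi"])
    significant_de = [
        t[t["p_adjusted"] < 0.05] for t in de_tables if len(t)
    ]
    database = build_database(reference, significant_de, gene_annot, ppi)
    db_path = outdir / "lrdb.tsv"
    write_database(database, db_path)
    record("build-db", t0, {"lrdb": db_path}, database_size=database.size)

    # ---- score ----------------------------------------------------------
    t0 = time.perf_counter()
    comparisons = config.scoring["comparisons"]
    if comparisons is None:
        sender = config.scoring["sender"]
        comparisons = []
        for region in regions:
            subtypes_here = sorted(
                cells_kept.loc[cells_kept["region"] == region, "subtype"].unique()
            )
            for receiver in subtypes_here:
                if receiver != sender and sender in subtypes_here:
                    comparisons.append(
                        {"region": region, "sender": sender, "receiver": receiver}
                    )
    results = []
    for comp in comparisons:
        spec = scoring.ComparisonSpec(
            comp["region"], comp["sender"], comp["region"], comp["receiver"]
        )
        comp_seed = derive_seed(
            config.seed, f"score:{comp['region']}:{comp['sender']}->{comp['receiver']}"
        )
        results.append(
            scoring.score_pairs(
                norm,
                cells_kept,
                database,
                spec,
                alpha=config.scoring["alpha"],
                n_iterations=config.scoring["iterations"],
                seed=comp_seed,
                fixed_cutoff=config.scoring["fixed_cutoff"],
            )
        )
    if not results:
        raise ValueError(
            "no sender/receiver comparison could be formed from the "
            "QC-passing cells"
        )
    combined = pd.concat(results, ignore_index=True)

    # pericyte-specific exclusion in the ME: drop pairs that look
    # significant in every other receiving subtype but not in pericytes
    me_mask = combined["region"] == "ME"
    if me_mask.any() and (combined.loc[me_mask, "receiver"] == "pericyte").any():
        me_results = combined[me_mask]
        all_subtypes = set(me_results["receiver"].unique())
        sig_map: dict[tuple[str, str], set[str]] = {}
        for row in me_results.itertuples(index=False):
            if row.significant:
                sig_map.setdefault((row.ligand, row.receptor), set()).add(row.receiver)
        peri_mask = me_mask & (combined["receiver"] == "pericyte")
        updated = scoring.exclude_nonspecific(
            combined[peri_mask], sig_map, all_subtypes
        )
        combined.loc[peri_mask, "excluded_nonspecific"] = updated[
            "excluded_nonspecific"
        ].to_numpy()
        combined.loc[peri_mask, "significant"] = updated["significant"].to_numpy()
    results_path = outdir / "results.tsv"
    write_table(combined, results_path)
    record(
        "score",
        t0,
        {"results": results_path},
        n_comparisons=len(comparisons),
        n_significant=int(combined["significant"].sum()),
    )

    # ---- report ---------------------------------------------------------
    t0 = time.perf_counter()
    summary = scoring.summarize(combined)
    summary_path = outdir / "summary.tsv"
    write_table(summary, summary_path)
    record("report", t0, {"summary": summary_path})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
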