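"""Self-contained synthetic two-region vascular scRNA-seq datasets.

Emulates the study design the pipeline targets: droplet-style UMI counts
from two brain regions ("cortex" and "ME") over vascular and perivascular
subtypes (capillary endothelial cells, pericytes, astrocytes, fibroblasts
and, in the ME, tanycytes), with planted region-enriched marker genes,
planted directional ligand-receptor pairs, mitochondrial genes, and
contaminant barcodes (low-quality, doublet, empty-droplet) constructed to
fall on the failing side of the QC module's default thresholds.

Count model: gene baseline rates are lognormal, per-cell library depth is
lognormal, and counts are negative binomial around ``rate x depth`` with
a shared dispersion. Planted markers multiply a gene's rate by its fold
change within one (subtype, region); planted pairs do the same for the
ligand in the sender subtype and the receptor in the receiver subtype.
Genes are otherwise independent — no gene-gene correlation structure, no
batch effects, no ambient-RNA soup.

Seeding: one master seed; every stage (baseline rates, depths, counts,
contaminants, annotations, PPI, reference pairs) derives an independent
stream from the master seed and the stage name, so adding a stage never
perturbs earlier draws and identical configs give bit-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_formats import (
    CountMatrix,
    PPINetwork,
    write_cell_annotation,
    write_counts,
    write_gene_annotation,
    write_ppi,
    write_reference_pairs,
)
from .qc import QCThresholds

__all__ = [
    "MarkerSpec",
    "PlantedPair",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_null_dataset",
    "default_config",
    "write_dataset",
]


class MarkerSpec(NamedTuple):
    gene: str
    subtype: str
    region: str
    fold_change: float


class PlantedPair(NamedTuple):
    ligand: str
    receptor: str
    sender_subtype: str
    receiver_subtype: str
    region: str
    ligand_fold: float
    receptor_fold: float


#: The study's two-region subtype layout: vascular/perivascular subtypes
#: in both regions, tanycytes only in the ME.
DEFAULT_SUBTYPE_SPEC: tuple[tuple[str, str, int], ...] = (
    ("cortex", "cEC", 150),
    ("cortex", "pericyte", 150),
    ("cortex", "astrocyte", 150),
    ("cortex", "fibroblast", 150),
    ("ME", "cEC", 150),
    ("ME", "pericyte", 150),
    ("ME", "astrocyte", 150),
    ("ME", "fibroblast", 150),
    ("ME", "tanycyte", 150),
)


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic dataset.

    Baseline defaults are chosen so that clean cells resemble the study's
    droplet libraries relative to the QC gates: a few thousand UMIs, on
    the order of a thousand genes detected, novelty well above 0.4, and a
    sub-percent mitochondrial fraction.
    """

    n_genes: int = 2000
    n_mito_genes: int = 13
    subtype_spec: Sequence[tuple[str, str, int]] = DEFAULT_SUBTYPE_SPEC
    baseline_log_mean: float = -0.3
    baseline_log_sd: float = 0.3
    nb_dispersion: float = 2.0
    depth_log_mean: float = 0.0
    depth_log_sd: float = 0.25
    marker_spec: Sequence[MarkerSpec] = field(default_factory=list)
    planted_pairs: Sequence[PlantedPair] = field(default_factory=list)
    n_reference_pairs: int = 200
    frac_low_quality: float = 0.0
    frac_doublet: float = 0.0
    frac_empty: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.subtype_spec = [tuple(s) for s in self.subtype_spec]
        self.marker_spec = [MarkerSpec(*m) for m in self.marker_spec]
        self.planted_pairs = [PlantedPair(*p) for p in self.planted_pairs]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes: must be a positive integer")
        if not (0 <= self.n_mito_genes < self.n_genes):
            raise ValueError("n_mito_genes: must be in [0, n_genes)")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd: must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion: must be positive")
        if self.n_reference_pairs < 0:
            raise ValueError("n_reference_pairs: must be nonnegative")
        seen: set[tuple[str, str]] = set()
        for region, subtype, n_cells in self.subtype_spec:
            if n_cells <= 0:
                raise ValueError(f"subtype_spec: n_cells for {region}:{subtype} <= 0")
            if (region, subtype) in seen:
                raise ValueError(
                    f"subtype_spec: duplicate subtype {subtype!r} in region {region!r}"
                )
            seen.add((region, subtype))
        genes = set(self.gene_names())
        groups = {(r, s) for r, s, _ in self.subtype_spec}
        for m in self.marker_spec:
            if m.fold_change <= 1:
                raise ValueError(f"marker_spec: fold_change for {m.gene} must be > 1")
            if m.gene not in genes:
                raise ValueError(f"marker_spec: gene {m.gene!r} not among n_genes")
            if (m.region, m.subtype) not in groups:
                raise ValueError(
                    f"marker_spec: group {m.region}:{m.subtype} not in subtype_spec"
                )
        for p in self.planted_pairs:
            if p.ligand_fold <= 1 or p.receptor_fold <= 1:
                raise ValueError(
                    f"planted_pairs: folds for {p.ligand}-{p.receptor} must be > 1"
                )
            for g in (p.ligand, p.receptor):
                if g not in genes:
                    raise ValueError(f"planted_pairs: gene {g!r} not among n_genes")
            for st in (p.sender_subtype, p.receiver_subtype):
                if (p.region, st) not in groups:
                    raise ValueError(
                        f"planted_pairs: group {p.region}:{st} not in subtype_spec"
                    )
        for name in ("frac_low_quality", "frac_doublet", "frac_empty"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name}: must be in [0, 1)")
        if self.frac_low_quality + self.frac_doublet + self.frac_empty >= 1:
            raise ValueError("frac_low_quality: contaminant fractions must sum to < 1")

    # -- helpers ---------------------------------------------------------

    def gene_names(self) -> list[str]:
        """Deterministic gene identifiers; mitochondrial genes last, with
        the conventional mt- prefix."""
        n_plain = self.n_genes - self.n_mito_genes
        names = [f"g{i:04d}" for i in range(1, n_plain + 1)]
        names += [f"mt-g{i:02d}" for i in range(1, self.n_mito_genes + 1)]
        return names

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["subtype_spec"] = [list(s) for s in self.subtype_spec]
        raw["marker_spec"] = [list(m) for m in self.marker_spec]
        raw["planted_pairs"] = [list(p) for p in self.planted_pairs]
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


@dataclass
class GroundTruth:
    """What was planted, for recovery testing."""

    true_markers: set[tuple[str, str, str]]  # (gene, subtype, region)
    true_pairs: set[tuple[str, str, str, str, str]]  # (lig, rec, sender, receiver, region)
    contaminant_barcodes: dict[str, set[str]]  # class -> barcodes
    doublet_parents: dict[str, tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_markers": sorted(list(m) for m in self.true_markers),
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "contaminant_barcodes": {
                k: sorted(v) for k, v in self.contaminant_barcodes.items()
            },
            "doublet_parents": {k: list(v) for k, v in self.doublet_parents.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            true_markers={tuple(m) for m in raw["true_markers"]},
            true_pairs={tuple(p) for p in raw["true_pairs"]},
            contaminant_barcodes={
                k: set(v) for k, v in raw["contaminant_barcodes"].items()
            },
            doublet_parents={k: tuple(v) for k, v in raw["doublet_parents"].items()},
        )


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    ppi: PPINetwork
    reference_pairs: pd.DataFrame
    truth: GroundTruth


def _stream(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream derived from the master seed and stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic input tuple with known ground truth."""
    config.validate()
    genes = config.gene_names()
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    qc_defaults = QCThresholds()

    baseline = np.exp(
        config.baseline_log_mean
        + config.baseline_log_sd * _stream(config.seed, "baseline").standard_normal(n_genes)
    )

    # fold-change multipliers per (region, subtype)
    fold: dict[tuple[str, str], np.ndarray] = {}
    for region, subtype, _ in config.subtype_spec:
        fold[(region, subtype)] = np.ones(n_genes)
    for m in config.marker_spec:
        fold[(m.region, m.subtype)][gene_idx[m.gene]] *= m.fold_change
    for p in config.planted_pairs:
        fold[(p.region, p.sender_subtype)][gene_idx[p.ligand]] *= p.ligand_fold
        fold[(p.region, p.receiver_subtype)][gene_idx[p.receptor]] *= p.receptor_fold

    depth_rng = _stream(config.seed, "depth")
    counts_rng = _stream(config.seed, "counts")
    blocks: list[np.ndarray] = []
    barcodes: list[str] = []
    regions: list[str] = []
    subtypes: list[str] = []
    for region, subtype, n_cells in config.subtype_spec:
        depths = np.exp(
            config.depth_log_mean
            + config.depth_log_sd * depth_rng.standard_normal(n_cells)
        )
        mu = (baseline * fold[(region, subtype)])[:, None] * depths[None, :]
        blocks.append(_nb_draw(counts_rng, mu, config.nb_dispersion))
        barcodes += [f"{region}_{subtype}_{i:04d}" for i in range(1, n_cells + 1)]
        regions += [region] * n_cells
        subtypes += [subtype] * n_cells
    clean = np.concatenate(blocks, axis=1)
    n_clean = clean.shape[1]

    flags_rng = _stream(config.seed, "flags")
    doublet_score = flags_rng.uniform(0.0, 0.2, size=n_clean)
    empty_fdr = flags_rng.uniform(0.0, 0.009, size=n_clean)

    # ---- contaminants, built to land on the failing side of QC ----------
    cont_rng = _stream(config.seed, "contaminants")
    contaminants: dict[str, set[str]] = {"low_quality": set(), "doublet": set(), "empty": set()}
    doublet_parents: dict[str, tuple[str, str]] = {}
    extra_cols: list[np.ndarray] = []
    extra_rows: list[tuple[str, str, str, float, float]] = []

    n_low = int(round(config.frac_low_quality * n_clean))
    low_target = max(1, qc_defaults.min_counts // 4)  # well under min_counts
    for k in range(1, n_low + 1):
        parent = int(cont_rng.integers(n_clean))
        col = clean[:, parent]
        total = int(col.sum())
        keep_p = min(0.9, low_target / max(total, 1))
        thinned = cont_rng.binomial(col, keep_p)
        while thinned.sum() >= qc_defaults.min_counts:  # pragma: no cover
            thinned = cont_rng.binomial(thinned, 0.5)
        bc = f"lowq_{k:04d}"
        contaminants["low_quality"].add(bc)
        extra_cols.append(thinned)
        extra_rows.append(
            (
                bc,
                regions[parent],
                subtypes[parent],
                float(cont_rng.uniform(0.0, 0.2)),
                float(cont_rng.uniform(0.0, 0.009)),
            )
        )

    n_doub = int(round(config.frac_doublet * n_clean))
    region_cols: dict[str, list[int]] = {}
    for j, r in enumerate(regions):
        region_cols.setdefault(r, []).append(j)
    for k in range(1, n_doub + 1):
        region = list(region_cols)[int(cont_rng.integers(len(region_cols)))]
        cols = region_cols[region]
        a, b = cont_rng.choice(len(cols), size=2, replace=False)
        pa, pb = cols[int(a)], cols[int(b)]
        bc = f"doublet_{k:04d}"
        contaminants["doublet"].add(bc)
        doublet_parents[bc] = (barcodes[pa], barcodes[pb])
        extra_cols.append(clean[:, pa] + clean[:, pb])
        extra_rows.append(
            (
                bc,
                region,
                subtypes[pa],
                float(cont_rng.uniform(0.26, 0.9)),  # fails the >0.25 gate
                float(cont_rng.uniform(0.0, 0.009)),
            )
        )

    n_empty = int(round(config.frac_empty * n_clean))
    ambient = baseline / baseline.sum()
    for k in range(1, n_empty + 1):
        total = int(cont_rng.poisson(low_target))
        col = cont_rng.multinomial(total, ambient)
        bc = f"empty_{k:04d}"
        contaminants["empty"].add(bc)
        region, subtype, _ = config.subtype_spec[
            int(cont_rng.integers(len(config.subtype_spec)))
        ]
        extra_cols.append(col)
        extra_rows.append(
            (
                bc,
                region,
                subtype,
                float(cont_rng.uniform(0.0, 0.2)),
                float(cont_rng.uniform(0.011, 0.9)),  # fails the >0.01 gate
            )
        )

    if extra_cols:
        matrix = np.concatenate([clean] + [c[:, None] for c in extra_cols], axis=1)
    else:
        matrix = clean
    all_barcodes = barcodes + [r[0] for r in extra_rows]
    cells = pd.DataFrame(
        {
            "barcode": all_barcodes,
            "region": regions + [r[1] for r in extra_rows],
            "subtype": subtypes + [r[2] for r in extra_rows],
            "doublet_score": np.concatenate(
                [doublet_score, np.array([r[3] for r in extra_rows])]
            )
            if extra_rows
            else doublet_score,
            "empty_fdr": np.concatenate(
                [empty_fdr, np.array([r[4] for r in extra_rows])]
            )
            if extra_rows
            else empty_fdr,
        }
    )
    counts = CountMatrix(sp.csr_matrix(matrix), genes, all_barcodes)

    # ---- gene annotation -------------------------------------------------
    annot_rng = _stream(config.seed, "annotation")
    classes = np.array(["plasma_membrane", "secreted", "extracellular_matrix", "other", "unknown"])
    probs = np.array([0.15, 0.10, 0.05, 0.50, 0.20])
    localization = classes[annot_rng.choice(len(classes), size=n_genes, p=probs)]
    for p in config.planted_pairs:  # planted genes carry eligible localization
        localization[gene_idx[p.ligand]] = "secreted"
        localization[gene_idx[p.receptor]] = "plasma_membrane"
    is_mito = np.array([g.startswith("mt-") for g in genes])
    localization[is_mito] = "other"
    gene_annot = pd.DataFrame(
        {"gene": genes, "localization_class": localization, "is_mito": is_mito}
    )

    # ---- PPI network: one experimental edge per planted pair + decoys ----
    ppi_rng = _stream(config.seed, "ppi")
    edge_records: list[tuple[str, str, bool]] = []
    edge_seen: set[frozenset] = set()
    for p in config.planted_pairs:
        key = frozenset((p.ligand, p.receptor))
        if key not in edge_seen:
            edge_seen.add(key)
            edge_records.append((p.ligand, p.receptor, True))
    n_decoy_edges = 3 * len(config.planted_pairs) + 20
    while len(edge_records) < len(config.planted_pairs) + n_decoy_edges:
        a, b = ppi_rng.choice(n_genes, size=2, replace=False)
        key = frozenset((genes[int(a)], genes[int(b)]))
        if key in edge_seen:
            continue
        edge_seen.add(key)
        edge_records.append(
            (genes[int(a)], genes[int(b)], bool(ppi_rng.random() < 0.5))
        )
    ppi = PPINetwork.from_records(edge_records)

    # ---- reference pairs: planted pairs + random decoy pairs -------------
    ref_rng = _stream(config.seed, "reference")
    ref_records: list[tuple[str, str]] = []
    ref_seen: set[tuple[str, str]] = set()
    for p in config.planted_pairs:
        key = (p.ligand, p.receptor)
        if key not in ref_seen:
            ref_seen.add(key)
            ref_records.append(key)
    non_mito = [g for g in genes if not g.startswith("mt-")]
    n_planted_pairs = len({(p.ligand, p.receptor) for p in config.planted_pairs})
    while len(ref_records) < config.n_reference_pairs + n_planted_pairs:
        a, b = ref_rng.choice(len(non_mito), size=2, replace=False)
        key = (non_mito[int(a)], non_mito[int(b)])
        if key in ref_seen:
            continue
        ref_seen.add(key)
        ref_records.append(key)
    reference = pd.DataFrame(ref_records, columns=["ligand", "receptor"])

    truth = GroundTruth(
        true_markers={(m.gene, m.subtype, m.region) for m in config.marker_spec},
        true_pairs={
            (p.ligand, p.receptor, p.sender_subtype, p.receiver_subtype, p.region)
            for p in config.planted_pairs
        },
        contaminant_barcodes=contaminants,
        doublet_parents=doublet_parents,
    )
    return SyntheticDataset(counts, cells, gene_annot, ppi, reference, truth)


def generate_null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Same generator with no planted signal: all genes exchangeable
    within a subtype, ground-truth pair and marker sets empty."""
    null_config = SimulationConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "marker_spec": [],
            "planted_pairs": [],
        }
    )
    return generate_dataset(null_config)


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard study-like scenario: region-enriched cEC markers and
    directional ligand-receptor pairs from cECs to perivascular receivers
    in both regions, plus a tanycyte-to-cEC pair unique to the ME."""
    markers = [
        MarkerSpec("g0101", "cEC", "ME", 8.0),
        MarkerSpec("g0102", "cEC", "ME", 6.0),
        MarkerSpec("g0103", "cEC", "ME", 4.0),
        MarkerSpec("g0104", "cEC", "cortex", 8.0),
        MarkerSpec("g0105", "cEC", "cortex", 6.0),
        MarkerSpec("g0106", "cEC", "cortex", 4.0),
        MarkerSpec("g0107", "astrocyte", "ME", 5.0),
        MarkerSpec("g0108", "astrocyte", "cortex", 5.0),
    ]
    pairs = [
        PlantedPair("g0201", "g0202", "cEC", "pericyte", "ME", 6.0, 6.0),
        PlantedPair("g0203", "g0204", "cEC", "pericyte", "cortex", 6.0, 6.0),
        PlantedPair("g0205", "g0206", "cEC", "astrocyte", "ME", 6.0, 6.0),
        PlantedPair("g0207", "g0208", "cEC", "astrocyte", "cortex", 6.0, 6.0),
        PlantedPair("g0209", "g0210", "tanycyte", "cEC", "ME", 6.0, 6.0),
    ]
    return SimulationConfig(
        marker_spec=markers,
        planted_pairs=pairs,
        frac_low_quality=0.02,
        frac_doublet=0.02,
        frac_empty=0.02,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all on-disk artifacts the pipeline reads; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "cells": outdir / "cells.tsv",
        "genes_annot": outdir / "genes_annot.tsv",
        "ppi": outdir / "ppi.tsv",
        "reference_pairs": outdir / "reference_pairs.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_counts(dataset.counts, paths["matrix"], paths["genes"], paths["barcodes"])
    write_cell_annotation(dataset.cells, paths["cells"])
    write_gene_annotation(dataset.genes, paths["genes_annot"])
    write_ppi(dataset.ppi, paths["ppi"])
    write_reference_pairs(dataset.reference_pairs, paths["reference_pairs"])
    dataset.truth.to_json(paths["ground_truth"])
    return paths
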