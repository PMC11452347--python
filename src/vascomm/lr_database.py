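"""Assembly of the ligand-receptor database.

The database is a reference list of established ligand-receptor pairs
supplemented with candidate pairs derived from differentially expressed
genes: a DE gene is eligible for candidacy only if its predicted
subcellular localization is plasma membrane, secreted or extracellular
matrix, and its candidate partners are the genes linked to it by a
protein-protein interaction edge with experimental validation. Because
which member of a novel pair acts as the ligand is not known a priori,
candidate pairs are added in both orientations; the orientation is
resolved empirically by which direction scores significantly.

Display convention: established interactions in uppercase
("PDGFB–PDGFRB"), candidates in their original symbol case ("Bsg–Itga6"),
so provenance is visible in every downstream table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ELIGIBLE_LOCALIZATIONS, PPINetwork

__all__ = [
    "LRPair",
    "LRDatabase",
    "eligible_for_candidacy",
    "validated_partners",
    "build_database",
    "read_database",
    "write_database",
]

logger = logging.getLogger(__name__)

PAIR_SEPARATOR = "–"  # en-dash, the field's display convention


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    provenance: str  # "established" | "candidate"
    display_name: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty")
        if self.provenance not in ("established", "candidate"):
            raise ValueError(f"invalid provenance {self.provenance!r}")


def _display(ligand: str, receptor: str, provenance: str) -> str:
    if provenance == "established":
        return f"{ligand.upper()}{PAIR_SEPARATOR}{receptor.upper()}"
    return f"{ligand}{PAIR_SEPARATOR}{receptor}"


@dataclass
class LRDatabase:
    """Ordered, duplicate-free list of directed ligand-receptor pairs."""

    pairs: list[LRPair]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for pair in self.pairs:
            key = (pair.ligand, pair.receptor)
            if key in seen:
                raise ValueError(f"duplicate ordered pair {key}")
            seen.add(key)

    @property
    def size(self) -> int:
        return len(self.pairs)

    def ligands(self) -> list[str]:
        """Unique ligand genes in database order."""
        out, seen = [], set()
        for pair in self.pairs:
            if pair.ligand not in seen:
                seen.add(pair.ligand)
                out.append(pair.ligand)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.ligand, p.receptor, p.provenance, p.display_name)
                for p in self.pairs
            ],
            columns=["ligand", "receptor", "provenance", "display_name"],
        )


def eligible_for_candidacy(gene: str, genes: pd.DataFrame) -> bool:
    """True iff the gene's localization class makes it a plausible
    extracellular interactor (plasma membrane, secreted, ECM).

    Genes absent from the annotation are ineligible: candidacy requires
    positive localization evidence.
    """
    rows = genes.loc[genes["gene"] == gene, "localization_class"]
    if rows.empty:
        logger.warning("gene %r absent from annotation; not eligible", gene)
        return False
    return rows.iloc[0] in ELIGIBLE_LOCALIZATIONS


def validated_partners(gene: str, ppi: PPINetwork) -> set[str]:
    """Neighbors of ``gene`` whose PPI edge carries experimental validation."""
    return ppi.neighbors(gene, experimental_only=True)


def build_database(
    reference: pd.DataFrame,
    de_tables: Sequence[pd.DataFrame],
    genes: pd.DataFrame,
    ppi: PPINetwork,
) -> LRDatabase:
    """Reference pairs plus DE-derived candidate pairs.

    Established pairs keep the reference file's order; candidate pairs
    follow, sorted lexicographically, each novel (DE gene, validated
    partner) combination added in both orientations. A candidate
    identical to a reference pair is kept once with established
    provenance.
    """
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    for row in reference.itertuples(index=False):
        key = (row.ligand, row.receptor)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            LRPair(row.ligand, row.receptor, "established", _display(*key, "established"))
        )

    de_genes: list[str] = []
    de_seen: set[str] = set()
    for table in de_tables:
        for gene in table["gene"]:
            if gene not in de_seen:
                de_seen.add(gene)
                de_genes.append(gene)

    candidate_keys: set[tuple[str, str]] = set()
    for gene in de_genes:
        if not eligible_for_candidacy(gene, genes):
            continue
        for partner in validated_partners(gene, ppi):
            for key in ((gene, partner), (partner, gene)):
                if key not in seen:
                    candidate_keys.add(key)
    for key in sorted(candidate_keys):
        seen.add(key)
        pairs.append(LRPair(*key, "candidate", _display(*key, "candidate")))

    if not pairs:
        raise ValueError("empty database: no reference pairs and no candidates")
    return LRDatabase(pairs)


def write_database(db: LRDatabase, path) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)


def read_database(path) -> LRDatabase:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("ligand", "receptor", "provenance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pairs = []
    for row in df.itertuples(index=False):
        display = getattr(row, "display_name", "") or _display(
            row.ligand, row.receptor, row.provenance
        )
        pairs.append(LRPair(row.ligand, row.receptor, row.provenance, display))
    return LRDatabase(pairs)
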