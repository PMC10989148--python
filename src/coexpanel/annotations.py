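"""Per-gene annotations: subcellular flags, pathways, free-text description."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "signal_peptide",
    "transmembrane",
    "pathway",
    "description",
]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, signal_peptide, transmembrane, pathway,
    description. ``pathway`` is a semicolon-separated list, parsed into a
    Python list column ``pathways``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: annotation table missing columns {missing}")
    return normalize_annotations(df)


def normalize_annotations(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["signal_peptide"] = out["signal_peptide"].astype(str).isin({"1", "True", "true"}) \
        if out["signal_peptide"].dtype == object else out["signal_peptide"].astype(bool)
    out["transmembrane"] = out["transmembrane"].astype(str).isin({"1", "True", "true"}) \
        if out["transmembrane"].dtype == object else out["transmembrane"].astype(bool)
    out["pathways"] = [
        [p.strip() for p in str(p).split(";") if p.strip()] for p in out["pathway"]
    ]
    out["description"] = out["description"].fillna("").astype(str)
    return out


def write_annotation_table(annot: pd.DataFrame, path: str | Path) -> None:
    out = annot.copy()
    out["signal_peptide"] = out["signal_peptide"].astype(int)
    out["transmembrane"] = out["transmembrane"].astype(int)
    if "pathways" in out.columns:
        out["pathway"] = [";".join(p) for p in out["pathways"]]
        out = out.drop(columns=["pathways"])
    out.index.name = "gene_id"
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t")


def align_annotations(annot: pd.DataFrame, gene_ids: Iterable[str]) -> pd.DataFrame:
    """Reindex annotations onto a gene list; absent genes default to no flags,
    no pathways, empty description (coverage shortfall is logged)."""
    gene_ids = list(gene_ids)
    aligned = annot.reindex(gene_ids)
    n_missing = int(aligned["description"].isna().sum())
    if n_missing:
        logger.warning(
            "annotation coverage: %d/%d genes missing, defaulting to false/empty",
            n_missing,
            len(gene_ids),
        )
    for col in ("signal_peptide", "transmembrane"):
        aligned[col] = np.array(
            [False if pd.isna(v) else bool(v) for v in aligned[col]], dtype=bool
        )
    aligned["pathways"] = [p if isinstance(p, list) else [] for p in aligned["pathways"]]
    aligned["description"] = aligned["description"].fillna("").astype(str)
    return aligned


def pathway_members(annot: pd.DataFrame, pathway: str) -> list[str]:
    """Gene ids annotated to the given pathway."""
    return [g for g, paths in annot["pathways"].items() if pathway in paths]
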