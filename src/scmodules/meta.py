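"""Cross-dataset integration of regulatory tables and module annotation.

Regulatory tables from independent runs/datasets are merged by regulator name
into one landscape (missing regulators become 0, all-zero rows/columns are
dropped, rows are z-scored so a regulator's activity is comparable across
modules), and module gene sets are annotated against known signatures by
Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NamedRegulatoryTable:
    """A regulator x module table tagged with its dataset of origin.

    Module identifiers are qualified as ``<dataset>:<module>`` so they stay
    unique after merging.
    """

    values: np.ndarray
    regulator_names: list[str]
    module_ids: list[str]
    dataset_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regulator_names), len(self.module_ids)):
            raise ValueError("table shape does not match names")
        if len(set(self.regulator_names)) != len(self.regulator_names):
            raise ValueError("duplicate regulator names in table")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.dataset_label}:{m}" for m in self.module_ids]
        return pd.DataFrame(self.values, index=self.regulator_names, columns=cols)


def merge_regulatory_tables(tables: list[NamedRegulatoryTable]) -> pd.DataFrame:
    """Outer-join tables on regulator names and z-score per regulator.

    Missing entries become 0; rows and columns whose absolute sum is 0 are
    dropped before scaling. Rows constant after the merge are set to 0 with a
    warning (no scale information).
    """
    if not tables:
        raise ValueError("need at least one table")
    frames = [t.to_frame() for t in tables]
    cols = [c for f in frames for c in f.columns]
    if len(set(cols)) != len(cols):
        raise ValueError("module ids collide across tables; use distinct dataset labels")
    merged = pd.concat(frames, axis=1, join="outer").fillna(0.0)
    merged = merged[merged.abs().sum(axis=1) > 0]
    merged = merged.loc[:, merged.abs().sum(axis=0) > 0]

    values = merged.to_numpy()
    mu = values.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.nan_to_num(sd, nan=0.0)  # a single surviving column has no spread
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} regulator row(s) constant after merge; z-scores set to 0",
            stacklevel=2,
        )
    sd[flat] = 1.0
    z = (values - mu) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=merged.index, columns=merged.columns)


def jaccard_module_annotation(
    module_genes: dict[str, set[str]], signatures: dict[str, set[str]]
) -> pd.DataFrame:
    """Jaccard index of every module gene set against every signature.

    Gene symbols are compared case-insensitively. Empty modules yield a row of
    zeros with a warning; empty signatures are rejected.
    """
    for name, sig in signatures.items():
        if not sig:
            raise ValueError(f"signature {name!r} is empty")
    sig_sets = {name: {g.upper() for g in sig} for name, sig in signatures.items()}
    rows = {}
    for mod, genes in module_genes.items():
        gset = {g.upper() for g in genes}
        if not gset:
            warnings.warn(f"module {mod!r} is empty; Jaccard row set to 0", stacklevel=2)
            rows[mod] = {name: 0.0 for name in sig_sets}
            continue
        rows[mod] = {
            name: len(gset & sig) / len(gset | sig) for name, sig in sig_sets.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(sig_sets))


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene signatures in GMT format (name, description, genes...)."""
    signatures: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, _desc, *genes = parts
            signatures[name] = {g for g in genes if g}
    return signatures


def read_regulatory_table_tsv(path, dataset_label: str) -> NamedRegulatoryTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return NamedRegulatoryTable(
        values=df.to_numpy(dtype=float),
        regulator_names=[str(r) for r in df.index],
        module_ids=[str(c) for c in df.columns],
        dataset_label=dataset_label,
    )


def read_tables_from_manifest(manifest_path) -> list[NamedRegulatoryTable]:
    """Load regulatory tables listed in a JSON manifest.

    The manifest maps dataset labels to table TSV paths (relative paths are
    resolved against the manifest's directory)::

        {"cohortA": "tables/a.tsv", "cohortB": "tables/b.tsv"}
    """
    import json
    from pathlib import Path

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if not isinstance(manifest, dict) or not manifest:
        raise ValueError("manifest must be a non-empty JSON object of label -> path")
    tables = []
    for label, rel in manifest.items():
        path = Path(rel)
        if not path.is_absolute():
            path = manifest_path.parent / path
        tables.append(read_regulatory_table_tsv(path, str(label)))
    return tables
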