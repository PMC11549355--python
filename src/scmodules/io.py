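"""Reading expression data and preparing standardized training/assessment splits.

Expression matrices are stored genes x cells (the common on-disk convention for
single-cell data); the fitting code works on cells x genes blocks ``Zt``/``Zr``
for target genes and regulators respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionBundle:
    """A gene-named expression matrix plus regulator annotation.

    Parameters
    ----------
    values:
        Normalized expression, shape ``(n_genes, n_cells)``. Dense ndarray or
        scipy sparse matrix.
    gene_names, cell_names:
        Unique identifiers for rows and columns.
    is_regulator:
        Boolean flag per gene; regulators enter the design matrix, never the
        response.
    strata:
        Optional categorical label per cell (e.g. sample/patient of origin)
        used for stratified splitting.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    is_regulator: np.ndarray = None
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        p, n = self.values.shape
        if len(self.gene_names) != p:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {p} matrix rows"
            )
        if len(self.cell_names) != n:
            raise ValueError(
                f"{len(self.cell_names)} cell names for {n} matrix columns"
            )
        dup = _duplicates(self.gene_names)
        if dup:
            raise ValueError(f"duplicate gene names: {sorted(dup)[:5]}")
        dup = _duplicates(self.cell_names)
        if dup:
            raise ValueError(f"duplicate cell names: {sorted(dup)[:5]}")
        if self.is_regulator is None:
            self.is_regulator = np.zeros(p, dtype=bool)
        else:
            self.is_regulator = np.asarray(self.is_regulator, dtype=bool)
            if self.is_regulator.shape != (p,):
                raise ValueError("is_regulator must have one flag per gene")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape != (n,):
                raise ValueError("strata must have one label per cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def n_regulators(self) -> int:
        return int(self.is_regulator.sum())

    @property
    def n_targets(self) -> int:
        return self.n_genes - self.n_regulators

    def dense(self) -> np.ndarray:
        if scipy.sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class DataSplits:
    """Training/assessment halves with standardization statistics.

    ``Zt1``/``Zr1`` are the training-split target and regulator blocks
    (``n1`` cells in rows), ``Zt2``/``Zr2`` the assessment split. Target
    columns are centered and regulator columns centered and scaled to unit
    standard deviation using statistics computed on the training split and
    applied to both splits.
    """

    Zt1: np.ndarray
    Zr1: np.ndarray
    Zt2: np.ndarray
    Zr2: np.ndarray
    target_names: list[str]
    regulator_names: list[str]
    split_fraction: float
    seed: int
    target_centers: np.ndarray = None
    regulator_centers: np.ndarray = None
    regulator_scales: np.ndarray = None
    train_cells: np.ndarray = None
    test_cells: np.ndarray = None

    @property
    def n1(self) -> int:
        return self.Zt1.shape[0]

    @property
    def n2(self) -> int:
        return self.Zt2.shape[0]

    @property
    def n_targets(self) -> int:
        return self.Zt1.shape[1]

    @property
    def n_regulators(self) -> int:
        return self.Zr1.shape[1]


def _duplicates(names: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for name in names:
        if name in seen:
            dup.add(name)
        seen.add(name)
    return dup


def _read_name_column(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar file: {path}")
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                names.append(line.split("\t")[0])
    return names


def load_expression_matrix(path, fmt: str | None = None) -> ExpressionBundle:
    """Read a genes x cells expression matrix from disk.

    Supported formats: dense ``tsv``/``csv`` (genes in rows, header row of
    cell names, first column gene names) and MatrixMarket ``mtx`` following
    the 10x convention with ``genes.tsv`` and ``barcodes.tsv`` sidecar files
    in the same directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in {"mtx", "tsv", "csv"}:
        raise ValueError(f"unsupported format {fmt!r}; expected mtx, tsv or csv")

    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - message from scipy
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = scipy.sparse.csr_matrix(mat)
        genes = _read_name_column(path.parent / "genes.tsv", "gene-name")
        cells = _read_name_column(path.parent / "barcodes.tsv", "cell-name")
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"matrix declares {mat.shape[0]} genes but genes.tsv lists {len(genes)}"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"matrix declares {mat.shape[1]} cells but barcodes.tsv lists {len(cells)}"
            )
        return ExpressionBundle(mat, genes, cells)

    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    return ExpressionBundle(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
    )


def write_expression_tsv(bundle: ExpressionBundle, path) -> None:
    """Round-trippable dense TSV dump (full float precision)."""
    df = pd.DataFrame(bundle.dense(), index=bundle.gene_names, columns=bundle.cell_names)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_regulator_list(path) -> set[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_prior_links(path, target_names: list[str]) -> np.ndarray:
    """Read a gene-gene prior link matrix from a three-column edge list TSV.

    Each line is ``geneA<TAB>geneB<TAB>1``. Links between genes not in
    ``target_names`` are ignored (reported via a warning); the result is a
    symmetric 0/1 matrix over the target genes with zero diagonal, ready for
    :class:`~scmodules.allocate.PriorSpec`.
    """
    index = {g: i for i, g in enumerate(target_names)}
    J = np.zeros((len(target_names), len(target_names)))
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed prior edge at line {lineno}: {line!r}")
            a, b = parts[0], parts[1]
            if a not in index or b not in index or a == b:
                skipped += 1
                continue
            J[index[a], index[b]] = 1.0
            J[index[b], index[a]] = 1.0
    if skipped:
        warnings.warn(
            f"{skipped} prior link(s) referenced genes outside the target set "
            "(or self-links) and were ignored",
            stacklevel=2,
        )
    return J


def format_for_fit(bundle: ExpressionBundle, regulator_names) -> ExpressionBundle:
    """Flag regulators by name and reorder genes targets-first (stable).

    Regulator names absent from the bundle are reported via a warning; zero
    matches is a configuration error.
    """
    regulator_names = set(regulator_names)
    if not regulator_names:
        raise ValueError("regulator_names must be non-empty")
    matched = regulator_names & set(bundle.gene_names)
    if not matched:
        raise ValueError("none of the provided regulator names match the gene names")
    unmatched = regulator_names - matched
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} regulator name(s) not found in the data: "
            f"{sorted(unmatched)[:5]}",
            stacklevel=2,
        )
    is_reg = np.array([g in matched for g in bundle.gene_names], dtype=bool)
    order = np.concatenate([np.flatnonzero(~is_reg), np.flatnonzero(is_reg)])
    values = bundle.values[order] if not scipy.sparse.issparse(bundle.values) else bundle.values[order, :]
    return ExpressionBundle(
        values,
        [bundle.gene_names[i] for i in order],
        list(bundle.cell_names),
        is_regulator=is_reg[order],
        strata=bundle.strata,
    )


def make_data_splits(
    bundle: ExpressionBundle,
    fraction: float = 0.5,
    center_within_strata: bool = False,
    seed: int = 0,
) -> DataSplits:
    """Randomly split cells into training/assessment halves and standardize.

    Cells are shuffled with a dedicated RNG stream and split at ``fraction``
    (within each stratum when strata are present). Target genes are centered,
    regulator genes centered and scaled to standard deviation one; statistics
    are computed on the training split only and applied to both splits so that
    the assessment split stays untouched by the training data.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if bundle.n_regulators < 1 or bundle.n_targets < 1:
        raise ValueError("bundle must contain at least one regulator and one target")

    n = bundle.n_cells
    p_r = bundle.n_regulators
    if n < 2 * p_r:
        warnings.warn(
            f"number of cells ({n}) is less than twice the number of regulators "
            f"({p_r}); variance estimates will fall back to ridge regression",
            stacklevel=2,
        )
    if n < 4:
        raise ValueError("need at least 4 cells to form two usable splits")

    rng = np.random.default_rng(seed)
    if bundle.strata is None:
        strata_groups = [np.arange(n)]
    else:
        labels = pd.unique(bundle.strata)
        strata_groups = [np.flatnonzero(bundle.strata == lab) for lab in labels]
        for lab, idx in zip(labels, strata_groups):
            if idx.size < 2:
                raise ValueError(f"stratum {lab!r} has fewer than 2 cells")

    train_idx, test_idx = [], []
    for idx in strata_groups:
        perm = idx[rng.permutation(idx.size)]
        n1_s = int(round(fraction * idx.size))
        n1_s = min(max(n1_s, 1), idx.size - 1)
        train_idx.append(perm[:n1_s])
        test_idx.append(perm[n1_s:])
    train_cells = np.sort(np.concatenate(train_idx))
    test_cells = np.sort(np.concatenate(test_idx))

    dense = bundle.dense()
    t_mask = ~bundle.is_regulator
    r_mask = bundle.is_regulator
    target_names = [g for g, t in zip(bundle.gene_names, t_mask) if t]
    regulator_names = [g for g, r in zip(bundle.gene_names, r_mask) if r]

    # cells x genes blocks
    Zt = dense[t_mask].T.copy()
    Zr = dense[r_mask].T.copy()

    if center_within_strata and bundle.strata is not None:
        for idx in strata_groups:
            tr = np.intersect1d(idx, train_cells)
            mu = Zt[tr].mean(axis=0)
            Zt[idx] -= mu

    Zt1, Zt2 = Zt[train_cells], Zt[test_cells]
    Zr1, Zr2 = Zr[train_cells], Zr[test_cells]

    t_center = Zt1.mean(axis=0)
    r_center = Zr1.mean(axis=0)
    r_scale = Zr1.std(axis=0, ddof=1)
    bad = np.flatnonzero(r_scale == 0)
    if bad.size:
        names = [regulator_names[i] for i in bad[:5]]
        raise ValueError(
            f"regulator gene(s) constant on the training split (sd = 0): {names}"
        )
    Zt1 = Zt1 - t_center
    Zt2 = Zt2 - t_center
    Zr1 = (Zr1 - r_center) / r_scale
    Zr2 = (Zr2 - r_center) / r_scale

    return DataSplits(
        Zt1=Zt1,
        Zr1=Zr1,
        Zt2=Zt2,
        Zr2=Zr2,
        target_names=target_names,
        regulator_names=regulator_names,
        split_fraction=fraction,
        seed=seed,
        target_centers=t_center,
        regulator_centers=r_center,
        regulator_scales=r_scale,
        train_cells=train_cells,
        test_cells=test_cells,
    )
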