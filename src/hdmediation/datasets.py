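"""In-memory dataset container and delimited-file input.

A :class:`MediationDataset` holds a binary exposure, continuous outcome,
samples-by-mediators matrix and samples-by-confounders matrix with aligned
sample identifiers.  :func:`read_dataset` assembles one from a phenotype
table and a mediator matrix stored as delimited text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MediationDataset", "read_dataset"]


@dataclass
class MediationDataset:
    """Aligned exposure / outcome / mediator / confounder arrays.

    ``truth_alpha`` / ``truth_beta`` are optional generator-side effect
    vectors used by the benchmark to label true mediators.
    """

    X: np.ndarray
    Y: np.ndarray
    M: np.ndarray
    C: np.ndarray
    sample_ids: np.ndarray | None = None
    mediator_ids: np.ndarray | None = None
    truth_alpha: np.ndarray | None = None
    truth_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        n = self.X.shape[0]
        if not (self.Y.shape[0] == n and self.M.shape[0] == n and self.C.shape[0] == n):
            raise ValueError(
                f"inconsistent dimensions: X {n}, Y {self.Y.shape[0]}, "
                f"M {self.M.shape[0]} rows, C {self.C.shape[0]} rows"
            )
        levels = np.unique(self.X)
        if not np.isin(levels, [0.0, 1.0]).all():
            raise ValueError(f"exposure must be binary 0/1; observed levels {levels}")
        for name, arr in (("X", self.X), ("Y", self.Y), ("M", self.M), ("C", self.C)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing or non-finite values")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(n)])
        if self.mediator_ids is None:
            self.mediator_ids = np.array([f"M{k + 1}" for k in range(self.p)])

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def q(self) -> int:
        return self.C.shape[1]

    def require_both_groups(self) -> None:
        n1 = int(self.X.sum())
        if n1 == 0 or n1 == self.n:
            raise ValueError("exposure has an empty group; analysis requires both")

    @property
    def true_mediators(self) -> np.ndarray | None:
        """0-based indices of mediators with non-zero true indirect effect."""
        if self.truth_alpha is None or self.truth_beta is None:
            return None
        return np.flatnonzero(self.truth_alpha * self.truth_beta != 0.0)


def _read_table(path, sep: str | None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def read_dataset(
    pheno_path,
    mediator_path,
    exposure: str,
    outcome: str,
    confounders: list[str],
    id_column: str | None = None,
    sep: str | None = None,
    max_id_mismatch: float = 0.5,
) -> MediationDataset:
    """Load a dataset from a phenotype table and a mediator matrix.

    Both files are delimited text with a header row; the mediator matrix has
    samples in rows (first column = sample id unless ``id_column`` names
    one present in both files).  Samples are inner-joined on id; rows with
    missing values in the used columns are dropped with a logged count.
    """
    pheno = _read_table(pheno_path, sep)
    med = _read_table(mediator_path, sep)
    idc = id_column or pheno.columns[0]
    med_idc = id_column if (id_column and id_column in med.columns) else med.columns[0]
    med = med.rename(columns={med_idc: idc})

    used = [idc, exposure, outcome, *confounders]
    missing_cols = [c for c in used if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns: {missing_cols}")
    pheno = pheno[used]
    n_before = len(pheno)
    pheno = pheno.dropna()
    med = med.dropna()
    dropped = n_before - len(pheno)
    if dropped:
        logger.info("dropped %d phenotype rows with missing values", dropped)

    merged = pheno.merge(med, on=idc, how="inner")
    lost = max(len(pheno), len(med)) - len(merged)
    if len(merged) == 0 or lost / max(len(pheno), len(med)) > max_id_mismatch:
        raise ValueError(
            f"sample id mismatch: only {len(merged)} of {max(len(pheno), len(med))} "
            "ids are shared between the two files"
        )
    if lost:
        logger.info("dropped %d samples absent from one of the two files", lost)

    x = merged[exposure].to_numpy()
    levels = np.unique(x)
    if levels.shape[0] != 2:
        raise ValueError(f"exposure column {exposure!r} is not binary; levels {levels}")
    x = (x == levels.max()).astype(float)

    mediator_cols = [c for c in med.columns if c != idc]
    return MediationDataset(
        X=x,
        Y=merged[outcome].to_numpy(dtype=float),
        M=merged[mediator_cols].to_numpy(dtype=float),
        C=merged[confounders].to_numpy(dtype=float),
        sample_ids=merged[idc].to_numpy(),
        mediator_ids=np.asarray(mediator_cols),
    )
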