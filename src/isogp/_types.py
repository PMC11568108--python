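"""Validated containers for ADT count panels and design matrices.

The two containers mirror the raw inputs of the model: a cells-by-antibodies
matrix of nonnegative integer tag counts (with isotype controls flagged), and
a design matrix whose first column is the intercept and whose remaining
columns carry integer-coded categorical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ADTCountMatrix", "DesignMatrix"]

#: substring used to auto-flag isotype (negative-control) antibodies
DEFAULT_ISOTYPE_PATTERN = "IgG"


def _check_unique(names, what: str) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {what} name: {n!r}")
        seen.add(n)


@dataclass
class ADTCountMatrix:
    """Cells x antibodies matrix of raw ADT counts.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, one row per cell, one column per antibody.
    antibody_names
        Unique column labels.
    cell_ids
        Unique row labels.
    isotype_flags
        Boolean per antibody marking isotype (negative-control) antibodies.
        If omitted, antibodies whose name contains ``"IgG"`` are flagged.
    """

    counts: np.ndarray
    antibody_names: list[str]
    cell_ids: list[str]
    isotype_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (cells x antibodies)")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.isfinite(c)) or np.any(c != np.floor(c)):
                bad = np.argwhere((c != np.floor(c)) | ~np.isfinite(c))
                i, j = bad[0]
                raise ValueError(
                    f"counts must be integers; offending entry at row {i}, column {j}: {c[i, j]!r}"
                )
            c = c.astype(np.int64)
        if np.any(c < 0):
            i, j = np.argwhere(c < 0)[0]
            raise ValueError(
                f"counts must be nonnegative; offending entry at row {i}, column {j}: {c[i, j]}"
            )
        self.counts = c
        self.antibody_names = [str(n) for n in self.antibody_names]
        self.cell_ids = [str(n) for n in self.cell_ids]
        if len(self.antibody_names) != c.shape[1]:
            raise ValueError("antibody_names length must equal the number of columns")
        if len(self.cell_ids) != c.shape[0]:
            raise ValueError("cell_ids length must equal the number of rows")
        _check_unique(self.antibody_names, "antibody")
        _check_unique(self.cell_ids, "cell")
        if self.isotype_flags is None:
            self.isotype_flags = np.array(
                [DEFAULT_ISOTYPE_PATTERN in n for n in self.antibody_names], dtype=bool
            )
        else:
            self.isotype_flags = np.asarray(self.isotype_flags, dtype=bool)
            if self.isotype_flags.shape != (c.shape[1],):
                raise ValueError("isotype_flags must have one entry per antibody")

    # -- convenience accessors ------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_antibodies(self) -> int:
        return self.counts.shape[1]

    @property
    def isotype_names(self) -> list[str]:
        return [n for n, f in zip(self.antibody_names, self.isotype_flags) if f]

    def column(self, name: str) -> np.ndarray:
        """Counts for one antibody, as a 1-D integer vector."""
        try:
            j = self.antibody_names.index(name)
        except ValueError:
            raise KeyError(f"antibody {name!r} not in panel") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.antibody_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, isotype_flags=None) -> "ADTCountMatrix":
        return cls(
            counts=df.to_numpy(),
            antibody_names=[str(c) for c in df.columns],
            cell_ids=[str(i) for i in df.index],
            isotype_flags=isotype_flags,
        )


@dataclass
class DesignMatrix:
    """Intercept plus integer-coded categorical covariates, one row per cell.

    The first column must be named ``"mu0"`` and contain only ones (the
    intercept).  Every further column holds level codes ``1..L`` with every
    level occupied by at least one cell.  Non-contiguous codes should be
    re-indexed before construction (see :func:`isogp.io.read_design`).
    """

    table: pd.DataFrame
    # mapping column -> original level label per re-indexed code, if re-indexed
    level_maps: dict[str, dict[int, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        if df.shape[1] < 1 or df.columns[0] != "mu0":
            raise ValueError('the first design column must be named "mu0" (intercept)')
        if not np.all(df["mu0"].to_numpy() == 1):
            raise ValueError('the intercept column "mu0" must be constant 1')
        for col in df.columns[1:]:
            v = df[col].to_numpy()
            if not np.issubdtype(v.dtype, np.integer):
                if np.any(v != np.floor(v)):
                    raise ValueError(f"covariate {col!r} must be integer-coded")
                v = v.astype(np.int64)
                df[col] = v
            levels = np.unique(v)
            expected = np.arange(1, levels.size + 1)
            if not np.array_equal(levels, expected):
                raise ValueError(
                    f"covariate {col!r} must use contiguous level codes 1..L "
                    f"with every level occupied; got levels {levels.tolist()}"
                )
        self.table = df

    @property
    def n_cells(self) -> int:
        return self.table.shape[0]

    @property
    def covariate_names(self) -> list[str]:
        return [str(c) for c in self.table.columns[1:]]

    @property
    def n_levels(self) -> dict[str, int]:
        return {c: int(self.table[c].max()) for c in self.covariate_names}

    def codes(self) -> np.ndarray:
        """Covariate level codes as an (n_cells, n_covariates) int array."""
        cols = self.covariate_names
        if not cols:
            return np.zeros((self.n_cells, 0), dtype=np.int64)
        return self.table[cols].to_numpy(dtype=np.int64)

    def combinations(self) -> list[tuple[int, ...]]:
        """Cartesian product of occupied levels, lexicographic in column order.

        For an intercept-only design this is a single empty tuple.
        """
        import itertools

        ranges = [range(1, L + 1) for L in self.n_levels.values()]
        return list(itertools.product(*ranges))

    def combination_labels(self) -> list[str]:
        names = self.covariate_names
        if not names:
            return ["(intercept)"]
        return [
            ",".join(f"{n}={v}" for n, v in zip(names, combo)) for combo in self.combinations()
        ]

    @classmethod
    def from_codes(cls, n_cells: int, **covariates) -> "DesignMatrix":
        """Build a design from keyword level-code vectors, adding the intercept."""
        data = {"mu0": np.ones(n_cells, dtype=np.int64)}
        for name, v in covariates.items():
            data[name] = np.asarray(v, dtype=np.int64)
        return cls(pd.DataFrame(data))

    @classmethod
    def intercept_only(cls, n_cells: int) -> "DesignMatrix":
        return cls.from_codes(n_cells)
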