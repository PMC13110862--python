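"""Gene × sample expression container with a concentration-response design.

The matrix holds log2-scale normalized expression values.  Samples are grouped
by exposure concentration (nM); every concentration group has replicate
samples.  The TSV dialect used throughout the package is: first column the
gene identifier, remaining columns named ``conc_<nM>_rep<j>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COLUMN_RE = re.compile(r"^conc_(?P<conc>[0-9.eE+-]+)_rep(?P<rep>\d+)$")


@dataclass
class ExpressionMatrix:
    """Log2 expression values with sample → concentration labels.

    Parameters
    ----------
    gene_ids
        One identifier per row.
    values
        Array of shape ``(n_genes, n_samples)``; all entries finite.
    concentrations
        Concentration (nM) of each sample column, length ``n_samples``.
    replicates
        Replicate label of each sample column (defaults to 1..n within group).
    """

    gene_ids: list[str]
    values: np.ndarray
    concentrations: np.ndarray
    replicates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes × samples)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length must match number of rows")
        if self.values.shape[1] != self.concentrations.size:
            raise ValueError("one concentration label per sample column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all expression values must be finite")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        levels, counts = np.unique(self.concentrations, return_counts=True)
        if levels.size < 2 or 0.0 not in levels:
            raise ValueError("need >= 2 distinct concentrations including 0 (control)")
        if np.any(counts < 2):
            raise ValueError("every concentration group needs >= 2 replicates")
        if not self.replicates:
            reps: dict[float, int] = {}
            labels = []
            for c in self.concentrations:
                reps[c] = reps.get(c, 0) + 1
                labels.append(str(reps[c]))
            self.replicates = labels

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dose_levels(self) -> np.ndarray:
        """Sorted distinct concentrations (nM), control first."""
        return np.unique(self.concentrations)

    def group_indices(self) -> list[np.ndarray]:
        """Sample-column indices per dose level, in dose order."""
        return [np.flatnonzero(self.concentrations == c) for c in self.dose_levels]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"conc_{c:g}_rep{r}" for c, r in zip(self.concentrations, self.replicates)
        ]
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"), columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        concs, reps = [], []
        for col in df.columns:
            m = _COLUMN_RE.match(col)
            if m is None:
                raise ValueError(f"column {col!r} does not match 'conc_<nM>_rep<j>'")
            concs.append(float(m.group("conc")))
            reps.append(m.group("rep"))
        return cls(
            gene_ids=[str(g) for g in df.index],
            values=df.to_numpy(dtype=float),
            concentrations=np.array(concs),
            replicates=reps,
        )
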