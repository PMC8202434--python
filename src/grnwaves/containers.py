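"""Core in-memory containers: count matrices and sample designs.

A :class:`CountMatrix` couples an integer gene x sample matrix with a
:class:`SampleDesign` describing each sample (condition, time, replicate,
optional perturbation label). Everything downstream — normalization, the
differential-expression tests, wave detection, perturbation scoring —
consumes this pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved perturbation label for the non-targeting (scramble) control.
SCRAMBLE_LABEL = "SCR"

DESIGN_COLUMNS = ["condition", "time_h", "replicate", "perturbation"]


@dataclass
class SampleDesign:
    """Per-sample metadata table.

    The underlying frame is indexed by sample id and carries the columns
    ``condition`` ("control" / "treated"), ``time_h`` (hours, float),
    ``replicate`` (label) and ``perturbation`` (shRNA label or ``None``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample design missing columns: {missing}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> pd.Series:
        return self.table["condition"]

    @property
    def times(self) -> pd.Series:
        return self.table["time_h"]

    def subset(self, mask) -> "SampleDesign":
        return SampleDesign(self.table.loc[mask].copy())

    def replicate_counts(self) -> pd.Series:
        """Number of replicates per (condition, time_h) design cell."""
        return self.table.groupby(["condition", "time_h"], observed=True).size()


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix plus its sample design."""

    values: pd.DataFrame  # genes x samples
    design: SampleDesign = field(repr=False)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.values.index.duplicated().any():
            raise ValueError("gene identifiers are not unique")
        if list(self.values.columns) != self.design.sample_ids:
            raise ValueError("count columns do not match design rows (order matters)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.values[sample_ids].copy(),
            SampleDesign(self.design.table.loc[sample_ids].copy()),
        )

    def to_files(self, counts_path, sheet_path) -> None:
        """Write genes x samples TSV and a sample-sheet CSV."""
        self.values.to_csv(counts_path, sep="\t", index_label="gene")
        sheet = self.design.table.copy()
        sheet.insert(0, "sample_id", sheet.index)
        sheet.to_csv(sheet_path, index=False)

    @classmethod
    def from_files(cls, counts_path, sheet_path) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path)
        if "sample_id" not in sheet.columns:
            raise ValueError(f"{sheet_path}: sample sheet lacks a sample_id column")
        sheet = sheet.set_index("sample_id")
        if "perturbation" not in sheet.columns:
            sheet["perturbation"] = None
        sheet["perturbation"] = sheet["perturbation"].astype("object")
        sheet.loc[sheet["perturbation"].isna(), "perturbation"] = None
        values = values[list(sheet.index)]
        values = values.astype(np.int64)
        return cls(values, SampleDesign(sheet))
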