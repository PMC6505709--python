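"""Stage-labelled expression matrix container.

The unit of analysis is a probe set (row) measured across samples (columns),
each sample assigned to one of four disease stages: a control group and three
progressively worse disease groups (incipient, moderate, severe). Values are
log-scale intensities; no normalisation is assumed beyond the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
DISEASE_STAGES = ("incipient", "moderate", "severe")
STAGES = (CONTROL,) + DISEASE_STAGES


class ValidationError(ValueError):
    """Raised when input data violate the container contracts."""


def normalize_sample_id(sample_id: str) -> str:
    """Collapse internal whitespace in a sample identifier.

    Printed sample IDs sometimes carry spurious spaces ("GSM 21215"); matching
    against a stage map is done on the whitespace-stripped form.
    """
    return "".join(str(sample_id).split())


@dataclass(frozen=True)
class StagedExpressionMatrix:
    """Genes x samples matrix of log-scale expression with a stage per sample.

    Parameters
    ----------
    values
        DataFrame with probe-set identifiers as the index and sample
        identifiers as columns. All entries must be finite floats.
    stage_of
        Mapping from sample identifier to stage label; every column of
        ``values`` must be present and every stage that occurs must have at
        least two samples (a single-sample stage makes the within-stage
        average degenerate).
    """

    values: pd.DataFrame
    stage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        gene_ids = values.index
        if gene_ids.has_duplicates:
            dups = sorted(gene_ids[gene_ids.duplicated()].unique())
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if values.columns.has_duplicates:
            dups = sorted(values.columns[values.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            i, j = bad[0]
            raise ValidationError(
                f"non-finite value at gene {gene_ids[i]!r}, sample "
                f"{values.columns[j]!r} ({len(bad)} bad entries total)"
            )
        missing = [s for s in values.columns if s not in self.stage_of]
        if missing:
            raise ValidationError(f"samples missing from stage map: {missing}")
        unknown = sorted(
            {v for v in self.stage_of.values() if v not in STAGES}
        )
        if unknown:
            raise ValidationError(
                f"unknown stage labels {unknown}; expected one of {list(STAGES)}"
            )
        counts: dict[str, int] = {}
        for s in values.columns:
            counts[self.stage_of[s]] = counts.get(self.stage_of[s], 0) + 1
        thin = sorted(st for st, c in counts.items() if c < 2)
        if thin:
            raise ValidationError(
                f"stages with fewer than 2 samples: {thin}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def stages_present(self) -> list[str]:
        """Stage labels occurring in this matrix, in canonical order."""
        present = {self.stage_of[s] for s in self.values.columns}
        return [s for s in STAGES if s in present]

    def samples_for(self, stage: str) -> list[str]:
        """Sample identifiers belonging to one stage, in column order."""
        return [s for s in self.values.columns if self.stage_of[s] == stage]

    def stage_slice(self, stage: str) -> pd.DataFrame:
        """The genes x samples block for one stage.

        Raises :class:`ValidationError` if the stage has no samples here.
        """
        cols = self.samples_for(stage)
        if not cols:
            raise ValidationError(f"stage {stage!r} absent from matrix")
        return self.values[cols]

    def stage_counts(self) -> dict[str, int]:
        return {st: len(self.samples_for(st)) for st in self.stages_present()}

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, stage_of: dict[str, str]
    ) -> "StagedExpressionMatrix":
        """Build a validated matrix from a DataFrame and a stage mapping."""
        return cls(values=values.astype(float), stage_of=dict(stage_of))
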