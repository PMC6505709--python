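"""Synthetic stage-labelled expression matrices with planted monotone genes.

The generator emulates the structure of a four-stage microarray study: a
shared gene list measured in control, incipient, moderate and severe sample
groups (default group sizes 9/7/8/7). Each observation is

    value(i, j) = baseline_i + stage_shift(i, stage_j) + offset_j + noise_ij

on the log scale: a per-gene baseline drawn uniformly from a plausible
log-intensity window, a per-sample additive offset (array/batch effect that
column-centering must remove), i.i.d. noise, and for planted genes a
stage-mean shift that rises (or falls) monotonically across the three
disease stages. Null genes have stage-invariant means. The truth table
records each gene's status and is the ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    CONTROL,
    DISEASE_STAGES,
    STAGES,
    StagedExpressionMatrix,
    ValidationError,
)

NULL, UP, DOWN = "null", "up", "down"


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic four-stage expression study.

    Defaults mirror a small brain-tissue microarray cohort: 9 control, 7
    incipient, 8 moderate and 7 severe samples; log2-scale baselines in
    [5, 12]; observation noise sd 0.5 log2 units; per-sample offsets of the
    same scale; 10 up- and 10 down-trending planted genes among 1,000 with
    stage shifts of (4, 5, 6) log2 units, i.e. 8-12x the noise sd.
    """

    n_genes: int = 1000
    samples_per_stage: tuple[int, int, int, int] = (9, 7, 8, 7)
    n_up: int = 10
    n_down: int = 10
    effect_profile: tuple[float, float, float] = (4.0, 5.0, 6.0)
    noise_sd: float = 0.5
    sample_offset_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    noise: str = "gaussian"
    t_df: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_up < 0 or self.n_down < 0:
            raise ValidationError("planted gene counts must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("n_up + n_down exceeds n_genes")
        if len(self.samples_per_stage) != 4 or any(
            n < 2 for n in self.samples_per_stage
        ):
            raise ValidationError(
                "samples_per_stage must be four counts, each >= 2"
            )
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be > 0")
        if self.sample_offset_sd < 0:
            raise ValidationError("sample_offset_sd must be >= 0")
        if len(self.effect_profile) != 3:
            raise ValidationError("effect_profile needs three magnitudes")
        if self.noise not in ("gaussian", "student_t"):
            raise ValidationError("noise must be 'gaussian' or 'student_t'")
        if self.noise == "student_t" and not self.t_df > 2:
            raise ValidationError("t_df must be > 2 for finite variance")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ValidationError("baseline_mean_range must be (low, high)")


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth status ('null'/'up'/'down') per synthetic gene."""

    status: dict[str, str]

    def genes_with(self, label: str) -> list[str]:
        return sorted(g for g, s in self.status.items() if s == label)

    @property
    def planted(self) -> set[str]:
        return {g for g, s in self.status.items() if s != NULL}

    def counts(self) -> dict[str, int]:
        out = {NULL: 0, UP: 0, DOWN: 0}
        for s in self.status.values():
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.status.items()), columns=["gene_id", "status"]
        )


def _draw_noise(rng: np.random.Generator, design: SyntheticDesign, shape):
    if design.noise == "gaussian":
        return rng.normal(0.0, design.noise_sd, size=shape)
    # standardized Student-t scaled to the requested sd
    raw = rng.standard_t(design.t_df, size=shape)
    return raw / np.sqrt(design.t_df / (design.t_df - 2.0)) * design.noise_sd


def generate(
    design: SyntheticDesign,
) -> tuple[StagedExpressionMatrix, TruthTable]:
    """Generate a matrix and its truth table, reproducibly from the seed."""
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"g{k:0{width}d}" for k in range(1, n + 1)]

    planted_idx = rng.choice(
        n, size=design.n_up + design.n_down, replace=False
    )
    up_idx = planted_idx[: design.n_up]
    down_idx = planted_idx[design.n_up :]

    status = {g: NULL for g in gene_ids}
    for i in up_idx:
        status[gene_ids[i]] = UP
    for i in down_idx:
        status[gene_ids[i]] = DOWN

    lo, hi = design.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n)

    # per-gene shift per stage: zero for control and null genes
    shift = np.zeros((n, 4))
    effects = np.asarray(design.effect_profile, dtype=float)
    shift[up_idx, 1:] = effects
    shift[down_idx, 1:] = -effects

    sample_ids: list[str] = []
    stage_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    k = 0
    for s_idx, (stage, count) in enumerate(
        zip(STAGES, design.samples_per_stage)
    ):
        for _ in range(count):
            k += 1
            sid = f"s{k:02d}"
            sample_ids.append(sid)
            stage_of[sid] = stage
            offset = rng.normal(0.0, design.sample_offset_sd)
            col = (
                baseline
                + shift[:, s_idx]
                + offset
                + _draw_noise(rng, design, n)
            )
            columns.append(col)

    values = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    matrix = StagedExpressionMatrix.from_dataframe(values, stage_of)
    return matrix, TruthTable(status=status)


def write_dataset(
    matrix: StagedExpressionMatrix, truth: TruthTable, out_dir
) -> dict[str, str]:
    """Write matrix.tsv, stages.tsv and truth.tsv under ``out_dir``."""
    from pathlib import Path

    from .io import write_matrix_tsv, write_stage_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": str(out / "matrix.tsv"),
        "stages": str(out / "stages.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_matrix_tsv(matrix, paths["matrix"])
    write_stage_map(matrix, paths["stages"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
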