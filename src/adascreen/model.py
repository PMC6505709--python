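"""Model/Results interface for the amplitude-deviation screen.

`ADAModel` holds the validated data and configuration; `fit` executes the
five-step procedure and returns an `ADAResults` carrying every intermediate
(deviation matrices, per-stage overall deviations, signed and absolute
amplitudes, thresholds) along with the candidate calls and a text summary.
"""

from __future__ import annotations

import pandas as pd

from . import core
from .core import (
    ADAConfig,
    AmplitudeProfile,
    CandidateCall,
    DeviationMatrix,
    ThresholdSet,
)
from .matrix import (
    DISEASE_STAGES,
    STAGES,
    StagedExpressionMatrix,
    ValidationError,
)

_METHODS = ("strict", "relaxed", "both")


class ADAModel:
    """Amplitude-deviation screen over a stage-labelled expression matrix.

    Parameters
    ----------
    matrix
        A validated :class:`StagedExpressionMatrix`. All four stages must be
        present, each with at least two samples.
    config
        Numeric conventions (:class:`ADAConfig`); defaults to the 3-sigma
        population-variance absolute-amplitude configuration.

    Examples
    --------
    >>> model = ADAModel.from_dataframe(values, stage_of)
    >>> res = model.fit(method="both")
    >>> print(res.summary())
    """

    def __init__(
        self,
        matrix: StagedExpressionMatrix,
        config: ADAConfig | None = None,
    ) -> None:
        missing = [s for s in STAGES if s not in matrix.stages_present()]
        if missing:
            raise ValidationError(f"missing stage(s): {missing}")
        self.matrix = matrix
        self.config = config or ADAConfig()

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        stage_of: dict[str, str],
        config: ADAConfig | None = None,
    ) -> "ADAModel":
        """Build from a genes x samples DataFrame and a sample->stage map."""
        return cls(
            StagedExpressionMatrix.from_dataframe(values, stage_of),
            config=config,
        )

    @classmethod
    def from_tsv(
        cls,
        path,
        stage_map_path,
        config: ADAConfig | None = None,
        **read_kwargs,
    ) -> "ADAModel":
        """Build from a matrix TSV and a two-column stage-map TSV."""
        from .io import read_matrix_tsv

        return cls(read_matrix_tsv(path, stage_map_path, **read_kwargs),
                   config=config)

    def fit(self, method: str = "both") -> "ADAResults":
        """Execute the screen and return results with all intermediates."""
        if method not in _METHODS:
            raise ValidationError(
                f"method must be one of {_METHODS}, got {method!r}"
            )
        matrix = self.matrix
        deviations = {
            stage: core.column_center(matrix, stage) for stage in STAGES
        }
        profile = pd.DataFrame(
            {s: core.overall_deviation(d) for s, d in deviations.items()}
        )
        amplitudes = core.amplitude_profile(profile)
        thresholds = core.compute_thresholds(amplitudes, self.config)
        candidates: list[CandidateCall] = []
        if method in ("strict", "both"):
            candidates += core.strict_3sigma_candidates(
                profile, amplitudes, thresholds
            )
        if method in ("relaxed", "both"):
            candidates += core.criterion_candidates(
                profile, amplitudes, thresholds
            )
        return ADAResults(
            model=self,
            method=method,
            deviations=deviations,
            profile=profile,
            amplitudes=amplitudes,
            thresholds=thresholds,
            candidates=candidates,
        )


class ADAResults:
    """Fitted screen: intermediates, thresholds and candidate calls.

    Attributes
    ----------
    deviations : dict[str, DeviationMatrix]
        Column-centered block per stage.
    profile : DataFrame
        Per-gene overall deviations, genes x four stages.
    amplitudes : AmplitudeProfile
        Signed and absolute amplitudes, genes x three disease stages.
    thresholds : ThresholdSet
        Per-stage means, sigmas and cutoffs.
    candidates : list[CandidateCall]
        Flagged genes, sorted by (criterion, direction, gene_id).
    """

    def __init__(
        self,
        model: ADAModel,
        method: str,
        deviations: dict[str, DeviationMatrix],
        profile: pd.DataFrame,
        amplitudes: AmplitudeProfile,
        thresholds: ThresholdSet,
        candidates: list[CandidateCall],
    ) -> None:
        self.model = model
        self.method = method
        self.deviations = deviations
        self.profile = profile
        self.amplitudes = amplitudes
        self.thresholds = thresholds
        self.candidates = candidates

    def calls_for(self, criterion: str) -> list[CandidateCall]:
        return [c for c in self.candidates if c.criterion == criterion]

    def candidates_frame(self) -> pd.DataFrame:
        """Candidate calls as a tidy DataFrame (one row per call)."""
        from .io import candidates_to_frame

        return candidates_to_frame(self.candidates)

    def to_tsv(self, path) -> None:
        """Write the candidate table in the standard column layout."""
        from .io import write_candidates

        write_candidates(self.candidates, path)

    def diagnostics(self, n_bins: int = 60) -> dict:
        """Amplitude distribution summaries for every stage x definition."""
        from .diagnostics import summarize_all

        return summarize_all(self.amplitudes, n_bins=n_bins)

    def plot_amplitude_histogram(
        self, stage: str, definition: str = "signed", n_bins: int = 60,
        path=None,
    ):
        from .diagnostics import plot_amplitude_histogram

        return plot_amplitude_histogram(
            self.amplitudes, stage=stage, definition=definition,
            n_bins=n_bins, path=path,
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        m = self.model.matrix
        cfg = self.model.config
        lines = [
            "Amplitude deviation screen",
            "==========================",
            f"genes: {m.n_genes}   samples: {len(m.sample_ids)}   "
            f"method: {self.method}",
            "stage sizes: "
            + ", ".join(f"{s}={c}" for s, c in m.stage_counts().items()),
            f"multiplier: {cfg.multiplier}   variance: {cfg.variance}   "
            f"relaxed amplitude: {cfg.relaxed_amplitude}",
            "",
            f"{'stage':<10}{'mean(A)':>10}{'sigma(A)':>10}"
            f"{'sigma(|A|)':>12}{'cut strict':>12}{'cut relaxed':>12}",
        ]
        thr = self.thresholds
        for t in DISEASE_STAGES:
            lines.append(
                f"{t:<10}{thr.mean_signed[t]:>10.4f}"
                f"{thr.sigma_signed[t]:>10.4f}"
                f"{thr.sigma_absolute[t]:>12.4f}"
                f"{thr.cutoff_strict[t]:>12.4f}"
                f"{thr.cutoff_relaxed[t]:>12.4f}"
            )
        lines.append("")
        counts: dict[str, int] = {}
        for c in self.candidates:
            key = f"{c.criterion}/{c.direction}"
            counts[key] = counts.get(key, 0) + 1
        lines.append(f"candidate calls: {len(self.candidates)}")
        for key in sorted(counts):
            lines.append(f"  {key}: {counts[key]}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ADAResults method={self.method!r} "
            f"genes={self.model.matrix.n_genes} "
            f"candidates={len(self.candidates)}>"
        )
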