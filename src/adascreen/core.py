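"""Core amplitude-deviation computations.

The screening procedure works on a stage-labelled log-expression matrix in
five steps:

1. column-center each stage block (deviation matrix ``S``): a gene's
   deviation in a sample is its value minus that sample's across-gene mean,
   which removes per-sample additive offsets;
2. average deviations within a stage (overall deviation ``D`` per gene per
   stage), damping sample-to-sample noise;
3. signed amplitudes ``A_t = D_t - D_control`` for the three disease stages;
4. absolute amplitudes ``A'_t = |A_t|``;
5. flag genes whose amplitudes are extreme relative to a 3-sigma cutoff in
   every disease stage AND whose overall deviations move strictly
   monotonically across control -> incipient -> moderate -> severe.

Two selection rules are provided. The strict rule mean-centers the signed
amplitudes and requires ``|A_t - mean(A_t)| > 3 sigma_t`` in all three stages
with a strictly monotone trend in either direction. The relaxed rule uses the
absolute amplitudes, whose standard deviation ``sigma*`` is smaller than the
signed one on symmetric data, so the cutoff ``3 sigma*_t`` is lower; genes
must exceed it in all three stages and trend strictly up ("criterion 1") or
strictly down ("criterion 2").
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

STRICT = "strict3sigma"
CRITERION_UP = "criterion1"
CRITERION_DOWN = "criterion2"


@dataclass(frozen=True)
class ADAConfig:
    """Numeric conventions for the screen.

    multiplier
        Cutoff multiplier on sigma (default 3.0, the classical three-sigma
        rule: ~99.7% of normal data fall within it).
    variance
        'population' divides by N (the raw moment identity
        ``sigma^2 = E[x^2] - E[x]^2``); 'sample' divides by N-1.
    relaxed_amplitude
        Amplitude definition used by the relaxed rule: 'absolute' (the
        default; magnitudes of the signed amplitudes) or 'signed' (a literal
        reading in which the relaxed threshold is compared against the signed
        amplitude itself, under which down-trending genes can never pass).
    """

    multiplier: float = 3.0
    variance: str = "population"
    relaxed_amplitude: str = "absolute"

    def __post_init__(self) -> None:
        if not self.multiplier > 0:
            raise ValidationError("multiplier must be > 0")
        if self.variance not in ("population", "sample"):
            raise ValidationError("variance must be 'population' or 'sample'")
        if self.relaxed_amplitude not in ("absolute", "signed"):
            raise ValidationError(
                "relaxed_amplitude must be 'absolute' or 'signed'"
            )

    @property
    def ddof(self) -> int:
        return 0 if self.variance == "population" else 1


@dataclass(frozen=True)
class DeviationMatrix:
    """Column-centered deviations S(i, j) for one stage block."""

    stage: str
    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class AmplitudeProfile:
    """Signed and absolute per-gene amplitudes for the disease stages."""

    signed: pd.DataFrame
    absolute: pd.DataFrame

    def vector(self, definition: str, stage: str) -> np.ndarray:
        if definition == "signed":
            return self.signed[stage].to_numpy()
        if definition == "absolute":
            return self.absolute[stage].to_numpy()
        raise ValidationError("definition must be 'signed' or 'absolute'")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-stage amplitude means, sigmas and cutoffs.

    ``cutoff_strict[t] = multiplier * sigma_signed[t]`` applies to the
    mean-centered signed amplitude; ``cutoff_relaxed[t] = multiplier *
    sigma_relaxed[t]`` applies to the relaxed-rule amplitude (absolute by
    default).
    """

    mean_signed: dict[str, float]
    sigma_signed: dict[str, float]
    sigma_absolute: dict[str, float]
    multiplier: float = 3.0
    relaxed_amplitude: str = "absolute"

    @property
    def cutoff_strict(self) -> dict[str, float]:
        return {t: self.multiplier * s for t, s in self.sigma_signed.items()}

    @property
    def sigma_relaxed(self) -> dict[str, float]:
        if self.relaxed_amplitude == "absolute":
            return self.sigma_absolute
        return self.sigma_signed

    @property
    def cutoff_relaxed(self) -> dict[str, float]:
        return {t: self.multiplier * s for t, s in self.sigma_relaxed.items()}

    def to_dict(self) -> dict:
        return {
            "multiplier": self.multiplier,
            "relaxed_amplitude": self.relaxed_amplitude,
            "mean_signed": dict(self.mean_signed),
            "sigma_signed": dict(self.sigma_signed),
            "sigma_absolute": dict(self.sigma_absolute),
            "cutoff_strict": self.cutoff_strict,
            "cutoff_relaxed": self.cutoff_relaxed,
        }


@dataclass(frozen=True)
class CandidateCall:
    """One gene flagged by a named selection rule.

    ``criterion1`` calls are always up-trending and ``criterion2`` calls
    down-trending; a strict-rule call's direction follows the sign of its
    monotone trend. Amplitudes are the signed values; deviations are the four
    per-stage overall deviations.
    """

    gene_id: str
    criterion: str
    direction: str
    amplitudes: dict[str, float] = field(default_factory=dict)
    deviations: dict[str, float] = field(default_factory=dict)

    def sort_key(self) -> tuple:
        return (self.criterion, self.direction, self.gene_id)


def column_center(
    matrix: StagedExpressionMatrix, stage: str
) -> DeviationMatrix:
    """Center one stage block: S(i, j) = T(i, j) - mean_i T(i, j).

    Each sample column is reduced by its across-gene average, so every
    deviation column sums to zero and per-sample additive offsets vanish.
    Requires the stage to have at least two samples.
    """
    block = matrix.stage_slice(stage)
    if block.shape[1] < 2:
        raise ValidationError(
            f"stage {stage!r} has {block.shape[1]} sample(s); need >= 2"
        )
    centered = block - block.mean(axis=0)
    return DeviationMatrix(stage=stage, values=centered)


def overall_deviation(dev: DeviationMatrix) -> pd.Series:
    """Average a gene's deviations across the samples of one stage."""
    return dev.values.mean(axis=1)


def stage_deviation_profile(
    matrix: StagedExpressionMatrix,
) -> pd.DataFrame:
    """Overall deviations D_t(i) for every stage present, genes x stages."""
    cols = {}
    for stage in matrix.stages_present():
        cols[stage] = overall_deviation(column_center(matrix, stage))
    return pd.DataFrame(cols)


def signed_amplitude(profile: pd.DataFrame) -> pd.DataFrame:
    """A_t(i) = D_t(i) - D_control(i) for the three disease stages."""
    _require_all_stages(profile)
    out = {t: profile[t] - profile[CONTROL] for t in DISEASE_STAGES}
    return pd.DataFrame(out)


def absolute_amplitude(profile: pd.DataFrame) -> pd.DataFrame:
    """A'_t(i) = |D_t(i) - D_control(i)|."""
    return signed_amplitude(profile).abs()


def amplitude_profile(profile: pd.DataFrame) -> AmplitudeProfile:
    signed = signed_amplitude(profile)
    return AmplitudeProfile(signed=signed, absolute=signed.abs())


def estimate_sigma(x, ddof: int = 0) -> tuple[float, float]:
    """Mean and standard deviation of an amplitude vector.

    With ``ddof=0`` this is the raw moment identity
    ``sigma = sqrt(E[x^2] - E[x]^2)`` (population convention).
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot estimate sigma of an empty vector")
    if not np.isfinite(arr).all():
        raise ValidationError("amplitude vector contains non-finite values")
    return float(arr.mean()), float(arr.std(ddof=ddof))


def compute_thresholds(
    amps: AmplitudeProfile, config: ADAConfig | None = None
) -> ThresholdSet:
    """Per-stage means and sigmas of both amplitude definitions."""
    config = config or ADAConfig()
    mean_signed, sigma_signed, sigma_abs = {}, {}, {}
    for t in DISEASE_STAGES:
        m, s = estimate_sigma(amps.signed[t], ddof=config.ddof)
        mean_signed[t] = m
        sigma_signed[t] = s
        _, s_abs = estimate_sigma(amps.absolute[t], ddof=config.ddof)
        sigma_abs[t] = s_abs
    return ThresholdSet(
        mean_signed=mean_signed,
        sigma_signed=sigma_signed,
        sigma_absolute=sigma_abs,
        multiplier=config.multiplier,
        relaxed_amplitude=config.relaxed_amplitude,
    )


def _require_all_stages(profile: pd.DataFrame) -> None:
    missing = [s for s in STAGES if s not in profile.columns]
    if missing:
        raise ValidationError(f"missing stage(s): {missing}")


def _monotone_direction(row: np.ndarray) -> str | None:
    """'up' if strictly increasing across the four stages, 'down' if strictly
    decreasing, else None. Ties fail both."""
    if np.all(np.diff(row) > 0):
        return "up"
    if np.all(np.diff(row) < 0):
        return "down"
    return None


def _make_call(
    gene_id: str,
    criterion: str,
    direction: str,
    profile: pd.DataFrame,
    signed: pd.DataFrame,
) -> CandidateCall:
    return CandidateCall(
        gene_id=gene_id,
        criterion=criterion,
        direction=direction,
        amplitudes={t: float(signed.at[gene_id, t]) for t in DISEASE_STAGES},
        deviations={s: float(profile.at[gene_id, s]) for s in STAGES},
    )


def strict_3sigma_candidates(
    profile: pd.DataFrame,
    amps: AmplitudeProfile,
    thr: ThresholdSet,
) -> list[CandidateCall]:
    """Strict rule: mean-centered signed amplitude beyond the cutoff in every
    disease stage, plus a strictly monotone deviation trend.

    A gene is called iff ``|A_t(i) - mean(A_t)| > multiplier * sigma_t`` for
    all three disease stages and its overall deviations are strictly
    increasing (direction 'up') or strictly decreasing ('down') across the
    four stages.
    """
    _require_all_stages(profile)
    exceed = np.ones(len(profile), dtype=bool)
    for t in DISEASE_STAGES:
        centered = np.abs(amps.signed[t].to_numpy() - thr.mean_signed[t])
        exceed &= centered > thr.cutoff_strict[t]
    dev = profile[list(STAGES)].to_numpy()
    calls: list[CandidateCall] = []
    for idx in np.nonzero(exceed)[0]:
        direction = _monotone_direction(dev[idx])
        if direction is None:
            continue
        calls.append(
            _make_call(
                profile.index[idx], STRICT, direction, profile, amps.signed
            )
        )
    calls.sort(key=CandidateCall.sort_key)
    return calls


def criterion_candidates(
    profile: pd.DataFrame,
    amps: AmplitudeProfile,
    thr: ThresholdSet,
) -> list[CandidateCall]:
    """Relaxed rule: amplitude above the relaxed cutoff in every disease
    stage, plus a strictly monotone trend.

    Criterion 1 (direction 'up'): amplitude exceeds ``multiplier *
    sigma*_t`` in all three stages and D is strictly increasing across the
    four stages. Criterion 2 ('down'): same amplitude condition with D
    strictly decreasing. The two directions are mutually exclusive, so the
    union contains each gene at most once.
    """
    _require_all_stages(profile)
    definition = thr.relaxed_amplitude
    exceed = np.ones(len(profile), dtype=bool)
    for t in DISEASE_STAGES:
        exceed &= amps.vector(definition, t) > thr.cutoff_relaxed[t]
    dev = profile[list(STAGES)].to_numpy()
    calls: list[CandidateCall] = []
    for idx in np.nonzero(exceed)[0]:
        direction = _monotone_direction(dev[idx])
        if direction is None:
            continue
        criterion = CRITERION_UP if direction == "up" else CRITERION_DOWN
        calls.append(
            _make_call(
                profile.index[idx], criterion, direction, profile, amps.signed
            )
        )
    calls.sort(key=CandidateCall.sort_key)
    return calls


def run_ada(
    matrix: StagedExpressionMatrix,
    method: str = "both",
    config: ADAConfig | None = None,
):
    """Run the full screen and return a results object with all
    intermediates (deviation profile, amplitudes, thresholds, calls).

    ``method`` selects the rule(s): 'strict', 'relaxed' or 'both'. Strict
    calls and criterion calls are kept distinct in the returned candidate
    list (the criterion field names the rule), never merged.
    """
    from .model import ADAModel

    return ADAModel(matrix, config=config).fit(method=method)
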