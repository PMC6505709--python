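"""Amplitude distribution diagnostics.

The 3-sigma cutoff is justified when the signed amplitudes are roughly
normal: ~99.7% of normal data fall within three standard deviations of the
mean. These summaries report the moments, a histogram, and the observed
fraction within 3 sigma so that judgement can be made per dataset. The
absolute amplitudes are folded magnitudes: their mean is positive and their
distribution right-skewed even when the signed amplitudes are symmetric,
which is what makes their sigma (and hence the relaxed cutoff) smaller.
Normality is reported descriptively; an optional D'Agostino omnibus test
adds a p-value for users who want a formal number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import AmplitudeProfile
from .matrix import DISEASE_STAGES, ValidationError

DEFAULT_BINS = 60


@dataclass(frozen=True)
class AmplitudeSummary:
    """Moments, histogram and 3-sigma coverage of one amplitude vector."""

    stage: str
    definition: str
    n: int
    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float
    bin_edges: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    fraction_within_3sigma: float = 0.0
    normality_pvalue: float | None = None

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "definition": self.definition,
            "n": self.n,
            "mean": self.mean,
            "variance": self.variance,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "bin_edges": list(self.bin_edges),
            "counts": list(self.counts),
            "fraction_within_3sigma": self.fraction_within_3sigma,
        }
        if self.normality_pvalue is not None:
            d["normality_pvalue"] = self.normality_pvalue
        return d


def summarize_vector(
    x,
    stage: str = "",
    definition: str = "signed",
    n_bins: int = DEFAULT_BINS,
    normality_test: bool = False,
) -> AmplitudeSummary:
    """Summarize an arbitrary amplitude vector.

    Moments use the population convention (divide by N). The histogram has
    ``n_bins`` equal-width bins spanning [min, max]. The 3-sigma fraction is
    the proportion of entries with ``|x - mean| <= 3 sigma``; for a constant
    vector (sigma = 0) every entry trivially qualifies.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty amplitude vector")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    mean = float(arr.mean())
    var = float(arr.var(ddof=0))
    sigma = float(np.sqrt(var))
    counts, edges = np.histogram(arr, bins=n_bins)
    frac = float(np.mean(np.abs(arr - mean) <= 3.0 * sigma))
    pval = None
    if normality_test and arr.size >= 20 and sigma > 0:
        pval = float(stats.normaltest(arr).pvalue)
    return AmplitudeSummary(
        stage=stage,
        definition=definition,
        n=int(arr.size),
        mean=mean,
        variance=var,
        skewness=float(stats.skew(arr, bias=True)) if sigma > 0 else 0.0,
        excess_kurtosis=(
            float(stats.kurtosis(arr, bias=True)) if sigma > 0 else 0.0
        ),
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
        fraction_within_3sigma=frac,
        normality_pvalue=pval,
    )


def summarize_amplitudes(
    amps: AmplitudeProfile,
    definition: str = "signed",
    stage: str = "incipient",
    n_bins: int = DEFAULT_BINS,
    normality_test: bool = False,
) -> AmplitudeSummary:
    """Summarize one stage x definition slice of an amplitude profile."""
    if stage not in DISEASE_STAGES:
        raise ValidationError(
            f"stage must be one of {list(DISEASE_STAGES)}, got {stage!r}"
        )
    vec = amps.vector(definition, stage)
    return summarize_vector(
        vec, stage=stage, definition=definition, n_bins=n_bins,
        normality_test=normality_test,
    )


def summarize_all(
    amps: AmplitudeProfile,
    n_bins: int = DEFAULT_BINS,
    normality_test: bool = False,
) -> dict:
    """Summaries for every disease stage under both definitions."""
    out: dict[str, dict] = {}
    for definition in ("signed", "absolute"):
        out[definition] = {
            stage: summarize_amplitudes(
                amps, definition=definition, stage=stage, n_bins=n_bins,
                normality_test=normality_test,
            ).to_dict()
            for stage in DISEASE_STAGES
        }
    return out


def plot_amplitude_histogram(
    amps: AmplitudeProfile,
    stage: str,
    definition: str = "signed",
    n_bins: int = DEFAULT_BINS,
    path=None,
):
    """Histogram of one amplitude vector with the 3-sigma band marked.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_amplitudes(
        amps, definition=definition, stage=stage, n_bins=n_bins
    )
    vec = amps.vector(definition, stage)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vec, bins=n_bins, color="steelblue", edgecolor="white")
    sigma = float(np.sqrt(summary.variance))
    for k, style in ((0, "-"), (-3, "--"), (3, "--")):
        ax.axvline(summary.mean + k * sigma, color="crimson", ls=style,
                   lw=1.0)
    ax.set_xlabel(f"{definition} amplitude, {stage}")
    ax.set_ylabel("genes")
    ax.set_title(
        f"{stage} ({definition}): mean={summary.mean:.3f}, "
        f"var={summary.variance:.3f}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
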