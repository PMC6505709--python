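"""Independent straight-loop reimplementation of the screening pipeline.

Deliberately written with plain Python scalars and loops (no numpy, no
pandas arithmetic) so it cannot share a code path with the vectorized
implementation it checks.
"""

import math

STAGES = ("control", "incipient", "moderate", "severe")
DISEASE = STAGES[1:]


def _mean(xs):
    return sum(xs) / len(xs)


def oracle_pipeline(values, gene_order, sample_order, stage_of,
                    multiplier=3.0):
    """Run the whole screen with scalar loops.

    Parameters
    ----------
    values : dict gene -> dict sample -> float
    gene_order, sample_order : lists fixing iteration order
    stage_of : dict sample -> stage

    Returns a dict with D, A, A_abs, thresholds and the two call lists
    (each a list of (gene, direction) tuples, sorted).
    """
    samples_by_stage = {
        st: [s for s in sample_order if stage_of[s] == st] for st in STAGES
    }

    col_mean = {}
    for s in sample_order:
        col_mean[s] = _mean([values[g][s] for g in gene_order])

    S = {
        g: {s: values[g][s] - col_mean[s] for s in sample_order}
        for g in gene_order
    }

    D = {
        g: {
            st: _mean([S[g][s] for s in samples_by_stage[st]])
            for st in STAGES
        }
        for g in gene_order
    }

    A = {
        g: {t: D[g][t] - D[g]["control"] for t in DISEASE}
        for g in gene_order
    }
    A_abs = {g: {t: abs(A[g][t]) for t in DISEASE} for g in gene_order}

    def moments(xs):
        m = _mean(xs)
        m2 = _mean([x * x for x in xs])
        return m, math.sqrt(max(m2 - m * m, 0.0))

    mean_signed, sigma_signed, sigma_abs = {}, {}, {}
    for t in DISEASE:
        mean_signed[t], sigma_signed[t] = moments(
            [A[g][t] for g in gene_order]
        )
        _, sigma_abs[t] = moments([A_abs[g][t] for g in gene_order])

    def trend(g):
        d = [D[g][st] for st in STAGES]
        if all(d[k] < d[k + 1] for k in range(3)):
            return "up"
        if all(d[k] > d[k + 1] for k in range(3)):
            return "down"
        return None

    strict_calls = []
    for g in gene_order:
        if all(
            abs(A[g][t] - mean_signed[t]) > multiplier * sigma_signed[t]
            for t in DISEASE
        ):
            direction = trend(g)
            if direction is not None:
                strict_calls.append((g, direction))

    criterion_calls = []
    for g in gene_order:
        if all(A_abs[g][t] > multiplier * sigma_abs[t] for t in DISEASE):
            direction = trend(g)
            if direction is not None:
                criterion_calls.append((g, direction))

    return {
        "D": D,
        "A": A,
        "A_abs": A_abs,
        "mean_signed": mean_signed,
        "sigma_signed": sigma_signed,
        "sigma_abs": sigma_abs,
        "strict": sorted(strict_calls),
        "criterion": sorted(criterion_calls),
    }
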