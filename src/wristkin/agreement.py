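"""Agreement analytics: target-referenced errors, Bland–Altman statistics, and
Pearson correlation.

Method-validation logic mirrors standard practice for comparing two
measurement systems: per-target errors are estimates minus the reference
(ground-truth) per-target mean; agreement is summarized by the mean error
(bias) and the 95% limits of agreement (bias ± 1.96 sample SD), pooled across
all errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, TargetLookupError, UndefinedMetricError

__all__ = [
    "AgreementResult",
    "target_referenced_errors",
    "bland_altman",
    "pearson",
    "plot_bland_altman",
]


@dataclass
class AgreementResult:
    """Bland–Altman summary.

    ``loa_low = bias - 1.96*sd`` and ``loa_high = bias + 1.96*sd`` hold
    exactly; ``sd`` is the sample (n-1 denominator) standard deviation.
    ``pair_means`` is populated when the input was paired values, for
    plotting differences against pair means.
    """

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    pair_means: np.ndarray | None = None
    diffs: np.ndarray | None = None


def target_referenced_errors(
    estimates: dict[str, np.ndarray], reference_means: dict[str, float]
) -> dict[str, np.ndarray]:
    """Errors of grouped estimates against per-target reference means.

    ``error = estimate - reference_means[target]``, preserving the grouping.
    """
    out: dict[str, np.ndarray] = {}
    for target, values in estimates.items():
        if target not in reference_means:
            raise TargetLookupError(f"no reference mean for target {target!r}")
        out[target] = np.asarray(values, dtype=float) - float(reference_means[target])
    return out


def bland_altman(
    errors: np.ndarray | None = None,
    *,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> AgreementResult:
    """Bland–Altman statistics from a vector of differences or from paired values.

    With ``pairs=(a, b)`` the differences are ``a - b`` and per-pair means are
    returned for plotting.  Requires n >= 2.
    """
    pair_means = None
    if pairs is not None:
        a = np.asarray(pairs[0], dtype=float)
        b = np.asarray(pairs[1], dtype=float)
        if a.shape != b.shape:
            raise InsufficientDataError("paired inputs must have equal length")
        diffs = a - b
        pair_means = 0.5 * (a + b)
    elif errors is not None:
        diffs = np.asarray(errors, dtype=float)
    else:
        raise InsufficientDataError("provide errors or pairs")
    n = diffs.size
    if n < 2:
        raise InsufficientDataError("Bland–Altman needs at least 2 differences")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(n),
        pair_means=pair_means,
        diffs=diffs,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson product-moment correlation with a two-sided p value.

    The p value comes from the t transform ``t = r sqrt((n-2)/(1-r^2))`` with
    n-2 degrees of freedom.  Requires n >= 3 and nonzero variance in both
    inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("pearson needs matched inputs of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def plot_bland_altman(result: AgreementResult, path: str, *, title: str = "", units: str = ""):
    """Render the standard Bland–Altman layout (difference vs. pair mean, bias
    line, dashed 95% limits of agreement) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = result.pair_means if result.pair_means is not None else np.arange(result.n, dtype=float)
    if result.diffs is not None:
        ax.plot(x, result.diffs, "o", ms=5, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias = {result.bias:.3g}")
    ax.axhline(result.loa_high, color="k", ls="--", lw=1.0)
    ax.axhline(result.loa_low, color="k", ls="--", lw=1.0, label="95% LoA")
    ax.set_xlabel(f"pair mean {units}".strip() if result.pair_means is not None else "index")
    ax.set_ylabel(f"difference {units}".strip())
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
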